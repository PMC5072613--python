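"""Core domain containers for focus-level IHC score data.

A *cohort* is a collection of tumors; each tumor is a small grid of
ordinal staining scores indexed by (focus, marker).  Scores follow the
three-level nuclear-staining convention used in tissue-microarray work:

    2  — strong expression (majority of tumor cells positive)
    1  — weak/partial expression (minority positive, still "retained")
    0  — loss of expression (at most a small residual fraction positive)

A missing cell is *non-evaluable* (e.g. the core fell off the slide or
staining failed); it is never treated as retained or lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

#: Default marker registry, in the fixed reporting order used throughout.
#: PBRM1, ARID1A, BRG1 (SMARCA4) and BRM (SMARCA2) are SWI/SNF subunits;
#: SETD2 is a histone methyltransferase.  All five are scored by nuclear IHC.
DEFAULT_MARKERS: tuple[str, ...] = ("PBRM1", "ARID1A", "SETD2", "BRG1", "BRM")

#: Pathologic stage labels, Roman on I/O, ordinal 1-4 internally.
STAGE_LABELS: tuple[str, ...] = ("I", "II", "III", "IV")
_ROMAN_TO_ORDINAL = {lab: i + 1 for i, lab in enumerate(STAGE_LABELS)}

VALID_SCORES = frozenset({0, 1, 2})

#: Canonical long-format column order.
LONG_COLUMNS = ("tumor_id", "stage", "focus_id", "marker", "score", "fraction_positive")


class CohortValidationError(ValueError):
    """Raised when an input table violates a hard invariant."""


def stage_to_ordinal(stage: object) -> int:
    """Map a stage label (Roman numeral, 'Stage III', or 1-4) to ordinal 1-4."""
    if isinstance(stage, (int,)) and not isinstance(stage, bool):
        if stage in (1, 2, 3, 4):
            return int(stage)
        raise CohortValidationError(f"stage out of range: {stage!r}")
    s = str(stage).strip().upper()
    if s.startswith("STAGE"):
        s = s[5:].strip()
    if s in _ROMAN_TO_ORDINAL:
        return _ROMAN_TO_ORDINAL[s]
    if s in {"1", "2", "3", "4"}:
        return int(s)
    raise CohortValidationError(f"unrecognized stage label: {stage!r}")


def stage_to_roman(stage: int) -> str:
    if stage not in (1, 2, 3, 4):
        raise CohortValidationError(f"stage out of range: {stage!r}")
    return STAGE_LABELS[stage - 1]


@dataclass(frozen=True)
class FocusRecord:
    """One measurement: the score of one marker in one focus of one tumor.

    Either ``fraction_positive`` (proportion of positively stained tumor
    cells) or ``score`` (already-called ordinal) must be present when the
    record is evaluable.
    """

    tumor_id: str
    stage: int
    focus_id: str
    marker: str
    fraction_positive: Optional[float] = None
    score: Optional[int] = None
    evaluable: bool = True

    def __post_init__(self) -> None:
        if self.evaluable and self.fraction_positive is None and self.score is None:
            raise CohortValidationError(
                f"evaluable record {self.key} has neither fraction nor score"
            )
        if self.score is not None and self.score not in VALID_SCORES:
            raise CohortValidationError(
                f"score {self.score!r} outside {{0,1,2}} at {self.key}"
            )
        if self.fraction_positive is not None and not (0.0 <= self.fraction_positive <= 1.0):
            raise CohortValidationError(
                f"fraction_positive {self.fraction_positive!r} outside [0,1] at {self.key}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.tumor_id, self.focus_id, self.marker)


@dataclass
class TumorGrid:
    """Score grid of a single tumor: (focus, marker) -> ordinal score or None.

    ``None`` cells are non-evaluable.  Foci keep their input order.
    """

    tumor_id: str
    stage: int
    foci: list[str]
    grid: dict[tuple[str, str], Optional[int]] = field(default_factory=dict)

    def score(self, focus: str, marker: str) -> Optional[int]:
        return self.grid.get((focus, marker))

    def marker_scores(self, marker: str) -> list[Optional[int]]:
        """Scores for one marker across foci, in focus order."""
        return [self.grid.get((f, marker)) for f in self.foci]

    def evaluable_foci(self, markers: Iterable[str]) -> list[str]:
        """Foci with at least one evaluable marker score."""
        ms = list(markers)
        return [f for f in self.foci if any(self.grid.get((f, m)) is not None for m in ms)]

    @property
    def n_foci(self) -> int:
        return len(self.foci)


@dataclass
class Cohort:
    """Validated collection of tumors with a shared marker registry."""

    tumors: list[TumorGrid]
    markers: tuple[str, ...] = DEFAULT_MARKERS
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.tumors:
            if t.tumor_id in seen:
                raise CohortValidationError(f"duplicate tumor_id {t.tumor_id!r}")
            seen.add(t.tumor_id)
            if not t.foci:
                raise CohortValidationError(f"tumor {t.tumor_id!r} has no foci")
            for (f, m) in t.grid:
                if f not in t.foci:
                    raise CohortValidationError(
                        f"grid key focus {f!r} not in focus list of tumor {t.tumor_id!r}"
                    )
                if m not in self.markers:
                    raise CohortValidationError(
                        f"grid key marker {m!r} not in registry of tumor {t.tumor_id!r}"
                    )

    def __len__(self) -> int:
        return len(self.tumors)

    def __iter__(self):
        return iter(self.tumors)

    def tumor(self, tumor_id: str) -> TumorGrid:
        for t in self.tumors:
            if t.tumor_id == tumor_id:
                return t
        raise KeyError(tumor_id)

    @property
    def stages(self) -> list[int]:
        return sorted({t.stage for t in self.tumors})

    def by_stage(self, stage: int) -> list[TumorGrid]:
        return [t for t in self.tumors if t.stage == stage]

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame, one row per (tumor, focus, marker) cell.

        Non-evaluable cells are emitted with an empty score so that a
        round-trip preserves the focus list exactly.
        """
        rows = []
        for t in self.tumors:
            for f in t.foci:
                for m in self.markers:
                    s = t.grid.get((f, m))
                    rows.append(
                        {
                            "tumor_id": t.tumor_id,
                            "stage": stage_to_roman(t.stage),
                            "focus_id": f,
                            "marker": m,
                            "score": s if s is not None else pd.NA,
                            "fraction_positive": pd.NA,
                        }
                    )
        df = pd.DataFrame(rows, columns=list(LONG_COLUMNS))
        df["score"] = df["score"].astype("Int64")
        return df


def cohort_from_records(
    records: Iterable[FocusRecord],
    markers: tuple[str, ...] = DEFAULT_MARKERS,
    provenance: str = "",
    thresholds: tuple[float, float] = (0.05, 0.50),
) -> Cohort:
    """Assemble a Cohort from FocusRecords, calling scores from fractions
    where only a fraction is given.

    Raises on duplicate (tumor, focus, marker) keys and on stage conflicts
    within a tumor.
    """
    from .loss_calling import call_score  # local import to avoid cycle

    tumors: dict[str, TumorGrid] = {}
    seen_keys: set[tuple[str, str, str]] = set()
    for r in records:
        if r.key in seen_keys:
            raise CohortValidationError(f"duplicate (tumor, focus, marker) key: {r.key}")
        seen_keys.add(r.key)
        t = tumors.get(r.tumor_id)
        if t is None:
            t = TumorGrid(tumor_id=r.tumor_id, stage=r.stage, foci=[])
            tumors[r.tumor_id] = t
        elif t.stage != r.stage:
            raise CohortValidationError(
                f"tumor {r.tumor_id!r} carries conflicting stages "
                f"{stage_to_roman(t.stage)} and {stage_to_roman(r.stage)}"
            )
        if r.focus_id not in t.foci:
            t.foci.append(r.focus_id)
        if not r.evaluable:
            t.grid[(r.focus_id, r.marker)] = None
            continue
        score = r.score
        if score is None:
            score = call_score(r.fraction_positive, thresholds=thresholds)
        t.grid[(r.focus_id, r.marker)] = score
    return Cohort(tumors=list(tumors.values()), markers=markers, provenance=provenance)
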