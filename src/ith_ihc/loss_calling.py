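"""Loss calling and prevalence summaries.

Converts staining fractions to ordinal scores, calls focus- and
tumor-level expression losses, and tabulates prevalences by marker,
level (tumor vs focus) and stage.

Calling conventions
-------------------
* A focus *loses* a marker iff its ordinal score is 0, i.e. at most
  ``t0`` (default 5%) of tumor cells stain positive.  Weak staining
  (score 1) is deliberately counted as retained.
* A tumor loses a marker iff **any** evaluable focus scores 0 — the
  single-biopsy convention: one loss-positive region makes the tumor
  loss-positive.
* Non-evaluable cells never enter numerators or denominators.
"""

from __future__ import annotations

import math
from typing import Optional

import pandas as pd

from .cohort import Cohort, TumorGrid, stage_to_roman

#: Focus-level call labels.
LOST = "lost"
RETAINED = "retained"
NON_EVALUABLE = "non-evaluable"

#: Default score thresholds (t0, t1): f <= t0 -> 0; t0 < f <= t1 -> 1; f > t1 -> 2.
DEFAULT_THRESHOLDS = (0.05, 0.50)


def call_score(
    fraction_positive: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> int:
    """Convert a fraction of positively stained tumor cells to a score.

    Parameters
    ----------
    fraction_positive
        Proportion of tumor cells with positive nuclear staining, in [0, 1].
    thresholds
        ``(t0, t1)``: scores are 0 for ``f <= t0``, 1 for ``t0 < f <= t1``,
        2 for ``f > t1``.  The loss boundary is inclusive: exactly-t0
        staining is a loss.

    Returns
    -------
    int
        Ordinal score in {0, 1, 2}.
    """
    t0, t1 = thresholds
    if not (0.0 <= t0 < t1 <= 1.0):
        raise ValueError(f"invalid thresholds {thresholds!r}")
    if fraction_positive is None or not (0.0 <= fraction_positive <= 1.0):
        raise ValueError(f"fraction_positive {fraction_positive!r} outside [0,1]")
    if fraction_positive <= t0:
        return 0
    if fraction_positive <= t1:
        return 1
    return 2


def focus_call(score: Optional[int]) -> str:
    """Map one ordinal score (or None) to lost / retained / non-evaluable."""
    if score is None:
        return NON_EVALUABLE
    return LOST if score == 0 else RETAINED


def tumor_marker_loss(scores: list[Optional[int]]) -> str:
    """Tumor-level call for one marker from its per-focus scores.

    Lost iff any evaluable focus scores 0; retained otherwise;
    non-evaluable when no focus is evaluable (including empty input).
    """
    evaluable = [s for s in scores if s is not None]
    if not evaluable:
        return NON_EVALUABLE
    return LOST if any(s == 0 for s in evaluable) else RETAINED


def loss_matrix(tumor: TumorGrid, markers: tuple[str, ...]) -> pd.DataFrame:
    """Per-tumor call matrix: rows = foci, columns = markers, values in
    {lost, retained, non-evaluable}."""
    data = {
        m: [focus_call(tumor.score(f, m)) for f in tumor.foci] for m in markers
    }
    return pd.DataFrame(data, index=list(tumor.foci))


def marker_support(tumor: TumorGrid, marker: str) -> frozenset[str]:
    """Foci of a tumor in which `marker` is lost (the marker's support set)."""
    return frozenset(f for f in tumor.foci if tumor.score(f, marker) == 0)


def prevalence_summary(
    cohort: Cohort, level: str = "tumor", stratify_by_stage: bool = False
) -> pd.DataFrame:
    """Loss prevalence per marker.

    At the tumor level the denominator counts tumors with >=1 evaluable
    focus for the marker; at the focus level it counts evaluable foci,
    pooled across tumors.  With ``stratify_by_stage`` each stage gets its
    own rows in addition to the pooled ``'all'`` stratum.

    Returns a DataFrame with columns
    ``marker, level, stage, numerator, denominator, proportion``;
    empty strata get denominator 0 and NaN proportion.
    """
    if level not in ("tumor", "focus"):
        raise ValueError(f"level must be 'tumor' or 'focus', got {level!r}")
    strata: list[Optional[int]] = [None]
    if stratify_by_stage:
        strata += cohort.stages
    rows = []
    for stage in strata:
        tumors = cohort.tumors if stage is None else cohort.by_stage(stage)
        for m in cohort.markers:
            if level == "tumor":
                calls = [tumor_marker_loss(t.marker_scores(m)) for t in tumors]
            else:
                calls = [
                    focus_call(t.score(f, m)) for t in tumors for f in t.foci
                ]
            num = sum(c == LOST for c in calls)
            den = sum(c != NON_EVALUABLE for c in calls)
            rows.append(
                {
                    "marker": m,
                    "level": level,
                    "stage": "all" if stage is None else stage_to_roman(stage),
                    "numerator": num,
                    "denominator": den,
                    "proportion": (num / den) if den else math.nan,
                }
            )
    return pd.DataFrame(rows)


def any_loss_fraction(cohort: Cohort, by_stage: bool = True) -> pd.DataFrame:
    """Fraction of tumors with >=1 marker lost (tumor-level rule), per stratum."""
    strata: list[Optional[int]] = [None]
    if by_stage:
        strata += cohort.stages
    rows = []
    for stage in strata:
        tumors = cohort.tumors if stage is None else cohort.by_stage(stage)
        n_any = sum(
            any(
                tumor_marker_loss(t.marker_scores(m)) == LOST
                for m in cohort.markers
            )
            for t in tumors
        )
        n = len(tumors)
        rows.append(
            {
                "stage": "all" if stage is None else stage_to_roman(stage),
                "numerator": n_any,
                "denominator": n,
                "proportion": (n_any / n) if n else math.nan,
            }
        )
    return pd.DataFrame(rows)


def format_percent(p: float) -> str:
    """Render a proportion the way prevalence figures print it: whole
    percents, one decimal below 10% (e.g. 0.061 -> '6.1%', 0.17 -> '17%')."""
    if p != p:  # NaN
        return "NA"
    pct = 100.0 * p
    if pct < 10.0 and pct != round(pct):
        return f"{pct:.1f}%"
    return f"{pct:.0f}%"
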