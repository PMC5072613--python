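"""All-pairs co-loss contingency analysis.

For each unordered marker pair a 2x2 table is tallied at the tumor level
(tumor-level loss calls) and at the focus level (foci pooled across
tumors), and tested for association with a two-sided Fisher exact test.
Focus-level pooling ignores within-tumor correlation of foci — a
deliberate replication of the standard tissue-microarray tally; treat
focus-level p values as descriptive.

The exact test is implemented from log-factorials.  Two-sided p uses the
point-probability method: the sum of hypergeometric probabilities of all
tables with the observed margins whose probability does not exceed the
observed table's (with a 1e-7 relative tolerance on the comparison),
which matches the common definition used by mainstream implementations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort, stage_to_roman
from .loss_calling import LOST, RETAINED, focus_call, tumor_marker_loss

_REL_TOL = 1e-7


@dataclass
class PairTable:
    """2x2 co-loss table for one marker pair at one level/stratum.

    Cell convention: n11 = both lost, n10 = only `marker_a` lost,
    n01 = only `marker_b` lost, n00 = neither lost.
    """

    marker_a: str
    marker_b: str
    level: str
    stage: str
    n11: int
    n10: int
    n01: int
    n00: int
    p_two_sided: Optional[float] = None
    odds_ratio: Optional[float] = None
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def cells(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n10, self.n01, self.n00)


def _unit_calls(cohort: Cohort, marker: str, level: str) -> list[str]:
    """Per-unit call sequence for one marker at tumor or focus level."""
    if level == "tumor":
        return [tumor_marker_loss(t.marker_scores(marker)) for t in cohort]
    if level == "focus":
        return [focus_call(t.score(f, marker)) for t in cohort for f in t.foci]
    raise ValueError(f"level must be 'tumor' or 'focus', got {level!r}")


def _unit_stages(cohort: Cohort, level: str) -> list[int]:
    if level == "tumor":
        return [t.stage for t in cohort]
    return [t.stage for t in cohort for _ in t.foci]


def contingency(
    cohort: Cohort,
    a: str,
    b: str,
    level: str = "tumor",
    stage: Optional[int] = None,
) -> PairTable:
    """Tally the 2x2 co-loss table of markers `a` and `b`.

    Units non-evaluable for either marker are excluded, so the table
    total is the number of units evaluable for both.
    """
    if a == b:
        raise ValueError(f"marker pair must be distinct, got {a!r} twice")
    calls_a = _unit_calls(cohort, a, level)
    calls_b = _unit_calls(cohort, b, level)
    stages = _unit_stages(cohort, level)
    n11 = n10 = n01 = n00 = 0
    for ca, cb, st in zip(calls_a, calls_b, stages):
        if stage is not None and st != stage:
            continue
        if ca not in (LOST, RETAINED) or cb not in (LOST, RETAINED):
            continue
        if ca == LOST and cb == LOST:
            n11 += 1
        elif ca == LOST:
            n10 += 1
        elif cb == LOST:
            n01 += 1
        else:
            n00 += 1
    return PairTable(
        marker_a=a,
        marker_b=b,
        level=level,
        stage="all" if stage is None else stage_to_roman(stage),
        n11=n11, n10=n10, n01=n01, n00=n00,
    )


def _log_hypergeom_pmf(k: int, row1: int, col1: int, n: int) -> float:
    """log P(X = k) for X ~ Hypergeom(n, row1, col1), via log-factorials."""
    lf = math.lgamma

    def lchoose(a: int, b: int) -> float:
        if b < 0 or b > a:
            return -math.inf
        return lf(a + 1) - lf(b + 1) - lf(a - b + 1)

    return lchoose(row1, k) + lchoose(n - row1, col1 - k) - lchoose(n, col1)


def fisher_two_sided(table: PairTable | tuple[int, int, int, int]) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability method).

    Degenerate tables (an all-zero row pair or column pair margin, i.e.
    one variable is constant) return p = 1 by convention with a warning.
    """
    if isinstance(table, PairTable):
        n11, n10, n01, n00 = table.cells()
    else:
        n11, n10, n01, n00 = table
    for c in (n11, n10, n01, n00):
        if c < 0 or int(c) != c:
            raise ValueError(f"cells must be non-negative integers, got {table!r}")
    row1 = n11 + n10
    row2 = n01 + n00
    col1 = n11 + n01
    col2 = n10 + n00
    n = row1 + row2
    if n == 0 or row1 == 0 or row2 == 0 or col1 == 0 or col2 == 0:
        warnings.warn("degenerate 2x2 margins; Fisher p set to 1 by convention")
        return 1.0
    log_p_obs = _log_hypergeom_pmf(n11, row1, col1, n)
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    total = 0.0
    for k in range(lo, hi + 1):
        lp = _log_hypergeom_pmf(k, row1, col1, n)
        if lp <= log_p_obs + math.log1p(_REL_TOL):
            total += math.exp(lp)
    return min(total, 1.0)


def odds_ratio(
    table: PairTable | tuple[int, int, int, int], haldane: bool = False
) -> float:
    """Cross-product odds ratio (n11*n00)/(n10*n01).

    With the Haldane correction, 0.5 is added to every cell first, so the
    result is always finite; without it a zero denominator gives inf
    (or NaN for 0/0).
    """
    if isinstance(table, PairTable):
        n11, n10, n01, n00 = table.cells()
    else:
        n11, n10, n01, n00 = table
    if haldane:
        n11, n10, n01, n00 = (c + 0.5 for c in (n11, n10, n01, n00))
    num = n11 * n00
    den = n10 * n01
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def conditional_coloss(
    cohort: Cohort,
    given: str,
    then: str,
    level: str = "tumor",
    by_stage: bool = False,
) -> pd.DataFrame:
    """P(`then` lost | `given` lost) per stratum.

    Returns columns stage, n_given_lost, n_coloss, fraction; strata with
    no `given` losses get NaN fraction and are flagged undefined.
    """
    strata: list[Optional[int]] = [None]
    if by_stage:
        strata += cohort.stages
    rows = []
    for stage in strata:
        tab = contingency(cohort, given, then, level=level, stage=stage)
        denom = tab.n11 + tab.n10
        rows.append(
            {
                "stage": "all" if stage is None else stage_to_roman(stage),
                "level": level,
                "given": given,
                "then": then,
                "n_given_lost": denom,
                "n_coloss": tab.n11,
                "fraction": (tab.n11 / denom) if denom else math.nan,
                "undefined": denom == 0,
            }
        )
    return pd.DataFrame(rows)


def all_pairs(cohort: Cohort, levels: tuple[str, ...] = ("tumor", "focus")) -> pd.DataFrame:
    """Fisher tests for every unordered marker pair at each level.

    One row per pair x level with raw two-sided p, Benjamini-Hochberg q
    over all rows, odds ratio (Haldane-corrected companion column) and
    the conditional co-loss fractions in both directions.  Raw p values
    are the replication quantity; q values are supplementary.
    """
    if len(cohort.markers) < 2:
        raise ValueError("need at least two markers for pairwise analysis")
    rows = []
    for level in levels:
        for a, b in combinations(cohort.markers, 2):
            tab = contingency(cohort, a, b, level=level)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = fisher_two_sided(tab)
            denom_a = tab.n11 + tab.n10
            denom_b = tab.n11 + tab.n01
            rows.append(
                {
                    "marker_a": a,
                    "marker_b": b,
                    "level": level,
                    "n11": tab.n11, "n10": tab.n10,
                    "n01": tab.n01, "n00": tab.n00,
                    "n": tab.n,
                    "p_two_sided": p,
                    "odds_ratio": odds_ratio(tab),
                    "odds_ratio_haldane": odds_ratio(tab, haldane=True),
                    "coloss_b_given_a": (tab.n11 / denom_a) if denom_a else math.nan,
                    "coloss_a_given_b": (tab.n11 / denom_b) if denom_b else math.nan,
                }
            )
    df = pd.DataFrame(rows)
    df["q_bh"] = multipletests(df["p_two_sided"], method="fdr_bh")[1]
    return df
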