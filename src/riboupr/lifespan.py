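"""Replicative-lifespan survival statistics and the longevity screen.

Yeast replicative lifespan (RLS) is the number of daughter cells a mother
produces before senescence; every mother is followed to the end, so there is
no censoring and the survival curve is a plain empirical tail function.
Mutant cohorts are compared to experiment-matched wild-type controls with a
two-sided Wilcoxon rank-sum test; a strain is called long-lived when its mean
RLS exceeds the control's and the test rejects at the chosen alpha (raw
p-values — the screen uses fold thresholds and uncorrected tests throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_CUTOFF = 12  # enumerate the exact rank-sum null for min(n) <= this, tie-free


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (display convention for means
    and percent changes)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LifespanCohort:
    """Per-mother-cell division counts for one strain."""

    strain: str
    divisions: tuple[int, ...]
    control: str | None = None
    mating_type: str | None = None

    def __post_init__(self) -> None:
        self.divisions = tuple(int(d) for d in self.divisions)
        if not self.divisions:
            raise ValueError("cohort must contain at least one cell")
        if any(d < 0 for d in self.divisions):
            raise ValueError("division counts must be non-negative")

    def __len__(self) -> int:
        return len(self.divisions)


def pool_cohorts(cohorts: Sequence[LifespanCohort], strain: str | None = None) -> LifespanCohort:
    """Pool cohorts of one strain (e.g. MATa + MATalpha) into one."""
    if not cohorts:
        raise ValueError("no cohorts to pool")
    strains = {c.strain for c in cohorts}
    if strain is None:
        if len(strains) != 1:
            raise ValueError(f"pooling cohorts of different strains: {sorted(strains)}")
        strain = cohorts[0].strain
    divisions = tuple(d for c in cohorts for d in c.divisions)
    return LifespanCohort(strain=strain, divisions=divisions, control=cohorts[0].control)


def survival_curve(cohort: LifespanCohort) -> pd.DataFrame:
    """Empirical tail survival: fraction of mothers with >= d divisions.

    Rows cover d = 0, every observed division count, and max+1 (where the
    curve reaches 0). Monotone non-increasing, starts at 1.
    """
    div = np.asarray(cohort.divisions)
    points = sorted({0, *cohort.divisions, int(div.max()) + 1})
    frac = [float((div >= d).mean()) for d in points]
    return pd.DataFrame({"divisions": points, "surviving": frac})


def mean_rls(cohort: LifespanCohort) -> float:
    """Arithmetic mean division count (unrounded; display to one decimal)."""
    return float(np.mean(cohort.divisions))


def percent_change(mutant_mean: float, control_mean: float) -> float:
    """Percent mean-RLS change vs control, one decimal, ties away from zero."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return round_half_away(100.0 * (mutant_mean - control_mean) / control_mean, 1)


@dataclass
class RankSumResult:
    statistic: float  # rank sum W of the first sample (midranks)
    u: float  # Mann-Whitney U of the first sample
    z: float  # standardized statistic (tie- and continuity-corrected)
    p_value: float
    method: str  # "exact" or "asymptotic"

    def __iter__(self):
        yield self.statistic
        yield self.p_value


def ranksum_test(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration when min(n1, n2) <= 12 with no ties; otherwise the
    normal approximation with midranks, tie correction and a 0.5 continuity
    correction. The returned statistic is the rank sum of ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 > 0:
        z = (u - mu - 0.5 * math.copysign(1.0, u - mu)) / math.sqrt(sigma2) if u != mu else 0.0
    else:
        z = 0.0

    method = "exact" if (min(n1, n2) <= EXACT_CUTOFF and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return RankSumResult(statistic=w, u=float(u), z=float(z),
                         p_value=float(min(res.pvalue, 1.0)), method=method)


@dataclass
class ScreenResult:
    strain: str
    mutant_mean: float
    control_mean: float
    pct_change: float
    statistic: float
    p_value: float
    longevity_class: str  # long-lived | short-lived | unchanged


def classify_call(pct_change: float, p_value: float, alpha: float = 0.05) -> str:
    """Long-lived iff the mean increased and the test rejects; short-lived
    iff it decreased and the test rejects; unchanged otherwise."""
    if p_value < alpha and pct_change > 0:
        return "long-lived"
    if p_value < alpha and pct_change < 0:
        return "short-lived"
    return "unchanged"


def classify_longevity(
    pairs: Iterable[tuple[LifespanCohort, LifespanCohort]],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the screen over (mutant, control) cohort pairs.

    Returns the per-strain table and summary counts by longevity class.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    for mutant, control in pairs:
        if control is None:
            raise ValueError(f"strain {mutant.strain} has no matched control cohort")
        mm, cm = mean_rls(mutant), mean_rls(control)
        pct = percent_change(mm, cm)
        test = ranksum_test(mutant.divisions, control.divisions)
        rows.append(
            ScreenResult(
                strain=mutant.strain,
                mutant_mean=round_half_away(mm, 1),
                control_mean=round_half_away(cm, 1),
                pct_change=pct,
                statistic=test.statistic,
                p_value=test.p_value,
                longevity_class=classify_call(pct, test.p_value, alpha),
            )
        )
    frame = pd.DataFrame([r.__dict__ for r in rows])
    counts = {
        cls: int((frame["longevity_class"] == cls).sum())
        for cls in ("long-lived", "short-lived", "unchanged")
    }
    return frame, counts


def classify_from_summary(
    summary: pd.DataFrame,
    alpha: float = 0.05,
    pct_col: str = "pct_change",
    p_col: str = "p_value",
) -> pd.DataFrame:
    """Apply the longevity rule to an already-summarised screen table
    (printed means / percent changes / p-values)."""
    out = summary.copy()
    out["longevity_class"] = [
        classify_call(pc, pv, alpha) for pc, pv in zip(out[pct_col], out[p_col])
    ]
    return out
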