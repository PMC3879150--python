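"""Translation-efficiency analysis of paired footprint/mRNA rpkm tables.

The analysis follows the fold-change protocol of the source assay: rpkm
values are averaged over biological replicates per condition, genes with a
replicate-mean rpkm below 10 in either side of a comparison are excluded,
translation efficiency (TE) is the ratio of footprint to mRNA replicate-mean
rpkm, and a gene counts as regulated on an axis (footprint, mRNA or TE) when
its log2 fold change versus the reference condition exceeds 0.6 in absolute
value (strictly; 2^0.6 ~ 1.52, the operational reading of "1.5-fold").
No per-gene statistical test is involved — the screen is threshold-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

AXES = ("footprint", "mrna", "te")
DEFAULT_MIN_RPKM = 10.0
DEFAULT_LOG2_THRESHOLD = 0.6


def condition_groups(condition_map: Mapping[str, str]) -> dict[str, list[str]]:
    """Invert a sample -> condition map into condition -> [samples]."""
    groups: dict[str, list[str]] = {}
    for sample, cond in condition_map.items():
        groups.setdefault(cond, []).append(sample)
    return groups


def average_replicates(rpkm: pd.DataFrame, groups: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Arithmetic mean rpkm per condition; single replicates pass through."""
    out = {}
    for cond, samples in groups.items():
        if not samples:
            raise ValueError(f"condition {cond!r} has no replicates")
        missing = [s for s in samples if s not in rpkm.columns]
        if missing:
            raise ValueError(f"unknown samples in replicate group {cond!r}: {missing}")
        out[cond] = rpkm[list(samples)].mean(axis=1)
    return pd.DataFrame(out)


def compute_te(fp_mean: pd.DataFrame, mrna_mean: pd.DataFrame) -> pd.DataFrame:
    """TE = footprint mean rpkm / mRNA mean rpkm; NaN where mRNA mean is 0.

    Zero-mRNA genes never pass the expression filter, so the NaN can only
    surface for genes already excluded from fold-change analysis.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        te = fp_mean / mrna_mean
    return te.where(mrna_mean > 0)


@dataclass
class ExpressionTable:
    """Replicate means, TE, filter flags and log2 fold changes vs reference.

    ``pass_filter[axis]`` is a genes x non-reference-conditions boolean frame:
    True when the gene's replicate-mean rpkm is >= ``min_rpkm`` in *both* the
    condition and the reference on that axis (the TE axis requires both the
    footprint and mRNA axes to pass). ``log2fc[axis]`` is NaN wherever the
    filter fails.
    """

    fp_rpkm: pd.DataFrame
    mrna_rpkm: pd.DataFrame
    condition_map: dict[str, str]
    reference: str
    min_rpkm: float = DEFAULT_MIN_RPKM
    fp_mean: pd.DataFrame = field(init=False)
    mrna_mean: pd.DataFrame = field(init=False)
    te: pd.DataFrame = field(init=False)
    pass_filter: dict[str, pd.DataFrame] = field(init=False)
    log2fc: dict[str, pd.DataFrame] = field(init=False)

    def __post_init__(self) -> None:
        if self.min_rpkm < 0:
            raise ValueError("rpkm threshold must be non-negative")
        if not self.fp_rpkm.index.equals(self.mrna_rpkm.index):
            raise ValueError("footprint and mRNA tables must share the gene index")
        groups = condition_groups(self.condition_map)
        if self.reference not in groups:
            raise ValueError(f"reference condition {self.reference!r} has no samples")
        self.fp_mean = average_replicates(self.fp_rpkm, groups)
        self.mrna_mean = average_replicates(self.mrna_rpkm, groups)
        self.te = compute_te(self.fp_mean, self.mrna_mean)
        self._recompute()

    @property
    def conditions(self) -> list[str]:
        return list(self.fp_mean.columns)

    @property
    def contrast_conditions(self) -> list[str]:
        return [c for c in self.conditions if c != self.reference]

    def _recompute(self) -> None:
        ref = self.reference
        contrasts = self.contrast_conditions
        means = {"footprint": self.fp_mean, "mrna": self.mrna_mean}
        self.pass_filter = {}
        for axis, mean in means.items():
            flags = {}
            for cond in contrasts:
                flags[cond] = (mean[cond] >= self.min_rpkm) & (mean[ref] >= self.min_rpkm)
            self.pass_filter[axis] = pd.DataFrame(flags)
        # TE is a ratio of the two; its filter requires both axes to pass
        self.pass_filter["te"] = self.pass_filter["footprint"] & self.pass_filter["mrna"]

        self.log2fc = {}
        for axis, mean in means.items():
            fc = {}
            for cond in contrasts:
                with np.errstate(divide="ignore", invalid="ignore"):
                    fc[cond] = np.log2(mean[cond] / mean[ref])
            self.log2fc[axis] = pd.DataFrame(fc).where(self.pass_filter[axis])
        te_fc = {}
        for cond in contrasts:
            with np.errstate(divide="ignore", invalid="ignore"):
                te_fc[cond] = np.log2(self.te[cond] / self.te[self.reference])
        self.log2fc["te"] = pd.DataFrame(te_fc).where(self.pass_filter["te"])


def build_expression_table(
    fp_rpkm: pd.DataFrame,
    mrna_rpkm: pd.DataFrame,
    condition_map: Mapping[str, str],
    reference: str,
    min_rpkm: float = DEFAULT_MIN_RPKM,
) -> ExpressionTable:
    return ExpressionTable(
        fp_rpkm=fp_rpkm,
        mrna_rpkm=mrna_rpkm,
        condition_map=dict(condition_map),
        reference=reference,
        min_rpkm=min_rpkm,
    )


def filter_low_expression(expr: ExpressionTable, threshold: float = DEFAULT_MIN_RPKM) -> ExpressionTable:
    """Return a copy of the table with the rpkm floor set to ``threshold``.

    Raising the threshold can only remove genes from the analysable set
    (the filter flag is monotone in the threshold).
    """
    if threshold < 0:
        raise ValueError("rpkm threshold must be non-negative")
    return ExpressionTable(
        fp_rpkm=expr.fp_rpkm,
        mrna_rpkm=expr.mrna_rpkm,
        condition_map=dict(expr.condition_map),
        reference=expr.reference,
        min_rpkm=threshold,
    )


def classify_regulation(
    expr: ExpressionTable,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene regulation calls on every axis and contrast condition.

    Tidy frame with columns gene_id, condition, axis, log2fc, direction;
    only filter-passing genes appear, each exactly once per (axis, condition).
    Direction is "up" iff log2fc > threshold, "down" iff < -threshold
    (strict inequalities), else "unchanged".
    """
    if log2_threshold < 0:
        raise ValueError("log2 threshold must be non-negative")
    rows = []
    for axis in AXES:
        fc = expr.log2fc[axis]
        mask = expr.pass_filter[axis]
        for cond in expr.contrast_conditions:
            passing = mask.index[mask[cond]]
            vals = fc.loc[passing, cond]
            direction = np.where(
                vals > log2_threshold, "up", np.where(vals < -log2_threshold, "down", "unchanged")
            )
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": passing,
                        "condition": cond,
                        "axis": axis,
                        "log2fc": vals.to_numpy(),
                        "direction": direction,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def regulated_set(
    calls: pd.DataFrame, axis: str, condition: str, direction: str | None = None
) -> set[str]:
    """Gene ids called regulated on an axis in a condition ("up", "down",
    or both when direction is None)."""
    sel = (calls["axis"] == axis) & (calls["condition"] == condition)
    if direction is None:
        sel &= calls["direction"] != "unchanged"
    else:
        sel &= calls["direction"] == direction
    return set(calls.loc[sel, "gene_id"])


def overlap_sets(a: set[str], b: set[str]) -> tuple[int, int, int]:
    """(|A|, |B|, |A intersect B|) for two gene-id sets."""
    a, b = set(a), set(b)
    return len(a), len(b), len(a & b)


def replicate_correlation(
    rpkm: pd.DataFrame, pair: tuple[str, str], log: bool = True
) -> float:
    """Pearson r between two replicates over genes expressed in both.

    Computed on log2 rpkm (the assay's display scale) restricted to genes
    with positive rpkm in both replicates; NaN (with a warning) if either
    vector is constant.
    """
    s1, s2 = pair
    x, y = rpkm[s1].to_numpy(float), rpkm[s2].to_numpy(float)
    mask = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    x, y = x[mask], y[mask]
    if x.size < 2:
        raise ValueError("need at least 2 genes expressed in both replicates")
    if log:
        x, y = np.log2(x), np.log2(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant replicate vector: correlation undefined")
        return float("nan")
    r, _ = stats.pearsonr(x, y)
    return float(r)


@dataclass
class TEClusterResult:
    """Average-linkage hierarchy over genes under 1 - Pearson distance."""

    gene_ids: list[str]  # row order fed to the clustering (lexicographic)
    linkage: np.ndarray  # scipy linkage matrix (merge tree)
    leaf_order: list[str]  # gene ids in dendrogram leaf order


def cluster_te_changes(
    log2_te_fc: pd.DataFrame,
    min_abs_log2: float | None = None,
) -> TEClusterResult:
    """Cluster genes by their log2 TE-change profiles across conditions.

    Distance is 1 - Pearson correlation between row profiles; linkage is
    average (UPGMA). Rows are sorted lexicographically by gene id first, which
    fixes tie-breaking and makes the merge tree invariant to input row order.
    When ``min_abs_log2`` is given, rows are first restricted to genes whose
    TE changed beyond that threshold in at least one condition.
    """
    mat = log2_te_fc.dropna(how="any")
    if min_abs_log2 is not None:
        mat = mat[(mat.abs() > min_abs_log2).any(axis=1)]
    mat = mat.sort_index()
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    X = mat.to_numpy(float)
    dist = pdist(X, metric="correlation")
    if np.isnan(dist).any():
        warnings.warn("constant TE profiles: undefined correlations treated as distance 1")
        dist = np.nan_to_num(dist, nan=1.0)
    Z = hierarchy.linkage(dist, method="average")
    order = [mat.index[i] for i in hierarchy.leaves_list(Z)]
    return TEClusterResult(gene_ids=list(mat.index), linkage=Z, leaf_order=order)
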