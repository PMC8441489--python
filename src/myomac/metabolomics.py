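"""Targeted metabolomics normalization and univariate analysis.

The processing chain is fixed: per-sample median normalization, then the
generalized log transform

    glog2(x) = log2( (x + sqrt(x^2 + lambda^2)) / 2 ),

variance-stabilizing near zero and ~log2(x) for x >> lambda, then Pareto
scaling per metabolite ((x - mean) / sqrt(sd)). Fold changes for the
volcano analysis are computed on the median-normalized (pre-transform)
scale; Welch t-tests run on the glog2-transformed values. A metabolite is
significant when |FC| passes the 1.5-fold cutoff (inclusive) and p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .containers import MetaboliteTable
from .markers import bh_adjust

DEFAULT_FC_CUT = 1.5
DEFAULT_P_CUT = 0.05


def default_lambda(table: MetaboliteTable) -> float:
    """Data-driven glog2 lambda: min positive value / 10."""
    vals = table.values.to_numpy()
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("no positive values to derive lambda from")
    return float(pos.min() / 10.0)


def median_normalize(table: MetaboliteTable) -> MetaboliteTable:
    """Divide each sample by its median; post-normalization medians are 1.

    Rejects re-normalization (provenance guard) and zero medians.
    """
    if "median" in table.provenance:
        raise ValueError("table is already median-normalized (provenance guard)")
    med = table.values.median(axis=0)
    if (med <= 0).any():
        bad = med.index[med <= 0][0]
        raise ValueError(f"sample {bad!r} has non-positive median")
    return MetaboliteTable(table.values / med, table.groups,
                           provenance=table.provenance + ("median",))


def glog2(values, lam: float):
    """Generalized log: log2((x + sqrt(x^2 + lambda^2)) / 2); needs lambda > 0."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    x = np.asarray(values, dtype=float)
    return np.log2((x + np.sqrt(x ** 2 + lam ** 2)) / 2.0)


def glog2_table(table: MetaboliteTable, lam: float | None = None) -> MetaboliteTable:
    """Apply glog2 to a (median-normalized) table; provenance-guarded."""
    if "glog2" in table.provenance:
        raise ValueError("table is already glog2-transformed (provenance guard)")
    if lam is None:
        lam = default_lambda(table)
    out = pd.DataFrame(glog2(table.values.to_numpy(), lam),
                       index=table.values.index, columns=table.values.columns)
    res = MetaboliteTable(out, table.groups, provenance=table.provenance + ("glog2",))
    res.glog_lambda = lam  # carried for provenance reporting
    return res


@dataclass
class ProcessedMetabolites:
    """Fully processed table plus the parameters that produced it."""

    values: pd.DataFrame          # metabolites x samples, Pareto-scaled
    groups: pd.Series
    glog_lambda: float | None
    row_means: pd.Series
    row_sqrt_sds: pd.Series
    provenance: tuple[str, ...]


def pareto_scale(table) -> ProcessedMetabolites:
    """Per-metabolite (x - mean) / sqrt(sd); zero-variance rows map to zeros.

    Accepts a MetaboliteTable (appends to its provenance) or a bare
    DataFrame/array (provenance starts at ``pareto``).
    """
    if isinstance(table, MetaboliteTable):
        if "pareto" in table.provenance:
            raise ValueError("table is already Pareto-scaled (provenance guard)")
        df = table.values
        groups = table.groups
        provenance = table.provenance + ("pareto",)
        lam = getattr(table, "glog_lambda", None)
    else:
        df = pd.DataFrame(table)
        groups = None
        provenance = ("pareto",)
        lam = None
    if df.shape[1] < 2:
        raise ValueError("Pareto scaling needs >= 2 samples")
    means = df.mean(axis=1)
    sds = df.std(axis=1, ddof=1)
    scaled = (df.sub(means, axis=0)).div(np.sqrt(sds.where(sds > 0, 1.0)), axis=0)
    scaled = scaled.where(sds > 0, 0.0)
    return ProcessedMetabolites(scaled, groups, lam, means, np.sqrt(sds), provenance)


def process_metabolites(table: MetaboliteTable, lam: float | None = None) -> ProcessedMetabolites:
    """The fixed chain: median normalize -> glog2 -> Pareto scale."""
    if table.provenance:
        raise ValueError("process_metabolites expects a raw table (provenance guard)")
    norm = median_normalize(table)
    trans = glog2_table(norm, lam)
    out = pareto_scale(trans)
    assert out.provenance == ("median", "glog2", "pareto")
    return out


def hierarchical_cluster(processed, metric: str = "euclidean",
                         method: str = "ward") -> tuple[np.ndarray, list[int]]:
    """Agglomerative merge tree over metabolites (rows) with leaf order.

    Returns (scipy linkage matrix, left-first leaf order). Ties are
    resolved deterministically by item index (scipy's convention).
    """
    values = processed.values if hasattr(processed, "values") else processed
    arr = np.asarray(pd.DataFrame(values), dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    Z = hierarchy.linkage(arr, method=method, metric=metric)
    return Z, list(hierarchy.leaves_list(Z))


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage as a Newick string (branch lengths = heights)."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def welch_ttest(x, y) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test; returns (t, p)."""
    t, p = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(t), float(p)


def volcano(
    table: MetaboliteTable,
    numerator: str = "old",
    denominator: str = "young",
    fc_cut: float = DEFAULT_FC_CUT,
    p_cut: float = DEFAULT_P_CUT,
    lam: float | None = None,
) -> pd.DataFrame:
    """Volcano analysis between two groups (>= 3 samples each).

    Fold change = numerator/denominator group-mean ratio on the
    median-normalized scale; p = Welch t-test on glog2-transformed values.
    ``significant`` is True when (FC >= fc_cut or FC <= 1/fc_cut, boundary
    inclusive) and p < p_cut. Nominal p drives the flag; BH-adjusted p is
    reported alongside.
    """
    for g in (numerator, denominator):
        if g not in set(table.groups):
            raise ValueError(f"group {g!r} not present in table")
    norm = median_normalize(table) if "median" not in table.provenance else table
    trans = glog2_table(norm, lam) if "glog2" not in norm.provenance else norm
    num_cols = norm.group_samples(numerator)
    den_cols = norm.group_samples(denominator)
    if len(num_cols) < 3 or len(den_cols) < 3:
        raise ValueError("volcano needs >= 3 samples per group")
    mean_num = norm.values[num_cols].mean(axis=1)
    mean_den = norm.values[den_cols].mean(axis=1)
    fc = mean_num / mean_den
    tvals, pvals = stats.ttest_ind(trans.values[num_cols], trans.values[den_cols],
                                   axis=1, equal_var=False)
    pvals = np.clip(np.asarray(pvals, float), np.finfo(float).tiny, 1.0)
    padj = bh_adjust(pvals)
    fc_arr = fc.to_numpy()
    sig = ((fc_arr >= fc_cut) | (fc_arr <= 1.0 / fc_cut)) & (pvals < p_cut)
    return pd.DataFrame({
        "metabolite": table.metabolites,
        "fold_change": fc_arr,
        "log2_fc": np.log2(fc_arr),
        "t": tvals,
        "pvalue": pvals,
        "padj": padj,
        "significant": sig,
    })
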