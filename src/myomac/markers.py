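"""Differential expression by Wilcoxon rank-sum.

One-vs-rest marker detection per cluster with natural-log ratios of
de-logged mean expression, Benjamini-Hochberg adjustment within each
cluster's tested gene set, and expression-fraction prefilters. The
resulting cluster signatures feed reference-based identity scoring.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

EXACT_MAX_POOLED_N = 10  # exact enumeration up to this pooled sample size


def wilcoxon_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U statistic for ``x``, two-sided p). Exact p by enumeration of
    all rank assignments when the pooled size is <= 10 (handles ties);
    otherwise the normal approximation with tie and continuity correction.
    p is clipped to (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    if n <= EXACT_MAX_POOLED_N:
        us = np.array([
            ranks[list(combo)].sum() - nx * (nx + 1) / 2.0
            for combo in itertools.combinations(range(n), nx)
        ])
        eps = 1e-9
        p_le = np.mean(us <= u_obs + eps)
        p_ge = np.mean(us >= u_obs - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic", use_continuity=True)
        p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return float(u_obs), float(p)


def log_ratio(expr: ExpressionMatrix, cells_in, cells_out, pseudo: float = 1.0) -> np.ndarray:
    """Per-gene d = ln(mean de-logged expr + pseudo)_in - (same)_out.

    De-logged means expm1 of the log-normalized values, i.e. back on the
    scaled-count scale.
    """
    cells_in = np.asarray(cells_in)
    cells_out = np.asarray(cells_out)
    if cells_in.dtype == bool:
        cells_in = np.flatnonzero(cells_in)
    if cells_out.dtype == bool:
        cells_out = np.flatnonzero(cells_out)
    if cells_in.size == 0 or cells_out.size == 0:
        raise ValueError("both cell sets must be non-empty")
    mean_in = np.expm1(expr.values[:, cells_in]).mean(axis=1)
    mean_out = np.expm1(expr.values[:, cells_out]).mean(axis=1)
    return np.log(mean_in + pseudo) - np.log(mean_out + pseudo)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _tie_terms(values: np.ndarray) -> np.ndarray:
    """Per-row sum of t^3 - t over tied groups (for rank-sum variance)."""
    sv = np.sort(values, axis=1)
    out = np.zeros(values.shape[0])
    for g in range(values.shape[0]):
        _, counts = np.unique(sv[g], return_counts=True)
        t = counts[counts > 1].astype(float)
        out[g] = (t ** 3 - t).sum()
    return out


def _ranksum_p_vectorized(values: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Two-sided normal-approximation rank-sum p for each row of ``values``.

    Same tie and continuity correction as the scalar test's asymptotic path.
    Rows where every value ties give p = 1.
    """
    n1 = int(in_mask.sum())
    n = values.shape[1]
    n2 = n - n1
    ranks = stats.rankdata(values, axis=1)
    r1 = ranks[:, in_mask].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    ties = _tie_terms(values)
    var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    diff = u - mu
    z = np.where(sd > 0, (diff - 0.5 * np.sign(diff)) / np.maximum(sd, 1e-300), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[sd == 0] = 1.0
    return p


@dataclass
class ClusterSignature:
    """Per-cluster DE table: gene, log_ratio, pvalue, padj, pct_in, pct_out."""

    cluster: int | str
    table: pd.DataFrame


@dataclass
class MarkerResult:
    signatures: list[ClusterSignature]
    excluded_clusters: list = field(default_factory=list)  # < 3 cells

    def get(self, cluster) -> ClusterSignature:
        for sig in self.signatures:
            if sig.cluster == cluster:
                return sig
        raise KeyError(f"no signature for cluster {cluster!r}")


def find_markers(
    expr: ExpressionMatrix,
    clusters: np.ndarray,
    min_pct: float = 0.1,
    min_abs_logratio: float = 0.25,
    pseudo: float = 1.0,
) -> MarkerResult:
    """One-vs-rest Wilcoxon markers for every cluster with >= 3 cells.

    A gene is tested only if expressed in >= ``min_pct`` of cells on either
    side and |log-ratio| >= ``min_abs_logratio``. BH adjustment is applied
    within each cluster's tested set; tables are sorted by p, then |d|
    descending, then gene ID. Clusters with fewer than 3 cells are skipped
    and recorded in ``excluded_clusters``.
    """
    clusters = np.asarray(clusters)
    if clusters.size != expr.n_cells:
        raise ValueError("cluster labels do not match cell count")
    uniq, sizes = np.unique(clusters, return_counts=True)
    eligible = [c for c, s in zip(uniq, sizes) if s >= 3]
    excluded = [c for c, s in zip(uniq, sizes) if s < 3]
    if len(eligible) < 2:
        raise ValueError("need at least 2 clusters with >= 3 cells")
    delog = np.expm1(expr.values)
    expressed = expr.values > 0
    genes = np.asarray(expr.gene_ids)
    signatures = []
    for c in eligible:
        in_mask = clusters == c
        n_in = int(in_mask.sum())
        n_out = expr.n_cells - n_in
        pct_in = expressed[:, in_mask].sum(axis=1) / n_in
        pct_out = expressed[:, ~in_mask].sum(axis=1) / n_out
        mean_in = delog[:, in_mask].mean(axis=1)
        mean_out = delog[:, ~in_mask].mean(axis=1)
        d = np.log(mean_in + pseudo) - np.log(mean_out + pseudo)
        tested = ((pct_in >= min_pct) | (pct_out >= min_pct)) & (np.abs(d) >= min_abs_logratio)
        idx = np.flatnonzero(tested)
        if idx.size:
            p = _ranksum_p_vectorized(expr.values[idx], in_mask)
            padj = bh_adjust(p)
        else:
            p = np.array([])
            padj = np.array([])
        table = pd.DataFrame({
            "gene": genes[idx],
            "log_ratio": d[idx],
            "pvalue": p,
            "padj": padj,
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
        })
        table["abs_d"] = table["log_ratio"].abs()
        table = table.sort_values(["pvalue", "abs_d", "gene"],
                                  ascending=[True, False, True],
                                  kind="mergesort").drop(columns="abs_d")
        signatures.append(ClusterSignature(c, table.reset_index(drop=True)))
    return MarkerResult(signatures, excluded)
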