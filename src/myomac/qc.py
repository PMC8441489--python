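"""Cell quality control and normalization.

Dead and dying cells carry abnormal mitochondrial read fractions, so cells
are filtered on the fraction of counts mapping to mitochondrial genes (and
on total counts). Retained cells are library-size log-normalized and
highly variable genes are selected by binned dispersion.

Default thresholds (0.5%-15% mito fraction, >=200 counts) are repository
choices bracketing common practice; they are exposed on every entry point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix

DEFAULT_MITO_LOW = 0.005
DEFAULT_MITO_HIGH = 0.15
DEFAULT_MIN_COUNTS = 200


def compute_qc(
    counts: CountMatrix,
    mito_genes: set[str] | list[str],
    low: float = DEFAULT_MITO_LOW,
    high: float = DEFAULT_MITO_HIGH,
    min_counts: int = DEFAULT_MIN_COUNTS,
) -> pd.DataFrame:
    """Per-cell QC record: barcode, total counts, mito fraction, pass flag.

    Zero-count cells get mito fraction 0 and fail. Raises if a mito gene is
    not in the matrix.
    """
    mito_genes = list(mito_genes)
    mito_idx = counts.gene_index(mito_genes)  # KeyError on unknown ID
    total = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    mito_total = np.asarray(counts.values[mito_idx].sum(axis=0)).ravel().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)
    passed = (total >= min_counts) & (total > 0) & (frac >= low) & (frac <= high)
    return pd.DataFrame({
        "barcode": counts.barcodes,
        "total_counts": total.astype(int),
        "mito_fraction": frac,
        "pass": passed,
    })


def filter_cells(
    counts: CountMatrix,
    qc: pd.DataFrame,
    low: float = DEFAULT_MITO_LOW,
    high: float = DEFAULT_MITO_HIGH,
    min_counts: int = DEFAULT_MIN_COUNTS,
) -> CountMatrix:
    """Retain cells with low <= mito fraction <= high and total >= min_counts."""
    if not 0 <= low < high <= 1:
        raise ValueError("need 0 <= low < high <= 1")
    qc = qc.set_index("barcode").loc[counts.barcodes]
    keep = (
        (qc["mito_fraction"].to_numpy() >= low)
        & (qc["mito_fraction"].to_numpy() <= high)
        & (qc["total_counts"].to_numpy() >= min_counts)
        & (qc["total_counts"].to_numpy() > 0)
    )
    if not keep.any():
        raise ValueError("QC filtering removed every cell")
    return counts.subset_cells(keep)


def log_normalize(counts: CountMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """entry = ln(1 + scale * count / cell_total); zero pattern preserved."""
    total = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    if (total == 0).any():
        raise ValueError("zero-total cell; filter cells before normalizing")
    dense = counts.values.toarray().astype(float)
    values = np.log1p(scale * dense / total[None, :])
    return ExpressionMatrix(values, list(counts.gene_ids), list(counts.barcodes),
                            scale_factor=scale)


@dataclass
class HvgResult:
    genes: list[str]
    stats: pd.DataFrame  # per-gene mean, dispersion, normalized dispersion


def select_hvg(expr: ExpressionMatrix, n_top: int = 2000, n_bins: int = 20) -> HvgResult:
    """Highly variable genes by binned dispersion.

    Dispersion = variance/mean of the de-logged normalized values, z-scored
    within ``n_bins`` mean bins (quantile bins). Deterministic tie-break by
    gene ID; constant genes rank last.
    """
    if n_top > expr.n_genes:
        raise ValueError("n_top exceeds number of genes")
    delog = np.expm1(expr.values)
    mean = delog.mean(axis=1)
    var = delog.var(axis=1, ddof=1) if expr.n_cells > 1 else np.zeros_like(mean)
    # variance of a constant gene rounds to ~1e-30, not 0: clip it
    var = np.where(var <= 1e-12 * np.maximum(mean, 1.0) ** 2, 0.0, var)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    df = pd.DataFrame({"gene": expr.gene_ids, "mean": mean, "dispersion": disp})
    try:
        bins = pd.qcut(df["mean"], q=min(n_bins, max(df["mean"].nunique(), 1)),
                       duplicates="drop")
    except ValueError:  # all means identical
        bins = pd.Series(0, index=df.index)
    grouped = df.groupby(bins, observed=True)["dispersion"]
    center = grouped.transform("mean")
    spread = grouped.transform("std").fillna(0.0)
    z = np.where(spread.to_numpy() > 0,
                 (disp - center.to_numpy()) / np.maximum(spread.to_numpy(), 1e-12),
                 0.0)
    z = np.where(disp > 0, z, -np.inf)  # constant genes never beat varying ones
    df["norm_dispersion"] = z
    order = df.sort_values(["norm_dispersion", "gene"],
                           ascending=[False, True], kind="mergesort")
    return HvgResult(list(order["gene"].head(n_top)), df)
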