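"""Preranked gene-set enrichment with a signal-to-noise ranking metric.

Genes are ranked by s = (mu_A - mu_B) / (sigma_A + sigma_B) between two
cell groups (per-group sigma floored at max(sigma, 0.2*|mu|, 1e-8), the
classical GSEA convention). Enrichment of a set is the weighted
Kolmogorov-Smirnov running-sum statistic; significance comes from a
gene-permutation null (size-matched random sets drawn from the ranked
universe), with NES = ES / mean |null ES of the same sign| and BH
adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection
from .markers import bh_adjust

SIGMA_FLOOR_FRACTION = 0.2
SIGMA_FLOOR_ABS = 1e-8


def signal_to_noise(expr: ExpressionMatrix, group_a, group_b) -> pd.Series:
    """Per-gene signal-to-noise score between two cell groups (>= 3 cells each).

    Positive scores mean higher in group A.
    """
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if a.dtype == bool:
        a = np.flatnonzero(a)
    if b.dtype == bool:
        b = np.flatnonzero(b)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 cells for signal-to-noise")
    xa = expr.values[:, a]
    xb = expr.values[:, b]
    mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)
    sd_a = xa.std(axis=1, ddof=1)
    sd_b = xb.std(axis=1, ddof=1)
    sd_a = np.maximum(np.maximum(sd_a, SIGMA_FLOOR_FRACTION * np.abs(mu_a)), SIGMA_FLOOR_ABS)
    sd_b = np.maximum(np.maximum(sd_b, SIGMA_FLOOR_FRACTION * np.abs(mu_b)), SIGMA_FLOOR_ABS)
    return pd.Series((mu_a - mu_b) / (sd_a + sd_b), index=expr.gene_ids, name="s2n")


@dataclass
class RankedGeneList:
    """Genes sorted by descending score; ties broken by gene ID."""

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.genes.size != self.scores.size:
            raise ValueError("genes and scores must align")
        if len(set(self.genes.tolist())) != self.genes.size:
            raise ValueError("duplicate genes in ranking")

    def __len__(self) -> int:
        return int(self.genes.size)


def rank_genes(scores: pd.Series) -> RankedGeneList:
    """Sort by descending score, gene ID ascending on ties (deterministic)."""
    df = pd.DataFrame({"gene": scores.index.astype(str), "s": scores.to_numpy(dtype=float)})
    df = df.sort_values(["s", "gene"], ascending=[False, True], kind="mergesort")
    return RankedGeneList(df["gene"].to_numpy(), df["s"].to_numpy())


def _es_core(abs_scores: np.ndarray, hit_pos: np.ndarray, weight: float) -> tuple[float, int]:
    """ES and extremum index from sorted 0-based hit positions."""
    n = abs_scores.size
    m = hit_pos.size
    w = abs_scores[hit_pos] ** weight
    total = w.sum()
    if total <= 0:  # all hit scores zero: hits carry equal weight
        w = np.ones(m)
        total = float(m)
    cum = np.cumsum(w) / total
    miss = 1.0 / (n - m)
    after = cum - (hit_pos - np.arange(m)) * miss        # just after each hit
    before = np.concatenate([[0.0], cum[:-1]]) - (hit_pos - np.arange(m)) * miss
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    pos_dev = after[i_max]
    neg_dev = before[i_min]
    if pos_dev >= -neg_dev:
        return float(pos_dev), i_max
    return float(neg_dev), i_min


def enrichment_score(
    ranked: RankedGeneList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score, full running sum, and leading edge.

    Hits advance the running sum by |s|^weight normalized to the set's
    total; misses retreat by 1/(N - N_hit). ES is the signed maximal
    deviation; the leading edge is the hits at or before the extremum for
    positive ES (at or after it for negative ES).
    """
    members = set(gene_set)
    n = len(ranked)
    in_set = np.isin(ranked.genes, list(members))
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if m == n:
        raise ValueError("gene set covers the whole ranked universe")
    hit_pos = np.flatnonzero(in_set)
    es, i_ext = _es_core(np.abs(ranked.scores), hit_pos, weight)
    # full running sum for output
    w = np.abs(ranked.scores[hit_pos]) ** weight
    total = w.sum()
    if total <= 0:
        w = np.ones(m)
        total = float(m)
    steps = np.full(n, -1.0 / (n - m))
    steps[hit_pos] = w / total
    running = np.cumsum(steps)
    if es >= 0:
        leading = ranked.genes[hit_pos[: i_ext + 1]].tolist()
    else:
        leading = ranked.genes[hit_pos[i_ext:]].tolist()
    return es, running, leading


def _null_es(abs_scores: np.ndarray, m: int, n_perm: int, weight: float,
             rng: np.random.Generator) -> np.ndarray:
    """ES of ``n_perm`` random size-m gene sets from the ranked universe."""
    n = abs_scores.size
    # sorted random positions without replacement, vectorized
    keys = rng.random((n_perm, n))
    pos = np.sort(np.argpartition(keys, m - 1, axis=1)[:, :m], axis=1)
    w = abs_scores[pos] ** weight
    total = w.sum(axis=1, keepdims=True)
    bad = total[:, 0] <= 0
    if bad.any():
        w[bad] = 1.0
        total[bad] = float(m)
    cum = np.cumsum(w, axis=1) / total
    miss = 1.0 / (n - m)
    offsets = (pos - np.arange(m)[None, :]) * miss
    after = cum - offsets
    before = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - offsets
    pos_dev = after.max(axis=1)
    neg_dev = before.min(axis=1)
    return np.where(pos_dev >= -neg_dev, pos_dev, neg_dev)


@dataclass
class GseaResult:
    table: pd.DataFrame  # set, size, es, nes, pval, padj, leading_edge
    n_perm: int


def gsea(
    ranked: RankedGeneList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_overlap: int = 1,
) -> GseaResult:
    """Permutation GSEA over a collection of gene sets.

    The null for each set is the ES of ``n_perm`` random size-matched gene
    sets; the nominal p is the plus-one-corrected same-sign tail fraction,
    NES = ES / mean |same-sign null ES|, and p-values are BH-adjusted
    across sets. Deterministic given the seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    abs_scores = np.abs(ranked.scores)
    universe = set(ranked.genes.tolist())
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, members in sets.items():
        overlap = [g for g in members if g in universe]
        if len(overlap) > len(ranked):
            raise ValueError(f"set {name!r} larger than ranked universe")
        if len(overlap) < min_overlap or len(overlap) == 0:
            raise ValueError(f"set {name!r} does not overlap the ranked universe")
        if len(overlap) == len(ranked):
            raise ValueError(f"set {name!r} covers the whole universe")
        es, _, leading = enrichment_score(ranked, overlap, weight)
        m = len(overlap)
        if m not in null_cache:
            null_cache[m] = _null_es(abs_scores, m, n_perm, weight, rng)
        null = null_cache[m]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        n_extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        pval = (1.0 + n_extreme) / (1.0 + n_same)
        denom = np.abs(null[same_sign]).mean() if n_same else np.nan
        nes = es / denom if (denom and np.isfinite(denom) and denom > 0) else 0.0
        rows.append({"set": name, "size": m, "es": es, "nes": nes,
                     "pval": pval, "leading_edge": leading})
    table = pd.DataFrame(rows)
    table["padj"] = bh_adjust(table["pval"].to_numpy())
    table = table[["set", "size", "es", "nes", "pval", "padj", "leading_edge"]]
    return GseaResult(table, n_perm)
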