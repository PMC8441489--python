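"""Reference-based cluster identity scoring.

For every reference cell type c and gene g the panel signal S is reduced to
a natural-log ratio against the gene's whole-panel average,

    r_{c,g} = ln( S_{c,g} / mean_c' S_{c',g} ),

positive for genes upregulated in type c and negative for downregulated
ones. A cluster's identity score against type c is the sum over its
significant DE genes of the product of its DE log-ratio d and r:

    I_{k,c} = sum_{g in DE(k) & panel} d_{k,g} * r_{c,g}.

Genes regulated in the same direction in both the cluster and the reference
type add to the score; inversely regulated genes subtract. The assigned
identity is the argmax over types, with an ambiguity flag when the margin
over the runner-up is small or the top score is non-positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ReferencePanel
from .markers import ClusterSignature

AMBIGUITY_MARGIN = 0.10  # flag when margin < 10% of |top score|


@dataclass
class ReferenceLogRatios:
    """Natural-log ratios of type signal to per-gene panel average.

    For every gene, mean_c exp(r_{c,g}) = 1 by construction (arithmetic
    mean over types).
    """

    values: pd.DataFrame  # types x genes

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


def reference_log_ratios(panel: ReferencePanel) -> ReferenceLogRatios:
    """r_{c,g} = ln(S_{c,g} / mean over types of S_{.,g}); needs >= 2 types."""
    if len(panel.cell_types) < 2:
        raise ValueError("reference panel needs >= 2 cell types")
    S = panel.values
    if (S.to_numpy() <= 0).any():
        raise ValueError("panel signals must be strictly positive for the log ratio")
    return ReferenceLogRatios(np.log(S / S.mean(axis=0)))


@dataclass
class IdentityScoreTable:
    """Aggregate identity scores per (cluster, reference type)."""

    scores: pd.DataFrame          # clusters x types
    n_genes_used: pd.Series       # cluster -> genes entering the sum
    n_genes_skipped: pd.Series    # cluster -> DE genes absent from the panel
    assignments: pd.DataFrame     # cluster, identity, score, margin, rank info, flag

    def rank(self, cluster) -> pd.Series:
        """1-based rank of each reference type for a cluster (1 = best)."""
        row = self.scores.loc[cluster]
        return row.rank(ascending=False, method="first").astype(int)


def identity_scores(
    signatures: list[ClusterSignature],
    ref: ReferenceLogRatios,
    alpha: float = 0.05,
    top_n: int | None = None,
) -> IdentityScoreTable:
    """Score every cluster signature against every reference type.

    Signatures are restricted to genes with BH-adjusted p < ``alpha``
    (optionally capped at the ``top_n`` most significant); genes absent
    from the panel are skipped and counted. A cluster with no usable gene
    scores 0 against every type and is flagged unassignable.
    """
    r = ref.values
    clusters = [sig.cluster for sig in signatures]
    scores = pd.DataFrame(0.0, index=clusters, columns=r.index)
    n_used = pd.Series(0, index=clusters, dtype=int)
    n_skipped = pd.Series(0, index=clusters, dtype=int)
    panel_genes = set(r.columns)
    for sig in signatures:
        table = sig.table
        de = table[table["padj"] < alpha]
        if top_n is not None:
            de = de.head(top_n)
        in_panel = de["gene"].isin(panel_genes)
        n_skipped[sig.cluster] = int((~in_panel).sum())
        de = de[in_panel]
        n_used[sig.cluster] = len(de)
        if len(de) == 0:
            continue
        d = de.set_index("gene")["log_ratio"]
        sub = r[d.index]  # types x used genes
        scores.loc[sig.cluster] = sub.to_numpy() @ d.to_numpy()
    assignments = assign_identities_frame(scores, n_used)
    return IdentityScoreTable(scores, n_used, n_skipped, assignments)


def assign_identities_frame(scores: pd.DataFrame,
                            n_used: pd.Series | None = None) -> pd.DataFrame:
    """Argmax identity per cluster with margin and ambiguity flag.

    Ties break toward the lexicographically first type name; a cluster is
    flagged ambiguous when margin < 10% of |top score| or the top score is
    <= 0, and unassignable when no gene contributed.
    """
    if scores.shape[1] < 2:
        raise ValueError("need >= 2 reference types to assign identities")
    cols_sorted = sorted(scores.columns)
    rows = []
    for cluster, row in scores.iterrows():
        vals = row[cols_sorted]
        top_val = vals.max()
        identity = vals.idxmax()  # first (lexicographic) among ties
        runner = vals.drop(identity).max()
        margin = float(top_val - runner)
        unassignable = bool(n_used is not None and n_used.get(cluster, 0) == 0)
        ambiguous = bool(margin < AMBIGUITY_MARGIN * abs(top_val) or top_val <= 0)
        flag = "unassignable" if unassignable else ("ambiguous" if ambiguous else "ok")
        rows.append({"cluster": cluster, "identity": identity,
                     "score": float(top_val), "margin": margin, "flag": flag})
    return pd.DataFrame(rows)


def assign_identities(table: IdentityScoreTable) -> pd.DataFrame:
    """Per-cluster (identity, margin, flag) from a complete score table."""
    return assign_identities_frame(table.scores, table.n_genes_used)


def identity_recovery(assignments: pd.DataFrame, cluster_labels: np.ndarray,
                      true_types: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Fraction of clusters assigned their generating type.

    The generating type of a cluster is the majority true label among its
    cells. Returns (accuracy, per-cluster frame with generating type,
    assigned identity and correctness).
    """
    cluster_labels = np.asarray(cluster_labels)
    true_types = np.asarray(true_types)
    rows = []
    for _, rec in assignments.iterrows():
        members = cluster_labels == rec["cluster"]
        gen = pd.Series(true_types[members]).mode().iloc[0]
        rows.append({"cluster": rec["cluster"], "generating_type": gen,
                     "identity": rec["identity"],
                     "correct": bool(rec["identity"] == gen)})
    frame = pd.DataFrame(rows)
    return float(frame["correct"].mean()), frame


def merge_clusters(labels: np.ndarray, groups: list[list[int]]) -> np.ndarray:
    """Merge the given cluster-label groups (e.g. indistinct macrophage
    subsets) into single clusters; relabels contiguously by first occurrence.

    A manual curation utility: the merge decision itself is the analyst's.
    """
    labels = np.asarray(labels).copy()
    for group in groups:
        if len(group) < 2:
            continue
        target = min(group)
        for g in group:
            labels[labels == g] = target
    _, out = np.unique(labels, return_inverse=True)
    first_seen: dict[int, int] = {}
    res = np.empty_like(out)
    nxt = 0
    for i, lab in enumerate(out):
        if lab not in first_seen:
            first_seen[lab] = nxt
            nxt += 1
        res[i] = first_seen[lab]
    return res
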