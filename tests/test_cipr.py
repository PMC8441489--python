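"""Reference log-ratios, identity scores and assignment logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from myomac import cipr
from myomac.containers import ReferencePanel
from myomac.markers import ClusterSignature


def _panel(values, types=None, genes=None):
    values = np.asarray(values, dtype=float)
    types = types or [f"T{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return ReferencePanel(pd.DataFrame(values, index=types, columns=genes))


def _signature(cluster, genes, d, padj=None):
    n = len(genes)
    return ClusterSignature(cluster, pd.DataFrame({
        "gene": genes,
        "log_ratio": d,
        "pvalue": [0.001] * n,
        "padj": padj if padj is not None else [0.001] * n,
        "pct_in": [0.9] * n,
        "pct_out": [0.1] * n,
    }))


class TestReferenceLogRatios:
    def test_two_type_hand_case(self):
        # signals (2, 1): mean 1.5 -> r = (ln(4/3), ln(2/3))
        ref = cipr.reference_log_ratios(_panel([[2.0], [1.0]]))
        np.testing.assert_allclose(ref.values["g0"].to_numpy(),
                                   [np.log(4 / 3), np.log(2 / 3)])

    def test_constant_gene_gives_zero(self):
        ref = cipr.reference_log_ratios(_panel([[3.0, 2.0], [3.0, 8.0]]))
        np.testing.assert_allclose(ref.values["g0"].to_numpy(), [0.0, 0.0])

    def test_single_type_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            cipr.reference_log_ratios(_panel([[1.0, 2.0]]))

    def test_nonpositive_signal_rejected_at_panel(self):
        with pytest.raises(ValueError, match="positive"):
            _panel([[1.0], [0.0]])

    @given(st.integers(0, 10_000))
    def test_exp_ratio_sums_to_n_types(self, seed):
        rng = np.random.default_rng(seed)
        n_types = int(rng.integers(2, 7))
        panel = _panel(rng.lognormal(0, 1, size=(n_types, 5)))
        ref = cipr.reference_log_ratios(panel)
        sums = np.exp(ref.values.to_numpy()).sum(axis=0)
        np.testing.assert_allclose(sums, n_types, rtol=1e-12)


class TestIdentityScores:
    def test_single_gene_score_continues_hand_case(self):
        panel = _panel([[2.0], [1.0]], types=["A", "B"])
        ref = cipr.reference_log_ratios(panel)
        table = cipr.identity_scores([_signature(0, ["g0"], [1.0])], ref)
        np.testing.assert_allclose(table.scores.loc[0, ["A", "B"]].to_numpy(),
                                   [np.log(4 / 3), np.log(2 / 3)])
        assert table.assignments.iloc[0]["identity"] == "A"

    def test_zero_d_scores_flagged(self):
        panel = _panel([[2.0, 1.0], [1.0, 2.0]], types=["A", "B"])
        ref = cipr.reference_log_ratios(panel)
        table = cipr.identity_scores([_signature(0, ["g0", "g1"], [0.0, 0.0])], ref)
        assert (table.scores.loc[0] == 0).all()
        assert table.assignments.iloc[0]["flag"] != "ok"

    def test_no_panel_overlap_unassignable(self):
        panel = _panel([[2.0], [1.0]], types=["A", "B"], genes=["g0"])
        ref = cipr.reference_log_ratios(panel)
        table = cipr.identity_scores([_signature(0, ["other"], [1.0])], ref)
        assert (table.scores.loc[0] == 0).all()
        assert table.assignments.iloc[0]["flag"] == "unassignable"
        assert table.n_genes_skipped[0] == 1

    def test_insignificant_genes_excluded(self):
        panel = _panel([[2.0, 4.0], [1.0, 1.0]], types=["A", "B"])
        ref = cipr.reference_log_ratios(panel)
        sig = _signature(0, ["g0", "g1"], [1.0, 1.0], padj=[0.001, 0.9])
        table = cipr.identity_scores([sig], ref, alpha=0.05)
        assert table.n_genes_used[0] == 1
        np.testing.assert_allclose(table.scores.loc[0, "A"], np.log(4 / 3))

    @pytest.mark.parametrize("seed", range(50))
    def test_brute_force_triple_loop_oracle(self, seed):
        # vectorized scores equal an explicit (cluster, type, gene) loop
        rng = np.random.default_rng(seed)
        n_types, n_genes = 5, 30
        panel = _panel(rng.lognormal(0, 1, size=(n_types, n_genes)))
        ref = cipr.reference_log_ratios(panel)
        genes = ref.genes
        signatures = []
        for k in range(3):
            chosen = rng.choice(genes, size=12, replace=False)
            signatures.append(_signature(k, list(chosen),
                                         rng.normal(size=12).tolist()))
        table = cipr.identity_scores(signatures, ref)
        # independent oracle: triple loop over (k, c, g)
        for sig in signatures:
            d = dict(zip(sig.table["gene"], sig.table["log_ratio"]))
            for c in ref.cell_types:
                expected = 0.0
                for g, dv in d.items():
                    expected += dv * ref.values.loc[c, g]
                assert abs(table.scores.loc[sig.cluster, c] - expected) < 1e-12

    def test_bilinearity_in_d(self):
        rng = np.random.default_rng(1)
        panel = _panel(rng.lognormal(0, 1, size=(4, 20)))
        ref = cipr.reference_log_ratios(panel)
        genes = ref.genes[:10]
        d = rng.normal(size=10).tolist()
        t1 = cipr.identity_scores([_signature(0, genes, d)], ref)
        t2 = cipr.identity_scores([_signature(0, genes, [3.0 * v for v in d])], ref)
        np.testing.assert_allclose(3.0 * t1.scores.to_numpy(), t2.scores.to_numpy(),
                                   rtol=1e-12)

    def test_per_gene_panel_scaling_leaves_scores_unchanged(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(0, 1, size=(4, 20))
        scale = rng.lognormal(0, 1, size=20)
        ref1 = cipr.reference_log_ratios(_panel(base))
        ref2 = cipr.reference_log_ratios(_panel(base * scale[None, :]))
        genes = ref1.genes[:8]
        d = rng.normal(size=8).tolist()
        t1 = cipr.identity_scores([_signature(0, genes, d)], ref1)
        t2 = cipr.identity_scores([_signature(0, genes, d)], ref2)
        np.testing.assert_allclose(t1.scores.to_numpy(), t2.scores.to_numpy(),
                                   atol=1e-10)

    def test_negating_d_reverses_ranks(self):
        rng = np.random.default_rng(3)
        panel = _panel(rng.lognormal(0, 1, size=(4, 20)))
        ref = cipr.reference_log_ratios(panel)
        genes = ref.genes[:10]
        d = rng.normal(size=10).tolist()
        t1 = cipr.identity_scores([_signature(0, genes, d)], ref)
        t2 = cipr.identity_scores([_signature(0, genes, [-v for v in d])], ref)
        np.testing.assert_allclose(t1.scores.to_numpy(), -t2.scores.to_numpy(),
                                   rtol=1e-12)
        r1 = t1.rank(0)
        r2 = t2.rank(0)
        assert (r1.sort_values().index == r2.sort_values().index[::-1]).all()


class TestAssignIdentities:
    def test_argmax_and_margin(self):
        scores = pd.DataFrame([[5.0, 3.0, -1.0]], index=[0],
                              columns=["A", "B", "C"])
        out = cipr.assign_identities_frame(scores)
        assert out.iloc[0]["identity"] == "A"
        assert out.iloc[0]["margin"] == pytest.approx(2.0)
        assert out.iloc[0]["flag"] == "ok"

    def test_tie_lexicographic_and_ambiguous(self):
        scores = pd.DataFrame([[4.0, 4.0]], index=[0], columns=["Zeta", "Alpha"])
        out = cipr.assign_identities_frame(scores)
        assert out.iloc[0]["identity"] == "Alpha"
        assert out.iloc[0]["flag"] == "ambiguous"

    def test_nonpositive_top_score_flagged(self):
        scores = pd.DataFrame([[-0.5, -2.0]], index=[0], columns=["A", "B"])
        out = cipr.assign_identities_frame(scores)
        assert out.iloc[0]["flag"] == "ambiguous"


def test_merge_clusters_relabels_contiguously():
    labels = np.array([0, 1, 2, 3, 1, 2, 0])
    merged = cipr.merge_clusters(labels, [[1, 2]])
    assert merged.max() == 2
    assert merged[1] == merged[2] == merged[4] == merged[5]
    assert merged[0] != merged[1]
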