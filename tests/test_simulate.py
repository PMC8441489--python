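"""Synthetic-data generator: construction contracts, determinism, and the
statistical structure downstream stages rely on."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from myomac.simulate import (
    SimulationConfig,
    make_reference,
    simulate_bead_counts,
    simulate_counts,
    simulate_ecar_trace,
    simulate_metabolites,
)


class TestConfigValidation:
    def test_marker_fold_must_exceed_one(self):
        with pytest.raises(ValueError, match="marker_fold"):
            SimulationConfig(marker_fold=1.0)

    def test_outlier_fraction_bounded(self):
        with pytest.raises(ValueError, match="outlier_cell_frac"):
            SimulationConfig(outlier_cell_frac=0.5)

    def test_negative_ecar_phase_mean_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(ecar_phase_means=(10.0, -1.0, 50.0, 8.0))

    def test_counts_positive(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)


class TestMakeReference:
    def test_marker_cells_at_fold_baseline_elsewhere(self):
        cfg = SimulationConfig(n_types=8, n_genes=400, markers_per_type=5)
        ref = make_reference(cfg)
        # Il1b is the signature marker of the first macrophage subset
        col = ref.values["Il1b"]
        assert col["Macrophage_Il1b"] == 8.0
        assert (col.drop("Macrophage_Il1b") == 1.0).all()

    def test_overlapping_marker_sets_rejected(self):
        cfg = SimulationConfig(n_types=2, n_genes=10, markers_per_type=6,
                               mito_gene_count=1)
        with pytest.raises(ValueError, match="overlap"):
            make_reference(cfg)

    def test_panel_mean_of_marker_gene(self):
        # 8 types, fold 8: whole-panel mean of a marker gene = (8+7)/8
        cfg = SimulationConfig(n_types=8, n_genes=400, markers_per_type=5)
        ref = make_reference(cfg)
        assert ref.values["Il1b"].mean() == pytest.approx(1.875)

    def test_marker_sets_disjoint(self, small_config):
        ref = make_reference(small_config)
        cfg = small_config
        marker_cols = (ref.values == cfg.marker_fold).sum(axis=0)
        assert (marker_cols[marker_cols > 0] == 1).all()


class TestSimulateCounts:
    def test_same_seed_bit_identical(self, small_config):
        ref = make_reference(small_config)
        a, meta_a, _ = simulate_counts(ref, small_config)
        b, meta_b, _ = simulate_counts(ref, small_config)
        assert (a.values != b.values).nnz == 0
        assert a.barcodes == b.barcodes
        pd.testing.assert_frame_equal(meta_a, meta_b)

    def test_gene_space_mismatch_rejected(self, small_config):
        other = dataclasses.replace(small_config, n_genes=301)
        ref = make_reference(other)
        with pytest.raises(ValueError, match="gene spaces"):
            simulate_counts(ref, small_config)

    def test_zero_outlier_fraction_flags_nothing(self, small_config):
        cfg = dataclasses.replace(small_config, outlier_cell_frac=0.0)
        ref = make_reference(cfg)
        _, _, truth = simulate_counts(ref, cfg)
        assert truth.qc_outliers.sum() == 0

    def test_every_cell_has_one_true_label(self, small_sim):
        _, counts, _, truth = small_sim
        assert list(truth.cell_types.index) == counts.barcodes
        assert truth.cell_types.notna().all()

    def test_poisson_limit_means_match_expectation(self):
        # Poisson limit, dropout off, one population: per-gene empirical mean
        # should sit within 3 standard errors of the analytic expectation.
        cfg = SimulationConfig(
            n_types=1, n_genes=200, markers_per_type=10,
            samples=(("s1", "old", "control"),), cells_per_sample=(8000, 8000),
            nb_dispersion=np.inf, dropout_logit_slope=None,
            library_sd_log=0.0, outlier_cell_frac=0.0, seed=3,
        )
        ref = make_reference(cfg)
        counts, _, truth = simulate_counts(ref, cfg)
        soma = [g for g in counts.gene_ids if g not in truth.mito_genes]
        idx = counts.gene_index(soma)
        X = counts.values[idx].toarray().astype(float)
        profile = (ref.values.iloc[0].loc[soma].to_numpy()
                   * truth.gene_scales.loc[soma].to_numpy())
        a, b = cfg.mito_beta_params
        expected = profile / profile.sum() * cfg.mean_library_size * (b / (a + b))
        emp_mean = X.mean(axis=1)
        se = X.std(axis=1, ddof=1) / np.sqrt(X.shape[1])
        within = np.abs(emp_mean - expected) <= 3 * se
        assert within.mean() >= 0.99

    def test_marker_fidelity_without_dropout(self):
        # one-vs-rest mean differences recover >=90% of planted markers
        cfg = SimulationConfig(
            n_types=4, n_genes=300, markers_per_type=10,
            samples=(("s1", "old", "control"),), cells_per_sample=(1200, 1200),
            dropout_logit_slope=None, outlier_cell_frac=0.0, seed=5,
        )
        ref = make_reference(cfg)
        counts, _, truth = simulate_counts(ref, cfg)
        X = counts.values.toarray().astype(float)
        labels = truth.cell_types.to_numpy()
        genes = np.asarray(counts.gene_ids)
        for t, markers in truth.marker_sets.items():
            in_mask = labels == t
            assert in_mask.sum() >= 200
            diff = X[:, in_mask].mean(axis=1) - X[:, ~in_mask].mean(axis=1)
            top = set(genes[np.argsort(-diff)[: len(markers)]])
            assert len(top & set(markers)) >= 0.9 * len(markers)

    def test_non_outlier_mito_fractions_inside_qc_window(self, small_sim):
        from myomac import qc

        _, counts, _, truth = small_sim
        qc_df = qc.compute_qc(counts, truth.mito_genes).set_index("barcode")
        non_out = truth.qc_outliers.index[~truth.qc_outliers]
        frac = qc_df.loc[non_out, "mito_fraction"]
        assert (frac >= qc.DEFAULT_MITO_LOW).all()
        assert (frac <= qc.DEFAULT_MITO_HIGH).all()


class TestSimulateMetabolites:
    def test_zero_noise_planted_ratio_exact(self):
        effects = (("succinate", -1.0, 0.0),)
        cfg = SimulationConfig(metab_effects=effects, metab_noise_sd=0.0)
        table, truth = simulate_metabolites(cfg)
        young = table.values[table.group_samples("young")].mean(axis=1)
        old = table.values[table.group_samples("old")].mean(axis=1)
        ratio = old / young
        assert ratio["succinate"] == pytest.approx(0.5, abs=1e-12)
        assert ratio["lactate"] == pytest.approx(1.0, abs=1e-12)
        assert truth.metab_log2fc["succinate"] == -1.0

    def test_default_effect_panel(self):
        table, truth = simulate_metabolites(SimulationConfig())
        assert truth.metab_log2fc["succinate"] == -1.0
        for met in ("glucose", "glycerol-3-phosphate", "sedoheptulose-7-phosphate"):
            assert truth.metab_log2fc[met] == 1.0
        assert (table.values.to_numpy() > 0).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3"):
            SimulationConfig(metab_samples_per_group=2)

    def test_same_seed_identical(self):
        t1, _ = simulate_metabolites(SimulationConfig(seed=9))
        t2, _ = simulate_metabolites(SimulationConfig(seed=9))
        pd.testing.assert_frame_equal(t1.values, t2.values)


class TestSimulateEcar:
    def test_zero_noise_equals_phase_means(self):
        cfg = SimulationConfig(ecar_noise_sd=0.0,
                               ecar_group_scale=(("young", 1.0), ("old", 1.0)))
        trace = simulate_ecar_trace(cfg)
        for phase, mean in zip(("baseline", "glucose", "oligomycin", "2DG"),
                               cfg.ecar_phase_means):
            vals = trace.measurements.loc[trace.measurements["phase"] == phase, "ecar"]
            assert (vals == mean).all()

    def test_phases_in_injection_order(self):
        trace = simulate_ecar_trace(SimulationConfig(seed=2))
        order = {"baseline": 0, "glucose": 1, "oligomycin": 2, "2DG": 3}
        for well in trace.wells:
            codes = trace.well_trace(well)["phase"].map(order).to_numpy()
            assert (np.diff(codes) >= 0).all()

    def test_same_seed_identical(self):
        a = simulate_ecar_trace(SimulationConfig(seed=4))
        b = simulate_ecar_trace(SimulationConfig(seed=4))
        pd.testing.assert_frame_equal(a.measurements, b.measurements)


def test_bead_counts_structure():
    beads = simulate_bead_counts(SimulationConfig(seed=1))
    assert set(beads["group"]) == {"young", "old"}
    assert (beads["beads"] >= 0).all()
    per_well = beads.groupby(["group", "well"]).size()
    assert (per_well == 200).all()
    assert len(per_well) == 6  # 3 wells per group
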