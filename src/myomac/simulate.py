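"""Synthetic study-design generator.

Emulates the data this pipeline analyses: pooled CD45+ single-cell UMI
count matrices from six samples (young/old x control / hindlimb-unloading /
4-day reload), an ImmGen-like reference expression panel, a targeted
glycolysis/TCA metabolite panel with planted age effects, glycolysis
stress-test ECAR traces, and phagocytosis bead counts — each with the
ground truth needed to score the downstream stages.

Counts are negative-binomial with a lognormal per-cell library-size factor
and logistic-in-log-mean dropout. Marker genes are disjoint across cell
types so planted-identity recovery is unambiguous. An age-modulated
"inflammatory" gene program is planted in young macrophages, mirroring the
young-enriched inflammatory signature the analysis is designed to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, EcarTrace, GeneSetCollection, MetaboliteTable, ReferencePanel

# Mouse mitochondrial protein-coding genes (13, as on the MT chromosome).
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)

# Pan-macrophage surface markers, elevated in every macrophage subset.
PAN_MACROPHAGE_GENES = ("Cd68", "Cd86", "Adgre1", "Csf1r")

# Canonical CD45+ population names; the four macrophage subsets are
# distinguished by their signature cytokine/chemokine.
CELL_TYPE_NAMES = (
    "Macrophage_Il1b", "Macrophage_Ccl8", "Macrophage_Spp1", "Macrophage_S100a9",
    "Neutrophil", "Monocyte_Ly6Chi", "T_cell_CD8", "B_cell",
    "NK_cell", "Dendritic_cell_Cd209", "Monocyte_Ly6Clo", "T_cell_gd",
    "ILC", "T_cell_CD8_mem", "Dendritic_cell_Irf8", "Mast_cell",
    "Basophil", "Fibrocyte", "Stromal_cell", "EPC",
    "T_cell_immature", "Dendritic_cell_Retnla", "LN_monocyte", "T_cell_CD8_eff",
)

# First marker of each macrophage subset carries its signature gene name.
_SIGNATURE_MARKERS = {
    "Macrophage_Il1b": "Il1b",
    "Macrophage_Ccl8": "Ccl8",
    "Macrophage_Spp1": "Spp1",
    "Macrophage_S100a9": "S100a9",
}

DEFAULT_SAMPLES = (
    ("young_control", "young", "control"),
    ("young_HU", "young", "HU"),
    ("young_RL4", "young", "RL4"),
    ("old_control", "old", "control"),
    ("old_HU", "old", "HU"),
    ("old_RL4", "old", "RL4"),
)

# Metabolite panel: glycolysis + TCA intermediates measured by targeted GC-MS.
DEFAULT_METABOLITES = (
    "glucose", "glucose-6-phosphate", "fructose-6-phosphate",
    "glycerol-3-phosphate", "sedoheptulose-7-phosphate", "pyruvate",
    "lactate", "citrate", "isocitrate", "alpha-ketoglutarate",
    "succinate", "fumarate", "malate", "itaconate",
)

# Planted age effects: (metabolite, log2 fold old-vs-young, lognormal noise sd
# on the log2 scale). Succinate falls in old; glucose, glycerol-3-phosphate
# and sedoheptulose-7-phosphate accumulate.
DEFAULT_METAB_EFFECTS = (
    ("succinate", -1.0, 0.1),
    ("glucose", 1.0, 0.1),
    ("glycerol-3-phosphate", 1.0, 0.1),
    ("sedoheptulose-7-phosphate", 1.0, 0.1),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; identical seed => identical outputs."""

    n_types: int = 8
    n_genes: int = 2000
    markers_per_type: int = 20
    marker_fold: float = 8.0
    pan_macrophage_fold: float = 4.0
    samples: tuple[tuple[str, str, str], ...] = DEFAULT_SAMPLES
    cells_per_sample: tuple[int, int] = (300, 500)
    mean_library_size: float = 2000.0
    library_sd_log: float = 0.3
    nb_dispersion: float = 10.0  # NB inverse-dispersion; inf = Poisson
    gene_scale_sd: float = 0.75  # lognormal sd of per-gene detection efficiency
    dropout_logit_slope: float | None = 1.0  # None disables dropout
    dropout_midpoint: float = 0.5  # mean count at which dropout prob = 1/2
    mito_gene_count: int = 13
    mito_beta_params: tuple[float, float] = (10.0, 190.0)
    outlier_cell_frac: float = 0.05
    n_age_effect_genes: int = 40
    age_effect_log2fc: float = 1.0
    metab_effects: tuple[tuple[str, float, float], ...] = DEFAULT_METAB_EFFECTS
    metab_noise_sd: float = 0.1
    metab_samples_per_group: int = 4
    metabolites: tuple[str, ...] = DEFAULT_METABOLITES
    ecar_phase_means: tuple[float, float, float, float] = (10.0, 30.0, 50.0, 8.0)
    ecar_group_scale: tuple[tuple[str, float], ...] = (("young", 1.0), ("old", 0.6))
    ecar_noise_sd: float = 1.0
    ecar_wells_per_group: int = 4
    ecar_measurements_per_phase: int = 3
    bead_mean_per_group: tuple[tuple[str, float], ...] = (("young", 2.5), ("old", 1.2))
    bead_cells_per_well: int = 200
    bead_wells_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_types", "n_genes", "markers_per_type", "mito_gene_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must be > 1")
        if not 0 <= self.outlier_cell_frac < 0.5:
            raise ValueError("outlier_cell_frac must be in [0, 0.5)")
        if self.n_types > len(CELL_TYPE_NAMES):
            raise ValueError(f"n_types capped at {len(CELL_TYPE_NAMES)}")
        if self.mito_gene_count > len(MITO_GENES):
            raise ValueError(f"mito_gene_count capped at {len(MITO_GENES)}")
        lo, hi = self.cells_per_sample
        if not 0 < lo <= hi:
            raise ValueError("cells_per_sample must satisfy 0 < low <= high")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0 (inf for Poisson)")
        if any(m < 0 for m in self.ecar_phase_means):
            raise ValueError("ECAR phase means must be non-negative")
        if self.metab_samples_per_group < 3:
            raise ValueError("need >=3 metabolite samples per group")

    @property
    def cell_types(self) -> list[str]:
        return list(CELL_TYPE_NAMES[: self.n_types])

    @property
    def mito_genes(self) -> list[str]:
        return list(MITO_GENES[: self.mito_gene_count])

    def paper_scale(self) -> "SimulationConfig":
        """Preset at the deposited study's per-sample cell depth."""
        return replace(self, n_types=min(24, len(CELL_TYPE_NAMES)),
                       cells_per_sample=(1700, 3700))


@dataclass
class GroundTruth:
    """What was planted, for scoring the pipeline against."""

    cell_types: pd.Series | None = None      # barcode -> true population
    qc_outliers: pd.Series | None = None     # barcode -> bool
    gene_scales: pd.Series | None = None     # somatic gene -> efficiency factor
    marker_sets: dict[str, list[str]] = field(default_factory=dict)
    enriched_sets: dict[str, list[str]] = field(default_factory=dict)
    metab_log2fc: dict[str, float] = field(default_factory=dict)
    mito_genes: list[str] = field(default_factory=list)


def _gene_names(config: SimulationConfig) -> tuple[list[str], dict[str, list[str]], list[str]]:
    """Allocate gene names: mito + pan-macrophage + per-type markers + background.

    Returns (all gene IDs, marker sets per type, pan-macrophage genes used).
    """
    types = config.cell_types
    n_markers = config.n_types * config.markers_per_type
    if n_markers > config.n_genes:
        raise ValueError(
            f"marker sets would overlap: {config.n_types} types x "
            f"{config.markers_per_type} markers > {config.n_genes} genes"
        )
    macro_types = [t for t in types if t.startswith("Macrophage")]
    pan = list(PAN_MACROPHAGE_GENES) if macro_types else []
    overhead = config.mito_gene_count + len(pan)
    if n_markers + overhead > config.n_genes:
        raise ValueError("n_genes too small for markers + mito + pan genes")
    marker_sets: dict[str, list[str]] = {}
    counter = 0
    for t in types:
        names = []
        if t in _SIGNATURE_MARKERS:
            names.append(_SIGNATURE_MARKERS[t])
        while len(names) < config.markers_per_type:
            counter += 1
            names.append(f"Gene{counter:05d}")
        marker_sets[t] = names
    n_background = config.n_genes - n_markers - overhead
    background = [f"Gene{counter + 1 + i:05d}" for i in range(n_background)]
    genes = (
        [g for t in types for g in marker_sets[t]]
        + pan
        + background
        + config.mito_genes
    )
    assert len(genes) == config.n_genes and len(set(genes)) == config.n_genes
    return genes, marker_sets, pan


def make_reference(config: SimulationConfig) -> ReferencePanel:
    """Build the ImmGen-like reference panel: baseline 1.0 everywhere, each
    type's markers at ``marker_fold``; pan-macrophage genes elevated in all
    macrophage subsets. Marker sets are disjoint across types."""
    genes, marker_sets, pan = _gene_names(config)
    types = config.cell_types
    values = pd.DataFrame(1.0, index=types, columns=genes)
    for t in types:
        values.loc[t, marker_sets[t]] = config.marker_fold
        if t.startswith("Macrophage") and pan:
            values.loc[t, pan] = config.pan_macrophage_fold
    return ReferencePanel(values)


def simulate_counts(
    ref: ReferencePanel, config: SimulationConfig
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw the single-cell count matrix, per-cell metadata, and ground truth.

    Each cell's expected expression is proportional to its true type's
    reference row; mitochondrial genes receive the cell's drawn mito
    fraction of the (post-dropout expected) library; QC-outlier cells get
    mito fractions outside the default QC window (0 for "low", 0.3-0.6 for
    "high").
    """
    _, marker_sets, _ = _gene_names(config)
    if list(ref.genes) != list(_gene_names(config)[0]):
        raise ValueError("reference and config gene spaces differ")
    rng = np.random.default_rng(config.seed)
    genes = ref.genes
    types = config.cell_types
    mito = config.mito_genes
    mito_idx = np.array([genes.index(g) for g in mito])
    soma_idx = np.array([i for i in range(len(genes)) if genes[i] not in set(mito)])

    # One dominant macrophage compartment: first type has double weight.
    weights = np.ones(config.n_types)
    weights[0] = 2.0
    props = weights / weights.sum()

    # Planted young-enriched "inflammatory" program: background genes
    # upregulated 2**age_effect_log2fc in young macrophage cells.
    background = [g for g in genes
                  if g not in set(mito)
                  and g not in set(PAN_MACROPHAGE_GENES)
                  and not any(g in ms for ms in marker_sets.values())]
    n_age = min(config.n_age_effect_genes, len(background))
    age_genes = list(rng.choice(background, size=n_age, replace=False))
    age_idx = np.array([genes.index(g) for g in age_genes], dtype=int)

    ref_vals = ref.values.to_numpy()  # types x genes
    type_lookup = {t: i for i, t in enumerate(types)}

    barcodes, sample_ids, ages, timepoints, true_types = [], [], [], [], []
    for sample_id, age, timepoint in config.samples:
        lo, hi = config.cells_per_sample
        n_cells = int(rng.integers(lo, hi + 1))
        t_idx = rng.choice(config.n_types, size=n_cells, p=props)
        for i, ti in enumerate(t_idx):
            barcodes.append(f"{sample_id}_{i:04d}")
            sample_ids.append(sample_id)
            ages.append(age)
            timepoints.append(timepoint)
            true_types.append(types[ti])
    n_total = len(barcodes)

    # Per-cell library size and mito fraction (with planted outliers).
    lib = rng.lognormal(math.log(config.mean_library_size), config.library_sd_log, n_total)
    a, b = config.mito_beta_params
    mito_frac = rng.beta(a, b, n_total)
    n_out = int(round(config.outlier_cell_frac * n_total))
    outlier = np.zeros(n_total, dtype=bool)
    if n_out:
        out_idx = rng.choice(n_total, size=n_out, replace=False)
        outlier[out_idx] = True
        high = rng.random(n_out) < 0.5
        mito_frac[out_idx[high]] = rng.uniform(0.3, 0.6, high.sum())
        mito_frac[out_idx[~high]] = 0.0

    # Expected somatic expression per cell, proportional to the type row.
    # Gene layout puts mitochondrial genes last, so the somatic block is
    # contiguous; the hot path runs in float32 for memory-bandwidth reasons.
    tcode = np.array([type_lookup[t] for t in true_types])
    profiles = ref_vals[:, soma_idx].astype(np.float32)  # types x somatic genes
    # Per-gene detection-efficiency factor: the reference panel is a
    # *normalized* signal, whereas UMI capture varies over orders of
    # magnitude between genes; a lognormal per-gene scale reproduces the
    # baseline heterogeneity of real count data.
    if config.gene_scale_sd > 0:
        gene_scale = rng.lognormal(0.0, config.gene_scale_sd, len(soma_idx))
    else:
        gene_scale = np.ones(len(soma_idx))
    profiles *= gene_scale.astype(np.float32)[None, :]
    soma_pos = {gi: k for k, gi in enumerate(soma_idx)}
    age_cols = np.array([soma_pos[i] for i in age_idx], dtype=int)
    is_macro = np.array([t.startswith("Macrophage") for t in true_types])
    is_young = np.array([a_ == "young" for a_ in ages])
    boost = 2.0 ** config.age_effect_log2fc

    mu_soma = profiles[tcode]  # cells x somatic genes (copy via fancy index)
    bump = is_macro & is_young
    mu_soma[np.ix_(bump, age_cols)] *= np.float32(boost)
    mu_soma /= mu_soma.sum(axis=1, keepdims=True)
    mu_soma *= (((1.0 - mito_frac) * lib)[:, None]).astype(np.float32)

    # Dropout keep-probability, logistic in log mean:
    # keep = q^slope / (1 + q^slope) with q = mu / midpoint.
    if config.dropout_logit_slope is not None:
        keep_prob = mu_soma / np.float32(config.dropout_midpoint)
        if config.dropout_logit_slope != 1.0:
            np.power(keep_prob, np.float32(config.dropout_logit_slope), out=keep_prob)
        np.divide(keep_prob, 1.0 + keep_prob, out=keep_prob)
    else:
        keep_prob = None

    # Mito means calibrated so the expected post-dropout mito fraction equals
    # the drawn fraction.
    if keep_prob is not None:
        soma_expected = np.einsum("ij,ij->i", mu_soma, keep_prob, dtype=np.float64)
    else:
        soma_expected = mu_soma.sum(axis=1, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_total = np.where(mito_frac < 1.0,
                              mito_frac / (1.0 - mito_frac) * soma_expected, 0.0)
    mu_mito = np.repeat(mito_total[:, None] / len(mito), len(mito), axis=1)

    theta = config.nb_dispersion

    def _draw_small(mu: np.ndarray) -> np.ndarray:
        if np.isinf(theta):
            return rng.poisson(mu)
        return rng.negative_binomial(theta, theta / (theta + mu))

    # NB via its Poisson-gamma mixture on the big somatic block.
    if np.isinf(theta):
        counts_soma = rng.poisson(mu_soma)
    else:
        lam = rng.standard_gamma(theta, mu_soma.shape, dtype=np.float32)
        lam *= mu_soma
        lam /= np.float32(theta)
        counts_soma = rng.poisson(lam)
    if keep_prob is not None:
        counts_soma[rng.random(counts_soma.shape, dtype=np.float32) >= keep_prob] = 0
    counts_mito = _draw_small(mu_mito)

    counts = np.concatenate([counts_soma, counts_mito], axis=1)  # cells x genes
    assert soma_idx[-1] == len(genes) - len(mito) - 1  # mito genes are last
    rows, cols = np.nonzero(counts)
    indptr = np.concatenate([[0], np.cumsum(np.bincount(rows, minlength=n_total))])
    cells_by_genes = sp.csr_matrix(
        (counts[rows, cols].astype(np.int64), cols, indptr),
        shape=(n_total, len(genes)))
    cm = CountMatrix(cells_by_genes.T.tocsr(), list(genes), barcodes)
    metadata = pd.DataFrame({
        "barcode": barcodes, "sample_id": sample_ids,
        "age": ages, "timepoint": timepoints,
    })
    truth = GroundTruth(
        cell_types=pd.Series(true_types, index=barcodes, name="true_type"),
        qc_outliers=pd.Series(outlier, index=barcodes, name="qc_outlier"),
        gene_scales=pd.Series(gene_scale, index=[genes[i] for i in soma_idx],
                              name="gene_scale"),
        marker_sets=marker_sets,
        enriched_sets={"YOUNG_INFLAMMATORY_RESPONSE": age_genes},
        mito_genes=list(mito),
    )
    return cm, metadata, truth


def simulate_metabolites(config: SimulationConfig) -> tuple[MetaboliteTable, GroundTruth]:
    """Log-normal metabolite abundances with planted old-vs-young log2 folds."""
    rng = np.random.default_rng(config.seed + 1)
    effects = {name: (fc, sd) for name, fc, sd in config.metab_effects}
    unknown = set(effects) - set(config.metabolites)
    if unknown:
        raise ValueError(f"metab_effects refer to unknown metabolites: {sorted(unknown)}")
    n = config.metab_samples_per_group
    samples = [f"young_{i+1}" for i in range(n)] + [f"old_{i+1}" for i in range(n)]
    groups = pd.Series(["young"] * n + ["old"] * n, index=samples)
    baselines = 10.0 ** rng.uniform(3, 6, len(config.metabolites))
    if (baselines <= 0).any():
        raise ValueError("non-positive baseline abundance")
    rows = {}
    for met, base in zip(config.metabolites, baselines):
        fc, sd = effects.get(met, (0.0, config.metab_noise_sd))
        log2x = np.full(2 * n, math.log2(base))
        log2x[n:] += fc
        if sd > 0:
            log2x = log2x + rng.normal(0.0, sd, 2 * n)
        rows[met] = 2.0 ** log2x
    table = MetaboliteTable(pd.DataFrame.from_dict(rows, orient="index", columns=samples),
                            groups)
    truth = GroundTruth(metab_log2fc={m: effects.get(m, (0.0, 0.0))[0]
                                      for m in config.metabolites})
    return table, truth


def simulate_ecar_trace(config: SimulationConfig) -> EcarTrace:
    """Glycolysis stress-test traces: four phases x 3 measurements per well,
    replicate wells per age group, additive Gaussian noise."""
    if any(m < 0 for m in config.ecar_phase_means):
        raise ValueError("negative ECAR phase mean")
    rng = np.random.default_rng(config.seed + 2)
    from .containers import ECAR_PHASES

    rows = []
    protein = {}
    for group, scale in config.ecar_group_scale:
        for w in range(config.ecar_wells_per_group):
            well = f"{group}_w{w+1}"
            t = 0
            for phase, mean in zip(ECAR_PHASES, config.ecar_phase_means):
                for _ in range(config.ecar_measurements_per_phase):
                    val = mean * scale
                    if config.ecar_noise_sd > 0:
                        val += rng.normal(0.0, config.ecar_noise_sd)
                    rows.append({"well": well, "time_index": t,
                                 "phase": phase, "ecar": max(val, 0.0)})
                    t += 1
            protein[well] = max(rng.normal(15.0, 1.0), 1.0)
    return EcarTrace(pd.DataFrame(rows), pd.Series(protein))


def simulate_bead_counts(config: SimulationConfig) -> pd.DataFrame:
    """Per-cell phagocytosed-bead counts (Poisson), 3 wells per group."""
    rng = np.random.default_rng(config.seed + 3)
    rows = []
    for group, mean in config.bead_mean_per_group:
        for w in range(config.bead_wells_per_group):
            well = f"{group}_w{w+1}"
            beads = rng.poisson(mean, config.bead_cells_per_well)
            for c, b in enumerate(beads):
                rows.append({"group": group, "well": well, "cell": c, "beads": int(b)})
    return pd.DataFrame(rows)


def decoy_gene_sets(
    universe: Sequence[str], planted: dict[str, list[str]],
    n_decoys: int = 10, seed: int = 0,
) -> GeneSetCollection:
    """Planted enriched sets plus size-matched random decoy sets, for GSEA."""
    rng = np.random.default_rng(seed + 4)
    sets: dict[str, list[str]] = {k: list(v) for k, v in planted.items()}
    sizes = [len(v) for v in planted.values()] or [20]
    for i in range(n_decoys):
        size = sizes[i % len(sizes)]
        sets[f"RANDOM_SET_{i+1:02d}"] = list(rng.choice(list(universe), size=size, replace=False))
    desc = {k: ("planted" if k in planted else "size-matched random decoy") for k in sets}
    return GeneSetCollection(sets, desc)
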