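# Methods

`myomac` re-implements, as a tested pipeline, the computational analysis of a
muscle disuse–recovery immune-profiling study design: CD45+ single-cell
transcriptomes from six pooled samples (young/old × ambulatory control /
14-day hindlimb unloading / 4-day reload), followed up by macrophage
functional assays (glycolysis stress test, phagocytosis, targeted GC-MS
metabolomics). Because the real accession is not required, a first-class
synthetic-data module generates every input with known ground truth; all
statements below about recovery rates are computed by the test suite and
`scripts/acceptance.py`, never assumed.

## Synthetic study design (`myomac.simulate`)

**Reference panel.** `make_reference` builds an ImmGen-like compendium:
cell types × genes, baseline signal 1.0, each type's markers elevated
`marker_fold`-fold (default 8) with *disjoint* marker sets so planted
identity is unambiguous, and four pan-macrophage genes (Cd68, Cd86, Adgre1,
Csf1r) elevated 4-fold in every macrophage subset. The default 8 populations
include the four macrophage subsets distinguished by Il1b, Ccl8, Spp1 and
S100a9; the panel scales to 24 types.

**Counts.** Each cell's expected somatic expression is its true type's
reference row times a per-gene lognormal detection-efficiency factor
(sd 0.75). The efficiency factor reproduces the order-of-magnitude baseline
heterogeneity of real UMI data — a *normalized* reference signal of 1.0
does not mean every gene is captured equally — and is what makes
mean-binned dispersion statistics meaningful. Counts are negative-binomial
(inverse dispersion θ = 10; θ → ∞ gives the Poisson limit) via the
Poisson–gamma mixture, with a lognormal per-cell library-size factor
(median 2,000 counts, sd 0.3 log-units). Dropout is Bernoulli with
probability logistic in the log of the expected count (midpoint 0.5 counts,
slope 1), applied to somatic genes.

**Mitochondrial structure and QC outliers.** Each cell draws a mito
fraction from Beta(10, 190) (mean 5%); the 13 mouse MT protein-coding genes
split that fraction of the *expected post-dropout* library, so the observed
mito fraction is unbiased for the drawn one. A 5% outlier fraction is
planted deterministically outside the default QC window: half at fraction 0
("low-mito" debris), half uniform on 0.30–0.60 ("high-mito" dying cells).

**Age effect.** 40 background genes are upregulated 2-fold in *young
macrophage* cells — the young-enriched inflammatory program the GSEA stage
is designed to detect; their identities are recorded in the ground truth
and exported as a GMT set alongside size-matched random decoys.

**Metabolites, ECAR, beads.** The 14-metabolite glycolysis/TCA panel is
log-normal per metabolite (baselines 10³–10⁶), with planted old-vs-young
log2 folds: succinate −1; glucose, glycerol-3-phosphate and
sedoheptulose-7-phosphate +1; noise sd 0.1 log2-units; 4 samples per age
group. ECAR traces have four phases (baseline, glucose, oligomycin, 2-DG) ×
3 measurements × 4 wells per group, phase means (10, 30, 50, 8) mPH/min,
Gaussian noise sd 1, and an old-group scale of 0.6 emulating suppressed
glycolysis. Bead counts are Poisson per cell (young mean 2.5, old 1.2), 200
cells × 3 wells per group.

**Scale.** Defaults emulate the study at reduced depth: 300–500 cells per
sample (~2,400 total) instead of 1,700–3,700, so the full pipeline runs in
seconds; `SimulationConfig.paper_scale()` restores the original depth and
24 populations. Every generator is a pure function of (config, seed).

What the generator does *not* model: ambient RNA, doublets, batch effects
beyond library size, read-level noise, cell-type-specific library sizes, or
correlated gene programs beyond the planted ones. Passing tests therefore
demonstrate correctness of the algorithms under the stated noise model, not
performance on real tissue data.

## QC and normalization (`myomac.qc`)

Cells are filtered on mitochondrial fraction (defaults 0.5%–15%, a
repository choice bracketing common practice — the underlying protocol
states the filter without thresholds) and on total counts (≥ 200).
Zero-count cells fail QC by contract. Normalization is
ln(1 + 10⁴·count/total). Highly variable genes: dispersion = variance/mean
of the de-logged values, z-scored within 20 quantile bins of the mean,
ties broken by gene ID; constant genes are ranked last unconditionally.

## Clustering (`myomac.clustering`)

Cells are embedded on the top 20 PCs of the standardized HVG expression
(full SVD; deterministic sign convention: each component's
largest-magnitude loading is positive). kNN (k = 20) uses exact all-pairs
Euclidean distances with stable index tie-breaking. SNN edge weights are
Jaccard overlaps of self-inclusive neighbor sets, pruned below 1/15.
Communities come from greedy Louvain-style maximization of

    Q(γ) = Σ_c [ w_c/W − γ·(s_c/2W)² ],   γ = 0.8 by default,

with seeded node-visit order, move-then-aggregate passes, and Q tracked
incrementally (the final Q is recomputed from scratch and must agree to
1e-10 — a standing unit test). k, prune and γ mirror the defaults of the
standard single-cell toolkit, since the protocol names none. Exact
modularity maximization is NP-hard; the greedy optimum is the accepted
practice. Greedy moves are not equivariant to node relabelling in general;
on well-separated data (the two-clique toy, the default simulation) the
recovered partition is relabelling-invariant and tests assert this there.

## Marker detection (`myomac.markers`)

One-vs-rest Wilcoxon rank-sum per cluster. Exact p by enumeration of all
rank assignments when the pooled size is ≤ 10 (ties handled by mid-ranks);
otherwise the normal approximation with tie and continuity correction (the
vectorized per-gene path is tested to match the scalar scipy-backed one to
1e-10). Effect size d = ln(mean de-logged + 1)_in − ln(… )_out. Genes are
tested when expressed in ≥ 10% of either side and |d| ≥ 0.25;
Benjamini-Hochberg runs within each cluster's tested set. Clusters under 3
cells are excluded and recorded.

## Identity scoring (`myomac.cipr`)

Reference log-ratios r_{c,g} = ln(S_{c,g} / mean_c' S_{c',g}) — positive
for genes above the panel average in type c. A cluster's score against
type c is I_{k,c} = Σ_g d_{k,g}·r_{c,g} over its significant DE genes
(adjusted p < 0.05, no top-N cap by default) present in the panel; genes
missing from the panel are counted and skipped. Concordantly regulated
genes add, discordant ones subtract. Assignment is the argmax with
lexicographic tie-break; a cluster is flagged *ambiguous* when the margin
over the runner-up is below 10% of the top score or the top score is ≤ 0,
and *unassignable* when no gene contributed. The scoring is bilinear: it is
invariant to per-gene positive rescaling of the panel (hence to the
synthetic detection-efficiency factors) and equivariant in d. A
`merge_clusters` utility supports the manual curation step of collapsing
indistinct subsets (e.g. the four macrophage clusters); no automatic merge
criterion is provided because that judgement is the analyst's.

## Preranked GSEA (`myomac.gsea`)

Genes are ranked by the signal-to-noise metric
s = (μ_A − μ_B)/(σ_A + σ_B), each group's σ floored at
max(σ, 0.2·|μ|, 1e-8) (the classical convention, inherited silently by
most GSEA tooling). Enrichment is the weighted (weight = 1)
Kolmogorov-Smirnov running sum: hits advance by |s|/Σ_hits|s|, misses
retreat by 1/(N − N_hit); ES is the signed maximal deviation, the leading
edge the hits at or before (after, for negative ES) the extremum. The null
is *gene permutation*: n_perm (default 1000) random size-matched sets from
the ranked universe, shared across same-size sets within a call;
p = (1 + #{same-sign null at least as extreme})/(1 + #{same-sign null}),
NES = ES / mean|same-sign null ES|, BH across sets. Phenotype permutation
would require re-ranking per relabelling and is out of scope. A property
worth knowing: under gene permutation, NES *saturates* for extreme planted
effects — very large planted |s| values inflate the null sets that happen
to contain them — so NES is monotone in effect size only up to moderate
shifts; ES keeps increasing. Positive NES means enriched in group A
(young, in the pipeline's young-vs-old contrast).

## Metabolomics (`myomac.metabolomics`)

The fixed chain is median normalization (each sample divided by its
median), the generalized log transform
glog2(x) = log2((x + √(x² + λ²))/2) with λ defaulting to the table's
minimum positive value / 10 (CLI-overridable), then Pareto scaling
((x − mean)/√sd per metabolite; zero-variance rows map to zeros). Each
container carries a provenance chain and every step rejects re-application,
preventing silent double transformation. Hierarchical clustering is Ward on
Euclidean distances (scipy), exported as Newick. The volcano contrast
computes fold changes on the *median-normalized* scale (old/young group
means) and Welch t-tests on the *glog2* scale; a metabolite is significant
when FC ≥ 1.5 or ≤ 1/1.5 (boundary inclusive) and nominal p < 0.05.
Adjusted p is reported alongside but does not drive the flag, matching the
stated 1.5-fold/p < 0.05 rule; both are in the output.

## Bioenergetics (`myomac.bioenergetics`)

From a glycolysis stress test: non-glycolytic acidification = min of the
2-DG phase; glycolysis = max ECAR after glucose − last baseline
measurement; glycolytic capacity = max ECAR after oligomycin − last
baseline; reserve = capacity − glycolysis, an exact identity preserved
under protein normalization (all four metrics divided by µg protein).
Max-after-injection with last-pre-injection baseline is the stress-test
kinetics convention; a mean-of-phase mode is provided because the exact
aggregation variant is not recoverable from the protocol text. Phagocytosis
uses the well as the experimental unit: group mean = mean of per-well mean
beads/cell.

## Pipeline (`myomac.pipeline`, `myomac.cli`)

`run-all` executes simulate → QC → cluster → markers → identify → GSEA plus
the metabolomics and bioenergetics branches from one validated config
(unknown keys rejected, all violations listed at once). The global seed
fans out to stages by fixed offsets (simulate +0, cluster +101, GSEA +202),
so stages are independently reproducible and a fixed seed yields
byte-identical outputs. Stage wall-clock goes to the run log only;
`report.json` is fully deterministic.

## Numerical and degenerate-input choices

- Wilcoxon exact/asymptotic switch at pooled n = 10; p clipped to (0, 1].
- All-tied samples: rank-sum σ = 0 → p = 1.
- ES with all-zero hit scores: hits fall back to equal weights.
- GSEA with no same-sign null draws: p = 1, NES = 0 (plus-one convention
  makes this unreachable at n_perm ≥ 100 in practice).
- PCA on an all-constant matrix is an error; individually constant genes
  are centered and left unscaled.
- kNN ties (including duplicate points) resolve by cell index via stable
  sort; Louvain move ties prefer the current community, then the lowest
  community id.
- Pareto scaling of a constant metabolite returns zeros, not NaN.
- Volcano p-values are floored at the smallest positive double before BH.

## Problem sizes used by the tests and acceptance script

The default simulation (~2,400 cells × 2,000 genes) is used for the
20-seed identity-recovery and ARI sweeps and the end-to-end determinism
check; reduced designs (4 types, 300–600 genes, ~400–600 cells) back the
statistical-calibration simulations (GSEA power at n_perm = 1000 over 50
seeds, volcano power/type-I over 200 seeds, marker type-I over permuted
labels). These sizes were chosen so the statistical assertions have narrow
Monte-Carlo error while the whole suite stays interactive.

## Known limitations

- The synthetic noise model is deliberately simple; none of the acceptance
  properties certify behavior under batch effects, doublets or ambient RNA.
- The gene-permutation GSEA null is anti-conservative for correlated gene
  sets (correlation between set members is not modeled by random sets);
  the planted sets here are conditionally independent given type and age.
- Louvain finds a local optimum; only the toy cases carry a brute-force
  optimality certificate.
- The identity scorer needs the reference panel and the count matrix to
  share gene identifiers; no ortholog or alias mapping is attempted.
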