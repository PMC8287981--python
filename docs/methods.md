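# Methods

This note documents the models and procedures behind `cafpaths`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Synthetic data model

`cafpaths.syndata` simulates a matched tumour/normal single-cell dataset
with a known answer. Counts for gene *g* in cell *c* are negative
binomial,

    K_gc ~ NB(mean = mu_gc * L_c, var = mean + phi * mean^2)

with per-gene/cell mean `mu_gc`, a log-normal library-size factor
`L_c = exp(N(0, sigma_lib^2))`, and a dispersion `phi`
(`nb_dispersion`, default 0.4) shared across genes; `phi = 0` reduces to
Poisson. Sampling uses the gamma–Poisson mixture, so the `phi -> 0` limit
is exact.

Genes fall into disjoint marker programs (fibroblast, epithelial, immune,
endothelial, CAF-related, BM-MSC, myCAF, iCAF, plus the single-gene
*PRRX1* activation program and the two-gene HSC program) and a background
majority. The mean is

    log mu_gc = log(baseline_mean) + w_pc * log(marker_fold_change)

for a marker gene of program *p* active in cell *c* with weight
`w_pc in [0, 1]`, `log(baseline_mean)` for background genes, and
`log(offstate_mean)` for marker genes of inactive programs.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_cells_tumour` / `n_cells_normal` | 2500 / 2500 | ~5,000-cell desk-scale dataset |
| `fibroblast_fraction` | 0.08 | fibroblasts are a <10% minority of mixed-tissue data |
| `caf_composition` | non-paCAF 0.35, iCAF 0.35, myCAF 0.30 | paCAFs (iCAF+myCAF) are 50–80% of CAFs; 65% sits mid-band |
| `nf_composition` | tr-RF 0.60, tr-MSCF 0.40 | resting fibroblasts dominate normal tissue |
| `n_genes` / markers per program | 2000 / 25 | desk-scale transcriptome with realistic marker panel sizes |
| `baseline_mean` | 0.3 | sparse counts (~25% detection), typical of droplet data |
| `offstate_mean` | 0.001 | lineage-defining markers are essentially absent outside their lineage; see below |
| `marker_fold_change` | 8 | strong but not degenerate marker contrast |
| `library_size_lognormal_sigma` | 0.2 | moderate depth variation |
| `continuum_noise_sd` | 0.2 | per-cell, per-program jitter on the continuum log-mean |
| `logistic_steepness` | 12 | smooth but distinct program transitions along the continuum |
| `n_samples_per_tissue` | 1 | the clustering unit is the whole per-dataset CAF (resp. NF) set |

`offstate_mean` deserves a comment: the step-2 exclusion threshold
(0.25 on the log1p-CP10K scale) is below the normalized value of a single
count, so step 2 effectively excludes any cell with a nonzero lineage
marker. That is only a sane screen if lineage markers really are
(near-)absent outside their lineage, which is the biological reality for
genes like *EPCAM* or *PTPRC*; planting them at the generic background
rate would make almost every true fibroblast show a stray count in some
exclusion marker. The default off-state mean of 1e-3 leaves ~1–3% of true
fibroblasts excluded — the "strict procedure loses some real fibroblasts"
behaviour expected of this screen.

**Continuum.** tr-MSCF, iCAF, myCAF (and optional BM-MSC) cells carry a
latent pseudotime *t*, drawn uniformly from staggered windows
(BM-MSC 0–0.12, tr-MSCF 0.02–0.30, iCAF 0.38–0.62, myCAF 0.70–0.98).
Program activities are logistic in *t* with steepness *s* = 12:

* iCAF program: `w = sigmoid(s * (0.66 - t))` — decreasing, high at the root;
* myCAF program: `w = sigmoid(s * (t - 0.66))` — increasing;
* BM-MSC program: `w = 0.5 + 0.5 * sigmoid(s * (0.34 - t))` — highest near
  `t = 0` and floored at half activity, because CAFs (paCAFs) retain
  elevated MSC-marker expression relative to resting fibroblasts. The
  floor is what makes the myCAF → tr-MSCF origin correlation
  identifiable: without it a late-pseudotime myCAF cluster would share no
  elevated program with tr-MSCFs beyond the pan-fibroblast one.

The gaps between pseudotime windows keep the subtypes clusterable while
preserving a monotone continuum; window boundaries, not cluster labels,
define the planted ordering.

A single `numpy` Generator is seeded once per call and consumed in a
fixed order (cell types → sample assignment → pseudotimes → continuum
noise → library factors → counts), so identical configs and seeds give
byte-identical datasets.

**What the generator does not emulate:** doublets, ambient RNA,
batch/chemistry effects, mitochondrial stress signatures, gene–gene
correlation beyond the program structure, and branched trajectories.
Passing tests therefore show that the pipeline's logic is correct under
its stated assumptions, not that it is robust to every artefact of real
droplet data.

## Normalization and QC

Counts are library-size normalized to 10,000 per cell and log1p
transformed (`value = log(1 + 1e4 * count / total)`); all-zero cells pass
through as zeros with a warning. QC keeps cells detecting at least
`min_genes_per_cell` genes (default 200), then genes detected in at least
`min_cells_per_gene` cells (default 3) — cells first, then genes, so the
result is order-deterministic.

## Two-step fibroblast identification

All cells are embedded by PCA (top 2,000 most variable genes,
standardized, 20 components) and clustered by k-means with
`coarse_k = 10`. A cluster is a fibroblast candidate iff its mean
fibroblast-marker score exceeds the across-cluster mean of cluster scores
by at least `step1_margin = 1.0` standard deviations (population SD over
cluster means; ties at zero SD never qualify). Within candidate clusters,
a cell whose normalized expression of any epithelial/immune/endothelial
marker exceeds `step2_max_norm_expr = 0.25` is excluded, with the highest
offending marker recorded. Cells are processed in lexicographic barcode
order internally, so calls are invariant to input order.

## Per-sample clustering and the elbow rule

Fibroblasts are embedded once (PCA as above) and clustered per sample.
For each k in 1..10, k-means runs with 10 restarts plus one warm-started
candidate built from the best (k-1)-solution's centroids and the
worst-fit point; taking the best of these guarantees a non-increasing
SSE(k) curve by construction. The chosen k is the smallest k after which
every relative drop `(SSE(k) - SSE(k+1)) / SSE(k)` stays below
`drop_threshold = 0.10`; if drops never level off, k_max is returned with
a warning. A useful rule of thumb: splitting a pure noise cluster in a
*d*-dimensional embedding drops SSE by roughly `0.64 * lambda_max / d`
(with `lambda_max` the top sample-covariance eigenvalue spread), so the
0.10 threshold at 20 components tolerates noise splits while catching
real structure.

## Signature scoring and taxonomy

A cell's score for a gene set is its mean normalized expression over the
set's matched genes; a cluster's score is the **median** of member-cell
scores (mean available behind a flag). The taxonomy rules:

* **paCAF**: a tumour cluster whose activation (*PRRX1*) score *and*
  CAF-related score both exceed the across-tumour-cluster mean by
  `high_margin_sd = 0.5` SDs. With a single tumour cluster the margin
  rule is vacuous; an absolute floor of 0.5 (log1p-CP10K) on both scores
  applies instead — ~an order of magnitude above the background score of
  a silent gene set at typical depth.
* **tr-MSCF**: a normal cluster whose BM-MSC score stands out the same
  way *and* whose HSC score is at most `low_ceiling = 0.1`; other normal
  clusters are tr-RF.
* **myCAF vs iCAF**: each paCAF cluster's per-cell (myCAF − iCAF) score
  difference is compared with the pooled differences of the other paCAF
  clusters by a two-sided rank-sum test; the cluster is labelled by the
  sign of its cluster-level score difference when `p < alpha = 0.05` and
  it has ≥ 3 cells, else left unassigned. No multiple-testing correction
  is applied: the comparisons are few and confirmatory. A single merged
  paCAF cluster is first re-clustered (k = 2) in its *own* PCA embedding
  over ~100 subset-level variable genes — within the paCAF subset the
  most variable genes are the subtype programs, so this narrow embedding
  carries the myCAF/iCAF contrast that the global embedding dilutes
  across noise dimensions.

## Rank statistics

The rank-sum test is Mann–Whitney U on midranks: exact null enumeration
when the pooled sample size is ≤ 12 with no ties (two-sided p =
`P(|U - mu| >= |u - mu|)`, which equals the doubled tail for the
symmetric null), otherwise the normal approximation with tie correction
and a 0.5 continuity correction. Spearman's rho is the Pearson
correlation of midranks. Both are validated in the test suite against
independent oracles (scipy's exact enumeration, a permutation test, and
rank-then-Pearson).

## Origin tracing

Cluster centroids are per-gene **mean** normalized expression over member
cells, correlated by Spearman over the top 2,000 variable genes (variance
pooled over all fibroblasts). The median variant exists but is degenerate
at scRNA-seq sparsity: with most per-gene medians tied at zero or one
count, median centroids reduce Spearman to the tie structure and origin
calls become near-coin-flips, so the mean is the default. "Exclusive"
correlation is operationalized as best-match rho exceeding the runner-up
by `delta = 0.05`; with a single reference cluster the gap is undefined
and reported as such. BM-MSC clusters, when present, enter as additional
reference columns.

## Principal-curve pseudotime

The trajectory cells are those in tr-MSCF, iCAF and myCAF clusters
(plus BM-MSC-like when present), in the fibroblast PCA embedding. The
curve is fitted Hastie–Stuetzle style: initialize the parameterization by
projection on the first principal component, then iterate { sort by
parameter; smooth each coordinate against the parameter by lowess
(`smooth_span = 0.3` of points, zero robustifying iterations);
reparameterize by arclength; project all points orthogonally onto the
polyline } until the mean squared projection distance changes by less
than `tol = 1e-6` or 50 iterations. Exact parameter ties are broken by a
rank-proportional jitter of 1e-9 of the parameter range; the polyline is
decimated to ≤ 512 vertices. The fitter is deterministic.

Pseudotime is the min–max normalized arclength of each cell's projection,
oriented so the root population's median is at the low end; absolute
scale is meaningless and never compared across runs. Ordering claims
(myCAF later than iCAF, iCAF later than tr-MSCF) are rank-sum tests on
pseudotime. When BM-MSC cells join the trajectory, a crude batch
alignment first matches the per-gene mean of non-marker (background)
genes between the BM batch and the tissue cells before a joint
re-embedding; this removes a constant per-gene offset and nothing
subtler, and is documented as a stand-in for proper batch integration.

Branched trajectories (e.g. a second direct tr-MSCF → myCAF route) are
out of scope; the fitter models a single lineage.

## Pipeline and reproducibility

`run_all` executes simulate/ingest → QC/normalize/identify → cluster →
classify → origin → trajectory, writes every stage's tables, and emits a
JSON report (fibroblast fraction, chosen k per sample, paCAF share of
CAFs, taxonomy, origin calls, ordering tests, plus recovery metrics
against ground truth when simulating). One top-level seed fans out to
per-stage seeds by fixed offsets; identical config + seed reproduces the
report byte for byte. Stage failures abort with the stage name (e.g. a
config without normal tissue fails in `classify` with an informative
error).

Problem sizes: the default study conditions use ~5,000 cells and 2,000
genes per run; the test suite's unit fixtures use ~2,000-cell simulations
with 800 genes, and the multi-seed stability checks run the full default
pipeline 20 times.

## Known limitations

* Step-1/step-2 thresholds and marker panels are declared defaults, not a
  reproduction of any specific study's (unpublished) criteria; panels are
  overridable via YAML.
* The elbow criterion is one precise formalization of "optimal k by SSE";
  other formalizations (gap statistic, silhouette) may choose different k
  on the same curve.
* The margin-over-mean rules assume the informative clusters are a
  minority; when most clusters are of one class the across-cluster SD
  inflates and calls become conservative.
* Pseudotime recovers ordering, not time; the reported values are only
  comparable within a run.
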