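# Methods

phosnet analyzes two-group (control vs. mutant) quantitative proteomics and
phosphoproteomics experiments: differential abundance with fold-change
thresholds expressed in Gaussian-fitted SD units, protein-normalized kinase
activity inference from predicted substrate sets, signed weighted
co-expression modules, and gene-set enrichment. This note documents the
statistical models, the defaults and why they were chosen, the synthetic-data
generator used for validation, and the numerical and design decisions that
were genuinely open.

## Differential abundance

Intensities are analyzed on the log2 scale. Preprocessing log-transforms raw
intensities (or accepts already-log2 data), drops features observed in fewer
than `min_nonmissing_per_group` samples per group (default 2), and imputes
the rest. The default imputation is half-minimum — each missing cell gets
half the feature's smallest observed intensity, i.e. its log2 minimum minus
one — a standard choice for abundance-biased missingness in proteomics;
per-feature-minimum, group-minimum and no-imputation variants are available,
and the choice is recorded in the output provenance.

Per-feature statistics are empirical-Bayes moderated t statistics. The
pooled two-group variance s² with d residual degrees of freedom is shrunk
toward a prior (d₀, s₀²) estimated by moment matching on log s²: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess dispersion
var(e) − mean(ψ′(d_g/2)) determines d₀ through the inverse trigamma
(solved by bracketed root finding), and s₀² follows from mean(e). The
posterior variance is s²_post = (d₀s₀² + d s²)/(d₀ + d),
t = log2FC / (s_post·√(1/n₁+1/n₂)), and p comes from a t distribution with
d₀ + d degrees of freedom. When the variances show no excess dispersion, d₀
is capped at 10⁶, which reproduces the fixed-prior limit.

Fold-change thresholds are expressed in units of the SD of a Gaussian fitted
to the bulk of the log2FC distribution. The default fit is maximum-likelihood
on values within the 1st–99th percentile, multiplied by the analytic
correction for the variance lost to truncation, so that pure Gaussian data
is estimated without bias while a minority of genuinely differential
features inflates the estimate only mildly. Plain-SD and
normal-consistent-MAD variants are selectable.

A feature is called up if log2FC > k·SD (strictly) and its significance gate
passes; down symmetrically; null otherwise. Two gates are supported:
BH FDR < 0.05 with k = 2 (the default for proteome-wide data), and
p < 0.05 with k = 1.5–2 plus a dataset-level permutation gate (the mode used
for smaller interactome-style tables). k, the cutoffs and the mode are
configurable per dataset.

The permutation FDR of the selected set is mean(N_b)/O, where O is the
number of features selected on the true labels and N_b the count under each
balanced group-label relabeling (exhaustive when the number of distinct
relabelings is at most n_perm — 70 for a 4v4 design — otherwise seeded
sampling). By default the fold-change SD is refit inside every permutation,
which keeps the null self-consistent but is deliberately conservative: the
refit threshold shrinks along with the permuted contrast, so features with
strong real effects keep passing it and the estimate cannot approach zero
even for clean signal. A SAM-style alternative (`refit_sd=False`) holds the
observed-fit threshold fixed across permutations and lets strong signal
drive the estimate down; the choice is recorded in the run summary. When
O = 0 the estimate is reported as not applicable rather than zero.

## Kinase-substrate scoring and activity

Phosphosite analysis uses sites with a ±7-residue sequence window
(15 characters, acceptor at the center). Stably phosphorylated sites — the
lowest-variance fraction (default 10%) after per-sample median centering —
serve as negative-control anchors for batch correction, which removes
additive batch offsets estimated on the stable sites, anchored to the first
batch so the operation is exactly idempotent and a single-batch dataset
passes through unchanged.

Protein-level normalization subtracts the parent protein's per-sample
profile from each site (log-space subtraction), and significance is
recomputed by the moderated t on the difference profiles. Sites whose
parent protein is undetected keep their unnormalized statistics and are
flagged.

Each (site, kinase) pair receives:

* a **motif score**: mean per-position log-odds of the window under the
  kinase PSSM against a uniform background, mapped to (0, 1] as the
  average-rank percentile among all scored windows for that kinase;
* a **profile score**: (r+1)/2, where r is the Pearson correlation between
  the site's standardized across-sample profile and the kinase centroid
  (the standardized mean profile of its annotated substrates);
* a **combined score**: the weighted geometric mean motif^w·profile^(1−w)
  (w = 0.5 by default), which is monotone in both components and zero if
  either component is zero.

Substrate prediction is an adaptive-sampling positive-unlabeled ensemble:
annotated substrates are positives; in each of B = 50 rounds,
pseudo-negatives (one per positive) are drawn from the unlabeled sites with
probability proportional to a sampling weight initialized to 1 − combined;
an L2-regularized logistic classifier on (motif, profile, combined) scores
all sites; the weights are then multiplied by one minus the running mean
probability, steering later rounds away from sites the ensemble already
considers substrates. The PU probability is the mean positive-class
probability across rounds. Kinases with fewer annotated positives than
features + 1 fall back to ranking by the combined score.

Kinase activity is computed on the top-N predicted substrates (N = 200 by
default, 400 intended for a primary kinase of interest; the ranking key —
PU probability or combined score — is configurable). Sites are first
assigned competitively, each counting only toward the kinase that scores
it highest, so strong substrates of one kinase cannot leak signal into
another kinase's set. The activity score is the mean protein-normalized
fold change of the substrate set in SD units of all scored sites. The
direction call uses a two-group t-test on the per-sample mean substrate
difference profile: testing at the sample level is calibrated against
substrate-selection effects (a set selected for correlation with a noisy
centroid is biased along it, which makes the naive site-level one-sample
t-test anti-conservative), while the site-level one-sample test is still
reported (`p_site`). The per-sample aggregate is the plain mean of the
difference profiles: per-site z-scoring before averaging would divide each
site by a variance that includes its own group effect and shrink true
signal; a standardized variant is kept for heatmap display.

Consensus-substrate mapping intersects detected sites with a kinase's
annotated substrates and classifies each at deliberately relaxed
thresholds (FDR < 0.2, |fc| > 1·SD by default) into trend-up, trend-down
or flat.

## Signed co-expression networks

The network is signed: a_ij = ((1 + cor(x_i, x_j))/2)^β, so anti-correlated
features are unconnected. Features with more than 20% missing values or
zero variance are excluded; correlations use complete pairwise observations.
The soft-threshold power is the smallest β (scanned over 1–20) whose signed
scale-free fit reaches R² ≥ 0.85 while the mean connectivity stays below
100. The fit bins connectivity into 10 equal-width bins and regresses
log10(frequency) on log10(mean k) over non-empty bins, with
signed R² = −sign(slope)·R² so only decreasing degree distributions can
reach the target. When no power qualifies, the scan falls back to the
standard sample-size default for signed networks (power 18 below 20
samples), restricted to powers that keep the mean connectivity in bounds;
the fallback is announced with a warning and recorded. On few-sample data
with a small number of planted blocks the degree distribution is a mixture
of a null bulk and module plateaus rather than a power law, so the R²
target is typically unreachable there — the scan quantities are always
reported so the fit quality is visible.

The signed topological overlap is
TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), with unit
diagonal; modules are detected on 1 − TOM by average-linkage hierarchical
clustering with an adaptive valley cut: the dendrogram is cut at the
midpoint of the widest low-density run of merge heights (branch-internal
merges form a dense low band, background merges a dense high band).
There is no PAM-style reassignment, so module membership adheres strictly
to the dendrogram; clusters below the minimum size (default 50) stay
unassigned, and a dendrogram with no density valley leaves everything
unassigned. Module eigengenes are the first principal component of the
standardized module expression across samples, sign-aligned so the
eigengene correlates non-negatively with the module mean profile; modules
whose eigengenes correlate above 1 − merge_cut (default 0.25) are merged
iteratively, recomputing after each merge. A branch over-split by the cut
is rejoined at this stage.

Module–trait association is the Pearson correlation of each eigengene with
the numeric trait (control = 0, mutant = 1) with a two-sided p-value from
the t distribution with n − 2 degrees of freedom. Per-feature module
membership (MM) is the correlation with the own-module eigengene; peptide
significance (PS) is the signed correlation with the trait. Hubs are
assigned features with MM ≥ 0.8 and |PS| ≥ 0.5 (both configurable — the
cutoffs are this package's defaults, not canonical values), ranked by
MM·|PS|. PS is defined as a correlation rather than a transformed DE
statistic; that is one documented reading of "peptide significance".

## Enrichment and sample QC

Over-representation uses the hypergeometric upper tail
P(X ≥ k | N, K, n) per term against a user-supplied GMT collection, with
the universe defaulting to all detected features (standard for proteomics
ORA) and BH adjustment across terms. GSEA ranks features by a score
(e.g. log2FC), computes the weighted Kolmogorov–Smirnov running sum
(weights |score|), takes the signed maximum deviation as ES, and builds the
null from seeded gene-label permutations — a deliberate divergence from
sample-permutation GSEA, since stage inputs are precomputed rankings.
NES = ES / mean |null ES| over same-sign nulls; the permutation p counts
same-sign nulls at least as extreme with denominator n_perm + 1 (slightly
conservative when the null splits across signs, and exactly 1/(n_perm+1)
for a maximally enriched set). BH is applied within each analysis only.

PCA sample screening standardizes features, projects samples on PC1–PC2,
and flags samples farther from their group's coordinate-wise median
centroid than k_sd (default 3) times the median within-group distance.
The median centroid keeps one outlier from dragging the centroid toward
itself in small groups. Flags are reported, never silently applied.

## The synthetic-data generator

The generator emulates the statistical structure this pipeline assumes,
with known ground truth:

* protein log2 intensities = baseline (N(25, 2²)) + module latent factor ×
  per-protein loading (U(0.5, 1.5) × latent_strength 2.0) + group effect for
  truly differential proteins (±effect_log2fc, default 2.0) + optional batch
  offsets + N(0, noise_sd²) residuals, noise_sd 0.5 by default — chosen as a
  plausible replicate SD for DIA-style data and fully configurable;
* the default design is 4 replicates per group, 2000 proteins, 10% truly
  differential;
* three latent-factor modules (200 proteins each by default); the factors
  are orthogonalized across samples because with few samples independently
  drawn factors are often strongly correlated by chance and two planted
  modules genuinely coalesce — orthogonality is what "distinct modules"
  means at small n. The first module's factor carries a trait component
  (association 3.0) so one module is trait-linked;
* phosphosite log2 intensities = parent protein profile + site offset +
  kinase shift × trait (substrates of shifted kinases only) + site residual.
  The site-specific residual defaults to noise_sd/2: a site measured in the
  same run shares most of the parent protein's measurement error, so its
  independent component is smaller. Kinase shifts are absolute log2
  quantities; the default shifts the first kinase up and the second down by
  1 × noise_sd;
* windows of true substrates are drawn from the kinase's PSSM (all mass on
  S/T at the center; off-center positions put 1/20 + (1−entropy)·19/20 on a
  kinase-specific residue, uniform at entropy 1); other windows come from a
  uniform background with an S/T/Y acceptor mix;
* missingness is MCAR by default (rate 0 unless configured); a
  left-censored option makes low intensities more likely to be missing;
* `SimConfig.null()` produces a fully exchangeable null — no DE, no kinase
  shifts, no block correlation — under which per-feature test statistics
  are independent and exactly null-distributed.

What the generator does **not** emulate: peptide-to-protein rollup,
intensity-dependent variance (variance is homoscedastic on the log2
scale), real amino-acid background frequencies (uniform by default),
multiply-phosphorylated peptides, and correlated (non-MCAR beyond the
left-censoring option) missingness. Tests passing on this generator show
the statistical machinery is correct and calibrated under its assumptions;
they do not certify performance on real data whose noise violates them.

## Validation problem sizes

The test suite validates exact statistics against brute-force oracles on
≤10-feature fixtures (tolerance 1e-10) and the stochastic properties at the
design sizes: null calibration on 20 simulated proteomes (2000 × 4v4), DE
recovery over 10 seeds, kinase recovery (30 substrates/kinase among 1000
sites) over 10 seeds, and module recovery (3 modules, 2000 proteins, 8
samples) over 10 seeds. `scripts/acceptance.py` recomputes the same
quantities at 5–10 seeds per scenario and 300 ORA null draws; these sizes
give stable estimates while keeping a full run in minutes on one core.

## Known limitations

* With 8 samples the sample space has ~8 dimensions: a power-law degree
  distribution (scale-free R² ≥ 0.85) and crisply separable planted modules
  cannot coexist, so on the module-recovery data the soft-threshold scan
  always uses its documented fallback. Real tissue proteomes, with a
  continuum of co-expression, do reach the target.
* Background features that correlate with a module eigengene by chance at
  small n are statistically indistinguishable from members; module
  assignments therefore carry an irreducible false-member rate that shrinks
  with sample count.
* The permutation FDR with per-permutation SD refit is conservative by
  construction (see above); use the fixed-threshold variant when an
  anti-conservative null is acceptable.
* Two-group designs only; no multi-factor models, no consensus networks,
  no module preservation statistics.
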