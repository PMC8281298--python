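# Methods

This note documents the models and procedures methyltraj implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Study design and data model

The package targets a bulk differentiation time course assayed on a
two-chemistry methylation bead array: `n_stages` cell stages (default 4,
e.g. stem cells → neural precursors → maturing neurons at two time points)
with `replicates_per_stage` technical replicates (default 4, so 16
samples). Methylation at each CpG is summarized as a beta value
β = M/(M+U+100); the offset 100 is the array-ecosystem convention and keeps
β well-defined at low intensity.

## Synthetic data generator

`datasets.simulate_study` emits everything downstream stages consume, with
ground truth for recovery tests.

- **Latent time.** Each stage sits at an equally spaced latent time
  t ∈ [0,1]; replicates get Gaussian jitter (sd 0.01, clipped to [0,1]).
  The jitter makes within-stage samples distinguishable (and k-means
  well-posed); it is a free parameter of the generator, not an inference
  about real replicate variability.
- **Trajectory loci.** A fraction `frac_associated` (default 5%) of probes
  follow one of nine shape templates on [0,1] (linear up/down, early
  drop, late rise, sigmoid up/down, steep early drop, transient
  peak/dip), scaled to mean curve μ(t) = base + amp·(f(t) − ½) with
  base ~ U(0.35, 0.65) and amp ~ U(0.3, 0.6). Remaining probes are flat
  with the bimodal baseline typical of arrays.
- **Noise** is added on the logit scale with a delta-method sd
  (`noise_sd`/(μ(1−μ)), default `noise_sd` = 0.03 on the beta scale), so
  emitted values respect [0,1] without clipping artifacts.
- **Intensities.** M = βT + o, U = (1−β)T + o with per-entry gamma total
  T (mean 5000, CV 0.15) and an additive type-I brightness offset
  (o = 200); detection p ~ Beta(1, 2000); bead counts ≥ 4. Two planted
  failing samples (defaults mirror the emulated design, where the failures
  were stem-cell samples) have intensities scaled by 0.04 and 5% of their
  detection p-values inflated above 0.05, so the p-filter and the
  median-intensity check each flag exactly those samples.
- **Annotation.** Gene-region and CpG-island categories are drawn from
  realistic base frequencies; for associated loci the odds of a chosen
  category can be tilted by a factor θ, which makes the population Fisher
  odds ratio of that category exactly θ (verified empirically in tests).
  Genes are assigned with heavy-tailed weights so probes-per-gene is
  uneven — the bias the gene-set test corrects.
- **Clock.** Clock CpGs are drawn from the linear-up module; weights are
  solved so the linear predictor equals 48 + 49t days post-conception
  exactly on the noiseless data (a fetal-range target). A pan-tissue-style
  variant targets m = −1 + 2t on the pre-transform scale, crossing the
  transform's knot.
- **Network.** `simulate_network` plants a directed cycle + chords as the
  unique nontrivial SCC inside an acyclic periphery (upstream chain → SCC →
  downstream chain), so strong connectivity of exactly the planted set is
  guaranteed by construction. `reference_like_network` is a deterministic
  synthetic stand-in at the scale of a curated regulatory network: 398
  genes / 622 interactions with one 60-gene / 158-interaction SCC whose hub
  ("STAT3") has in-degree 7 and out-degree 20 and a sparse neighborhood.

What the generator does **not** emulate: chip/batch spatial effects, probe
cross-hybridization structure, biological replicate variability (replicates
are technical), realistic genomic coordinates, or linkage between
annotation categories and methylation level. Tests passing on this data
show the algorithms are correct and calibrated under the stated model, not
that real-data headline counts will reproduce.

## QC and normalization

Order of operations: sample p-filter → median-intensity sample check →
probe filters → dasen normalization → annotation-based exclusion. The
p-filter flags samples with detection p > 0.05 in more than 1% of probes,
then probes failing in >1% of surviving samples (and, when bead counts are
present, probes with <3 beads in >5% of samples). The median-intensity
threshold has no universal default and must be supplied relative to the
array's intensity scale; the pipeline default for synthetic data is a
quarter of the mean total intensity. The dasen step estimates the type-I
vs type-II background per sample and channel as the difference of 5th
percentiles and shifts type-I intensities, then quantile-normalizes M and U
separately within probe type; the original's smoothed positional fit is
deliberately simplified to this quantile shift. Missing values are not
imputed; probes with any missing entry after QC are dropped (downstream
PCA/GAM need complete data). Multi-valued region annotations are collapsed
by the promoter-favoring precedence TSS200 > TSS1500 > 5′UTR > 1stExon >
Body > 3′UTR > intergenic before single-category tests.

## Clocks

A clock is `age = f(intercept + Σ coefᵢ βᵢ)` over its CpGs; CpGs absent
from the matrix are skipped and counted (strict mode errors). The adult-age
transform is `(1+A)e^m − 1` for m < 0 and `(1+A)m + A` otherwise (A = 20
years): continuous, strictly increasing, bounded below by −1 year. Unit
conversion uses 365.25 days/year and a 280-day gestation; these constants
are a documented convention (they matter only at day-level resolution).
Stage comparisons use one-way fixed-effects ANOVA plus Tukey HSD with
Tukey–Kramer standard errors; for two groups this reduces exactly to the
pooled-variance t-test.

## Trajectory inference

MAD (with the 1.4826 normal-consistency factor; selection is invariant to
any positive constant) ranks probes; the top ⌈fraction·n⌉ are kept, ties
broken lexicographically for determinism. The ceiling rule is what turns
837,018 probes into exactly 41,851 at fraction 0.05. PCA treats samples as
observations and centers but does not scale features — beta values share a
scale, and scaling would up-weight near-constant probes. The trajectory
uses the first two components: k-means (k = 4 matching the stage count,
≥10 restarts, re-seeded on empty clusters), exact enumeration of the k!/2
open orderings of the centers (k ≤ 8 enforced; exact beats a heuristic at
this scale), then Hastie–Stuetzle iteration: project samples onto the
current polyline, re-fit each coordinate against arc length with a
degree-3 polynomial smoother (df = 4 — the stable instance of a ≤ 4
effective-df cubic smoother at n = 14), repeat until the relative change in
total squared projection distance is < 1e−4 (max 50 iterations; the
iteration approaches its fixed point from below after the first smoothing
step, so convergence, not monotone descent, is the monitored property).
Pseudotime is min–max-scaled arc length; orientation anchors the
designated origin stage (mean pseudotime ≤ 0.5, else flipped).

## Per-locus GAM and the signature

Pseudotime is rounded half-up to two decimals before regression (kept as
specified upstream of this package; it only coarsens the design). Each
locus is fit with a cubic B-spline basis on [0,1] (basis_dim = 4 including
the intercept — with 14 samples a small basis is forced). Two fits are
computed:

- **Significance** comes from the *unpenalized* spline's exact F-test
  against the intercept-only model (df = basis_dim − 1, n − basis_dim).
  Under a Gaussian null this p-value is exactly uniform; measured KS
  distance from U(0,1) under the generator's (logit-scale) noise is ≈ 0.01
  at 10,000 nulls. The far tail is mildly anti-conservative under that
  noise — loci with baselines near 0 or 1 have skewed beta-scale errors —
  so the measured family-wise error of the Bonferroni signature on null
  data is ≈ 0.075 rather than the nominal ≈ 0.049; it stays within the
  binomial tolerance of the error-control check. Selecting a smoothing parameter by GCV and then using
  the GCV fit's effective df in the same F-test is *not* calibrated — the
  selection effect roughly doubles the rate of p < 0.05 (measured KS
  distance 0.18) — so estimation and testing deliberately use different
  amounts of shrinkage.
- **The reported curve** (fitted values on a 101-point grid, endpoint
  difference, effective df) comes from the penalized fit with a curvature
  penalty and per-locus GCV over a 33-point log-spaced grid; curves are
  clipped to the plausible range [−0.1, 1.1].

Bonferroni keeps loci with p ≤ α/n_tests (≤, a measure-zero convention).
Direction is hypo/hyper from the fitted endpoint difference (exact zero →
hyper with a warning). Modules: z-score each fitted curve, Ward linkage on
Euclidean distance, cut at n_modules = 9; labels are ordered by each
module's mean pseudotime of maximum absolute change, so labels are
reproducible across runs and seeds. Per-module stage changes are mean beta
differences in percentage points. No FDR alternative is offered
(family-wise control is the method's convention); replicate-aware or
mixed-effects GAMs are out of scope.

## Enrichment

Feature enrichment builds a 2×2 table per category against the tested
universe (default: the MAD-selected loci — enrichment is conditional on
what was tested; the whole-array universe is also supported since the
choice is genuinely open). The odds ratio is the sample cross-product
(a·d)/(b·c) (infinite when b·c = 0), and the two-sided Fisher p is the sum
of hypergeometric probabilities of all tables with the observed margins no
more probable than the observed one (tie tolerance 1e−7). Hypo- and
hypermethylated subsets can each be tested against the same universe.

The gene-set test corrects for probes-per-gene bias: a gene's chance of
containing ≥1 significant probe grows with its probe count. Each gene's
selection probability is estimated as a moving average of the significance
indicator over probe-count-ordered genes (window ≈ a tenth of the
universe, odd, then averaged within tied counts so the weight is a
function of the covariate). Each set's p-value is the Wallenius noncentral
hypergeometric tail of observing at least the seen number of significant
in-set genes, with odds = (p̄_in/(1−p̄_in))/(p̄_out/(1−p̄_out)); at odds 1
this reduces to the central hypergeometric (to ~1e−14). BH correction is
applied across sets. Gene-set hierarchies (parent propagation) are taken
as given in the GMT.

## Network topology

Edge lists are parsed with self-loops dropped and duplicate directed pairs
collapsed (both logged) — interaction counts refer to unique directed
pairs. SCCs are mutual-reachability classes; extraction returns the unique
nontrivial component (warning and largest if several). Metrics follow the
NetworkAnalyzer convention: in/out-degree and Brandes betweenness
(normalized by (N−1)(N−2)) on the directed graph; clustering coefficient
CC(v) = 2e(N(v))/(k_v(k_v−1)) and neighborhood connectivity (mean neighbor
degree) on the undirected projection; CC = 0 for degree < 2. "Hub" rank is
total degree, ties by betweenness then name. Note the directed
normalization: the middle of a 3-node directed path has betweenness 0.5
(one realized path over two ordered pairs).

## Numerical choices and degenerate inputs

- Quantile normalization assigns tied values the mean of their reference
  values (per column).
- k-means determinism: fixed seed, 10 restarts; empty clusters re-seed up
  to 10 times then error.
- Constant loci (zero residual variance) get p = 1 with a warning rather
  than NaN; degenerate Fisher margins give p = 1 with a warning.
- All generators derive independent child streams from one global seed;
  equal seeds give byte-identical outputs.

## Problem sizes used in validation

The test suite and acceptance script run at desk scale: 1,500–10,000
probes for pipeline runs, 20 seeds for pseudotime recovery, 200 null
replicates of 10,000 loci for family-wise error, the full 837,018-probe
selection arithmetic (a single MAD pass), and 100 random digraphs (n ≤ 50)
for the SCC oracle. These sizes were chosen so every claimed property is
measured at meaningful replication while the whole suite stays fast.

## Known limitations

- No IDAT parsing; intensities enter as matrices.
- dasen is a documented simplification of the original (no positional
  smoothing); bit-exact replication of reference normalizers is a
  non-goal.
- Single-lineage trajectories only (no branching, no graph-based
  pseudotime).
- The GAM basis is small by necessity at n = 14; with many samples a
  larger basis and penalized-test machinery would be preferable.
- Real clock coefficient files are consumed via the same CSV schema but
  are not shipped; shipped clocks are synthetic.
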