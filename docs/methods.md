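# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Synthetic cohort generator

The generator is the package's source of test data and defines the study
conditions every calibration claim refers to.

**Latent structure.** Each subject has a standard-normal latent stress
score (NAS). The five scale scores are `scale_k = λ_k·NAS + √(1−λ_k²)·ε`
with default loadings (0.8, 0.8, 0.7, 0.7, 0.6); the satisfaction-with-life
scale is generated with the opposite sign and reverse-keyed before factor
fitting, so all indicators track stress positively. Ten health/support
measures load on three orthogonal latent factors (HE, FS, HAR) with
loadings 0.6–0.8; family conflict, substance use and attachment avoidance
are reverse-indicators. HAR is drawn with correlation −0.35 to NAS,
emulating the empirical pattern that mothers with poorer health/relationship
profiles carry more stress.

**Connectivity.** ROI timeseries are zero-mean multivariate normal draws.
The target correlation matrix is block-structured: `rho_within = 0.6`
inside each planted network, `rho_between = 0.05` across networks. For
edges in the designated stress-coupled network pairs, the per-subject
correlation is shifted by `coupling_slope · NAS_i · (1 + har_moderation_slope
· HAR_i)`, clipped to ±0.98, and the matrix is repaired to positive
definite by eigenvalue flooring at 1e−6 followed by renormalisation to unit
diagonal (a deterministic repair; at the default slope it essentially never
triggers). Frame counts are normal (mean 159, sd 42), rounded and floored
at 20, mirroring the censoring *outcome* rather than simulating censoring.

**Parameter defaults and why.**

| parameter | default | rationale |
|---|---|---|
| `n_subjects` | 118 | study-scale cohort size |
| `n_roi` / `n_networks` | 60 / 16 | test-scale parcellation; up to 197 supported |
| `coupling_slope` | 0.02 z-units per NAS SD | pilot power analysis: with ~156 frames the across-subject sd of a null edge's z is ≈ 0.08, so slope 0.02 gives per-edge \|r\| ≈ 0.25 and ~80% detection power at n = 118 with the estimated (not latent) stress score |
| `har_moderation_slope` | 0.3 | a moderate multiplicative moderation; only the existence and sign of moderation are anchored, not its magnitude |
| `delivery_beta` | −0.396 weeks per NAS SD | equals a standardized β of −0.36 against the 1.1-week delivery-age sd |
| `har_nas_r` | −0.35 | stress–health/support coupling of realistic size |
| `n_close_pairs` | 1 | plants one ROI pair < 10 mm apart to exercise the distance exclusion |

**Geometry.** ROI centres sit on an 18 mm grid with ±1 mm jitter, which
guarantees all non-planted pairs are > 10 mm apart; each planted close pair
is offset by 3.9 mm. Gestational age at scan is truncated-normal 32.9 ± 3.87
on [26, 39] weeks; delivery age is 39.4 + `delivery_beta`·NAS + N(0, 1.1),
floored at scan age + 0.2 weeks (a rare clip for late scans).

**What the generator does not emulate.** Voxel-level signal and motion,
scanner noise spectra, non-Gaussian BOLD marginals, spatial autocorrelation
beyond the planted blocks, heteroscedastic measurement error in the scales,
and missing-data mechanisms. Passing tests therefore demonstrate that the
*statistical chain* behaves as designed under its own assumptions, not that
those assumptions hold in real fetal fMRI.

## Stress factor

ML factor analysis uses the profile-likelihood parameterisation: for fixed
uniquenesses Ψ the optimal loadings come from the eigendecomposition of
Ψ^{-1/2} S Ψ^{-1/2}, and `F_ML` is minimised over log-uniquenesses
(L-BFGS-B, bounds [1e−4, 1], multiple jittered restarts). Heywood cases are
clamped at 1e−4 with a warning. Fit indices: χ² = (n−1)·F_ML; baseline =
zero-correlation model (df p(p−1)/2); CFI and TLI clamped to [0, 1]; RMSEA
= √(max(χ²−df, 0)/(df(n−1))); SRMR over the strict lower triangle. The
5-indicator single-factor model has 15 − 10 = 5 df. Factor scores use the
regression (Thomson) method; subjects with missing indicators are excluded
from fitting (listwise) but scored from the model-implied covariance of
their observed indicators. The factor sign makes the majority of loadings
positive. Split-half dimensionality: one factor is kept if it fits well
(CFI ≥ 0.95 and RMSEA ≤ 0.08), otherwise the higher-CFI model wins, with
one factor preferred on ties.

## Connectome

Fisher z with r clipped to ±(1 − 1e−12); diagonal excluded everywhere.
Distance exclusion is strict (< 10 mm excluded, exactly 10 mm retained).
Densities are fractions of *post-exclusion* eligible pairs; the kept count
is `floor(d·E + 0.5)` (round half away from zero); ranking is by signed z
with deterministic (z desc, i asc, j asc) tie-breaks; the grid 0.010 …
0.100 is built over integers (`i/1000 for i in 10..100`) to avoid float
drift, giving exactly 91 thresholds.

## Communities

Detection delegates the map-equation search to igraph's Infomap with a
seeded Python RNG (fixed seed ⇒ identical membership); reported codelength
is the package's own textbook two-level map-equation value (igraph's
internal number uses a teleportation variant and is not comparable across
implementations — the exhaustive two-clique oracle in the test suite checks
the package's formula). Isolated ROIs keep singleton labels so all 91
partitions share the ROI universe. Consensus: window of 5 adjacent
densities; within each window the solution maximising mean NMI
(arithmetic-mean normalisation, via scikit-learn) to the other members is a
candidate; the median-density solution always competes; the final partition
maximises Newman–Girvan modularity on the median-density graph. Window
size, normalisation and evaluation graph are configurable; these defaults
were fixed before any calibration run.

A geometric constraint worth knowing: a planted network of size m is only
recoverable inside the 1–10% density grid if the within-network edges
(≈ n_networks·m²/2) are at most ~10% of all eligible pairs. At 60 ROIs this
holds for 16 networks (blocks of 3–4) but not for 6 networks of 10; the
community-recovery tests therefore use 128–197 ROIs with 16 networks,
matching the scale regime the method is designed for.

## Enrichment

Edge significance is two-sided p < 0.05 from the t distribution (n−2 df);
the sign of r is deliberately ignored — enriched pairs may mix positive and
negative edges. The per-pair 2×2 table is {in-pair vs out-of-pair} ×
{significant vs not}, χ² with df = 1 and no Yates correction; pairs with
zero eligible edges are absent. Permutations shuffle the NAS residuals
(equivalently the subject pairing), preserving the across-edge covariance
of connectivity; each permutation recomputes all edge correlations (as one
BLAS matrix product over standardized data, streamed in blocks of 500
permutations for O(edges) memory) and all pair χ² values. The add-one
estimator keeps p_perm strictly positive. A pair is *enriched* when p_perm
< 0.05 and its significant-edge rate exceeds the global rate
(over-representation). No multiplicity correction is applied across pairs,
so with P pairs about 0.025·P null pairs are flagged in expectation; at 21
pairs this is ≈ 0.5 per run, at 136 pairs ≈ 3–4. A work guard
(`B·edges·subjects` against a configurable budget) requires an explicit
override for oversized runs.

## WQS index

Quartile scoring (q = 4) is within-sample; components with fewer than q
distinct values fall back to coarser scoring with a warning. The train
fraction is 40% (seeded permutation split). Each of `n_boot = 100`
bootstrap resamples of the training split maximises the signed t-statistic
of the index–outcome slope over the weight simplex (SLSQP; bounds [0, 1],
equality constraint Σw = 1, uniform start) — the positive-direction
constraint reflects the expected positive stress–connectivity association;
a negative-direction run is a matter of negating the outcome. Resamples
with a positive slope are averaged with |t| weights; if none is positive
the fit aborts ("no positive-direction signal"). Validation β (raw and
standardized) comes from OLS in the held-out 60%; with the split held out,
the validation test is calibrated (measured null rate 3.5% over 200
replicates at α = 0.05). Moderation models standardize index and moderator
within the validation set and report interaction β, its SE/p, and simple
slopes at ±1 sd. At n = 118 (≈ 71 validation subjects) the moderation
interaction is weakly powered: its run-level estimate can change sign, and
sign consistency is only demonstrated in the tests at n = 400.

Support factors: Bartlett sphericity, Horn's parallel analysis (95th
percentile of eigenvalues from standard-normal data, 1000 resamples by
default), ML EFA at the retained count, promax (power 4) oblique rotation,
regression-method scores standardized to unit variance. When the canonical
ten measures are present, factors are named HE/FS/HAR by their strongest
marker block and signed so the marker keying (reverse-indicators negated)
is positive; otherwise factors are F1…Fk signed by their largest loading.

## Delivery-age models and screens

Single-predictor OLS with intercept; the standardized β of a
single-predictor model equals the Pearson correlation and is reported
alongside the raw coefficient, SE, t and p. The per-pair family is
Holm–Bonferroni adjusted (statsmodels step-down, monotone, capped at 1).
No covariates are included by default; a covariates hook exists. Confound
screens report Pearson r and p of the NAS residual against maternal age,
income, translational and rotational motion and frame count, and of the
WQS index against motion; constant or missing columns are reported as
not-computable instead of raising.

## Pipeline

Stage seeds derive from one master seed via `numpy.random.SeedSequence`
spawning (reduced mod 2³¹), recorded in the manifest with a SHA-256 config
hash, so any stage can be re-run in isolation and identical configs yield
byte-identical artifacts. A stage failure halts the run with the stage
named; partial artifacts remain on disk. If no pair is enriched, the WQS
and per-pair delivery stages are skipped and recorded as such.

## Problem sizes used in the test and acceptance runs

Calibration suites run at n = 118 subjects with 60 ROIs / 6 networks
(≥ 45 edges per network pair keeps the χ² distribution effectively
continuous under permutation): 200 null replicates at B = 1000 for the
false-positive rate, 50 replicates for planted-pair recovery. Community
recovery runs one 118-subject cohort at 128 ROIs / 16 networks over all 91
thresholds; the acceptance script runs the full chain once at 197 ROIs.
WQS recovery uses n = 500 with planted weights (0.5, 0.3, 0.2, 0, 0, 0)
and 50 null replicates at n = 200.

## Known limitations

- The consensus procedure's window size, NMI variant and evaluation graph
  are conventions, not identified from data; different choices can shift
  the recovered network count by ±1–2 on marginal configurations.
- Enrichment flags ~2.5% of null network pairs by design (no cross-pair
  correction); downstream WQS components therefore occasionally include a
  spurious pair, which the validation split is designed to down-weight.
- The positive-direction WQS constraint assumes the index–outcome
  association is positive; purely negative mixtures abort rather than
  silently fitting zero.
- The generator's Gaussian, block-constant covariance is idealised; power
  numbers quoted here do not transfer to real fetal fMRI effect sizes.
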