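# Methods notes

This document records the models behind each stage, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Synthetic data model

The generator produces every input of the analysis with known ground truth.

- **Geometry.** Regions are points on the unit sphere (Fibonacci lattice
  with seeded jitter) or a 3D lattice; the distance matrix is Euclidean
  between centroids. The sphere stands in for a cortical parcellation of a
  few hundred parcels; all spatial scales below are expressed in these
  unit-sphere coordinates (maximum pairwise distance 2, nearest-neighbour
  spacing ≈ 0.2–0.25 at 150–300 regions).
- **Expression.** Each gene's latent regional profile is a zero-mean
  Gaussian field with exponential covariance exp(−d/ℓ); donors observe the
  profile plus i.i.d. noise (default SD 0.3). The exponential kernel is the
  simplest stationary choice and matches the variogram family the surrogate
  generator fits.
- **Atrophy.** Either a weighted sum of z-scored gene profiles plus an
  autocorrelated noise field (`make_atrophy`; the planted correlation
  attenuates as w/√(w²+σ²)), or — when many genes must share a target
  correlation with a single map — gene profiles rewritten as
  r·z(map) + √(1−r²)·(independent field) (`plant_gene_correlates`).
- **Cohorts.** Control grey matter per region is baseline + linear
  covariate effects (age, sex, education, total intracranial volume by
  default; centred numeric covariates, categorical as indicators) +
  Gaussian noise (SD 0.5). Patients subtract the z-scored atrophy map times
  a per-patient severity factor — atrophy is tissue loss, so the
  atrophy-positive W convention below yields positive W where the planted
  map is high.
- **Gene labels.** HAR and CS memberships are Bernoulli draws; the CS odds
  are multiplied by `overlap_enrichment` for HAR genes so the generating
  odds ratio equals the parameter exactly.
- **Sequences.** i.i.d. ACGT background with per-gene probability of
  inserting a GT run of geometric length (≥ 3 dinucleotide units). Planting
  operates on runs rather than motif counts so that the k-mer counting code
  is validated against an independent mechanism.
- **Connectivity library.** Seed s's map is exp(−d(s,·)/κ) plus small
  noise; κ defaults to 0.25 in epicentre validation so that neighbouring
  seeds' maps are distinguishable at the simulated noise level.

What the generator does **not** emulate: voxel-level image structure,
scanner and site effects, microarray probe chemistry, hemispheric
asymmetries of real cortex, long-tailed expression distributions, or
gene–gene co-regulation beyond shared spatial smoothness. Passing
recovery tests therefore demonstrates the correctness and calibration of
the statistical machinery under the stated assumptions, not robustness to
real-data artefacts.

## W-scores

Per-unit OLS on controls; W = −(Raw − Expected)/SDε. SDε uses the
unbiased (n − p − 1) denominator — the convention is configurable in the
sense that the biased alternative differs only by a constant factor √((n−p−1)/n)
and the choice is documented here because published normative models do not
always state it. Units with (numerically) zero residual SD are flagged
degenerate and excluded rather than producing infinite W. The sign flip
(atrophy-positive) is the default and can be disabled. Hold-out
standardization — across-unit average of per-unit hold-out means ≈ 0 and of
per-unit SDs ≈ 1 — is the validated property; individual units fluctuate by
±1/√n around those values, which is why the check aggregates across units.

## Expression preprocessing

A deliberately simplified re-implementation of the standard donor
microarray chain: probes kept when they exceed background in strictly more
than 50% of samples; one representative probe per gene chosen by
differential stability (mean pairwise inter-donor Spearman correlation of
regional profiles; constant profiles score −∞ so they never win); samples
assigned to the nearest region centroid within a maximum distance (default
twice the median nearest-centroid spacing; left-hemisphere samples are
never mirrored); per-gene, per-donor scaled robust sigmoid normalization
1/(1+exp(−(x−median)/(IQR/1.35))) rescaled to [0, 1] (per-donor z-scoring
available behind a flag); genes kept when inter-donor stability exceeds
0.1; donor averaging over contributing donors; subcortical regions removed.
Threshold defaults follow the conventions of the widely used abagen-style
toolchain where the exact parameterization is not otherwise pinned down.

## Surrogate maps and empirical inference

Surrogates preserve the value distribution (permutation) and the spatial
autocorrelation (variogram matching) of the source map:

1. permute the map values;
2. smooth with row-normalized exponential kernels exp(−d/s) over 25
   log-spaced scales from d_max/100 to d_max;
3. for each scale, fit γ_src ≈ β·γ_smooth + α by weighted least squares on
   25 equal-count distance bins (weights 1/lag — short lags dominate
   because they control the width of the null correlation distribution;
   α is the white-noise nugget, both coefficients clipped at 0);
4. keep the best-fitting scale, form √β·smoothed + √α·noise, and rescale
   to the source mean and variance exactly.

Empirical p-values follow the counting rule p = #{surrogate r ≥ r_obs}/B
for non-negative observed correlations, with the tail mirrored for negative
ones — otherwise every negatively correlated gene would receive p ≈ 1. Two
consequences are worth stating plainly:

- p = 0 is representable; an optional (count+1)/(B+1) smoothing exists but
  is off by default, because with B surrogates and m ≫ B genes the +1 floor
  can push even perfect correlates above the Benjamini–Hochberg cutoff.
- the sign-matched one-tailed p is exactly half the two-sided (|r|-based)
  p under a symmetric null, so it is supported on [0, 0.5]. Calibration
  (uniformity of null p-values) is therefore assessed on the two-sided
  variant; the one-tailed default simply doubles power at fixed nominal
  level in a way that is absorbed by the FDR step being applied to
  comparable quantities across genes.

Selection requires both FDR-adjusted p < α and |r| ≥ τ (default 0.2, the
value the uniqueness-index sweep identifies; the sweep itself picks the
smallest threshold reaching 90% of the maximum defined uniqueness index,
a configurable operationalization of "optimal while preserving longer
lists").

### Validation problem sizes

The validation suite runs at desk scale, chosen to make each property
measurable while keeping the full suite under a minute of compute:
variogram fidelity at 200 regions / B=100; null calibration at 200 regions
× 200 genes / B=200 (field scale 0.4); planted-gene recovery at 300
regions × 1000 genes / B=500 with 20 genes planted at |r| ≈ 0.5 and field
scale 0.15. The recovery scale matters scientifically: the |r| ≥ 0.2
discard rule presupposes a regime where chance map–gene correlations
rarely reach 0.2. Under strong autocorrelation (few effective spatial
degrees of freedom) some null genes genuinely resemble any single map
realization — no conditional test can separate them from planted
correlates, and the false-discovery proportion rises accordingly. The
moderate-autocorrelation regime used here (adjacent-region correlation
≈ 0.26) is the one the threshold was designed for.

## Gene-set statistics

- Fisher overlap tests are exact hypergeometric upper tails ("greater"
  alternative), matching the one-tailed published usage.
- χ² proportion comparisons use the uncorrected Pearson statistic on the
  2×2 table: with Yates continuity correction the published statistics
  (26.39 and 0.41) are not reproduced (they become 25.49 and 0.27), so the
  uncorrected form is the fixed default.
- The background universe is always explicit; the published analyses use
  the 15 655 brain-expressed genes.
- Length matching is greedy 1:1 nearest-neighbour on log length, queries in
  descending length order, ties broken by candidate id; greedy is within a
  factor ≤ 2 of the optimal assignment on the tested instances and is
  deterministic, which matters more here than exact optimality.
- The uniqueness index U = ΣUnique/ΣShared over three subtypes returns an
  explicit undefined sentinel (None) when no gene is shared, rather than
  ∞ or NaN, so sweeps can distinguish "no sharing" from "no data".

## GU repeats

"GU tetramer / pentamer / hexamer" are read as the alternating motifs of
4–6 nucleotides (GTGT, GTGTG, GTGTGT on the DNA sense strand), not 4–6
GU dinucleotide units — standard k-mer semantics and the convention of
common motif scanners; occurrences are counted overlapping (non-overlapping
mode behind a flag), N matches nothing, and only the provided sense strand
is scanned (TDP-43 binds pre-mRNA). High-GU classification is strictly
above-median in any of c4, c5, c6 (disjunction), with even-n midpoint
medians.

## Co-expression graph

Edges require signed r > θ (default 0.3) strictly; negative correlations
never form edges in the default mode (an |r| mode exists). Degree is the
row sum of the adjacency; Σdegree = 2|edges| is enforced by construction
and verified against brute-force pair scans.

## Epicentres

Best-fit seed by Pearson correlation between each seed's normative
connectivity map and the patient's parcel W-map; ties (within 1e-12,
absorbing floating-point jitter of the vectorized correlation) go to the
lowest seed index. Constant W-maps yield an explicit no-epicentre result.
The cross-subtype expression comparison defaults to the exact Mann–Whitney
rank-sum test: the comparison is structurally unpaired (different patients
per subtype), so a signed-rank test would require an arbitrary pairing; a
signed-rank mode (equal group sizes, paired by rank order) is provided for
strict replication attempts. Fold changes are computed on the normalized
(non-negative) expression scale to avoid sign flips.

## Orchestration

Per-stage seeds are derived by hashing (global seed, stage name), so adding
a stage never perturbs existing ones and every run is bit-reproducible from
its config. All tables are TSV with a header comment carrying the config
hash; the manifest records SHA-256 checksums, and `report` verifies them
without recomputation.

## Known limitations

- The surrogate family is the permute-and-smooth variogram matcher only;
  spin tests and vertex-wise modes are out of scope.
- The expression chain accepts probe→gene annotations as given (no
  re-annotation) and supports no donor weighting beyond presence/absence.
- Enrichment is over-representation only; no ranked-list enrichment.
- Epicentre expression uses the single epicentre region's value per
  patient, not a neighbourhood average.
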