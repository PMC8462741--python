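# Methods

## Model and posterior computation

The segmentation model treats pooled per-site conversion counts within one
cluster as X_t ~ Binomial(n, θ_t) at informative sites τ₁ < … < τ_N, with
the accessibility θ piecewise constant along the sequence. Change
indicators I_t ~ Bernoulli(p_t) (I₁ = 1 by convention) mark the sites where
θ is redrawn from a Beta(μ₀, ν₀) prior written in mean/sample-size form,
Beta(μν, (1−μ)ν). Because the state is continuous, accessibility can change
*within* what a finite-state HMM would call a single "accessible" state —
boundaries of a BAR and quantitative changes inside it are treated
identically.

Posteriors are exact, by dynamic programming over segment hypotheses:

- **Forward**: p_{i,t} = Pr(most recent change at or before t is at τ_i |
  x₁..x_t), updated per site with segment marginal-likelihood ratios.
- **Backward**: q_{j,t+1} over the last site j of the segment containing
  τ_t given x_{t+1}..x_N; the "segment ends at t" mass is exactly p_{t+1},
  because data after a change carry no information about θ_t.
- **Combination**: normalized weights w_{i,j,t} over all segments covering
  t, with the correction factor c_{i,t}·c_{t+1,j}/(c_{i,j}·c₀), where
  c_{i,j} is the reciprocal Beta-function normalizer of the segment's
  posterior. E(θ_t|X) = Σ w_{i,j,t}·μ_{i:j}; the change probability at t+1
  is the posterior mass Σ_i w_{i,t,t} on segments ending exactly at t,
  which with unnormalized weights equals p_{t+1} divided by the per-site
  weight normalizer.

All recursions run in log space with per-site normalization; Beta-function
ratios go through log-gamma, and factorials are replaced by gamma functions
so real-valued (rescaled) counts are handled transparently. The marginal
likelihood is the product of the per-site forward normalizers times the
per-site binomial coefficients; the coefficients are constant in λ, so
including them only fixes the absolute scale.

**Oracle validation.** An independent brute-force implementation
(`enumerate_posterior_oracle`) sums over all 2^(N−1) change configurations
and computes posterior means, change probabilities and the marginal
likelihood by conjugacy. The dynamic program agrees with it to ~1e-14 on
random instances (N ≤ 10, n ≤ 30); this is asserted in the test suite and
re-measured by the acceptance script. Two boundary conventions that the
recursions leave open were fixed by the oracle: the sequence end acts as a
certain boundary (p_{N+1} := 1), and the printed change-probability formula
is read with the same per-site normalizer as the segment weights.

## Hyperparameters

- **ν₀ = n** (prior worth one pooled data point) and **μ₀ = Σx_t/(N·n)**
  (prior mean = sample mean), both estimated from the cluster being
  segmented. μ₀ is clamped to [1e-6, 1−1e-6] so degenerate all-zero or
  all-converted clusters keep positive Beta parameters.
- **λ** (changes per bp) maximizes the marginal likelihood over a default
  grid of 40 log-spaced values in [1e-4, 1]; ties take the smallest value.
  On data with no true changes the marginal comparison between "one
  segment" and "many segments" is close at small N, so λ̂ is noisy there;
  with genuine structure it concentrates sharply (the tests assert the
  aggregate ordering over seeds rather than per-draw dominance).
- **Scaling**: clusters of different n can be rescaled to a common n
  (`scale_counts`); posterior means are exactly invariant, posterior
  variances shrink as (μ+X/n)(1−μ−X/n)/(1+n). Scaling is exposed as an
  option and off by default.

## BAR calling and patch sizes

A cluster contains a nontrivial BAR iff ≥ 2 consecutive C sites have
posterior accessibility ≥ 3×μ₀ (both thresholds configurable); each maximal
such run yields one call, anchored at the site of maximal observed
frequency and spanned by the maximum-a-posteriori segment there. The
model-based size is the expectation of segment size under {w_{i,j,peak}}.

Boundary conventions: "last-C" size is the inclusive length
τ_last − τ_first + 1; "midpoint" places each boundary at the midpoint of
the terminal converted C and its flanking unconverted C. A segment end at
the amplicon edge has no flanking C; it contributes its last-C edge
(τ ± 0.5), so a full-span segment reproduces the inclusive last-C length
exactly. This makes midpoint ≥ last-C hold for every segment (site spacing
is ≥ 1 bp), which the tests assert on every called patch. Grand means in
the four-definition summary average cluster-level values unweighted, with
sequence-count weighting available as an option.

## Clustering

Distinct binary profiles are deduplicated with multiplicity weights (exact,
since duplicates are at Hamming distance 0) and clustered by complete
linkage on integer Hamming distances via scipy's agglomerative machinery;
rows are canonically sorted so results are independent of input order. A
brute-force agglomeration that exhaustively recomputes max pairwise
distances is kept in the tests as an independent check of merge heights.

The gap statistic compares log within-cluster dispersion against B = 50
(configurable) reference datasets. For binary profiles the classical
uniform-over-range reference box is degenerate, so references resample each
column as independent Bernoulli at its empirical frequency, preserving
marginal site accessibility while destroying between-site structure.
Selection uses the one-standard-error rule. The selected k is advisory; k
is normally fixed by the user.

## Spatial analyses

Hotspot-to-BAR distances are posterior-weighted: d = Σ(site − τ_t)·θ̄_t /
Σθ̄_t over the BAR's sites, with θ̄ the posterior accessibility — a
centroid-style distance, positive when the site lies 3′ of the BAR. The
15 bp window restriction for the nearest-BAR correlation reflects the
approximate transcription-bubble size. Cross-strand comparisons (C sites
never coincide with G sites) embed both tracks on the full 1..L grid with
zeros at non-informative positions and smooth with a discrete Gaussian
kernel (σ = 1 bp default, truncated at 4σ, renormalized at edges).
Correlations are Pearson with two-sided t-distribution p-values (Spearman
available); the strand accessibility comparison is a 2×2 chi-squared test
without continuity correction.

## Synthetic data

The generator draws each molecule's archetype from a mixture, then
independent Bernoulli(θ_t) calls at every site — exactly the model's
assumed structure plus archetype mixing. The default fixture mimics the
geometry of a bisulfite-treated IGHV amplicon: L = 346 bp, 80 irregularly
spaced C sites, a 75.4% patternless majority and five single-BAR archetypes
(proportions 8.1/5.9/4.5/3.5/2.6%, θ between 0.35 and 0.55 against a 0.01
baseline). What it does **not** emulate: PCR/sequencing error, UMI
collisions, within-molecule correlation of conversion beyond the shared θ,
strand-specific sequence composition, or incomplete bisulfite conversion
chemistry. Passing recovery tests therefore demonstrates correctness of the
inference under the model's own assumptions, not robustness to those
real-data artefacts.

## Problem sizes and numerical choices

Tests and the acceptance script use deliberately compact instances: oracle
cross-checks at N ≤ 10 sites (enumeration is 2^(N−1)), boundary recovery at
60 sites × 500 molecules × 50 replicates, and pipeline fixtures of one to
four thousand molecules — large enough for the posteriors to concentrate,
small enough that the whole suite runs in well under a minute per
component. The combination step is O(N³) per cluster and the forward pass
O(N²) per λ grid point; amplicon-scale N (~80) is far below any practical
limit. Degenerate inputs (all-identical sequences, all-zero counts, single
sites, empty clusters) return the documented closed forms or raise
explicit errors rather than NaNs; any non-finite value inside the
recursions raises immediately.

## Known limitations

- The model assumes sequences within a cluster share one accessibility
  profile; heterogeneous clusters blur boundaries rather than failing
  loudly.
- λ is shared along the whole amplicon; locally varying change rates are
  not modelled.
- The gap-statistic reference for binary data is a pragmatic choice, not a
  canonical one; k should be confirmed by inspection.
- Weighted-centroid distances are reported by default; minimum-edge
  distances differ for wide BARs and are available as an option.
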