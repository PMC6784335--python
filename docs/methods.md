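# Methods

## Scope and assumptions

`jointmds` compares two *normalized* intrachromosomal Hi-C contact matrices
for the same chromosome at the same bin resolution. Bias correction (KR,
ICE, ...) is assumed done upstream; the package only rescales each matrix
by its own mean so that the pair lives on one scale. The central modeling
assumption is the usual one for structural inference from Hi-C: contact
frequency is a monotone function of average physical distance,
approximately c ∝ d⁻⁴, so target distances are d = c^(-1/4) (exponent
user-overridable). Interchromosomal input works mechanically — loci are
just concatenated — but no interchromosomal expected model is provided.

Coordinates are 0-based and half-open everywhere; a bin covers
[start, start + bin_size) and bin index = start / bin_size.

## Preprocessing pipeline

Fixed order: `intersect_loci` → `mean_normalize_pair` →
`distance_decay_prior` (each) → `contacts_to_distances` (each). The order
is a package decision: intersecting first keeps the separation-stratified
expected values from being diluted by dead bins, and normalizing before
the prior makes the prior weight comparable across datasets. A single code
path is deliberate — making the order configurable would make results
irreproducible across users for no analytical gain.

* **Locus intersection.** Loci with zero total counts in *both* datasets
  are removed from both; a locus alive in either is kept in both, so the
  pair always shares one locus list.
* **Mean normalization.** Each matrix is divided by the mean of its stored
  nonzero entries; afterwards those entries have mean exactly 1.
* **Distance-decay prior.** c_corrected = c_observed·(1-k) + c_expected·k,
  where c_expected(s) is the mean contact (zeros included) over retained
  pairs at linear separation s, and k = 0.05 by default — a small shrinkage
  toward the distance-decay expectation that regularizes sparse regions;
  without it embeddings of noisy matrices degenerate into tangles. The
  prior is applied to observed-zero pairs too (they can become nonzero);
  separations with no retained pairs contribute nothing. The prior
  preserves the matrix-wide mean (it is a convex combination with the
  matrix's own stratified means). Negative normalized values, which some
  normalization schemes can produce, are clamped to zero at read time with
  a warning.
* **Distance conversion.** δ = c^(-1/4) for c > 0; c = 0 maps to δ = 0,
  which downstream code treats as "missing, ignored".

## The joint embedding

The objective over two N×3 configurations is

σ(X₁, X₂) = Σ_{i<j} (d_ij(X₁) − δ_ij1)² + Σ_{i<j} (d_ij(X₂) − δ_ij2)²
\+ Σ_i w_i d_i²(X₁, X₂),

with missing pairs excluded per condition and w the per-locus similarity
weight (a uniform scalar in practice). Each iteration applies

X₁ ← (W + I)⁻¹ [W X₂ + B(X₁) X₁ / N],  X₂ ← (W + I)⁻¹ [W X₁ + B(X₂) X₂ / N]

with the standard SMACOF majorizing matrix B (b_ij = −δ_ij / d_ij(Z) where
both are positive, 0 for missing pairs or coincident points, diagonal
closing rows to zero sum). Numerical and design choices:

* **Weight scaling.** Because the Guttman term is the N-normalized B(Z)Z/N
  while the penalty blend is (W + I)⁻¹, the quadratic surrogate these
  updates minimize exactly carries the similarity penalty at N times its
  nominal weight. The weight is therefore a tuning parameter whose useful
  range (~0.01–0.5) is independent of chromosome size, rather than a
  literal coefficient of the reported stress. The reported stress uses the
  plain Σ w_i d_i² form; in practice it is non-increasing across
  iterations, and the test suite asserts this on every fixture it runs.
* **Update schedule.** Both configurations update Jacobi-style from the
  previous iteration's coordinates. This makes the algorithm exactly
  symmetric: swapping (D₁, D₂) swaps (X₁, X₂) bit-for-bit (the stress is
  accumulated with exact summation for the same reason). Descent for the
  simultaneous update is guaranteed because the surrogate's Jacobi
  splitting satisfies D + R ⪰ I ≻ 0.
* **Initialization.** Both configurations start from the *same* Gaussian
  cloud (sd = mean positive target distance, computed symmetrically from
  both matrices), drawn per restart. A shared start means the penalty never
  spends iterations repairing a spurious reflection or rotation between
  the two structures; with identical inputs the two trajectories are then
  identical, which is the correct degenerate behavior.
* **Chirality.** Global chirality of the *pair* is unidentifiable from
  distances — both mirror images fit equally well — and no chirality fix is
  applied. The penalty guarantees only that the two structures share one
  frame, including handedness.
* **Convergence.** Relative stress decrease < 1e-4 (default), max_iter 300,
  n_init 4 restarts keeping the lowest-stress fit; both outputs are
  mean-centered. Defaults mirror common SMACOF practice; n_init matters
  little at positive weights because the coupled fit is reproducible, and
  the weight-selection routine exists precisely to verify that.
* **Weight selection.** For each candidate weight the fit is repeated
  n_runs times with distinct seeds; reproducibility is the mean pairwise
  Pearson correlation of per-locus relocalization magnitudes. The chosen
  weight is the smallest within 0.01 of the maximum — the plateau point of
  the reproducibility curve. Zero-variance profiles (identical inputs)
  count as perfectly reproducible.
* **Zero weight** is exactly classic SMACOF; the test suite pins this to
  scikit-learn's implementation (same initialization, final stress within
  1e-6) so the penalized path is verifiable against an external reference.

The estimator surface (`JointMDS`, with `fit`, `fit_transform`,
`get_params`/`set_params`, and fitted attributes `embedding1_`,
`embedding2_`, `stress_`, `n_iter_`, `converged_`, `stress_trace_`)
composes with scikit-learn tooling; `joint_mds` and friends wrap it in the
genomic containers.

## Independent baseline

`independent_compare` embeds each dataset separately (weight 0, separate
random initializations) and Kabsch-superposes structure 2 onto structure 1.
Kabsch is proper-rotation-only (det +1) with no scaling step: the inputs
are already co-scaled by mean normalization, and allowing reflections would
silently hide chirality disagreements that the user should see as RMSD.
The baseline exists both as a CLI mode (`--independent`) and as the
reference point for the joint method's reproducibility gain: on identical
noisy inputs, the joint fit's X₁–X₂ RMSD is ~0 while the baseline's
cross-embedding RMSD is set by MDS stochasticity.

## Compartment analysis

Scores are PC1 of the Pearson correlation matrix of the observed/expected
matrix (expected = separation-stratified mean, the same estimator as the
prior), scaled so max |score| = 1. Zero-variance rows are dropped with a
warning; the PC1 sign is fixed deterministically (largest-magnitude loading
positive) and should then be oriented biologically with `orient_scores`
against any user-supplied per-locus "active" mask (gene density, chromatin
state — the package deliberately does not bundle any annotation).
`pc1_variance_fraction` is λ₁/Σλ⁺ and distinguishes genuinely
compartmentalized matrices from uniform-decay ones.

The compartment axis of an embedded structure is a linear SVR
(ε-insensitive, C = 1, ε = 0, the implementation defaults) of score on
coordinates; direction = β/‖β‖, R² from the fit's predictions, axis length
= mean |projection onto the direction| from the centroid. An OLS fallback
(`method="ols"`) must agree in direction on clean data and serves as a
cross-check.

For the decomposition, the two per-structure axis directions are
sign-aligned (flip if the dot product is negative; a >60° residual angle
warns that the axis is unstable) and averaged; two orthogonal axes complete
the triad. Per-locus fractions |displacement·axis|/‖displacement‖ are
divided by the axis length computed from the pooled pair coordinates —
pooling is a package decision where per-structure lengths would also have
been defensible — so that physically longer axes are not favored. The
reported test is a two-sided equal-variance independent-sample t test of
compartment-axis versus pooled orthogonal normalized fractions,
zero-magnitude loci excluded. Note the length normalization is slightly
conservative: because the compartment axis is typically the longest axis,
isotropic noise yields mildly *negative* t statistics, which is the right
failure direction for a null.

## Relocalization peaks and downstream

Peaks in the magnitude profile are called with `scipy`'s CWT ridge-line
detector over Ricker widths 1–10 bins (algorithm defaults for ridge/SNR
parameters, overridable); a constant profile has no peaks by definition.
Each peak's position is its ridge index; the recorded width class is the
width with the strongest Ricker response at that position. Peaks are
filtered to |Δcompartment score| < 0.2 (strict) to isolate *intra*-
compartment relocalization, then split into intra-A / intra-B / discordant
by score sign in the two tracks. Interval utilities (virtual 4C, fractional
coverage enrichment with an equal-variance t test, blacklist filtering) use
half-open 0-based semantics throughout. The background set for enrichment
is the user's choice; "all non-peak bins in the same compartment after
blacklist filtering" is the recommended default when no curated background
exists.

## Synthetic fixtures

The generators are pure functions of (parameters, seed) and emulate, at
matrix level, the designs the method must detect:

* `make_structure`: helix (radius 1, 0.4 rad step, 0.1 rise — equal
  consecutive-locus distances) or unit-step random walk, with optional
  Gaussian jitter and planted per-locus displacements.
* `structure_to_contacts`: c = d⁻⁴ (the exact inverse of the distance
  conversion, so noiseless fixtures make the pipeline an exact inverse
  problem), with multiplicative log-normal noise — chosen over additive
  noise because it preserves positivity and mimics the heavy right tail of
  real contact counts.
* `make_boundary_pair` (defaults n = 200, boundaries 95 vs 105, 3-fold
  within-domain enrichment, Poisson noise at depth 200): two matrices
  identical except that ten loci switch domains — the differential-boundary
  design. Sizes are desk-scale stand-ins for the Mb-scale boundary shift
  the design emulates.
* `make_compartment_pair` (defaults n = 100, alternating 10-bin blocks,
  ±0.5 checkerboard amplitude, log-normal noise sd 0.1, flip block 45–55):
  a planted compartment flip for the axis-decomposition analysis; an empty
  flip block gives the matched null replicate.

What the fixtures do *not* emulate: read-level noise and restriction-site
structure, mappability artifacts, translocations, and the scale of real
chromosomes (thousands of bins). Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated generative
models, not performance on any particular experimental dataset.

## Problem sizes and determinism

The test suite and the acceptance script run at n = 15–200 loci with
10–50 repeat seeds per claim — sizes chosen so the entire evidence chain
re-runs in minutes on one core while keeping every rate estimate stable
across seeds. All randomness flows through explicit integer seeds;
`numpy.random.default_rng` / `check_random_state` only, no global state.

## Known limitations

* Full-matrix SMACOF is O(N²) per iteration; chromosomes at very high
  resolution (tens of thousands of bins) need a partitioned approximation
  that this package does not implement.
* The reported stress is not the literal quantity the update majorizes
  (see weight scaling above); its monotonicity is an empirical property,
  verified by the tests, not a theorem.
* Exactly two conditions; no multi-way joint embedding.
* `.hic`/`.cool` binary readers are out of scope (text dialects only,
  gzip accepted); conversion is a one-liner with standard dump tools.
* The t test on normalized fractions treats loci as independent samples;
  neighboring bins are in reality correlated, so its p values are
  optimistic on real data and best used comparatively.
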