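# Methods

This note documents the statistical models behind `pandemicdp`, the
parameters that matter, what the synthetic-data generators emulate,
and the numerical choices made where the design was genuinely open.

## Privacy model

All mechanisms satisfy pure ε-differential privacy (δ = 0). The
neighboring relation is *unbounded* (add/remove one record), under
which any single cell count, and the edge count of a graph under
edge-level neighboring, has ℓ1 sensitivity 1; the bounded convention
(sensitivity 2 for a count) is available via the `sensitivity`
argument. Budget arithmetic follows basic composition: sequential
queries on the same data add their losses, queries on disjoint data
cost the maximum. `BudgetLedger` makes this executable — every noisy
draw is logged with a stage label and ε share, and a draw that would
exceed the total is refused. Laplace variates come from the inverse
CDF applied to one uniform stream, so a fixed `numpy` generator seed
reproduces every release bit-for-bit across platforms.

## Table sanitization

The flat sanitizer adds Laplace(0, m/ε) noise to each of the K cells,
independently per release. Negative cells are truncated to 0 by
default (redraw-until-nonnegative is the alternative; truncation is
the variant natural when the total is fixed). When the grand total n
is public, each release is rescaled to n·ỹ_k/Σ_k ỹ_k — the sum runs
over *cells within one release*, the only normalization that makes
each published table total n. Integer output uses largest-remainder
(Hamilton) apportionment with ties broken by cell index: plain
rounding would break the total by a few units. A release whose
pre-normalization sum is non-positive (possible only at extreme ε) is
redrawn and the retry counted.

Utility fits use a Poisson log-linear model on the sanitized counts
*as they are* — normalization leaves non-integer values, and the
Poisson quasi-score only needs the mean model; rounding first is an
option flag. Marginal tables are sums of sanitized cells
(post-processing, no extra privacy cost); a summed cell carries the
sum of the component noise variances, which is documented rather than
removed.

The 2×2×2 simulation generator draws multinomial(n, p) counts with
p_k ∝ exp(β₀ + β₁x₁ + β₂x₂ + β₃x₃ + β₄x₁x₂ + β₅x₁x₃ + β₆x₂x₃). The
intercept cancels in the normalization, so inference targets β₁..β₆.
The default effect vector (0, 0.3, −0.3, 0.2, 0.25, −0.2, 0.15) gives
cell probabilities spanning roughly a factor of 3 — sparse enough
that sanitization bites at n = 200 and ε = 0.5, dense enough that
every cell is usually populated.

## Location sanitization

Geo-indistinguishability bounds the likelihood ratio of any released
location between two true locations at distance γ by e^{εγ}. The
planar Laplace mechanism attains it: displacement radius
r ~ gamma(2, rate), angle uniform. "Loss ε per u distance units"
means the gamma rate in coordinate units is ε/u — the loss is linear
in distance, so the per-unit rate just rescales. With m releases and
h locations per person, each draw runs at rate (ε/u)/(m·h), making
the whole release set ε-GI per person by composition.

Out-of-bound draws are clamped coordinate-wise into the public
bounding rectangle. Clamping is exactly the published post-processing
rule; it is privacy-neutral but a known source of estimation bias,
which is the point of studying it. Re-drawing until inside would be a
different (and not privacy-neutral, without care) mechanism and is
deliberately not offered.

### Cluster-process generator

The simulation design is an inhomogeneous Matérn cluster process on
the unit square: homogeneous Poisson parents on the square dilated by
the cluster radius (0.03), Poisson(μ) offspring per parent uniform in
the disc, offspring retained by independent thinning with probability
exp(β·z(x,y)) / max, where z = (1, x, y, x², y², xy) and
β = (4.53, 3.30, 3.43, −0.27, 1.58, 2.24).

Two generator constants are free and were fixed once from the two
dispersion facts the design states — a mean of ~970 points with a
range of roughly 769–1217 across realizations:

* `mean_offspring` μ = 20 proposals per cluster. Together with the
  calibrated parent intensity this gives count sd
  √(970 + κμ²⟨p²⟩·|W|) ≈ 76, matching the stated range, and a
  cluster-induced variance inflation of the intensity fit of ~2×.
* `parent_intensity` κ is *calibrated*: the retained-count expectation
  is κμ∫_W exp(β·z − s_max) dx (by Fubini over parent positions), so
  κ is set to hit a target mean of 970. The printed β is therefore
  treated as the *shape* of the intensity; the realized truth is
  (β₀ + log(κμ) − s_max, β₁, ..., β₅), with s_max the exact maximum
  of the quadratic over the square (stationary point / edges /
  corners, enumerated in closed form). Disc smoothing over radius
  0.03 perturbs this truth by well under 1% of the Monte-Carlo scale
  and is ignored.

The acceptance integral uses a 400×400 midpoint rule; an
endpoint-weighted grid misallocates mass at the intensity peak in the
corner and was measurably (≈2.5%) off.

What the generator does *not* emulate: real case locations come with
per-person multiplicity (handled in the sanitizer via ε/(mh) but not
exercised by the simulator, which makes every point its own person),
irregular coastline-shaped windows, and temporal structure. Passing
tests therefore speak to the mechanism and the inference machinery,
not to geography-specific artifacts.

### Intensity fitting and honest variance

`fit_intensity_loglinear` maximizes the Poisson composite likelihood
Σ log λ(x_i) − ∫λ with a Berman–Turner quadrature: a 64×64 dummy
grid, counting-tile weights a/(1 + n_data-in-tile), and a weighted
Poisson GLM. Coefficients move by well under the standard error when
the grid is doubled.

For clustered (non-Poisson) patterns the information-based vcov is
too small. The variance correction estimates the score variance from
6×6 spatial blocks: S_b = Σ_{i∈b} z(x_i) − ∫_b z λ̂, and
Σ̂ = B/(B−1) Σ_b S_b S_bᵀ; the reported vcov is the sandwich
H⁻¹ Σ̂ H⁻¹ floored at the naive vcov (clustering can only inflate, so
adjusted variances never undercut naive ones; the floor is a PSD
clip of Σ̂ − H). Blocks of side 1/6 are ~3× the cluster diameter, so
cross-block score correlation is negligible, while 36 blocks keep the
variance of the variance modest.

A more classical two-step — minimum contrast of the empirical
inhomogeneous K-function against the Matérn-cluster K, then a
pair-correlation sandwich — is provided as
`estimate_cluster_params` and works when the fitted trend is mild.
It is *not* used inside the fit: under the study's log-quadratic
surface the intensity spans e^{14.5} across the window, and the
1/λ̂-weighted K estimator becomes so heavy-tailed that its small-r
mean sits below even the Poisson baseline (verified empirically with
both fitted and true intensities), driving the contrast fit to the
no-clustering boundary. The blocked estimator restores 0.93–0.96
empirical coverage for all six coefficients where the naive vcov
gives 0.81–0.86.

Known limitation: with the calibrated design the intercept's
composite-likelihood standard error is ~1.3. Published results for
this design report an original-column RMSE of 0.466 for the
intercept, which is below the Poisson-information lower bound (~0.93)
of any point process with ~970 points on this surface — the printed
generating parameters and the printed dispersion cannot both hold.
This package reproduces the *calibrated* design faithfully:
no-sanitization coverage is nominal, coverage stays near-nominal at
ε = 1 (the sanitization bias is small relative to the estimator
noise), and at ε = 0.5 intervals over-cover because the between-set
variance inflates T. The published under-coverage at ε ≤ 1 requires
the unreachable bias-to-SE ratio and is not reproduced.

### Heat maps

Gaussian kernel intensity on a regular grid, each kernel renormalized
by its erf mass inside the rectangle so the raster integrates to the
point count over the region (±1% at a 128×128 grid). The bandwidth
has no canonical value for this application; it is a required
argument rather than a default.

## Network release

The edge-count-only ERGM p(𝓔|θ) ∝ exp(θ·E) is the Bernoulli graph
with dyad probability logit⁻¹(θ); its MLE is closed-form,
θ̂ = log(E/(N−E)), Var = 1/E + 1/(N−E), identical to an
intercept-only logistic regression on the N dyad indicators (asserted
to 1e-8 in tests).

`dp_ergm_release` spends each release's budget ε/m in two equal
halves: (a) sanitize E with Laplace noise, clamp to [0, N], and draw
θ from the induced posterior — with a uniform prior on the dyad
probability, p | Ẽ ~ Beta(Ẽ+1, N−Ẽ+1) and θ = logit(p); E is
sufficient for this model, so the draw is post-processing of a
sanitized statistic; (b) independently sanitize E again, round,
clamp, and generate the surrogate from ERGM(θ) *conditional on the
edge count*, which for the edge-only model is the uniform law over
graphs with that many edges (θ cancels). Richer conditional
generation (edge-swap MCMC for multi-statistic models) sits behind
the same contract but only the edge-only model is exercised.

Consequence worth stating: surrogates from the edge-only model carry
no triangle surplus (expected triangles C(n,3)p³ < 0.1 at n = 100,
E ≈ 39), so descriptive statistics that depend on closure are *not*
preserved by this model class; the summary-statistics toolkit
(degree distribution, edgewise shared partners, TVD between ESPDs,
betweenness, and closeness (A_i/(n−1))²/C_i with isolated nodes at 0)
is there to measure exactly that kind of structural fidelity. The
`simulate_ctn` clustering knob (triangle-closing rewires at constant
edge count) exists to build such fixtures.

The randomized-response baseline flips each dyad independently with
probability 1/(1+e^ε) (kept with e^ε/(1+e^ε)), which is ε-DP per
dyad by direct likelihood-ratio computation; the edge count is
debiased by (count − Nq)/(1 − 2q).

## Multiple-synthesis inference

With m releases, estimates β̂⁽ˡ⁾ and within variances w⁽ˡ⁾ combine as
β̄, B (between), W (within), T = B/m + W, and a t reference with
ν = (m−1)(1 + mW/B)². B = 0 (all estimates identical) takes the
ν → ∞ limit — the normal reference — instead of failing. m defaults
to 3, the low end of the recommended 3–5: more releases sharpen the
between-variance estimate but thin each release's budget. Calibration
is property-tested: with Gaussian data-level noise shared across
releases (entering W) and independent per-release synthesis noise
(entering B), 95% intervals cover at 0.95 ± 0.02 over 5,000
replicates.

## Evaluation harness

`run_study` repeats simulate → sanitize → estimate, with per-repeat
generators spawned as `default_rng([seed, repeat])` so studies are
reproducible and order-independent. Metrics are bias, RMSE, and
95%-CI coverage per parameter, each with a Monte-Carlo standard error
(delta method for RMSE); RMSE² ≥ bias² is asserted on every report.
Failed fits (non-convergence, boundary MLE) are dropped and counted;
more than 10% failures aborts the study rather than reporting a
quietly biased summary. Presets mirror the three study designs —
ε ∈ {0.5, 1, 2, 5}, m = 3, with 1,000 / 1,000 / 500 repeats — and a
`scale` factor shrinks repeats proportionally; the package's own
end-to-end tests run the location studies at 200 repeats and the
network study at 500, sizes at which the binomial error of a coverage
estimate (±0.03 at 95%) is still informative.

## Degenerate inputs and tie-breaks

* Largest-remainder ties: broken by cell index (stable argsort).
* All-zero tables: sanitizable (truncation keeps zeros); not fittable.
* Empty point sets: heat map warns and returns zeros; intensity fit
  requires at least p + 1 points.
* Edge counts 0 or N: no finite ERGM MLE — a boundary signal the
  harness counts as a failed fit.
* ε = 0 in RR debiasing leaves q = 1/2 and is rejected (the released
  graph is independent of the data).
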