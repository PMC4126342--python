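# Methods

## Model

The ribosome is treated as a two-state motor moving along its mRNA under a
constant opposing force `F`:

- **TRANSLATING.**  Instantaneous one-codon (3-nt) steps occur as a Poisson
  process with rate `v(F) = v0·exp(−F·x̃/kBT)` (codons/s).  The Arrhenius
  form encodes a single force-sensitive barrier crossing with characteristic
  distance `x̃`.  The state is left for PAUSED at rate `k_p`.
- **PAUSED.**  No stepping; return to TRANSLATING at rate `k_−p`.  Pauses
  are off-pathway: their entry and exit rates do not depend on force.

Each step shortens the measured tether extension by the worm-like-chain
extension of one codon at the applied force.  The WLC uses the Marko–Siggia
interpolation `F = (kBT/P)·[1/(4(1−z)²) − 1/4 + z]` with persistence length
`P = 1 nm`, rise 0.59 nm/nt and `T = 296 K`; the model names only these two
polymer parameters, so no enthalpic-stretch term is included.  The inverse
map (force → fractional extension `z`) is obtained with Brent's method on
`z ∈ [0, 1−1e−9]`, leaving residual force errors far below 1e−9 pN;
bracketed root finding is guaranteed to converge and needs no derivative.
At 8 pN one codon corresponds to 3 × 0.357 = 1.07 nm of extension.

Simulation is event-driven (Gillespie): competing exponential clocks are
drawn exactly, so there is no time-discretisation bias.  The recorded trace
is the sample-and-hold staircase at 1 kHz plus stationary
Ornstein–Uhlenbeck noise (autocorrelation `σ²·exp(−t/τ)`,
`τ = 1/(2π·f_c)`), emulating low-pass bead/trap fluctuations.  The force
clamp is ideal; bead/handle Brownian dynamics, feedback transients, EF-G
binding kinetics and mRNA secondary structure are out of scope.

## Generator defaults (the study conditions)

| parameter | default | why |
| --- | --- | --- |
| `v0` | 2.9 codons/s | published zero-force velocity |
| `x̃` | 1.4 nm | published characteristic distance |
| `k_p`, `k_−p` | 0.16, 0.14 s⁻¹ | published pause entry/exit rates |
| forces | 2, 4, 6, 8, 10 pN × (10, 11, 11, 11, 11) traces | 54 traces spanning 2–10 pN, the published dataset size, with the lowest force under-represented as in the source data |
| `mrna_codons` | 62 | the (TTC)₆₂ template used in the assay |
| `sample_rate` | 1 kHz | instrument sampling |
| `baseline_duration` | 30 s | pre-elongation recording; comfortably longer than the 4001-sample smoothing span required for noise calibration |
| `max_duration` | 360 s | typical single-molecule recording cap; high-force traces end censored |
| `noise_sd`, `f_c` | 2 nm, 50 Hz | plausible bead noise; the source reports no noise figures, so these are declared assumptions, not inferences |

The generator emulates the statistical structure the analysis assumes —
exponential dwells, force-independent pausing, WLC geometry, stationary
correlated noise.  It does **not** emulate drift, tether rupture,
force-feedback transients, position-correlated pausing, or heterogeneity
between ribosomes, so passing tests say nothing about robustness to those
features of real data.

## Analysis chain

1. **Smoothing.**  Savitzky–Golay, span 4000 samples (widened to 4001; SG
   windows must be odd and one sample is immaterial at 1 kHz), polynomial
   order 2 — the standard choice that preserves local curvature.  Kernels
   are applied by FFT convolution, mathematically identical to direct
   convolution (asserted against a normal-equations oracle in the tests)
   but O(n log n).
2. **Instantaneous velocity** from the SG first-derivative coefficients
   over the same window, i.e. the slope of the local polynomial fit;
   divided by the WLC extension per codon *at each trace's force* (the
   conversion is applied per trace, not globally).  Sign convention:
   extension decrease → positive velocity.  Samples within half a span of
   either end are trimmed, not extrapolated.
3. **Noise calibration.**  `σ_pause` = standard deviation of baseline
   velocity samples.  Only samples whose full window lies inside the
   baseline are used (an edge guard of half a span), so no window mixes in
   elongation data.  A zero-variance baseline is refused: the threshold
   would be degenerate, and the caller must supply a noise scale.
4. **Segmentation.**  `|v| < 2.5·σ_pause` → pause, else burst; contiguous
   runs become segments; segments shorter than `min_segment = 0.5 s` are
   merged into their longer neighbour (sub-second chatter is not scored).
   Segment boundaries are shared samples, so durations partition the
   analyzed region exactly and distances (smoothed-extension drop per
   segment, in codons) telescope to the end-to-end drop.  Boundary
   segments are flagged censored.
5. **Per-trace summary.**  Pause-free velocity = Σ burst distance / Σ burst
   duration.  Censored segments contribute distance but are excluded from
   the dwell-time lists, the standard dwell-time convention.
6. **Aggregation and fits.**  Per force, the mean velocity is weighted by
   each trace's total translocated distance; its standard error uses the
   distance-weighted variance over the effective sample size
   `(Σd)²/Σd²`.  The Arrhenius law is fitted by weighted nonlinear least
   squares (weights 1/sem²; groups without a defined sem get the weight of
   the least precise defined group).  The initializer is the ln-linear
   regression of velocity on force, so the fit is deterministic.  95% CIs
   use the t quantile with n−2 degrees of freedom on the parameter
   covariance; uniformly rescaling the sems leaves the estimates unchanged
   and widens the CIs.  The stall force solves `v(F) = 0.1 nt/s`
   (`v0` × 3 converts codons/s to nt/s), with first-order error
   propagation from the fit covariance.
7. **Dwell times.**  Non-censored burst and pause durations are pooled
   across traces and forces (raw pooling, no per-trace weighting) and
   fitted by the exponential MLE, `rate = 1/mean` — identical to the
   inverse-mean estimator — with the exact gamma-relation 95% CI
   (`2·rate·Σt ~ χ²(2n)`) and a one-sample KS statistic as goodness of
   fit.  Per-force rates feed a weighted straight-line fit of rate vs
   force; the verdict is "independent" iff the slope CI contains zero.
8. **Mechanism call.**  Candidates 1.48/3, 2·1.48/3 and 1.48 nm are tested
   for containment in the `x̃` 95% CI.  Full step inside with both substeps
   excluded → `brownian_ratchet_consistent`; full step excluded with a
   substep inside → `substep`; otherwise `indeterminate`.  The strict CI
   rule is deliberately conservative: a "very close to the step" point
   estimate is reported as text, never promoted to the machine verdict,
   and a power stroke with a transition state near the full step can never
   be excluded by `x̃` alone.
9. **Energetics.**  Fixed constants (kB = 0.0138065 pN·nm/K,
   N_A = 6.02214×10²³ mol⁻¹, 1 kcal = 4184 J) make the conversion graph
   exactly consistent.  "±" values are treated as SEMs and propagated in
   quadrature.  Stored values keep full precision; the kBT equivalent of
   the transpeptidation energy is additionally reported through the
   stepwise-rounded chain (kcal/mol rounded to one decimal before
   conversion), which is how such numbers are conventionally quoted —
   full precision gives −6.25 kBT, the rounded chain −6.3 kBT.

## Numerical conventions and degenerate inputs

- WLC inversion: Brent, xtol 1e−14; vectorised over force grids.
- Even smoothing spans are widened by one sample; spans longer than the
  series raise with an instruction to shorten.
- Merging ties (equal-length neighbours) go to the right; after merging,
  adjacent equal labels coalesce, so labels always alternate.
- A trace with no burst yields an undefined velocity and is flagged;
  force groups that are all-undefined are dropped with a warning.
- Fits refuse fewer than 3 force points; dwell fits refuse n < 2 or
  non-positive durations; fewer than 5 pooled pauses sets a warning flag.
- All simulation randomness flows through one integer seed per trace;
  experiment collections derive child seeds from a master seed via
  `numpy.random.SeedSequence`, and repeated runs are bit-identical.

## Validation strategy and problem sizes

The test suite validates each stage against independent oracles: plain
bisection for the WLC, normal-equations SG coefficients with brute-force
convolution for the smoother, recomputed velocity series for σ_pause,
ground-truth event records for segmentation, closed forms for the
arithmetic identities, and exact-coverage simulation for the dwell-time
CIs.  The flagship recovery study simulates ten independent 54-trace
experiments at the default (published) parameters and reports median
recovered `v0`, `x̃`, `k_p`, `k_−p`; it completes in about half a minute on
one CPU, which is why ten replicates is the chosen study size.

## Known limitations

**Threshold segmentation is biased at high force under these study
conditions, and the recovery study inherits that bias.**  Quantitatively:

- The minimum achievable noise of any 4-s slope estimator on the default
  OU noise is ≈0.07 nm/s, so the 2.5 σ_pause threshold (≈0.17 nm/s in
  velocity units) exceeds the true signal at 10 pN (0.11 nm/s):
  translocation there is classified as pausing.
- With the default kinetics the mean burst contains `v(F)/k_p` ≈ 9 codons
  at 2 pN but only ≈0.6–1.2 codons at 8–10 pN.  A single 3-nt step smeared
  over the smoothing span produces a velocity excursion of ≈0.4 codons/s
  regardless of the true rate, so above ~6 pN detected "bursts" are
  isolated steps and the measured velocity saturates near that excursion
  scale, compressing the fitted force–velocity curve (both `v0` and `x̃`
  biased low).
- At 8–10 pN the inter-step dwell (5–11 s) is comparable to the pause
  dwell (7 s), so pauses and slow stepping are statistically
  indistinguishable for any velocity-threshold rule; pooled dwell-time
  sets are contaminated accordingly (`k_p` biased high, `k_−p` low).

These are properties of the threshold method at signal-to-noise ≲ 1, not
of the surrounding machinery: replacing only the segmentation step with the
ground-truth pause intervals (everything else identical) recovers
`v0 = 2.9 codons/s`, `x̃ = 1.4 nm`, `k_p = 0.166 s⁻¹`, `k_−p = 0.142 s⁻¹`
to within a few percent, and the bias is not cured by lowering the noise —
at low noise the shrinking threshold starts resolving individual codon
steps, and inter-step dwells are scored as pauses.  The method requires
burst velocity ≫ threshold ≫ intra-burst fluctuation, a condition that the
default kinetics violate beyond ~4–6 pN for any smoothing span.  Median
recovered values under the default chain are approximately `v0 ≈ 1.5`,
`x̃ ≈ 0.65 nm`, `k_p ≈ 0.23 s⁻¹`, `k_−p ≈ 0.09 s⁻¹`; the acceptance script
reports whatever the pipeline honestly produces.  Hidden-Markov or
changepoint segmentation would be the statistically sound alternative in
this regime but is deliberately out of scope.

Other limitations: no drift correction; no step-finding (individual steps
are not scored even when visible); single constant force per trace
(force-ramp protocols unsupported); `min_segment` and the SG order are
declared conventions, exposed in the configuration, not inferences from
data.
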