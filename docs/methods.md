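# Methods

This note documents the models implemented in `nanorelease`, the
calibration of the synthetic-data generator, the numerical choices made
where the design was genuinely open, and the limits of what the test suite
demonstrates.

## The problem

An electrospun core–shell nanofiber mat carries 5-fluorouracil (5FU) and
Fe₃O₄ nanoparticles; its release behaviour is governed by four structural
factors — sheath:core feeding ratio, chitosan share of the sheath polymer
(CS%), Fe₃O₄ % and 5FU % — explored over an 18-run Taguchi design (plus an
AMF-frequency factor that has no effect on release). The computational task
is inverse design: learn the map *structure → release parameters* from few
measurements, then search the structure space for the formulation whose
predicted release profile is closest to an ideal (no burst, full release,
240-hour duration, full loading).

## Synthetic-data generator

Raw cumulative-release curves for the 18 runs are available only as
figures, so all pipeline stages run on synthetic data from an explicit
generating model. It is a **linear main-effects model with Gaussian
replicate noise**; interactions are deliberately absent (an L18 cannot
identify them, and only main effects are reported for the real system).

Calibration (defaults of `EffectSpec`):

| quantity | value | rationale |
|---|---|---|
| baseline (at design centroid) | BR 30%, TRmax 120 h, RTRmax 75%, Le 74% | centre of the reported ranges (release windows 96–144 h, Le 62–86%) |
| CS span 7.69→25% effect | +4 BR, +28 min TRmax, +10 RTRmax, +17 Le | the reported CS main effects |
| Fe₃O₄ 1→5% effect on TRmax | ∓16 min (default −) | reported magnitude; the two reported statements disagree in sign, so `fe3o4_trmax_sign` switches it |
| feeding-ratio effects | +2.5 BR, +4 h TRmax, +3 RTRmax per unit | direct positive effects are reported without magnitudes; chosen modest |
| drug %, AMF frequency | 0 | reported as having no effect |
| noise SD | BR/RTRmax/Le 1.5 points, TRmax 4 h | replicate SDs of the published loading-efficiency table are 0.9–2.2; TRmax noise set larger since release times are read off 12–24 h sampling grids |

Post-processing enforces physical invariants: Le clipped to [60, 90],
0 ≤ BR ≤ RTRmax ≤ 100, TRmax ≥ 1 h. Curves are Korsmeyer–Peppas power-law
shapes **anchored** to each record's (TRmax, RTRmax) with the exponent
chosen to pass through (0.5 h, BR), so that extracted release parameters
and fitted kinetics coefficients are mutually consistent (the implied
k ≈ 0.34–0.44, n ≈ 0.12–0.17 match the published coefficient table without
being fitted to it). Gaussian noise on the curve is followed by an isotonic
pass, clipping to [0, 100] and pinning to 0 at t = 0.

What the generator does **not** emulate: pH dependence (the acidic-medium
contrast is descriptive only), mechanistic diffusion/erosion, factor
interactions, and non-Gaussian measurement error. Passing tests therefore
demonstrate that the pipeline recovers structure *of this kind* at this
noise level — not that the real system satisfies a linear model.

`validate_dataset` provides a self-check: per factor × response, the
difference of extreme-level means with a 2×SE flag. It is a generator
sanity summary, not an inferential ANOVA.

## Kinetics

All six dissolution models are least-squares fits of the release fraction
f = cumulative/100 versus hours, with R² always on the untransformed
fraction scale. Numerical choices:

- **First order** is used in fraction form f = 1 − e^(−k₁t) (asymptote 1),
  because curves are normalized percentages.
- **Korsmeyer–Peppas** is fitted only on points with f ≤ 0.6 (the standard
  validity window of the power law) and t > 0; a log–log linear fit
  (`peppas_loglog`) provides starting values and an independent
  cross-check. Constraints: k > 0, 0 < n < 1.5.
- **Hixson–Crowell** is fitted as f = 1 − (1 − k·t)³ with the cube-root
  core clipped at 0; the transformed-scale linear fit seeds the optimizer.
- **Weibull** uses the f = 1 − exp(−t^b/a) convention with t in hours.
  The published per-run (a, b) values (a ≈ 13–53) cannot be reconciled
  with hour-scale fractions under any common form of the model, so they
  ship as reference data only and are never used as numerical anchors.
- Nonlinear fits run `scipy.optimize.curve_fit` with tolerances 1e−14,
  giving parameter recovery to ≲1e−8 relative on noiseless data.
- `extract_release_params` defines TRmax as the **earliest** time attaining
  the curve maximum, so plateaus resolve to their onset; BR interpolates
  linearly at 0.5 h.
- Transport classification (Peppas exponent, cylinder): n ≤ 0.45 Fickian,
  0.45 < n < 0.89 anomalous, n ≥ 0.89 case II; boundaries inclusive toward
  the named classes. Film and sphere thresholds are included for
  completeness.

## Surrogate

Architecture: 4 inputs → H hidden (tanh) → 4 outputs (logistic), H ∈ [2, 7]
with 6 as default. Inputs normalize to [−1, 1] (bipolar). Outputs normalize
to **[0.1, 0.9]** rather than bipolar form: the logistic output activation
has range (0, 1), so bipolar output targets would be unreachable; keeping
targets strictly inside the activation range is the standard resolution and
is treated here as a deliberate design choice.

Training is Levenberg–Marquardt on F = β·E_D + α·E_W with Foresee–Hagan
evidence updates after every accepted step:
γ = N_w − 2α·tr(H⁻¹) with H = 2β·JᵀJ + 2α·I, then α = γ/(2E_W),
β = (n − γ)/(2E_D). Initial α = 1e−4, β = 1; μ (LM damping) starts at 1e−3
with ×10 / ÷10 adaptation. Training is deterministic given the seed (used
only for the uniform [−0.5, 0.5] weight init). Guards: γ clipped to
(0, N_w]; β frozen when E_D ≈ 0 or γ ≥ n; hitting the iteration cap
(default 150) returns the model with a warning rather than failing.
Setting `bayes=False` pins α = 0, giving the unregularized network used in
the shrinkage comparison (‖w‖ under regularization ≤ ‖w‖ without, on the
same data and seed).

Small-data protocol (mirroring the study): replicate 1 of each run is the
real training set (18), replicates 2–3 the test set (36); Gaussian-noise
augmentation (μ=0, SD=0.05 normalized, 10 copies each, originals excluded)
of all 54 records yields 540 derived records; training uses 540 + 18 and
testing the 36 real records. This literal protocol leaks test information
through augmentation and normalization; `leakage=False` restricts both to
the training records, and both behaviours are exercised in tests. The
alternative strategy is 10-fold CV on the raw 54 records. Metrics (MSE and
R² pooled over the four outputs) are computed on the normalized scale —
the scale the comparison needs; whether the original metrics were
normalized is not stated, so this is fixed by decision. Reported sweep and
comparison metrics are means over `repeats` (default 10) seeded trainings.

## Genetic algorithm

Real-coded chromosomes (feeding ratio, CS%, Fe₃O₄%, 5FU%) in the box
([1,2], [7,23], [1,7], [1,5]). Note the CS box keeps the published upper
bound 23% although the derived chitosan share of the 1:2 sheath ratio is
25.0%; the 23% figure is retained for the optimizer as printed, while the
data-side CS values use the derived 7.69/14.29/25.00%.

Interpretations where the original description is underspecified:

- **Selection**: roulette-wheel on *rank-inverted* weights (best rank gets
  the largest slice). Fitness-proportional selection is ill-defined for a
  minimization objective near zero; rank weights are the standard fix.
- **Fitness TRmax term**: implemented as |240 − TRmax|/240. For
  TRmax ≤ 240 h (always, in practice) this equals (240 − TRmax)/240 and
  rewards longer release, consistent with the stated goal; the divisor 5
  is kept as the original convention even though four terms are summed.
- **Migration** ("forward", fraction 0.2): the population (20) is split
  into two demes; each generation the best ⌈0.2·deme⌉ individuals of deme
  i replace the worst of deme i+1 around a ring.
- **Mutation**: Gaussian, SD = 10% of gene span, annealed linearly to a 5%
  floor over the generations. Blend crossover with extension 0.25.
- Individuals are clipped to the box every generation; one elite per deme
  is preserved, so the best-so-far trace is non-increasing by construction.
- Stopping: 100 generations, fitness limit 0, or < 1e−6 improvement for 5
  consecutive generations (stall). Non-finite objective values are
  assigned worst fitness and logged, not fatal.

The study-scale procedure runs the GA 20 times from derived seeds and
reports the best run. On a separable convex test objective this recovers a
known optimum to < 1% of each gene span (best of 20) with the median run
under 2%.

## Pipeline and problem sizes

`run_pipeline` chains the stages with stage seeds derived from the single
pipeline seed, making the whole run a pure function of its configuration
(verified bit-for-bit in tests). Default sizes are the study conditions:
54 records, 540 augmented, hidden sweep 2–7 × 10 repeats, GA 20 × 100
generations — about 20 seconds on one CPU. Stage artifacts (CSV/JSON)
embed a hash of the configuration, and the report renderer refuses to mix
artifacts with different hashes.

## Known limitations

- The surrogate's accuracy statements are conditional on the generator's
  linear main-effects world; real release data could break monotonicity
  assumptions the tests rely on (e.g. monotone CS predictions).
- The published fitness value of the optimal chromosome (0.2065) is not
  reproduced exactly by the fitness formula applied to the published
  rounded network estimates (0.2098); the discrepancy plausibly reflects
  unrounded network outputs and neither value anchors any test.
- The published RTRmax estimation error (10.65%) is inconsistent with the
  printed measured/estimated pair under the error formula that reproduces
  the other three columns (10.23%); the formula is implemented uniformly.
- GA "forward" migration semantics and the activation-function permutation
  sweep are reconstructions: the two-deme ring above, and an activation
  pair fixed at tanh/logistic (the selected pair), respectively.
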