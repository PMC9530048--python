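# Methods

This note documents the models, numerical choices and synthetic-data design
behind `rbcmech`, and what the test suite does and does not establish about
real measurements.

## Contact models

Two views of the same cell are deliberately kept separate, mirroring common
practice in force spectroscopy of soft cells.

**Sneddon cone (module `sneddon`).** Force–distance curves are reduced to an
apparent Young's modulus E by least squares of F against δ² with prefactor
2 tan(α)/(π(1−ν²)). The model is linear in E, so the estimate is a
closed-form projection and is exactly invariant to data beyond the fit range
(default δ_max = 0.5 µm). ν is fixed at 0.5 (incompressible cell). The tip
half-angle α is a required calibration input, default 20° — typical for the
sharp conical probes used on RBCs; fitted E scales as 1/tan α, so all E
values are conditional on α. When δ_max exceeds 10% of the local sample
height the fit emits a warning rather than applying a bottom-effect
correction; thin-film corrections are out of scope.

**Standard linear solid with cantilever (modules `sls`, `simulate`).** The
cell is an equilibrium spring k₂ in parallel with a Maxwell arm (spring k₁
in series with dashpot f); the cantilever adds spring k_c. Which spring sits
in the Maxwell arm is fixed by the equations themselves: the dwell
equilibrium and the post-step equilibrium both involve k₂ alone, and
τ_c → f/k₁ as k_c → ∞, so k₂ is the lone equilibrium spring and k₁ the
Maxwell-arm spring. The SLS parameters are reported as spring constants
(N/m) and damping (N·s/m), not moduli: converting them to Pa would require a
contact-geometry model the linear network does not carry.

## The two-step relaxation protocol and its inversion

The protocol is: indent fast (35 µm/s) to a trigger force (2 nN), hold at
constant height (dwell 1), retract the tip by a known step J within one
sample, hold again (dwell 2). Dwell 1 is fitted with a single exponential
d(t) = A e^(−t/τ_c) + d_b; dwell 2 supplies the new equilibrium d_c; then
(k₁, k₂, f) follow in closed form (see README). Design choices:

- **J is measured, not configured**: the difference of the median piezo
  levels of the two dwells. The trace is the ground truth for the step the
  instrument actually executed.
- **Exponential fit initialisation** is deterministic: d_b0 = mean of the
  final 10% of samples, A₀ = d(0) − d_b0, τ₀ = first time the residual
  decays to A₀/e; τ_c is bounded to [2 samples, 10 dwell lengths]. The fit
  runs on deflection normalised to O(1) — metre-scale residuals otherwise
  leave the optimiser's cost gradient below its termination tolerance.
  Fits with amplitude at the noise floor or τ_c pinned at a bound are
  flagged, not silently accepted.
- **Finite-ramp amplitude correction.** The inversion assumes the
  indentation is instantaneous, but at 35 µm/s the ramp lasts a few
  milliseconds and the cell relaxes slightly during it. For a linear ramp
  the dwell amplitude is attenuated by exactly (1 − e^(−x))/x with
  x = t_ramp/τ_c, so the fitted amplitude is multiplied by the inverse
  (≈ +1.3% at the default settings). Without this correction k₁ and f carry
  a systematic ≈ 2% low bias even on noiseless data.
- **Single exponentials only.** Multi-exponential or power-law relaxation
  models are out of scope by design.
- Dwell 2 falls back to the mean of its final 10% when its exponential is
  degenerate (already at equilibrium).

Aggregation is hierarchical: curve fits average to cell means (± SEM), cell
means average to subject means — subjects are never pooled over raw curves,
so cells with different curve counts weigh equally.

## Forward simulator

During contact the deflection obeys a first-order linear ODE driven by the
piezo trajectory (README). For piecewise-linear Z(t) the exact solution on
each piece is (linear particular solution) + (exponential transient with
time constant τ_c); the integrator propagates this closed form between
knots. Consequences used by the tests: dwell segments equal the analytic
exponential to < 1e−9 relative; the quasi-static ramp limit gives sample
stiffness k₂ and the fast limit k₁ + k₂ (each verified within 2%); the
instantaneous step J is modelled as a one-sample ramp, whose fast-limit
response equals the elastic-network jump.

The **speed sweep** composes the linear SLS contact force with the Sneddon
fit: at each speed an FD ramp is simulated to 0.5 µm of indentation and the
(δ, F) record is fitted by the cone parabola. Apparent E is then exactly
proportional to the effective stiffness, so E(fast)/E(slow) → (k₁+k₂)/k₂.
Two caveats are intentional. First, the absolute E scale of this composition
is arbitrary (a linear spring has no Pa scale), so only ratios and rankings
of apparent E are meaningful in the synthetic cohort. Second, the E(v) rise
of the linear SLS spreads over ~2 decades of speed, so the E_low asymptote
of a linear-v sigmoid is weakly identified on such data (the offset term
absorbs it); asymptote checks therefore evaluate the fitted curve at v = 0
rather than the raw E_low parameter. On narrow, genuinely sigmoidal data
(e.g. 1–20 µm/s) the four parameters are recovered exactly.

## Synthetic cohorts: what is emulated

The patient data behind the study conditions are not public, so the cohort
generator is a first-class module. Defaults (all configurable in
`CohortSpec`):

- **Design**: 20 controls + 16 patients, 10 cells/subject, 64 curves per
  cell map; deflection noise σ_d = 0.5 nm; control ages ~ N(66, 8²), patient
  ages ~ N(75, 7²) (groups deliberately not age-matched, so the ANCOVA has
  work to do).
- **Mechanics**: subject parameters lognormal around group means (CV 0.25),
  cell parameters lognormal around the subject (CV 0.12). Control means
  (k₁, k₂, f) = (0.015 N/m, 0.010 N/m, 0.0015 N·s/m), i.e. τ_c ≈ 0.16 s at
  k_c = 0.03 N/m. The patient group multiplies (k₁, k₂, f) by
  (1.48, 1.34, 1.50) — upward shifts with damping affected most, set via the
  binormal identity AUC = Φ(Δlog/(σ_log√2)) so the single-marker AUCs land
  near 0.87/0.80/0.88. Within a group the three latents are conditionally
  independent; their pooled correlation arises from the group effect alone.
- **Apparent E**: reference apparent modulus (control-mean SLS element
  composed with the Sneddon fit at 5 µm/s) times a lognormal
  geometry/contact factor (CV 0.20) with identical means in both groups —
  apparent E at the acquisition speed is modelled as dominated by tip
  placement and contact geometry, not by the cells' SLS shift. E is
  therefore null both marginally and conditionally on the SLS parameters.
  An earlier design that scaled each subject's own speed-dependent stiffness
  by a group-calibrated factor was rejected: it hid a perfectly
  discriminative linear combination (E minus a function of k₁,k₂,f) that no
  real dataset would contain.
- **Covariates**: ten routine hematological indices with clinically
  plausible marginals, coupled to the mechanical latents through a Gaussian
  copula with group-specific Spearman targets (e.g. MCV–k₁ −0.7 in
  controls); targets are converted to copula correlations by
  r = 2 sin(πρ/6) and the joint matrix is verified positive definite.
- **Reproducibility**: one seed fixes everything; `simulate_cohort_table`
  draws subject-level tables directly from the hierarchy (used for
  replicate-heavy statistical studies, where refitting thousands of raw
  curves would only add fitting noise orders of magnitude below the
  between-subject spread), while `simulate_cohort` generates and optionally
  writes every raw curve.

What passing tests on this generator do **not** show about real data: real
FD curves carry baseline drift, adhesion, and contact-geometry variation
that the linear-SLS contact does not produce; real relaxation curves can be
multi-exponential; real covariate distributions are skewed and censored. The
generator establishes that the analysis chain is correct and well
conditioned, not that real RBC data meet the SLS assumptions.

## Statistics layer

- **Wilcoxon (Mann–Whitney)**: exact enumeration for combined n ≤ 20 without
  ties, otherwise normal approximation with tie and continuity correction
  (scipy backend).
- **Sequential ANCOVA**: Type I sums of squares with age entered before the
  group factor, computed from nested OLS fits (statsmodels) so the entry
  order is pinned regardless of design-matrix conventions. Missing
  covariates drop a subject from that model only, with the count reported.
- **Spearman maps**: midrank ρ; exact permutation p for n ≤ 9 (full
  enumeration with cached permutation matrices), t approximation otherwise;
  per-group maps mask entries at α = 0.05 with strength bands weak/moderate/
  strong at 0.3 and 0.7. No multiplicity adjustment, by design.
- **Logistic regression**: maximum likelihood on standardized features
  (statsmodels). Perfect separation is detected from fitted probabilities
  and reported with coefficients capped at ±25 rather than left to diverge.
- **Backward stepwise**: IC = −2 log L + penalty × (number of coefficients),
  default penalty ln(n) — a strong, sample-size-dependent per-parameter
  penalty for small cohorts. The literal printed form of the criterion this
  mirrors (a constant 2k with k = ln n) cannot penalise model size and is
  not implemented; the per-parameter reading is the standard one. The full
  IC trace is recorded. Small-sample caution: with ~36 subjects and 10
  candidate features the in-sample fit approaches separation and the
  removal order among near-redundant or null features becomes unstable —
  cross-checked against R's `MASS::stepAIC`, which produces identical traces
  on the same tables. Single runs of backward selection at this sample size
  should be read qualitatively, not as a stable ranking.
- **ROC/AUC**: pair-counting (Mann–Whitney) AUC with ties at ½, equal by
  construction to the trapezoidal area of the empirical curve; markers whose
  low values indicate disease are auto-flipped with a flag. Confidence
  intervals use the DeLong structural-components variance (verified
  numerically identical to R pROC's) with a logit-scale Wald interval
  truncated to [0, 1]; the logit transform is this package's choice for
  small-sample stability, so interval endpoints differ from pROC's
  untransformed default while the variance is the same. Coverage at n=50+50
  measures ≈ 95% in simulation.

## Problem sizes used in the checks

End-to-end recovery uses 200 noisy replicates of a single default curve;
the cohort signature uses 50 subject-table replicates of the default 36-
subject design; DeLong coverage and the null-AUC baseline use 1000 Monte-
Carlo replicates at 50+50. The pipeline-level tests run a reduced design
(≤ 10 subjects, ≤ 5 cells, ≤ 8 curves) — chosen as the smallest sizes at
which the between-subject spread still dominates fitting noise.

## Known limitations

- Contact-point detection assumes a flat baseline followed by parabolic
  growth; strongly adhesive or drifting baselines will bias it.
- The ramp-amplitude correction assumes the whole approach segment is in
  contact (true for protocol-generated curves; for re-segmented real data
  the in-contact portion should be supplied).
- Apparent-E absolute values from the speed-sweep composition have no
  physical Pa scale (see above).
- In-sample AUCs and stepwise selections are reported without resampling or
  optimism correction, matching the analysis style this package mirrors.
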