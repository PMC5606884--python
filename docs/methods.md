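# Methods

This note documents the models implemented in `aposignal`, the
assumptions behind them, the defaults of the synthetic-data generator,
and the numerical choices that matter for reproducing results.

## Receptor-noise-limited conspicuousness

The color model assumes a tetrachromatic passerine eye with cone classes
U, S, M, L, Weber–Fechner transduction (receptor signal = ln quantum
catch) and discrimination limited by independent Gaussian receptor noise
whose standard deviation per channel is the Weber fraction ω. Quantum
catches are trapezoidal integrals of sensitivity × illuminant ×
reflectance on a canonical 1-nm grid over 300–700 nm; all input spectra
are linearly interpolated onto that grid and never extrapolated. Because
the receptor signal difference between stimulus and background is a log
ratio, a uniform rescaling of the illuminant cancels exactly — a
von-Kries-style adaptation assumption, which is also why ΔS, ΔL and E are
invariant to illuminant intensity.

The chromatic distance ΔS uses the standard six-pair tetrachromatic
expansion. Restatements of this expansion in the applied literature
sometimes repeat a pair coefficient — giving (ω_U ω_S)² on the
(Δf_L − Δf_S)² term where the standard form requires (ω_U ω_M)². We
implement the standard form: it is the unique version that equals the
generic n-receptor quadratic form (the Mahalanobis distance of Δf
projected off the uniform-brightness direction), is symmetric under
receptor relabeling, and is invariant to adding a constant to all Δf.
The test suite checks this equivalence against an independently coded
projection-form oracle on random (Δf, ω) draws to 1e-10 relative.

The achromatic channel re-uses the L cone (sensitivity and ω = 0.515);
no separate double-cone sensitivity is modeled. Whole-wing
conspicuousness is the area-weighted arithmetic mean of per-patch E —
area weighting is well motivated (signal size drives avoidance
learning), and the arithmetic mean keeps the result in JND units.

Default parameters: Weber fractions ω_U = 1.0, ω_S = 0.857, ω_M = 0.520,
ω_L = 0.515 (relative cone abundances of a typical passerine retina);
flat (ideal-white) illuminant; packaged synthetic cone sensitivities
(unit-peak Gaussians at 372/445/508/565 nm, sd 25/30/35/40 nm) and a
synthetic green-foliage background (low baseline, 550-nm bump, far-red
shoulder). The sensitivities and background are stand-ins with the right
qualitative shape, all overridable by measured curves; absolute E values
therefore carry no meaning across studies — only contrasts and orderings
computed within one visual system do.

## Pattern simplicity score

PSS = Σ w_i Q_i with Q_i = 4πS_i/L_i² and w_i = S_i/ΣS_i over the
contours of a binarized wing image. Contours are 8-connected foreground
components (preserving thin diagonal elements); area is the pixel count
(× pixel_size²); holes are ignored by default (a flag includes them).
Components under 5 px are dropped as raster noise.

Perimeter estimation is the step that decides whether the analytic
anchors hold. Counting pixel edges inflates a circle's perimeter by
~27% (Q ≈ 0.62); the raw marching-squares polygon at the 0.5 level still
overshoots by ~6% (Q ≈ 0.88). We therefore simplify the marching-squares
polygon with Ramer–Douglas–Peucker (tolerance 1 px) before measuring arc
length: RDP flattens staircase noise into straight segments while
preserving true corners, giving Q within ~0.015 of 1 for disks of radius
≥ 20 px and within ~0.04 of π/4 for squares of side ≥ 20 px. Residual
bias is a fixed corner-cut deficit (half-pixel diagonals at true
corners), so it shrinks with shape size; fragments of only a few pixels
measure biased-low Q, which the generator's bias-characterization test
documents. PSS of a large-shape composite changes by well under 2% under
2× upsampling.

## Attack scoring and background predation pressure

Mark depth implements the field rules: < 2 mm excluded (wear), 2–5 mm
ambiguous (bird or other natural causes), > 5 mm diagnostic bird attack.
Ambiguous marks count toward attacks by default — the conservative
bird-only tally is available via `include_ambiguous=False`, since the
field protocol does not pin this down. Symmetric damage (wings closed at
rest) is one attack. The binary specimen index (attacked / not) is
preferred over the raw count index because it is insensitive to specimen
age; both are computed and their site-level agreement is reported as an
OLS R². Re-captured specimens are removed by ID deduplication. Rate CIs
are Wilson score intervals, which behave at rates near 0 or 1.

Background predation pressure at a site is the binary attack rate on
palatable non-mimetic specimens with wingspan > 50 mm. All rates are
escape-conditional: killed individuals are never inspected, so these are
relative predation proxies, valid for comparisons across sites and
groups, not absolute kill rates.

## Surveys

Encounter rate = summed counts / number of walks, zero-sighting walks
included; sightings beyond 30 m (inclusive boundary) are discarded. No
detection-function modeling is applied: detection distances do not
differ systematically between conspicuous and cryptic rings at these
ranges, so raw counts are comparable; a distance histogram is provided
as a diagnostic. Relative abundance is the mimic:model encounter-rate
ratio.

## Mixed models

The attack model is a binomial-logit GLMM with Gaussian random
intercepts for site and transect-within-site. Estimation is maximum
likelihood with a Laplace approximation: for trial variance parameters
θ = (log σ_site, log σ_transect), the joint penalized likelihood in
(β, u) is maximized by damped Newton iterations (PIRLS) — binary rows
sharing a design cell are first aggregated to binomial counts, which
leaves the likelihood unchanged and makes each fit take milliseconds —
and the Laplace objective l(β̂, û) − ‖û‖²/2 − ½ log det(MᵀWM + I) is
optimized over θ by Nelder–Mead. Wald covariance of β is the Schur
complement of the joint Hessian, i.e. conditional on θ̂, the usual
convention; with 11 sites this undercovers mildly, which is why the
calibration experiments assert ≥ 85% empirical coverage for nominal 95%
intervals rather than exact nominal coverage. Fits against `lme4::glmer`
on the same data agree to a fraction of a percent in estimates, SEs and
log-likelihood (frozen reference values in the test suite).

Treatment contrasts use the most conspicuous ring (Danaus) and model
status as references, so `pp` is the conspicuous ring's slope and the
`ring[...]:pp` interactions are slope differences from it. Complete
separation (all-identical responses, or a diverging coefficient
> 30 on the logit scale) raises an error naming the offending term;
near-zero variance components are flagged as singular but returned.
Model selection across fixed-effect sets is by AIC.

Counts (abundance) use the same machinery with a Poisson or NB2 family
(NB2 dispersion by profile likelihood, alternated with the variance-
parameter fit); a Gaussian-identity family is provided via statsmodels
MixedLM because abundance effects are sometimes reported on the identity
scale — CIs like "0.563–141.407 individuals" only make sense there.
One-way ANOVA (ring effects on traits) is the classical F test.

## LD50

The modified Kärber estimator log₁₀ LD50 = X_m − i(Σp − 0.5) requires a
geometric dose series (constant log-spacing to 1e-6), at least three
groups, and both mortality anchors (0% at the lowest dose, 100% at the
highest); violations raise specific errors rather than extrapolating.
The estimator is exactly the trapezoid-rule mean of the tolerance
distribution in log dose, which the tests verify, and is equivariant
under dose-unit rescaling. The named "improved" small-sample variants of
this estimator are not specified precisely enough in the applied
literature to reproduce; we implement the standard sequential-design
formula, which matches the stated constraints (geometric 1:0.85 spacing,
anchored series, small groups). Relative toxicity is min LD50 / LD50.

## Synthetic-data generator

The generator's defaults are the study conditions: 11 sites × 5
transects, background predation pressure spread evenly over 0.3–0.8,
about 200 inspected specimens per site (90 palatable, 60 ring members at
a 0.22 mimic fraction, 50 other — matching the field totals of ~1000
palatable and ~650 ring specimens), 8 walks per transect (~440 walks),
and a 0.1 mimic:model abundance ratio. Attack outcomes are Bernoulli:
palatable specimens at exactly the site PP; ring specimens at
logit⁻¹(α_ring + β_ring·PP + δ·mimic) with defaults Danaus (−4.6, +8),
Tirumala (−0.4, 0), Euploea (+1.2, −3) and δ = +0.75 — a steep rising,
flat, and shallow declining trio that crosses within the PP range, with
mimics attacked more than models. Attacked specimens carry at least one
> 5 mm mark; unattacked specimens carry only sub-2-mm noise marks; age
class is drawn independently of attack status from a discretized normal.
Dose–mortality tables are Binomial(10, logistic in log₁₀ dose, scale
0.04) on a 15-dose 1:0.85 series bracketing a true LD50 of 150 mg/kg.
One top-level seed fans out to independent per-stage substreams
(SeedSequence spawning), so regenerating one stage never perturbs
another; structural ground truth depends only on the configuration.

What the generator does **not** emulate: true site- or transect-level
random effects beyond the PP gradient (the GLMM's variance components
are genuinely zero in the truth, so singular fits are expected),
overdispersion from species composition, spatial autocorrelation,
detection failure, measurement error in mark depth, or predator
learning dynamics (the logit-linear structure summarizes their
equilibrium effect). Passing calibration therefore demonstrates that the
estimators recover the assumed data-generating structure at the study's
design size — not that real field data satisfy that structure.

## Calibration experiments

`aposignal.calibration` (used by the test suite and by
`scripts/acceptance.py`) runs seeded Monte-Carlo experiments, all at the
11 × 5 design: 100-replicate CI coverage of the true PP slope,
ring-slope differences and mimic penalty (fitting with the true site PP,
to isolate the estimator); 100-replicate null calibration (all effects
zero; per-term false-exclusion rate); 100-seed Kärber recovery on
logistic dose data (within one log-spacing of truth); and a 100-run
end-to-end experiment that recovers PP from the palatable specimens —
so covariate measurement error is exercised — and checks the qualitative
pattern (slope ordering, mimic > model). Problem sizes were chosen so
the whole suite runs in a few minutes on one CPU.

## Known limitations

* Absolute conspicuousness values depend on the synthetic visual-system
  stand-ins; only within-system contrasts are meaningful.
* Wald intervals conditional on estimated variance components undercover
  with few sites; profile or bootstrap intervals are not implemented.
* The NB2 dispersion is profiled, not jointly estimated, so its
  uncertainty is not propagated into coefficient SEs.
* PSS carries a small size-dependent raster bias for fragments of only a
  few pixels.
* The Kärber estimator requires anchored, geometric designs; it does not
  handle unanchored series (a probit/logit dose–response regression
  would, but is out of scope).
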