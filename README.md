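# aposignal

Quantitative machinery for field studies of aposematism and mimicry in
butterflies: how conspicuous a wing is to a bird, how simple its pattern
is, how often local birds attack it, and how toxic it is — plus the mixed
models that tie attack rates to a gradient of background predation
pressure.

The package is aimed at visual ecologists and field entomologists who
have (or want to simulate) four kinds of data: reflectance spectra of
wing color patches, binarized wing-pattern images, beak-mark inspection
records with transect sightings, and grouped dose–mortality tables.

## What it computes

**Avian conspicuousness (receptor-noise-limited model).** For each cone
class *i* of a tetrachromatic passerine eye, the quantum catch is
*Q<sub>i</sub>* = ∫ S<sub>i</sub>(λ) I(λ) R(λ) dλ over 300–700 nm, receptor
signals are *f<sub>i</sub>* = ln *Q<sub>i</sub>*, and a patch seen against
green foliage is scored by the chromatic distance ΔS (pairwise expansion
with Weber fractions ω<sub>U</sub>=1.0, ω<sub>S</sub>=0.857,
ω<sub>M</sub>=0.520, ω<sub>L</sub>=0.515), the achromatic contrast
ΔL = |Δf<sub>L</sub>|/ω<sub>L</sub>, and the combined conspicuousness
E = √(ΔS² + ΔL²) in just-noticeable-difference units. Whole-wing
conspicuousness is the area-weighted mean of patch E values.

**Pattern simplicity score.** PSS = Σ w<sub>i</sub> Q<sub>i</sub> with
Q<sub>i</sub> = 4πS<sub>i</sub>/L<sub>i</sub>² the isoperimetric quotient
of each contour of the binarized pattern and w<sub>i</sub> its area
weight — 1 for a single round patch, low for many small fragments.

**Attack scoring.** Wing-damage depth classifies marks (<2 mm excluded,
2–5 mm ambiguous, >5 mm bird attack); symmetric damage counts as one
attack; a site's *background predation pressure* is the binary attack
rate on palatable, non-mimetic butterflies with wingspan >50 mm.

**Mixed models.** A binomial GLMM (Laplace approximation, random
intercepts for site and transect-within-site) relates per-specimen attack
outcomes to background predation pressure, mimicry ring, model/mimic
status and their interactions; count GLMMs (negative-binomial or Poisson,
plus a Gaussian-identity option) do the same for abundance; one-way ANOVA
compares ring-level traits.

**Toxicity.** The modified Kärber estimator
log₁₀ LD50 = X<sub>m</sub> − i(Σp − 0.5) on a 1:0.85 geometric dose
series, and relative toxicity = min LD50 / LD50.

A synthetic-data module generates all of these inputs with known ground
truth (spectra, patterns, a full beak-mark survey along a 0.3–0.8
predation-pressure gradient with a ~10:1 model:mimic abundance ratio, and
logistic dose–mortality tables), so the entire pipeline is testable
without field data.

## Worked example

```python
import numpy as np
from aposignal import (
    SimConfig, gen_survey, gen_spectra, ring_patches,
    attack_analysis_table, fit_attack_glmm, ModelSpec,
    default_visual_system, flat_irradiance, wing_conspicuousness,
)

vs, illum = default_visual_system(), flat_irradiance()
spectra = gen_spectra(SimConfig(seed=1))
for ring in ("Danaus", "Tirumala", "Euploea"):
    e = wing_conspicuousness(ring_patches(spectra, ring), spectra["foliage"], illum, vs)
    print(f"{ring:9s} wing E = {e:.2f} JND")

records, sightings, walks, truth = gen_survey(SimConfig(seed=1))
tab = attack_analysis_table(records)      # recovers background PP per site
spec = ModelSpec(response="attacked", fixed_terms=["pp", "ring", "status"],
                 interactions=[("ring", "pp")])
print(fit_attack_glmm(tab, spec).summary())
```

prints

```
Danaus    wing E = 2.73 JND
Tirumala  wing E = 2.51 JND
Euploea   wing E = 1.85 JND
AttackRateModel (binomial-logit)
  groups: 11 sites, 55 transects
  loglik -402.381   AIC 822.761   converged=True
  variance components: site=0.01018, transect=0.08427
  term                              coef       se      2.5%     97.5%
  Intercept                      -4.5777   0.6969    -5.944    -3.212
  pp                              7.3287   1.1744     5.027     9.630
  ring[Euploea]                   5.8864   0.8752     4.171     7.602
  ring[Tirumala]                  2.9446   0.8620     1.255     4.634
  status[mimic]                   1.2807   0.2112     0.867     1.695
  ring[Euploea]:pp              -10.6538   1.5032   -13.600    -7.707
  ring[Tirumala]:pp              -5.0436   1.4667    -7.918    -2.169
```

The wing conspicuousness ordering (conspicuous orange ring > intermediate
blue ring > cryptic brown ring) and a steep positive attack-rate slope in
background predation pressure for the conspicuous ring — with the
interactions pulling the intermediate ring flat (7.33 − 5.04 ≈ 2.3, CI
spanning modest values) and the cryptic ring negative (7.33 − 10.65 ≈
−3.3) plus a positive mimic penalty (+1.28) — are the structure the
generator encodes and the fit recovers. Exact numbers vary with the seed.

A `aposignal` command-line tool wraps the same functionality
(`aposignal simulate`, `aposignal pattern`, `aposignal attacks`,
`aposignal fit`, `aposignal ld50`, ...).

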