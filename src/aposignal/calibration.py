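"""Reproducible calibration experiments for the whole pipeline.

Each function runs a seeded Monte-Carlo experiment at the study's design
size (11 sites x 5 transects) and reports recovery/calibration summaries:
CI coverage of true attack-model coefficients, sign recovery of the
ring x predation-pressure interaction ordering, null false-exclusion
rates, LD50 recovery, and the end-to-end qualitative attack-rate pattern.
They are what the test suite asserts against and what the results script
reports; they contain no expected values of their own.
"""

from __future__ import annotations

import numpy as np

from .attacks import attack_analysis_table
from .simulate import RingParams, SimConfig, gen_dose_response, gen_survey, site_pp_values
from .stats import ModelSpec, fit_attack_glmm
from .toxicity import DoseGroup, estimate_ld50

ATTACK_SPEC = ModelSpec(
    response="attacked",
    fixed_terms=["pp", "ring", "status"],
    interactions=[("ring", "pp")],
)

#: Recovery-simulation design: 200 ring specimens per transect.
RECOVERY_RING_PER_SITE = 1000
RECOVERY_PALATABLE_PER_SITE = 200


def rnl_quadratic_form(delta_f: np.ndarray, omega: np.ndarray) -> float:
    """Generic n-receptor noise-limited chromatic distance.

    Projection form: Mahalanobis length of delta_f after removing the
    uniform (brightness) direction under noise covariance diag(omega^2).
    Kept deliberately independent of the pairwise expansion implemented in
    the vision module.
    """
    df = np.asarray(delta_f, dtype=float)
    a = 1.0 / np.asarray(omega, dtype=float) ** 2
    return float(np.sqrt(np.dot(a, df**2) - np.dot(a, df) ** 2 / a.sum()))


def ds_oracle_max_rel_err(n_draws: int = 1000, seed: int = 0) -> float:
    """Worst relative disagreement between the implemented tetrachromatic
    distance and the generic quadratic form over random (delta_f, omega)."""
    from .vision import CONE_CLASSES, VisualSystem, chromatic_distance, default_visual_system

    rng = np.random.default_rng(seed)
    sens = default_visual_system().sensitivities
    worst = 0.0
    for _ in range(n_draws):
        df = rng.normal(0.0, 2.0, 4)
        omega = rng.uniform(0.1, 1.5, 4)
        vs = VisualSystem(sens, dict(zip(CONE_CLASSES, omega)))
        got = chromatic_distance(dict(zip(CONE_CLASSES, df)), vs)
        want = rnl_quadratic_form(df, omega)
        if want > 0:
            worst = max(worst, abs(got - want) / want)
    return worst


def _recovery_config(seed: int, **overrides) -> SimConfig:
    return SimConfig(
        seed=seed,
        ring_specimens_per_site=RECOVERY_RING_PER_SITE,
        palatable_specimens_per_site=RECOVERY_PALATABLE_PER_SITE,
        **overrides,
    )


def glmm_recovery(n_rep: int = 100, seed: int = 0) -> dict:
    """Coverage of 95% Wald CIs for the true attack-model coefficients and
    recovery of the ring-slope ordering, at the recovery design size.

    The fit uses the generator's true site PP as covariate so that the
    experiment isolates the estimator (PP measurement error is exercised
    by the end-to-end experiment instead).
    """
    base = SimConfig()
    truth = {
        "pp": base.ring_params["Danaus"].slope,
        "ring[Tirumala]:pp": base.ring_params["Tirumala"].slope - base.ring_params["Danaus"].slope,
        "ring[Euploea]:pp": base.ring_params["Euploea"].slope - base.ring_params["Danaus"].slope,
        "status[mimic]": base.mimic_logit_offset,
    }
    covered = {k: 0 for k in truth}
    sign_ok = 0
    for r in range(n_rep):
        cfg = _recovery_config(seed=seed * 100_003 + r)
        records, *_ = gen_survey(cfg)
        tab = attack_analysis_table(records, pp_by_site=site_pp_values(cfg))
        res = fit_attack_glmm(tab, ATTACK_SPEC)
        ci = res.conf_int()
        for term, value in truth.items():
            if ci.loc[term, "lower"] <= value <= ci.loc[term, "upper"]:
                covered[term] += 1
        slope_d = res.params["pp"]
        slope_t = slope_d + res.params["ring[Tirumala]:pp"]
        slope_e = slope_d + res.params["ring[Euploea]:pp"]
        if slope_d > slope_t > slope_e:
            sign_ok += 1
    return {
        "coverage": {k: v / n_rep for k, v in covered.items()},
        "sign_ordering_rate": sign_ok / n_rep,
        "n_rep": n_rep,
    }


def glmm_null_exclusion(n_rep: int = 100, seed: int = 0) -> dict:
    """False-exclusion rate of each fixed-effect CI when all effects are 0."""
    null_rings = {r: RingParams(0.0, 0.0) for r in ("Danaus", "Tirumala", "Euploea")}
    excluded: dict[str, int] = {}
    for r in range(n_rep):
        cfg = _recovery_config(
            seed=seed * 100_019 + r, ring_params=null_rings, mimic_logit_offset=0.0
        )
        records, *_ = gen_survey(cfg)
        tab = attack_analysis_table(records, pp_by_site=site_pp_values(cfg))
        res = fit_attack_glmm(tab, ATTACK_SPEC)
        ci = res.conf_int()
        for term in res.params.index:
            if term == "Intercept":
                continue
            excluded.setdefault(term, 0)
            if not (ci.loc[term, "lower"] <= 0.0 <= ci.loc[term, "upper"]):
                excluded[term] += 1
    return {"exclusion": {k: v / n_rep for k, v in excluded.items()}, "n_rep": n_rep}


def ld50_recovery(n_rep: int = 100, seed: int = 0) -> dict:
    """Fraction of replicates whose Karber estimate lands within one
    log-spacing of the true LD50 on logistic dose-mortality data."""
    hits = 0
    for r in range(n_rep):
        cfg = SimConfig(seed=seed * 100_043 + r)
        df, true_ld50 = gen_dose_response(cfg)
        groups = [
            DoseGroup(float(row.dose_mg_per_kg), int(row.n), int(row.deaths))
            for row in df.itertuples()
        ]
        res = estimate_ld50(groups)
        if abs(np.log10(res.ld50) - np.log10(true_ld50)) <= res.log_spacing:
            hits += 1
    return {"within_one_spacing_rate": hits / n_rep, "n_rep": n_rep}


def end_to_end_pattern_rate(n_rep: int = 100, seed: int = 0) -> dict:
    """simulate -> score attacks -> recover PP -> fit, on the default
    (field-scale) design; counts runs reproducing the qualitative pattern:
    conspicuous slope > intermediate slope > cryptic slope, and mimics
    attacked more than models."""
    ok = 0
    for r in range(n_rep):
        cfg = SimConfig(seed=seed * 100_057 + r)
        records, *_ = gen_survey(cfg)
        tab = attack_analysis_table(records)  # PP recovered from palatable specimens
        res = fit_attack_glmm(tab, ATTACK_SPEC)
        slope_d = res.params["pp"]
        slope_t = slope_d + res.params["ring[Tirumala]:pp"]
        slope_e = slope_d + res.params["ring[Euploea]:pp"]
        if slope_d > slope_t > slope_e and res.params["status[mimic]"] > 0:
            ok += 1
    return {"pattern_rate": ok / n_rep, "n_rep": n_rep}
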