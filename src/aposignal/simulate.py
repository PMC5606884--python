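"""Synthetic field-study generator.

Emulates every input of the pipeline with known ground truth, so each
stage can be tested end to end without field data:

* smooth reflectance spectra for ring-typical wing patches plus a green
  foliage background and a flat illuminant;
* binary wing patterns assembled from disjoint disks and rectangles whose
  analytic isoperimetric geometry gives an exact expected PSS;
* a beak-mark survey across sites spanning a background-predation-pressure
  (PP) gradient: palatable specimens are attacked Bernoulli(PP); mimicry
  ring specimens follow logit P(attack) = a_ring + b_ring * PP + d * mimic,
  with a steep positive PP slope for the conspicuous ring (Danaus-like), a
  flat intermediate ring (Tirumala-like), a shallow negative slope for the
  cryptic ring (Euploea-like), and a positive mimic penalty d;
* transect sightings with a ~10:1 model:mimic abundance ratio;
* logistic dose-mortality tables on a 1:0.85 geometric dose series.

One top-level seed fans out to independent per-stage substreams, so e.g.
regenerating the survey does not perturb the dose tables.  Structural
ground truth (site PP values, logit coefficients, true PSS, true LD50)
depends only on the configuration, never on the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attacks import DamageMark, SpecimenRecord
from .errors import ConfigError, PlacementError
from .pattern import BinaryPatternImage
from .spectra import CANONICAL_GRID, Spectrum
from .survey import Sighting
from .vision import ColorPatch


@dataclass(frozen=True)
class RingParams:
    """Logit-linear attack model of one mimicry ring: a + b * PP."""

    intercept: float
    slope: float


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic survey.

    Defaults mirror the field design: 11 sites x 5 transects, background
    predation pressure spread over 0.3-0.8, ~200 inspected specimens per
    site (90 palatable, 60 ring members at a ~3.5:1 model:mimic split, 50
    other), a mimic:model abundance ratio of 0.1, and a steep/flat/shallow
    trio of ring PP slopes producing the crossing attack-rate pattern.
    """

    seed: int = 0
    n_sites: int = 11
    transects_per_site: int = 5
    pp_range: tuple[float, float] = (0.3, 0.8)
    ring_params: Mapping[str, RingParams] = field(
        default_factory=lambda: {
            "Danaus": RingParams(-4.6, 8.0),
            "Tirumala": RingParams(-0.4, 0.0),
            "Euploea": RingParams(1.2, -3.0),
        }
    )
    mimic_logit_offset: float = 0.75
    mimic_model_abundance_ratio: float = 0.1
    ring_specimens_per_site: int = 60
    palatable_specimens_per_site: int = 90
    other_specimens_per_site: int = 50
    mimic_specimen_frac: float = 0.22
    walks_per_transect: int = 8
    model_rate_per_walk: float = 1.0
    palatable_rate_per_walk: float = 25.0
    # spectra
    spectra_jitter: float = 0.03
    # wing patterns: list of ("disk", radius_px) / ("rect", h_px, w_px)
    pattern_shapes: tuple = (("disk", 40),)
    pattern_canvas: tuple[int, int] = (256, 256)
    # dose-response
    true_ld50_mg_per_kg: float = 150.0
    dose_ratio: float = 0.85
    n_doses: int = 15
    dose_scale_log10: float = 0.04
    mice_per_group: int = 10

    def __post_init__(self):
        lo, hi = self.pp_range
        if not (0 <= lo < hi <= 1):
            raise ConfigError("pp_range must satisfy 0 <= low < high <= 1")
        for name, n in [
            ("ring_specimens_per_site", self.ring_specimens_per_site),
            ("palatable_specimens_per_site", self.palatable_specimens_per_site),
        ]:
            if n < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0 < self.mimic_model_abundance_ratio < 1:
            raise ConfigError("mimic_model_abundance_ratio must lie in (0, 1)")
        if not self.dose_scale_log10 > 0:
            raise ConfigError("dose_scale_log10 must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Structural truth paired with every generated dataset."""

    pp_by_site: Mapping[str, float]
    ring_params: Mapping[str, RingParams]
    mimic_logit_offset: float
    mimic_model_abundance_ratio: float
    true_pss: float | None = None
    true_ld50_mg_per_kg: float | None = None

    def to_json(self) -> str:
        d = asdict(self)
        d["ring_params"] = {k: asdict(v) if isinstance(v, RingParams) else v
                            for k, v in dict(self.ring_params).items()}
        d["pp_by_site"] = dict(self.pp_by_site)
        return json.dumps(d, indent=2, sort_keys=True)


def _stage_rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    children = np.random.SeedSequence(cfg.seed).spawn(4)
    return np.random.default_rng(children[stage])


def site_pp_values(cfg: SimConfig) -> dict[str, float]:
    """True background PP per site: evenly spread over pp_range."""
    lo, hi = cfg.pp_range
    vals = np.linspace(lo, hi, cfg.n_sites)
    return {f"S{i + 1:02d}": float(v) for i, v in enumerate(vals)}


# ---------------------------------------------------------------------------
# Spectra

def _smooth(w, baseline, bumps, shoulders=()):
    v = np.full_like(w, baseline, dtype=float)
    for mu, sd, amp in bumps:
        v = v + amp * np.exp(-0.5 * ((w - mu) / sd) ** 2)
    for loc, width, amp in shoulders:
        v = v + amp / (1.0 + np.exp(-(w - loc) / width))
    return np.clip(v, 1e-4, 1.0)


def gen_spectra(cfg: SimConfig) -> dict[str, Spectrum]:
    """Ring-typical patch reflectances + foliage + flat illuminant.

    Patch shapes are structural; the seed only jitters amplitudes a few
    percent (measurement-repeatability noise).
    """
    rng = _stage_rng(cfg, 0)
    w = CANONICAL_GRID

    def jit():
        return float(1.0 + cfg.spectra_jitter * rng.standard_normal())

    curves = {
        "foliage": _smooth(w, 0.05, [(550, 35, 0.17 * jit())], [(695, 5, 0.20)]),
        # conspicuous ring: saturated long-wavelength step (orange)
        "danaus_orange": _smooth(w, 0.03, [], [(565, 12, 0.68 * jit())]),
        "danaus_white": _smooth(w, 0.78 * jit(), []),
        # intermediate ring: mid-amplitude bluish bump
        "tirumala_blue": _smooth(w, 0.05, [(465, 38, 0.26 * jit())]),
        # cryptic ring: low broadband brown + small bright white fragments
        "euploea_brown": _smooth(w, 0.04, [], [(600, 60, 0.10 * jit())]),
        "euploea_white": _smooth(w, 0.80 * jit(), []),
        "black": _smooth(w, 0.05, []),
    }
    out = {
        k: Spectrum(w, v, kind="reflectance", label=k) for k, v in curves.items()
    }
    out["illuminant"] = Spectrum(
        w, np.ones_like(w), kind="irradiance", label="illuminant"
    )
    return out


#: Wing composition per ring (patch label -> area fraction), used to build
#: area-weighted wing conspicuousness from the generated spectra.
RING_WING_COMPOSITION: dict[str, dict[str, float]] = {
    "Danaus": {"danaus_orange": 0.62, "black": 0.28, "danaus_white": 0.10},
    "Tirumala": {"tirumala_blue": 0.38, "black": 0.62},
    "Euploea": {"euploea_brown": 0.88, "euploea_white": 0.12},
}


def ring_patches(spectra: Mapping[str, Spectrum], ring: str) -> list[ColorPatch]:
    comp = RING_WING_COMPOSITION[ring]
    return [
        ColorPatch(reflectance=spectra[lab], area_fraction=frac, label=lab)
        for lab, frac in comp.items()
    ]


# ---------------------------------------------------------------------------
# Wing patterns

def _analytic_q(shape) -> tuple[float, float]:
    """(area, isoperimetric quotient) of an ideal shape spec."""
    if shape[0] == "disk":
        r = float(shape[1])
        return np.pi * r * r, 1.0
    if shape[0] == "rect":
        h, w = float(shape[1]), float(shape[2])
        return h * w, 4.0 * np.pi * h * w / (2.0 * (h + w)) ** 2
    raise ConfigError(f"unknown shape {shape[0]!r}")


def true_pss(shapes: Sequence) -> float:
    areas, qs = zip(*(_analytic_q(s) for s in shapes))
    areas = np.asarray(areas)
    return float(np.dot(areas / areas.sum(), qs))


def gen_wing_pattern(cfg: SimConfig) -> tuple[BinaryPatternImage, float]:
    """Render disjoint ideal shapes onto a canvas; return the analytic PSS.

    Placement is rejection sampling with a 3 px clearance; after 1000
    failed attempts for a shape a PlacementError is raised (canvas too
    small for the requested shapes).
    """
    rng = _stage_rng(cfg, 1)
    H, W = cfg.pattern_canvas
    img = np.zeros((H, W), dtype=np.uint8)
    occupied: list[tuple[float, float, float]] = []  # (y, x, clearance radius)
    margin = 3.0
    for shape in cfg.pattern_shapes:
        if shape[0] == "disk":
            r = float(shape[1])
            half_y = half_x = r
        else:
            half_y, half_x = shape[1] / 2.0, shape[2] / 2.0
        rad = float(np.hypot(half_y, half_x))
        for attempt in range(1000):
            cy = rng.uniform(half_y + margin, H - half_y - margin)
            cx = rng.uniform(half_x + margin, W - half_x - margin)
            if all(np.hypot(cy - y, cx - x) > rad + orad + margin for y, x, orad in occupied):
                break
        else:
            raise PlacementError(f"could not place shape {shape} after 1000 attempts")
        occupied.append((cy, cx, rad))
        yy, xx = np.mgrid[:H, :W]
        if shape[0] == "disk":
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= shape[1] ** 2] = 1
        else:
            h, w2 = shape[1], shape[2]
            img[
                (np.abs(yy - cy) <= h / 2.0) & (np.abs(xx - cx) <= w2 / 2.0)
            ] = 1
    return BinaryPatternImage(img), true_pss(cfg.pattern_shapes)


# ---------------------------------------------------------------------------
# Survey: specimens with marks + transect sightings

_AGE_PROBS = np.array([1, 4, 6, 4, 1], dtype=float) / 16.0  # discretized normal

RING_NAMES = ("Danaus", "Tirumala", "Euploea")


def _noise_marks(rng) -> list[DamageMark]:
    k = rng.poisson(1.0)
    return [
        DamageMark(depth_mm=float(rng.uniform(0.2, 1.9)), edge="smeared", symmetric=False,
                   wing=str(rng.choice(["left", "right"])))
        for _ in range(k)
    ]


def _attack_marks(rng) -> list[DamageMark]:
    sym = bool(rng.random() < 0.4)
    return [
        DamageMark(
            depth_mm=float(rng.uniform(5.5, 12.0)),
            edge="sharp",
            symmetric=sym,
            wing="both" if sym else str(rng.choice(["left", "right"])),
        )
    ]


def gen_survey(
    cfg: SimConfig,
) -> tuple[list[SpecimenRecord], list[Sighting], pd.DataFrame, GroundTruth]:
    """Specimen records, sightings, walk table and the paired ground truth."""
    rng = _stage_rng(cfg, 2)
    pp = site_pp_values(cfg)
    records: list[SpecimenRecord] = []
    sightings: list[Sighting] = []
    walk_rows = []
    sid = 0

    def expit(x):
        return 1.0 / (1.0 + np.exp(-x))

    for site, p_bg in pp.items():
        transects = [f"{site}-T{j + 1}" for j in range(cfg.transects_per_site)]
        # --- inspected specimens -----------------------------------------
        def add_specimen(species, category, ring, wingspan, p_attack):
            nonlocal sid
            sid += 1
            attacked = rng.random() < p_attack
            marks = _attack_marks(rng) if attacked else []
            marks += _noise_marks(rng)
            records.append(
                SpecimenRecord(
                    id=f"B{sid:06d}",
                    species=species,
                    category=category,
                    ring=ring,
                    wingspan_mm=float(wingspan),
                    age_class=int(rng.choice([1, 2, 3, 4, 5], p=_AGE_PROBS)),
                    site=site,
                    transect=str(rng.choice(transects)),
                    marks=tuple(marks),
                )
            )

        for _ in range(cfg.palatable_specimens_per_site):
            add_specimen(
                "palatable_sp", "palatable_nonmimic", "none",
                rng.uniform(55, 95), p_bg,
            )
        for _ in range(cfg.other_specimens_per_site):
            add_specimen(
                "toxic_plain_sp", "toxic_nonaposematic", "none",
                rng.uniform(55, 95), p_bg,
            )
        n_ring = cfg.ring_specimens_per_site
        per_ring = np.full(len(RING_NAMES), n_ring // len(RING_NAMES))
        per_ring[: n_ring % len(RING_NAMES)] += 1
        for ring, n_r in zip(RING_NAMES, per_ring):
            par = cfg.ring_params[ring]
            for _ in range(int(n_r)):
                is_mimic = rng.random() < cfg.mimic_specimen_frac
                eta = par.intercept + par.slope * p_bg + (
                    cfg.mimic_logit_offset if is_mimic else 0.0
                )
                add_specimen(
                    f"{ring}_{'mimic' if is_mimic else 'model'}_sp",
                    "mimic" if is_mimic else "model",
                    ring,
                    rng.uniform(70, 100),
                    expit(eta),
                )
        # --- transect sightings ------------------------------------------
        for tr in transects:
            for k in range(cfg.walks_per_transect):
                wid = f"{tr}-W{k + 1}"
                walk_rows.append({"site": site, "transect": tr, "walk_id": wid})
                for ring in RING_NAMES:
                    for status, lam in (
                        ("model", cfg.model_rate_per_walk),
                        ("mimic", cfg.model_rate_per_walk * cfg.mimic_model_abundance_ratio),
                    ):
                        c = int(rng.poisson(lam))
                        if c > 0:
                            sightings.append(
                                Sighting(
                                    site=site, transect=tr, walk_id=wid,
                                    species=f"{ring}_{status}_sp",
                                    category=status, ring=ring,
                                    distance_m=float(rng.uniform(0, 35)),
                                    count=c,
                                )
                            )
                c = int(rng.poisson(cfg.palatable_rate_per_walk))
                if c > 0:
                    sightings.append(
                        Sighting(
                            site=site, transect=tr, walk_id=wid,
                            species="palatable_sp", category="palatable_nonmimic",
                            ring="none", distance_m=float(rng.uniform(0, 35)), count=c,
                        )
                    )

    truth = GroundTruth(
        pp_by_site=pp,
        ring_params=dict(cfg.ring_params),
        mimic_logit_offset=cfg.mimic_logit_offset,
        mimic_model_abundance_ratio=cfg.mimic_model_abundance_ratio,
        true_pss=true_pss(cfg.pattern_shapes),
        true_ld50_mg_per_kg=cfg.true_ld50_mg_per_kg,
    )
    return records, sightings, pd.DataFrame(walk_rows), truth


# ---------------------------------------------------------------------------
# Dose-response

def gen_dose_response(cfg: SimConfig) -> tuple[pd.DataFrame, float]:
    """Grouped mortality on a 1:0.85 series bracketing the true LD50.

    Mortality is Binomial(n, logistic((log10 d - log10 LD50) / scale)).
    The series is wide enough that the extreme doses are (with very high
    probability) the 0%/100% anchors the Karber estimator requires.
    """
    rng = _stage_rng(cfg, 3)
    i = -np.log10(cfg.dose_ratio)
    k = cfg.n_doses
    # true LD50 sits off-grid, 0.3 spacings above the middle dose
    mid = (k - 1) / 2.0
    log_top = np.log10(cfg.true_ld50_mg_per_kg) + (mid - 0.3) * i
    logd = log_top - i * np.arange(k)
    if not (logd.min() < np.log10(cfg.true_ld50_mg_per_kg) < logd.max()):
        raise ConfigError("true LD50 outside the generated dose range")
    from scipy.special import expit

    p = expit((logd - np.log10(cfg.true_ld50_mg_per_kg)) / cfg.dose_scale_log10)
    deaths = rng.binomial(cfg.mice_per_group, p)
    df = pd.DataFrame(
        {
            "species": "synthetic_sp",
            "dose_mg_per_kg": 10.0**logd,
            "n": cfg.mice_per_group,
            "deaths": deaths,
        }
    ).sort_values("dose_mg_per_kg", ignore_index=True)
    return df, float(cfg.true_ld50_mg_per_kg)
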