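"""Receptor-noise-limited avian colorimetry.

Implements the tetrachromatic receptor-noise model of color discrimination
for a passerine-type eye.  A stimulus seen against a background is scored
by the chromatic distance dS (in just-noticeable-difference units), the
achromatic (brightness) contrast dL carried by the long-wave channel, and
their Euclidean combination E = sqrt(dS^2 + dL^2) -- the "conspicuousness"
of the stimulus.

The chain is:

1. quantum catch  Q_i = integral S_i(l) I(l) R(l) dl  over 300-700 nm,
2. receptor signal f_i = ln Q_i  (Weber-Fechner transduction),
3. signal difference Df_i = ln(Q_iA / Q_iB) between stimulus A and
   background B (the illuminant cancels in the ratio, a von-Kries-style
   adaptation assumption),
4. dS from the four Df_i weighted by receptor noise (Weber fractions w_i),
   dL = |Df_L| / w_L.

The tetrachromatic dS uses the standard six-pair expansion

    dS^2 = [ (w_U w_S)^2 (Df_L - Df_M)^2 + (w_U w_M)^2 (Df_L - Df_S)^2
           + (w_U w_L)^2 (Df_M - Df_S)^2 + (w_S w_M)^2 (Df_L - Df_U)^2
           + (w_S w_L)^2 (Df_M - Df_U)^2 + (w_M w_L)^2 (Df_S - Df_U)^2 ]
           / [ (w_U w_S w_M)^2 + (w_U w_S w_L)^2
             + (w_U w_M w_L)^2 + (w_S w_M w_L)^2 ]

which is algebraically the Mahalanobis distance of Df projected onto the
chromatic hyperplane (orthogonal to uniform brightness shifts) under
independent Gaussian receptor noise with standard deviations w_i.  Some
published restatements of this expansion carry a typographical slip in the
pair coefficients; the form above is the one that satisfies receptor
symmetry and matches the generic n-receptor quadratic form.

Default Weber fractions follow the relative cone abundances of a typical
passerine retina: w_U = 1.0, w_S = 0.857, w_M = 0.520, w_L = 0.515.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateStimulusError, ValidationError
from .spectra import CANONICAL_GRID, Spectrum

CONE_CLASSES = ("U", "S", "M", "L")

#: Default single-receptor noise-to-signal ratios (Weber fractions).
DEFAULT_WEBER = {"U": 1.0, "S": 0.857, "M": 0.520, "L": 0.515}

#: Peak wavelength (nm) and Gaussian width of the packaged synthetic
#: average-passerine cone sensitivities (unit peak).  These are synthetic
#: stand-in curves with the qualitative shape of UVS-type passerine cones,
#: overridable by measured sensitivities.
_CONE_PEAKS_NM = {"U": 372.0, "S": 445.0, "M": 508.0, "L": 565.0}
_CONE_SD_NM = {"U": 25.0, "S": 30.0, "M": 35.0, "L": 40.0}


@dataclass(frozen=True)
class VisualSystem:
    """Four cone sensitivities plus their Weber fractions.

    The achromatic (double-cone) channel re-uses the L cone sensitivity
    and its Weber fraction unless ``achromatic_weber`` says otherwise.
    """

    sensitivities: Mapping[str, Spectrum]
    weber: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEBER))
    achromatic_weber: float | None = None

    def __post_init__(self):
        if set(self.sensitivities) != set(CONE_CLASSES):
            raise ValidationError(f"sensitivities must cover exactly {CONE_CLASSES}")
        if set(self.weber) != set(CONE_CLASSES):
            raise ValidationError(f"weber fractions must cover exactly {CONE_CLASSES}")
        for k, w in self.weber.items():
            if not w > 0:
                raise ValidationError(f"weber fraction for {k} must be > 0")
        if self.achromatic_weber is not None and not self.achromatic_weber > 0:
            raise ValidationError("achromatic_weber must be > 0")

    @property
    def omega_achromatic(self) -> float:
        return self.achromatic_weber if self.achromatic_weber is not None else self.weber["L"]


@dataclass(frozen=True)
class ReceptorSignals:
    """Quantum catches and their logs for the four cone classes."""

    q: Mapping[str, float]
    f: Mapping[str, float]

    def __post_init__(self):
        for k in CONE_CLASSES:
            if not self.q[k] > 0:
                raise DegenerateStimulusError(f"non-positive quantum catch in cone {k}")


@dataclass(frozen=True)
class ContrastResult:
    """Chromatic, achromatic and combined contrast of one stimulus pair."""

    delta_f: Mapping[str, float]
    dS: float
    dL: float

    @property
    def E(self) -> float:
        return float(np.hypot(self.dS, self.dL))


@dataclass(frozen=True)
class ColorPatch:
    """A wing color patch: its reflectance plus fractional wing area."""

    reflectance: Spectrum
    area_fraction: float
    label: str = ""

    def __post_init__(self):
        if not 0 < self.area_fraction <= 1:
            raise ValidationError(f"{self.label!r}: area_fraction must lie in (0, 1]")


def _gaussian_sensitivity(cone: str) -> Spectrum:
    mu, sd = _CONE_PEAKS_NM[cone], _CONE_SD_NM[cone]
    v = np.exp(-0.5 * ((CANONICAL_GRID - mu) / sd) ** 2)
    return Spectrum(CANONICAL_GRID, v, kind="sensitivity", label=f"cone_{cone}")


def default_visual_system() -> VisualSystem:
    """Synthetic average-passerine visual system on the canonical grid."""
    return VisualSystem({c: _gaussian_sensitivity(c) for c in CONE_CLASSES})


def flat_irradiance(level: float = 1.0) -> Spectrum:
    """Ideal-white illuminant (the default when none is measured)."""
    return Spectrum(
        CANONICAL_GRID, np.full(CANONICAL_GRID.size, float(level)), kind="irradiance", label="flat"
    )


def green_foliage_background() -> Spectrum:
    """Synthetic tropical green-foliage reflectance (smooth bump near 550 nm).

    Stand-in for a measured leaf spectrum: low broadband baseline, a green
    peak at 550 nm, and the rising far-red shoulder of living vegetation.
    """
    w = CANONICAL_GRID
    v = (
        0.05
        + 0.17 * np.exp(-0.5 * ((w - 550.0) / 35.0) ** 2)
        + 0.28 / (1.0 + np.exp(-(w - 693.0) / 8.0))
    )
    return Spectrum(w, v, kind="reflectance", label="green_foliage")


def _require_canonical(s: Spectrum, role: str) -> Spectrum:
    if s.wavelengths_nm.size != CANONICAL_GRID.size or not np.allclose(
        s.wavelengths_nm, CANONICAL_GRID
    ):
        raise ValidationError(f"{role} spectrum must be on the canonical 1-nm 300-700 nm grid")
    return s


def quantum_catch(sensitivity: Spectrum, irradiance: Spectrum, reflectance: Spectrum) -> float:
    """Photon catch of one cone: trapezoidal integral of S * I * R."""
    _require_canonical(sensitivity, "sensitivity")
    _require_canonical(irradiance, "irradiance")
    _require_canonical(reflectance, "reflectance")
    integrand = sensitivity.values * irradiance.values * reflectance.values
    q = float(np.trapezoid(integrand, sensitivity.wavelengths_nm))
    if q <= 0:
        raise DegenerateStimulusError(
            f"quantum catch <= 0 for stimulus {reflectance.label!r}; receptor signal undefined"
        )
    return q


def receptor_signals(reflectance: Spectrum, irradiance: Spectrum, vs: VisualSystem) -> ReceptorSignals:
    q = {c: quantum_catch(vs.sensitivities[c], irradiance, reflectance) for c in CONE_CLASSES}
    f = {c: float(np.log(q[c])) for c in CONE_CLASSES}
    return ReceptorSignals(q=q, f=f)


def signal_differences(
    patch: Spectrum, background: Spectrum, irradiance: Spectrum, vs: VisualSystem
) -> dict[str, float]:
    """Df_i = ln(Q_i^patch / Q_i^background) per cone class."""
    a = receptor_signals(patch, irradiance, vs)
    b = receptor_signals(background, irradiance, vs)
    return {c: a.f[c] - b.f[c] for c in CONE_CLASSES}


def chromatic_distance(delta_f: Mapping[str, float], vs: VisualSystem) -> float:
    """Tetrachromatic receptor-noise-limited dS (JND units)."""
    missing = set(CONE_CLASSES) - set(delta_f)
    if missing:
        raise ValidationError(f"delta_f missing cone classes {sorted(missing)}")
    dU, dS_, dM, dL = (float(delta_f[c]) for c in CONE_CLASSES)
    wU, wS, wM, wL = (float(vs.weber[c]) for c in CONE_CLASSES)
    num = (
        (wU * wS) ** 2 * (dL - dM) ** 2
        + (wU * wM) ** 2 * (dL - dS_) ** 2
        + (wU * wL) ** 2 * (dM - dS_) ** 2
        + (wS * wM) ** 2 * (dL - dU) ** 2
        + (wS * wL) ** 2 * (dM - dU) ** 2
        + (wM * wL) ** 2 * (dS_ - dU) ** 2
    )
    den = (wU * wS * wM) ** 2 + (wU * wS * wL) ** 2 + (wU * wM * wL) ** 2 + (wS * wM * wL) ** 2
    return float(np.sqrt(num / den))


def achromatic_contrast(delta_f_L: float, vs: VisualSystem) -> float:
    """dL = |Df_L| / w_L : brightness contrast on the double-cone channel."""
    return abs(float(delta_f_L)) / vs.omega_achromatic


def conspicuousness(
    patch: Spectrum, background: Spectrum, irradiance: Spectrum, vs: VisualSystem
) -> ContrastResult:
    """Full contrast of a patch against its background: dS, dL and E."""
    df = signal_differences(patch, background, irradiance, vs)
    return ContrastResult(
        delta_f=df,
        dS=chromatic_distance(df, vs),
        dL=achromatic_contrast(df["L"], vs),
    )


def wing_conspicuousness(
    patches: Sequence[ColorPatch],
    background: Spectrum,
    irradiance: Spectrum,
    vs: VisualSystem,
) -> float:
    """Area-weighted mean conspicuousness of a whole wing.

    Every patch (including dark brown/black elements) is scored against
    the foliage background and weighted by its fractional wing area; the
    result stays in JND units.
    """
    if not patches:
        raise ValidationError("patch list is empty")
    total = sum(p.area_fraction for p in patches)
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"patch area fractions sum to {total}, expected 1")
    return float(
        sum(
            p.area_fraction * conspicuousness(p.reflectance, background, irradiance, vs).E
            for p in patches
        )
    )
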