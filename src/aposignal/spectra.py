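"""Reading, validating and resampling spectral curves.

Reflectance, irradiance and receptor-sensitivity curves all travel through
the same :class:`Spectrum` container: a wavelength-indexed vector on the
300-700 nm visible range of birds.  All downstream colorimetry integrates
on a canonical 1-nm grid, so everything read from disk is validated here
and resampled (linear interpolation, never extrapolation) before use.

CSV layout: first column ``wavelength_nm``, one column per spectrum.
Reflectance exported in percent (values up to ~100) is auto-detected and
converted to proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ExtrapolationError, SpectrumFormatError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical integration grid: 300-700 nm at 1 nm (avian visible range).
CANONICAL_GRID = np.arange(300.0, 701.0, 1.0)

#: A reflectance column whose maximum exceeds this is taken to be in percent.
PERCENT_DETECT_THRESHOLD = 1.5

#: Glossy surfaces can reflect slightly above the white standard.
REFLECTANCE_MAX = 1.2

KINDS = ("reflectance", "irradiance", "sensitivity")


@dataclass(frozen=True)
class Spectrum:
    """A single spectral curve.

    Parameters
    ----------
    wavelengths_nm : ndarray
        Strictly increasing wavelengths in [300, 700] nm.
    values : ndarray
        Non-negative values; reflectance as proportion, irradiance in
        arbitrary photon-flux units, sensitivity normalized to unit peak.
    kind : str
        One of ``reflectance``, ``irradiance``, ``sensitivity``.
    label : str
        Identifier (column name in the source table).
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str
    label: str = ""

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)
        if self.kind not in KINDS:
            raise ValidationError(f"unknown spectrum kind {self.kind!r}")
        if w.ndim != 1 or v.ndim != 1 or w.size != v.size or w.size < 2:
            raise ValidationError(
                f"{self.label!r}: wavelengths and values must be equal-length 1-d arrays (>= 2 points)"
            )
        if np.any(~np.isfinite(w)) or np.any(~np.isfinite(v)):
            raise ValidationError(f"{self.label!r}: missing or non-finite entries")
        if np.any(np.diff(w) <= 0):
            raise ValidationError(f"{self.label!r}: wavelengths must be strictly increasing")
        if w[0] < 300.0 - 1e-9 or w[-1] > 700.0 + 1e-9:
            raise ValidationError(f"{self.label!r}: wavelengths outside [300, 700] nm")
        if np.any(v < 0):
            raise ValidationError(f"{self.label!r}: negative spectral values")
        if self.kind == "reflectance" and np.any(v > REFLECTANCE_MAX):
            raise ValidationError(
                f"{self.label!r}: reflectance above {REFLECTANCE_MAX} after unit normalization"
            )

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def with_label(self, label: str) -> "Spectrum":
        return replace(self, label=label)


def read_spectra_table(path: str | Path, kind: str) -> list[Spectrum]:
    """Read a spectral CSV into one :class:`Spectrum` per data column.

    Percent-scale reflectance (column maximum > 1.5) is divided by 100,
    with a log record, so proportion and percent exports mix safely.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2 or df.columns[0] != "wavelength_nm":
        raise SpectrumFormatError(
            f"{path}: first column must be 'wavelength_nm' followed by >=1 data column"
        )
    w = df["wavelength_nm"].to_numpy(dtype=float)
    out = []
    for col in df.columns[1:]:
        v = df[col].to_numpy(dtype=float)
        if np.any(pd.isna(v)):
            raise ValidationError(f"{path}:{col}: missing values")
        if kind == "reflectance" and np.nanmax(v) > PERCENT_DETECT_THRESHOLD:
            logger.info("column %r looks percent-scaled (max %.3g); dividing by 100", col, v.max())
            v = v / 100.0
        out.append(Spectrum(w, v, kind=kind, label=str(col)))
    return out


def write_spectra_table(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra sharing one wavelength grid to CSV (inverse of read)."""
    if not spectra:
        raise ValidationError("no spectra to write")
    w = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths_nm, w):
            raise ValidationError("all spectra must share one wavelength grid to be written together")
    df = pd.DataFrame({"wavelength_nm": w})
    for s in spectra:
        df[s.label] = s.values
    # %.17g guarantees an exact binary round-trip through the text file
    df.to_csv(path, index=False, float_format="%.17g")


def resample(s: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation).

    Linear interpolation is monotone-safe: it cannot overshoot below zero
    or above the measured values, which matters for reflectance.
    """
    grid = np.asarray(list(grid), dtype=float)
    lo, hi = s.range_nm
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise ExtrapolationError(
            f"{s.label!r}: grid [{grid.min()}, {grid.max()}] outside measured range [{lo}, {hi}]"
        )
    v = np.interp(grid, s.wavelengths_nm, s.values)
    return Spectrum(grid, v, kind=s.kind, label=s.label)


def to_canonical(s: Spectrum) -> Spectrum:
    """Resample onto the canonical 1-nm 300-700 nm grid."""
    return resample(s, CANONICAL_GRID)
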