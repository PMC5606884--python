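"""LD50 estimation from grouped dose-mortality data.

Acute-toxicity assays use a descending geometric dose series (adjacent
doses in ratio 1:0.85, e.g. 100, 85, 72.25 mg/kg), small fixed-size animal
groups, and require the series to bracket the response: the lowest dose
kills nobody and the highest kills everybody.  Under that design the
modified Karber (Spearman-Karber type) estimator gives

    log10 LD50 = X_m - i * (sum(p) - 0.5)

where X_m is log10 of the highest dose, i the constant log10 spacing
between adjacent doses, and p the per-group death proportions.  It is the
trapezoid-rule mean of the tolerance distribution in log-dose, needs no
iterative fitting, and is the standard sequential-design LD50 formula for
animal-sparing protocols.  Relative toxicity rescales a panel of species
LD50s so the most toxic species (smallest LD50) scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnchorError, NoDataError, SpacingError, ValidationError

#: Standard progression factor between adjacent doses.
DEFAULT_RATIO = 0.85

_SPACING_TOL = 1e-6


@dataclass(frozen=True)
class DoseGroup:
    dose: float  # mg/kg
    n: int
    deaths: int

    def __post_init__(self):
        if not self.dose > 0:
            raise ValidationError("dose must be > 0")
        if self.n < 1:
            raise ValidationError("group size must be >= 1")
        if not 0 <= self.deaths <= self.n:
            raise ValidationError("need 0 <= deaths <= n")

    @property
    def p(self) -> float:
        return self.deaths / self.n


@dataclass(frozen=True)
class LD50Result:
    ld50: float  # mg/kg
    log_spacing: float  # log10 ratio between adjacent doses
    groups_used: int
    method: str = "modified-karber"


def design_dose_series(top_dose: float, ratio: float = DEFAULT_RATIO, k: int = 4) -> list[float]:
    """Descending geometric dose series top_dose * ratio^j, j = 0..k-1."""
    if k < 2:
        raise ValidationError("need >= 2 doses")
    if not 0 < ratio < 1:
        raise ValidationError("ratio must lie in (0, 1)")
    if not top_dose > 0:
        raise ValidationError("top dose must be > 0")
    return [top_dose * ratio**j for j in range(k)]


def estimate_ld50(groups: Sequence[DoseGroup]) -> LD50Result:
    """Modified Karber LD50 from a geometric, anchored dose series."""
    if len(groups) < 3:
        raise ValidationError("need >= 3 dose groups")
    groups = sorted(groups, key=lambda g: g.dose)
    logd = np.log10([g.dose for g in groups])
    spacings = np.diff(logd)
    if np.any(spacings <= 0):
        raise SpacingError("duplicate doses in series")
    if np.max(spacings) - np.min(spacings) > _SPACING_TOL:
        raise SpacingError(
            f"doses must form a geometric series (log10 spacings {spacings.round(6).tolist()})"
        )
    p = np.array([g.p for g in groups])
    if p[0] != 0.0:
        raise AnchorError("lowest dose must produce 0% mortality")
    if p[-1] != 1.0:
        raise AnchorError("highest dose must produce 100% mortality")
    i = float(np.mean(spacings))
    xm = float(logd[-1])
    log_ld50 = xm - i * (float(p.sum()) - 0.5)
    return LD50Result(
        ld50=float(10.0**log_ld50), log_spacing=i, groups_used=len(groups)
    )


def relative_toxicity(ld50s: Mapping[str, float]) -> dict[str, float]:
    """min(LD50)/LD50 per species: 1 for the most toxic, <1 otherwise."""
    if not ld50s:
        raise NoDataError("no LD50 values")
    for sp, v in ld50s.items():
        if not v > 0:
            raise ValidationError(f"LD50 for {sp!r} must be > 0")
    best = min(ld50s.values())
    return {sp: best / v for sp, v in ld50s.items()}


def read_dose_table(path: str | Path) -> dict[str, list[DoseGroup]]:
    """CSV columns species,dose_mg_per_kg,n,deaths -> groups per species."""
    df = pd.read_csv(path)
    need = {"species", "dose_mg_per_kg", "n", "deaths"}
    if not need <= set(df.columns):
        raise ValidationError(f"dose table must have columns {sorted(need)}")
    out: dict[str, list[DoseGroup]] = {}
    for sp, grp in df.groupby("species", sort=False):
        out[str(sp)] = [
            DoseGroup(dose=float(r["dose_mg_per_kg"]), n=int(r["n"]), deaths=int(r["deaths"]))
            for _, r in grp.iterrows()
        ]
    return out
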