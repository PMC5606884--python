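"""Beak-mark scoring: from wing-damage marks to site-level attack rates.

Escaped bird attacks leave characteristic beak marks on butterfly wings.
Depth classifies a mark: below 2 mm it is discounted as wear, 2-5 mm is
ambiguous (bird or other natural causes), above 5 mm it is diagnostic of a
bird attack.  Symmetric damage (mirrored on both wings, made while the
butterfly rested with wings closed) counts as a single attack.  A specimen
is "attacked" if it carries at least one counted mark; the binary index is
preferred over the raw mark count because it is less sensitive to specimen
age.

Background predation pressure at a site is the binary attack rate on
medium-to-large (wingspan > 50 mm) palatable, non-mimetic butterflies --
species with neither toxin nor warning signal, whose attack rate therefore
tracks how willing the local bird community is to strike at butterflies.

All rates are escape-conditional proxies: killed individuals are never
inspected, so these are relative, not absolute, predation measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .errors import NoDataError, ValidationError

CATEGORIES = (
    "model",
    "mimic",
    "aposematic_nonmodel",
    "toxic_nonaposematic",
    "palatable_nonmimic",
)
RINGS = ("Danaus", "Tirumala", "Euploea", "Pachliopta", "Delias", "none")

#: Depth rules (mm): below EXCLUDE_BELOW dropped; above BIRD_ABOVE diagnostic.
EXCLUDE_BELOW_MM = 2.0
BIRD_ABOVE_MM = 5.0

#: Wingspan cutoff for the background-predation-pressure reference group.
PP_MIN_WINGSPAN_MM = 50.0


@dataclass(frozen=True)
class DamageMark:
    depth_mm: float
    edge: str = "sharp"  # sharp | smeared
    symmetric: bool = False
    wing: str = "left"  # left | right | both

    def __post_init__(self):
        if self.depth_mm < 0:
            raise ValidationError("mark depth must be >= 0")
        if self.edge not in ("sharp", "smeared"):
            raise ValidationError(f"unknown edge type {self.edge!r}")
        if self.wing not in ("left", "right", "both"):
            raise ValidationError(f"unknown wing {self.wing!r}")
        if self.symmetric and self.wing != "both":
            raise ValidationError("symmetric damage must span both wings")


@dataclass(frozen=True)
class SpecimenRecord:
    id: str
    species: str
    category: str
    ring: str
    wingspan_mm: float
    age_class: int
    site: str
    transect: str
    marks: tuple[DamageMark, ...] = ()

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.ring not in RINGS:
            raise ValidationError(f"unknown ring {self.ring!r}")
        if self.ring != "none" and self.category not in ("model", "mimic"):
            raise ValidationError("ring membership is only defined for models and mimics")
        if not self.wingspan_mm > 0:
            raise ValidationError("wingspan must be > 0")
        if self.age_class not in (1, 2, 3, 4, 5):
            raise ValidationError("age_class must be 1..5")
        object.__setattr__(self, "marks", tuple(self.marks))


@dataclass(frozen=True)
class SiteAttackSummary:
    site: str
    group: str
    n_inspected: int
    n_attacked: int
    ci95: tuple[float, float]

    @property
    def rate(self) -> float:
        return self.n_attacked / self.n_inspected

    def __post_init__(self):
        if not 0 <= self.n_attacked <= self.n_inspected:
            raise ValidationError("need 0 <= n_attacked <= n_inspected")


def classify_mark(m: DamageMark) -> str:
    """'excluded' (<2 mm), 'ambiguous' (2-5 mm) or 'bird_attack' (>5 mm)."""
    if m.depth_mm < EXCLUDE_BELOW_MM:
        return "excluded"
    if m.depth_mm <= BIRD_ABOVE_MM:
        return "ambiguous"
    return "bird_attack"


def score_specimen(s: SpecimenRecord, include_ambiguous: bool = True) -> tuple[int, int]:
    """(attack_count, attacked) for one specimen.

    Each counted mark contributes 1 attack; a symmetric mark is one attack
    even though it spans both wings.  Ambiguous 2-5 mm marks are counted
    by default (set ``include_ambiguous=False`` for the conservative
    bird-diagnostic-only tally).
    """
    count = 0
    for m in s.marks:
        cls = classify_mark(m)
        if cls == "bird_attack" or (cls == "ambiguous" and include_ambiguous):
            count += 1
    return count, int(count >= 1)


def dedupe_records(records: Iterable[SpecimenRecord]) -> list[SpecimenRecord]:
    """Drop re-captured specimens: keep the first occurrence of each id."""
    seen: set[str] = set()
    out = []
    for r in records:
        if r.id in seen:
            continue
        seen.add(r.id)
        out.append(r)
    return out


def site_attack_rate(
    records: Sequence[SpecimenRecord],
    predicate: Callable[[SpecimenRecord], bool] | None = None,
    site: str = "all",
    group: str = "all",
    include_ambiguous: bool = True,
) -> SiteAttackSummary:
    """Binary attack rate over the records passing ``predicate``.

    The 95% CI is a Wilson score interval, which stays sensible at rates
    near 0 or 1 where the Wald interval collapses.
    """
    subset = [r for r in records if predicate is None or predicate(r)]
    if not subset:
        raise NoDataError(f"no records match filter {group!r} at site {site!r}")
    attacked = sum(score_specimen(r, include_ambiguous)[1] for r in subset)
    lo, hi = proportion_confint(attacked, len(subset), alpha=0.05, method="wilson")
    return SiteAttackSummary(
        site=site, group=group, n_inspected=len(subset), n_attacked=attacked, ci95=(float(lo), float(hi))
    )


def background_predation_pressure(
    records: Sequence[SpecimenRecord], site: str = "all", include_ambiguous: bool = True
) -> SiteAttackSummary:
    """Attack rate on palatable non-mimics with wingspan > 50 mm."""
    return site_attack_rate(
        records,
        predicate=lambda r: r.category == "palatable_nonmimic"
        and r.wingspan_mm > PP_MIN_WINGSPAN_MM,
        site=site,
        group="background_pp",
        include_ambiguous=include_ambiguous,
    )


def compare_indices(records: Sequence[SpecimenRecord], by: str = "site") -> dict[str, float]:
    """OLS agreement between the count and binary attack indices.

    Aggregates both indices per site (mean marks per specimen vs attacked
    fraction) and reports the R^2 and p-value of their linear relation.
    """
    rows = []
    for r in records:
        count, attacked = score_specimen(r)
        rows.append({"g": getattr(r, by), "count": count, "attacked": attacked})
    df = pd.DataFrame(rows).groupby("g").mean()
    if len(df) < 3:
        raise NoDataError("need >= 3 site-level index pairs to compare")
    if np.allclose(df["count"], df["count"].iloc[0]) or np.allclose(
        df["attacked"], df["attacked"].iloc[0]
    ):
        return {"r2": 0.0, "p": 1.0, "n_sites": len(df)}
    res = sps.linregress(df["count"], df["attacked"])
    return {"r2": float(res.rvalue**2), "p": float(res.pvalue), "n_sites": len(df)}


def site_background_pp(records: Sequence[SpecimenRecord]) -> dict[str, float]:
    """Recovered background predation pressure per site."""
    sites = sorted({r.site for r in records})
    out = {}
    for site in sites:
        subset = [r for r in records if r.site == site]
        out[site] = background_predation_pressure(subset, site=site).rate
    return out


def attack_analysis_table(
    records: Sequence[SpecimenRecord],
    pp_by_site: dict[str, float] | None = None,
    include_ambiguous: bool = True,
) -> pd.DataFrame:
    """Specimen-level modeling table for the mimicry-ring attack GLMM.

    One row per model/mimic specimen: site, transect, ring, status and the
    site-level background PP covariate (recomputed from the palatable
    specimens unless supplied).
    """
    if pp_by_site is None:
        pp_by_site = site_background_pp(records)
    rows = []
    for r in records:
        if r.category not in ("model", "mimic"):
            continue
        rows.append(
            {
                "site": r.site,
                "transect": r.transect,
                "ring": r.ring,
                "status": r.category,
                "pp": pp_by_site[r.site],
                "attacked": score_specimen(r, include_ambiguous)[1],
            }
        )
    if not rows:
        raise NoDataError("no model/mimic specimens in records")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV round-trip (one row per mark, specimen metadata repeated)

_MARK_COLUMNS = [
    "specimen_id",
    "species",
    "category",
    "ring",
    "wingspan_mm",
    "age_class",
    "site",
    "transect",
    "depth_mm",
    "edge",
    "symmetric",
    "wing",
]


def read_marks_table(path: str | Path) -> list[SpecimenRecord]:
    """Read the one-row-per-mark CSV and assemble deduplicated specimens.

    A specimen row with an empty ``depth_mm`` means "inspected, no marks".
    """
    df = pd.read_csv(path)
    missing = set(_MARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"marks table missing columns {sorted(missing)}")
    records = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        first = grp.iloc[0]
        marks = []
        for _, row in grp.iterrows():
            if pd.isna(row["depth_mm"]):
                continue
            marks.append(
                DamageMark(
                    depth_mm=float(row["depth_mm"]),
                    edge=str(row["edge"]),
                    symmetric=bool(row["symmetric"]),
                    wing=str(row["wing"]),
                )
            )
        records.append(
            SpecimenRecord(
                id=str(sid),
                species=str(first["species"]),
                category=str(first["category"]),
                ring=str(first["ring"]),
                wingspan_mm=float(first["wingspan_mm"]),
                age_class=int(first["age_class"]),
                site=str(first["site"]),
                transect=str(first["transect"]),
                marks=tuple(marks),
            )
        )
    return dedupe_records(records)


def write_marks_table(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        base = {
            "specimen_id": r.id,
            "species": r.species,
            "category": r.category,
            "ring": r.ring,
            "wingspan_mm": r.wingspan_mm,
            "age_class": r.age_class,
            "site": r.site,
            "transect": r.transect,
        }
        if not r.marks:
            rows.append({**base, "depth_mm": np.nan, "edge": "sharp", "symmetric": False, "wing": "left"})
        for m in r.marks:
            rows.append(
                {**base, "depth_mm": m.depth_mm, "edge": m.edge, "symmetric": m.symmetric, "wing": m.wing}
            )
    pd.DataFrame(rows, columns=_MARK_COLUMNS).to_csv(path, index=False)
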