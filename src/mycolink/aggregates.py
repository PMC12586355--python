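"""Soil aggregate stability indices from wet-sieve fraction masses.

Wet sieving fractionates a soil sample into size classes; the mass
distribution over those classes summarises how well the soil's structure
resists slaking.  Three standard indices are computed here:

* **WSA** — water-stable aggregate fraction: the proportion of total mass
  retained on sieves of opening >= 0.25 mm.
* **MWD** — mean weight diameter: the mass-weighted arithmetic mean of the
  representative fraction diameters, ``sum(x_i * w_i) / sum(w_i)``.
* **GMD** — geometric mean diameter: ``exp(sum(w_i * ln x_i) / sum(w_i))``.

``x_i`` is the representative (mean) diameter of the *i*-th size class and
``w_i`` its mass.  By the weighted AM-GM inequality GMD <= MWD always, with
equality only when all mass sits at a single diameter.

The default size classes follow the common seven-sieve wet-sieving stack
(> 2, 2-1, 1-0.5, 0.5-0.25, 0.25-0.106, 0.106-0.053, < 0.053 mm).  The two
open-ended classes have no defined midpoint; the representative diameter of
the top class defaults to the midpoint between 2 mm and a configurable cap
(5 mm), and the bottom class to 0.053 / 2 mm.  Both are overridable because
different labs use different conventions and the choice shifts MWD/GMD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "SizeClass",
    "SievingProfile",
    "AggregateIndices",
    "default_size_classes",
    "compute_wsa",
    "compute_mwd",
    "compute_gmd",
    "compute_indices",
    "indices_table",
    "read_sieving_csv",
    "write_sieving_csv",
]

#: Default cap (mm) used as the upper bound of the open top class.
DEFAULT_TOP_CAP_MM = 5.0


@dataclass(frozen=True)
class SizeClass:
    """One sieve fraction.

    ``upper_mm is None`` marks the open top class (> lower_mm); a
    ``lower_mm`` of 0 marks the open bottom class (< upper_mm).
    ``mean_diameter_mm`` is the representative diameter x_i used by MWD/GMD.
    """

    lower_mm: float
    upper_mm: float | None
    mean_diameter_mm: float

    def __post_init__(self) -> None:
        if self.mean_diameter_mm <= 0:
            raise ValueError("mean_diameter_mm must be positive")
        if self.upper_mm is not None and not self.lower_mm < self.upper_mm:
            raise ValueError("require lower_mm < upper_mm")

    @property
    def label(self) -> str:
        if self.upper_mm is None:
            return f">{self.lower_mm:g}mm"
        if self.lower_mm == 0:
            return f"<{self.upper_mm:g}mm"
        return f"{self.upper_mm:g}-{self.lower_mm:g}mm"


def default_size_classes(top_cap_mm: float = DEFAULT_TOP_CAP_MM) -> tuple[SizeClass, ...]:
    """The seven-class wet-sieving stack with midpoint representative diameters."""
    bounds = [2.0, 1.0, 0.5, 0.25, 0.106, 0.053]
    classes = [SizeClass(2.0, None, (2.0 + top_cap_mm) / 2.0)]
    for hi, lo in zip(bounds[:-1], bounds[1:]):
        classes.append(SizeClass(lo, hi, (lo + hi) / 2.0))
    classes.append(SizeClass(0.0, 0.053, 0.053 / 2.0))
    return tuple(classes)


@dataclass(frozen=True)
class SievingProfile:
    """Per-sample masses across size classes (g)."""

    sample_id: str
    size_classes: tuple[SizeClass, ...]
    masses_g: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.size_classes) != len(self.masses_g):
            raise ValueError("one mass per size class required")
        if any(m < 0 for m in self.masses_g):
            raise ValueError("fraction masses must be nonnegative")

    @property
    def total_mass_g(self) -> float:
        return float(sum(self.masses_g))


@dataclass(frozen=True)
class AggregateIndices:
    wsa: float
    mwd_mm: float
    gmd_mm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.wsa <= 1.0 + 1e-12:
            raise ValueError("WSA must lie in [0, 1]")


def _require_mass(profile: SievingProfile) -> float:
    total = profile.total_mass_g
    if total <= 0:
        raise ValueError(
            f"sample {profile.sample_id!r}: total sieved mass is zero; "
            "aggregate indices are undefined"
        )
    return total


def compute_wsa(profile: SievingProfile, cutoff_mm: float = 0.25) -> float:
    """Mass fraction of aggregates retained on sieves >= ``cutoff_mm``.

    Classes are treated as [lower, upper): the mass caught on the 0.25 mm
    sieve itself counts as water-stable.
    """
    total = _require_mass(profile)
    stable = sum(
        m for sc, m in zip(profile.size_classes, profile.masses_g)
        if sc.lower_mm >= cutoff_mm
    )
    return float(stable / total)


def compute_mwd(profile: SievingProfile) -> float:
    """Mass-weighted arithmetic mean diameter (mm)."""
    total = _require_mass(profile)
    num = sum(sc.mean_diameter_mm * m for sc, m in zip(profile.size_classes, profile.masses_g))
    return float(num / total)


def compute_gmd(profile: SievingProfile) -> float:
    """Mass-weighted geometric mean diameter (mm).

    Zero-mass classes contribute nothing (0 * ln x == 0 convention), so a
    class of zero mass with any diameter is harmless.
    """
    total = _require_mass(profile)
    acc = 0.0
    for sc, m in zip(profile.size_classes, profile.masses_g):
        if m == 0:
            continue
        if sc.mean_diameter_mm <= 0:
            raise ValueError(
                f"sample {profile.sample_id!r}: positive mass in class with "
                "nonpositive mean diameter"
            )
        acc += m * math.log(sc.mean_diameter_mm)
    return float(math.exp(acc / total))


def compute_indices(profile: SievingProfile, cutoff_mm: float = 0.25) -> AggregateIndices:
    return AggregateIndices(
        wsa=compute_wsa(profile, cutoff_mm=cutoff_mm),
        mwd_mm=compute_mwd(profile),
        gmd_mm=compute_gmd(profile),
    )


def indices_table(profiles: Sequence[SievingProfile], cutoff_mm: float = 0.25) -> pd.DataFrame:
    """Tidy per-sample indices: columns sample_id, wsa, mwd_mm, gmd_mm."""
    rows = []
    for p in profiles:
        idx = compute_indices(p, cutoff_mm=cutoff_mm)
        rows.append({"sample_id": p.sample_id, "wsa": idx.wsa,
                     "mwd_mm": idx.mwd_mm, "gmd_mm": idx.gmd_mm})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# I/O: one row per (sample, class) with explicit bounds so nonstandard sieve
# stacks round-trip.

def write_sieving_csv(profiles: Sequence[SievingProfile], path) -> None:
    rows = []
    for p in profiles:
        for sc, m in zip(p.size_classes, p.masses_g):
            rows.append({
                "sample_id": p.sample_id,
                "lower_mm": sc.lower_mm,
                "upper_mm": "" if sc.upper_mm is None else sc.upper_mm,
                "mean_diameter_mm": sc.mean_diameter_mm,
                "mass_g": m,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sieving_csv(path) -> list[SievingProfile]:
    df = pd.read_csv(path)
    required = {"sample_id", "lower_mm", "upper_mm", "mean_diameter_mm", "mass_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sieving CSV missing columns: {sorted(missing)}")
    profiles = []
    for sid, grp in df.groupby("sample_id", sort=False):
        classes = tuple(
            SizeClass(
                lower_mm=float(r.lower_mm),
                upper_mm=None if pd.isna(r.upper_mm) else float(r.upper_mm),
                mean_diameter_mm=float(r.mean_diameter_mm),
            )
            for r in grp.itertuples()
        )
        masses = tuple(float(m) for m in grp["mass_g"])
        profiles.append(SievingProfile(str(sid), classes, masses))
    return profiles
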