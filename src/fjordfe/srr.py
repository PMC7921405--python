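"""Sulfate reduction rates from ³⁵S radiotracer incubations.

Carrier-free ³⁵S-sulfate is injected into intact sediment cores; after
incubation the cores are sliced and the radioactivity recovered in the total
reduced inorganic sulfur pool (TRIS, by cold-chromium distillation) and the
residual sulfate pool is counted.  The volumetric rate follows the standard
single-injection tracer formula:

    SRR = [SO4] · φ · (a_TRIS / (a_TRIS + a_SO4)) · f / t

with [SO4] the porewater sulfate in nmol per cm³ of porewater (mM × 1000),
φ the porosity (scales porewater to whole sediment), f the isotope
fractionation correction (1.06 by default for the cold-chromium method), and
t the incubation time in days — giving nmol cm⁻³ d⁻¹.  Depth integration of
1-cm sliced profiles uses the piecewise-constant rule (rate × thickness).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "TracerMeasurement",
    "RateProfile",
    "srr_from_tracer",
    "depth_integrate",
    "DEFAULT_FRACTIONATION",
]

DEFAULT_FRACTIONATION = 1.06


@dataclass(frozen=True)
class TracerMeasurement:
    """One ³⁵S incubation slice.

    sulfate_mM : porewater sulfate, mmol L⁻¹
    porosity   : porewater volume fraction, in (0, 1)
    a_tris     : radioactivity in the reduced-sulfur (TRIS) pool, counts
    a_so4      : radioactivity in the sulfate pool, counts
    t_days     : incubation time, days
    frac       : isotope fractionation correction, default 1.06
    depth_top, thickness : slice position and extent, cm
    """

    sulfate_mM: float
    porosity: float
    a_tris: float
    a_so4: float
    t_days: float
    frac: float = DEFAULT_FRACTIONATION
    depth_top: float = 0.0
    thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.a_tris < 0 or self.a_so4 < 0:
            raise ValueError("activities must be non-negative")
        if self.a_tris + self.a_so4 <= 0:
            raise ValueError("total activity must be positive")
        if not (0 < self.porosity < 1):
            raise ValueError("porosity must lie in (0, 1)")
        if not self.t_days > 0:
            raise ValueError("incubation time must be positive")


@dataclass(frozen=True)
class RateProfile:
    """Ordered, non-overlapping depth slices of volumetric SRR.

    ``slices`` is a sequence of ``(depth_top_cm, thickness_cm, rate)`` with
    rates in nmol cm⁻³ d⁻¹, ordered by depth.
    """

    slices: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        sl = tuple((float(a), float(b), float(c)) for a, b, c in self.slices)
        object.__setattr__(self, "slices", sl)
        prev_bottom = -np.inf
        for top, thick, _rate in sl:
            if thick <= 0:
                raise ValueError("slice thickness must be positive")
            if top < prev_bottom - 1e-12:
                raise ValueError("depth intervals overlap or are out of order")
            prev_bottom = top + thick


def srr_from_tracer(m: TracerMeasurement) -> float:
    """Volumetric sulfate reduction rate, nmol cm⁻³ d⁻¹."""
    nmol_per_cm3_pw = m.sulfate_mM * 1000.0          # mM → nmol cm⁻³ porewater
    frac_reduced = m.a_tris / (m.a_tris + m.a_so4)
    return nmol_per_cm3_pw * m.porosity * frac_reduced * m.frac / m.t_days


def depth_integrate(profile: RateProfile) -> float:
    """Areal rate, nmol cm⁻² d⁻¹: Σ rate × thickness over the slices."""
    if not profile.slices:
        raise ValueError("profile has no slices")
    return float(sum(rate * thick for _top, thick, rate in profile.slices))


def profile_from_measurements(ms: Sequence[TracerMeasurement]) -> RateProfile:
    """Build an ordered rate profile from per-slice tracer measurements."""
    ordered = sorted(ms, key=lambda m: m.depth_top)
    return RateProfile(
        slices=tuple((m.depth_top, m.thickness, srr_from_tracer(m)) for m in ordered)
    )
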