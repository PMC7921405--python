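"""Wet-chemistry reductions: calibration, curve building, speciation, porosity.

Everything upstream of the kinetic model lives here: the linear calibration of
colorimetric assays (ferrozine for Fe(II), formaldoxime for Mn — both are
plain absorbance-vs-concentration lines), conversion of timed vessel
concentrations into per-gram-dry-weight dissolution curves, the two-step
sequential HCl speciation bookkeeping, porosity/water content from drying, and
replicate aggregation with uninoculated controls kept separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .rcm import DissolutionCurve

__all__ = [
    "CalibrationLine",
    "StepSpeciation",
    "SpeciationResult",
    "PhysicalProps",
    "ReplicateSummary",
    "calibrate_linear",
    "absorbance_to_conc",
    "build_dissolution_curve",
    "hcl_speciation",
    "physical_props",
    "aggregate_replicates",
]

HCL_STEPS = ("0.5M", "6M")   # poorly crystalline, then crystalline pool


@dataclass(frozen=True)
class CalibrationLine:
    """OLS calibration of absorbance vs concentration (µM)."""

    slope: float        # absorbance per µM
    intercept: float    # absorbance
    r2: float
    n_standards: int

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be > 0")
        if self.n_standards < 2:
            raise ValueError("calibration needs at least 2 standards")


@dataclass(frozen=True)
class StepSpeciation:
    """Fe speciation in one HCl step, µmol per g dry weight."""

    fe2: float
    fe_total: float
    fe3: float
    clipped: bool


@dataclass(frozen=True)
class SpeciationResult:
    """Sequential-HCl Fe pools: 0.5 M (poorly crystalline), 6 M (crystalline)."""

    steps: dict[str, StepSpeciation]
    total_hcl: float


@dataclass(frozen=True)
class PhysicalProps:
    """Porosity (volume fraction) and water content (wet mass fraction)."""

    porosity: float
    water_content: float


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sd: float | None
    n: int
    control: float | None = None


def calibrate_linear(standards: Sequence[tuple[float, float]]) -> CalibrationLine:
    """Fit an OLS calibration line through (concentration µM, absorbance) pairs."""
    conc = np.asarray([s[0] for s in standards], dtype=float)
    absb = np.asarray([s[1] for s in standards], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("need at least 2 distinct standard concentrations")
    res = stats.linregress(conc, absb)
    return CalibrationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_standards=int(conc.size),
    )


def absorbance_to_conc(
    cal: CalibrationLine, absorbance: float, dilution_factor: float = 1.0
) -> tuple[float, bool]:
    """Invert the calibration: ((A − intercept)/slope) × dilution, in µM.

    Negative results (absorbance below the blank) are clipped to 0 and
    flagged.  Returns ``(concentration, clipped)``.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    conc = (absorbance - cal.intercept) / cal.slope * dilution_factor
    if conc < 0:
        return 0.0, True
    return float(conc), False


def build_dissolution_curve(
    times_s: Sequence[float],
    conc_uM: Sequence[float],
    volume_l: float,
    dry_mass_g: float,
    withdrawal_l: float | Sequence[float] = 0.0,
    correct: bool = False,
    label: str = "",
    is_control: bool = False,
) -> DissolutionCurve:
    """Convert timed vessel Fe(II) concentrations into a per-g-dw curve.

    Without correction, ``cumulative_fe[i] = conc[i] · volume / dry_mass``.
    With ``correct=True`` each point additionally credits the Fe mass removed
    in earlier sampling aliquots and debits the remaining extractant volume:

        fe[i] = (conc[i] · V_i + Σ_{j<i} conc[j] · w_j) / dry_mass,
        V_i = volume − Σ_{j<i} w_j

    where ``w_j`` is the aliquot volume withdrawn at sample ``j``.  The
    default ``correct=False`` reflects aliquots that are negligible relative
    to the vessel volume.
    """
    t = np.asarray(times_s, dtype=float)
    c = np.asarray(conc_uM, dtype=float)
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate timestamps in concentration series")
    w = np.broadcast_to(np.asarray(withdrawal_l, dtype=float), t.shape).copy()

    if correct:
        removed_before = np.concatenate([[0.0], np.cumsum(w * c)[:-1]])  # µmol
        vol_remaining = volume_l - np.concatenate([[0.0], np.cumsum(w)[:-1]])
        if np.any(vol_remaining <= 0):
            raise ValueError("withdrawals exceed the extraction volume")
        fe = (c * vol_remaining + removed_before) / dry_mass_g
    else:
        fe = c * volume_l / dry_mass_g

    return DissolutionCurve(
        times=t,
        cumulative_fe=fe,
        dry_mass=dry_mass_g,
        volume=volume_l,
        label=label,
        is_control=is_control,
    )


def hcl_speciation(
    step_measurements: dict[str, tuple[float, float]]
) -> SpeciationResult:
    """Sequential-HCl speciation bookkeeping.

    ``step_measurements`` maps each step (``"0.5M"``, ``"6M"``) to
    ``(fe2, fe_total)`` in µmol g dw⁻¹.  Fe(III) is obtained by difference,
    ``fe_total − fe2``, clipped at zero (with a flag) when the Fe(II)
    measurement exceeds the total; ``total_hcl`` sums the step totals.
    """
    missing = [s for s in HCL_STEPS if s not in step_measurements]
    if missing:
        raise ValueError(f"missing HCl step(s): {missing}")
    steps: dict[str, StepSpeciation] = {}
    total = 0.0
    for name in HCL_STEPS:
        fe2, fetot = (float(x) for x in step_measurements[name])
        if fe2 < 0 or fetot < 0:
            raise ValueError(f"negative Fe measurement in step {name}")
        fe3 = fetot - fe2
        clipped = fe3 < 0
        steps[name] = StepSpeciation(
            fe2=fe2, fe_total=fetot, fe3=max(fe3, 0.0), clipped=clipped
        )
        total += fetot
    return SpeciationResult(steps=steps, total_hcl=total)


def physical_props(
    wet_mass_g: float,
    dry_mass_g: float,
    sample_volume_cm3: float,
    water_density: float = 1.0,
) -> PhysicalProps:
    """Porosity and water content from weight loss on drying a known volume.

    water_content = (wet − dry) / wet (wet-mass basis);
    porosity = ((wet − dry)/ρ_w) / sample volume.
    """
    if not (wet_mass_g >= dry_mass_g > 0):
        raise ValueError("require wet_mass >= dry_mass > 0")
    if not sample_volume_cm3 > 0:
        raise ValueError("sample_volume must be > 0")
    water_content = (wet_mass_g - dry_mass_g) / wet_mass_g
    porosity = ((wet_mass_g - dry_mass_g) / water_density) / sample_volume_cm3
    if porosity > 1:
        raise ValueError(
            f"computed porosity {porosity:.3f} > 1: inconsistent mass/volume inputs"
        )
    return PhysicalProps(porosity=porosity, water_content=water_content)


def aggregate_replicates(
    values: Sequence[float], control_value: float | None = None
) -> ReplicateSummary:
    """Mean ± sample SD over inoculated replicates; control reported alongside.

    The uninoculated control measures native iron-reducer activity — it is a
    measurement in its own right, never pooled with or subtracted from the
    inoculated replicates.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one replicate")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else None
    return ReplicateSummary(
        mean=float(np.mean(x)), sd=sd, n=int(x.size), control=control_value
    )
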