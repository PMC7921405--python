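"""Reactive continuum model (RCM) of iron dissolution kinetics.

Time-course Fe extractions (chemical, with ascorbate, or microbial, with an
iron-reducing culture) release Fe(II) into solution from a sediment pool whose
reactivity is not uniform: the most reactive mineral surfaces dissolve first
and the apparent rate constant of the remaining pool decreases over time.  The
reactive continuum model captures this with three parameters,

    M(t) = M0 * (a / (a + t))**v

where ``M0`` is the total extractable iron (µmol per g dry weight), ``a`` a
time-scale parameter (s) and ``v`` a dimensionless heterogeneity exponent.
The dissolution rate follows

    J(t) = M0 * (v/a) * (M(t)/M0)**(1 + 1/v)

and the cumulative iron released into solution is ``Fe_d(t) = M0 - M(t)``.

Interpretive parameters derived from a fit:

* reducibility ``v/a`` (s⁻¹) — apparent rate constant of the pool,
* composition ``1 + 1/v`` — heterogeneity index (≈1: uniform pool; >1:
  mixture of reactivities),
* lability ``(v/a) * M0`` (µmol g dw⁻¹ s⁻¹) — initial dissolution rate.

Calibration follows the field convention: ``M0`` is *fixed* from the observed
plateau of the dissolution curve (the maximum Fe released by the end of the
extraction), then ``a`` and ``v`` are fitted by nonlinear least squares to the
cumulative release curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RCMParams",
    "DerivedParams",
    "RCMFit",
    "DissolutionCurve",
    "PlateauRule",
    "FitOptions",
    "rcm_remaining",
    "rcm_dissolved",
    "rcm_rate",
    "estimate_m0",
    "fit_rcm",
    "derive_params",
    "grid_search_rcm",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RCMParams:
    """The kinetic triple (M0, a, v).

    Attributes
    ----------
    m0 : float
        Total extractable Fe, µmol per g dry weight. > 0.
    a : float
        Time-scale parameter, seconds. > 0.
    v : float
        Heterogeneity exponent, dimensionless. > 0.
    """

    m0: float
    a: float
    v: float

    def __post_init__(self) -> None:
        for name in ("m0", "a", "v"):
            x = getattr(self, name)
            if not (math.isfinite(x) and x > 0):
                raise ValueError(f"RCMParams.{name} must be finite and > 0, got {x}")


@dataclass(frozen=True)
class DerivedParams:
    """Interpretive parameters of a fitted extractable-iron pool.

    reducibility : v/a, s⁻¹ (apparent rate constant)
    composition  : 1 + 1/v, dimensionless (heterogeneity index)
    lability     : (v/a)·M0, µmol g dw⁻¹ s⁻¹ (initial dissolution rate)
    """

    reducibility: float
    composition: float
    lability: float


@dataclass(frozen=True)
class DissolutionCurve:
    """Cumulative Fe released per g dry weight over one extraction.

    ``times`` are seconds since the start of the extraction, strictly
    increasing with ``times[0] == 0``.  ``cumulative_fe[0]`` may be positive
    (instantaneous release on contact with the extractant).
    """

    times: np.ndarray
    cumulative_fe: np.ndarray
    dry_mass: float
    volume: float
    label: str = ""
    is_control: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        fe = np.asarray(self.cumulative_fe, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumulative_fe", fe)
        if t.ndim != 1 or fe.shape != t.shape:
            raise ValueError("times and cumulative_fe must be 1-D and equal length")
        if t.size and t[0] != 0:
            raise ValueError("first sampling time must be 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(fe < 0):
            raise ValueError("cumulative_fe must be non-negative")
        if not self.dry_mass > 0:
            raise ValueError("dry_mass must be > 0")
        if not self.volume > 0:
            raise ValueError("volume must be > 0")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class RCMFit:
    """Result of calibrating the RCM to a dissolution curve."""

    params: RCMParams
    m0_source: str
    residuals: np.ndarray          # model − data, µmol g dw⁻¹
    converged: bool
    n_points: int
    se_a: float | None = None
    se_v: float | None = None
    cost: float = float("nan")     # 0.5 * sum(residuals²)

    def __post_init__(self) -> None:
        r = np.asarray(self.residuals, dtype=float)
        object.__setattr__(self, "residuals", r)
        if r.size != self.n_points:
            raise ValueError("residual vector length must equal n_points")


@dataclass(frozen=True)
class PlateauRule:
    """How M0 is fixed from the observed dissolution curve.

    method
        ``"max"`` (default): M0 = maximum observed cumulative Fe, i.e. the
        maximum amount released by the end of the extraction.
        ``"tail_mean"``: mean of the final ``k`` points, provided they lie
        within the relative stability window.
    k
        Number of tail points inspected by the stability criterion.
    rel_window
        Relative spread (max−min)/max allowed across the tail for the curve
        to count as stabilized.
    """

    method: Literal["max", "tail_mean"] = "max"
    k: int = 3
    rel_window: float = 0.05


@dataclass(frozen=True)
class FitOptions:
    """Options for the (a, v) nonlinear least-squares fit.

    Initial values default to a0 = median sampling time and v0 = 1; the fit
    runs on log10-transformed parameters for conditioning, with bounds
    a ∈ [1, 1e9] s and v ∈ [1e-3, 1e3].  Weighting is unweighted by default;
    ``weighting="relative"`` divides residuals by max(data, eps).
    """

    a0: float | None = None
    v0: float = 1.0
    a_bounds: tuple[float, float] = (1.0, 1e9)
    v_bounds: tuple[float, float] = (1e-3, 1e3)
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12
    weighting: Literal["none", "relative"] = "none"
    max_nfev: int = 2000


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def rcm_remaining(params: RCMParams, t):
    """Extractable Fe remaining in the sediment at time ``t`` (s).

    Returns ``M0 * (a/(a+t))**v`` in µmol g dw⁻¹; vectorizes over ``t``.
    """
    t = _check_time(t)
    return params.m0 * (params.a / (params.a + t)) ** params.v


def rcm_dissolved(params: RCMParams, t):
    """Cumulative Fe released into solution at time ``t``: M0 − M(t)."""
    return params.m0 - rcm_remaining(params, t)


def rcm_rate(params: RCMParams, t):
    """Instantaneous dissolution rate J(t), µmol g dw⁻¹ s⁻¹.

    J = M0 · (v/a) · (M(t)/M0)^(1+1/v); equals −dM/dt and J(0) = M0·v/a.
    """
    t = _check_time(t)
    frac = (params.a / (params.a + t)) ** params.v   # M(t)/M0
    return params.m0 * (params.v / params.a) * frac ** (1.0 + 1.0 / params.v)


# ---------------------------------------------------------------------------
# M0 from the plateau
# ---------------------------------------------------------------------------

def estimate_m0(
    curve: DissolutionCurve, rule: PlateauRule = PlateauRule()
) -> tuple[float, bool]:
    """Fix M0 from the dissolution curve's end-of-extraction plateau.

    Returns ``(m0, stable)``.  Under the default ``"max"`` rule M0 is the
    maximum observed cumulative Fe; ``stable`` reports whether the final
    ``rule.k`` samples lie within the relative window ``rule.rel_window``
    (the "stable Fe(II) concentration" stopping criterion).  A curve that
    never stabilizes returns ``stable=False``, never an exception.
    """
    fe = curve.cumulative_fe
    if fe.size < 3:
        raise ValueError("need at least 3 points to estimate a plateau")

    tail = fe[-rule.k:]
    tmax = float(tail.max())
    if tmax == 0.0:
        stable = bool(np.all(tail == 0.0))
    else:
        stable = bool((tmax - tail.min()) / tmax <= rule.rel_window)

    if rule.method == "max":
        m0 = float(fe.max())
    elif rule.method == "tail_mean":
        m0 = float(tail.mean()) if stable else float(fe.max())
    else:  # pragma: no cover - guarded by the Literal type
        raise ValueError(f"unknown plateau rule {rule.method!r}")
    return m0, stable


def plateau_onset(curve: DissolutionCurve) -> float:
    """Earliest time at which the maximum cumulative Fe is attained (s)."""
    fe = curve.cumulative_fe
    return float(curve.times[int(np.argmax(fe))])


# ---------------------------------------------------------------------------
# Nonlinear least-squares calibration of (a, v) with M0 fixed
# ---------------------------------------------------------------------------

def _residual_vec(log_av, times, data, m0, weighting):
    a = 10.0 ** log_av[0]
    v = 10.0 ** log_av[1]
    model = m0 - m0 * (a / (a + times)) ** v
    r = model - data
    if weighting == "relative":
        r = r / np.maximum(np.abs(data), 1e-12)
    return r


def fit_rcm(
    curve: DissolutionCurve,
    m0: float,
    options: FitOptions = FitOptions(),
    m0_source: str = "max",
) -> RCMFit:
    """Fit (a, v) of the RCM to a cumulative dissolution curve, M0 fixed.

    Minimizes the squared deviation between ``curve.cumulative_fe`` and
    ``rcm_dissolved`` with M0 held at ``m0``, on log10-transformed parameters
    (trust-region reflective).  Deterministic for given inputs and options.
    Non-convergence is reported via ``converged=False`` with the best iterate.
    """
    if not m0 > 0:
        raise ValueError("m0 must be > 0")
    if len(curve) < 4:
        raise ValueError("need at least 4 time points to fit a and v")
    data = curve.cumulative_fe
    if np.all(data == 0):
        raise ValueError("degenerate curve: all cumulative Fe values are zero")

    times = curve.times
    a0 = options.a0 if options.a0 is not None else float(np.median(times[times > 0]))
    a0 = float(np.clip(a0, *options.a_bounds))
    v0 = float(np.clip(options.v0, *options.v_bounds))

    lo = [math.log10(options.a_bounds[0]), math.log10(options.v_bounds[0])]
    hi = [math.log10(options.a_bounds[1]), math.log10(options.v_bounds[1])]
    x0 = [math.log10(a0), math.log10(v0)]

    sol = least_squares(
        _residual_vec,
        x0,
        bounds=(lo, hi),
        args=(times, data, m0, options.weighting),
        xtol=options.xtol,
        ftol=options.ftol,
        gtol=options.gtol,
        max_nfev=options.max_nfev,
        method="trf",
    )

    a_hat, v_hat = 10.0 ** sol.x[0], 10.0 ** sol.x[1]
    params = RCMParams(m0=m0, a=a_hat, v=v_hat)
    resid = rcm_dissolved(params, times) - data

    se_a = se_v = None
    dof = times.size - 2
    if sol.success and dof > 0:
        # Gauss-Newton covariance on the log10 scale, propagated via ln(10)·x
        J = sol.jac
        s2 = 2.0 * sol.cost / dof
        try:
            cov_log = s2 * np.linalg.inv(J.T @ J)
            se_log = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
            se_a = float(math.log(10.0) * a_hat * se_log[0])
            se_v = float(math.log(10.0) * v_hat * se_log[1])
        except np.linalg.LinAlgError:
            pass

    return RCMFit(
        params=params,
        m0_source=m0_source,
        residuals=resid,
        converged=bool(sol.success),
        n_points=int(times.size),
        se_a=se_a,
        se_v=se_v,
        cost=float(sol.cost),
    )


def grid_search_rcm(
    curve: DissolutionCurve,
    m0: float,
    a_bounds: tuple[float, float] = (1.0, 1e9),
    v_bounds: tuple[float, float] = (1e-3, 1e3),
    n: int = 200,
) -> RCMParams:
    """Brute-force (a, v) minimizer on an ``n`` × ``n`` log-spaced grid.

    An independent, derivative-free check on :func:`fit_rcm`: evaluates the
    sum of squared deviations at every grid node and returns the best node.
    Accurate only to the grid resolution.
    """
    a_grid = np.logspace(math.log10(a_bounds[0]), math.log10(a_bounds[1]), n)
    v_grid = np.logspace(math.log10(v_bounds[0]), math.log10(v_bounds[1]), n)
    t = curve.times[np.newaxis, np.newaxis, :]
    A = a_grid[:, np.newaxis, np.newaxis]
    V = v_grid[np.newaxis, :, np.newaxis]
    model = m0 - m0 * (A / (A + t)) ** V
    sse = np.sum((model - curve.cumulative_fe[np.newaxis, np.newaxis, :]) ** 2, axis=2)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return RCMParams(m0=m0, a=float(a_grid[i]), v=float(v_grid[j]))


# ---------------------------------------------------------------------------
# Derived interpretive parameters
# ---------------------------------------------------------------------------

def derive_params(fit: RCMFit) -> DerivedParams:
    """Reducibility, composition and lability from a converged fit.

    Raises ``ValueError`` on a non-converged fit: its parameters are the best
    iterate of a failed optimization, not an estimate.
    """
    if not fit.converged:
        raise ValueError("derived parameters refused for a non-converged fit")
    p = fit.params
    red = p.v / p.a
    return DerivedParams(
        reducibility=red,
        composition=1.0 + 1.0 / p.v,
        lability=red * p.m0,
    )
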