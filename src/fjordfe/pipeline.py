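"""End-to-end pipeline: read → curves → RCM fits → speciation → SRR → gradients.

One :func:`run` call takes either a directory of delimited-text tables or a
synthetic scenario, executes every stage, and returns (and optionally writes)
tidy result tables keyed by station/depth/vessel.  Runs are deterministic
given the configuration and seed; the configuration is echoed into the output
so a run can be reproduced from its own results directory.

Input schemas (CSV, one header row):

* ``dissolution.csv`` — station, depth_top_cm, extraction, vessel,
  is_control, time_s, conc_uM, dry_mass_g, volume_l
* ``hcl.csv`` — station, depth_top_cm, step, fe2_umol_gdw, fetot_umol_gdw
* ``tracer.csv`` — station, core, depth_top_cm, thickness_cm, sulfate_mM,
  porosity, a_tris, a_so4, t_days
* ``stations.csv`` — station, fjord, transect, distance_km
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assays import build_dissolution_curve, hcl_speciation, aggregate_replicates
from .gradients import TransectRecord, fit_exponential_gradient, transect_fold_change
from .rcm import FitOptions, PlateauRule, derive_params, estimate_m0, fit_rcm
from .srr import RateProfile, TracerMeasurement, depth_integrate, srr_from_tracer
from .synthetic import ScenarioConfig, SyntheticBundle, simulate_transect

__all__ = [
    "RunConfig",
    "RunResult",
    "SchemaError",
    "read_table",
    "run",
    "report",
    "SCHEMAS",
]

logger = logging.getLogger("fjordfe")

SCHEMAS: dict[str, tuple[str, ...]] = {
    "dissolution": (
        "station", "depth_top_cm", "extraction", "vessel", "is_control",
        "time_s", "conc_uM", "dry_mass_g", "volume_l",
    ),
    "hcl": ("station", "depth_top_cm", "step", "fe2_umol_gdw", "fetot_umol_gdw"),
    "tracer": (
        "station", "core", "depth_top_cm", "thickness_cm", "sulfate_mM",
        "porosity", "a_tris", "a_so4", "t_days",
    ),
    "stations": ("station", "fjord", "transect", "distance_km"),
}

_FLOAT_FMT = "%.10g"   # fixed text formatting keeps repeated runs byte-identical


class SchemaError(ValueError):
    """An input table violates its documented schema."""

    def __init__(self, file: str, message: str):
        self.file = file
        super().__init__(f"{file}: {message}")


@dataclass(frozen=True)
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``input_dir`` (directory of CSV tables) or ``scenario``
    (synthetic scenario) must be given.  ``gradient_subsets`` maps a transect
    id to a maximum distance (km); stations beyond it are excluded from that
    transect's gradient fit (reported alongside the full fit).
    """

    input_dir: str | None = None
    scenario: ScenarioConfig | None = None
    out_dir: str | None = None
    seed: int = 0
    plateau_rule: PlateauRule = field(default_factory=PlateauRule)
    fit_options: FitOptions = field(default_factory=FitOptions)
    withdrawal_correction: bool = False
    gradient_subsets: dict[str, float] = field(default_factory=dict)
    alpha: float = 0.05
    verbosity: int = 1

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.scenario is None):
            raise ValueError("exactly one of input_dir or scenario must be set")


@dataclass
class RunResult:
    """All result tables of one pipeline run."""

    params: pd.DataFrame          # per-vessel RCM parameters
    replicate_summary: pd.DataFrame
    speciation: pd.DataFrame
    srr_slices: pd.DataFrame
    srr_integrated: pd.DataFrame
    gradient_fits: pd.DataFrame
    fold_changes: pd.DataFrame
    config_echo: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "params": self.params,
            "replicate_summary": self.replicate_summary,
            "speciation": self.speciation,
            "srr_slices": self.srr_slices,
            "srr_integrated": self.srr_integrated,
            "gradient_fits": self.gradient_fits,
            "fold_changes": self.fold_changes,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in self.tables().items():
            tab.to_csv(out / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
        (out / "config_echo.json").write_text(
            json.dumps(self.config_echo, indent=2, sort_keys=True, default=str) + "\n"
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_table(path, kind: str) -> pd.DataFrame:
    """Read one input CSV and validate its schema.

    Raises :class:`SchemaError` naming the file and the missing column(s).
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(str(path), "file not found")
    df = pd.read_csv(path)
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(str(path), f"missing required column(s): {missing}")
    return df


def _load_bundle(input_dir) -> SyntheticBundle:
    d = Path(input_dir)
    return SyntheticBundle(
        dissolution=read_table(d / "dissolution.csv", "dissolution"),
        hcl=read_table(d / "hcl.csv", "hcl"),
        tracer=read_table(d / "tracer.csv", "tracer"),
        stations=read_table(d / "stations.csv", "stations"),
        truth=pd.DataFrame(),
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _fit_all_vessels(diss: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    rows = []
    keys = ["station", "depth_top_cm", "extraction", "vessel"]
    for (station, depth, extraction, vessel), g in diss.groupby(keys, sort=True):
        g = g.sort_values("time_s")
        curve = build_dissolution_curve(
            g["time_s"].to_numpy(),
            g["conc_uM"].to_numpy(),
            volume_l=float(g["volume_l"].iloc[0]),
            dry_mass_g=float(g["dry_mass_g"].iloc[0]),
            correct=cfg.withdrawal_correction,
            label=f"{station}/{depth}/{extraction}/{vessel}",
            is_control=bool(g["is_control"].iloc[0]),
        )
        m0, stable = estimate_m0(curve, cfg.plateau_rule)
        fit = fit_rcm(curve, m0, cfg.fit_options, m0_source=cfg.plateau_rule.method)
        row = {
            "station": station,
            "depth_top_cm": depth,
            "extraction": extraction,
            "vessel": vessel,
            "is_control": bool(g["is_control"].iloc[0]),
            "m0": fit.params.m0,
            "a": fit.params.a,
            "v": fit.params.v,
            "converged": fit.converged,
            "stable": stable,
            "n_points": fit.n_points,
        }
        if fit.converged:
            d = derive_params(fit)
            row.update(
                reducibility=d.reducibility,
                composition=d.composition,
                lability=d.lability,
            )
        else:
            logger.warning("fit did not converge for %s", curve.label)
            row.update(reducibility=np.nan, composition=np.nan, lability=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _summarize_replicates(params: pd.DataFrame) -> pd.DataFrame:
    rows = []
    keys = ["station", "depth_top_cm", "extraction"]
    for (station, depth, extraction), g in params.groupby(keys, sort=True):
        inoc = g[~g["is_control"]]
        ctrl = g[g["is_control"]]
        for quantity in ("m0", "reducibility", "composition", "lability"):
            vals = inoc[quantity].dropna()
            if vals.empty:
                continue
            ctrl_val = (
                float(ctrl[quantity].iloc[0])
                if len(ctrl) and np.isfinite(ctrl[quantity].iloc[0])
                else np.nan
            )
            s = aggregate_replicates(vals.to_numpy())
            rows.append(
                {
                    "station": station,
                    "depth_top_cm": depth,
                    "extraction": extraction,
                    "quantity": quantity,
                    "mean": s.mean,
                    "sd": s.sd if s.sd is not None else np.nan,
                    "n": s.n,
                    "control": ctrl_val,
                }
            )
    return pd.DataFrame(rows)


def _speciate(hcl: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (station, depth), g in hcl.groupby(["station", "depth_top_cm"], sort=True):
        meas = {
            str(r["step"]): (float(r["fe2_umol_gdw"]), float(r["fetot_umol_gdw"]))
            for _, r in g.iterrows()
        }
        res = hcl_speciation(meas)
        row: dict = {"station": station, "depth_top_cm": depth}
        for step, s in res.steps.items():
            key = step.replace(".", "p")
            row[f"fe2_{key}"] = s.fe2
            row[f"fe3_{key}"] = s.fe3
            row[f"fetot_{key}"] = s.fe_total
            row[f"clipped_{key}"] = s.clipped
        row["total_hcl"] = res.total_hcl
        rows.append(row)
    return pd.DataFrame(rows)


def _rates(tracer: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    slice_rows, integ_rows = [], []
    for (station, core), g in tracer.groupby(["station", "core"], sort=True):
        g = g.sort_values("depth_top_cm")
        slices = []
        for _, r in g.iterrows():
            m = TracerMeasurement(
                sulfate_mM=float(r["sulfate_mM"]),
                porosity=float(r["porosity"]),
                a_tris=float(r["a_tris"]),
                a_so4=float(r["a_so4"]),
                t_days=float(r["t_days"]),
                depth_top=float(r["depth_top_cm"]),
                thickness=float(r["thickness_cm"]),
            )
            rate = srr_from_tracer(m)
            slices.append((m.depth_top, m.thickness, rate))
            slice_rows.append(
                {
                    "station": station,
                    "core": core,
                    "depth_top_cm": m.depth_top,
                    "thickness_cm": m.thickness,
                    "srr_nmol_cm3_d": rate,
                }
            )
        integ_rows.append(
            {
                "station": station,
                "core": core,
                "integrated_srr_nmol_cm2_d": depth_integrate(
                    RateProfile(slices=tuple(slices))
                ),
            }
        )
    return pd.DataFrame(slice_rows), pd.DataFrame(integ_rows)


def _gradients(
    summary: pd.DataFrame, stations: pd.DataFrame, cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    fit_rows, fold_rows = [], []
    surface = summary[summary["depth_top_cm"] == summary["depth_top_cm"].min()]
    meta = stations.set_index("station")
    for transect, tg in meta.groupby("transect", sort=True):
        for extraction in sorted(surface["extraction"].unique()):
            for quantity in ("m0", "lability"):
                sub = surface[
                    (surface["extraction"] == extraction)
                    & (surface["quantity"] == quantity)
                    & surface["station"].isin(tg.index)
                ]
                records = [
                    TransectRecord(
                        station=str(r["station"]),
                        distance_km=float(meta.loc[r["station"], "distance_km"]),
                        value=float(r["mean"]),
                    )
                    for _, r in sub.iterrows()
                    if np.isfinite(r["mean"]) and r["mean"] > 0
                ]
                variants: list[tuple[str, list[TransectRecord]]] = [("all", records)]
                if transect in cfg.gradient_subsets:
                    dmax = cfg.gradient_subsets[transect]
                    variants.append(
                        (
                            f"<= {dmax} km",
                            [r for r in records if r.distance_km <= dmax],
                        )
                    )
                for label, recs in variants:
                    if len(recs) < 3:
                        continue
                    fit = fit_exponential_gradient(recs, subset_label=label)
                    fit_rows.append(
                        {
                            "transect": transect,
                            "extraction": extraction,
                            "quantity": quantity,
                            "subset": label,
                            "growth_rate_per_km": fit.growth_rate,
                            "intercept": fit.intercept,
                            "r2": fit.r2,
                            "p_slope": fit.p_slope,
                            "significant": fit.significant(cfg.alpha),
                            "n": fit.n,
                        }
                    )
                if len(records) >= 2:
                    fold_rows.append(
                        {
                            "transect": transect,
                            "extraction": extraction,
                            "quantity": quantity,
                            "fold_change": transect_fold_change(records),
                        }
                    )
    return pd.DataFrame(fit_rows), pd.DataFrame(fold_rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline; deterministic given ``cfg`` (incl. seed)."""
    logging.basicConfig(
        level=logging.WARNING if cfg.verbosity < 2 else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
    if cfg.scenario is not None:
        scenario = dataclasses.replace(cfg.scenario, seed=cfg.seed)
        bundle = simulate_transect(scenario)
        logger.info("simulated scenario with %d stations", len(bundle.stations))
    else:
        bundle = _load_bundle(cfg.input_dir)

    params = _fit_all_vessels(bundle.dissolution, cfg)
    summary = _summarize_replicates(params)
    speciation = _speciate(bundle.hcl)
    srr_slices, srr_integrated = _rates(bundle.tracer)
    gradient_fits, fold_changes = _gradients(summary, bundle.stations, cfg)

    echo = {
        "fjordfe_version": __version__,
        "seed": cfg.seed,
        "input_dir": cfg.input_dir,
        "scenario": dataclasses.asdict(cfg.scenario) if cfg.scenario else None,
        "plateau_rule": dataclasses.asdict(cfg.plateau_rule),
        "fit_options": dataclasses.asdict(cfg.fit_options),
        "withdrawal_correction": cfg.withdrawal_correction,
        "gradient_subsets": cfg.gradient_subsets,
        "alpha": cfg.alpha,
    }
    result = RunResult(
        params=params,
        replicate_summary=summary,
        speciation=speciation,
        srr_slices=srr_slices,
        srr_integrated=srr_integrated,
        gradient_fits=gradient_fits,
        fold_changes=fold_changes,
        config_echo=echo,
    )
    if cfg.out_dir is not None:
        result.write(cfg.out_dir)
    return result


def report(result: RunResult) -> str:
    """Human-readable summary per transect: fit counts, folds, significance."""
    lines: list[str] = []
    p = result.params
    if p.empty:
        return ""
    n_fit = int(p["converged"].sum())
    n_flag = int((~p["converged"]).sum())
    lines.append(f"RCM fits: {n_fit} converged, {n_flag} flagged, of {len(p)} vessels")
    for _, r in result.gradient_fits.iterrows():
        sig = "significant" if r["significant"] else "not significant"
        lines.append(
            f"transect {r['transect']} {r['extraction']} {r['quantity']} "
            f"[{r['subset']}]: rate {r['growth_rate_per_km']:.4g} km^-1, "
            f"R^2 {r['r2']:.3f}, p {r['p_slope']:.3g} ({sig}, n={int(r['n'])})"
        )
    for _, r in result.fold_changes.iterrows():
        lines.append(
            f"transect {r['transect']} {r['extraction']} {r['quantity']}: "
            f"fold change {r['fold_change']:.3g} (farthest/nearest)"
        )
    if not result.srr_integrated.empty:
        for _, r in result.srr_integrated.iterrows():
            lines.append(
                f"station {r['station']} core {int(r['core'])}: depth-integrated "
                f"SRR {r['integrated_srr_nmol_cm2_d']:.4g} nmol cm^-2 d^-1"
            )
    return "\n".join(lines)
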