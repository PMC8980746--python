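"""Dataset I/O, configuration and the end-to-end calibration pipeline.

CSV formats
-----------
Long:  columns ``time_h, replicate, density_cfu_per_ml``.
Wide:  column ``time_h`` followed by one column per replicate
       (``rep1, rep2, ...``).

A YAML manifest ties conditions together::

    conditions:
      - {label: OFF,  file: off.csv,  role: off,       dialect: wide}
      - {label: ON,   file: on.csv,   role: on,        induction_time: 0}
      - {label: t5,   file: t5.csv,   role: induced,   induction_time: 5}
      - {label: QS,   file: qs.csv,   role: qs}
      - {label: ctrl, file: ctrl.csv, role: reference}

Roles: ``off`` (never induced; fits lambda0/kappa0), ``on`` (induced at 0;
fits lambda1/kappa1, also enters the fitness scan at t_i = 0), ``induced``
(externally induced; delay fits and fitness scan), ``qs`` (threshold scan),
``reference`` (uninduced control for relative fitness; the ``off`` dataset
is used when no explicit reference is given).

``run_pipeline`` executes the staged analysis — (lambda, kappa) calibration,
per-induction-time delay fits, the hinge delay function, the threshold scan
and the empirical/model fitness curves — writing per-stage CSV/JSON outputs
plus a JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import (
    GrowthDataset,
    default_alpha_grid,
    fit_delay,
    fit_delay_function,
    fit_rate_capacity,
    fit_threshold,
)
from .fitness import FitnessCurve, empirical_fitness_scan, model_fitness_scan
from .model import ControlSchedule, DelayFunction, GrowthParams, Trajectory, simulate

__all__ = [
    "read_growth_csv",
    "write_growth_csv",
    "read_manifest",
    "write_manifest",
    "write_fitness_curve",
    "scenario_config_to_inputs",
    "AnalysisConfig",
    "run_pipeline",
]

logger = logging.getLogger("qsgrowth")

_ROLES = ("off", "on", "qs", "induced", "reference")


def read_growth_csv(
    path,
    dialect: str = "wide",
    label: str = "",
    induction_time: Optional[float] = None,
) -> GrowthDataset:
    """Read one condition's replicate counts from CSV.

    Zero or negative densities and ragged replicate grids are rejected with
    a message identifying the offending rows.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if dialect == "long":
        required = {"time_h", "replicate", "density_cfu_per_ml"}
        if not required.issubset(frame.columns):
            raise ValueError(f"{path}: long dialect requires columns {sorted(required)}")
        bad = frame.index[frame["density_cfu_per_ml"] <= 0]
        if len(bad):
            raise ValueError(f"{path}: nonpositive density at data row(s) {list(bad[:5])}")
        pivot = frame.pivot_table(
            index="replicate", columns="time_h", values="density_cfu_per_ml", aggfunc="first"
        )
        if pivot.isna().any().any():
            raise ValueError(f"{path}: replicates do not share a common time grid")
        pivot = pivot.sort_index(axis=1)
        times = pivot.columns.to_numpy(dtype=float)
        counts = pivot.to_numpy(dtype=float)
    elif dialect == "wide":
        if "time_h" not in frame.columns:
            raise ValueError(f"{path}: wide dialect requires a time_h column")
        rep_cols = [c for c in frame.columns if c != "time_h"]
        if not rep_cols:
            raise ValueError(f"{path}: no replicate columns found")
        frame = frame.sort_values("time_h")
        values = frame[rep_cols].to_numpy(dtype=float)
        bad_rows = np.nonzero(~np.all(values > 0, axis=1))[0]
        if len(bad_rows):
            raise ValueError(f"{path}: nonpositive density at data row(s) {list(bad_rows[:5])}")
        times = frame["time_h"].to_numpy(dtype=float)
        counts = values.T
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return GrowthDataset(times=times, counts=counts, label=label, induction_time=induction_time)


def write_growth_csv(dataset: GrowthDataset, path, dialect: str = "wide") -> None:
    path = Path(path)
    if dialect == "wide":
        frame = pd.DataFrame({"time_h": dataset.times})
        for j in range(dataset.n_replicates):
            frame[f"rep{j + 1}"] = dataset.counts[j]
        frame.to_csv(path, index=False)
    elif dialect == "long":
        rows = []
        for j in range(dataset.n_replicates):
            for t, c in zip(dataset.times, dataset.counts[j]):
                rows.append({"time_h": t, "replicate": f"rep{j + 1}", "density_cfu_per_ml": c})
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_manifest(entries: list[dict], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"conditions": entries}, fh, sort_keys=False)


def read_manifest(path) -> list[dict]:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "conditions" not in doc:
        raise ValueError(f"{path}: manifest must contain a 'conditions' list")
    entries = []
    for entry in doc["conditions"]:
        entry = dict(entry)
        role = entry.get("role", "induced")
        if role not in _ROLES:
            raise ValueError(f"{path}: unknown role {role!r} (expected one of {_ROLES})")
        entry["role"] = role
        entry.setdefault("dialect", "wide")
        entry.setdefault("induction_time", None)
        if "label" not in entry or "file" not in entry:
            raise ValueError(f"{path}: every condition needs 'label' and 'file'")
        entries.append(entry)
    return entries


def _load_datasets(manifest_path) -> list[tuple[dict, GrowthDataset]]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    loaded = []
    for entry in read_manifest(manifest_path):
        file_path = base / entry["file"]
        t_i = entry["induction_time"]
        if entry["role"] == "on" and t_i is None:
            t_i = 0.0
        ds = read_growth_csv(
            file_path,
            dialect=entry["dialect"],
            label=entry["label"],
            induction_time=None if t_i is None else float(t_i),
        )
        loaded.append((entry, ds))
    return loaded


def write_fitness_curve(curve: FitnessCurve, path) -> None:
    pd.DataFrame(
        {"induction_time_h": curve.induction_times, "relative_fitness": curve.rf_values}
    ).to_csv(path, index=False)


def scenario_config_to_inputs(doc: dict):
    """Parse a simulation scenario config (keys ``params``, ``schedule``,
    ``delay.knots``, ``n0``, ``t_grid``) into simulation inputs."""
    params = GrowthParams(**{k: float(v) for k, v in doc["params"].items()})
    sched = doc.get("schedule", {"mode": "never"})
    schedule = ControlSchedule(
        mode=sched["mode"],
        t_induction=None if sched.get("t_induction") is None else float(sched["t_induction"]),
        alpha=None if sched.get("alpha") is None else float(sched["alpha"]),
    )
    delay_doc = doc.get("delay", {})
    knots = delay_doc.get("knots")
    delay_fn = (
        DelayFunction(tuple((float(d), float(h)) for d, h in knots))
        if knots
        else DelayFunction.zero()
    )
    n0 = float(doc["n0"])
    tg = doc.get("t_grid", {"start": 0.0, "stop": 24.0, "step": 1.0})
    if isinstance(tg, dict):
        step = float(tg.get("step", 1.0))
        stop = float(tg.get("stop", 24.0))
        t_grid = np.arange(0.0, stop + 0.5 * step, step)
    else:
        t_grid = np.asarray(tg, dtype=float)
    return params, schedule, delay_fn, n0, t_grid


@dataclass
class AnalysisConfig:
    """End-to-end pipeline configuration."""

    manifest: str
    output_dir: str = "qsgrowth_out"
    stages: dict = field(
        default_factory=lambda: {
            "fit_growth": True,
            "fit_delays": True,
            "fit_threshold": True,
            "fitness": True,
        }
    )
    alpha_grid: dict = field(default_factory=lambda: {"min": 1e5, "max": 1e9, "num": 60})
    weight_mode: str = "inv_var"
    n_starts: int = 5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(manifest=doc["manifest"])
        for key in ("output_dir", "weight_mode", "log_level"):
            if key in doc:
                setattr(cfg, key, doc[key])
        for key in ("n_starts", "seed"):
            if key in doc:
                setattr(cfg, key, int(doc[key]))
        if "stages" in doc:
            cfg.stages.update({k: bool(v) for k, v in doc["stages"].items()})
        if "alpha_grid" in doc:
            cfg.alpha_grid.update({k: float(v) for k, v in doc["alpha_grid"].items()})
        return cfg

    def alpha_grid_array(self) -> np.ndarray:
        return default_alpha_grid(
            num=int(self.alpha_grid["num"]),
            lo=float(self.alpha_grid["min"]),
            hi=float(self.alpha_grid["max"]),
        )


def _stage(report: dict, name: str):
    class _StageGuard:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s: failed (%s)", name, exc)
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _StageGuard()


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the staged analysis; returns (and writes) the run report.

    Stage order: (lambda, kappa) calibration on the OFF and ON cultures ->
    per-induction-time (N(0), D) fits -> hinge delay function -> threshold
    scan on the QS culture -> empirical and model fitness curves.  A stage
    failure aborts with the failing stage named; outputs written before the
    failure are preserved.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    logger.info("qsgrowth %s pipeline, seed=%d", __version__, config.seed)

    loaded = _load_datasets(config.manifest)
    by_role: dict[str, list] = {}
    for entry, ds in loaded:
        by_role.setdefault(entry["role"], []).append(ds)

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "weight_mode": config.weight_mode,
        "datasets": {
            ds.label: {
                "role": entry["role"],
                "n_replicates": ds.n_replicates,
                "n_times": ds.n_times,
                "induction_time": ds.induction_time,
            }
            for entry, ds in loaded
        },
    }

    params: Optional[GrowthParams] = None
    delay_fn: Optional[DelayFunction] = None

    def _single(role):
        items = by_role.get(role, [])
        if len(items) != 1:
            raise ValueError(f"expected exactly one dataset with role '{role}', found {len(items)}")
        return items[0]

    if config.stages.get("fit_growth", False):
        with _stage(report, "fit_growth"):
            off_fit = fit_rate_capacity(
                _single("off"),
                "single_phase_off",
                weight_mode=config.weight_mode,
                n_starts=config.n_starts,
                seed=config.seed,
            )
            on_fit = fit_rate_capacity(
                _single("on"),
                "single_phase_on",
                weight_mode=config.weight_mode,
                n_starts=config.n_starts,
                seed=config.seed + 1,
            )
            params = GrowthParams(
                lambda0=off_fit.estimates["lambda"],
                lambda1=on_fit.estimates["lambda"],
                kappa0=off_fit.estimates["kappa"],
                kappa1=on_fit.estimates["kappa"],
            )
            params.check_orientation(warn=False)
            report["growth_fits"] = {"off": off_fit.to_dict(), "on": on_fit.to_dict()}
            report["params"] = {
                "lambda0": params.lambda0,
                "lambda1": params.lambda1,
                "kappa0": params.kappa0,
                "kappa1": params.kappa1,
            }
            with open(out_dir / "params.json", "w") as fh:
                json.dump(report["params"], fh, indent=2)

    induced = sorted(
        by_role.get("on", []) + by_role.get("induced", []),
        key=lambda ds: ds.induction_time,
    )

    if config.stages.get("fit_delays", False):
        with _stage(report, "fit_delays"):
            if params is None:
                raise ValueError("delay fits require the fit_growth stage")
            if not induced:
                raise ValueError("no induced datasets for delay fitting")
            delay_rows = []
            for i, ds in enumerate(induced):
                fit = fit_delay(
                    ds,
                    ds.induction_time,
                    params,
                    weight_mode=config.weight_mode,
                    n_starts=config.n_starts,
                    seed=config.seed + 10 + i,
                )
                delay_rows.append(
                    {
                        "label": ds.label,
                        "induction_time_h": ds.induction_time,
                        "delay_h": fit.estimates["delay"],
                        "delay_se_h": fit.uncertainty.get("delay", float("inf")),
                        "zero_cost_ratio": fit.uncertainty.get("zero_cost_ratio", 1.0),
                        "n0_cfu_per_ml": fit.estimates["n0"],
                        "activation_density_cfu_per_ml": fit.fixed["activation_density"],
                        "wssr": fit.wssr,
                        "converged": fit.converged,
                    }
                )
            frame = pd.DataFrame(delay_rows)
            frame.to_csv(out_dir / "delays.csv", index=False)
            report["delays"] = delay_rows
            if len(delay_rows) >= 2:
                # Hinge inputs.  The t_i = 0 arm is the stage-1 calibration
                # culture: (lambda1, kappa1) were fitted to it as a
                # latency-free logistic, so any latency assigned to it is
                # parameter-error compensation; it enters as zero.  Any
                # other arm whose latency-free refit is not significantly
                # worse (F(1, dof) at 5%: cost ratio below ~1 + 4.3/dof)
                # also contributes zero — its data carry no evidence of
                # latency.  Arms are inverse-variance weighted with SEs
                # clipped so no single arm dominates.
                dof = max(1, induced[0].n_times - 3)
                f_cut = 1.0 + 4.3 / dof
                pairs, ses = [], []
                for row in delay_rows:
                    if row["induction_time_h"] == 0 or row["zero_cost_ratio"] <= f_cut:
                        d = 0.0
                    else:
                        d = row["delay_h"]
                    pairs.append((row["activation_density_cfu_per_ml"], d))
                    ses.append(row["delay_se_h"])
                delay_fn = fit_delay_function(
                    pairs, weights=1.0 / np.clip(ses, 0.25, 1e3) ** 2
                )
                report["delay_function"] = {
                    "knots": [list(k) for k in delay_fn.knots],
                    "n_break_cfu_per_ml": delay_fn.knots[0][0],
                }
                with open(out_dir / "delay_function.json", "w") as fh:
                    json.dump(report["delay_function"], fh, indent=2)
            else:
                logger.warning("fewer than two delay fits; skipping hinge fit")

    if config.stages.get("fit_threshold", False):
        with _stage(report, "fit_threshold"):
            if params is None:
                raise ValueError("threshold scan requires the fit_growth stage")
            qs_ds = _single("qs")
            scan = fit_threshold(
                qs_ds,
                params,
                delay_fn if delay_fn is not None else DelayFunction.zero(),
                config.alpha_grid_array(),
                weight_mode=config.weight_mode,
            )
            pd.DataFrame(
                {"alpha_cfu_per_ml": scan.alpha_grid, "wssr": scan.wssr_curve}
            ).to_csv(out_dir / "threshold_scan.csv", index=False)
            report["threshold"] = {
                "alpha_star_cfu_per_ml": scan.alpha_star,
                "grid_points": len(scan.alpha_grid),
                "wssr_min": float(scan.wssr_curve.min()),
            }

    if config.stages.get("fitness", False):
        with _stage(report, "fitness"):
            reference = (
                by_role["reference"][0] if by_role.get("reference") else _single("off")
            )
            if not induced:
                raise ValueError("no induced datasets for the fitness scan")
            emp = empirical_fitness_scan(
                {ds.induction_time: ds for ds in induced}, reference
            )
            write_fitness_curve(emp, out_dir / "fitness_empirical.csv")
            report["fitness"] = {
                "empirical": {
                    "induction_times_h": emp.induction_times.tolist(),
                    "relative_fitness": emp.rf_values.tolist(),
                    "t_opt_h": emp.t_opt,
                }
            }
            if params is not None:
                model_curve = model_fitness_scan(
                    params,
                    delay_fn if delay_fn is not None else DelayFunction.zero(),
                    reference.first_density(),
                    emp.induction_times,
                    horizon=float(reference.times[-1]),
                    dt=float(np.diff(reference.times).mean()),
                )
                write_fitness_curve(model_curve, out_dir / "fitness_model.csv")
                report["fitness"]["model"] = {
                    "induction_times_h": model_curve.induction_times.tolist(),
                    "relative_fitness": model_curve.rf_values.tolist(),
                    "t_opt_h": model_curve.t_opt,
                }

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("report written to %s", out_dir / "report.json")
    return report
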