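"""Scenario grids, outcome aggregation and the regression analyses.

The study design crosses maximum female fecundity R (10 equidistant points
on [2, 10]) with the dispersal parameter sigma (10 equidistant points on
[2, 20]) for each drive system, replicating every scenario with
deterministic per-replicate seeds.  On top of the per-replicate outcome
rows this module provides the log–log wave-width scaling regression and
univariate logistic models (with ROC AUC) of penetration / escape against
wave characteristics.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .model_core import DriveSystem, ScenarioConfig
from .simulator import SimulationRecord, run_simulation

__all__ = [
    "GridSpec",
    "record_to_row",
    "run_scenario_grid",
    "summarize_outcomes",
    "fit_width_scaling",
    "fit_event_model",
    "export_results",
]

ROW_COLUMNS = [
    "scenario_id",
    "drive_system",
    "R",
    "sigma",
    "replicate",
    "seed",
    "outcome",
    "failure_mode",
    "penetration",
    "chasing",
    "drive_loss",
    "generations",
    "final_population_size",
    "wt_velocity",
    "drive_velocity",
    "wt_height",
    "drive_height",
    "wt_width",
    "drive_leading_half_width",
    "drive_trailing_half_width",
    "drive_width",
]


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """The scenario grid: systems x R values x sigma values x replicates."""

    drive_systems: tuple[DriveSystem, ...] = (
        DriveSystem.W_SHREDDER,
        DriveSystem.X_SHREDDER,
    )
    R_values: tuple[float, ...] = tuple(np.linspace(2.0, 10.0, 10))
    sigma_values: tuple[float, ...] = tuple(np.linspace(2.0, 20.0, 10))
    replicates: int = 100
    seed_base: int = 0
    base_config: ScenarioConfig = ScenarioConfig()

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(
            self, "drive_systems", tuple(DriveSystem(s) for s in self.drive_systems)
        )

    def scenarios(self) -> list[ScenarioConfig]:
        out = []
        for system in self.drive_systems:
            for R in self.R_values:
                for sigma in self.sigma_values:
                    out.append(
                        self.base_config.replace(
                            drive_system=system, R=float(R), sigma=float(sigma)
                        )
                    )
        return out

    def seed_for(self, scenario_index: int, replicate: int) -> int:
        """Deterministic seed so any grid cell is reproducible in isolation."""
        return self.seed_base + scenario_index * self.replicates + replicate

    def to_dict(self) -> dict:
        return {
            "drive_systems": [s.value for s in self.drive_systems],
            "R_values": list(self.R_values),
            "sigma_values": list(self.sigma_values),
            "replicates": self.replicates,
            "seed_base": self.seed_base,
            "base_config": self.base_config.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GridSpec":
        data = dict(data)
        data["drive_systems"] = tuple(DriveSystem(s) for s in data["drive_systems"])
        data["R_values"] = tuple(data["R_values"])
        data["sigma_values"] = tuple(data["sigma_values"])
        data["base_config"] = ScenarioConfig.from_dict(data["base_config"])
        return cls(**data)


def record_to_row(
    record: SimulationRecord, scenario_id: int, replicate: int
) -> dict:
    """Flatten one replicate's outcome and wave metrics into a table row."""
    cfg = record.config
    label = record.outcome
    m = record.wave_metrics
    return {
        "scenario_id": scenario_id,
        "drive_system": cfg.drive_system.value,
        "R": cfg.R,
        "sigma": cfg.sigma,
        "replicate": replicate,
        "seed": cfg.seed,
        "outcome": label.outcome.value if label else None,
        "failure_mode": label.failure_mode.value if label else None,
        "penetration": bool(label.penetration) if label else None,
        "chasing": bool(label.chasing) if label else None,
        "drive_loss": bool(label.drive_loss) if label else None,
        "generations": record.generations_elapsed,
        "final_population_size": record.final_population_size,
        "wt_velocity": m.wt_velocity if m else None,
        "drive_velocity": m.drive_velocity if m else None,
        "wt_height": m.wt_height if m else None,
        "drive_height": m.drive_height if m else None,
        "wt_width": m.wt_width if m else None,
        "drive_leading_half_width": m.drive_leading_half_width if m else None,
        "drive_trailing_half_width": m.drive_trailing_half_width if m else None,
        "drive_width": m.drive_width if m else None,
    }


def run_scenario_grid(
    spec: GridSpec,
    out_csv: Optional[pathlib.Path] = None,
    resume: bool = False,
) -> pd.DataFrame:
    """Run every (scenario, replicate) cell of the grid.

    Rows are appended to ``out_csv`` as they complete (crash-safe); with
    ``resume=True`` cells already present in the file are skipped.  The
    result is identical to serial execution for a given ``seed_base``
    because every cell owns an independent seed.
    """
    done: set[tuple[int, int]] = set()
    rows: list[dict] = []
    out_path = pathlib.Path(out_csv) if out_csv is not None else None
    if out_path is not None and out_path.exists():
        if resume:
            prev = pd.read_csv(out_path)
            rows = prev.to_dict("records")
            done = {(int(r["scenario_id"]), int(r["replicate"])) for r in rows}
        else:
            out_path.unlink()
    header_needed = out_path is not None and not out_path.exists()
    scenarios = spec.scenarios()
    for sid, scenario in enumerate(scenarios):
        for rep in range(spec.replicates):
            if (sid, rep) in done:
                continue
            cfg = scenario.replace(seed=spec.seed_for(sid, rep))
            row = record_to_row(run_simulation(cfg), sid, rep)
            rows.append(row)
            if out_path is not None:
                pd.DataFrame([row], columns=ROW_COLUMNS).to_csv(
                    out_path, mode="a", header=header_needed, index=False
                )
                header_needed = False
    return pd.DataFrame(rows, columns=ROW_COLUMNS)


def summarize_outcomes(result: pd.DataFrame) -> dict:
    """Overall, per-system and event-conditional outcome frequencies."""
    if result.empty:
        raise ValueError("empty result table")
    df = result
    n = len(df)
    fail = df["outcome"] == "FAILURE"
    out: dict = {
        "n_runs": n,
        "failure_proportion": float(fail.mean()),
        "drive_loss_proportion": float(df["drive_loss"].astype(bool).mean()),
        "coexistence_proportion": float((df["failure_mode"] == "COEXISTENCE").mean()),
        "drift_loss_proportion": float((df["failure_mode"] == "DRIFT_LOSS").mean()),
        "wt_escape_proportion": float((df["failure_mode"] == "WT_ESCAPE").mean()),
    }
    out["failure_by_system"] = (
        df.groupby("drive_system")["outcome"].apply(lambda s: float((s == "FAILURE").mean())).to_dict()
    )
    if fail.any():
        out["chasing_given_failure"] = float(df.loc[fail, "chasing"].astype(bool).mean())
    loss = df["drive_loss"].astype(bool)
    if loss.any():
        out["escape_fraction_of_drive_loss"] = float(
            (df.loc[loss, "failure_mode"] == "WT_ESCAPE").mean()
        )
    out["per_scenario"] = (
        df.groupby(["drive_system", "R", "sigma"], as_index=False)
        .agg(
            failure_probability=("outcome", lambda s: float((s == "FAILURE").mean())),
            replicates=("outcome", "size"),
        )
    )
    return out


def fit_width_scaling(
    widths: Sequence[float], sigmas: Sequence[float]
) -> tuple[float, float, int]:
    """OLS of ln(width) on ln(sigma): the wave-width scaling exponent.

    Non-positive or missing widths cannot enter the log regression; they
    are dropped and the count of dropped rows is returned alongside the
    slope and its standard error.
    """
    w = np.asarray(widths, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if w.shape != s.shape:
        raise ValueError("widths and sigmas must align")
    if np.any(s <= 0):
        raise ValueError("sigma values must be positive")
    keep = np.isfinite(w) & (w > 0)
    dropped = int(w.size - keep.sum())
    if keep.sum() < 3:
        raise ValueError("need at least 3 positive widths for the regression")
    X = sm.add_constant(np.log(s[keep]))
    fit = sm.OLS(np.log(w[keep]), X).fit()
    return float(fit.params[1]), float(fit.bse[1]), dropped


def fit_event_model(outcomes: Sequence[bool], predictor: Sequence[float]) -> dict:
    """Univariate logistic model of a binary event with ROC AUC.

    AUC is the probability that a random event case outranks a random
    non-case (ties count 1/2).  Perfect separation is flagged; the AUC is
    still returned (it is 1.0 in that case by construction).
    """
    y = np.asarray(outcomes, dtype=float)
    x = np.asarray(predictor, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    y, x = y[keep], x[keep]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both outcome classes must be represented")
    auc = float(roc_auc_score(y, x))
    X = sm.add_constant(x, has_constant="add")
    separated = False
    try:
        import warnings

        with warnings.catch_warnings():
            # separated data produce benign log(0)/convergence warnings in
            # the MLE; separation is detected and flagged below instead
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = fit.params
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        params, converged = (np.nan, np.nan), False
    if not converged or np.max(np.abs(np.asarray(params))) > 1e3:
        separated = True
    return {
        "intercept": float(params[0]),
        "coefficient": float(params[1]),
        "auc": auc,
        "perfect_separation": separated,
        "n": int(y.size),
    }


def export_results(
    result: pd.DataFrame, spec: GridSpec, destination: pathlib.Path
) -> dict[str, pathlib.Path]:
    """Write outcome rows, per-scenario summary, heatmap table and manifest."""
    dest = pathlib.Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths = {
        "outcomes": dest / "outcomes.csv",
        "scenario_summary": dest / "scenario_summary.csv",
        "failure_grid": dest / "failure_grid.csv",
        "manifest": dest / "manifest.json",
    }
    result.to_csv(paths["outcomes"], index=False)
    summary = summarize_outcomes(result)
    per_scenario = summary.pop("per_scenario")
    per_scenario.to_csv(paths["scenario_summary"], index=False)
    per_scenario[["drive_system", "R", "sigma", "failure_probability"]].to_csv(
        paths["failure_grid"], index=False
    )
    manifest = {"spec": spec.to_dict(), "summary": summary}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
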