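"""Ensemble benchmarking (TPR/FPR sweeps) and file-based pair analysis.

The benchmark reproduces the coupled-Rossler study design: for each
condition (series length, noise level, sparsity level) and each realization
of the coupled systems, the chosen measure is surrogate-tested in both
directions; the true positive rate is the fraction of realizations with a
significant master->slave call and the false positive rate the fraction of
significant slave->master calls.  A master seed drives a per-condition,
per-realization seed hierarchy, so identical configurations give identical
result tables and any subset of a sweep can be reproduced in isolation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from .causality import CCCParams
from .infotheory import CmiParams
from .rossler import RosslerConfig, SparsitySpec, add_noise, random_initial_state, simulate_coupled_rossler
from .surrogates import MEASURES, causality_significance

__all__ = [
    "BenchConfig",
    "BenchRun",
    "PRESETS",
    "run_benchmark",
    "run_pair_analysis",
    "read_series",
    "load_config",
]

logger = logging.getLogger("pccc.benchmark")

#: Named parameter presets (per-dataset values from the study design).
PRESETS: dict[str, dict] = {
    "rossler-ccc": {
        "measure": "ccc",
        "ccc_params": CCCParams(L=300, w=30, delta=30, B=8),
        "m": 3, "eta_x": 5, "eta_y": 5,
    },
    "rossler-pccc": {
        "measure": "pccc",
        "ccc_params": CCCParams(L=25, w=15, delta=20),
        "m": 3, "eta_x": 5, "eta_y": 5,
    },
    "rossler-cmi1": {
        "measure": "cmi1",
        "cmi_params": CmiParams(tau=20, m=3, eta=5),
        "m": 3, "eta_x": 5, "eta_y": 5,
    },
    "rossler-cmi3": {
        "measure": "cmi3",
        "cmi_params": CmiParams(tau=20, m=3, eta=5),
        "m": 3, "eta_x": 5, "eta_y": 5,
    },
    "rossler-pcmi": {
        "measure": "pcmi",
        "cmi_params": CmiParams(tau=20, m=3, eta=5),
        "m": 3, "eta_x": 5, "eta_y": 5,
    },
    "climate-pccc": {
        "measure": "pccc",
        "ccc_params": CCCParams(L=30, w=15, delta=20),
        "m": 3,
    },
}


@dataclass(frozen=True)
class BenchConfig:
    """Configuration of a TPR/FPR sweep over Rossler realizations."""

    measure: str = "pccc"
    n_realizations: int = 100
    n_surrogates: int = 100
    lengths: tuple = (2048,)
    noise_percents: tuple = (0.0,)
    sparsity_alphas: tuple = (0.0,)
    sparsity_mode: str = "sync"
    alpha: float = 0.05
    master_seed: int = 0
    surrogate_method: str = "aaft"
    ccc_params: CCCParams = field(default_factory=CCCParams)
    cmi_params: CmiParams = field(default_factory=CmiParams)
    m: int = 3
    eta_x: int = 5
    eta_y: int = 5
    rossler: RosslerConfig = field(default_factory=RosslerConfig)

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.n_surrogates < 2:
            raise ValueError("n_surrogates must be >= 2")
        if not (self.lengths and self.noise_percents is not None and self.sparsity_alphas is not None):
            raise ValueError("grids must be non-empty")


@dataclass(frozen=True)
class BenchRun:
    """Result of a sweep: per-condition summary, per-realization decisions,
    and a machine-readable manifest of everything that produced them."""

    summary: pd.DataFrame
    decisions: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.decisions.to_csv(out / "decisions.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _realization_seed(master: int, cond: int, real: int) -> list[int]:
    return [int(master), int(cond), int(real)]


def run_benchmark(config: BenchConfig) -> BenchRun:
    """Run the full sweep defined by ``config``.

    A failed condition (integration or measure error) is logged and marked
    ``failed`` in the summary rather than dropped.
    """
    conditions = [
        {"length": int(n), "noise_percent": float(nz), "sparsity_alpha": float(sa)}
        for n in config.lengths
        for nz in config.noise_percents
        for sa in config.sparsity_alphas
    ]
    summary_rows = []
    decision_rows = []
    for ci, cond in enumerate(conditions):
        logger.info("condition %d/%d: %s", ci + 1, len(conditions), cond)
        tp = fp = 0
        failed = False
        try:
            for r in range(config.n_realizations):
                seed = _realization_seed(config.master_seed, ci, r)
                rng = np.random.default_rng(seed)
                cfg = RosslerConfig(
                    **{
                        **asdict(config.rossler),
                        "n_samples": cond["length"],
                        "seed": None,
                    }
                )
                traj = simulate_coupled_rossler(cfg, initial_state=random_initial_state(rng))
                x1, x2 = traj.x1, traj.x2
                if cond["noise_percent"] > 0:
                    x1 = add_noise(x1, cond["noise_percent"], rng)
                    x2 = add_noise(x2, cond["noise_percent"], rng)
                sparsity = None
                if cond["sparsity_alpha"] > 0:
                    sparsity = SparsitySpec(
                        alpha=cond["sparsity_alpha"],
                        mode=config.sparsity_mode,
                        seed=int(rng.integers(2**31)),
                    )
                res = causality_significance(
                    x1,
                    x2,
                    config.measure,
                    n_surr=config.n_surrogates,
                    surrogate_method=config.surrogate_method,
                    sparsity=sparsity,
                    alpha=config.alpha,
                    seed=rng,
                    ccc_params=config.ccc_params,
                    cmi_params=config.cmi_params,
                    m=config.m,
                    eta_x=config.eta_x,
                    eta_y=config.eta_y,
                )
                tp += int(res.forward.significant)
                fp += int(res.reverse.significant)
                decision_rows.append(
                    {
                        **cond,
                        "realization": r,
                        "seed": json.dumps(seed),
                        "value_fwd": res.forward.original_value,
                        "value_rev": res.reverse.original_value,
                        "z_fwd": res.forward.z_score,
                        "z_rev": res.reverse.z_score,
                        "significant_fwd": res.forward.significant,
                        "significant_rev": res.reverse.significant,
                    }
                )
        except Exception:
            logger.exception("condition failed: %s", cond)
            failed = True
        n_done = config.n_realizations
        summary_rows.append(
            {
                **cond,
                "measure": config.measure,
                "tpr": tp / n_done if not failed else np.nan,
                "fpr": fp / n_done if not failed else np.nan,
                "n_realizations": n_done,
                "failed": failed,
            }
        )
    manifest = {
        "measure": config.measure,
        "n_realizations": config.n_realizations,
        "n_surrogates": config.n_surrogates,
        "alpha": config.alpha,
        "master_seed": config.master_seed,
        "surrogate_method": config.surrogate_method,
        "sparsity_mode": config.sparsity_mode,
        "conditions": conditions,
        "ccc_params": asdict(config.ccc_params),
        "cmi_params": asdict(config.cmi_params),
        "embedding": {"m": config.m, "eta_x": config.eta_x, "eta_y": config.eta_y},
        "rossler": asdict(config.rossler),
    }
    return BenchRun(
        summary=pd.DataFrame(summary_rows),
        decisions=pd.DataFrame(decision_rows),
        manifest=manifest,
    )


def read_series(path) -> np.ndarray:
    """Read a one- or two-column numeric CSV time series.

    A header row is detected and skipped; with two columns the first is
    treated as a time stamp and ignored.  Empty cells and NA tokens are
    dropped (with a warning), mirroring how sparse benchmark data are
    treated: the remainder is concatenated.
    """
    df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.iloc[0].isna().all():  # header row
        df = df.iloc[1:]
    if df.shape[1] > 2:
        raise ValueError(f"{path}: expected one or two columns, got {df.shape[1]}")
    values = df.iloc[:, -1].to_numpy(dtype=float)
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        warnings.warn(
            f"{path}: dropped {n_missing} missing values (series concatenated)",
            stacklevel=2,
        )
        values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError(f"{path}: no numeric data")
    return values


def run_pair_analysis(
    x_file,
    y_file,
    measure: str = "pccc",
    *,
    n_surr: int = 100,
    surrogate_method: str = "stationary_bootstrap",
    p_geom: float = 0.1,
    alpha: float = 0.05,
    seed: int | None = None,
    ccc_params: CCCParams | None = None,
    cmi_params: CmiParams | None = None,
    m: int = 3,
    eta_x: int = 5,
    eta_y: int = 5,
    out_file=None,
) -> dict:
    """Surrogate-tested causality between two CSV time series.

    Uses the real-data protocol by default (stationary bootstrap with
    p=0.1).  The two series must be pre-aligned to a common sampling; only
    their usable common length is analyzed.  Returns (and optionally writes
    as JSON) a report with values, z-scores and decisions per direction.
    """
    x = read_series(x_file)
    y = read_series(y_file)
    n = min(x.size, y.size)
    if x.size != y.size:
        warnings.warn(
            f"length mismatch ({x.size} vs {y.size}); truncating both to {n}",
            stacklevel=2,
        )
    res = causality_significance(
        x[:n],
        y[:n],
        measure,
        n_surr=n_surr,
        surrogate_method=surrogate_method,
        p_geom=p_geom,
        alpha=alpha,
        seed=seed,
        ccc_params=ccc_params,
        cmi_params=cmi_params,
        m=m,
        eta_x=eta_x,
        eta_y=eta_y,
    )
    report = {
        "x_file": str(x_file),
        "y_file": str(y_file),
        "measure": measure,
        "n_used": int(n),
        "n_surrogates": n_surr,
        "surrogate_method": surrogate_method,
        "alpha": alpha,
        "seed": seed,
        "x_to_y": {
            "value": res.forward.original_value,
            "z_score": res.forward.z_score,
            "significant": bool(res.forward.significant),
        },
        "y_to_x": {
            "value": res.reverse.original_value,
            "z_score": res.reverse.z_score,
            "significant": bool(res.reverse.significant),
        },
    }
    if out_file is not None:
        Path(out_file).write_text(json.dumps(report, indent=2))
    return report


def load_config(path) -> BenchConfig:
    """Load a BenchConfig from a YAML or JSON file.

    A top-level ``preset`` key merges the named preset's measure parameters
    before the file's own fields are applied.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of BenchConfig fields")
    preset = raw.pop("preset", None)
    merged: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        merged.update(PRESETS[preset])
    merged.update(raw)
    for key, cls in (("ccc_params", CCCParams), ("cmi_params", CmiParams), ("rossler", RosslerConfig)):
        if key in merged and isinstance(merged[key], dict):
            merged[key] = cls(**merged[key])
    for key in ("lengths", "noise_percents", "sparsity_alphas"):
        if key in merged:
            merged[key] = tuple(merged[key])
    return BenchConfig(**merged)
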