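"""Factorial experiments: replicate runs, controls, aggregation, tables.

A sweep produces a long-format table with one row per completed run
(factors, replicate, seed, outcome).  Aggregations reproduce the summary
views of the model's results: evolved play-gene frequency versus
mortality cost averaged over reproductive delays, and frequency versus
delay by mortality cost.  Extinct runs and runs with undefined
frequencies are excluded from means but counted and reported, with one
documented exception baked into :func:`aggregate_over_delays`: at
parental investment P = 0.1 populations often go extinct for delays
above 45, so delay-averages at P = 0.1 use d in [0, 45] only.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .engine import run_simulation
from .params import ModelParams, SweepSpec, derive_seed, enumerate_sweep

__all__ = [
    "RESULT_COLUMNS",
    "run_replicates",
    "run_control",
    "run_sweep",
    "aggregate_over_delays",
    "aggregate_by_delay",
    "figure_tables",
]

RESULT_COLUMNS = [
    "R", "p", "c", "d", "P", "control", "config_index", "replicate", "seed",
    "gene_birth_frequency", "births_in_window", "play_mortality_percent",
    "extinct", "extinction_step",
]


def _row(params: ModelParams, config_index: int, replicate: int,
         seed: int, result) -> dict:
    return {
        "R": params.R,
        "p": params.p,
        "c": params.c,
        "d": params.d,
        "P": params.P,
        "control": not params.learn_fairness,
        "config_index": config_index,
        "replicate": replicate,
        "seed": seed,
        "gene_birth_frequency": (result.gene_birth_frequency
                                 if result.frequency_defined else np.nan),
        "births_in_window": result.births_in_window,
        "play_mortality_percent": result.play_mortality_percent,
        "extinct": result.extinct,
        "extinction_step": result.extinction_step,
    }


def run_replicates(params: ModelParams, n_reps: int,
                   base_seed: int, config_index: int = 0) -> pd.DataFrame:
    """Run ``n_reps`` independent replicates of one condition.

    Seeds come from :func:`derive_seed`, so the rows are reproducible and
    independent of how many other conditions a surrounding sweep holds.
    Extinct runs are recorded (flagged), never dropped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for k in range(n_reps):
        seed = derive_seed(base_seed, config_index, k)
        rows.append(_row(params, config_index, k, seed,
                         run_simulation(params, seed)))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_control(params: ModelParams, n_reps: int,
                base_seed: int, config_index: int = 0) -> pd.DataFrame:
    """Replicates of the control condition: juveniles play (and still pay
    the mortality cost c) but adults never acquire fairness."""
    return run_replicates(params.replace(learn_fairness=False),
                          n_reps, base_seed, config_index)


def run_sweep(spec: SweepSpec, out_csv: str | os.PathLike | None = None,
              resume: bool = False,
              progress: Callable[[int, int], None] | None = None) -> pd.DataFrame:
    """Run a full factorial sweep; optionally checkpoint row-by-row.

    With ``out_csv`` each completed run is appended immediately, and with
    ``resume=True`` runs whose (config_index, replicate) already appear in
    the file are skipped, so an interrupted sweep continues without
    duplicating rows.
    """
    done: set[tuple[int, int]] = set()
    existing: pd.DataFrame | None = None
    path = Path(out_csv) if out_csv is not None else None
    if path is not None and resume and path.exists():
        existing = pd.read_csv(path)
        done = set(zip(existing["config_index"].astype(int),
                       existing["replicate"].astype(int)))
    rows = []
    total = spec.n_runs
    n_done = 0
    for params, idx, k, seed in enumerate_sweep(spec):
        n_done += 1
        if (idx, k) in done:
            continue
        row = _row(params, idx, k, seed, run_simulation(params, seed))
        rows.append(row)
        if path is not None:
            header = not path.exists()
            pd.DataFrame([row], columns=RESULT_COLUMNS).to_csv(
                path, mode="a", header=header, index=False)
        if progress is not None:
            progress(n_done, total)
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if existing is not None and len(existing):
        table = pd.concat([existing, table], ignore_index=True)
    return table


def _mean_se(series: pd.Series) -> tuple[float, float, int, int]:
    """Mean, standard error, n used, n excluded (nan) for one cell."""
    vals = series.to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    n = int(ok.sum())
    excl = int(vals.size - n)
    if n == 0:
        return np.nan, np.nan, 0, excl
    mean = float(vals[ok].mean())
    se = float(vals[ok].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return mean, se, n, excl


def aggregate_over_delays(table: pd.DataFrame, P_value: float) -> pd.DataFrame:
    """Mean evolved frequency per (R, p, c) cell, averaged over delays.

    Averages gene_birth_frequency over replicates and over the delay grid
    d in [0, 50] — restricted to d in [0, 45] when P = 0.1, where longer
    delays routinely drive the population extinct.  Extinct/undefined
    runs are excluded from the mean; the exclusion count is reported per
    cell (``n_excluded``).
    """
    if table.empty:
        raise ValueError("empty result table")
    d_max = 45 if np.isclose(P_value, 0.1) else 50
    sub = table[np.isclose(table["P"], P_value) & (table["d"] <= d_max)]
    if sub.empty:
        raise ValueError(f"no rows for P={P_value}")
    out = []
    for (R, p, c), cell in sub.groupby(["R", "p", "c"]):
        mean, se, n, excl = _mean_se(cell["gene_birth_frequency"])
        out.append({"R": R, "p": p, "c": c, "P": P_value,
                    "mean_frequency": mean, "se_frequency": se,
                    "n_runs": n, "n_excluded": excl})
    return pd.DataFrame(out)


def aggregate_by_delay(table: pd.DataFrame) -> pd.DataFrame:
    """Mean evolved frequency per (R, p, P, c, d) cell over replicates."""
    if table.empty:
        raise ValueError("empty result table")
    out = []
    for (R, p, P, c, d), cell in table.groupby(["R", "p", "P", "c", "d"]):
        mean, se, n, excl = _mean_se(cell["gene_birth_frequency"])
        out.append({"R": R, "p": p, "P": P, "c": c, "d": d,
                    "mean_frequency": mean, "se_frequency": se,
                    "n_runs": n, "n_excluded": excl})
    return pd.DataFrame(out)


def figure_tables(table: pd.DataFrame,
                  out_dir: str | os.PathLike | None = None) -> dict[str, pd.DataFrame]:
    """Tidy summary tables behind the standard result views.

    * ``frequency_vs_cost`` — mean frequency vs mortality cost c for each
      parental investment P, averaged over delays and payoff conditions
      (delay window restricted at P = 0.1).
    * ``frequency_vs_delay`` — mean frequency vs delay d for each
      (R, p, P, c) cell.

    Control rows, if present, appear in both tables flagged by the
    ``control`` column.  With ``out_dir`` each table is also written as
    CSV.  Raises on an empty input rather than writing empty files.
    """
    if table.empty:
        raise ValueError("empty result table")
    vs_cost = []
    for (P_value, control), sub in table.groupby(["P", "control"]):
        d_max = 45 if np.isclose(P_value, 0.1) else 50
        sub = sub[sub["d"] <= d_max]
        for c, cell in sub.groupby("c"):
            mean, se, n, excl = _mean_se(cell["gene_birth_frequency"])
            vs_cost.append({"P": P_value, "control": control, "c": c,
                            "mean_frequency": mean, "se_frequency": se,
                            "n_runs": n, "n_excluded": excl})
    vs_delay = []
    for (R, p, P, c, d, control), cell in table.groupby(
            ["R", "p", "P", "c", "d", "control"]):
        mean, se, n, excl = _mean_se(cell["gene_birth_frequency"])
        vs_delay.append({"R": R, "p": p, "P": P, "c": c, "d": d,
                         "control": control,
                         "mean_frequency": mean, "se_frequency": se,
                         "n_runs": n, "n_excluded": excl})
    tables = {
        "frequency_vs_cost": pd.DataFrame(vs_cost),
        "frequency_vs_delay": pd.DataFrame(vs_delay),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return tables
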