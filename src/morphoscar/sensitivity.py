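"""Parameter sweep and z-score sensitivity measure.

Each of 31 parameters (30 kinetic/mechanical/equilibrium constants plus the
wound half-length) is varied one at a time by 0, +/-5, +/-10, +/-15, +/-20,
+/-25 percent around the mean set — 341 simulations — and each run is
reduced to the five scalar summaries.  For a fixed output r and variation
level j, z-scores are taken across the parameters,

    z_ij = (x_ij - mean_i(x_ij)) / sd_i(x_ij)    (sample sd, n-1),

and the sensitivity of parameter i for output r is S_i^r = sum_j |z_ij|.
The zero-variation column has zero spread; its z-scores are defined as 0,
the only finite value consistent with including every level in the sum.
The total score is the sum of the five per-output scores, rounded to the
nearest integer.

Derived parameters (q, k_rho) are recomputed from the perturbed inputs.
When the equilibrium collagen concentration is varied, the initial wound
collagen stays fixed at 20% of the mean 0.1125 (it is an independent
parameter of the sweep).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fem import NumericsConfig, simulate
from .observables import summarize_trajectory
from .params import ParameterSet

logger = logging.getLogger(__name__)

__all__ = ["SWEEP_PARAMETERS", "VARIATIONS_PCT", "SweepSpec", "run_sweep",
           "zscore_columns", "sensitivity_scores", "OUTPUTS"]

SWEEP_PARAMETERS = (
    "N_bar", "rho_bar", "c_tilde", "N_tilde", "rho_tilde",
    "delta_c", "delta_N", "delta_M", "delta_rho",
    "a_c_I", "a_c_II", "a_c_III", "a_c_IV",
    "eta_I", "eta_II", "D_c", "D_F", "chi_F",
    "k_c", "k_F", "r_F", "r_F_max", "k_rho_max", "kappa_F",
    "xi", "R", "mu", "E", "zeta", "rho_t", "L_w",
)

VARIATIONS_PCT = (-25, -20, -15, -10, -5, 0, 5, 10, 15, 20, 25)

OUTPUTS = ("RSA_min", "RSA_day", "RSA_365", "SED_max", "SED_day")


@dataclass
class SweepSpec:
    """What to vary, around which base set, at which resolution."""

    base: ParameterSet = dc_field(default_factory=ParameterSet)
    parameters: Sequence[str] = SWEEP_PARAMETERS
    variations_pct: Sequence[float] = VARIATIONS_PCT
    numerics: NumericsConfig = dc_field(default_factory=NumericsConfig)

    @property
    def n_runs(self) -> int:
        return len(self.parameters) * len(self.variations_pct)


def perturbed_set(base: ParameterSet, name: str, pct: float) -> ParameterSet:
    """Base set with one parameter scaled by (1 + pct/100).

    q and k_rho follow automatically (derived properties); rho_tilde is an
    independent parameter and therefore stays put when rho_bar is varied.
    """
    if name not in SWEEP_PARAMETERS:
        raise KeyError(f"unknown sweep parameter: {name}")
    value = getattr(base, name) * (1.0 + pct / 100.0)
    return base.replace(**{name: value})


def _param_hash(p: ParameterSet, cfg: NumericsConfig) -> str:
    payload = json.dumps({"p": p.to_dict(), "cfg": vars(cfg)},
                         sort_keys=True, default=float)
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def _one_run(base: ParameterSet, name: str, pct: float,
             numerics: NumericsConfig, cache_dir: Optional[Path]) -> dict:
    p = perturbed_set(base, name, pct)
    row = {"parameter": name, "variation_pct": pct}
    key = _param_hash(p, numerics)
    cache_file = cache_dir / f"{key}.json" if cache_dir else None
    if cache_file is not None and cache_file.exists():
        row.update(json.loads(cache_file.read_text()))
        return row
    try:
        traj = simulate(p, numerics)
        summ = summarize_trajectory(traj).to_dict()
        summ["error"] = ""
    except Exception as exc:   # recorded per-cell, not fatal
        logger.warning("sweep run (%s, %+g%%) failed: %s", name, pct, exc)
        summ = {k: np.nan for k in OUTPUTS}
        summ["error"] = str(exc)
    if cache_file is not None:
        tmp = cache_file.with_suffix(".tmp")
        tmp.write_text(json.dumps(summ))
        tmp.replace(cache_file)
    row.update(summ)
    return row


def run_sweep(spec: SweepSpec, n_jobs: int = 1,
              cache_dir: str | Path | None = None) -> pd.DataFrame:
    """Run the one-at-a-time sweep; one row per (parameter, variation).

    Individual simulation failures are recorded in the ``error`` column
    with NaN summaries.  With ``cache_dir`` set, finished runs are cached
    by a hash of their parameter set so interrupted sweeps resume.
    """
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
    tasks = [(name, pct) for name in spec.parameters
             for pct in spec.variations_pct]
    if n_jobs != 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_one_run)(spec.base, name, pct, spec.numerics, cache_dir)
            for name, pct in tasks)
    else:
        rows = [_one_run(spec.base, name, pct, spec.numerics, cache_dir)
                for name, pct in tasks]
    return pd.DataFrame(rows)


def zscore_columns(results: pd.DataFrame, output: str,
                   variation_pct: float) -> pd.Series:
    """z-scores across parameters for one output at one variation level.

    Zero spread (e.g. the 0% column, where every run is the base run) maps
    to z = 0 for every parameter.
    """
    sub = results[results["variation_pct"] == variation_pct]
    x = sub.set_index("parameter")[output].astype(float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        return pd.Series(0.0, index=x.index)
    return (x - x.mean()) / sd


def sensitivity_scores(results: pd.DataFrame,
                       levels: str = "all") -> pd.DataFrame:
    """Per-parameter sensitivity table S_i^r = sum_j |z_ij^r|.

    ``levels="all"`` sums over every variation level (the default);
    ``levels="extremes"`` restricts the sum to the +/-25% columns, the
    alternative reading of the sensitivity measure.  ``S_total`` is the
    rounded sum of the five per-output scores.
    """
    if levels == "all":
        var_levels = sorted(results["variation_pct"].unique())
    elif levels == "extremes":
        var_levels = [results["variation_pct"].min(),
                      results["variation_pct"].max()]
    else:
        raise ValueError("levels must be 'all' or 'extremes'")
    params = list(dict.fromkeys(results["parameter"]))
    table = pd.DataFrame(index=pd.Index(params, name="parameter"))
    for out in OUTPUTS:
        score = pd.Series(0.0, index=table.index)
        for j in var_levels:
            score = score + zscore_columns(results, out, j).abs()
        table[f"S_{out}"] = score
    table["S_total"] = (
        table[[f"S_{o}" for o in OUTPUTS]].sum(axis=1).round().astype(int))
    return table
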