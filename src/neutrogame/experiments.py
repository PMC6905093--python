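"""Reproducible computational experiments over the neutrophil game.

Each experiment is a pure function returning a pandas DataFrame (plus a
metadata dict where seeds and constants matter); file output and logging
live in the CLI layer.  Covered are the standard campaigns: two-parameter
equilibrium sweeps with invalid-region masking, sampling of the
data-consistent parameter cloud with round-trip verification, cumulative
necrosis trajectories averaged over random tuples, and the cellular
automaton versus power-law dose-response comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .game_core import PayoffParameters
from .meanfield import MeanFieldConfig, equilibrium_p
from .parameter_space import (
    DEFAULT_CONSTANTS,
    DataFitConstants,
    fit_constants_of,
    powerlaw_prediction,
    sample_parameter_space,
)
from .cellular_automaton import ITMScheme, run, sweep_ca, CAConfig

__all__ = [
    "SweepSpec",
    "payoff_grid_sweep",
    "parameter_cloud_experiment",
    "trajectory_experiment",
    "ca_vs_powerlaw_experiment",
]

_MODEL_PARAMS = ("alpha", "b_apoptosis", "c_necrosis", "m", "n")


@dataclass(frozen=True)
class SweepSpec:
    """Two varied model parameters on a grid, the rest held fixed.

    varied       two (name, low, high, num_points) entries; names from
                 {alpha, b_apoptosis, c_necrosis, m, n}
    fixed        values for the remaining three parameters
    itms_levels  initial ITM concentrations to evaluate at
    """

    varied: tuple[tuple[str, float, float, int], tuple[str, float, float, int]]
    fixed: dict[str, float]
    itms_levels: tuple[float, ...] = (0.0,)
    n_total: int = 2500
    k: float = 0.0929

    def __post_init__(self) -> None:
        names = [v[0] for v in self.varied]
        if len(set(names)) != 2:
            raise InvalidParameterError("varied parameters must be two distinct names")
        for name, lo, hi, num in self.varied:
            if name not in _MODEL_PARAMS:
                raise InvalidParameterError(f"unknown parameter {name!r}")
            if num < 1 or hi < lo:
                raise InvalidParameterError(f"empty range for {name!r}")
        missing = set(_MODEL_PARAMS) - set(names) - set(self.fixed)
        if missing:
            raise InvalidParameterError(f"fixed values missing for {sorted(missing)}")


def payoff_grid_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Closed-form equilibrium on the grid, one row per point and ITM level.

    Invalid solutions (outside [0, 1], constraint or log-domain failures)
    are kept with their reason code — sweeps mask them, never clip.
    """
    (name1, lo1, hi1, num1), (name2, lo2, hi2, num2) = spec.varied
    axis1 = np.linspace(lo1, hi1, num1)
    axis2 = np.linspace(lo2, hi2, num2)
    rows = []
    for itms in spec.itms_levels:
        for v1 in axis1:
            for v2 in axis2:
                values = dict(spec.fixed)
                values[name1] = float(v1)
                values[name2] = float(v2)
                params = PayoffParameters(values["b_apoptosis"], values["c_necrosis"])
                cfg = MeanFieldConfig(
                    alpha=values["alpha"],
                    m=values["m"],
                    n=values["n"],
                    n_total=spec.n_total,
                    k=spec.k,
                    itms_initial=float(itms),
                )
                res = equilibrium_p(params, cfg)
                rows.append(
                    {
                        "itms_initial": float(itms),
                        name1: float(v1),
                        name2: float(v2),
                        "p": res.p,
                        "valid": res.valid,
                        "reason": res.reason.value,
                    }
                )
    return pd.DataFrame(rows)


def parameter_cloud_experiment(
    count: int,
    seed: int,
    constants: DataFitConstants = DEFAULT_CONSTANTS,
    alpha_bounds: tuple[float, float] = (0.0, 3.0),
    m_bounds: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Sample the data-consistent cloud and verify the (gamma, beta) round trip.

    Returns the table (columns alpha, b_apoptosis, c_necrosis, m, n,
    gamma_check, beta_check, roundtrip_ok) and a metadata dict recording
    seed, bounds and constants.
    """
    tuples = sample_parameter_space(
        count, seed, constants=constants, alpha_bounds=alpha_bounds, m_bounds=m_bounds
    )
    rows = []
    for t in tuples:
        gamma, beta = fit_constants_of(t, constants.n_total)
        rows.append(
            {
                "alpha": t.alpha,
                "b_apoptosis": t.b_apoptosis,
                "c_necrosis": t.c_necrosis,
                "m": t.m,
                "n": t.n,
                "gamma_check": gamma,
                "beta_check": beta,
                "roundtrip_ok": bool(
                    math.isclose(gamma, constants.gamma, abs_tol=1e-9)
                    and math.isclose(beta, constants.beta, abs_tol=1e-9)
                ),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "alpha",
            "b_apoptosis",
            "c_necrosis",
            "m",
            "n",
            "gamma_check",
            "beta_check",
            "roundtrip_ok",
        ],
    )
    metadata = {
        "seed": seed,
        "count": count,
        "alpha_bounds": list(alpha_bounds),
        "m_bounds": list(m_bounds) if m_bounds is not None else None,
        "constants": {
            "k": constants.k,
            "beta": constants.beta,
            "gamma": constants.gamma,
            "n_total": constants.n_total,
            "fatal_dose": constants.fatal_dose,
        },
    }
    return table, metadata


def trajectory_experiment(
    itms_levels: Iterable[float],
    seed: int,
    n_tuples: int = 20,
    scheme: ITMScheme = ITMScheme.GLOBAL,
    side: int = 50,
    constants: DataFitConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Per-step mean and std of cumulative necrotic counts over random tuples.

    One automaton run per sampled tuple and ITM level; run seeds derive from
    ``seed`` and the tuple index.  Long-format columns: itms_initial, step
    (1-based decision index), mean_cumulative_necrotic, std_cumulative_necrotic.
    """
    tuples = sample_parameter_space(n_tuples, seed, constants=constants)
    rows = []
    for itms in itms_levels:
        trajectories = []
        for ti, tup in enumerate(tuples):
            cfg = CAConfig(
                parameters=tup,
                itms_initial=float(itms),
                scheme=scheme,
                constants=constants,
                side=side,
                seed=seed * 100003 + ti,
            )
            trajectories.append(run(cfg).cumulative_necrotic_per_step)
        arr = np.asarray(trajectories)
        mean = arr.mean(axis=0)
        std = arr.std(axis=0)
        for t in range(arr.shape[1]):
            rows.append(
                {
                    "itms_initial": float(itms),
                    "step": t + 1,
                    "mean_cumulative_necrotic": float(mean[t]),
                    "std_cumulative_necrotic": float(std[t]),
                }
            )
    return pd.DataFrame(rows)


def ca_vs_powerlaw_experiment(
    itms_grid: Sequence[float],
    seed: int,
    n_tuples: int = 20,
    n_seeds: int = 3,
    side: int = 50,
    constants: DataFitConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Dose-response comparison: both CA schemes against the clipped power law.

    Per dose: mean and std of percent necrosis for the Global and Local
    schemes over ``n_tuples`` sampled tuples x ``n_seeds`` replicate seeds,
    alongside the clipped data-fit prediction (as a percentage).
    """
    tuples = sample_parameter_space(n_tuples, seed, constants=constants)
    seeds = [seed + s for s in range(n_seeds)]
    frames = {}
    for scheme in (ITMScheme.GLOBAL, ITMScheme.LOCAL):
        frames[scheme] = sweep_ca(
            tuples, itms_grid, seeds, scheme=scheme, constants=constants, side=side
        )
    out = pd.DataFrame({"itms_initial": [float(v) for v in itms_grid]})
    out["powerlaw_percent"] = [
        100.0 * powerlaw_prediction(v, constants, clip=True) for v in out["itms_initial"]
    ]
    for scheme, label in ((ITMScheme.GLOBAL, "global"), (ITMScheme.LOCAL, "local")):
        f = frames[scheme]
        out[f"{label}_mean_percent"] = f["mean_percent_necrosis"].to_numpy()
        out[f"{label}_std_percent"] = f["std_percent_necrosis"].to_numpy()
    out["n_runs"] = frames[ITMScheme.GLOBAL]["n_runs"].to_numpy()
    return out
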