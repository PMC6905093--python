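"""Data-fit power law and the inverse map from fit constants to model parameters.

In-vitro dose–response measurements of neutrophil death (necrotic fraction
at 24 h against the LPS dose, a.k.a. the initial ITM concentration) follow

    p - gamma = beta * ITMs_initial^k

with fitted constants k = 0.0929, beta = e^-0.6, gamma = 0.17 (the baseline
necrotic fraction observed with no insult) for a population of N_T = 2500
neutrophils; 500 ng/ml LPS is the fatal reference dose, identified with
100% necrosis.  Matching this power law against the closed-form mean-field
equilibrium identifies the model parameters:

    gamma = -( ln((b+c) / (alpha (m-n))) + alpha n N_T ) / ( alpha N_T (m-n) )
    beta  = 1 / ( N_T (m - n) )        =>   n = m - 1 / (N_T beta)

Given (alpha, m) the remaining constants pin down n and the payoff sum
b + c; only the split of b + c between benefit and cost stays free.  Every
tuple sampled this way therefore produces the *identical* equilibrium curve
p(ITMs) = gamma + beta * ITMs^k — the data constrain a manifold, not a point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError
from .game_core import PayoffParameters
from .meanfield import MeanFieldConfig

__all__ = [
    "DataFitConstants",
    "ParameterTuple",
    "DEFAULT_CONSTANTS",
    "powerlaw_prediction",
    "n_from_m",
    "fit_constants_of",
    "bc_sum_from_constraints",
    "sample_parameter_space",
    "fit_loglog",
]

_UNDERFLOW_EXPONENT = -700.0


@dataclass(frozen=True)
class DataFitConstants:
    """Published power-law fit constants bridging model and measurements.

    k           power-law exponent (dimensionless)
    beta        power-law coefficient, e^-0.6 ~= 0.548812
    gamma       baseline necrotic fraction at zero dose
    n_total     neutrophil population size N_T
    fatal_dose  LPS-equivalent dose identified with 100% necrosis (ng/ml)
    """

    k: float = 0.0929
    beta: float = math.exp(-0.6)
    gamma: float = 0.17
    n_total: int = 2500
    fatal_dose: float = 500.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise InvalidParameterError(f"beta must be > 0, got {self.beta}")
        if self.k <= 0:
            raise InvalidParameterError(f"k must be > 0, got {self.k}")
        if not 0.0 <= self.gamma < 1.0:
            raise InvalidParameterError(f"gamma must be in [0, 1), got {self.gamma}")

    @property
    def m_lower_bound(self) -> float:
        """Smallest m giving n >= 0, i.e. 1 / (N_T beta)."""
        return 1.0 / (self.n_total * self.beta)


DEFAULT_CONSTANTS = DataFitConstants()


@dataclass(frozen=True)
class ParameterTuple:
    """One point (alpha, b_apoptosis, c_necrosis, m, n) of model-parameter space.

    Tuples emitted by :func:`sample_parameter_space` satisfy the data-fit
    constraints (m > n >= 0 and the (gamma, beta) round trip); directly
    constructed tuples are only checked for finiteness and payoff signs so
    that sweeps over degenerate regions (e.g. an m = n line) stay possible.
    """

    alpha: float
    b_apoptosis: float
    c_necrosis: float
    m: float
    n: float

    def __post_init__(self) -> None:
        for name in ("alpha", "b_apoptosis", "c_necrosis", "m", "n"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")
        if self.b_apoptosis < 0 or self.c_necrosis < 0:
            raise InvalidParameterError("b_apoptosis and c_necrosis must be >= 0")

    @property
    def payoff_params(self) -> PayoffParameters:
        return PayoffParameters(self.b_apoptosis, self.c_necrosis)

    @property
    def bc_sum(self) -> float:
        return self.b_apoptosis + self.c_necrosis

    def meanfield_config(
        self,
        constants: DataFitConstants = DEFAULT_CONSTANTS,
        itms_initial: float = 0.0,
    ) -> MeanFieldConfig:
        """Mean-field configuration for this tuple at a given initial dose."""
        return MeanFieldConfig(
            alpha=self.alpha,
            m=self.m,
            n=self.n,
            n_total=constants.n_total,
            k=constants.k,
            itms_initial=itms_initial,
        )


def powerlaw_prediction(
    itms_initial: float,
    constants: DataFitConstants = DEFAULT_CONSTANTS,
    clip: bool = False,
) -> float:
    """Necrotic fraction gamma + beta * ITMs^k predicted by the data fit.

    With ``clip`` the prediction is bounded to [0, 1]; the raw value exceeds
    1 above roughly ((1 - gamma)/beta)^(1/k), in particular at the fatal dose.
    """
    if itms_initial < 0:
        raise InvalidParameterError("itms_initial must be >= 0")
    p = constants.gamma + constants.beta * itms_initial ** constants.k
    if clip:
        p = min(1.0, max(0.0, p))
    return p


def n_from_m(m: float, constants: DataFitConstants = DEFAULT_CONSTANTS) -> float:
    """Apoptotic neutralization rate n = m - 1/(N_T beta) implied by the fit.

    Raises when the result would be negative: n counts ITMs neutralized.
    """
    n = m - constants.m_lower_bound
    if n < 0:
        raise InvalidParameterError(
            f"m = {m} gives n = {n} < 0; need m >= 1/(n_total*beta) "
            f"= {constants.m_lower_bound:.6g}"
        )
    return n


def fit_constants_of(tuple_: ParameterTuple, n_total: int) -> tuple[float, float]:
    """(gamma, beta) implied by a parameter tuple — the forward map.

    Raises on a log-domain violation ((b+c)/(alpha(m-n)) <= 0) or a
    degenerate tuple (m = n or alpha = 0).
    """
    bc = tuple_.bc_sum
    dm = tuple_.m - tuple_.n
    if dm == 0.0 or tuple_.alpha == 0.0 or bc == 0.0:
        raise InvalidParameterError(
            "fit constants undefined: need b+c != 0, m != n and alpha != 0"
        )
    ratio = bc / (tuple_.alpha * dm)
    if ratio <= 0.0:
        raise InvalidParameterError(f"log-domain violation: (b+c)/(alpha(m-n)) = {ratio}")
    gamma = -(math.log(ratio) + tuple_.alpha * tuple_.n * n_total) / (
        tuple_.alpha * n_total * dm
    )
    beta = 1.0 / (n_total * dm)
    return gamma, beta


def bc_sum_from_constraints(
    alpha: float, m: float, constants: DataFitConstants = DEFAULT_CONSTANTS
) -> float:
    """Payoff sum b + c that makes (alpha, m) consistent with the fit constants.

    Closed inversion of the gamma identity with n = n_from_m(m):

        b + c = alpha (m - n) exp( -gamma alpha N_T (m - n) - alpha n N_T )

    Raises when alpha <= 0, n would be negative, or the exponent underflows
    past representability (no positive float b+c exists).
    """
    if alpha <= 0:
        raise InvalidParameterError(f"alpha must be > 0, got {alpha}")
    n = n_from_m(m, constants)
    dm = m - n
    exponent = (
        -constants.gamma * alpha * constants.n_total * dm
        - alpha * n * constants.n_total
    )
    if exponent < _UNDERFLOW_EXPONENT:
        raise InvalidParameterError(
            f"b+c underflows (exponent {exponent:.1f} < {_UNDERFLOW_EXPONENT}); "
            "no representable payoff sum for these (alpha, m)"
        )
    return alpha * dm * math.exp(exponent)


def sample_parameter_space(
    count: int,
    seed: int,
    constants: DataFitConstants = DEFAULT_CONSTANTS,
    alpha_bounds: tuple[float, float] = (0.0, 3.0),
    m_bounds: tuple[float, float] | None = None,
) -> list[ParameterTuple]:
    """Sample ``count`` tuples from the data-consistent parameter manifold.

    alpha and m are drawn uniformly from their (half-open at the lower end)
    bounds, n and b+c follow from the constraints, and b+c is split between
    benefit and cost by a uniform ratio — the split is invisible to the
    equilibrium, which depends on the payoffs only through the sum.
    Deterministic for a given seed.
    """
    if count < 0:
        raise InvalidParameterError("count must be >= 0")
    if m_bounds is None:
        m_bounds = (constants.m_lower_bound, 0.01)
    a_lo, a_hi = alpha_bounds
    m_lo, m_hi = m_bounds
    if not (0.0 <= a_lo < a_hi):
        raise InvalidParameterError(
            f"alpha bounds violated: need 0 <= lo < hi, got {alpha_bounds}"
        )
    if m_lo < constants.m_lower_bound:
        raise InvalidParameterError(
            f"m bounds violated: lower bound {m_lo} < 1/(n_total*beta) "
            f"= {constants.m_lower_bound:.6g} would give n < 0"
        )
    if not m_lo < m_hi:
        raise InvalidParameterError(f"m bounds violated: need lo < hi, got {m_bounds}")

    rng = np.random.default_rng(seed)
    tuples: list[ParameterTuple] = []
    while len(tuples) < count:
        alpha = float(rng.uniform(a_lo, a_hi))
        if alpha == 0.0:  # measure-zero, but alpha must be strictly positive
            continue
        m = float(rng.uniform(m_lo, m_hi))
        bc = bc_sum_from_constraints(alpha, m, constants)
        split = float(rng.uniform(0.0, 1.0))
        tuples.append(
            ParameterTuple(
                alpha=alpha,
                b_apoptosis=split * bc,
                c_necrosis=(1.0 - split) * bc,
                m=m,
                n=n_from_m(m, constants),
            )
        )
    return tuples


def fit_loglog(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Ordinary least squares of ln(p - gamma) on ln(ITMs).

    ``points`` are (itms, p_minus_gamma) pairs with strictly positive
    coordinates.  On noiseless power-law input the recovery is exact to
    numerical precision.  Returns (slope, intercept).
    """
    pts = list(points)
    if len(pts) < 2:
        raise InvalidParameterError("need at least 2 points for a log-log fit")
    x = np.asarray([p[0] for p in pts], dtype=float)
    y = np.asarray([p[1] for p in pts], dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise InvalidParameterError("log-log fit requires strictly positive coordinates")
    slope, intercept = np.polyfit(np.log(x), np.log(y), deg=1)
    return float(slope), float(intercept)
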