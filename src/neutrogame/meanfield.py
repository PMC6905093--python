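"""Mean-field game: average fitness, stationarity, and the closed-form equilibrium.

Every neutrophil plays against the population average.  A focal cell goes
necrotic with probability q in a population whose necrotic fraction is p.
Its average fitness is the bilinear payoff mixture minus an exponential
penalty for the inflammation-triggering moieties (ITMs) still unresolved:

    F(q, p) = qpA + q(1-p)B + (1-q)pC + (1-q)(1-p)D - exp(alpha * R(q, p))

where the remaining-ITM ledger is

    R(q, p) = ITMs_initial^k - p m (N_T - 1) - q m - (1-p) n (N_T - 1) - (1-q) n

with m (n) the amount of ITMs a necrotic (apoptotic) neutrophil eventually
neutralizes, N_T the total neutrophil count, and k the empirical power-law
exponent linking dose to response.  R may go negative; the exponential keeps
the cost itself positive.  Setting dF/dq = 0 at the self-consistent point
q* = p yields the closed-form mixed-equilibrium necrotic fraction

    p = q* = -( ln((b+c) / (alpha (m-n))) + alpha n N_T - alpha ITMs_initial^k )
             / ( alpha N_T (m - n) )

valid only when b+c != 0, m != n, alpha != 0, the log argument is positive,
and p lands in [0, 1].  Violations are reported in the result, never raised
and never clipped: downstream sweeps mask invalid regions instead.

Without the exponential cost term the q-derivative is the constant -(b+c),
so no interior (mixed) equilibrium exists and apoptosis dominates — the
cost of unresolved inflammation is what sustains a necrotic subpopulation.

All logarithms are natural: the fitted coefficient beta = e^-0.6 fixes base e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

from .errors import InvalidParameterError
from .game_core import PayoffParameters, build_payoff_matrix

__all__ = [
    "OVERFLOW_EXPONENT",
    "MeanFieldConfig",
    "EquilibriumReason",
    "EquilibriumResult",
    "itms_remaining",
    "average_fitness",
    "fitness_gradient",
    "equilibrium_p",
]

# exp() argument beyond which the cost is reported as infinite (log-domain
# overflow guard; exp overflows a float64 just above 709).
OVERFLOW_EXPONENT = 700.0


@dataclass(frozen=True)
class MeanFieldConfig:
    """Everything the mean-field fitness needs besides the payoff pair.

    alpha         strength of the global remaining-ITM cost (> 0 for a
                  meaningful equilibrium; 0 is flagged, not raised)
    m, n          ITMs neutralized per necrotic / apoptotic neutrophil (>= 0)
    n_total       total neutrophil count N_T (integer > 1)
    k             power-law exponent applied to the initial ITM dose (> 0)
    itms_initial  initial ITM concentration (>= 0), same units as m and n
    """

    alpha: float
    m: float
    n: float
    n_total: int = 2500
    k: float = 0.0929
    itms_initial: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "m", "n", "k", "itms_initial"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")
        if self.m < 0 or self.n < 0:
            raise InvalidParameterError("m and n must be >= 0")
        if self.n_total <= 1:
            raise InvalidParameterError(f"n_total must be > 1, got {self.n_total}")
        if self.k <= 0:
            raise InvalidParameterError(f"k must be > 0, got {self.k}")
        if self.itms_initial < 0:
            raise InvalidParameterError("itms_initial must be >= 0")

    def with_itms(self, itms_initial: float) -> "MeanFieldConfig":
        return replace(self, itms_initial=itms_initial)


class EquilibriumReason(Enum):
    OK = "ok"
    OUT_OF_UNIT_INTERVAL = "out_of_unit_interval"
    CONSTRAINT_VIOLATION = "constraint_violation"
    LOG_DOMAIN = "log_domain"


@dataclass(frozen=True)
class EquilibriumResult:
    """Closed-form necrotic fraction with its validity verdict.

    ``p`` is reported even when outside [0, 1] (masked, never clipped);
    it is NaN when the closed form is undefined altogether.
    """

    p: float
    valid: bool
    reason: EquilibriumReason


def itms_remaining(q: float, p: float, cfg: MeanFieldConfig) -> float:
    """Remaining-ITM ledger R(q, p); may be negative (no floor)."""
    pool = cfg.itms_initial ** cfg.k
    others = cfg.n_total - 1
    return (
        pool
        - p * cfg.m * others
        - q * cfg.m
        - (1.0 - p) * cfg.n * others
        - (1.0 - q) * cfg.n
    )


def _exp_cost(exponent: float) -> float:
    """exp(exponent) with overflow flagged as an infinite cost."""
    if exponent > OVERFLOW_EXPONENT:
        return math.inf
    return math.exp(exponent)


def average_fitness(
    q: float, p: float, params: PayoffParameters, cfg: MeanFieldConfig
) -> float:
    """F(q, p): payoff mixture minus the exponential remaining-ITM cost.

    Returns -inf when the cost exponent overflows (infinite-cost flag).
    """
    mat = build_payoff_matrix(params)
    mixture = (
        q * p * mat.A
        + q * (1.0 - p) * mat.B
        + (1.0 - q) * p * mat.C
        + (1.0 - q) * (1.0 - p) * mat.D
    )
    cost = _exp_cost(cfg.alpha * itms_remaining(q, p, cfg))
    if math.isinf(cost):
        return -math.inf
    return mixture - cost


def fitness_gradient(
    q: float, p: float, params: PayoffParameters, cfg: MeanFieldConfig
) -> float:
    """Analytic dF/dq at (q, p).

    The payoff part contributes pA + (1-p)B - pC - (1-p)D = -(b+c); the cost
    part contributes -alpha (n - m) exp(alpha R(q, p)).
    """
    mat = build_payoff_matrix(params)
    payoff_part = p * mat.A + (1.0 - p) * mat.B - p * mat.C - (1.0 - p) * mat.D
    cost_part = cfg.alpha * (cfg.n - cfg.m) * _exp_cost(
        cfg.alpha * itms_remaining(q, p, cfg)
    )
    return payoff_part - cost_part


def equilibrium_p(params: PayoffParameters, cfg: MeanFieldConfig) -> EquilibriumResult:
    """Closed-form mixed-equilibrium necrotic fraction p = q*.

    Constraint violations (b+c = 0, m = n, alpha = 0) and log-domain
    failures are reported in the result, not raised.
    """
    bc = params.bc_sum
    if bc == 0.0 or cfg.m == cfg.n or cfg.alpha == 0.0:
        return EquilibriumResult(math.nan, False, EquilibriumReason.CONSTRAINT_VIOLATION)
    ratio = bc / (cfg.alpha * (cfg.m - cfg.n))
    if ratio <= 0.0:
        return EquilibriumResult(math.nan, False, EquilibriumReason.LOG_DOMAIN)
    pool = cfg.itms_initial ** cfg.k
    numerator = math.log(ratio) + cfg.alpha * cfg.n * cfg.n_total - cfg.alpha * pool
    denominator = cfg.alpha * cfg.n_total * (cfg.m - cfg.n)
    p = -numerator / denominator
    if 0.0 <= p <= 1.0:
        return EquilibriumResult(p, True, EquilibriumReason.OK)
    return EquilibriumResult(p, False, EquilibriumReason.OUT_OF_UNIT_INTERVAL)
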