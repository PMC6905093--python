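"""The two-strategy neutrophil death game.

A neutrophil facing unresolved inflammation commits to one of two death
pathways: *apoptosis* (quiet, anti-inflammatory — the game's defector) or
*necrosis* (violent, tissue-damaging but reinforcement-recruiting — the
cooperator/altruist).  The pairwise interaction is a symmetric 2x2 game
whose four payoffs derive from two non-negative parameters, the benefit of
apoptosis ``b_apoptosis`` and the cost of necrosis ``c_necrosis``:

    A = -c                (necrosis vs necrosis)
    B = -c + b            (necrosis vs apoptosis)
    C = b                 (apoptosis vs necrosis)
    D = 2b                (apoptosis vs apoptosis)

For b, c > 0 the ordering D > C > B > A makes this a deadlock game: the
mutually beneficial strategy (apoptosis) is also dominant.  Storing (b, c)
rather than the four entries makes the defining identities hold by
construction; everything downstream depends on the payoffs only through
the sum b + c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

from .errors import InvalidParameterError

__all__ = [
    "Strategy",
    "PayoffParameters",
    "PayoffMatrix",
    "build_payoff_matrix",
    "payoff",
]


class Strategy(IntEnum):
    """Death pathway a neutrophil can commit to.

    Integer codes are fixed (0 = apoptosis, 1 = necrosis) so lattice grids
    and serialized outputs are stable.
    """

    APOPTOSIS = 0
    NECROSIS = 1


@dataclass(frozen=True)
class PayoffParameters:
    """Benefit of apoptosis and cost of necrosis, in dimensionless fitness units.

    Both are non-negative; signs are encoded inside the payoff matrix.
    """

    b_apoptosis: float
    c_necrosis: float

    def __post_init__(self) -> None:
        for name in ("b_apoptosis", "c_necrosis"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise InvalidParameterError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {value!r}")

    @property
    def bc_sum(self) -> float:
        """b_apoptosis + c_necrosis, the only combination the equilibria see."""
        return self.b_apoptosis + self.c_necrosis


@dataclass(frozen=True)
class PayoffMatrix:
    """Row player's payoffs: A (nec,nec), B (nec,apo), C (apo,nec), D (apo,apo)."""

    A: float
    B: float
    C: float
    D: float


def build_payoff_matrix(params: PayoffParameters) -> PayoffMatrix:
    """Construct the symmetric payoff matrix from (b_apoptosis, c_necrosis)."""
    b = params.b_apoptosis
    c = params.c_necrosis
    return PayoffMatrix(A=-c, B=-c + b, C=b, D=2.0 * b)


def payoff(own: Strategy, other: Strategy, matrix: PayoffMatrix) -> float:
    """Row player's payoff for playing ``own`` against ``other``.

    The game is symmetric, so the column player's payoff for the same pair
    is ``payoff(other, own, matrix)``.
    """
    if own is Strategy.NECROSIS:
        return matrix.A if other is Strategy.NECROSIS else matrix.B
    return matrix.C if other is Strategy.NECROSIS else matrix.D
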