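"""2x2 game payoff matrices and dilemma classification.

A :class:`Game` is a single symmetric 2x2 game given by its payoff
quadruple ``(R, S, T, P)`` (row player: Reward, Sucker, Temptation,
Punishment).  A :class:`GameSpec` bundles one game per network layer for
multichannel play.

Games are classified by the two dilemma-strength parameters

    Dg' = (T - R) / (R - P)   (gamble-intending dilemma)
    Dr' = (P - S) / (R - P)   (risk-averting dilemma)

whose signs separate Prisoner's Dilemma, Snowdrift, Stag-Hunt and
Harmony regions of the 2x2 game space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "Game",
    "GameSpec",
    "donation_game",
    "snowdrift_game",
    "sculling_game",
    "classify_dilemma",
]


@dataclass(frozen=True)
class Game:
    """One symmetric 2x2 game.

    Parameters
    ----------
    R, S, T, P
        Payoffs of the row player for (C,C), (C,D), (D,C), (D,D).
    family
        Named construction the payoffs came from, if any.
    b, c
        Benefit and cost parameters when the game was built from a
        named family; ``None`` for custom payoff matrices.
    """

    R: float
    S: float
    T: float
    P: float
    family: str = "custom"
    b: Optional[float] = None
    c: Optional[float] = None

    @property
    def payoffs(self) -> np.ndarray:
        """Payoff vector ``[R, S, T, P]`` of the row player."""
        return np.array([self.R, self.S, self.T, self.P], dtype=float)


def donation_game(b: float, c: float) -> Game:
    """Donation game: cooperation pays ``b`` to the co-player at cost ``c``.

    The payoff matrix is ``R = b - c, S = -c, T = b, P = 0``.  Requires
    ``b > c > 0`` so that the game is a genuine Prisoner's Dilemma with
    ``Dg' = Dr' = c / (b - c)``.
    """
    if not (b > c > 0):
        raise ValueError(f"donation game requires b > c > 0, got b={b}, c={c}")
    return Game(R=b - c, S=-c, T=b, P=0.0, family="donation", b=b, c=c)


def snowdrift_game(b: float, c: float) -> Game:
    """Snowdrift game: ``R = b - c/2, S = b - c, T = b, P = 0``.

    A lone cooperator still obtains ``b - c`` (the cost of clearing the
    drift alone), so defection is not an equilibrium.
    """
    if b <= 0 or c <= 0:
        raise ValueError(f"snowdrift game requires b > 0 and c > 0, got b={b}, c={c}")
    return Game(R=b - c / 2.0, S=b - c, T=b, P=0.0, family="snowdrift", b=b, c=c)


def sculling_game(b: float, c: float) -> Game:
    """Sculling game (a Stag-Hunt variant with non-linear synergy).

    ``R = (4/3) b - c, S = b/3 - c, T = b/3, P = 0``: the benefit of
    cooperation is super-additive when both players row.
    """
    if b <= 0 or c <= 0:
        raise ValueError(f"sculling game requires b > 0 and c > 0, got b={b}, c={c}")
    return Game(
        R=4.0 * b / 3.0 - c, S=b / 3.0 - c, T=b / 3.0, P=0.0,
        family="sculling", b=b, c=c,
    )


def classify_dilemma(game: Game, *, tol: float = 1e-12) -> str:
    """Classify a 2x2 game by the signs of its dilemma strengths.

    Returns one of ``"PD"``, ``"SD"``, ``"SH"``, ``"Harmony"`` or
    ``"degenerate"`` (one of the dilemma strengths is exactly zero).
    Raises ``ValueError`` when ``R == P`` (strengths undefined).
    """
    denom = game.R - game.P
    if abs(denom) < tol:
        raise ValueError("dilemma strengths undefined for R == P")
    dg = (game.T - game.R) / denom
    dr = (game.P - game.S) / denom
    if abs(dg) < tol or abs(dr) < tol:
        return "degenerate"
    if dg > 0 and dr > 0:
        return "PD"
    if dg > 0 and dr < 0:
        return "SD"
    if dg < 0 and dr > 0:
        return "SH"
    return "Harmony"


def dilemma_strengths(game: Game) -> tuple[float, float]:
    """Return ``(Dg', Dr')`` for a game with ``R != P``."""
    denom = game.R - game.P
    if denom == 0:
        raise ValueError("dilemma strengths undefined for R == P")
    return (game.T - game.R) / denom, (game.P - game.S) / denom


@dataclass(frozen=True)
class GameSpec:
    """One 2x2 game per layer of a multiplex.

    The layer order matches the layer order of the network; two layers
    throughout the dynamics.
    """

    layers: tuple[Game, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.layers) < 1:
            raise ValueError("GameSpec requires at least one layer game")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def payoff_matrix(self) -> np.ndarray:
        """Stacked row-player payoffs, shape ``(n_layers, 4)`` as (R,S,T,P)."""
        return np.stack([g.payoffs for g in self.layers])

    @classmethod
    def donation(cls, b: Iterable[float], c: Iterable[float]) -> "GameSpec":
        return cls(tuple(donation_game(bi, ci) for bi, ci in zip(b, c)))

    @classmethod
    def snowdrift(cls, b: Iterable[float], c: Iterable[float]) -> "GameSpec":
        return cls(tuple(snowdrift_game(bi, ci) for bi, ci in zip(b, c)))

    @classmethod
    def sculling(cls, b: Iterable[float], c: Iterable[float]) -> "GameSpec":
        return cls(tuple(sculling_game(bi, ci) for bi, ci in zip(b, c)))
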