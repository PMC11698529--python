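"""Exact expected outcomes of one repeated pairwise multichannel interaction.

Two players repeatedly play one 2x2 game per layer.  With *reactive*
strategies each player's next action in layer ``a`` depends only on the
co-player's previous action(s):

* a **linked** strategy conditions the layer-``a`` move on the
  co-player's last action pair across both layers — a 10-tuple
  ``(p00^1, pCC^1, pCD^1, pDC^1, pDD^1; p00^2, ..., pDD^2)``;
* an **unlinked** strategy conditions only on the co-player's last move
  in the same layer — a per-layer triple ``(p0, pC, pD)``.

The round-to-round dynamics form a Markov chain on the joint action
state ``(a_i^1, a_i^2, a_j^1, a_j^2)``.  For continuation probability
``w < 1`` the relevant quantity is the discounted visit distribution
``(1-w) sum_t w^t v_0 M^t``; for ``w = 1`` it is the Cesàro (long-run
time-average) distribution reachable from the initial state, which
exists for periodic and absorbing chains alike and equals the unique
stationary vector when the chain is ergodic.  Payoffs and cooperation
rates are linear functionals of the per-layer visit distribution:

    pi_ij^a    = vCC R_a + vCD S_a + vDC T_a + vDD P_a
    gamma_ij^a = vCC + vCD

Perception error (imperfect memory) with layer probabilities
``(eps_1, eps_2)`` replaces a player's conditional response by the
mixture over mis-recalled opponent actions; it never alters the first
round.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .games import GameSpec

__all__ = [
    "LinkedStrategy",
    "UnlinkedStrategy",
    "PerceptionError",
    "PairOutcome",
    "build_transition",
    "visit_distribution",
    "pair_outcome",
    "apply_perception_error",
    "embed_unlinked",
    "rollout_pair",
]

# opponent action-pair columns, in this fixed order
_PAIRS = ("CC", "CD", "DC", "DD")

# 16-state encoding: index = 8*[a_i^1=D] + 4*[a_i^2=D] + 2*[a_j^1=D] + [a_j^2=D]
_STATE_BITS = np.array(
    [[(s >> 3) & 1, (s >> 2) & 1, (s >> 1) & 1, s & 1] for s in range(16)]
)


def _check_unit(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)) or not np.all(np.isfinite(x)):
        raise ValueError(f"{what} must lie in [0, 1]")
    return x


@dataclass(frozen=True)
class LinkedStrategy:
    """Multi-game linked reactive strategy (10-tuple for two layers).

    ``p0[a]`` is the first-round cooperation probability in layer ``a``;
    ``cond[a, k]`` the probability of cooperating in layer ``a`` after
    the co-player's action pair ``k`` in (CC, CD, DC, DD) order, the
    first letter being the co-player's layer-1 action.
    """

    p0: np.ndarray
    cond: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "p0", _check_unit(self.p0, "p0").reshape(2))
        object.__setattr__(self, "cond", _check_unit(self.cond, "cond").reshape(2, 4))

    @classmethod
    def from_tuple(cls, values) -> "LinkedStrategy":
        """Build from the flat 10-tuple ``(p00^1, pCC^1..pDD^1; p00^2, ..)``."""
        v = np.asarray(values, dtype=float).reshape(2, 5)
        return cls(p0=v[:, 0].copy(), cond=v[:, 1:].copy())

    def as_tuple(self) -> np.ndarray:
        return np.hstack([self.p0[:, None], self.cond]).ravel()

    @classmethod
    def allc(cls) -> "LinkedStrategy":
        return cls(p0=np.ones(2), cond=np.ones((2, 4)))

    @classmethod
    def alld(cls) -> "LinkedStrategy":
        return cls(p0=np.zeros(2), cond=np.zeros((2, 4)))


@dataclass(frozen=True)
class UnlinkedStrategy:
    """Per-layer unlinked reactive strategy ``(p0, pC, pD)`` per layer."""

    p0: np.ndarray
    pC: np.ndarray
    pD: np.ndarray

    def __post_init__(self):
        for name in ("p0", "pC", "pD"):
            object.__setattr__(self, name, _check_unit(getattr(self, name), name).reshape(2))

    @classmethod
    def from_tuple(cls, values) -> "UnlinkedStrategy":
        """Build from ``((p0^1, pC^1, pD^1), (p0^2, pC^2, pD^2))`` flat order."""
        v = np.asarray(values, dtype=float).reshape(2, 3)
        return cls(p0=v[:, 0].copy(), pC=v[:, 1].copy(), pD=v[:, 2].copy())

    @classmethod
    def allc(cls) -> "UnlinkedStrategy":
        return cls(p0=np.ones(2), pC=np.ones(2), pD=np.ones(2))

    @classmethod
    def alld(cls) -> "UnlinkedStrategy":
        return cls(p0=np.zeros(2), pC=np.zeros(2), pD=np.zeros(2))

    @classmethod
    def tft(cls) -> "UnlinkedStrategy":
        return cls(p0=np.ones(2), pC=np.ones(2), pD=np.zeros(2))


Strategy = Union[LinkedStrategy, UnlinkedStrategy]


@dataclass(frozen=True)
class PerceptionError:
    """Imperfect-memory probabilities ``(eps_1, eps_2)``, one per layer."""

    eps: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "eps", _check_unit(self.eps, "eps").reshape(2))

    @classmethod
    def none(cls) -> "PerceptionError":
        return cls(np.zeros(2))


@dataclass
class PairOutcome:
    """Expected outcome of one repeated pair interaction.

    ``v[a]`` is the layer-``a`` visit distribution over (CC, CD, DC, DD)
    with player ``i``'s action first; payoffs and cooperation rates
    follow as linear functionals.
    """

    v: np.ndarray            # (2, 4)
    pi_ij: np.ndarray        # (2,)
    pi_ji: np.ndarray        # (2,)
    gamma_ij: np.ndarray     # (2,)
    gamma_ji: np.ndarray     # (2,)

    def to_dict(self) -> dict:
        return {
            "v": self.v.tolist(),
            "pi_ij": self.pi_ij.tolist(),
            "pi_ji": self.pi_ji.tolist(),
            "gamma_ij": self.gamma_ij.tolist(),
            "gamma_ji": self.gamma_ji.tolist(),
        }


# ---------------------------------------------------------------------------
# perception error


# column permutations of (CC, CD, DC, DD) under flipping the recalled
# layer-1 action, the layer-2 action, or both
_FLIP1 = np.array([2, 3, 0, 1])
_FLIP2 = np.array([1, 0, 3, 2])
_FLIP12 = np.array([3, 2, 1, 0])


def apply_perception_error(strat: Strategy, mem: PerceptionError) -> Strategy:
    """Mix a strategy's conditionals over mis-recalled opponent actions.

    The first-round probabilities are unchanged.  For an unlinked
    strategy layer ``a``: ``pC' = (1-eps_a) pC + eps_a pD`` (and
    symmetrically); for a linked strategy the conditionals are averaged
    over independent recall flips in the two layers.
    """
    e1, e2 = mem.eps
    if isinstance(strat, UnlinkedStrategy):
        e = mem.eps
        return UnlinkedStrategy(
            p0=strat.p0.copy(),
            pC=(1 - e) * strat.pC + e * strat.pD,
            pD=(1 - e) * strat.pD + e * strat.pC,
        )
    if isinstance(strat, LinkedStrategy):
        c = strat.cond
        mixed = (
            (1 - e1) * (1 - e2) * c
            + e1 * (1 - e2) * c[:, _FLIP1]
            + (1 - e1) * e2 * c[:, _FLIP2]
            + e1 * e2 * c[:, _FLIP12]
        )
        return LinkedStrategy(p0=strat.p0.copy(), cond=mixed)
    raise TypeError(f"unsupported strategy type {type(strat)!r}")


def embed_unlinked(u: UnlinkedStrategy) -> LinkedStrategy:
    """Embed an unlinked strategy as the linked strategy ignoring the other layer."""
    cond = np.empty((2, 4))
    cond[0] = [u.pC[0], u.pC[0], u.pD[0], u.pD[0]]
    cond[1] = [u.pC[1], u.pD[1], u.pC[1], u.pD[1]]
    return LinkedStrategy(p0=u.p0.copy(), cond=cond)


# ---------------------------------------------------------------------------
# transition matrix and visit distributions


def _coop_prob_next(strat: LinkedStrategy, opp_bits: np.ndarray) -> np.ndarray:
    """Cooperation probabilities (layer 1, layer 2) after opponent pair bits."""
    col = 2 * opp_bits[0] + opp_bits[1]
    return strat.cond[:, col]


def build_transition(strat_i: LinkedStrategy, strat_j: LinkedStrategy):
    """16x16 transition matrix and initial distribution of the pair chain.

    State index is ``8[a_i^1=D] + 4[a_i^2=D] + 2[a_j^1=D] + [a_j^2=D]``.
    Next-round actions are independent Bernoulli draws: player ``i``
    cooperates in layer ``a`` with probability ``cond_i[a, (a_j^1 a_j^2)]``
    and symmetrically for ``j``.
    """
    if not isinstance(strat_i, LinkedStrategy) or not isinstance(strat_j, LinkedStrategy):
        raise TypeError("build_transition expects LinkedStrategy arguments")
    M = np.empty((16, 16))
    for s in range(16):
        bits = _STATE_BITS[s]
        pi_c = _coop_prob_next(strat_i, bits[2:])   # i reacts to j's pair
        pj_c = _coop_prob_next(strat_j, bits[:2])   # j reacts to i's pair
        probs_c = np.array([pi_c[0], pi_c[1], pj_c[0], pj_c[1]])
        # probability of each next state: product over the four coordinates
        p_bit = np.where(_STATE_BITS.astype(bool), 1 - probs_c, probs_c)
        M[s] = p_bit.prod(axis=1)
    probs_c0 = np.array([strat_i.p0[0], strat_i.p0[1], strat_j.p0[0], strat_j.p0[1]])
    v0 = np.where(_STATE_BITS.astype(bool), 1 - probs_c0, probs_c0).prod(axis=1)
    return M, v0


def _cesaro_distribution(M: np.ndarray, v0: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Long-run time-average distribution from ``v0``.

    Decomposes the chain into recurrent classes (bottom strongly
    connected components of the support graph), computes absorption
    probabilities from ``v0``, and mixes the per-class stationary
    vectors, which equal the Cesàro averages even for periodic classes.
    """
    n = M.shape[0]
    support = sp.csr_matrix((M > tol).astype(np.int8))
    n_comp, labels = connected_components(support, directed=True, connection="strong")
    # a component is recurrent iff no mass leaves it
    leaves = np.zeros(n_comp, dtype=bool)
    rows, cols = support.nonzero()
    for r, c in zip(rows, cols):
        if labels[r] != labels[c]:
            leaves[labels[r]] = True
    recurrent = [k for k in range(n_comp) if not leaves[k]]
    transient_states = np.array([s for s in range(n) if leaves[labels[s]]], dtype=int)

    # absorption probability into each recurrent class, starting from v0
    absorb = np.zeros(len(recurrent))
    class_states = {k: np.where(labels == k)[0] for k in recurrent}
    for idx, k in enumerate(recurrent):
        absorb[idx] = v0[class_states[k]].sum()
    if len(transient_states):
        Q = M[np.ix_(transient_states, transient_states)]
        solve_lhs = np.eye(len(transient_states)) - Q
        for idx, k in enumerate(recurrent):
            r = M[np.ix_(transient_states, class_states[k])].sum(axis=1)
            h = np.linalg.solve(solve_lhs, r)
            absorb[idx] += v0[transient_states] @ h

    out = np.zeros(n)
    for idx, k in enumerate(recurrent):
        if absorb[idx] <= 0:
            continue
        states = class_states[k]
        sub = M[np.ix_(states, states)]
        # stationary vector of the recurrent class
        m = len(states)
        A = (sub.T - np.eye(m))
        A[-1, :] = 1.0
        b = np.zeros(m)
        b[-1] = 1.0
        pi = np.linalg.solve(A, b)
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()
        out[states] += absorb[idx] * pi
    return out


def visit_distribution(M: np.ndarray, v0: np.ndarray, w: float = 1.0) -> np.ndarray:
    """Visit distribution of a repeated-game chain.

    For ``w < 1`` the normalized discounted visit distribution
    ``(1-w) sum_t w^t v0 M^t`` (a linear solve); for ``w = 1`` the
    Cesàro time-average reachable from ``v0``.
    """
    M = np.asarray(M, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[0] != v0.shape[0]:
        raise ValueError("shape mismatch between M and v0")
    if np.any(M < -1e-12) or np.any(np.abs(M.sum(axis=1) - 1) > 1e-9):
        raise ValueError("M must be row-stochastic")
    if np.any(v0 < -1e-12) or abs(v0.sum() - 1) > 1e-9:
        raise ValueError("v0 must be a distribution")
    if not (0 < w <= 1):
        raise ValueError("w must lie in (0, 1]")
    if w < 1:
        v = (1 - w) * np.linalg.solve(np.eye(M.shape[0]) - w * M.T, v0)
    else:
        v = _cesaro_distribution(M, v0)
    v = np.clip(v, 0.0, None)
    return v / v.sum()


# ---------------------------------------------------------------------------
# pair outcome


def _layer_marginals(v16: np.ndarray) -> np.ndarray:
    """Marginal per-layer visit distributions (2, 4) from the 16-state one."""
    out = np.zeros((2, 4))
    for s in range(16):
        b = _STATE_BITS[s]
        out[0, 2 * b[0] + b[2]] += v16[s]   # (a_i^1, a_j^1)
        out[1, 2 * b[1] + b[3]] += v16[s]   # (a_i^2, a_j^2)
    return out


def _unlinked_layer_chain(u_i: UnlinkedStrategy, u_j: UnlinkedStrategy, layer: int):
    """4-state chain on (a_i^a, a_j^a), index 2[a_i=D] + [a_j=D]."""
    pc_i, pd_i = u_i.pC[layer], u_i.pD[layer]
    pc_j, pd_j = u_j.pC[layer], u_j.pD[layer]
    M = np.empty((4, 4))
    for s in range(4):
        ai, aj = (s >> 1) & 1, s & 1
        x = pc_i if aj == 0 else pd_i    # i reacts to j's last action
        y = pc_j if ai == 0 else pd_j
        M[s] = [x * y, x * (1 - y), (1 - x) * y, (1 - x) * (1 - y)]
    x0, y0 = u_i.p0[layer], u_j.p0[layer]
    v0 = np.array([x0 * y0, x0 * (1 - y0), (1 - x0) * y0, (1 - x0) * (1 - y0)])
    return M, v0


def pair_outcome(
    strat_i: Strategy,
    strat_j: Strategy,
    games: GameSpec,
    w: float = 1.0,
    mem: Optional[PerceptionError] = None,
    linked: Optional[bool] = None,
) -> PairOutcome:
    """Exact expected payoffs and cooperation rates of one pair.

    Both strategies must be of the same kind; to pit an unlinked
    strategy against a linked one, :func:`embed_unlinked` it first.
    """
    is_linked = isinstance(strat_i, LinkedStrategy)
    if isinstance(strat_j, LinkedStrategy) != is_linked:
        raise TypeError(
            "cannot mix linked and unlinked strategies; embed_unlinked first"
        )
    if linked is not None and linked != is_linked:
        raise TypeError(f"strategies are {'linked' if is_linked else 'unlinked'}, "
                        f"but linked={linked} was requested")
    if mem is not None:
        strat_i = apply_perception_error(strat_i, mem)
        strat_j = apply_perception_error(strat_j, mem)

    if is_linked:
        M, v0 = build_transition(strat_i, strat_j)
        v16 = visit_distribution(M, v0, w)
        v = _layer_marginals(v16)
    else:
        v = np.empty((2, 4))
        for a in range(2):
            M, v0 = _unlinked_layer_chain(strat_i, strat_j, a)
            v[a] = visit_distribution(M, v0, w)

    payoffs = games.payoff_matrix()          # (layers, 4) as R,S,T,P
    pi_ij = (v * payoffs).sum(axis=1)
    # transposed state order for the co-player: CD and DC swap
    pi_ji = (v[:, [0, 2, 1, 3]] * payoffs).sum(axis=1)
    gamma_ij = v[:, 0] + v[:, 1]
    gamma_ji = v[:, 0] + v[:, 2]
    return PairOutcome(v=v, pi_ij=pi_ij, pi_ji=pi_ji, gamma_ij=gamma_ij, gamma_ji=gamma_ji)


# ---------------------------------------------------------------------------
# Monte-Carlo rollout (simulation cross-check, independent of the
# linear-algebra path)


def rollout_pair(
    strat_i: Strategy,
    strat_j: Strategy,
    n_rounds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Empirical per-layer visit frequencies from a sampled rollout.

    Plays ``n_rounds`` rounds of the repeated interaction (``w = 1``)
    by drawing every action, and tallies the per-layer state
    frequencies over (CC, CD, DC, DD).  Serves as a stochastic oracle
    for the exact engine.
    """
    if isinstance(strat_i, UnlinkedStrategy):
        strat_i = embed_unlinked(strat_i)
    if isinstance(strat_j, UnlinkedStrategy):
        strat_j = embed_unlinked(strat_j)
    counts = np.zeros((2, 4))
    # actions: 0 = C, 1 = D
    ai = (rng.random(2) >= strat_i.p0).astype(int)
    aj = (rng.random(2) >= strat_j.p0).astype(int)
    for _ in range(n_rounds):
        counts[0, 2 * ai[0] + aj[0]] += 1
        counts[1, 2 * ai[1] + aj[1]] += 1
        pi_c = strat_i.cond[:, 2 * aj[0] + aj[1]]
        pj_c = strat_j.cond[:, 2 * ai[0] + ai[1]]
        ai = (rng.random(2) >= pi_c).astype(int)
        aj = (rng.random(2) >= pj_c).astype(int)
    return counts / n_rounds
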