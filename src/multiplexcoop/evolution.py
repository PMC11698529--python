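"""Population dynamics of multichannel games on multiplex networks.

Every player carries a linked 10-tuple strategy (used against common
neighbors) and per-layer unlinked triples (used against unique
neighbors).  Each time step:

1. every realized pair interaction is evaluated *exactly* through the
   repeated-game engine (expected payoffs, no sampled rounds);
2. per-player payoffs are degree-normalized within each layer and
   summed across layers;
3. strategies update by mutation (probability ``mu``: fresh uniform
   components) or imitation of a random neighbor accepted with the
   Fermi pairwise-comparison probability ``1 / (1 + exp(-s (f_B - f_A)))``.

Two update schemes are supported.  *Independent*: one layer is chosen
uniformly per step and every player updates the chosen layer's strategy
components (5 linked + 3 unlinked entries).  *Simultaneous*: every
player updates in every layer; imitating a common neighbor copies the
full strategy set across layers, imitating a unique neighbor copies
only that layer's components.  Updates within a step are synchronous
(all copies reference the pre-step snapshot), which makes runs
reproducible from the seed alone.

Three interaction modes select which engine governs which edge:
``"mixed"`` (linked play on common edges, unlinked on unique ones — the
general model), ``"unlinked"`` (every edge played with unlinked
strategies, i.e. games are treated independently) and ``"linked"``
(every edge played with the linked strategy; meaningful when the layers
coincide, O = 1).

For speed, an ensemble of replicate runs is simulated as one batched
system: pair outcomes reduce to small closed-form solves vectorized
over every edge of every replicate.  A per-pair fallback to the general
Markov-chain engine covers the (measure-zero) degenerate strategy
combinations where the closed form is singular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numba
import numpy as np
from scipy.special import expit

from .games import GameSpec
from .multiplex import MultiplexNetwork
from . import pair_engine as pe

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "PopulationState",
    "fermi_probability",
    "classify_outcome",
    "player_payoffs",
    "population_rates",
    "update_step",
    "run_simulation",
    "run_ensemble",
]

_MODES = ("mixed", "unlinked", "linked")
_SCHEMES = ("independent", "simultaneous")


# ---------------------------------------------------------------------------
# vectorized pair computations


def _unlinked_layer_v(p0u, pCu, pDu, p0v, pCv, pDv, w: float) -> np.ndarray:
    """Visit distributions (B, 4) of unlinked pairs in one layer.

    For reactive strategies the joint action distribution stays a
    product of the two players' marginals round by round, so the
    stationary (or discounted) distribution follows from the two
    cooperation probabilities alone.
    """
    B = len(p0u)
    if w >= 1.0:
        ru = pCu - pDu
        rv = pCv - pDv
        denom = 1.0 - ru * rv
        bad = np.abs(denom) < 1e-9
        safe = np.where(bad, 1.0, denom)
        x = (pDu + ru * pDv) / safe
        y = (pDv + rv * pDu) / safe
        x = np.clip(x, 0.0, 1.0)
        y = np.clip(y, 0.0, 1.0)
        v = np.empty((B, 4))
        v[:, 0] = x * y
        v[:, 1] = x - v[:, 0]
        v[:, 2] = y - v[:, 0]
        v[:, 3] = 1.0 - x - v[:, 2]
        if bad.any():
            for idx in np.nonzero(bad)[0]:
                M, v0 = _scalar_unlinked_chain(
                    p0u[idx], pCu[idx], pDu[idx], p0v[idx], pCv[idx], pDv[idx]
                )
                v[idx] = pe.visit_distribution(M, v0, 1.0)
        return v
    # discounted: iterate the exact marginal recursion
    x = np.asarray(p0u, dtype=float).copy()
    y = np.asarray(p0v, dtype=float).copy()
    Sx = np.zeros(B)
    Sy = np.zeros(B)
    Sxy = np.zeros(B)
    weight = 1.0 - w
    total = 0.0
    t = 0
    while weight > 1e-14 * (1.0 - w) and t < 100_000:
        Sx += weight * x
        Sy += weight * y
        Sxy += weight * x * y
        total += weight
        x, y = pDu + (pCu - pDu) * y, pDv + (pCv - pDv) * x
        weight *= w
        t += 1
    Sx /= total
    Sy /= total
    Sxy /= total
    return np.stack([Sxy, Sx - Sxy, Sy - Sxy, 1 - Sx - Sy + Sxy], axis=1)


def _scalar_unlinked_chain(p0u, pCu, pDu, p0v, pCv, pDv):
    ui = pe.UnlinkedStrategy(p0=np.array([p0u, p0u]), pC=np.array([pCu, pCu]),
                             pD=np.array([pDu, pDu]))
    uj = pe.UnlinkedStrategy(p0=np.array([p0v, p0v]), pC=np.array([pCv, pCv]),
                             pD=np.array([pDv, pDv]))
    return pe._unlinked_layer_chain(ui, uj, 0)


def _moment_map(cond: np.ndarray):
    """Affine map from opponent action-pair moments to own moments.

    The distribution of a player's next action pair is determined by the
    three moments ``(q1, q2, q12)`` = (P(coop in 1), P(coop in 2),
    P(coop in both)); given the opponent's moments ``r`` the map is
    affine, ``q = b + M r``, with coefficients read off the strategy's
    conditionals (columns in CC, CD, DC, DD order).
    """
    g = cond[:, 0, :] * cond[:, 1, :]                  # joint coop given pair
    rows = [cond[:, 0, :], cond[:, 1, :], g]
    B = cond.shape[0]
    M = np.empty((B, 3, 3))
    b = np.empty((B, 3))
    for r, cmat in enumerate(rows):
        b[:, r] = cmat[:, 3]
        M[:, r, 0] = cmat[:, 1] - cmat[:, 3]
        M[:, r, 1] = cmat[:, 2] - cmat[:, 3]
        M[:, r, 2] = cmat[:, 0] - cmat[:, 1] - cmat[:, 2] + cmat[:, 3]
    return M, b


@numba.njit(cache=True, inline="always")
def _fill_moment_map(cond, p, M, bvec):
    for r in range(3):
        if r < 2:
            c0 = cond[p, r, 0]
            c1 = cond[p, r, 1]
            c2 = cond[p, r, 2]
            c3 = cond[p, r, 3]
        else:
            c0 = cond[p, 0, 0] * cond[p, 1, 0]
            c1 = cond[p, 0, 1] * cond[p, 1, 1]
            c2 = cond[p, 0, 2] * cond[p, 1, 2]
            c3 = cond[p, 0, 3] * cond[p, 1, 3]
        M[r, 0] = c1 - c3
        M[r, 1] = c2 - c3
        M[r, 2] = c0 - c1 - c2 + c3
        bvec[r] = c3


@numba.njit(cache=True)
def _linked_fixed_point(condi, condj):
    """Stationary cooperation probabilities of linked pairs.

    Explicit per-pair 3x3 algebra for the composed moment maps; returns
    ``(x, y, bad)`` with the per-layer cooperation probabilities of both
    players and a near-singular flag.
    """
    B = condi.shape[0]
    x = np.empty((B, 2))
    y = np.empty((B, 2))
    bad = np.zeros(B, dtype=np.bool_)
    Mi = np.empty((3, 3))
    Mj = np.empty((3, 3))
    bi = np.empty(3)
    bj = np.empty(3)
    A = np.empty((3, 3))
    rhs = np.empty(3)
    u = np.empty(3)
    for p in range(B):
        _fill_moment_map(condi, p, Mi, bi)
        _fill_moment_map(condj, p, Mj, bj)
        # A = I - Mi Mj ; rhs = bi + Mi bj
        for r in range(3):
            for c in range(3):
                acc = 0.0
                for k in range(3):
                    acc += Mi[r, k] * Mj[k, c]
                A[r, c] = (1.0 if r == c else 0.0) - acc
            rhs[r] = bi[r] + Mi[r, 0] * bj[0] + Mi[r, 1] * bj[1] + Mi[r, 2] * bj[2]
        det = (A[0, 0] * (A[1, 1] * A[2, 2] - A[1, 2] * A[2, 1])
               - A[0, 1] * (A[1, 0] * A[2, 2] - A[1, 2] * A[2, 0])
               + A[0, 2] * (A[1, 0] * A[2, 1] - A[1, 1] * A[2, 0]))
        if abs(det) < 1e-9:
            bad[p] = True
            x[p, 0] = x[p, 1] = y[p, 0] = y[p, 1] = 0.0
            continue
        u[0] = ((A[1, 1] * A[2, 2] - A[1, 2] * A[2, 1]) * rhs[0]
                + (A[0, 2] * A[2, 1] - A[0, 1] * A[2, 2]) * rhs[1]
                + (A[0, 1] * A[1, 2] - A[0, 2] * A[1, 1]) * rhs[2]) / det
        u[1] = ((A[1, 2] * A[2, 0] - A[1, 0] * A[2, 2]) * rhs[0]
                + (A[0, 0] * A[2, 2] - A[0, 2] * A[2, 0]) * rhs[1]
                + (A[0, 2] * A[1, 0] - A[0, 0] * A[1, 2]) * rhs[2]) / det
        u[2] = ((A[1, 0] * A[2, 1] - A[1, 1] * A[2, 0]) * rhs[0]
                + (A[0, 1] * A[2, 0] - A[0, 0] * A[2, 1]) * rhs[1]
                + (A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]) * rhs[2]) / det
        for l in range(2):
            xv = u[l]
            yv = bj[l] + Mj[l, 0] * u[0] + Mj[l, 1] * u[1] + Mj[l, 2] * u[2]
            x[p, l] = min(1.0, max(0.0, xv))
            y[p, l] = min(1.0, max(0.0, yv))
    return x, y, bad


def _linked_pair_v(p0i, condi, p0j, condj, w: float) -> np.ndarray:
    """Per-layer visit distributions (B, 2, 4) of linked pairs.

    In the stationary (or any fixed-round) regime the two players' action
    pairs are independent, so the 16-state chain collapses to a pair of
    coupled 3-moment affine maps whose fixed point is a 3x3 solve per
    pair.
    """
    B = condi.shape[0]
    if w >= 1.0:
        x, y, bad = _linked_fixed_point(
            np.ascontiguousarray(condi), np.ascontiguousarray(condj))
        v = np.empty((B, 2, 4))
        v[:, :, 0] = x * y
        v[:, :, 1] = x * (1 - y)
        v[:, :, 2] = (1 - x) * y
        v[:, :, 3] = (1 - x) * (1 - y)
        if bad.any():
            for idx in np.nonzero(bad)[0]:
                si = pe.LinkedStrategy(p0=p0i[idx], cond=condi[idx])
                sj = pe.LinkedStrategy(p0=p0j[idx], cond=condj[idx])
                M, v0 = pe.build_transition(si, sj)
                v[idx] = pe._layer_marginals(pe.visit_distribution(M, v0, 1.0))
        return v
    Mi, bi = _moment_map(condi)
    Mj, bj = _moment_map(condj)
    # discounted iteration on the moment pair
    u = np.stack([p0i[:, 0], p0i[:, 1], p0i[:, 0] * p0i[:, 1]], axis=1)
    m = np.stack([p0j[:, 0], p0j[:, 1], p0j[:, 0] * p0j[:, 1]], axis=1)
    Sx = np.zeros((B, 2))
    Sy = np.zeros((B, 2))
    Sxy = np.zeros((B, 2))
    weight = 1.0 - w
    total = 0.0
    t = 0
    while weight > 1e-14 * (1.0 - w) and t < 100_000:
        x = u[:, :2]
        y = m[:, :2]
        Sx += weight * x
        Sy += weight * y
        Sxy += weight * x * y
        total += weight
        u, m = (bi + np.einsum("bij,bj->bi", Mi, m),
                bj + np.einsum("bij,bj->bi", Mj, u))
        weight *= w
        t += 1
    Sx /= total
    Sy /= total
    Sxy /= total
    v = np.empty((B, 2, 4))
    v[:, :, 0] = Sxy
    v[:, :, 1] = Sx - Sxy
    v[:, :, 2] = Sy - Sxy
    v[:, :, 3] = 1 - Sx - Sy + Sxy
    return np.clip(v, 0.0, 1.0)


def _perceived_unlinked(unl: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Mix unlinked conditionals over mis-recalled opponent actions."""
    if not eps.any():
        return unl
    out = unl.copy()
    e = eps[None, :]
    out[:, :, 1] = (1 - e) * unl[:, :, 1] + e * unl[:, :, 2]
    out[:, :, 2] = (1 - e) * unl[:, :, 2] + e * unl[:, :, 1]
    return out


def _perceived_linked(lnk: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Mix linked conditionals over independent recall flips per layer."""
    if not eps.any():
        return lnk
    e1, e2 = eps
    c = lnk[:, :, 1:]
    mixed = (
        (1 - e1) * (1 - e2) * c
        + e1 * (1 - e2) * c[:, :, pe._FLIP1]
        + (1 - e1) * e2 * c[:, :, pe._FLIP2]
        + e1 * e2 * c[:, :, pe._FLIP12]
    )
    out = lnk.copy()
    out[:, :, 1:] = mixed
    return out


# ---------------------------------------------------------------------------
# topology preprocessing


class _Topology:
    """Batched edge structure of an ensemble of multiplex networks."""

    def __init__(self, nets: Sequence[MultiplexNetwork], mode: str):
        if mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        N = nets[0].n_nodes
        for net in nets:
            if net.n_nodes != N or net.n_layers != 2:
                raise ValueError("all ensemble networks must be 2-layer with equal N")
        self.R = len(nets)
        self.N = N
        self.NN = self.R * N
        self.mode = mode

        k = np.zeros((self.NN, 2), dtype=np.int64)
        common_edges = []
        unique_edges = [[], []]
        adj_src = [[], []]
        adj_dst = [[], []]
        adj_common = [[], []]
        for r, net in enumerate(nets):
            off = r * N
            sets = [net.edge_set(0), net.edge_set(1)]
            common = sets[0] & sets[1]
            if mode == "linked" and (sets[0] != sets[1]):
                raise ValueError("linked mode requires identical layers (O = 1)")
            for a in (0, 1):
                e = net.edges(a)
                if len(e) == 0:
                    raise ValueError(f"layer {a + 1} of a network has no edges")
                deg = net.degrees(a)
                if np.any(deg == 0):
                    raise ValueError(
                        "every player needs positive degree in each layer "
                        "(degree-normalized payoff undefined otherwise)"
                    )
                k[off:off + N, a] = deg
                is_common = np.array(
                    [tuple(edge) in common for edge in e], dtype=bool
                )
                adj_src[a].append(np.concatenate([e[:, 0], e[:, 1]]) + off)
                adj_dst[a].append(np.concatenate([e[:, 1], e[:, 0]]) + off)
                adj_common[a].append(np.concatenate([is_common, is_common]))
                if mode == "unlinked":
                    unique_edges[a].append(e + off)
                elif mode == "mixed":
                    unique_edges[a].append(e[~is_common] + off)
            if mode == "linked":
                common_edges.append(net.edges(0) + off)
            elif mode == "mixed":
                if common:
                    common_edges.append(np.array(sorted(common), dtype=np.int64) + off)

        self.k = k
        self.common = (
            np.vstack(common_edges) if common_edges else np.empty((0, 2), dtype=np.int64)
        )
        self.unique = [
            np.vstack(ue) if ue else np.empty((0, 2), dtype=np.int64)
            for ue in unique_edges
        ]
        # CSR adjacency per layer (for neighbor sampling)
        self.indptr = []
        self.indices = []
        self.indices_common = []
        for a in (0, 1):
            src = np.concatenate(adj_src[a])
            dst = np.concatenate(adj_dst[a])
            com = np.concatenate(adj_common[a])
            order = np.argsort(src, kind="stable")
            src, dst, com = src[order], dst[order], com[order]
            counts = np.bincount(src, minlength=self.NN)
            self.indptr.append(np.concatenate([[0], np.cumsum(counts)]))
            self.indices.append(dst)
            self.indices_common.append(com)
        # per-node common / unique neighbor counts
        self.cn_count = np.zeros(self.NN, dtype=np.int64)
        if len(self.common):
            np.add.at(self.cn_count, self.common[:, 0], 1)
            np.add.at(self.cn_count, self.common[:, 1], 1)
        self.un_count = np.zeros((self.NN, 2), dtype=np.int64)
        for a in (0, 1):
            if len(self.unique[a]):
                np.add.at(self.un_count[:, a], self.unique[a][:, 0], 1)
                np.add.at(self.un_count[:, a], self.unique[a][:, 1], 1)


# ---------------------------------------------------------------------------
# configuration and results


@dataclass
class SimulationConfig:
    """Parameters of one evolutionary run (network passed separately)."""

    games: GameSpec
    mode: str = "mixed"
    scheme: str = "independent"
    mu: float = 0.001
    w: float = 1.0
    s: float = 2.0
    eps: tuple = (0.0, 0.0)
    steps: int = 60_000
    record_stride: int = 1
    window: int = 1000

    def __post_init__(self):
        errors = []
        if self.mode not in _MODES:
            errors.append(f"mode: must be one of {_MODES}, got {self.mode!r}")
        if self.scheme not in _SCHEMES:
            errors.append(f"scheme: must be one of {_SCHEMES}, got {self.scheme!r}")
        if not (0.0 <= self.mu <= 1.0):
            errors.append(f"mu: must lie in [0, 1], got {self.mu}")
        if not (0.0 < self.w <= 1.0):
            errors.append(f"w: must lie in (0, 1], got {self.w}")
        if self.s < 0:
            errors.append(f"s: must be >= 0, got {self.s}")
        eps = np.asarray(self.eps, dtype=float)
        if eps.shape != (2,) or np.any((eps < 0) | (eps > 1)):
            errors.append(f"eps: must be two probabilities, got {self.eps}")
        if self.steps < 0:
            errors.append(f"steps: must be >= 0, got {self.steps}")
        if self.record_stride < 1:
            errors.append(f"record_stride: must be >= 1, got {self.record_stride}")
        if self.window < 1:
            errors.append(f"window: must be >= 1, got {self.window}")
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))


@dataclass
class SimulationResult:
    """Recorded time series and final summary of one run."""

    record_steps: np.ndarray      # (T,)
    zeta: np.ndarray              # (T, 2) population cooperation rate per layer
    zeta_cn: np.ndarray           # (T, 2) vs common neighbors (NaN if none)
    zeta_un: np.ndarray           # (T, 2) vs unique neighbors (NaN if none)
    final_zeta: np.ndarray        # (2,) window average of zeta
    final_zeta_cn: np.ndarray
    final_zeta_un: np.ndarray
    category: str
    mean_unlinked: np.ndarray     # (2, 3) population-average (p0, pC, pD)
    mean_linked: np.ndarray       # (2, 5) population-average (p00, pCC..pDD)
    seed: Optional[int] = None
    config: Optional[SimulationConfig] = None

    def summary(self) -> dict:
        return {
            "final_zeta": self.final_zeta.tolist(),
            "final_zeta_cn": self.final_zeta_cn.tolist(),
            "final_zeta_un": self.final_zeta_un.tolist(),
            "category": self.category,
            "mean_unlinked": self.mean_unlinked.tolist(),
            "mean_linked": self.mean_linked.tolist(),
            "seed": self.seed,
        }


@dataclass
class PopulationState:
    """Single-run population state: per-player strategy arrays.

    ``unlinked[i, a]`` is ``(p0, pC, pD)`` of player ``i`` in layer
    ``a``; ``linked[i, a]`` is ``(p00, pCC, pCD, pDC, pDD)``.  Payoff
    caches are filled by :func:`player_payoffs`.
    """

    unlinked: np.ndarray
    linked: np.ndarray
    pi_alpha: Optional[np.ndarray] = None    # (N, 2)
    pi_total: Optional[np.ndarray] = None    # (N,)

    @classmethod
    def random(cls, n_players: int, rng: np.random.Generator) -> "PopulationState":
        return cls(
            unlinked=rng.random((n_players, 2, 3)),
            linked=rng.random((n_players, 2, 5)),
        )

    def unlinked_strategy(self, i: int) -> pe.UnlinkedStrategy:
        u = self.unlinked[i]
        return pe.UnlinkedStrategy(p0=u[:, 0], pC=u[:, 1], pD=u[:, 2])

    def linked_strategy(self, i: int) -> pe.LinkedStrategy:
        l = self.linked[i]
        return pe.LinkedStrategy(p0=l[:, 0], cond=l[:, 1:])


# ---------------------------------------------------------------------------
# elementary operations


def fermi_probability(f_A: float, f_B: float, s: float) -> float:
    """Probability that A imitates B under pairwise comparison."""
    if s < 0:
        raise ValueError("selection strength s must be >= 0")
    return expit(s * (np.asarray(f_B, dtype=float) - np.asarray(f_A, dtype=float)))


def classify_outcome(zeta1: float, zeta2: float) -> str:
    """Classify final cooperation rates into the standard outcome classes."""
    hi1, hi2 = zeta1 >= 0.8, zeta2 >= 0.8
    lo1, lo2 = zeta1 <= 0.2, zeta2 <= 0.2
    if hi1 and hi2:
        return "full"
    if hi1 and lo2:
        return "layer1_only"
    if hi2 and lo1:
        return "layer2_only"
    if lo1 and lo2:
        return "none"
    return "mixed"


# ---------------------------------------------------------------------------
# core per-step quantities (batched)


def _step_quantities(top: _Topology, unl: np.ndarray, lnk: np.ndarray,
                     games: GameSpec, w: float, eps: np.ndarray,
                     payoff_mat: Optional[np.ndarray] = None,
                     need_rates: bool = True):
    """Per-player payoffs and cooperation-rate numerators for one step.

    Returns ``(pi_alpha, gam, gam_cn, gam_un)``, each ``(NN, 2)``;
    ``pi_alpha`` is already degree-normalized.  When ``need_rates`` is
    false the gamma accumulators are skipped (returned as None).
    """
    NN = top.NN
    if payoff_mat is None:
        payoff_mat = games.payoff_matrix()
    unl_eff = _perceived_unlinked(unl, eps)
    lnk_eff = _perceived_linked(lnk, eps)

    pi = np.zeros((NN, 2))
    gam = np.zeros((NN, 2)) if need_rates else None
    gam_cn = np.zeros((NN, 2)) if need_rates else None
    gam_un = np.zeros((NN, 2)) if need_rates else None

    def _acc(buf, col, idx_u, idx_v, w_u, w_v):
        buf[:, col] += np.bincount(idx_u, weights=w_u, minlength=NN)
        buf[:, col] += np.bincount(idx_v, weights=w_v, minlength=NN)

    for a in (0, 1):
        edges = top.unique[a]
        if len(edges) == 0:
            continue
        u, v = edges[:, 0], edges[:, 1]
        vdist = _unlinked_layer_v(
            unl_eff[u, a, 0], unl_eff[u, a, 1], unl_eff[u, a, 2],
            unl_eff[v, a, 0], unl_eff[v, a, 1], unl_eff[v, a, 2], w,
        )
        R, S, T, P = payoff_mat[a]
        pi_u = vdist[:, 0] * R + vdist[:, 1] * S + vdist[:, 2] * T + vdist[:, 3] * P
        pi_v = vdist[:, 0] * R + vdist[:, 2] * S + vdist[:, 1] * T + vdist[:, 3] * P
        _acc(pi, a, u, v, pi_u, pi_v)
        if need_rates:
            g_u = vdist[:, 0] + vdist[:, 1]
            g_v = vdist[:, 0] + vdist[:, 2]
            _acc(gam, a, u, v, g_u, g_v)
            _acc(gam_un, a, u, v, g_u, g_v)

    if len(top.common):
        cu, cv = top.common[:, 0], top.common[:, 1]
        vdist = _linked_pair_v(
            lnk_eff[cu, :, 0], lnk_eff[cu, :, 1:],
            lnk_eff[cv, :, 0], lnk_eff[cv, :, 1:], w,
        )
        for a in (0, 1):
            R, S, T, P = payoff_mat[a]
            va = vdist[:, a, :]
            pi_u = va[:, 0] * R + va[:, 1] * S + va[:, 2] * T + va[:, 3] * P
            pi_v = va[:, 0] * R + va[:, 2] * S + va[:, 1] * T + va[:, 3] * P
            _acc(pi, a, cu, cv, pi_u, pi_v)
            if need_rates:
                g_u = va[:, 0] + va[:, 1]
                g_v = va[:, 0] + va[:, 2]
                _acc(gam, a, cu, cv, g_u, g_v)
                _acc(gam_cn, a, cu, cv, g_u, g_v)

    pi /= top.k
    return pi, gam, gam_cn, gam_un


def _population_rates(top: _Topology, gam, gam_cn, gam_un):
    """Population-average rates per run: ``zeta``, ``zeta_cn``, ``zeta_un``.

    Players without neighbors of a class are excluded from that class's
    average; an empty class yields NaN.
    """
    R, N = top.R, top.N

    def _avg(num, count):
        with np.errstate(invalid="ignore", divide="ignore"):
            per = np.where(count > 0, num / np.maximum(count, 1), np.nan)
        per = per.reshape(R, N, -1)
        valid = np.isfinite(per)
        out = np.where(
            valid.sum(axis=1) > 0,
            np.nansum(per, axis=1) / np.maximum(valid.sum(axis=1), 1),
            np.nan,
        )
        return out  # (R, 2)

    zeta = _avg(gam, top.k)
    zeta_cn = _avg(gam_cn, np.repeat(top.cn_count[:, None], 2, axis=1))
    zeta_un = _avg(gam_un, top.un_count)
    return zeta, zeta_cn, zeta_un


# ---------------------------------------------------------------------------
# strategy update


def _sample_neighbors(top: _Topology, layer_of_player: np.ndarray,
                      r_nbr: np.ndarray) -> np.ndarray:
    """Uniform random neighbor of each player in its assigned layer."""
    j = np.empty(top.NN, dtype=np.int64)
    common_flag = np.empty(top.NN, dtype=bool)
    for a in (0, 1):
        mask = layer_of_player == a
        if not mask.any():
            continue
        ids = np.nonzero(mask)[0]
        start = top.indptr[a][ids]
        deg = top.indptr[a][ids + 1] - start
        pos = start + np.floor(r_nbr[ids] * deg).astype(np.int64)
        j[ids] = top.indices[a][pos]
        common_flag[ids] = top.indices_common[a][pos]
    return j, common_flag


def _update_independent(top, unl, lnk, pi_total, mu, s, rng):
    NN = top.NN
    alpha_run = rng.integers(0, 2, size=top.R)
    alpha = np.repeat(alpha_run, top.N)
    r_mut = rng.random(NN)
    mut_unl = rng.random((NN, 3))
    mut_lnk = rng.random((NN, 5))
    r_nbr = rng.random(NN)
    r_acc = rng.random(NN)

    j, _ = _sample_neighbors(top, alpha, r_nbr)
    accept = r_acc < expit(s * (pi_total[j] - pi_total))
    mut = r_mut < mu
    imitate = (~mut) & accept

    new_unl = unl.copy()
    new_lnk = lnk.copy()
    rows = np.arange(NN)
    src = j
    for a in (0, 1):
        sel = imitate & (alpha == a)
        new_unl[rows[sel], a] = unl[src[sel], a]
        new_lnk[rows[sel], a] = lnk[src[sel], a]
        msel = mut & (alpha == a)
        new_unl[rows[msel], a] = mut_unl[msel]
        new_lnk[rows[msel], a] = mut_lnk[msel]
    return new_unl, new_lnk


def _update_simultaneous(top, unl, lnk, pi_total, mu, s, rng):
    NN = top.NN
    new_unl = unl.copy()
    new_lnk = lnk.copy()
    rows = np.arange(NN)
    for a in (0, 1):
        r_mut = rng.random(NN)
        mut_unl = rng.random((NN, 3))
        mut_lnk = rng.random((NN, 5))
        r_nbr = rng.random(NN)
        r_acc = rng.random(NN)
        layer = np.full(NN, a)
        j, common_flag = _sample_neighbors(top, layer, r_nbr)
        accept = r_acc < expit(s * (pi_total[j] - pi_total))
        mut = r_mut < mu
        imitate = (~mut) & accept

        full_copy = imitate & common_flag
        new_unl[rows[full_copy]] = unl[j[full_copy]]
        new_lnk[rows[full_copy]] = lnk[j[full_copy]]
        part_copy = imitate & ~common_flag
        new_unl[rows[part_copy], a] = unl[j[part_copy], a]
        new_lnk[rows[part_copy], a] = lnk[j[part_copy], a]
        new_unl[rows[mut], a] = mut_unl[mut]
        new_lnk[rows[mut], a] = mut_lnk[mut]
    return new_unl, new_lnk


# ---------------------------------------------------------------------------
# public single-run operations


def player_payoffs(
    state: PopulationState,
    net: MultiplexNetwork,
    games: GameSpec,
    w: float = 1.0,
    mem: Optional[pe.PerceptionError] = None,
    mode: str = "mixed",
):
    """Degree-normalized per-layer payoffs and totals for every player.

    Fills the state's payoff caches and returns ``(pi_alpha, pi_total)``.
    """
    top = _Topology([net], mode)
    eps = mem.eps if mem is not None else np.zeros(2)
    pi, _, _, _ = _step_quantities(top, state.unlinked, state.linked, games, w, eps)
    state.pi_alpha = pi
    state.pi_total = pi.sum(axis=1)
    return state.pi_alpha, state.pi_total


def population_rates(
    state: PopulationState,
    net: MultiplexNetwork,
    games: Optional[GameSpec] = None,
    w: float = 1.0,
    mem: Optional[pe.PerceptionError] = None,
    mode: str = "mixed",
) -> dict:
    """Per-player and population cooperation rates by neighbor class.

    ``games`` only sets the layer count context; rates are payoff-free.
    Returns per-player ``zeta_i``, ``zeta_i_cn``, ``zeta_i_un`` (NaN for
    empty classes) and the population averages ``zeta``, ``zeta_cn``,
    ``zeta_un``.
    """
    if games is None:
        from .games import donation_game
        games = GameSpec((donation_game(2, 1), donation_game(2, 1)))
    top = _Topology([net], mode)
    eps = mem.eps if mem is not None else np.zeros(2)
    _, gam, gam_cn, gam_un = _step_quantities(
        top, state.unlinked, state.linked, games, w, eps
    )
    zeta, zeta_cn, zeta_un = _population_rates(top, gam, gam_cn, gam_un)
    with np.errstate(invalid="ignore", divide="ignore"):
        zi = gam / top.k
        zi_cn = np.where(top.cn_count[:, None] > 0,
                         gam_cn / np.maximum(top.cn_count[:, None], 1), np.nan)
        zi_un = np.where(top.un_count > 0,
                         gam_un / np.maximum(top.un_count, 1), np.nan)
    return {
        "zeta_i": zi, "zeta_i_cn": zi_cn, "zeta_i_un": zi_un,
        "zeta": zeta[0], "zeta_cn": zeta_cn[0], "zeta_un": zeta_un[0],
    }


def update_step(
    state: PopulationState,
    net: MultiplexNetwork,
    scheme: str,
    mu: float,
    s: float,
    rng: np.random.Generator,
    mode: str = "mixed",
) -> PopulationState:
    """One synchronous mutation–imitation sweep (payoff caches must be current)."""
    if scheme not in _SCHEMES:
        raise ValueError(f"scheme must be one of {_SCHEMES}")
    if state.pi_total is None:
        raise ValueError("payoff caches stale: call player_payoffs first")
    top = _Topology([net], mode)
    fn = _update_independent if scheme == "independent" else _update_simultaneous
    new_unl, new_lnk = fn(top, state.unlinked, state.linked, state.pi_total, mu, s, rng)
    return PopulationState(unlinked=new_unl, linked=new_lnk)


# ---------------------------------------------------------------------------
# simulation loops


def _run_batch(nets: Sequence[MultiplexNetwork], config: SimulationConfig,
               seed: Optional[int]) -> list[SimulationResult]:
    top = _Topology(nets, config.mode)
    rng = np.random.default_rng(seed)
    eps = np.asarray(config.eps, dtype=float)
    NN = top.NN
    unl = rng.random((NN, 2, 3))
    lnk = rng.random((NN, 2, 5))

    update = (_update_independent if config.scheme == "independent"
              else _update_simultaneous)

    rec_steps = []
    rec_z, rec_zcn, rec_zun = [], [], []

    def record(step, gam, gam_cn, gam_un):
        zeta, zcn, zun = _population_rates(top, gam, gam_cn, gam_un)
        rec_steps.append(step)
        rec_z.append(zeta)
        rec_zcn.append(zcn)
        rec_zun.append(zun)

    payoff_mat = config.games.payoff_matrix()
    for t in range(config.steps):
        recording = t % config.record_stride == 0
        pi, gam, gam_cn, gam_un = _step_quantities(
            top, unl, lnk, config.games, config.w, eps,
            payoff_mat=payoff_mat, need_rates=recording,
        )
        if recording:
            record(t, gam, gam_cn, gam_un)
        unl, lnk = update(top, unl, lnk, pi.sum(axis=1), config.mu, config.s, rng)
    # final state
    _, gam, gam_cn, gam_un = _step_quantities(
        top, unl, lnk, config.games, config.w, eps, payoff_mat=payoff_mat
    )
    record(config.steps, gam, gam_cn, gam_un)

    rec_steps = np.array(rec_steps)
    z = np.stack(rec_z)        # (T, R, 2)
    zcn = np.stack(rec_zcn)
    zun = np.stack(rec_zun)
    W = min(config.window, len(rec_steps))

    results = []
    for r in range(top.R):
        final_z = z[-W:, r, :].mean(axis=0)
        with np.errstate(invalid="ignore"):
            final_zcn = np.nanmean(zcn[-W:, r, :], axis=0) if np.isfinite(
                zcn[-W:, r, :]).any() else np.full(2, np.nan)
            final_zun = np.nanmean(zun[-W:, r, :], axis=0) if np.isfinite(
                zun[-W:, r, :]).any() else np.full(2, np.nan)
        sl = slice(r * top.N, (r + 1) * top.N)
        results.append(SimulationResult(
            record_steps=rec_steps,
            zeta=z[:, r, :], zeta_cn=zcn[:, r, :], zeta_un=zun[:, r, :],
            final_zeta=final_z, final_zeta_cn=final_zcn, final_zeta_un=final_zun,
            category=classify_outcome(final_z[0], final_z[1]),
            mean_unlinked=unl[sl].mean(axis=0),
            mean_linked=lnk[sl].mean(axis=0),
            seed=seed, config=config,
        ))
    return results


def run_simulation(net: MultiplexNetwork, config: SimulationConfig,
                   seed: Optional[int] = None) -> SimulationResult:
    """Run the evolutionary dynamics on one network; reproducible from seed."""
    return _run_batch([net], config, seed)[0]


def run_ensemble(nets: Sequence[MultiplexNetwork], config: SimulationConfig,
                 seed: Optional[int] = None) -> list[SimulationResult]:
    """Run one replicate per network as a single batched simulation.

    All replicates advance together, sharing the vectorized pair
    computations, which is considerably faster than looping over
    :func:`run_simulation`.
    """
    return _run_batch(list(nets), config, seed)
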