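"""Reduced-strategy analysis: LGTFT vs ALLD vs ALLC.

The full reactive-strategy space is approximated by three named
strategies: linked generous tit-for-tat ``LGTFT(q) = (1, 1, q, q, q; 1,
1, q, q, q)`` (cooperate after mutual cooperation, otherwise cooperate
with generosity ``q`` in both games), ``ALLD`` and ``ALLC``.  With
``q = 0`` LGTFT reduces to linked TFT.

Analytic invasion conditions for LGTFT entering an ALLD resident
population bound the benefit-to-cost sum ratio ``(b1+b2)/(c1+c2)``:
``[3 - 2(1-q)w] / [(1-q)w]`` in a well-mixed population, reduced by a
``3(1-(1-q)w) / [(k+1)(1-q)w]`` term on a degree-``k`` graph.  The
generosity threshold ``q* = [(b1+b2)-(c1+c2)] / [(b1+b2)+(c1+c2)]``
bounds the window in which LGTFT and ALLD coexist under weak selection.

Because the strategy set is finite and imitation copies whole
strategies, the dynamics reduce to label dynamics: pairwise payoffs are
precomputed once per ordered strategy pair with the exact pair engine
and looked up per step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import binomtest

from .games import GameSpec
from .multiplex import MultiplexNetwork
from . import pair_engine as pe

__all__ = [
    "ReducedStrategy",
    "make_reduced",
    "q_star",
    "invasion_threshold",
    "fixation_probability",
    "FixationResult",
    "three_strategy_run",
    "ThreeStrategyResult",
]

_NAMES = ("LGTFT", "LTFT", "ALLD", "ALLC")


@dataclass(frozen=True)
class ReducedStrategy:
    """A named strategy of the reduced three-strategy system."""

    name: str
    q: float
    linked: pe.LinkedStrategy

    def __eq__(self, other):
        return (
            isinstance(other, ReducedStrategy)
            and np.allclose(self.linked.as_tuple(), other.linked.as_tuple())
        )


def make_reduced(name: str, q: float = 0.0) -> ReducedStrategy:
    """Build a named reduced strategy; ``q`` applies to LGTFT only."""
    if name not in _NAMES:
        raise ValueError(f"unknown reduced strategy {name!r}; choose from {_NAMES}")
    if name == "LTFT":
        name, q = "LGTFT", 0.0
    if name == "LGTFT":
        if not (0.0 <= q <= 1.0):
            raise ValueError("generosity q must lie in [0, 1]")
        vec = (1, 1, q, q, q, 1, 1, q, q, q)
    elif name == "ALLD":
        vec, q = (0,) * 10, 0.0
    else:  # ALLC
        vec, q = (1,) * 10, 0.0
    return ReducedStrategy(name=name, q=float(q),
                           linked=pe.LinkedStrategy.from_tuple(vec))


def q_star(b1: float, b2: float, c1: float, c2: float) -> float:
    """Generosity threshold ``q* = (B - C) / (B + C)`` with B = b1+b2, C = c1+c2."""
    B, C = b1 + b2, c1 + c2
    if not (B >= C > 0):
        raise ValueError("requires b1 + b2 >= c1 + c2 > 0")
    return (B - C) / (B + C)


def invasion_threshold(q: float, w: float, k: Optional[int] = None) -> float:
    """Critical ``(b1+b2)/(c1+c2)`` for LGTFT to invade an ALLD resident.

    ``k=None`` gives the well-mixed bound ``[3 - 2(1-q)w] / [(1-q)w]``;
    a finite degree ``k`` subtracts the network correction
    ``3(1 - (1-q)w) / [(k+1)(1-q)w]``, which vanishes as ``k`` grows and
    makes invasion strictly easier on sparse graphs.
    """
    g = (1.0 - q) * w
    if g <= 0:
        raise ValueError("threshold undefined: (1-q) w must be positive")
    base = (3.0 - 2.0 * g) / g
    if k is None:
        return base
    if k < 1:
        raise ValueError("degree k must be >= 1")
    return base - 3.0 * (1.0 - g) / ((k + 1) * g)


# ---------------------------------------------------------------------------
# label dynamics


def _pair_tables(strategies: Sequence[ReducedStrategy], games: GameSpec, w: float):
    """Pairwise payoff and cooperation-rate lookup tables.

    ``P[a, b, l]``: layer-``l`` payoff of an ``a``-player against a
    ``b``-player; ``G`` likewise for cooperation rates.  Computed once
    with the exact pair engine (Cesàro limits handle the deterministic
    strategies at ``w = 1``).
    """
    L = len(strategies)
    P = np.zeros((L, L, 2))
    G = np.zeros((L, L, 2))
    for a in range(L):
        for b in range(L):
            out = pe.pair_outcome(strategies[a].linked, strategies[b].linked,
                                  games, w=w)
            P[a, b] = out.pi_ij
            G[a, b] = out.gamma_ij
    return P, G


class _LabelDynamics:
    """Whole-strategy imitation dynamics over a finite strategy set.

    ``net=None`` means well-mixed (everyone interacts with everyone).
    Both multiplex layers are assumed identical (O = 1), so linked play
    applies on every edge and one adjacency serves both layers.
    """

    def __init__(self, strategies, games, w, net: Optional[MultiplexNetwork],
                 n_nodes: Optional[int] = None):
        self.strategies = list(strategies)
        self.L = len(self.strategies)
        self.P, self.G = _pair_tables(self.strategies, games, w)
        if net is not None:
            if net.edge_set(0) != net.edge_set(1):
                raise ValueError("label dynamics requires identical layers (O = 1)")
            self.N = net.n_nodes
            deg = net.degrees(0)
            if np.any(deg == 0):
                raise ValueError("all nodes need positive degree")
            self.k = deg.astype(float)
            e = net.edges(0)
            src = np.concatenate([e[:, 0], e[:, 1]])
            dst = np.concatenate([e[:, 1], e[:, 0]])
            order = np.argsort(src, kind="stable")
            self.adj_indices = dst[order]
            self.adj_indptr = np.concatenate(
                [[0], np.cumsum(np.bincount(src, minlength=self.N))]
            )
            self.wellmixed = False
        else:
            if n_nodes is None:
                raise ValueError("well-mixed dynamics needs n_nodes")
            self.N = int(n_nodes)
            self.k = np.full(self.N, self.N - 1, dtype=float)
            self.wellmixed = True

    def payoffs(self, labels: np.ndarray) -> np.ndarray:
        """Total (both-layer) expected payoff of every player."""
        counts = self.neighbor_label_counts(labels)
        ptab = self.P.sum(axis=2)  # (L, L) payoff summed over layers
        return (counts * ptab[labels]).sum(axis=1) / self.k

    def neighbor_label_counts(self, labels: np.ndarray) -> np.ndarray:
        onehot = np.eye(self.L)[labels]
        if self.wellmixed:
            return onehot.sum(axis=0)[None, :] - onehot
        counts = np.zeros((self.N, self.L))
        seg = np.repeat(np.arange(self.N), np.diff(self.adj_indptr))
        np.add.at(counts, seg, onehot[self.adj_indices])
        return counts

    def cooperation_rate(self, labels: np.ndarray) -> np.ndarray:
        """Population cooperation rate per layer."""
        counts = self.neighbor_label_counts(labels)
        out = np.empty(2)
        for a in (0, 1):
            out[a] = ((counts * self.G[labels, :, a]).sum(axis=1) / self.k).mean()
        return out

    def sample_neighbor(self, rng: np.random.Generator) -> np.ndarray:
        if self.wellmixed:
            j = rng.integers(0, self.N - 1, size=self.N)
            j += j >= np.arange(self.N)   # skip self
            return j
        start = self.adj_indptr[:-1]
        deg = np.diff(self.adj_indptr)
        pos = start + np.floor(rng.random(self.N) * deg).astype(np.int64)
        return self.adj_indices[pos]

    def step(self, labels: np.ndarray, mu: float, s: float,
             rng: np.random.Generator) -> np.ndarray:
        """One synchronous sweep: mutate (uniform label) or Fermi-imitate."""
        f = self.payoffs(labels) if s > 0 else np.zeros(self.N)
        r_mut = rng.random(self.N)
        mut_label = rng.integers(0, self.L, size=self.N)
        j = self.sample_neighbor(rng)
        accept = rng.random(self.N) < expit(s * (f[j] - f))
        new = labels.copy()
        imit = (r_mut >= mu) & accept
        new[imit] = labels[j[imit]]
        mut = r_mut < mu
        new[mut] = mut_label[mut]
        return new


@dataclass
class FixationResult:
    """Fixation-probability estimate with a Clopper-Pearson interval."""

    estimate: float
    ci_low: float
    ci_high: float
    n_fixed: int
    n_lost: int
    n_censored: int
    n_trials: int


def _padded_neighbors(net: Optional[MultiplexNetwork], n_nodes: Optional[int]):
    """Neighbor matrix (N, k_max) padded with self-index, plus degrees."""
    if net is None:
        if n_nodes is None:
            raise ValueError("well-mixed dynamics needs n_nodes")
        N = int(n_nodes)
        nbr = np.empty((N, N - 1), dtype=np.int64)
        for i in range(N):
            nbr[i] = np.concatenate([np.arange(i), np.arange(i + 1, N)])
        return nbr, np.full(N, N - 1, dtype=np.int64)
    if net.edge_set(0) != net.edge_set(1):
        raise ValueError("label dynamics requires identical layers (O = 1)")
    N = net.n_nodes
    deg = net.degrees(0)
    if np.any(deg == 0):
        raise ValueError("all nodes need positive degree")
    kmax = int(deg.max())
    nbr = np.tile(np.arange(N)[:, None], (1, kmax))
    fill = np.zeros(N, dtype=np.int64)
    for u, v in net.edge_set(0):
        nbr[u, fill[u]] = v
        fill[u] += 1
        nbr[v, fill[v]] = u
        fill[v] += 1
    return nbr, deg.astype(np.int64)


def fixation_probability(
    mutant: ReducedStrategy,
    resident: ReducedStrategy,
    net: Optional[MultiplexNetwork],
    games: GameSpec,
    w: float = 0.5,
    s: float = 0.01,
    n_trials: int = 1000,
    seed: Optional[int] = None,
    n_nodes: Optional[int] = None,
    max_steps: int = 10_000_000,
) -> FixationResult:
    """Estimate the fixation probability of a single mutant.

    One mutant is placed uniformly at random in a resident population
    and mutation-free pairwise-comparison dynamics run to absorption:
    each elementary update picks a random player and a random neighbor
    and copies the neighbor's whole strategy with the Fermi probability.
    This asynchronous process is the one the analytic invasion
    thresholds describe; under neutrality (``s = 0``) the estimate
    approaches ``1/N`` on regular graphs.  Trials exceeding
    ``max_steps`` elementary updates are censored, never counted as
    fixation.  All trials advance together in a vectorized batch.
    """
    P, _ = _pair_tables([resident, mutant], games, w)
    Pt = P.sum(axis=2)                     # total payoff lookup (2, 2)
    nbr, deg = _padded_neighbors(net, n_nodes)
    N = len(deg)
    rng = np.random.default_rng(seed)

    labels = np.zeros((n_trials, N), dtype=np.int8)
    labels[np.arange(n_trials), rng.integers(0, N, size=n_trials)] = 1
    # cnt[b, i]: number of mutant neighbors of node i in trial b
    pad_mask = nbr != np.arange(N)[:, None]
    cnt = (labels[:, nbr] * pad_mask).sum(axis=2)
    nm = labels.sum(axis=1).astype(np.int64)
    active = np.ones(n_trials, dtype=bool)
    trials_idx = np.arange(n_trials)

    for _ in range(max_steps):
        idx = trials_idx[active]
        if len(idx) == 0:
            break
        nb = len(idx)
        i = rng.integers(0, N, size=nb)
        pos = np.floor(rng.random(nb) * deg[i]).astype(np.int64)
        j = nbr[i, pos]
        li = labels[idx, i]
        lj = labels[idx, j]
        r = rng.random(nb)
        diff = li != lj
        if diff.any():
            ci = cnt[idx, i]
            cj = cnt[idx, j]
            fi = (ci * Pt[li, 1] + (deg[i] - ci) * Pt[li, 0]) / deg[i]
            fj = (cj * Pt[lj, 1] + (deg[j] - cj) * Pt[lj, 0]) / deg[j]
            flip = diff & (r < expit(s * (fj - fi)))
            if flip.any():
                fb = idx[flip]
                fnode = i[flip]
                newl = lj[flip]
                labels[fb, fnode] = newl
                delta = 2 * newl.astype(np.int64) - 1
                touched = nbr[fnode]                      # (F, kmax)
                np.add.at(cnt, (np.broadcast_to(fb[:, None], touched.shape),
                                touched), delta[:, None] * pad_mask[fnode])
                nm[fb] += delta
                active[fb] = (nm[fb] > 0) & (nm[fb] < N)

    n_censored = int(active.sum())
    n_fixed = int(((nm == N) & ~active).sum())
    n_lost = int(((nm == 0) & ~active).sum())
    n_done = n_fixed + n_lost
    est = n_fixed / n_done if n_done else float("nan")
    if n_done:
        ci_ = binomtest(n_fixed, n_done).proportion_ci(confidence_level=0.95)
        lo, hi = ci_.low, ci_.high
    else:
        lo = hi = float("nan")
    return FixationResult(est, lo, hi, n_fixed, n_lost, n_censored, n_trials)


@dataclass
class ThreeStrategyResult:
    """Long-run composition of the {ALLC, ALLD, LGTFT} competition."""

    composition: np.ndarray        # (3,) frequencies in (ALLC, ALLD, LGTFT) order
    cooperation_rate: float        # both-layer average over the window
    cooperation_by_layer: np.ndarray
    strategies: tuple = ("ALLC", "ALLD", "LGTFT")


def three_strategy_run(
    q: float,
    b1: float,
    b2: float,
    c1: float = 1.0,
    c2: float = 1.0,
    s: float = 0.01,
    mu: float = 0.001,
    net: Optional[MultiplexNetwork] = None,
    n_nodes: int = 200,
    w: float = 1.0,
    steps: int = 100_000,
    window: int = 1000,
    seed: Optional[int] = None,
) -> ThreeStrategyResult:
    """Simulate the three-strategy competition and average the tail window.

    Mutation redraws a player's strategy uniformly among the three; the
    composition and cooperation rate are averaged over the final
    ``window`` steps.
    """
    games = GameSpec.donation((b1, b2), (c1, c2))
    strategies = [make_reduced("ALLC"), make_reduced("ALLD"), make_reduced("LGTFT", q)]
    dyn = _LabelDynamics(strategies, games, w, net, n_nodes=n_nodes)
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 3, size=dyn.N)
    comp_acc = np.zeros(3)
    coop_acc = np.zeros(2)
    n_acc = 0
    for t in range(steps):
        labels = dyn.step(labels, mu, s, rng)
        if t >= steps - window:
            comp_acc += np.bincount(labels, minlength=3) / dyn.N
            coop_acc += dyn.cooperation_rate(labels)
            n_acc += 1
    comp = comp_acc / max(n_acc, 1)
    coop = coop_acc / max(n_acc, 1)
    return ThreeStrategyResult(
        composition=comp,
        cooperation_rate=float(coop.mean()),
        cooperation_by_layer=coop,
    )
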