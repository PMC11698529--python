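# Methods

## Model

A population of `N` players occupies the shared node set of a two-layer
multiplex network. In each layer `α` a repeated symmetric 2×2 game with
payoffs `(R_α, S_α, T_α, P_α)` is played along that layer's edges, with
continuation probability `w` per round (`w = 1`: infinitely repeated).
Players use *reactive* strategies — the next move depends only on the
co-player's previous action(s):

- against **common neighbors** (connected in both layers) a *linked*
  strategy conditions the move in each game on the co-player's last
  action pair across both games: the 10-tuple
  `(p00^1, pCC^1, pCD^1, pDC^1, pDD^1; p00^2, …, pDD^2)`;
- against **unique neighbors** (connected in one layer only) an
  *unlinked* per-layer triple `(p0^α, pC^α, pD^α)` conditions only on
  the co-player's last move in the same game.

Unlinked strategies are exactly the linked strategies that ignore the
other game (`p_{a1,a2}^α = p_{aα}^α`); the package exposes this
embedding and tests the two engines against each other through it.

Structural similarity between layers is measured by the average edge
overlap `O = |E¹∩E²| / |E¹∪E²|` (Jaccard). `O = 1` means identical
layers (every neighbor common), `O = 0` edge-disjoint layers (every
neighbor unique).

### Pair outcomes

One repeated pair interaction is a Markov chain on the joint action
state `(a_i^1, a_i^2, a_j^1, a_j^2)` (16 states; 4 per layer for
unlinked play). The engine computes, exactly:

- for `w < 1`, the normalized discounted visit distribution
  `(1−w) Σ_t w^t v0 M^t` via a linear solve;
- for `w = 1`, the Cesàro (long-run time-average) distribution from the
  initial state. The chain's support graph is decomposed into strongly
  connected components (`scipy.sparse.csgraph`); bottom components are
  the recurrent classes, absorption probabilities are solved on the
  transient part, and each recurrent class contributes its stationary
  vector (which equals the Cesàro average even for periodic classes).
  This handles deterministic strategies — e.g. the both-or-nothing
  resident `(1,0,0,1; 1,0,0,1)` against a single-layer defector
  `(0,0,0,0; 1,0,0,1)` locks into the state paying the resident `b_2`
  and the defector `−c_2`.

Per-layer payoffs and cooperation rates are linear in the per-layer
visit distribution `v^α` over (CC, CD, DC, DD):
`π_ij^α = v·(R,S,T,P)` and `γ_ij^α = v_CC + v_CD`. For the donation
game the identity `π_ij^α = b_α γ_ji^α − c_α γ_ij^α` holds exactly and
is asserted in tests.

**Fast path used by the population engine.** For reactive strategies
the two players' action pairs remain independent round by round, so the
16-state chain factors: each player's action-pair distribution is
summarized by three moments `(q1, q2, q12)` = (P(C in game 1), P(C in
game 2), P(C in both)), and each strategy induces an *affine* map from
the opponent's moments to the player's. The stationary outcome is the
fixed point of the composition — one 3×3 linear solve per pair,
vectorized (numba) over every edge of every replicate. The same
factorization gives a scalar closed form for unlinked pairs. Both fast
paths are verified against the general chain engine to ~1e−15;
near-singular (degenerate, measure-zero) pairs fall back to the general
Cesàro path automatically.

Perception error (imperfect memory) `ε = (ε1, ε2)` replaces each
player's conditional response by its mixture over mis-recalled opponent
actions (independent flips per game); first-round probabilities are
untouched. The error enters the player's *own* recall only, so it is a
linear transform of the strategy applied before pair evaluation.

### Population dynamics

Each time step, every realized pair interaction is evaluated as an
*expected* outcome (no sampled rounds). Player payoffs are
degree-normalized per layer and summed across layers:
`π_i = Σ_α (1/k_i^α) Σ_j π_ij^α`. Strategies then update
synchronously — all copies reference the pre-step snapshot, which makes
runs bit-reproducible from the seed:

- **independent scheme**: one layer `α` is drawn per step; each player
  either redraws its layer-`α` strategy components uniformly on [0,1]
  (probability `μ`) or picks a uniform random layer-`α` neighbor and
  copies that neighbor's layer-`α` components (5 linked + 3 unlinked
  entries) with the Fermi probability `1/(1+exp(−s(π_B−π_A)))`;
- **simultaneous scheme**: every player updates in every layer;
  imitating a common neighbor copies the full strategy set across
  layers, a unique neighbor only that layer's components.

Layer-restricted copying under the independent scheme is what lets
single-layer defectors (`(0,0,0,0; 1,0,0,1)`) arise from a cooperative
resident — the mechanism behind the robustness of linked cooperation.

Interaction modes: `mixed` (linked play on common edges, unlinked on
unique ones — the general model), `unlinked` (every edge treated as two
independent games) and `linked` (linked play on every edge; requires
identical layers, `O = 1`).

Recorded observables per step: population cooperation rate `ζ^α`
(all neighbors), `ζ_CN^α` (common neighbors, linked play) and
`ζ̄_UN^α` (unique neighbors); players without neighbors of a class are
excluded from that class's average. Final outcomes are classified from
the mean over a terminal window (default: the last 1,000 recorded
steps) as *full* (both `ζ^α ≥ 0.8`), *layer-α only* (`≥ 0.8` vs
`≤ 0.2`), *none* (both `≤ 0.2`), else *mixed*.

### Network generation

Layer 1 is drawn from the requested topology (random-regular via
configuration-model matching, scale-free via preferential attachment
with `m = k/2`, or complete; all through networkx). Layer 2 starts as
an exact copy and undergoes degree-preserving double-edge swaps,
accepting a swap only if it moves the shared-edge count toward the
value implied by the target overlap (`I* = 2|E|·O/(1+O)`), until the
measured overlap is within tolerance (default 0.02) or a swap budget
(`200·|E|` attempts) is exhausted (then an error — never a silent
miss). Both layers therefore have identical per-node degrees at every
overlap, isolating the effect of overlap from degree effects.

### Reduced-strategy analysis

The three-strategy system {ALLC, ALLD, LGTFT(q)} with
`LGTFT(q) = (1,1,q,q,q; 1,1,q,q,q)` collapses the dynamics to label
dynamics: pairwise payoff/cooperation tables are precomputed once with
the exact pair engine and looked up per step.

- `q* = [(b1+b2)−(c1+c2)] / [(b1+b2)+(c1+c2)]` bounds the generosity
  window; for `2q*−1 < q < q*` LGTFT and ALLD coexist under weak
  selection.
- Invasion thresholds on `(b1+b2)/(c1+c2)` for LGTFT entering ALLD:
  well-mixed `[3−2(1−q)w]/[(1−q)w]`; on a degree-`k` graph the
  correction `−3(1−(1−q)w)/[(k+1)(1−q)w]` applies. This is the single
  algebraically coherent grouping of the condition: it reduces to the
  well-mixed form as `k → ∞`, is strictly lower for finite `k`, and
  the simulated fixation probability crosses `1/N` at the predicted
  benefit (b1 ≈ 4.5 at k=3, w=0.5, q=0, b2=2) within sampling error.
- `fixation_probability` uses *asynchronous* pairwise comparison (one
  random player copies one random neighbor's whole strategy per
  elementary update, Fermi acceptance), vectorized across trials. This
  is a deliberate design choice: the analytic `(k+1)`-type invasion
  conditions describe asynchronous imitation, and empirically the
  synchronous sweep scheme shifts the `1/N` crossing far above the
  predicted benefit while the asynchronous process matches it. Neutral
  (`s = 0`) fixation is `1/N` on regular graphs in both schemes
  (martingale argument), which the tests verify. Trials hitting the
  step cap are reported as censored, never as fixations.
- `three_strategy_run` keeps the synchronous per-step sweep of the main
  model (whole-strategy copies, mutation drawing uniformly among the
  three strategies) and averages composition and cooperation rate over
  the final window.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| `b_α`, `c_α` | benefit/cost of cooperation per game | (5, 3), (1, 1) | canonical unequal-benefit pair used throughout the main experiments |
| `N`, `k` | population size, per-layer degree | 100, 4 | sparse-regular reference case |
| `O` | average edge overlap | 1.0 | identical layers unless sweeping overlap |
| `μ` | exploration (mutation) probability | 0.001 | low-mutation regime |
| `w` | continuation probability | 1.0 | infinitely repeated games; first-round probabilities irrelevant |
| `s` | selection intensity (Fermi) | 2.0 | strong-but-finite selection |
| `ε_IM^α` | perception-error probability per game | 0.0 | perfect memory unless studying imperfect recall |
| steps | update steps per run | 60,000 | rates plateau well within this horizon at k=4 |
| window | terminal classification window | last 1,000 steps | averages out step-to-step fluctuation |

## What the synthetic generator emulates — and what it does not

All experiments run on synthetic networks (random-regular or
scale-free layers with controlled overlap) and synthetic initial
strategies (iid uniform components, matching the mutation kernel).
This emulates the study conditions of the model: identical degree
sequences across layers, tunable structural overlap, no degree-overlap
correlation. Real multiplex networks (the edge-list reader supports
them) have heterogeneous degrees, clustering, and node-level overlap
variation that the generator deliberately omits; passing tests
therefore validate the mechanism (overlap → strategy linking →
cooperation), not quantitative predictions for any empirical network.

## Numerical choices

- Stationary/Cesàro tolerance: recurrent-class support threshold 1e−10;
  near-singular fixed-point fallback threshold |det| < 1e−9; visit
  distributions renormalized and clipped at 0.
- Discounted iterations truncate when the residual geometric weight
  falls below 1e−14 of the leading weight, then renormalize, so the
  result sums to 1 exactly.
- Mutation draws are uniform on [0,1); interior strategies are
  therefore generic and the fast fixed-point path is essentially always
  valid (the fallback handles hand-constructed deterministic cases).
- Monotone-overlap rewiring accepts distance-neutral swaps with
  probability 1/2 to keep the walk mixing on plateaus.
- Fermi probabilities go through `scipy.special.expit` (no overflow).
- Ensembles of replicates advance as one batched system; replicate `r`
  of an ensemble is *not* bitwise-identical to a standalone run with
  the same seed (the batch shares one RNG stream), but any given call
  is fully reproducible from its seed.

## Problem sizes used in tests and acceptance runs

Replicate counts are reduced relative to the published-style settings
(20 instead of 100–500 runs; 60,000 steps for the cooperation-rate and
sculling runs and 100,000 for the imperfect-memory runs; the
perception-error grid uses four ε values at 12 replicates; the overlap
sweep uses k = 16, 8 replicates, 40,000 steps). Monte-Carlo standard
errors are
reported alongside all aggregates so comparisons use uncertainty-aware
tolerances. Fixation estimates in tests use 2×10⁴ trials at N = 50,
k = 3.

## Known limitations

- Dynamics are restricted to two layers (overlap metrics generalize to
  m ≥ 2).
- No implementation error (action noise): the imperfect-memory model
  perturbs recall only.
- Memory-one and longer-memory strategies are out of scope; the
  reactive factorization the fast path exploits would not survive
  conditioning on one's own previous action.
- The simultaneous scheme resolves cross-layer write conflicts by
  applying layer-2 updates after layer-1 within the synchronous step;
  other conflict rules are defensible.
- In coordination-class (stag-hunt) games the population outcome is
  bimodal — runs settle into either the full-cooperation or the
  one-layer-cooperation basin and switch between them only on very long
  timescales. The *fraction* of runs entering each basin is therefore
  the observable most sensitive to unprinted details of the update
  process and the initial strategy distribution; the mean rates within
  a basin are robust. Copy-scope variants of the independent scheme
  were compared during development and do not move this fraction.
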