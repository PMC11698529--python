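"""Preset experiments, fixtures and result aggregation.

Each preset bundles the parameters of one published-style experiment
(network topology, games, dynamics parameters, replicate and step
counts) and can be scaled down uniformly for quick runs: ``scale``
multiplies both the number of replicates and, for the longest runs, the
step count.  Outputs are plain CSV/JSON files with the seed and a
config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .games import GameSpec
from .multiplex import MultiplexNetwork, generate_multiplex, average_edge_overlap
from .evolution import SimulationConfig, run_ensemble
from .reduced import fixation_probability, make_reduced, three_strategy_run
from . import pair_engine as pe

__all__ = ["ExperimentConfig", "PRESETS", "run_preset", "make_fixture",
           "ensemble_summary", "generate_ensemble_nets"]


# Base parameter sets.  Donation games b=(5,3), c=(1,1) with mu=0.001,
# w=1, s=2 on N=100 RRN layers recur throughout; presets override pieces.
_BASE_NET = {"topology": "rrn", "n_nodes": 100, "degree": 4, "overlap": 1.0}
_BASE_GAMES = {"family": "donation", "b": (5.0, 3.0), "c": (1.0, 1.0)}

PRESETS: dict[str, dict] = {
    "fig2_unlinked": {
        "kind": "evolution", "net": _BASE_NET, "games": _BASE_GAMES,
        "config": {"mode": "unlinked", "scheme": "independent", "mu": 1e-3,
                   "w": 1.0, "s": 2.0, "steps": 60_000},
        "n_runs": 200,
    },
    "fig2_linked": {
        "kind": "evolution", "net": _BASE_NET, "games": _BASE_GAMES,
        "config": {"mode": "linked", "scheme": "independent", "mu": 1e-3,
                   "w": 1.0, "s": 2.0, "steps": 60_000},
        "n_runs": 200,
    },
    "fig3": {
        "kind": "evolution", "net": _BASE_NET, "games": _BASE_GAMES,
        "config": {"mode": "linked", "scheme": "simultaneous", "mu": 1e-3,
                   "w": 1.0, "s": 2.0, "steps": 60_000},
        "n_runs": 100,
    },
    "fig5": {
        "kind": "fixation", "net": {**_BASE_NET, "degree": 3},
        "b1_grid": [2.0, 3.0, 4.0, 5.0, 6.0, 7.0], "k_grid": [3, 5],
        "b2": 2.0, "c": 1.0, "w": 0.5, "s": 0.01, "q": 0.0,
        "n_trials": 1_000_000,
    },
    "fig6": {
        "kind": "simplex", "n_nodes": 200, "b1": 4.0, "b2": 2.0, "c": 1.0,
        "q": 0.3, "mu": 1e-3, "w": 1.0, "s_grid": [0.01, 1.0],
        "structured_degree": 4, "steps": 100_000, "n_runs": 1000,
    },
    "fig7_overlap_sweep": {
        "kind": "overlap_sweep", "net": {**_BASE_NET, "degree": 20},
        "games": _BASE_GAMES,
        "overlaps": [0.0, 0.25, 0.5, 0.75, 1.0],
        "config": {"mode": "mixed", "scheme": "independent", "mu": 1e-3,
                   "w": 1.0, "s": 2.0, "steps": 60_000},
        "n_runs": 500,
    },
    "fig8_grid": {
        "kind": "overlap_benefit_grid", "net": {**_BASE_NET, "degree": 15},
        "b1_grid": [1.0, 2.0, 3.0, 4.0, 5.0], "b2": 1.5,
        "overlaps": [0.0, 0.25, 0.5, 0.75, 1.0],
        "config": {"mode": "mixed", "scheme": "independent", "mu": 1e-3,
                   "w": 1.0, "s": 2.0, "steps": 60_000},
        "n_runs": 100,
    },
    "fig9_heatmap": {
        "kind": "benefit_heatmap", "net": {**_BASE_NET, "degree": 20},
        "b_grid": [1.0, 2.0, 3.0, 4.0, 5.0],
        "overlaps": [0.0, 0.5, 1.0],
        "config": {"mode": "mixed", "scheme": "independent", "mu": 1e-3,
                   "w": 1.0, "s": 2.0, "steps": 60_000},
        "n_runs": 100,
    },
    "fig10_memory": {
        "kind": "memory_grid", "net": _BASE_NET, "games": _BASE_GAMES,
        "eps1_grid": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5],
        "config": {"scheme": "independent", "mu": 1e-3, "w": 1.0, "s": 2.0,
                   "steps": 100_000},
        "n_runs": 100,
    },
    "s2_snowdrift": {
        "kind": "evolution", "net": _BASE_NET,
        "games": {"family": "snowdrift", "b": (2.5, 1.2), "c": (1.0, 1.0)},
        "config": {"mode": "unlinked", "scheme": "independent", "mu": 1e-3,
                   "w": 1.0, "s": 2.0, "steps": 60_000},
        "n_runs": 100,
    },
    "s3_sculling": {
        "kind": "evolution", "net": _BASE_NET,
        "games": {"family": "sculling", "b": (2.5, 1.2), "c": (1.0, 1.0)},
        "config": {"mode": "unlinked", "scheme": "independent", "mu": 1e-3,
                   "w": 1.0, "s": 2.0, "steps": 60_000},
        "n_runs": 100,
    },
}


@dataclass
class ExperimentConfig:
    """A preset name plus scale, seed and output directory."""

    name: str
    scale: float = 1.0
    seed: int = 0
    outdir: Optional[str] = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in PRESETS:
            raise ValueError(f"unknown preset {self.name!r}; "
                             f"choose from {sorted(PRESETS)}")
        if not (0 < self.scale <= 1):
            raise ValueError("scale must lie in (0, 1]")

    def resolved(self) -> dict:
        spec = json.loads(json.dumps(PRESETS[self.name]))  # deep copy
        for key, value in self.overrides.items():
            node = spec
            parts = key.split(".")
            for p in parts[:-1]:
                if p not in node:
                    raise ValueError(f"unknown override path {key!r}")
                node = node[p]
            if parts[-1] not in node:
                raise ValueError(f"unknown override path {key!r}")
            node[parts[-1]] = value
        return spec

    def config_hash(self) -> str:
        payload = json.dumps(
            {"spec": self.resolved(), "scale": self.scale, "seed": self.seed},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _make_games(gspec: dict) -> GameSpec:
    family = gspec["family"]
    ctor = {"donation": GameSpec.donation, "snowdrift": GameSpec.snowdrift,
            "sculling": GameSpec.sculling}[family]
    return ctor(gspec["b"], gspec["c"])


def generate_ensemble_nets(net_spec: dict, n_runs: int, seed: int,
                           overlap: Optional[float] = None) -> list[MultiplexNetwork]:
    """One independently seeded network per replicate."""
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_runs)
    O = net_spec["overlap"] if overlap is None else overlap
    return [
        generate_multiplex(
            net_spec["topology"], net_spec["n_nodes"], net_spec["degree"],
            O, seed=int(c.generate_state(1)[0] % (2**31)),
        )
        for c in child
    ]


def ensemble_summary(results) -> dict:
    """Cross-run aggregates: final rates, SE, category abundances, strategies."""
    fz = np.stack([r.final_zeta for r in results])
    cats = [r.category for r in results]
    n = len(results)
    out = {
        "n_runs": n,
        "mean_final_zeta": fz.mean(axis=0).tolist(),
        "sd_final_zeta": fz.std(axis=0, ddof=1).tolist() if n > 1 else [0.0, 0.0],
        "se_final_zeta": (fz.std(axis=0, ddof=1) / np.sqrt(n)).tolist()
        if n > 1 else [0.0, 0.0],
        "category_abundance": {
            c: cats.count(c) / n
            for c in ("full", "layer1_only", "layer2_only", "none", "mixed")
        },
        "mean_unlinked_strategy": np.stack(
            [r.mean_unlinked for r in results]).mean(axis=0).tolist(),
        "mean_linked_strategy": np.stack(
            [r.mean_linked for r in results]).mean(axis=0).tolist(),
    }
    zcn = np.stack([r.final_zeta_cn for r in results])
    zun = np.stack([r.final_zeta_un for r in results])
    out["mean_final_zeta_cn"] = [
        float(np.nanmean(zcn[:, a])) if np.isfinite(zcn[:, a]).any() else float("nan")
        for a in range(2)
    ]
    out["mean_final_zeta_un"] = [
        float(np.nanmean(zun[:, a])) if np.isfinite(zun[:, a]).any() else float("nan")
        for a in range(2)
    ]
    return out


def _scaled(n: int, scale: float) -> int:
    return max(1, int(round(n * scale)))


def run_preset(config: ExperimentConfig) -> dict:
    """Execute a preset experiment; write CSV/JSON outputs if requested.

    Returns the aggregate summary dictionary (also written to
    ``summary.json`` when an output directory is set).
    """
    spec = config.resolved()
    kind = spec["kind"]
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "preset": config.name, "scale": config.scale, "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    series_rows = []

    if kind == "evolution":
        n_runs = _scaled(spec["n_runs"], config.scale)
        nets = generate_ensemble_nets(spec["net"], n_runs, config.seed)
        sim = SimulationConfig(games=_make_games(spec["games"]), **spec["config"])
        results = run_ensemble(nets, sim, seed=config.seed)
        summary.update(ensemble_summary(results))
        for r_idx, r in enumerate(results):
            for t_idx, step in enumerate(r.record_steps):
                for a in (0, 1):
                    series_rows.append({
                        "run": r_idx, "step": int(step), "layer": a + 1,
                        "zeta": r.zeta[t_idx, a],
                        "zeta_cn": r.zeta_cn[t_idx, a],
                        "zeta_un": r.zeta_un[t_idx, a],
                    })

    elif kind == "overlap_sweep":
        n_runs = _scaled(spec["n_runs"], config.scale)
        sweep = []
        for O in spec["overlaps"]:
            nets = generate_ensemble_nets(spec["net"], n_runs, config.seed, overlap=O)
            sim = SimulationConfig(games=_make_games(spec["games"]), **spec["config"])
            results = run_ensemble(nets, sim, seed=config.seed)
            agg = ensemble_summary(results)
            agg["overlap"] = O
            agg["measured_overlap"] = float(
                np.mean([average_edge_overlap(n) for n in nets]))
            sweep.append(agg)
        summary["sweep"] = sweep

    elif kind == "memory_grid":
        n_runs = _scaled(spec["n_runs"], config.scale)
        grid = []
        for mode, overlap in (("unlinked", 0.0), ("linked", 1.0)):
            for eps1 in spec["eps1_grid"]:
                net_spec = dict(spec["net"])
                nets = generate_ensemble_nets(
                    net_spec, n_runs, config.seed, overlap=overlap)
                sim = SimulationConfig(
                    games=_make_games(spec["games"]), mode=mode,
                    eps=(eps1, 0.0), **spec["config"])
                results = run_ensemble(nets, sim, seed=config.seed)
                agg = ensemble_summary(results)
                agg.update({"mode": mode, "eps1": eps1, "eps2": 0.0})
                grid.append(agg)
        summary["grid"] = grid

    elif kind == "fixation":
        rows = []
        n_trials = _scaled(spec["n_trials"], config.scale)
        for k in spec["k_grid"]:
            for b1 in spec["b1_grid"]:
                net = generate_multiplex(
                    spec["net"]["topology"], spec["net"]["n_nodes"], k, 1.0,
                    seed=config.seed)
                games = GameSpec.donation((b1, spec["b2"]),
                                          (spec["c"], spec["c"]))
                res = fixation_probability(
                    make_reduced("LGTFT", spec["q"]), make_reduced("ALLD"),
                    net, games, w=spec["w"], s=spec["s"],
                    n_trials=n_trials, seed=config.seed)
                rows.append({"k": k, "b1": b1, "estimate": res.estimate,
                             "ci_lo": res.ci_low, "ci_hi": res.ci_high,
                             "n_trials": res.n_trials,
                             "n_censored": res.n_censored})
        summary["fixation"] = rows

    elif kind == "simplex":
        n_runs = _scaled(spec["n_runs"], config.scale)
        steps = _scaled(spec["steps"], config.scale)
        rows = []
        rng = np.random.default_rng(config.seed)
        for s_sel in spec["s_grid"]:
            for structured in (False, True):
                net = (generate_multiplex(
                    "rrn", spec["n_nodes"], spec["structured_degree"], 1.0,
                    seed=config.seed) if structured else None)
                for rep in range(n_runs):
                    res = three_strategy_run(
                        spec["q"], spec["b1"], spec["b2"], spec["c"], spec["c"],
                        s=s_sel, mu=spec["mu"], net=net,
                        n_nodes=spec["n_nodes"], w=spec["w"], steps=steps,
                        seed=int(rng.integers(2**31)))
                    rows.append({
                        "s": s_sel, "structured": structured, "rep": rep,
                        "f_allc": res.composition[0],
                        "f_alld": res.composition[1],
                        "f_lgtft": res.composition[2],
                        "coop": res.cooperation_rate})
        summary["simplex"] = rows

    else:  # pragma: no cover
        raise ValueError(f"unhandled preset kind {kind!r}")

    if outdir:
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        if series_rows:
            pd.DataFrame(series_rows).to_csv(outdir / "series.csv", index=False)
        (outdir / "run.log").write_text(
            f"preset={config.name} seed={config.seed} scale={config.scale} "
            f"hash={config.config_hash()}\n")
    return summary


# ---------------------------------------------------------------------------
# fixtures


def make_fixture(kind: str, seed: int = 0, path=None):
    """Small deterministic objects shared across the test suite.

    ``tiny_net``: the 4-node two-layer network with overlap 1/3;
    ``toy_strategies``: named linked/unlinked strategy vectors, including
    the both-or-nothing resident ``p = (1,0,0,1; 1,0,0,1)`` and the
    single-layer defector ``p' = (0,0,0,0; 1,0,0,1)``;
    ``edgelist_file``: the tiny network written as an edge-list file.
    """
    if kind == "tiny_net":
        return MultiplexNetwork([[(0, 1), (1, 2)], [(0, 1), (2, 3)]], 4, seed=seed)
    if kind == "toy_strategies":
        return {
            "allc_linked": pe.LinkedStrategy.allc(),
            "alld_linked": pe.LinkedStrategy.alld(),
            "allc_unlinked": pe.UnlinkedStrategy.allc(),
            "alld_unlinked": pe.UnlinkedStrategy.alld(),
            "tft_unlinked": pe.UnlinkedStrategy.tft(),
            "resident": pe.LinkedStrategy.from_tuple(
                (1, 1, 0, 0, 1, 1, 1, 0, 0, 1)),
            "single_layer_defector": pe.LinkedStrategy.from_tuple(
                (0, 0, 0, 0, 0, 1, 1, 0, 0, 1)),
        }
    if kind == "edgelist_file":
        if path is None:
            raise ValueError("edgelist_file fixture needs a path")
        net = make_fixture("tiny_net", seed)
        from .multiplex import write_multiplex_edgelist
        write_multiplex_edgelist(net, path)
        return net
    raise ValueError(f"unknown fixture kind {kind!r}")
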