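"""Experiment orchestration: plans, deterministic seed fan-out, fixtures.

A plan names one of the canned experiments, its parameter grid, replicate
count and a master seed; every individual run's seed is derived
deterministically from (master seed, grid index, rep index) so grids can be
extended without disturbing existing runs. Outputs are CSV tables plus a
JSON manifest with checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import interface_analysis, lineage_analysis, mutation_rate_ml, selection_response
from .core_sim import DEFAULT_MU, DEFAULT_N_TARGET, SimConfig, auto_lattice_size, run_colony

EXPERIMENTS = ("percolation", "exponents", "fmt-sweep", "lineages", "adapt-rate", "infer-mu")

_SCHEMA: dict[str, set[str]] = {
    "common": {"experiment", "seed", "out", "reps"},
    "percolation": {"k", "L", "rho_grid"},
    "exponents": {"rho", "k", "L", "h_target"},
    "fmt-sweep": {"rho_grid", "k_grid", "s_grid", "N", "mu"},
    "lineages": {"rho", "k", "N", "mu"},
    "adapt-rate": {"rho_grid", "k_grid", "s_grid", "N", "mu", "s_bar", "ratio"},
    "infer-mu": {"data", "lambda0", "generations", "mu_true", "s_true"},
}


@dataclass
class ExperimentPlan:
    experiment: str
    seed: int
    out: Path
    reps: int
    params: dict[str, Any] = field(default_factory=dict)

    def run_seed(self, grid_index: int, rep_index: int) -> int:
        """Deterministic per-run seed from (master, grid index, rep index)."""
        ss = np.random.SeedSequence([self.seed, grid_index, rep_index])
        return int(ss.generate_state(1)[0] % 2**31)


def load_plan(path: str | Path) -> ExperimentPlan:
    """Parse and validate a JSON plan file; unknown keys are rejected."""
    raw = json.loads(Path(path).read_text())
    if "experiment" not in raw:
        raise ValueError("plan is missing 'experiment'")
    exp = raw["experiment"]
    if exp not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {exp!r}; one of {EXPERIMENTS}")
    if "seed" not in raw:
        raise ValueError("plan is missing 'seed' (no silent nondeterminism)")
    allowed = _SCHEMA["common"] | _SCHEMA[exp]
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown plan keys for {exp}: {sorted(unknown)}")
    params = {k: v for k, v in raw.items() if k not in _SCHEMA["common"]}
    # fill study defaults
    params.setdefault("N", DEFAULT_N_TARGET)
    params.setdefault("mu", DEFAULT_MU)
    _validate_params(params)
    return ExperimentPlan(
        experiment=exp,
        seed=int(raw["seed"]),
        out=Path(raw.get("out", "results")),
        reps=int(raw.get("reps", 10)),
        params=params,
    )


def _validate_params(params: dict[str, Any]) -> None:
    for key in ("rho", "k", "mu"):
        if key in params and not 0.0 <= float(params[key]) <= 1.0:
            raise ValueError(f"{key}={params[key]} outside [0, 1]")
    for key in ("rho_grid", "k_grid"):
        if key in params:
            vals = np.asarray(params[key], dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{key} contains values outside [0, 1]")


def run_plan(plan: ExperimentPlan) -> dict[str, Any]:
    """Execute a plan; write tables + manifest; return the manifest dict."""
    plan.out.mkdir(parents=True, exist_ok=True)
    p = plan.params
    outputs: list[Path] = []
    failures: list[str] = []

    if plan.experiment == "percolation":
        rho_c, width, probs = interface_analysis.estimate_critical_density(
            k=float(p.get("k", 0.0)),
            L=int(p.get("L", 128)),
            rho_grid=p["rho_grid"],
            reps=plan.reps,
            seed=plan.seed,
        )
        df = pd.DataFrame({"rho": p["rho_grid"], "spanning_prob": probs})
        outputs.append(_write(df, plan.out / "spanning.csv"))
        outputs.append(
            _write_json(
                {"rho_c": rho_c, "uncertainty": width}, plan.out / "rho_c.json"
            )
        )
    elif plan.experiment == "exponents":
        exps, curves = interface_analysis.kpz_exponent_study(
            L=int(p.get("L", 256)),
            rho=float(p.get("rho", 0.0)),
            k=float(p.get("k", 0.0)),
            reps=plan.reps,
            seed=plan.seed,
            h_target=p.get("h_target"),
        )
        t, wg = interface_analysis._ensemble_mean_curve(curves)
        outputs.append(_write(pd.DataFrame({"h_mean": t, "W_G": wg}), plan.out / "w_g.csv"))
        wl = np.mean([c.W_loc for c in curves], axis=0)
        outputs.append(
            _write(pd.DataFrame({"l": curves[0].l, "W_loc": wl}), plan.out / "w_loc.csv")
        )
        outputs.append(
            _write_json(
                {
                    "beta": exps.beta,
                    "beta_stderr": exps.beta_err,
                    "alpha_loc": exps.alpha_loc,
                    "alpha_loc_stderr": exps.alpha_loc_err,
                },
                plan.out / "exponents.json",
            )
        )
    elif plan.experiment == "fmt-sweep":
        base = SimConfig(
            L=auto_lattice_size(int(p["N"]), max(map(float, p.get("rho_grid", [0.0])))),
            N_target=int(p["N"]),
            mu=float(p["mu"]),
            seed=0,
        )
        rows = []
        for gi, rho in enumerate(p.get("rho_grid", [0.0])):
            for gj, k in enumerate(p.get("k_grid", [0.0])):
                tab = selection_response.sweep_fMT(
                    base,
                    s_grid=p.get("s_grid", selection_response.DEFAULT_S_GRID),
                    rho=float(rho),
                    k=float(k),
                    reps=plan.reps,
                    seed=plan.run_seed(gi * 1000 + gj, 0),
                )
                rows.append(tab.df)
        df = pd.concat(rows, ignore_index=True)
        outputs.append(_write(df, plan.out / "fmt_sweep.csv"))
    elif plan.experiment == "lineages":
        trees = []
        gi = 0
        rho = float(p.get("rho", 0.0))
        N = int(p["N"])
        L = auto_lattice_size(N, rho)
        attempts = 0
        while len(trees) < plan.reps and attempts < 10 * plan.reps:
            cfg = SimConfig(
                L=L,
                rho=rho,
                k=float(p.get("k", 0.0)),
                mu=float(p["mu"]),
                N_target=N,
                seed=plan.run_seed(0, attempts),
            )
            attempts += 1
            r = run_colony(cfg)
            if r.terminated_by != "reached_N":
                failures.append(f"attempt {attempts}: {r.terminated_by}")
                continue
            trees.append(lineage_analysis.build_tree(r))
        fl = lineage_analysis.lineage_fluctuations(trees)
        outputs.append(
            _write(pd.DataFrame({"t": fl.t, "l_perp": fl.l_perp}), plan.out / "l_perp.csv")
        )
        tabs = [
            lineage_analysis.pair_coalescence(t, seed=plan.run_seed(1, i))
            for i, t in enumerate(trees)
        ]
        dxs, t2s = lineage_analysis.binned_t2(tabs)
        outputs.append(
            _write(pd.DataFrame({"dx_norm": dxs, "t2_norm_mean": t2s}), plan.out / "t2_dx.csv")
        )
        t2, u = lineage_analysis.persistence_curve(tabs)
        outputs.append(_write(pd.DataFrame({"t2_norm": t2, "U": u}), plan.out / "persistence.csv"))
        outputs.append(
            _write_json({"xi": fl.xi, "xi_stderr": fl.xi_stderr}, plan.out / "xi.json")
        )
    elif plan.experiment == "adapt-rate":
        base = SimConfig(
            L=auto_lattice_size(int(p["N"]), max(map(float, p["rho_grid"]))),
            N_target=int(p["N"]),
            mu=float(p["mu"]),
            seed=0,
        )
        tables = {}
        for gi, rho in enumerate(p["rho_grid"]):
            for gj, k in enumerate(p["k_grid"]):
                tables[(float(rho), float(k))] = selection_response.sweep_fMT(
                    base,
                    s_grid=p.get("s_grid", selection_response.DEFAULT_S_GRID),
                    rho=float(rho),
                    k=float(k),
                    reps=plan.reps,
                    seed=plan.run_seed(gi * 1000 + gj, 0),
                )
        dfe = selection_response.DFE(
            s_bar=float(p.get("s_bar", 0.03)), R=float(p.get("ratio", 2.0))
        )
        df = selection_response.adaptation_rate_sweep(tables, dfe)
        outputs.append(_write(df, plan.out / "adaptation_rate.csv"))
    elif plan.experiment == "infer-mu":
        exp = mutation_rate_ml.PlatingExperiment(
            lambda0=float(p.get("lambda0", 10.0)),
            generations=int(p.get("generations", 7)),
        )
        if "data" in p:
            obs = _read_observations(p["data"])
        else:
            obs = mutation_rate_ml.generate_observations(
                float(p.get("mu_true", 0.003)),
                float(p.get("s_true", 0.3)),
                exp,
                seed=plan.run_seed(0, 0),
            )
        est = mutation_rate_ml.ml_infer(
            obs, experiment=exp, sims_per_theta=plan.reps, seed=plan.seed
        )
        outputs.append(
            _write_json(
                {
                    "mu_star": est.mu_star,
                    "s_star": est.s_star,
                    "delta_mu": est.delta_mu,
                    "on_boundary": est.on_boundary,
                },
                plan.out / "mu_estimate.json",
            )
        )
        grid = pd.DataFrame(
            [
                {"mu": mu, "s": s, "loglik": est.loglik[i, j]}
                for i, mu in enumerate(est.mu_grid)
                for j, s in enumerate(est.s_grid)
            ]
        )
        outputs.append(_write(grid, plan.out / "loglik_grid.csv"))

    manifest = {
        "experiment": plan.experiment,
        "seed": plan.seed,
        "reps": plan.reps,
        "params": {k: v for k, v in plan.params.items()},
        "failures": failures,
        "outputs": {
            str(path.name): _checksum(path) for path in outputs
        },
    }
    (plan.out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _read_observations(path: str | Path) -> np.ndarray:
    """Replicate table: either a mutant_fraction column or wt/mt counts."""
    df = pd.read_csv(path)
    if "mutant_fraction" in df.columns:
        return df["mutant_fraction"].to_numpy(dtype=float)
    if {"wt_count", "mt_count"} <= set(df.columns):
        tot = df.wt_count + df.mt_count
        return (df.mt_count / tot).to_numpy(dtype=float)
    raise ValueError("need a mutant_fraction column or wt_count/mt_count columns")


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def _write_json(obj: dict, path: Path) -> Path:
    path.write_text(json.dumps(obj, indent=2))
    return path


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# deterministic micro-fixtures with enumerated outcomes
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    name: str
    config: SimConfig
    expected: dict[str, Any]


def make_fixture(name: str) -> Fixture:
    """Tiny deterministic scenarios with exactly known outcomes.

    - 'founder4': lone founder, homogeneous 7x7 lattice; the first daughter
      lands on each of the 4 neighbors with probability 1/4.
    - 'obstacle-ring': founder surrounded by k=0 obstacles; pinned at size 1.
    - 'two-rates': one WT and one MT (s=0.2) eligible mother; selection odds
      1 : 1.2.
    """
    if name == "founder4":
        return Fixture(
            name=name,
            config=SimConfig(L=7, rho=0.0, N_target=2, seed=0),
            expected={"placement_prob": 0.25},
        )
    if name == "obstacle-ring":
        return Fixture(
            name=name,
            config=SimConfig(L=7, rho=1.0, k=0.0, N_target=10, seed=0),
            expected={"terminated_by": "pinned", "n_occupied": 1},
        )
    if name == "two-rates":
        return Fixture(
            name=name,
            config=SimConfig(L=9, rho=0.0, s=0.2, mu=1.0, N_target=3, seed=0),
            expected={"selection_odds": (1.0, 1.2)},
        )
    raise ValueError(f"unknown fixture {name!r}")
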