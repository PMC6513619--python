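"""Generalized Eden model with quenched environmental disorder.

The model grows a population on a square lattice. Each occupied site with at
least one colonizable empty 4-neighbor ("boundary site") divides with
probability proportional to its growth rate; the daughter occupies a uniformly
random colonizable empty neighbor. Quenched disorder sites, placed i.i.d. at
density ``rho``, scale the growth rate of their occupant by the transparency
``k``; at ``k=0`` they are impassable obstacles and the expansion pins at the
square-lattice site-percolation threshold. Mutants carry a relative growth
rate ``1+s`` and arise at wild-type divisions with probability ``mu``; each
mutation founds a new clone and mutants never mutate again.

Time advances by the mean-field increment ``dt = 1/(sum of eligible rates)``
per division, in units of wild-type generations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from . import _kernels

Geometry = Literal["radial", "linear"]

TERMINATION_NAMES = {
    _kernels.REACHED_N: "reached_N",
    _kernels.PINNED: "pinned",
    _kernels.MAX_EVENTS: "max_events",
    _kernels.EDGE: "edge",
}

#: default target population size and mutation rate for ensemble studies
DEFAULT_N_TARGET = 100_000
DEFAULT_MU = 5e-4

EDGE_MARGIN = 2


@dataclass(frozen=True)
class SimConfig:
    """All parameters of a single simulation run.

    Parameters
    ----------
    L : lattice side length (radial) or front width (linear), in sites.
    geometry : ``"radial"`` (single founder at center) or ``"linear"``
        (occupied bottom row, periodic lateral boundaries).
    rho : density of disorder sites in [0, 1].
    k : disorder transparency in [0, 1]; k=0 means impassable obstacles,
        k=1 is a degenerate control where disorder is inert.
    s : mutant selection coefficient (mutant growth rate is 1+s).
    mu : mutation probability per wild-type division.
    N_target : stop once this many sites are occupied (radial).
    h_target : stop once the mean front height reaches this (linear);
        defaults to ``N_target / L``.
    max_events : hard cap on division events (default: lattice capacity).
    seed : master seed; the disorder field and the growth dynamics use
        independent streams derived from it.
    """

    L: int
    geometry: Geometry = "radial"
    rho: float = 0.0
    k: float = 0.0
    s: float = 0.0
    mu: float = 0.0
    N_target: int = DEFAULT_N_TARGET
    h_target: Optional[float] = None
    max_events: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.L < 3:
            raise ValueError("L must be at least 3")
        if self.geometry not in ("radial", "linear"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("k must lie in [0, 1]")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if 1.0 + self.s <= 0.0:
            raise ValueError("1+s must be positive")
        if self.N_target < 1:
            raise ValueError("N_target must be positive")
        if self.geometry == "radial" and self.N_target > self.L**2:
            raise ValueError("N_target exceeds lattice capacity L^2")

    @property
    def height(self) -> int:
        """Lattice height: L for radial, padded above h_target for linear."""
        if self.geometry == "radial":
            return self.L
        h = self.h_target if self.h_target is not None else self.N_target / self.L
        return int(h + 8 * self.L**0.55 + 64)

    def resolved_h_target(self) -> float:
        if self.h_target is not None:
            return float(self.h_target)
        return self.N_target / self.L


def auto_lattice_size(N_target: int, rho: float = 0.0) -> int:
    """Radial lattice side large enough that the colony never nears the edge.

    For rho=0 the colony is compact with radius sqrt(N/pi); near the pinning
    threshold colonies are fractal and sprawl further, so the margin grows
    with 1/(1-rho)."""
    base = 2.5 * math.sqrt(N_target / math.pi) * 2.0
    if rho > 0:
        base /= math.sqrt(max(1.0 - rho, 0.25))
    return int(base) | 1  # odd, so the founder sits on an exact center


@dataclass
class DisorderField:
    mask: np.ndarray  # (H, W) bool
    rho_realized: float


@dataclass
class ColonyState:
    occupied: np.ndarray  # (H, W) uint8
    genotype: np.ndarray  # (H, W) uint8; 0 WT, 1 MT (valid where occupied)
    clone_id: np.ndarray  # (H, W) int32; 0 WT, >0 mutant clone
    t_now: float
    n_occupied: int
    pinned: bool


@dataclass
class DivisionLog:
    """Append-only record of divisions, as parallel arrays over events."""

    mother: np.ndarray  # flat site index
    daughter: np.ndarray  # flat site index
    time: np.ndarray
    genotype: np.ndarray
    clone_id: np.ndarray
    mutated: np.ndarray
    W: int  # lattice width, to unflatten coordinates

    def __len__(self) -> int:
        return len(self.mother)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(len(self.mother)),
                "time": self.time,
                "mother_x": self.mother % self.W,
                "mother_y": self.mother // self.W,
                "daughter_x": self.daughter % self.W,
                "daughter_y": self.daughter // self.W,
                "genotype": self.genotype,
                "clone_id": self.clone_id,
                "mutated": self.mutated,
            }
        )


@dataclass
class SimResult:
    config: SimConfig
    final_state: ColonyState
    log: DivisionLog
    disorder: DisorderField
    terminated_by: str

    @property
    def center(self) -> tuple[float, float]:
        """(x, y) of the founder (radial geometry)."""
        return (self.config.L // 2, self.config.L // 2)


def _derive_seeds(seed: int) -> tuple[int, int]:
    """Disorder and growth seeds from the master seed.

    The growth seed depends only on the master seed (not on rho or k), so a
    k=1 run reproduces the rho=0 trajectory bit-for-bit at equal seed."""
    ss = np.random.SeedSequence(seed)
    a, b = ss.generate_state(2)
    return int(a % (2**31)), int(b % (2**31))


def generate_disorder(
    L: int,
    rho: float,
    seed: int,
    protected: Optional[list[tuple[int, int]]] = None,
    height: Optional[int] = None,
) -> DisorderField:
    """I.i.d. Bernoulli(rho) disorder mask with protected (forced-normal) sites.

    ``protected`` entries are (x, y) pairs; ``height`` defaults to L (square).
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    H = height if height is not None else L
    rng = np.random.default_rng(seed)
    mask = rng.random((H, L)) < rho
    for x, y in protected or []:
        if not (0 <= x < L and 0 <= y < H):
            raise ValueError(f"protected site ({x}, {y}) out of bounds")
        mask[y, x] = False
    return DisorderField(mask=mask, rho_realized=float(mask.mean()))


def growth_rate(
    state: ColonyState, disorder: DisorderField, site: tuple[int, int], k: float, s: float
) -> float:
    """Division rate of an occupied site: (k if disorder) x (1+s if mutant)."""
    x, y = site
    if not state.occupied[y, x]:
        raise ValueError(f"site ({x}, {y}) is not occupied")
    rate = k if disorder.mask[y, x] else 1.0
    if state.genotype[y, x] == 1:
        rate *= 1.0 + s
    return rate


def _run(config: SimConfig) -> SimResult:
    W = config.L
    H = config.height
    linear = config.geometry == "linear"
    n_sites = W * H

    disorder_seed, growth_seed = _derive_seeds(config.seed)
    if linear:
        protected = [(x, 0) for x in range(W)]
    else:
        protected = [(W // 2, H // 2)]
    disorder = generate_disorder(W, config.rho, disorder_seed, protected, height=H)

    occ = np.zeros(n_sites, dtype=np.uint8)
    geno = np.zeros(n_sites, dtype=np.uint8)
    clone = np.zeros(n_sites, dtype=np.int32)
    dis = disorder.mask.reshape(-1).astype(np.uint8)
    for x, y in protected:
        occ[y * W + x] = 1

    max_events = config.max_events if config.max_events is not None else n_sites
    max_events = min(max_events, n_sites)
    log_mother = np.empty(max_events, dtype=np.int32)
    log_daughter = np.empty(max_events, dtype=np.int32)
    log_time = np.empty(max_events, dtype=np.float64)
    log_geno = np.empty(max_events, dtype=np.uint8)
    log_clone = np.empty(max_events, dtype=np.int32)
    log_mut = np.empty(max_events, dtype=np.uint8)
    colh = np.zeros(W, dtype=np.int64)

    n_events, code, t, n_occ, _ = _kernels.run_kernel(
        occ,
        geno,
        clone,
        dis,
        W,
        H,
        linear,
        float(config.k),
        float(config.s),
        float(config.mu),
        config.N_target,
        config.resolved_h_target(),
        max_events,
        EDGE_MARGIN if not linear else 0,
        growth_seed,
        colh,
        log_mother,
        log_daughter,
        log_time,
        log_geno,
        log_clone,
        log_mut,
    )

    state = ColonyState(
        occupied=occ.reshape(H, W),
        genotype=geno.reshape(H, W),
        clone_id=clone.reshape(H, W),
        t_now=float(t),
        n_occupied=int(n_occ),
        pinned=(code == _kernels.PINNED),
    )
    log = DivisionLog(
        mother=log_mother[:n_events].copy(),
        daughter=log_daughter[:n_events].copy(),
        time=log_time[:n_events].copy(),
        genotype=log_geno[:n_events].copy(),
        clone_id=log_clone[:n_events].copy(),
        mutated=log_mut[:n_events].copy(),
        W=W,
    )
    return SimResult(
        config=config,
        final_state=state,
        log=log,
        disorder=disorder,
        terminated_by=TERMINATION_NAMES[code],
    )


def run_colony(config: SimConfig) -> SimResult:
    """Grow a radial colony from a single protected wild-type founder."""
    if config.geometry != "radial":
        raise ValueError("run_colony requires radial geometry")
    return _run(config)


def run_linear(config: SimConfig) -> SimResult:
    """Grow a flat-front population upward from a full bottom row."""
    if config.geometry != "linear":
        raise ValueError("run_linear requires linear geometry")
    return _run(config)


def replay_final_state(result: SimResult) -> ColonyState:
    """Reconstruct the final state from the initial condition and the log.

    Used as an integrity check: the replayed grids must equal the final
    state exactly."""
    cfg = result.config
    W, H = cfg.L, cfg.height
    occ = np.zeros((H, W), dtype=np.uint8)
    geno = np.zeros((H, W), dtype=np.uint8)
    clone = np.zeros((H, W), dtype=np.int32)
    if cfg.geometry == "linear":
        occ[0, :] = 1
    else:
        occ[H // 2, W // 2] = 1
    log = result.log
    ys, xs = log.daughter // W, log.daughter % W
    occ[ys, xs] = 1
    geno[ys, xs] = log.genotype
    clone[ys, xs] = log.clone_id
    t = float(log.time[-1]) if len(log) else 0.0
    return ColonyState(
        occupied=occ,
        genotype=geno,
        clone_id=clone,
        t_now=t,
        n_occupied=int(occ.sum()),
        pinned=result.final_state.pinned,
    )


# ---------------------------------------------------------------------------
# plain-text persistence (CSV grids + JSON manifest)
# ---------------------------------------------------------------------------


def save_result(result: SimResult, outdir: str | Path) -> None:
    """Write event log (CSV), final grids (CSV matrices) and a JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.log.to_dataframe().to_csv(out / "events.csv", index=False)
    st = result.final_state
    # 0 empty, 1 WT, clone_id+1 for mutants
    grid = np.where(
        st.occupied > 0, np.where(st.genotype > 0, st.clone_id + 1, 1), 0
    )
    np.savetxt(out / "state.csv", grid, fmt="%d", delimiter=",")
    np.savetxt(out / "disorder.csv", result.disorder.mask.astype(int), fmt="%d", delimiter=",")
    cfg = result.config
    manifest = {
        "config": {
            "L": cfg.L,
            "geometry": cfg.geometry,
            "rho": cfg.rho,
            "k": cfg.k,
            "s": cfg.s,
            "mu": cfg.mu,
            "N_target": cfg.N_target,
            "h_target": cfg.h_target,
            "max_events": cfg.max_events,
            "seed": cfg.seed,
        },
        "terminated_by": result.terminated_by,
        "n_occupied": st.n_occupied,
        "t_now": st.t_now,
        "rho_realized": result.disorder.rho_realized,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_result(indir: str | Path) -> SimResult:
    """Reload a run written by :func:`save_result`."""
    src = Path(indir)
    manifest = json.loads((src / "manifest.json").read_text())
    config = SimConfig(**manifest["config"])
    W = config.L
    grid = np.loadtxt(src / "state.csv", dtype=np.int64, delimiter=",")
    dis = np.loadtxt(src / "disorder.csv", dtype=np.int64, delimiter=",")
    occupied = (grid > 0).astype(np.uint8)
    genotype = (grid > 1).astype(np.uint8)
    clone_id = np.where(grid > 1, grid - 1, 0).astype(np.int32)
    df = pd.read_csv(src / "events.csv")
    log = DivisionLog(
        mother=(df.mother_y.to_numpy() * W + df.mother_x.to_numpy()).astype(np.int32),
        daughter=(df.daughter_y.to_numpy() * W + df.daughter_x.to_numpy()).astype(np.int32),
        time=df.time.to_numpy(dtype=np.float64),
        genotype=df.genotype.to_numpy(dtype=np.uint8),
        clone_id=df.clone_id.to_numpy(dtype=np.int32),
        mutated=df.mutated.to_numpy(dtype=np.uint8),
        W=W,
    )
    state = ColonyState(
        occupied=occupied,
        genotype=genotype,
        clone_id=clone_id,
        t_now=float(manifest["t_now"]),
        n_occupied=int(manifest["n_occupied"]),
        pinned=manifest["terminated_by"] == "pinned",
    )
    disorder = DisorderField(mask=dis.astype(bool), rho_realized=float(dis.mean()))
    return SimResult(
        config=config,
        final_state=state,
        log=log,
        disorder=disorder,
        terminated_by=manifest["terminated_by"],
    )
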