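"""Selection efficacy: fMT(s) sweeps, exponential fits, rate of adaptation.

The final mutant frequency responds to the selection coefficient roughly
exponentially, fMT(s) = f0 * exp(ks * s): f0 is the neutral diversity (the
frequency neutral mutants reach by surfing on the front) and ks the
selection efficacy, an inverse selection scale. Environmental heterogeneity
drives ks toward 0 near the pinning transition — selection stops mattering.
Weighting fMT(s) by a two-sided exponential distribution of fitness effects
gives the rate of adaptation ∫ D(s) s fMT(s) ds, which can change sign as
heterogeneity increases (expansion load).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clone_analysis import mutant_frequency
from .core_sim import SimConfig, run_colony

#: default selection-coefficient grid, mirroring the experimental range
#: (beneficial up to +20%, deleterious down to -15%)
DEFAULT_S_GRID = (-0.15, -0.1, -0.05, 0.0, 0.05, 0.1, 0.15, 0.2)


@dataclass
class SelectionTable:
    """Ensemble means of fMT per (rho, k, s)."""

    df: pd.DataFrame  # columns: rho, k, s, f_mt_mean, f_mt_stderr, n_reps

    def subset(self, rho: float, k: float) -> pd.DataFrame:
        m = (self.df.rho == rho) & (self.df.k == k)
        return self.df[m].sort_values("s")


@dataclass
class SelectionFit:
    f0: float
    ks: float
    cov: np.ndarray  # 2x2 covariance of (log f0, ks)

    @property
    def f0_stderr(self) -> float:
        return float(self.f0 * np.sqrt(self.cov[0, 0]))

    @property
    def ks_stderr(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))


@dataclass
class DFE:
    """Two-sided exponential distribution of fitness effects.

    D(s) = 1/(s_bar (1+R)) * { exp(-s/s_bar)     for s > 0
                             { R exp(-|s|/s_bar) for s < 0
    Both branches share the scale s_bar; R is the total relative frequency
    of deleterious to beneficial mutations (deleterious mass R/(1+R)).
    """

    s_bar: float
    R: float

    def __post_init__(self):
        if self.s_bar <= 0:
            raise ValueError("s_bar must be positive")
        if self.R < 0:
            raise ValueError("R must be nonnegative")


def dfe_density(s: np.ndarray | float, dfe: DFE) -> np.ndarray | float:
    """Evaluate D(s); integrates to 1 with beneficial mass 1/(1+R)."""
    s = np.asarray(s, dtype=float)
    sb, R = dfe.s_bar, dfe.R
    pos = np.exp(-np.clip(s, 0, None) / sb)
    neg = R * np.exp(-np.clip(-s, 0, None) / sb)
    out = np.where(s > 0, pos, neg) / (sb * (1.0 + R))
    return out if out.ndim else float(out)


def sweep_fMT(
    base: SimConfig,
    s_grid: Sequence[float] = DEFAULT_S_GRID,
    rho: float = 0.0,
    k: float = 0.0,
    reps: int = 8,
    seed: int = 0,
) -> SelectionTable:
    """Ensemble mean and stderr of the final mutant frequency per s.

    Each (s, rep) gets an independent seed derived from ``seed``; runs that
    hit the event cap or the lattice edge are excluded with a warning count.
    """
    rows = []
    for si, s in enumerate(s_grid):
        ss = np.random.SeedSequence([seed, si])
        seeds = [int(x % 2**31) for x in ss.generate_state(reps)]
        fs = []
        for sd in seeds:
            cfg = SimConfig(
                L=base.L,
                geometry="radial",
                rho=rho,
                k=k,
                s=s,
                mu=base.mu,
                N_target=base.N_target,
                max_events=base.max_events,
                seed=sd,
            )
            r = run_colony(cfg)
            if r.terminated_by != "reached_N":
                continue
            fs.append(mutant_frequency(r.final_state))
        if not fs:
            continue
        fs = np.asarray(fs)
        rows.append(
            {
                "rho": rho,
                "k": k,
                "s": s,
                "f_mt_mean": fs.mean(),
                "f_mt_stderr": fs.std(ddof=1) / np.sqrt(len(fs)) if len(fs) > 1 else 0.0,
                "n_reps": len(fs),
            }
        )
    return SelectionTable(df=pd.DataFrame(rows))


def fit_selection(table: SelectionTable | pd.DataFrame, weighted: bool = True) -> SelectionFit:
    """Fit fMT(s) = f0 exp(ks s) by (weighted) least squares on log fMT.

    The model is exactly linear in log space; weights follow from the
    delta method, var(log f) = (stderr/mean)^2. Unweighted OLS is exposed
    as an option since the reference fitting protocol is heuristic.
    """
    df = table.df if isinstance(table, SelectionTable) else table
    df = df[df.f_mt_mean > 0]
    if len(df) < 3:
        raise ValueError("need at least 3 s-points with positive mean fMT")
    s = df.s.to_numpy(dtype=float)
    y = np.log(df.f_mt_mean.to_numpy(dtype=float))
    X = np.column_stack([np.ones_like(s), s])
    if weighted:
        rel = df.f_mt_stderr.to_numpy(dtype=float) / df.f_mt_mean.to_numpy(dtype=float)
        w = 1.0 / np.clip(rel, 1e-3, None) ** 2
    else:
        w = np.ones_like(s)
    WX = X * w[:, None]
    xtx = X.T @ WX
    beta = np.linalg.solve(xtx, WX.T @ y)
    resid = y - X @ beta
    dof = max(len(s) - 2, 1)
    sigma2 = float((w * resid**2).sum() / dof)
    cov = np.linalg.inv(xtx) * sigma2
    return SelectionFit(f0=float(np.exp(beta[0])), ks=float(beta[1]), cov=cov)


def rescale_master_curve(
    tables: Sequence[SelectionTable],
    fits: Sequence[SelectionFit],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pool (ks*s, fMT/f0) over conditions; master curve is exp(ks*s).

    Returns (x = ks*s, y = fMT/f0, rms log deviation from exp(x)).
    """
    if len(tables) != len(fits):
        raise ValueError("one fit per table required")
    xs, ys = [], []
    for tab, fit in zip(tables, fits):
        df = tab.df[tab.df.f_mt_mean > 0]
        xs.append(fit.ks * df.s.to_numpy(dtype=float))
        ys.append(df.f_mt_mean.to_numpy(dtype=float) / fit.f0)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    rms = float(np.sqrt(np.mean((np.log(y) - x) ** 2)))
    return x, y, rms


@dataclass
class AdaptationRate:
    raw: float
    normalized: Optional[float] = None


def rate_of_adaptation(
    s_grid: np.ndarray,
    f_mt: np.ndarray,
    dfe: DFE,
    step: float = 0.005,
    tail_mass_max: float = 0.01,
) -> float:
    """Quadrature of ∫ D(s) s fMT(s) ds over the tabulated range.

    fMT is linearly interpolated on a grid refined to ``step``; beyond the
    tabulated range fMT is held constant at its boundary value and the tail
    contribution ∫ s D(s) ds is added analytically. Raises if the DFE mass
    outside the tabulated range exceeds ``tail_mass_max``.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    f_mt = np.asarray(f_mt, dtype=float)
    order = np.argsort(s_grid)
    s_grid, f_mt = s_grid[order], f_mt[order]
    lo, hi = s_grid[0], s_grid[-1]
    sb, R = dfe.s_bar, dfe.R
    # DFE mass outside [lo, hi]
    mass_hi = np.exp(-hi / sb) / (1 + R) if hi > 0 else 1.0 / (1 + R)
    mass_lo = np.exp(lo / sb) * R / (1 + R) if lo < 0 else R / (1 + R)
    if mass_hi + mass_lo > tail_mass_max:
        raise ValueError(
            f"DFE mass beyond tabulated s-range is {mass_hi + mass_lo:.3g} "
            f"> {tail_mass_max}; extend the s grid"
        )
    fine = np.arange(lo, hi + step / 2, step)
    ffine = np.interp(fine, s_grid, f_mt)
    integrand = dfe_density(fine, dfe) * fine * ffine
    core = float(np.trapezoid(integrand, fine))
    # analytic tails with fMT frozen at the boundary values:
    # ∫_hi^inf s e^{-s/sb}/(sb(1+R)) ds = (hi+sb) e^{-hi/sb}/(1+R)
    tail_hi = f_mt[-1] * (hi + sb) * np.exp(-hi / sb) / (1 + R) if hi > 0 else 0.0
    tail_lo = (
        -f_mt[0] * (abs(lo) + sb) * np.exp(lo / sb) * R / (1 + R)
        if (lo < 0 and R > 0)
        else 0.0
    )
    return core + float(tail_hi) + float(tail_lo)


def adaptation_rate_sweep(
    tables: dict[tuple[float, float], SelectionTable],
    dfe: DFE,
) -> pd.DataFrame:
    """Rate of adaptation per (rho, k), normalized by the rho=0 value."""
    rows = []
    for (rho, k), tab in tables.items():
        df = tab.df.sort_values("s")
        rate = rate_of_adaptation(
            df.s.to_numpy(), df.f_mt_mean.to_numpy(), dfe
        )
        rows.append({"rho": rho, "k": k, "rate_raw": rate})
    out = pd.DataFrame(rows)
    ref = out[out.rho == out.rho.min()]
    norm = float(ref.rate_raw.iloc[0]) if len(ref) else np.nan
    out["rate_norm"] = out.rate_raw / abs(norm) if norm else np.nan
    return out
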