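"""Robust errors-in-variables normalization of dual-luciferase data.

Firefly luminescence (y) is normalized against the co-transfected Renilla
control (x) by estimating the slope β of the line y = βx.  Both channels
carry transfection-efficiency noise, so the fit minimizes *orthogonal*
distances, and outlying wells are down-weighted by Tukey's bounded biweight
loss:

    minimize over β:   Σ_i ρ( d_i(β) / S ),      ρ with c = 4.7
    d_i(β) = (1 + β²)^(−1/2) (y_i − β x_i)       (orthogonal distance)

with the residual scale S the M-estimate solving

    (1/n) Σ_i χ( d_i / S ) = κ,   χ = Tukey's loss with c = 1.56, κ = 0.05.

The estimator is the S-estimate of orthogonal regression: β̂ minimizes the
M-scale S(β) of the orthogonal distances, and Ŝ = S(β̂) satisfies the
χ-equation at the solution.  (Minimizing the bounded ρ-loss directly — with
S either re-solved at each β or held fixed — is not robust at these
constants: the scale solving the χ-equation at κ = 0.05 sits far above the
typical residual, the capped loss then prefers compromise lines through
gross outliers, and an "efficiency" M-step drifts with the contamination.
The scale itself is what resists outliers, so its minimizer is the
estimate.)

Confidence intervals come from the basic bootstrap over B = 999 pair
resamples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar


class UnidentifiableError(ValueError):
    """Slope undefined (e.g. all Renilla readings are zero)."""


class BootstrapError(RuntimeError):
    """Too many bootstrap replicates failed to converge."""


@dataclass(frozen=True)
class RobustConfig:
    """Tuning constants of the robust EIV fit."""

    c_rho: float = 4.7
    c_chi: float = 1.56
    kappa: float = 0.05
    xtol: float = 1e-7
    max_eval: int = 1000
    n_boot: int = 999
    ci_level: float = 0.95

    def __post_init__(self):
        if min(self.c_rho, self.c_chi, self.xtol, self.n_boot, self.ci_level) <= 0:
            raise ValueError("all robust-config fields must be positive")
        if not (0 < self.kappa < 0.5):
            raise ValueError("kappa must be in (0, 0.5)")


@dataclass(frozen=True)
class SlopeFit:
    beta: float
    scale: float
    n: int
    converged: bool
    degenerate: bool = False  # exact fit / unsolvable scale equation
    beta_s: Optional[float] = None  # S-stage (high-breakdown) slope
    ci: Optional[tuple[float, float]] = None
    seed: Optional[int] = None


def tukey_rho(t, c: float):
    """Tukey's biweight loss: t²/6·(3 − 3t²/c² + t⁴/c⁴) for |t| ≤ c, capped
    at c²/6 beyond; even, bounded, nondecreasing in |t|."""
    if c <= 0:
        raise ValueError("c must be > 0")
    t = np.asarray(t, dtype=float)
    u = np.minimum(np.abs(t) / c, 1.0)
    out = (c * c / 6.0) * (3.0 * u**2 - 3.0 * u**4 + u**6)
    return out if out.ndim else float(out)


def m_scale(
    residuals: Sequence[float],
    c: float = 1.56,
    kappa: float = 0.05,
    rtol: float = 1e-12,
) -> tuple[float, bool]:
    """M-estimate of scale: S ≥ 0 solving mean(χ(r_i/S)) = κ.

    Returns (S, degenerate).  mean χ is continuous and decreasing in S with
    supremum (c²/6)·frac_nonzero as S → 0; when that supremum is below κ
    (too many exactly-zero residuals) the equation has no root and S = 0 is
    returned with the degenerate flag.  Solved by bracketed bisection.
    """
    r = np.abs(np.asarray(residuals, dtype=float))
    if r.size == 0:
        raise ValueError("m_scale requires at least one residual")
    if not np.isfinite(r).all():
        raise ValueError("non-finite residuals")
    rmax = r.max()
    if rmax == 0.0:
        return 0.0, True
    cap = c * c / 6.0
    if cap * np.mean(r > 0) <= kappa:
        return 0.0, True
    lo, hi = rmax * 1e-12, rmax * 10.0
    # mean chi(r/hi) < kappa guaranteed: chi(r/S)->0 as S->inf; widen if not
    while np.mean(tukey_rho(r / hi, c)) > kappa:
        hi *= 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(tukey_rho(r / mid, c)) > kappa:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rtol * hi:
            break
    return 0.5 * (lo + hi), False


def orthogonal_distances(beta: float, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return (y - beta * x) / np.hypot(1.0, beta)


def _scale_objective(beta: float, x: np.ndarray, y: np.ndarray, cfg: RobustConfig) -> float:
    """S-stage objective: the M-scale of the orthogonal distances."""
    s, _ = m_scale(orthogonal_distances(beta, x, y), cfg.c_chi, cfg.kappa)
    return s


def tukey_objective(
    beta: float, x: np.ndarray, y: np.ndarray, scale: float, cfg: RobustConfig
) -> float:
    """M-stage objective: Σρ(d_i(β)/S) with the scale held fixed."""
    d = orthogonal_distances(beta, x, y)
    if scale == 0.0:
        cap = cfg.c_rho**2 / 6.0
        tol = 1e-12 * max(1.0, float(np.abs(d).max(initial=0.0)))
        return cap * float(np.sum(np.abs(d) > tol))
    return float(np.sum(tukey_rho(d / scale, cfg.c_rho)))


def _start_candidates(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    pos = x != 0
    med = float(np.median(y[pos] / x[pos]))
    ols = float(x @ y / (x @ x))
    cands = [b for b in (med, ols) if np.isfinite(b) and b != 0]
    if not cands:
        cands = [1.0]
    return np.array(cands)


def eiv_slope(
    x: Sequence[float],
    y: Sequence[float],
    config: RobustConfig = RobustConfig(),
) -> SlopeFit:
    """Robust orthogonal-regression slope of y = βx (S-estimate).

    β̂ globally minimizes the M-scale S(β) of the orthogonal distances:
    log-spaced presearch over three decades around robust starting values,
    refined by bounded Brent to ``config.xtol`` within ``config.max_eval``
    objective evaluations.  The returned scale solves the χ-equation at β̂.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("at least 3 points are required")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.all(x == 0):
        raise UnidentifiableError("all x values are zero; slope unidentifiable")

    # exact-fit shortcut: a start that zeroes every orthogonal distance
    for b0 in _start_candidates(x, y):
        if np.allclose(y, b0 * x, rtol=1e-12, atol=1e-12 * max(1.0, np.abs(y).max())):
            return SlopeFit(
                beta=float(b0), scale=0.0, n=x.size, converged=True, degenerate=True
            )

    evals = 0
    budget = config.max_eval

    def refine(obj, grid: np.ndarray, vals=None) -> tuple[float, bool]:
        """argmin over grid, then bounded Brent on the bracketing neighbors."""
        nonlocal evals
        if vals is None:
            vals = np.array([obj(b) for b in grid])
        k = int(np.argmin(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, grid.size - 1)]
        if lo == hi:
            lo, hi = lo - max(abs(lo), 1e-6), hi + max(abs(hi), 1e-6)
        res = minimize_scalar(
            obj,
            bounds=(min(lo, hi), max(lo, hi)),
            method="bounded",
            options={
                "xatol": config.xtol * max(abs(grid[k]), 1e-3),
                "maxiter": max((budget - evals) // 2, 20),
            },
        )
        if vals[k] < res.fun:  # guard against a failed line search
            return float(grid[k]), bool(res.success)
        return float(res.x), bool(res.success)

    def counted(fun):
        def obj(b: float) -> float:
            nonlocal evals
            evals += 1
            return fun(b)

        return obj

    # S-stage: global presearch over three decades around robust starts
    starts = _start_candidates(x, y)
    scale0 = float(np.abs(starts).max())
    sign = float(np.sign(starts[np.argmax(np.abs(starts))])) or 1.0
    grid_s = sign * scale0 * np.logspace(-1.5, 1.5, 41)
    grid_s = np.unique(np.concatenate([grid_s, starts]))
    grid_s.sort()
    beta_s, ok_s = refine(
        counted(lambda b: _scale_objective(b, x, y, config)), grid_s
    )
    s_hat, degenerate = m_scale(
        orthogonal_distances(beta_s, x, y), config.c_chi, config.kappa
    )
    return SlopeFit(
        beta=beta_s,
        scale=float(s_hat),
        n=int(x.size),
        converged=ok_s,
        degenerate=bool(degenerate or s_hat == 0.0),
        beta_s=beta_s,
    )


# ---------------------------------------------------------------------------
# Vectorized bootstrap (golden-section over per-replicate brackets)

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def _scale_matrix(
    beta: np.ndarray, xm: np.ndarray, ym: np.ndarray, cfg: RobustConfig
) -> np.ndarray:
    """Row-wise M-scale of orthogonal distances; beta is (B,), xm/ym (B,n).
    Degenerate rows (scale equation unsolvable) get S = 0."""
    b = beta[:, None]
    ad = np.abs((ym - b * xm) / np.hypot(1.0, b))
    rmax = ad.max(axis=1)
    cap_chi = cfg.c_chi**2 / 6.0
    solvable = (rmax > 0) & (cap_chi * (ad > 0).mean(axis=1) > cfg.kappa)
    lo = np.where(solvable, rmax * 1e-11, 1.0)
    hi = np.where(solvable, rmax * 10.0, 1.0)
    # compare mean chi to kappa on the 6/c^2 normalized scale:
    # chi(t)/(c^2/6) = v(3 + v(v-3)) with v = min(t^2/c^2, 1)
    thresh = 6.0 * cfg.kappa / cfg.c_chi**2
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        v = np.square(np.minimum(ad / (cfg.c_chi * mid[:, None]), 1.0))
        gm = (v * (3.0 + v * (v - 3.0))).mean(axis=1)
        too_small = gm > thresh
        lo = np.where(too_small, mid, lo)
        hi = np.where(too_small, hi, mid)
    return np.where(solvable, 0.5 * (lo + hi), 0.0)


def _bootstrap_slopes(
    x: np.ndarray,
    y: np.ndarray,
    beta_hat: float,
    config: RobustConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Replicate slopes for B pair-resamples; returns (slopes, n_failed).

    All replicates run the S-estimator simultaneously: a shared log grid
    around the full-data slope picks per-replicate brackets, then
    golden-section narrows each bracket in lockstep on the M-scale
    objective.
    """
    n = x.size
    B = config.n_boot
    idx = rng.integers(0, n, size=(B, n))
    xm, ym = x[idx], y[idx]
    sign = float(np.sign(beta_hat)) or 1.0
    scale0 = abs(beta_hat) if beta_hat != 0 else 1.0
    grid = sign * scale0 * np.logspace(-1.0, 1.0, 17)
    xmm = np.concatenate([xm, xm])  # doubled views for fused probe evaluation
    ymm = np.concatenate([ym, ym])

    def golden(fun, fun2, beta_grid: np.ndarray, n_iter: int):
        # beta_grid: (G, B) candidate slopes per replicate
        vals = np.stack([fun(bg) for bg in beta_grid])
        k = vals.argmin(axis=0)
        cols = np.arange(B)
        a = beta_grid[np.maximum(k - 1, 0), cols]
        b = beta_grid[np.minimum(k + 1, beta_grid.shape[0] - 1), cols]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        for _ in range(n_iter):
            c1 = hi - _INVPHI * (hi - lo)
            c2 = lo + _INVPHI * (hi - lo)
            f = fun2(np.concatenate([c1, c2]))
            left = f[:B] < f[B:]
            hi = np.where(left, c2, hi)
            lo = np.where(left, lo, c1)
        edge = (k == 0) | (k == beta_grid.shape[0] - 1)
        return 0.5 * (lo + hi), edge

    # shared global grid around the full-data slope, then per-replicate
    # golden-section on the M-scale objective
    grid_s = grid[:, None] * np.ones((1, B))
    slopes, _ = golden(
        lambda b: _scale_matrix(b, xm, ym, config),
        lambda b: _scale_matrix(b, xmm, ymm, config),
        grid_s,
        40,
    )
    # degenerate replicates: all x zero (possible when x has zeros)
    failed = int((~np.isfinite(slopes)).sum() + (xm == 0).all(axis=1).sum())
    slopes = slopes[np.isfinite(slopes)]
    return slopes, failed


def bootstrap_ci(
    x: Sequence[float],
    y: Sequence[float],
    config: RobustConfig = RobustConfig(),
    seed: int = 0,
) -> tuple[float, float]:
    """Basic-bootstrap CI for the robust EIV slope.

    Pairs (x_i, y_i) are resampled with replacement B times; the interval is
    (2β̂ − q_{1−α/2}, 2β̂ − q_{α/2}) over replicate slope quantiles.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fit = eiv_slope(x, y, config)
    if fit.degenerate and fit.scale == 0.0 and np.allclose(y, fit.beta * x):
        return (fit.beta, fit.beta)  # exact line: zero-width interval
    rng = np.random.default_rng(seed)
    slopes, failed = _bootstrap_slopes(x, y, fit.beta, config, rng)
    if failed > 0.1 * config.n_boot:
        raise BootstrapError(
            f"{failed} of {config.n_boot} bootstrap replicates failed to converge"
        )
    alpha = 1.0 - config.ci_level
    q_lo, q_hi = np.quantile(slopes, [alpha / 2.0, 1.0 - alpha / 2.0])
    low, high = 2.0 * fit.beta - q_hi, 2.0 * fit.beta - q_lo
    return float(low), float(high)


def bootstrap_slope_replicates(
    x: Sequence[float],
    y: Sequence[float],
    config: RobustConfig = RobustConfig(),
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Full-data slope plus the raw bootstrap replicate slopes (used for
    ratio CIs where numerator and denominator replicates are paired)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fit = eiv_slope(x, y, config)
    if fit.degenerate and fit.scale == 0.0 and np.allclose(y, fit.beta * x):
        return fit.beta, np.full(config.n_boot, fit.beta)
    rng = np.random.default_rng(seed)
    slopes, failed = _bootstrap_slopes(x, y, fit.beta, config, rng)
    if failed > 0.1 * config.n_boot:
        raise BootstrapError(
            f"{failed} of {config.n_boot} bootstrap replicates failed to converge"
        )
    return fit.beta, slopes
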