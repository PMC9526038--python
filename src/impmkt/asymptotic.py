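"""Asymptotic MKT: per-frequency alpha and exponential extrapolation.

alpha is computed per derived-allele-frequency bin,

    alpha(x_i) = 1 - (D_S / D_N) * (P_N(i) / P_S(i)),

and the exponential  alpha(x) = a + b * exp(-c x)  is fitted; its value at
x = 1 removes the contribution of slightly deleterious mutations, which
depress alpha only in the low-frequency bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .pooling import pool_records
from .sfs import GeneVariationRecord

#: Default trim interval for the fit: the lowest bins are SDM-dominated and
#: the highest are prone to polarization error.
DEFAULT_TRIM = (0.1, 0.9)


@dataclass(frozen=True)
class AlphaFunction:
    """Per-bin alpha estimates on the derived-allele-frequency grid i/n."""

    x: np.ndarray
    alpha_x: np.ndarray
    usable: np.ndarray  # bins with P_S(i) > 0

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())


@dataclass(frozen=True)
class AsymptoticFit:
    """Exponential (or fallback linear) fit of alpha(x) with bootstrap CI."""

    a: float
    b: float
    c: float
    alpha_inf: float
    ci_low: float
    ci_high: float
    converged: bool
    n_points: int
    model: str = "exponential"  # or "linear"


def alpha_function(
    records: GeneVariationRecord | Iterable[GeneVariationRecord],
    *,
    cumulative: bool = False,
) -> AlphaFunction:
    """Per-bin (default) or cumulative alpha over the pooled frequency spectrum.

    Requires unfolded spectra and pooled D_N, D_S > 0.  Bins with no
    synonymous polymorphism are masked out rather than dropped, so the grid
    always spans i/n for i = 1..n-1.
    """
    if isinstance(records, GeneVariationRecord):
        pooled = records
    else:
        pooled = pool_records(list(records))
    if pooled.folded:
        raise ValueError("alpha(x) requires an unfolded SFS")
    if pooled.dn <= 0 or pooled.ds <= 0:
        raise ValueError("pooled divergence counts must be positive")
    pn = pooled.sfs_n.counts.astype(float)
    ps = pooled.sfs_s.counts.astype(float)
    if cumulative:
        pn, ps = np.cumsum(pn), np.cumsum(ps)
    x = pooled.sfs_n.frequencies
    usable = ps > 0
    alpha_x = np.full_like(x, np.nan)
    ratio = pooled.ds / pooled.dn
    alpha_x[usable] = 1.0 - ratio * pn[usable] / ps[usable]
    if not usable.any():
        raise ValueError("all frequency bins are empty of synonymous polymorphism")
    return AlphaFunction(x=x, alpha_x=alpha_x, usable=usable)


def _exp_model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, b, c = params
    return a + b * np.exp(-c * x)


def _fit_exponential(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Bounded least squares with multi-start; the exponential is
    ill-conditioned when alpha(x) is near-linear, so three initial decay
    rates are tried and the best residual kept."""
    best, best_cost = None, np.inf
    spread = max(y.max() - y.min(), 1e-3)
    for c0 in (1.0, 5.0, 20.0):
        p0 = np.array([y[-1], -np.sign(y[-1] - y[0] + 1e-12) * spread, c0])
        try:
            sol = least_squares(
                lambda p: _exp_model(p, x) - y,
                p0,
                bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 100.0]),
                max_nfev=2000,
            )
        except Exception:
            continue
        if sol.success and sol.cost < best_cost:
            best, best_cost = sol.x, sol.cost
    return (best, True) if best is not None else (np.zeros(3), False)


def fit_asymptotic(
    alpha_fn: AlphaFunction,
    trim: tuple[float, float] = DEFAULT_TRIM,
    *,
    n_boot: int = 500,
    seed: int = 0,
) -> AsymptoticFit:
    """Fit alpha(x) = a + b exp(-c x) on bins inside the trim interval.

    Reports alpha_inf = alpha(1) = a + b exp(-c) with a percentile bootstrap
    CI over resampled bins.  If the exponential does not converge a linear
    fit a + b x is used (flagged via ``model='linear'``); if that also fails
    the fit is reported unconverged.
    """
    lo, hi = trim
    keep = alpha_fn.usable & (alpha_fn.x >= lo) & (alpha_fn.x <= hi)
    x = alpha_fn.x[keep]
    y = alpha_fn.alpha_x[keep]
    n_points = len(x)
    if n_points < 3:
        raise ValueError(
            f"need at least 3 usable frequency bins inside trim={trim}, got {n_points}"
        )

    def single_fit(xi: np.ndarray, yi: np.ndarray) -> tuple[float, np.ndarray, str, bool]:
        params, ok = _fit_exponential(xi, yi)
        if ok:
            a, b, c = params
            return a + b * np.exp(-c), params, "exponential", True
        coef = np.polyfit(xi, yi, 1)
        if np.all(np.isfinite(coef)):
            a, b = coef[1], coef[0]
            return a + b, np.array([a, b, 0.0]), "linear", True
        return float("nan"), np.zeros(3), "none", False

    alpha_inf, params, model, converged = single_fit(x, y)
    if not converged:
        return AsymptoticFit(
            a=float("nan"), b=float("nan"), c=float("nan"),
            alpha_inf=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            converged=False, n_points=n_points, model="none",
        )

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_points, n_points)
        if len(np.unique(x[idx])) < 3:
            continue
        order = np.argsort(x[idx])
        ai, _, _, ok = single_fit(x[idx][order], y[idx][order])
        if ok and np.isfinite(ai):
            boots.append(ai)
    if boots:
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        # the point estimate is kept inside the reported interval
        ci_low, ci_high = min(ci_low, alpha_inf), max(ci_high, alpha_inf)
    else:
        ci_low = ci_high = alpha_inf
    a, b, c = params
    return AsymptoticFit(
        a=float(a), b=float(b), c=float(c),
        alpha_inf=float(alpha_inf),
        ci_low=float(ci_low), ci_high=float(ci_high),
        converged=True, n_points=n_points, model=model,
    )


def amkt(
    records: GeneVariationRecord | Sequence[GeneVariationRecord],
    trim: tuple[float, float] = DEFAULT_TRIM,
    *,
    cumulative: bool = False,
    n_boot: int = 500,
    seed: int = 0,
) -> AsymptoticFit:
    """Convenience wrapper: pool records, build alpha(x), fit the asymptote."""
    return fit_asymptotic(
        alpha_function(records, cumulative=cumulative), trim, n_boot=n_boot, seed=seed
    )
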