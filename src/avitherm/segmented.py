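"""Continuous piecewise-linear (breakpoint) regression for thermal profiles.

An endotherm's resting metabolic rate plotted against ambient temperature
is U-shaped: it falls with Ta up to the lower critical temperature (Tlc),
is flat across the thermoneutral zone (TNZ), and rises again above the
upper critical temperature (Tuc).  Evaporative water loss is flat then
rises past an inflection temperature.  Both shapes are fitted here with
the continuous broken-line model

    y = b0 + b1 * x + sum_j d_j * (x - psi_j)_+

whose join points ``psi_j`` (the breakpoints) are the quantities of
scientific interest.  The profile residual sum of squares RSS(psi) — the
RSS of the linear fit conditional on the breakpoints — is minimized by
exhaustive grid search (breakpoints on a 0.05 degC grid inside
caller-supplied bounds) followed by a golden-section polish.  With only
~8 test temperatures per individual a global grid search is far more
reliable than iterative linearization, which is nevertheless provided
(:func:`iterative_refit`) for larger series.

Breakpoint standard errors use the delta method on the standard gap
reparameterization: refitting with the gap covariate ``-1{x > psi_j}``
gives a coefficient ``g_j`` whose SE divided by ``|d_j|`` estimates
SE(psi_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .respirometry import ThermalProfile

__all__ = [
    "SegmentedFit",
    "TNZEstimate",
    "fit_piecewise",
    "iterative_refit",
    "tnz_from_fit",
    "ewl_inflection",
    "population_summary",
    "DEFAULT_TNZ_BOUNDS",
    "DEFAULT_EWL_BOUNDS",
]

#: Default breakpoint search bounds for the two-breakpoint VO2 model,
#: reflecting a stepped 10-40 degC protocol: the lower critical
#: temperature is sought in [12, 28] and the upper in [28, 38].
DEFAULT_TNZ_BOUNDS = ((12.0, 28.0), (28.0, 38.0))

#: Default bounds for the single EWL inflection point.
DEFAULT_EWL_BOUNDS = ((20.0, 38.0),)


@dataclass
class SegmentedFit:
    """A fitted continuous piecewise-linear model."""

    n_breakpoints: int
    psi: np.ndarray  # breakpoints, degC
    psi_se: np.ndarray
    slopes: np.ndarray  # per-segment slopes, left to right
    slope_se: np.ndarray
    intercept: float
    rss: float
    n: int
    converged: bool
    method: str  # "grid" or "iterative"
    message: str = ""
    segment_counts: tuple[int, ...] = ()

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = self.intercept + self.slopes[0] * x
        slope_deltas = np.diff(self.slopes)
        for psi_j, d_j in zip(self.psi, slope_deltas):
            y = y + d_j * np.clip(x - psi_j, 0.0, None)
        return y


@dataclass
class TNZEstimate:
    """Thermoneutral-zone summary for one individual (or the population)."""

    individual_id: str
    tlc: float
    tuc: float
    breadth: float
    bmr: float
    tlc_se: float = np.nan
    tuc_se: float = np.nan
    flags: list[str] = field(default_factory=list)


def _hinge_design(x: np.ndarray, psi: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for p in psi:
        cols.append(np.clip(x - p, 0.0, None))
    return np.column_stack(cols)


def _rss_at(x: np.ndarray, y: np.ndarray, psi: np.ndarray) -> float:
    A = _hinge_design(x, psi)
    coef, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1] or res.size == 0:
        r = y - A @ coef
        return float(r @ r)
    return float(res[0])


def _grid_rss(x: np.ndarray, y: np.ndarray, psis: np.ndarray) -> np.ndarray:
    """Profile RSS at every row of ``psis`` (m, q), vectorized."""
    m, q = psis.shape
    n = x.size
    p = q + 2
    A = np.empty((m, n, p))
    A[:, :, 0] = 1.0
    A[:, :, 1] = x
    for j in range(q):
        A[:, :, 2 + j] = np.clip(x[None, :] - psis[:, j, None], 0.0, None)
    At = A.transpose(0, 2, 1)
    AtA = At @ A
    Aty = At @ y
    # tiny ridge keeps degenerate candidates (hinge outside the data)
    # solvable; it perturbs RSS far below any tolerance used downstream
    ridge = 1e-12 * np.eye(p)
    coef = np.linalg.solve(AtA + ridge, Aty[..., None])[..., 0]
    resid = y[None, :] - np.einsum("mnp,mp->mn", A, coef)
    return np.einsum("mn,mn->m", resid, resid)


def fit_piecewise(x: Sequence[float], y: Sequence[float],
                  n_breakpoints: int = 1,
                  bounds: Sequence[tuple[float, float]] | None = None,
                  grid_step: float = 0.05,
                  min_separation: float = 1.0,
                  polish: bool = True) -> SegmentedFit:
    """Fit a continuous broken-line model by exhaustive profile-RSS search.

    Parameters
    ----------
    x, y
        Test temperatures (degC) and the rate measured at each.  Order
        is irrelevant; points are sorted internally.
    n_breakpoints
        1 or 2.
    bounds
        One ``(lo, hi)`` interval per breakpoint, inside the x-range.
        Defaults to the interior of the data.  Intervals may touch but
        not overlap.
    grid_step
        Breakpoint grid resolution, degC.
    min_separation
        Minimum distance between the two breakpoints (two-breakpoint
        model only).
    polish
        Refine each breakpoint by bounded golden-section search within
        one grid step of the grid optimum.

    Ties in RSS across grid candidates are broken toward the midpoint of
    the bounds.  A fit is flagged ``converged=False`` when the RSS
    profile is flat over the whole grid (no breakpoint signal, e.g.
    noise-free flat data), when the design is rank-deficient at the
    optimum, or when a segment is left without any data point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if n_breakpoints not in (1, 2):
        raise ValueError("n_breakpoints must be 1 or 2")
    if x.size < 2 * n_breakpoints + 3:
        raise ValueError(
            f"need at least {2 * n_breakpoints + 3} points for "
            f"{n_breakpoints} breakpoint(s), got {x.size}"
        )
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if bounds is None:
        lo, hi = x[1], x[-2]
        if n_breakpoints == 1:
            bounds = ((lo, hi),)
        else:
            mid = 0.5 * (lo + hi)
            bounds = ((lo, mid), (mid, hi))
    bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
    if len(bounds) != n_breakpoints:
        raise ValueError("one bounds interval per breakpoint required")
    for lo, hi in bounds:
        if lo > hi:
            raise ValueError("bounds interval reversed")
        if lo < x[0] - 1e-9 or hi > x[-1] + 1e-9:
            raise ValueError("breakpoint bounds must lie within the x-range")
    if n_breakpoints == 2 and bounds[1][0] < bounds[0][1] - 1e-9:
        raise ValueError("breakpoint bounds overlap")

    grids = [np.arange(lo, hi + grid_step / 2, grid_step) for lo, hi in bounds]
    if n_breakpoints == 1:
        psis = grids[0][:, None]
    else:
        g1, g2 = np.meshgrid(grids[0], grids[1], indexing="ij")
        keep = (g2 - g1) >= min_separation - 1e-9
        psis = np.column_stack([g1[keep], g2[keep]])
        if psis.shape[0] == 0:
            raise ValueError("bounds leave no admissible breakpoint pair")

    rss = _grid_rss(x, y, psis)
    scale = max(float(np.var(y)) * x.size, 1e-30)
    # no breakpoint signal: constant response, or RSS indifferent to psi
    y_scale = max(1.0, float(np.mean(np.abs(y))))
    flat = (float(np.ptp(rss)) <= 1e-12 * scale
            or float(np.std(y)) <= 1e-12 * y_scale)

    near = rss <= rss.min() + 1e-12 * scale
    mids = np.array([0.5 * (lo + hi) for lo, hi in bounds])
    cand = psis[near]
    best = cand[np.argmin(((cand - mids) ** 2).sum(axis=1))]
    psi = best.astype(float).copy()

    if polish and not flat:
        psi = _polish(x, y, psi, bounds, grid_step, min_separation)
    rss_final = _rss_at(x, y, psi)

    return _finalize_fit(x, y, psi, rss_final, method="grid", flat=flat)


def _polish(x, y, psi, bounds, step, min_sep, sweeps: int = 2):
    psi = psi.copy()
    for _ in range(sweeps):
        for j in range(psi.size):
            lo = max(bounds[j][0], psi[j] - step)
            hi = min(bounds[j][1], psi[j] + step)
            if j > 0:
                lo = max(lo, psi[j - 1] + min_sep)
            if j < psi.size - 1:
                hi = min(hi, psi[j + 1] - min_sep)
            if hi <= lo:
                continue

            def obj(p, j=j):
                trial = psi.copy()
                trial[j] = p
                return _rss_at(x, y, trial)

            res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-6})
            if res.fun <= obj(psi[j]):
                psi[j] = float(res.x)
    return psi


def _segment_counts(x: np.ndarray, psi: np.ndarray) -> tuple[int, ...]:
    edges = np.concatenate([[-np.inf], psi, [np.inf]])
    return tuple(int(((x >= lo) & (x < hi)).sum())
                 for lo, hi in zip(edges[:-1], edges[1:]))


def _finalize_fit(x, y, psi, rss, method: str, flat: bool = False,
                  message: str = "") -> SegmentedFit:
    q = psi.size
    A = _hinge_design(x, psi)
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    slopes = np.cumsum(np.concatenate([[coef[1]], coef[2:]]))
    counts = _segment_counts(x, psi)
    converged = not flat and rank == A.shape[1] and all(c >= 1 for c in counts)
    if flat:
        message = message or "flat RSS profile: no breakpoint signal"
    elif rank < A.shape[1]:
        message = message or "rank-deficient design at the optimum"
    elif not all(c >= 1 for c in counts):
        message = message or "a segment contains no data point"
    psi_se, slope_se = _breakpoint_standard_errors(x, y, psi, coef)
    return SegmentedFit(
        n_breakpoints=q,
        psi=psi.astype(float),
        psi_se=psi_se,
        slopes=slopes,
        slope_se=slope_se,
        intercept=float(coef[0]),
        rss=float(rss),
        n=int(x.size),
        converged=bool(converged),
        method=method,
        message=message,
        segment_counts=counts,
    )


def _breakpoint_standard_errors(x, y, psi, coef):
    """Delta-method SEs: SE(psi_j) = SE(gap_j) / |d_j|."""
    q = psi.size
    n = x.size
    cols = [np.ones_like(x), x]
    for p in psi:
        cols.append(np.clip(x - p, 0.0, None))
    for p in psi:
        cols.append(-(x > p).astype(float))
    A = np.column_stack(cols)
    k = A.shape[1]
    psi_se = np.full(q, np.nan)
    slope_se = np.full(q + 1, np.nan)
    if n <= k:
        return psi_se, slope_se
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < k:
        return psi_se, slope_se
    resid = y - A @ beta
    sigma2 = float(resid @ resid) / (n - k)
    cov = sigma2 * np.linalg.pinv(A.T @ A)
    # slope of segment j is b1 + d_1 + ... + d_j: sum of columns 1..1+j
    for j in range(q + 1):
        sel = np.zeros(k)
        sel[1:2 + j] = 1.0
        slope_se[j] = np.sqrt(max(sel @ cov @ sel, 0.0))
    for j in range(q):
        d_j = beta[2 + j]
        g_var = cov[2 + q + j, 2 + q + j]
        if abs(d_j) > 1e-12:
            psi_se[j] = np.sqrt(max(g_var, 0.0)) / abs(d_j)
    return psi_se, slope_se


def iterative_refit(x: Sequence[float], y: Sequence[float],
                    psi_init: Sequence[float], max_iter: int = 50,
                    tol: float = 1e-4) -> SegmentedFit:
    """Broken-line fit by iterative linearization (gap-covariate updates).

    Starting from ``psi_init``, alternately fits the linear model with
    hinge covariates ``(x - psi_j)_+`` and gap covariates
    ``-1{x > psi_j}`` and updates ``psi_j <- psi_j + g_j / d_j`` until
    the largest breakpoint move is below ``tol`` (degC).  Suited to
    well-conditioned series with many points; falls back flagged
    non-converged on divergence (a breakpoint leaving the x-range, a
    vanishing slope change, or iteration exhaustion).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    psi = np.sort(np.asarray(psi_init, dtype=float))
    q = psi.size
    if np.any(psi < x[0]) or np.any(psi > x[-1]):
        raise ValueError("psi_init must lie within the x-range")
    message = "iteration limit reached"
    converged = False
    for _ in range(max_iter):
        cols = [np.ones_like(x), x]
        cols += [np.clip(x - p, 0.0, None) for p in psi]
        cols += [-(x > p).astype(float) for p in psi]
        A = np.column_stack(cols)
        beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < A.shape[1]:
            message = "rank-deficient linearization"
            break
        d = beta[2:2 + q]
        g = beta[2 + q:2 + 2 * q]
        if np.any(np.abs(d) < 1e-12):
            message = "vanishing slope change (unidentifiable breakpoint)"
            break
        step = g / d
        psi_new = psi + step
        if np.any(psi_new <= x[0]) or np.any(psi_new >= x[-1]) or \
                np.any(np.diff(psi_new) <= 0):
            message = "breakpoint left the admissible region"
            break
        psi = psi_new
        if np.max(np.abs(step)) < tol:
            converged = True
            message = ""
            break
    rss = _rss_at(x, y, psi)
    fit = _finalize_fit(x, y, psi, rss, method="iterative", message=message)
    fit.converged = fit.converged and converged
    return fit


def tnz_from_fit(fit: SegmentedFit, profile: ThermalProfile) -> TNZEstimate:
    """Thermoneutral-zone summary from a two-breakpoint VO2 fit.

    Tlc and Tuc are the fitted breakpoints and the breadth their
    difference.  BMR is the arithmetic mean of the *observed* VO2 values
    at test temperatures inside [Tlc, Tuc]; if no observation falls
    inside, the fitted plateau value at the TNZ midpoint is used and the
    estimate flagged.
    """
    if fit.n_breakpoints != 2:
        raise ValueError("TNZ summary requires a two-breakpoint fit")
    if not fit.converged:
        raise ValueError(f"fit did not converge: {fit.message}")
    tlc, tuc = float(fit.psi[0]), float(fit.psi[1])
    inside = (profile.temps >= tlc) & (profile.temps <= tuc)
    flags = []
    if np.any(inside):
        bmr = float(np.mean(profile.vo2[inside]))
    else:
        bmr = float(fit.predict(0.5 * (tlc + tuc)))
        flags.append("bmr_from_fitted_plateau")
    return TNZEstimate(
        individual_id=profile.individual_id,
        tlc=tlc,
        tuc=tuc,
        breadth=tuc - tlc,
        bmr=bmr,
        tlc_se=float(fit.psi_se[0]),
        tuc_se=float(fit.psi_se[1]),
        flags=flags,
    )


def ewl_inflection(fit: SegmentedFit) -> tuple[float, float]:
    """EWL inflection temperature (and SE) from a one-breakpoint fit."""
    if fit.n_breakpoints != 1:
        raise ValueError("EWL inflection requires a one-breakpoint fit")
    if not fit.converged:
        raise ValueError(f"fit did not converge: {fit.message}")
    return float(fit.psi[0]), float(fit.psi_se[0])


def population_summary(estimates: pd.DataFrame,
                       columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Mean +/- SE of per-individual estimates.

    ``estimates`` holds one row per converged individual.  Returns a
    frame indexed by quantity with columns ``mean``, ``se`` (SD/sqrt(n))
    and ``n``.  Requires at least two individuals.
    """
    if len(estimates) < 2:
        raise ValueError("population summary requires at least 2 individuals")
    if columns is None:
        columns = [c for c in estimates.columns
                   if pd.api.types.is_numeric_dtype(estimates[c])]
    rows = {}
    for c in columns:
        v = estimates[c].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        rows[c] = {
            "mean": float(np.mean(v)),
            "se": float(np.std(v, ddof=1) / np.sqrt(v.size)),
            "n": int(v.size),
        }
    return pd.DataFrame(rows).T
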