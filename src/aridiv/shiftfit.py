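"""Piecewise-constant reconstructed birth-death likelihood with incomplete
sampling, constant/k-shift fits by exhaustive grid search, and likelihood-
ratio model selection.

Likelihood
----------
For per-epoch rates (lam, mu), present-day sampling probability rho and
branching times ``x1 >= x2 >= ... >= x_{n-1}`` (``x1`` the crown age), let
``u(t) = 1 - p0(t)`` be the probability that a lineage alive at age ``t``
has at least one sampled descendant, and ``p1(t)`` the corresponding
one-sampled-descendant density factor.  Within an epoch these solve

    u' = r u - lam u^2            (r = lam - mu)
    (ln p1)' = r - 2 lam u

with ``u(0) = rho``, ``p1(0) = rho`` and continuity across shift times,
giving the closed forms used below.  The log-likelihood of the branching
times, conditioned on the crown age and on both crown lineages surviving to
the present with at least one sampled descendant each, is

    sum_{i>=2} [ln lam(x_i) + ln p1(x_i)] + 2 ln p1(x1) - 2 ln u(x1).

In the pure-birth complete-sampling limit (mu = 0, rho = 1) this reduces to
``sum_{i>=2} (ln lam - lam x_i) - 2 lam x1``.

Conventions
-----------
``ShiftModel`` epochs are in present-to-past order; ``shift_times`` are
ascending ages.  Grid search over shift times excludes a margin of 2
branching events at each end of the data and breaks loglik ties toward the
oldest shift time.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .treeio import BranchingTimes

__all__ = [
    "ShiftModel",
    "FitResult",
    "LRTResult",
    "bd_shift_loglik",
    "fit_constant",
    "fit_k_shifts",
    "lrt",
]

#: margin: a shift time must have at least this many branching events both
#: older and younger than itself
GRID_MARGIN_EVENTS = 2

_TINY_RATE = 1e-12


@dataclass(frozen=True)
class ShiftModel:
    """Piecewise-constant rates; epoch 0 is the youngest (present-side).

    ``shift_times`` are strictly ascending ages (Ma); epoch ``e`` covers ages
    in ``[shift_times[e-1], shift_times[e])``.  ``rho`` is the sampling
    probability at present.
    """

    lambdas: tuple[float, ...]
    mus: tuple[float, ...]
    shift_times: tuple[float, ...] = ()
    rho: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "lambdas", tuple(float(x) for x in self.lambdas))
        object.__setattr__(self, "mus", tuple(float(x) for x in self.mus))
        object.__setattr__(
            self, "shift_times", tuple(float(x) for x in self.shift_times)
        )
        if len(self.lambdas) != len(self.mus):
            raise ValueError("lambdas and mus must have equal length")
        if len(self.shift_times) != len(self.lambdas) - 1:
            raise ValueError("need exactly epochs - 1 shift times")
        if any(l <= 0 for l in self.lambdas):
            raise ValueError("speciation rates must be positive")
        if any(m < 0 for m in self.mus):
            raise ValueError("extinction rates must be non-negative")
        if any(t <= 0 for t in self.shift_times):
            raise ValueError("shift times must be positive")
        if any(a >= b for a, b in zip(self.shift_times, self.shift_times[1:])):
            raise ValueError("shift times must be strictly ascending")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must lie in (0, 1]")

    @property
    def n_epochs(self) -> int:
        return len(self.lambdas)


@dataclass(frozen=True)
class FitResult:
    model: ShiftModel
    loglik: float
    n_free_params: int
    converged: bool


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# likelihood


def _epoch_step(lam, mu, u0, lnp1_0, delta):
    """Propagate (u, ln p1) across a duration ``delta`` within one epoch.

    ``delta`` may be an array.  Returns (u, lnp1) at the endpoint(s).
    """
    r = lam - mu
    if r == 0.0:
        em = delta
        rdelta = 0.0 * np.asarray(delta)
    else:
        em = np.expm1(r * np.asarray(delta, dtype=float)) / r
        rdelta = r * np.asarray(delta, dtype=float)
    denom = 1.0 + lam * u0 * em  # > 1 for valid parameters
    u = u0 * np.exp(rdelta) / denom
    lnp1 = lnp1_0 + rdelta - 2.0 * np.log(denom)
    return u, lnp1


def _profile(model: ShiftModel, times: np.ndarray):
    """Evaluate (u, ln p1, ln lam) at each age in ``times``."""
    bounds = (0.0,) + model.shift_times
    # carried values at each epoch start
    u_start = [model.rho]
    lnp1_start = [math.log(model.rho)]
    for e in range(model.n_epochs - 1):
        u, lnp1 = _epoch_step(
            model.lambdas[e],
            model.mus[e],
            u_start[e],
            lnp1_start[e],
            bounds[e + 1] - bounds[e],
        )
        u_start.append(float(u))
        lnp1_start.append(float(lnp1))

    epoch_idx = np.searchsorted(np.asarray(model.shift_times), times, side="right")
    u_out = np.empty_like(times, dtype=float)
    lnp1_out = np.empty_like(times, dtype=float)
    lnlam_out = np.empty_like(times, dtype=float)
    for e in range(model.n_epochs):
        sel = epoch_idx == e
        if not np.any(sel):
            continue
        u, lnp1 = _epoch_step(
            model.lambdas[e],
            model.mus[e],
            u_start[e],
            lnp1_start[e],
            times[sel] - bounds[e],
        )
        u_out[sel] = u
        lnp1_out[sel] = lnp1
        lnlam_out[sel] = math.log(model.lambdas[e])
    return u_out, lnp1_out, lnlam_out


def bd_shift_loglik(bt: BranchingTimes, model: ShiftModel) -> float:
    """Log-density (nats) of the branching times under ``model``,
    conditioned on the crown age and survival of both crown lineages.

    Returns ``-inf`` where the density vanishes.
    """
    x = np.asarray(bt.times, dtype=float)
    if len(x) < 1:
        raise ValueError("need at least one branching time")
    u, lnp1, lnlam = _profile(model, x)
    if u[0] <= 0 or not np.all(np.isfinite(lnp1)):
        return float("-inf")
    ll = float(np.sum(lnlam[1:] + lnp1[1:]) + 2.0 * lnp1[0] - 2.0 * math.log(u[0]))
    return ll if np.isfinite(ll) else float("-inf")


# ---------------------------------------------------------------------------
# fitting


def _n_free(epochs: int, process: str) -> int:
    per = 1 if process == "yule" else 2
    return epochs * per + (epochs - 1)


def _neg_loglik_factory(bt, rho, shift_times, process):
    epochs = len(shift_times) + 1

    def neg(z):
        z = np.asarray(z)
        lam = tuple(np.exp(z[:epochs]))
        mu = (
            tuple([0.0] * epochs)
            if process == "yule"
            else tuple(np.exp(z[epochs:]))
        )
        try:
            model = ShiftModel(lam, mu, shift_times, rho)
        except ValueError:
            return 1e12
        ll = bd_shift_loglik(bt, model)
        return -ll if np.isfinite(ll) else 1e12

    return neg


_START_FACTORS = (0.25, 0.5, 1.0, 2.0, 4.0)  # fixed multi-start grid
_START_FACTORS_GRIDPOINT = (0.5, 2.0)  # cheaper starts inside the grid scan


def _optimize_rates(bt, rho, shift_times, process, starts=_START_FACTORS):
    """Deterministic multi-start Nelder-Mead over log rates with the shift
    times held fixed.  Returns (ShiftModel, loglik, converged)."""
    epochs = len(shift_times) + 1
    n = bt.n_tips
    lam0 = math.log(max(n, 3)) / bt.crown_age  # crude net-rate scale
    neg = _neg_loglik_factory(bt, rho, shift_times, process)
    best = None
    for f in starts:
        z0 = np.full(epochs, math.log(lam0 * f))
        if process == "birthdeath":
            z0 = np.concatenate([z0, np.full(epochs, math.log(lam0 * f * 0.25))])
        res = optimize.minimize(
            neg,
            z0,
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-8, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    z = np.asarray(best.x)
    lam = tuple(np.exp(z[:epochs]))
    mu = tuple([0.0] * epochs) if process == "yule" else tuple(np.exp(z[epochs:]))
    model = ShiftModel(lam, mu, shift_times, rho)
    return model, -float(best.fun), bool(best.success)


# -- closed-form pure-birth complete-sampling path --------------------------


def _yule_exposure(bt: BranchingTimes):
    """Pieces for the separable Yule (rho=1) likelihood.

    Returns (xb_asc, cum, crown, A_total) where ``xb_asc`` are the non-crown
    branching times ascending, ``cum`` their cumulative sum, and the total
    lineage exposure is ``A_total = sum(xb) + 2 * crown``.
    """
    x = np.asarray(bt.times, dtype=float)
    crown = x[0]
    xb = np.sort(x[1:])
    cum = np.concatenate([[0.0], np.cumsum(xb)])
    A_total = float(xb.sum() + 2.0 * crown)
    return xb, cum, crown, A_total


def _yule_exposure_at(s, xb, cum):
    """``I(s) = integral_0^s L(a) da = 2 s + sum_i min(x_i, s)`` vectorized."""
    s = np.asarray(s, dtype=float)
    idx = np.searchsorted(xb, s, side="right")
    return 2.0 * s + cum[idx] + s * (len(xb) - idx)


def _yule_segment_loglik(B, A):
    """Per-segment profiled loglik ``B ln(B/A) - B``; 0 for empty segments."""
    B = np.asarray(B, dtype=float)
    A = np.asarray(A, dtype=float)
    out = np.zeros_like(B)
    pos = B > 0
    out[pos] = B[pos] * np.log(B[pos] / A[pos]) - B[pos]
    return out


def _fit_shifts_yule_complete(bt, shift_times_grid, k):
    """Exhaustive grid search with the separable closed-form Yule (rho=1)
    likelihood.  Ties break toward older shift times."""
    xb, cum, crown, A_total = _yule_exposure(bt)
    if k == 1:
        s = shift_times_grid[::-1]  # oldest first for the tie-break
        I = _yule_exposure_at(s, xb, cum)
        B_young = np.searchsorted(xb, s, side="left").astype(float)
        B_old = len(xb) - B_young
        ll = _yule_segment_loglik(B_young, I) + _yule_segment_loglik(
            B_old, A_total - I
        )
        i = int(np.argmax(ll))  # first (= oldest) among exact ties
        sh = (float(s[i]),)
        lams = (
            max(B_young[i] / I[i], _TINY_RATE) if I[i] > 0 else _TINY_RATE,
            max(B_old[i] / (A_total - I[i]), _TINY_RATE),
        )
        return ShiftModel(lams, (0.0, 0.0), sh, 1.0), float(ll[i])
    best_ll = -np.inf
    best = None
    # descending lexicographic order => older combinations visited first
    for combo in itertools.combinations(sorted(shift_times_grid, reverse=True), k):
        sh = tuple(sorted(combo))
        bounds = np.array((0.0,) + sh)
        I = _yule_exposure_at(bounds, xb, cum)
        A = np.diff(np.concatenate([I, [A_total]]))
        cnt = np.searchsorted(xb, bounds, side="left")
        B = np.diff(np.concatenate([cnt, [len(xb)]])).astype(float)
        ll = float(_yule_segment_loglik(B, A).sum())
        if ll > best_ll:
            best_ll = ll
            lams = tuple(
                max(b / a, _TINY_RATE) if a > 0 else _TINY_RATE
                for b, a in zip(B, A)
            )
            best = ShiftModel(lams, (0.0,) * (k + 1), sh, 1.0)
    return best, best_ll


def fit_constant(bt: BranchingTimes, rho: float = 1.0, process: str = "yule") -> FitResult:
    """Maximum-likelihood single-epoch fit (1 free rate for ``yule``,
    2 for ``birthdeath``); deterministic multi-start optimization."""
    _check_process(process)
    if len(bt.times) < 2:
        raise ValueError("need at least 2 branching times to fit")
    if process == "yule" and rho == 1.0:
        xb, cum, crown, A_total = _yule_exposure(bt)
        lam = max(len(xb) / A_total, _TINY_RATE)
        model = ShiftModel((lam,), (0.0,), (), 1.0)
        return FitResult(model, bd_shift_loglik(bt, model), 1, True)
    model, ll, ok = _optimize_rates(bt, rho, (), process)
    return FitResult(model, ll, _n_free(1, process), ok)


def shift_time_grid(bt: BranchingTimes, grid_step: float) -> np.ndarray:
    """Ascending admissible shift times: multiples of ``grid_step`` with at
    least ``GRID_MARGIN_EVENTS`` branching events on each side."""
    t_asc = np.sort(bt.times)
    if len(t_asc) < 2 * GRID_MARGIN_EVENTS:
        raise ValueError(
            f"too few branching events ({len(t_asc)}) for the shift grid"
        )
    lo = t_asc[GRID_MARGIN_EVENTS - 1]
    hi = t_asc[-GRID_MARGIN_EVENTS]
    first = math.floor(lo / grid_step) + 1
    last = math.ceil(hi / grid_step) - 1
    grid = np.arange(first, last + 1) * grid_step
    grid = grid[(grid > lo) & (grid < hi)]
    if len(grid) == 0:
        raise ValueError(
            f"no admissible shift time on the {grid_step} Myr grid in "
            f"({lo:g}, {hi:g})"
        )
    return grid


def fit_k_shifts(
    bt: BranchingTimes,
    rho: float = 1.0,
    k: int = 1,
    grid_step: float = 0.1,
    process: str = "yule",
) -> FitResult:
    """Exhaustive search over the shift-time grid, maximizing over rates at
    each grid point.  The best model's loglik is never below the constant
    fit's (equal rates across epochs reproduce the constant model)."""
    _check_process(process)
    if k < 1:
        raise ValueError("k must be >= 1")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    grid = shift_time_grid(bt, grid_step)
    if process == "yule" and rho == 1.0:
        model, ll = _fit_shifts_yule_complete(bt, grid, k)
        return FitResult(model, ll, _n_free(k + 1, "yule"), True)
    best = None
    # descending lexicographic order => ties resolve to older shift times
    for combo in itertools.combinations(sorted(grid, reverse=True), k):
        sh = tuple(sorted(combo))
        model, ll, ok = _optimize_rates(
            bt, rho, sh, process, starts=_START_FACTORS_GRIDPOINT
        )
        if best is None or ll > best[1]:
            best = (model, ll, ok)
    # polish the winning grid point with the full multi-start schedule
    model, ll, ok = _optimize_rates(bt, rho, best[0].shift_times, process)
    if ll < best[1]:
        model, ll, ok = best
    return FitResult(model, ll, _n_free(k + 1, process), ok)


def _check_process(process: str) -> None:
    if process not in ("yule", "birthdeath"):
        raise ValueError(f"unknown process {process!r}")


def lrt(null_fit: FitResult, alt_fit: FitResult) -> LRTResult:
    """Likelihood-ratio test of nested fits: ``chi2 = 2 (ll_alt - ll_null)``,
    df = difference in free parameter counts, chi-square upper-tail p."""
    df = alt_fit.n_free_params - null_fit.n_free_params
    if df <= 0:
        raise ValueError(
            "alternative must have more free parameters than the null"
        )
    if alt_fit.loglik < null_fit.loglik - 1e-6:
        raise ValueError(
            "alternative loglik below null: models are not nested or the "
            "alternative fit failed"
        )
    chi2 = max(2.0 * (alt_fit.loglik - null_fit.loglik), 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return LRTResult(float(chi2), int(df), p)
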