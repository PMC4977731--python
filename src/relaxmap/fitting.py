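"""Per-pixel relaxation-time estimation.

The pipeline for a single pixel time-series is

1. initialization — a two-pass lookup-table search for T1 models (coarse
   50 ms grid over 0–4000 ms, then a 5 ms grid within ±100 ms of the coarse
   winner, scored by sum of absolute error on normalized curves), or a
   weighted log-linear regression with stepwise echo truncation for T2;
2. exclusion — T2 initial estimates outside the open interval
   (0, 400) ms are excluded and emitted as 0;
3. refinement — Nelder-Mead simplex over the model's 2 or 3 parameters,
   converged when the largest absolute change of the time-constant
   coordinate between corresponding vertices of consecutive simplexes
   drops below 0.10 ms;
4. residual — mean absolute misfit normalized by the pixel's maximum
   absolute signal, as a percentage.

Pixels that never refine are emitted as 0 in the maps.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, replace

import numpy as np

from .models import (
    ModelParams,
    SignalModel,
    predict_signal,
    t1_candidate_curve,
)

__all__ = [
    "FitSettings",
    "FitResult",
    "PixelSeries",
    "NoSignalError",
    "InitializationError",
    "lookup_init_t1",
    "loglinear_init_t2",
    "refine_fit",
    "apply_exclusion",
    "compute_residual",
    "fit_pixel",
    "T1LookupTable",
]


# Estimates this close (ms) to a T2 exclusion bound are classified outside:
# the interval is open, and rounding in the log-linear init can land an
# exactly-boundary estimate an ulp inside.  Far below any physical resolution.
_T2_EDGE = 1e-6


def _inside_t2_interval(tau: float, bounds: tuple[float, float]) -> bool:
    lo, hi = bounds
    return (lo + _T2_EDGE) < tau < (hi - _T2_EDGE)


class NoSignalError(ValueError):
    """The pixel's time-series is identically zero."""


class InitializationError(ValueError):
    """The initial estimate could not be computed (pixel left unrefined)."""


@dataclass(frozen=True)
class FitSettings:
    """Tunable parameters of the fitting pipeline (all times in ms)."""

    t1_grid_max: float = 4000.0
    t1_coarse_step: float = 50.0
    t1_fine_step: float = 5.0
    t1_fine_halfwidth: float = 100.0
    convergence_tol: float = 0.10
    t2_exclusion: tuple[float, float] = (0.0, 400.0)
    max_iterations: int = 1000
    objective: str = "sum_squared"  # or "sum_absolute"
    background_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.t1_fine_step >= self.t1_coarse_step:
            raise ValueError("t1_fine_step must be smaller than t1_coarse_step")
        if not self.convergence_tol > 0:
            raise ValueError("convergence_tol must be positive")
        lo, hi = self.t2_exclusion
        if not (lo >= 0 and hi > lo):
            raise ValueError("t2_exclusion bounds must be non-negative and ordered")
        if self.objective not in ("sum_squared", "sum_absolute"):
            raise ValueError(f"unknown objective {self.objective!r}")

    def digest(self) -> str:
        """Stable hash of the settings, embedded in map provenance."""
        payload = json.dumps(self.__dict__, sort_keys=True, default=float)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class PixelSeries:
    """One pixel's signal samples and matching preparation times (ms)."""

    values: np.ndarray
    times: np.ndarray
    convention: str = "magnitude"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape or self.values.ndim != 1:
            raise ValueError("values and times must be matching 1-D arrays")
        order = np.argsort(self.times, kind="stable")
        self.values = self.values[order]
        self.times = self.times[order]
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("duplicate preparation times are not allowed")
        if self.convention not in ("magnitude", "signed"):
            raise ValueError(f"unknown convention {self.convention!r}")


@dataclass
class FitResult:
    """Outcome of fitting one pixel (or one ROI-mean series)."""

    params: ModelParams
    tau_corrected: float  # Look-Locker corrected T1 for MOLLI, else == params.tau
    residual_pct: float
    refined: bool
    excluded: bool
    n_iterations: int = 0
    tau_spread: float = math.nan  # consecutive-simplex tau spread at termination
    objective_monotone: bool = True
    objective_value: float = math.nan
    initial_tau: float = math.nan

    @property
    def map_value(self) -> float:
        """Value this pixel contributes to the relaxation map."""
        if self.excluded or not self.refined:
            return 0.0
        return self.tau_corrected


# ---------------------------------------------------------------------------
# T1 lookup-table initialization


class T1LookupTable:
    """Two-pass grid search for the initial T1 of one timing schedule.

    Candidate curves assume unit amplitude and ideal preparation efficiency
    (B = 2 for inversion-based models, B = 1 for saturation recovery) and are
    normalized by their own maximum absolute value over the schedule so that
    they are compared on the same footing as the max-normalized pixel.
    Ties are broken toward the smallest T1.
    """

    def __init__(self, times: np.ndarray, model: SignalModel, settings: FitSettings):
        if model.family != "t1":
            raise ValueError("T1 lookup applies to T1 models only")
        self.times = np.asarray(times, dtype=float)
        self.model = model
        self.settings = settings
        self.coarse_grid = np.arange(
            0.0, settings.t1_grid_max + settings.t1_coarse_step / 2, settings.t1_coarse_step
        )
        self._coarse = self._curves(self.coarse_grid)
        self._fine_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def _curves(self, grid: np.ndarray) -> np.ndarray:
        rows = np.empty((grid.size, self.times.size))
        for i, tau in enumerate(grid):
            c = t1_candidate_curve(self.times, tau, self.model.ideal_b, self.model.magnitude)
            peak = np.max(np.abs(c))
            rows[i] = c / peak if peak > 0 else c
        return rows

    def _fine(self, center: float) -> tuple[np.ndarray, np.ndarray]:
        cached = self._fine_cache.get(center)
        if cached is None:
            s = self.settings
            lo = max(0.0, center - s.t1_fine_halfwidth)
            hi = min(s.t1_grid_max, center + s.t1_fine_halfwidth)
            grid = np.arange(lo, hi + s.t1_fine_step / 2, s.t1_fine_step)
            cached = (grid, self._curves(grid))
            self._fine_cache[center] = cached
        return cached

    def initial_t1(self, norm_values: np.ndarray) -> float:
        """Initial T1 for a pixel already normalized by its max |S|."""
        coarse_err = np.abs(self._coarse - norm_values).sum(axis=1)
        center = float(self.coarse_grid[int(np.argmin(coarse_err))])
        fine_grid, fine_curves = self._fine(center)
        fine_err = np.abs(fine_curves - norm_values).sum(axis=1)
        return float(fine_grid[int(np.argmin(fine_err))])


def lookup_init_t1(
    pixel: PixelSeries | np.ndarray,
    model: SignalModel,
    settings: FitSettings = FitSettings(),
    times: np.ndarray | None = None,
) -> float:
    """Two-pass lookup-table initial T1 estimate for one pixel series."""
    values, t = _coerce_series(pixel, times)
    if values.size < 2:
        raise InitializationError("need at least two samples to initialize T1")
    peak = float(np.max(np.abs(values)))
    if peak == 0.0:
        raise NoSignalError("all-zero pixel series")
    table = T1LookupTable(t, model, settings)
    return table.initial_t1(values / peak)


# ---------------------------------------------------------------------------
# T2 log-linear initialization


def loglinear_init_t2(
    pixel: PixelSeries | np.ndarray,
    settings: FitSettings = FitSettings(),
    times: np.ndarray | None = None,
) -> float:
    """Weighted log-linear initial T2 estimate with stepwise echo truncation.

    ``log S = log A - t/T2`` is fitted by linear regression weighted by the
    squared signal (compensating the variance inflation of the log
    transform), repeated while truncating the longest echo until three
    points remain; the candidate minimizing the summed absolute error of the
    back-transformed curve over *all* samples wins.  Non-positive samples
    are dropped before taking the logarithm.
    """
    values, t = _coerce_series(pixel, times)
    pos = values > 0
    vp, tp = values[pos], t[pos]
    if vp.size < 3:
        raise InitializationError("fewer than three positive samples for the log fit")
    best_t2 = math.nan
    best_score = math.inf
    for k in range(vp.size, 2, -1):
        tt, ss = tp[:k], vp[:k]
        # polyfit weights multiply the residuals, so w = S gives S^2 weighting
        slope, intercept = np.polyfit(tt, np.log(ss), 1, w=ss)
        if slope >= 0:
            continue
        t2 = -1.0 / slope
        amp = math.exp(intercept)
        score = float(np.abs(amp * np.exp(-t / t2) - values).sum())
        if score < best_score:
            best_score = score
            best_t2 = t2
    if not math.isfinite(best_t2):
        raise InitializationError("no decaying log-linear candidate found")
    return float(best_t2)


def _coerce_series(pixel, times):
    if isinstance(pixel, PixelSeries):
        return pixel.values, pixel.times
    values = np.asarray(pixel, dtype=float)
    if times is None:
        raise ValueError("times must be given when passing a bare array")
    return values, np.asarray(times, dtype=float)


# ---------------------------------------------------------------------------
# Nelder-Mead refinement


def _make_objective(model, values, times, objective, anchor_value=None):
    """Build a fast scalar objective over the model parameter vector.

    Parameter vectors are ``[A, tau]`` (2p) or ``[A, B, tau]`` (3p).  For
    offset-constrained T2 models the offset enters as ``|B|`` so a vanilla
    unconstrained simplex respects ``B >= 0``.  The optional SR anchor sample
    contributes a residual against the asymptote ``|B|``.  Non-positive tau
    is penalized with +inf.
    """
    vals = [float(v) for v in values]
    tms = [float(t) for t in times]
    squared = objective == "sum_squared"
    t1_family = model.family == "t1"
    magnitude = model.magnitude
    three = model.n_params == 3
    fixed_b = model.ideal_b
    exp = math.exp

    def f(x):
        tau = x[-1]
        if tau <= 0.0:
            return math.inf
        a = x[0]
        total = 0.0
        if t1_family:
            b = x[1] if three else fixed_b
            for v, t in zip(vals, tms):
                s = a * (1.0 - b * exp(-t / tau))
                if magnitude and s < 0.0:
                    s = -s
                d = s - v
                total += d * d if squared else abs(d)
        else:
            b = abs(x[1]) if three else 0.0
            for v, t in zip(vals, tms):
                d = a * exp(-t / tau) + b - v
                total += d * d if squared else abs(d)
            if anchor_value is not None:
                d = b - anchor_value
                total += d * d if squared else abs(d)
        return total

    return f


# The simplex must also have collapsed geometrically (per-coordinate
# diameter below this fraction of the best vertex) before the tau rule may
# fire: the tau coordinate can transiently stall while the simplex still
# crawls along the flat A/B valley of an offset T2 fit, and stopping there
# leaves the offset un-estimated.
_SIMPLEX_COLLAPSE_RTOL = 1e-5


def _collapsed(verts, n):
    xb = verts[0][1]
    for j in range(n):
        hi = lo = verts[0][1][j]
        for _, x in verts[1:]:
            if x[j] > hi:
                hi = x[j]
            elif x[j] < lo:
                lo = x[j]
        if hi - lo > _SIMPLEX_COLLAPSE_RTOL * max(1.0, abs(xb[j])):
            return False
    return True


def _nelder_mead(f, x0, steps, tau_idx, tol, max_iter):
    """Nelder-Mead simplex with the relaxometry convergence rule.

    Terminates when the maximum absolute difference of the tau coordinate
    over corresponding (rank-ordered) vertices of consecutive simplexes is
    below ``tol`` and the simplex has collapsed in every coordinate.
    Returns (x_best, f_best, n_iter, converged, monotone, final_spread,
    diverged).
    """
    n = len(x0)
    verts = []
    for i in range(n + 1):
        x = list(x0)
        if i > 0:
            x[i - 1] += steps[i - 1]
        fx = f(x)
        if not math.isfinite(fx):
            if i == 0:
                return list(x0), math.inf, 0, False, True, math.inf, True
            fx = math.inf
        verts.append([fx, x])
    verts.sort(key=lambda v: v[0])
    if not math.isfinite(verts[0][0]):
        return verts[0][1], math.inf, 0, False, True, math.inf, True

    monotone = True
    converged = False
    spread = math.inf
    it = 0
    while it < max_iter:
        it += 1
        prev_best = verts[0][0]
        prev_tau = [v[1][tau_idx] for v in verts]
        worst_f, worst_x = verts[-1]
        centroid = [0.0] * n
        for _, xv in verts[:-1]:
            for j in range(n):
                centroid[j] += xv[j]
        for j in range(n):
            centroid[j] /= n
        xr = [2.0 * centroid[j] - worst_x[j] for j in range(n)]
        fr = f(xr)
        fr = fr if math.isfinite(fr) else math.inf
        if fr < verts[0][0]:
            xe = [3.0 * centroid[j] - 2.0 * worst_x[j] for j in range(n)]
            fe = f(xe)
            fe = fe if math.isfinite(fe) else math.inf
            verts[-1] = [fe, xe] if fe < fr else [fr, xr]
        elif fr < verts[-2][0]:
            verts[-1] = [fr, xr]
        else:
            if fr < worst_f:  # outside contraction
                xc = [0.5 * (centroid[j] + xr[j]) for j in range(n)]
            else:  # inside contraction
                xc = [0.5 * (centroid[j] + worst_x[j]) for j in range(n)]
            fc = f(xc)
            fc = fc if math.isfinite(fc) else math.inf
            if fc < min(fr, worst_f):
                verts[-1] = [fc, xc]
            else:  # shrink toward the best vertex
                xb = verts[0][1]
                for k in range(1, n + 1):
                    xs = [0.5 * (xb[j] + verts[k][1][j]) for j in range(n)]
                    fs = f(xs)
                    verts[k] = [fs if math.isfinite(fs) else math.inf, xs]
        verts.sort(key=lambda v: v[0])
        if verts[0][0] > prev_best * (1 + 1e-12) + 1e-300:
            monotone = False
        spread = max(abs(v[1][tau_idx] - pt) for v, pt in zip(verts, prev_tau))
        if spread < tol and _collapsed(verts, n):
            converged = True
            break
    return verts[0][1], verts[0][0], it, converged, monotone, spread, False


def _simplex_steps(x0, tau_idx, amp_scale):
    """Initial vertex perturbations: 5 % per coordinate, with absolute
    fallbacks (5 ms for a zero tau; a twentieth of the amplitude for a zero
    offset) so degenerate starts still span the simplex."""
    steps = []
    for j, v in enumerate(x0):
        if v != 0.0:
            steps.append(0.05 * v)
        elif j == tau_idx:
            steps.append(5.0)
        else:
            steps.append(0.05 * amp_scale if amp_scale > 0 else 0.05)
    return steps


def refine_fit(
    pixel: PixelSeries | np.ndarray,
    model: SignalModel,
    init: ModelParams,
    settings: FitSettings = FitSettings(),
    times: np.ndarray | None = None,
    anchor_value: float | None = None,
) -> FitResult:
    """Nelder-Mead refinement of an initial parameter estimate.

    Returns a :class:`FitResult`; pixels whose objective is non-finite at the
    start are excluded, pixels hitting the iteration cap are left unrefined.
    MOLLI results carry the Look-Locker corrected T1 in ``tau_corrected``
    (pixels with fitted ``B <= 1`` are flagged excluded: the correction would
    be non-physical).
    """
    values, t = _coerce_series(pixel, times)
    f = _make_objective(model, values, t, settings.objective, anchor_value)
    if model.n_params == 2:
        x0 = [init.A, init.tau]
    else:
        x0 = [init.A, init.B, init.tau]
    tau_idx = len(x0) - 1
    steps = _simplex_steps(x0, tau_idx, abs(init.A))
    x, fval, n_iter, converged, monotone, spread, diverged = _nelder_mead(
        f, x0, steps, tau_idx, settings.convergence_tol, settings.max_iterations
    )
    if model.n_params == 2:
        params = ModelParams(A=x[0], B=model.ideal_b, tau=x[1])
    else:
        b = abs(x[1]) if model.offset_constrained else x[1]
        params = ModelParams(A=x[0], B=b, tau=x[2])
    refined = converged and not diverged
    excluded = diverged
    tau_corrected = params.tau
    if model.needs_look_locker:
        if params.B > 1.0 and params.tau > 0:
            tau_corrected = params.tau * (params.B - 1.0)
        else:
            tau_corrected = 0.0
            excluded = True
    residual = math.nan
    if refined and not excluded:
        try:
            residual = compute_residual(values, params, model, times=t)
        except NoSignalError:
            residual = math.nan
            excluded = True
    return FitResult(
        params=params,
        tau_corrected=tau_corrected,
        residual_pct=residual,
        refined=refined,
        excluded=excluded,
        n_iterations=n_iter,
        tau_spread=spread,
        objective_monotone=monotone,
        objective_value=fval,
        initial_tau=init.tau,
    )


def apply_exclusion(
    result: FitResult, model: SignalModel, settings: FitSettings = FitSettings()
) -> FitResult:
    """Apply the T2 plausibility interval: estimates outside the *open*
    interval (0, 400) ms are excluded and emitted as 0.  T1 results pass
    through unchanged; unrefined pixels always emit 0 via ``map_value``."""
    if model.family != "t2":
        return result
    if not _inside_t2_interval(result.params.tau, settings.t2_exclusion):
        return replace(result, excluded=True, refined=False, tau_corrected=0.0)
    return result


def compute_residual(
    pixel: PixelSeries | np.ndarray,
    fitted: ModelParams,
    model: SignalModel,
    times: np.ndarray | None = None,
) -> float:
    """Normalized mean absolute residual of a fitted curve, in percent.

    Mean over samples of |S_fit(t_i) - S_i|, divided by max_i |S_i|, x 100.
    """
    values, t = _coerce_series(pixel, times)
    peak = float(np.max(np.abs(values)))
    if peak == 0.0:
        raise NoSignalError("residual undefined for an all-zero series")
    pred = predict_signal(model, fitted, t)
    return float(np.mean(np.abs(pred - values)) / peak * 100.0)


def fit_pixel(
    pixel: PixelSeries | np.ndarray,
    model: SignalModel,
    settings: FitSettings = FitSettings(),
    times: np.ndarray | None = None,
    anchor_value: float | None = None,
    lookup: T1LookupTable | None = None,
) -> FitResult:
    """Full single-pixel pipeline: initialize, exclude, refine, residual.

    ``lookup`` allows reuse of a precomputed T1 lookup table across the
    pixels of a map (same schedule, model and settings).
    """
    values, t = _coerce_series(pixel, times)
    peak = float(np.max(np.abs(values))) if values.size else 0.0
    if peak == 0.0:
        return _unrefined_result(settings)
    if model.family == "t1":
        if lookup is not None:
            init_tau = lookup.initial_t1(values / peak)
        else:
            init_tau = lookup_init_t1(values, model, settings, times=t)
        init = ModelParams(A=peak, B=model.ideal_b, tau=init_tau)
    else:
        try:
            init_tau = loglinear_init_t2(values, settings, times=t)
        except InitializationError:
            return _unrefined_result(settings)
        if not _inside_t2_interval(init_tau, settings.t2_exclusion):
            return FitResult(
                params=ModelParams(A=peak, B=0.0, tau=init_tau),
                tau_corrected=0.0,
                residual_pct=math.nan,
                refined=False,
                excluded=True,
                initial_tau=init_tau,
            )
        init = ModelParams(A=peak, B=0.0, tau=init_tau)
    result = refine_fit(values, model, init, settings, times=t, anchor_value=anchor_value)
    return result


def _unrefined_result(settings: FitSettings) -> FitResult:
    return FitResult(
        params=ModelParams(A=0.0, B=0.0, tau=0.0),
        tau_corrected=0.0,
        residual_pct=math.nan,
        refined=False,
        excluded=False,
    )
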