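"""Assembles per-pixel fits into relaxation maps.

Every pixel of an :class:`ImageSeries` passes independently through the
fitting pipeline; excluded or unrefined pixels carry 0 in the map and NaN in
the residual map.  Pixels whose peak signal falls below a configurable
fraction of the image maximum (default 1 %) are skipped as background.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from .fitting import FitResult, FitSettings, T1LookupTable, fit_pixel
from .models import ModelParams, SignalModel, predict_signal

__all__ = ["ImageSeries", "RelaxationMap", "fit_map", "fit_roi_mean", "residual_map"]


@dataclass
class ImageSeries:
    """Co-registered frame stack with per-frame preparation times.

    ``times`` holds one preparation time (ms) per frame; the entry for an SR
    anchor frame (see ``sr_anchor_index``) is NaN — the anchor is a flag, not
    a finite preparation time.
    """

    frames: np.ndarray  # (n_frames, height, width)
    times: np.ndarray  # (n_frames,)
    convention: str = "magnitude"
    model_hint: str | None = None
    sr_anchor_index: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) stack")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError(
                f"{self.frames.shape[0]} frames but {self.times.size} preparation times"
            )
        if self.convention not in ("magnitude", "signed"):
            raise ValueError(f"unknown convention {self.convention!r}")
        if self.sr_anchor_index is not None:
            idx = int(self.sr_anchor_index)
            if not 0 <= idx < self.frames.shape[0]:
                raise ValueError("sr_anchor_index out of range")
            self.sr_anchor_index = idx
        finite = np.isfinite(self.times)
        if self.sr_anchor_index is not None:
            finite = np.delete(finite, self.sr_anchor_index)
        if not finite.all():
            raise ValueError("non-anchor frames must have finite preparation times")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def split_anchor(self) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        """(data frames sorted by time, their times, anchor frame or None)."""
        if self.sr_anchor_index is None:
            frames, times, anchor = self.frames, self.times, None
        else:
            keep = np.arange(self.frames.shape[0]) != self.sr_anchor_index
            frames, times = self.frames[keep], self.times[keep]
            anchor = self.frames[self.sr_anchor_index]
        order = np.argsort(times, kind="stable")
        times = times[order]
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("duplicate preparation times in series")
        return frames[order], times, anchor


@dataclass
class RelaxationMap:
    """Pixelwise relaxation map with residuals, masks and provenance."""

    tau_map: np.ndarray  # ms; Look-Locker corrected for MOLLI; 0 where not refined
    residual_map: np.ndarray  # %; NaN where not refined
    refined_mask: np.ndarray
    excluded_mask: np.ndarray
    tau_fit_map: np.ndarray  # raw fitted time constant (T1* for MOLLI)
    a_map: np.ndarray
    b_map: np.ndarray
    provenance: dict
    diagnostics: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tau_map.shape


def _check_convention(series: ImageSeries, model: SignalModel) -> None:
    if series.convention == "signed" and not model.signed:
        raise ValueError(
            f"signed (PSIR) data cannot be fitted with magnitude model {model.full_id}"
        )


def fit_map(
    series: ImageSeries,
    model: SignalModel,
    settings: FitSettings = FitSettings(),
    roi: np.ndarray | None = None,
) -> RelaxationMap:
    """Pixelwise relaxation mapping over the whole image or an ROI.

    Pixels outside the ROI, below the background gate, excluded by the T2
    interval rule or never refined all carry 0 in ``tau_map``.
    """
    _check_convention(series, model)
    frames, times, anchor = series.split_anchor()
    use_anchor = anchor is not None and model.offset_constrained
    h, w = series.shape
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != (h, w):
            raise ValueError("roi shape does not match the image frames")
        if not roi.any():
            raise ValueError("roi is empty")

    tau = np.zeros((h, w))
    tau_fit = np.zeros((h, w))
    residual = np.full((h, w), np.nan)
    refined = np.zeros((h, w), dtype=bool)
    excluded = np.zeros((h, w), dtype=bool)
    a_map = np.zeros((h, w))
    b_map = np.zeros((h, w))

    peak = np.max(np.abs(frames), axis=0)
    global_peak = float(peak.max())
    candidates = peak >= settings.background_fraction * global_peak
    if roi is not None:
        candidates &= roi

    lookup = T1LookupTable(times, model, settings) if model.family == "t1" else None
    t_start = time.perf_counter()
    max_spread = 0.0
    all_monotone = True
    n_refined = n_excluded = 0

    rows, cols = np.nonzero(candidates)
    pixel_stack = frames[:, rows, cols]  # (n_frames, n_candidates)
    anchor_vals = anchor[rows, cols] if use_anchor else None
    for k in range(rows.size):
        r, c = rows[k], cols[k]
        res = fit_pixel(
            pixel_stack[:, k],
            model,
            settings,
            times=times,
            anchor_value=float(anchor_vals[k]) if use_anchor else None,
            lookup=lookup,
        )
        tau[r, c] = res.map_value
        excluded[r, c] = res.excluded
        refined[r, c] = res.refined and not res.excluded
        if refined[r, c]:
            n_refined += 1
            tau_fit[r, c] = res.params.tau
            residual[r, c] = res.residual_pct
            a_map[r, c] = res.params.A
            b_map[r, c] = res.params.B
            if math.isfinite(res.tau_spread):
                max_spread = max(max_spread, res.tau_spread)
            all_monotone &= res.objective_monotone
        if res.excluded:
            n_excluded += 1

    provenance = {
        "model_id": model.model_id,
        "variant": model.variant,
        "settings_digest": settings.digest(),
        "sr_anchor_used": bool(use_anchor),
    }
    diagnostics = {
        "n_total": int(h * w),
        "n_candidates": int(rows.size),
        "n_refined": int(n_refined),
        "n_excluded": int(n_excluded),
        "max_tau_spread": max_spread,
        "objective_monotone": bool(all_monotone),
        "elapsed_s": time.perf_counter() - t_start,
    }
    return RelaxationMap(
        tau_map=tau,
        residual_map=residual,
        refined_mask=refined,
        excluded_mask=excluded,
        tau_fit_map=tau_fit,
        a_map=a_map,
        b_map=b_map,
        provenance=provenance,
        diagnostics=diagnostics,
    )


def fit_roi_mean(
    series: ImageSeries,
    model: SignalModel,
    settings: FitSettings = FitSettings(),
    roi: np.ndarray | None = None,
) -> FitResult:
    """Fit the ROI-averaged signal with the single-pixel pipeline."""
    _check_convention(series, model)
    if roi is None:
        raise ValueError("fit_roi_mean requires an ROI mask")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != series.shape:
        raise ValueError("roi shape does not match the image frames")
    if not roi.any():
        raise ValueError("roi is empty")
    frames, times, anchor = series.split_anchor()
    mean_series = frames[:, roi].mean(axis=1)
    anchor_value = float(anchor[roi].mean()) if (anchor is not None and model.offset_constrained) else None
    return fit_pixel(mean_series, model, settings, times=times, anchor_value=anchor_value)


def residual_map(series: ImageSeries, rmap: RelaxationMap, model: SignalModel) -> np.ndarray:
    """Recompute the spatial map of normalized mean absolute residuals (%).

    Unrefined pixels carry NaN.  Uses the raw fitted time constant (T1* for
    MOLLI), since the residual is defined against the fitted curve.
    """
    frames, times, _ = series.split_anchor()
    if rmap.shape != series.shape:
        raise ValueError("map and series shapes do not match")
    out = np.full(rmap.shape, np.nan)
    rows, cols = np.nonzero(rmap.refined_mask)
    for r, c in zip(rows, cols):
        params = ModelParams(A=rmap.a_map[r, c], B=rmap.b_map[r, c], tau=rmap.tau_fit_map[r, c])
        pred = predict_signal(model, params, times)
        values = frames[:, r, c]
        peak = np.max(np.abs(values))
        if peak > 0:
            out[r, c] = float(np.mean(np.abs(pred - values)) / peak * 100.0)
    return out
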