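"""Synthetic multi-vial relaxometry phantoms.

Emulates a Eurospin-style set of 12 gadolinium/agarose gel vials laid out on
a 3x4 grid, imaged with any of the supported signal models on realistic
timing schedules.  Magnitude data are corrupted with Rician noise (modulus
of two Gaussian-corrupted channels — the standard statistics of magnitude
MR images); signed (PSIR) data receive additive Gaussian noise.  Every
simulation is deterministic under a fixed seed and returns the aligned
per-pixel ground truth, so the whole mapping pipeline is testable without
scanner data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mapping import ImageSeries
from .models import get_model

__all__ = [
    "Vial",
    "PhantomSpec",
    "GroundTruth",
    "TIMING_PRESETS",
    "default_times",
    "default_eurospin_spec",
    "simulate_series",
    "simulate_molli_series",
    "molli_schedule",
    "vial_masks",
]

#: Per-sequence preparation-time schedules (ms) typical of phantom protocols.
TIMING_PRESETS: dict[str, tuple[float, ...]] = {
    "ir_se": (21, 60, 100, 200, 300, 500, 660, 900, 1050, 1300, 1600,
              2000, 2250, 2500, 3000, 3500, 4300),
    "psir": (150, 300, 400, 500, 700, 900, 1100, 1300, 1800, 2000, 2500,
             3000, 3700, 4300, 5000, 6300),
    "sr_bssfp": (150, 300, 400, 500, 700, 900, 1100, 1300, 1800, 2000,
                 2500, 3000, 3700, 4300, 5000, 5600, 6300, 8000),
    "molli": (130, 210, 1130, 1210, 2130, 2210, 3130, 4130),
    "se_t2_single": (6, 12, 20, 30, 40, 50, 70, 90, 120, 140, 180, 300, 400, 600, 1000),
    "se_t2_multi": (9, 18, 27, 36, 45, 54, 63, 72, 81, 90, 99, 108, 117, 126, 135, 144),
    "t2prep_bssfp": tuple(range(25, 201, 5)),
}

_MODEL_PRESET = {
    "ir_se_mag": "ir_se",
    "psir": "psir",
    "sr_bssfp": "sr_bssfp",
    "molli_mag": "molli",
    "molli_psir": "molli",
    "se_t2": "se_t2_multi",
    "t2prep_bssfp": "t2prep_bssfp",
}

# Reference-value ranges (ms) spanned by the vial presets at each field
# strength; interior vials are log-spaced between the endpoints.
_EUROSPIN_RANGES = {
    "1.5T": dict(t1=(214.0, 1643.0), t2=(46.0, 338.0)),
    "3T": dict(t1=(229.0, 1752.0), t2=(45.0, 316.0)),
}


def default_times(model_id: str) -> np.ndarray:
    """Default timing schedule for a model identifier."""
    base = model_id[:-3] if model_id.endswith(("_2p", "_3p")) else model_id
    try:
        return np.array(TIMING_PRESETS[_MODEL_PRESET[base]], dtype=float)
    except KeyError:
        raise ValueError(f"no timing preset for model {model_id!r}") from None


@dataclass(frozen=True)
class Vial:
    """One gel vial: circular region with homogeneous relaxation times."""

    center: tuple[float, float]  # (row, col)
    radius: float
    t1: float  # ms
    t2: float  # ms
    a: float = 100.0  # signal amplitude
    b: float = 2.0  # efficiency factor (T1 rows) / offset (T2 3p rows)


@dataclass
class PhantomSpec:
    """Configuration of one synthetic phantom acquisition."""

    vials: list[Vial]
    shape: tuple[int, int] = (72, 96)
    model_id: str = "sr_bssfp"
    variant: str = "3p"
    times: np.ndarray | None = None  # defaults to the model's preset schedule
    noise_sigma: float = 0.0
    seed: int = 0
    include_anchor: bool = False  # append an SR anchor frame (T2-prep 3p)

    def __post_init__(self) -> None:
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.size == 0:
                raise ValueError("timing schedule must not be empty")
        for i, u in enumerate(self.vials):
            for v in self.vials[i + 1:]:
                d = np.hypot(u.center[0] - v.center[0], u.center[1] - v.center[1])
                if d < u.radius + v.radius:
                    raise ValueError("vials must not overlap")

    def schedule(self) -> np.ndarray:
        return self.times if self.times is not None else default_times(self.model_id)


@dataclass
class GroundTruth:
    """Per-pixel true parameter maps aligned to a simulated series."""

    t1: np.ndarray
    t2: np.ndarray
    a: np.ndarray
    b: np.ndarray
    labels: np.ndarray  # 0 background, 1..n vial index


def vial_masks(spec: PhantomSpec) -> np.ndarray:
    """Integer label image: 0 background, k for vial k (1-based)."""
    h, w = spec.shape
    rr, cc = np.ogrid[:h, :w]
    labels = np.zeros((h, w), dtype=np.int16)
    for k, vial in enumerate(spec.vials, start=1):
        mask = (rr - vial.center[0]) ** 2 + (cc - vial.center[1]) ** 2 <= vial.radius**2
        labels[mask] = k
    return labels


def default_eurospin_spec(
    field_strength: str = "1.5T",
    model_id: str = "sr_bssfp",
    variant: str = "3p",
    shape: tuple[int, int] = (72, 96),
    radius: float | None = None,
    amplitude: float = 100.0,
    b: float | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    times: np.ndarray | None = None,
    include_anchor: bool = False,
) -> PhantomSpec:
    """Twelve-vial preset spanning the reference T1/T2 ranges at 1.5 T or 3 T.

    Vial T1 and T2 values are log-spaced between the endpoints of the
    reference ranges (endpoints included); vials sit on a 3x4 grid with a
    10 % margin.  ``b`` defaults to the model's ideal efficiency (2 for IR
    and MOLLI, 1 for SR) or, for 3-parameter T2 models, to 5 % of the
    amplitude as the additive offset.
    """
    if field_strength not in _EUROSPIN_RANGES:
        raise ValueError(f"unknown field strength {field_strength!r}; use '1.5T' or '3T'")
    rng = _EUROSPIN_RANGES[field_strength]
    t1s = np.geomspace(*rng["t1"], 12)
    t2s = np.geomspace(*rng["t2"], 12)
    model = get_model(model_id, variant)
    if b is None:
        if model.family == "t2":
            b = 0.05 * amplitude if model.n_params == 3 else 0.0
        else:
            b = model.ideal_b
    h, w = shape
    mr, mc = 0.1 * h, 0.1 * w
    cell_h, cell_w = (h - 2 * mr) / 3, (w - 2 * mc) / 4
    if radius is None:
        radius = 0.35 * min(cell_h, cell_w)
    vials = []
    for k in range(12):
        i, j = divmod(k, 4)
        center = (mr + (i + 0.5) * cell_h, mc + (j + 0.5) * cell_w)
        vials.append(Vial(center, radius, t1=float(t1s[k]), t2=float(t2s[k]),
                          a=amplitude, b=float(b)))
    return PhantomSpec(
        vials=vials, shape=shape, model_id=model_id, variant=variant,
        times=times, noise_sigma=noise_sigma, seed=seed, include_anchor=include_anchor,
    )


def _noiseless_frames(spec: PhantomSpec, model, times, truth: GroundTruth) -> np.ndarray:
    h, w = spec.shape
    frames = np.zeros((times.size, h, w))
    rr, cc = np.ogrid[:h, :w]
    for vial in spec.vials:
        mask = (rr - vial.center[0]) ** 2 + (cc - vial.center[1]) ** 2 <= vial.radius**2
        if model.family == "t1":
            tau = vial.t1
            if model.needs_look_locker:
                if vial.b <= 1.0:
                    raise ValueError("MOLLI synthesis requires efficiency B > 1")
                tau = vial.t1 / (vial.b - 1.0)  # synthesize the apparent T1*
            b = vial.b if model.n_params == 3 else model.ideal_b
            s = vial.a * (1.0 - b * np.exp(-times / tau))
            if model.magnitude:
                s = np.abs(s)
        else:
            b = vial.b if model.n_params == 3 else 0.0
            s = vial.a * np.exp(-times / vial.t2) + b
        frames[:, mask] = s[:, None]
        truth.t1[mask] = vial.t1
        truth.t2[mask] = vial.t2
        truth.a[mask] = vial.a
        truth.b[mask] = b if model.family == "t2" else vial.b
    return frames


def _add_noise(frames: np.ndarray, sigma: float, signed: bool, rng) -> np.ndarray:
    if sigma <= 0:
        return frames
    if signed:
        return frames + rng.normal(0.0, sigma, frames.shape)
    real = frames + rng.normal(0.0, sigma, frames.shape)
    imag = rng.normal(0.0, sigma, frames.shape)
    return np.hypot(real, imag)


def simulate_series(spec: PhantomSpec) -> tuple[ImageSeries, GroundTruth]:
    """Synthesize an image series (plus ground truth) for the spec's model.

    Magnitude conventions get Rician noise, signed conventions additive
    Gaussian noise; two calls with the same spec produce identical arrays.
    """
    model = get_model(spec.model_id, spec.variant)
    times = spec.schedule()
    h, w = spec.shape
    truth = GroundTruth(
        t1=np.zeros((h, w)), t2=np.zeros((h, w)),
        a=np.zeros((h, w)), b=np.zeros((h, w)), labels=vial_masks(spec),
    )
    frames = _noiseless_frames(spec, model, times, truth)
    anchor_index = None
    if spec.include_anchor:
        if not model.offset_constrained:
            raise ValueError("SR anchor frames apply only to 3-parameter T2 models")
        anchor = np.where(truth.labels > 0, truth.b, 0.0)
        frames = np.concatenate([frames, anchor[None]], axis=0)
        times = np.append(times, np.nan)
        anchor_index = frames.shape[0] - 1
    rng = np.random.default_rng(spec.seed)
    frames = _add_noise(frames, spec.noise_sigma, model.signed, rng)
    series = ImageSeries(
        frames=frames, times=times,
        convention=model.signal_convention,
        model_hint=model.model_id, sr_anchor_index=anchor_index,
    )
    return series, truth


# ---------------------------------------------------------------------------
# MOLLI breath-hold schemes

# images per inversion epoch and recovery beats between epochs
_MOLLI_SCHEMES = {
    "5(3b)3": ((5, 3), (3,)),
    "4(1b)3(1b)2": ((4, 3, 2), (1, 1)),
}


def molli_schedule(
    scheme: str = "5(3b)3",
    heart_rate_bpm: float = 60.0,
    ti_start: float = 130.0,
    ti_increment: float = 80.0,
) -> np.ndarray:
    """Merged inversion-time schedule of a MOLLI breath-hold scheme.

    Each inversion epoch k acquires its images at
    ``TI_k + j * RR`` (j = 0, 1, ...) with ``TI_k = ti_start + k *
    ti_increment`` and RR the cardiac interval; the merged TIs are sorted
    onto one recovery curve.  At 60 bpm the 5(3b)3 scheme yields the familiar
    eight delays 130, 210, 1130, ..., 4130 ms.
    """
    if scheme not in _MOLLI_SCHEMES:
        raise ValueError(
            f"unsupported MOLLI scheme {scheme!r}; supported: {sorted(_MOLLI_SCHEMES)}"
        )
    if not heart_rate_bpm > 0:
        raise ValueError("heart rate must be positive")
    groups, _pauses = _MOLLI_SCHEMES[scheme]
    rr = 60000.0 / heart_rate_bpm
    tis = [
        ti_start + k * ti_increment + j * rr
        for k, n_images in enumerate(groups)
        for j in range(n_images)
    ]
    return np.array(sorted(tis))


def simulate_molli_series(
    spec: PhantomSpec,
    scheme: str = "5(3b)3",
    heart_rate_bpm: float = 60.0,
) -> tuple[ImageSeries, GroundTruth]:
    """Simulate a MOLLI acquisition of the phantom at a given heart rate.

    The spec's vial ``t1`` values are the *true* T1; the apparent T1* used
    for synthesis is ``T1 / (B - 1)`` so that the Look-Locker correction
    recovers the truth exactly.  The spec's model must be a MOLLI row.
    """
    model = get_model(spec.model_id, spec.variant)
    if not model.needs_look_locker:
        raise ValueError("simulate_molli_series requires a MOLLI model")
    times = molli_schedule(scheme, heart_rate_bpm)
    return simulate_series(replace(spec, times=times))
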