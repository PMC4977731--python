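"""Relaxation signal models for quantitative T1/T2 mapping.

Each supported acquisition is described by a mono-exponential signal model
``S(t)`` of the preparation time ``t`` (inversion time TI, saturation time TS,
echo time TE or T2-preparation duration, all in ms):

====================  ============================================  =========================
model                 3-parameter form                              2-parameter form
====================  ============================================  =========================
``ir_se_mag``         ``|A (1 - B exp(-t/T1))|``                    ``|A (1 - 2 exp(-t/T1))|``
``psir``              ``A (1 - B exp(-t/T1))``                      ``A (1 - 2 exp(-t/T1))``
``sr_bssfp``          ``A (1 - B exp(-t/T1))``                      ``A (1 - exp(-t/T1))``
``molli_mag``         ``|A (1 - B exp(-t/T1*))|``                   n/a
``molli_psir``        ``A (1 - B exp(-t/T1*))``                     n/a
``se_t2``             ``A exp(-t/T2) + B``, ``B >= 0``              ``A exp(-t/T2)``
``t2prep_bssfp``      ``A exp(-t/T2) + B``, ``B >= 0``              ``A exp(-t/T2)``
====================  ============================================  =========================

``A`` is a signal amplitude, ``B`` a dimensionless recovery/efficiency factor
for the T1 models (2 for ideal inversion, 1 for ideal saturation) or an
additive signal offset for the 3-parameter T2 models, and the time constant is
T1, the apparent T1* (MOLLI) or T2.  The MOLLI readout perturbs the recovery
curve, so MOLLI fits estimate T1* and the Look-Locker correction
``T1 = T1* (B - 1)`` is applied afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SignalModel",
    "ModelParams",
    "MODEL_IDS",
    "get_model",
    "predict_signal",
    "look_locker_correct",
    "sr_anchor_prediction",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Unknown model identifier or model/operation mismatch."""


#: Stable model identifiers exposed in the CLI and config files.
MODEL_IDS = (
    "ir_se_mag",
    "psir",
    "sr_bssfp",
    "molli_mag",
    "molli_psir",
    "se_t2",
    "t2prep_bssfp",
)

# family: "t1" (recovery, tau = T1 or T1*) or "t2" (decay, tau = T2)
# fixed_b: value B is pinned to in the 2-parameter variant (None = no 2p row)
_MODEL_TABLE = {
    "ir_se_mag": dict(family="t1", magnitude=True, signed=False, look_locker=False, ideal_b=2.0),
    "psir": dict(family="t1", magnitude=False, signed=True, look_locker=False, ideal_b=2.0),
    "sr_bssfp": dict(family="t1", magnitude=False, signed=False, look_locker=False, ideal_b=1.0),
    "molli_mag": dict(family="t1", magnitude=True, signed=False, look_locker=True, ideal_b=2.0),
    "molli_psir": dict(family="t1", magnitude=False, signed=True, look_locker=True, ideal_b=2.0),
    "se_t2": dict(family="t2", magnitude=False, signed=False, look_locker=False, ideal_b=0.0),
    "t2prep_bssfp": dict(family="t2", magnitude=False, signed=False, look_locker=False, ideal_b=0.0),
}

_NO_2P = frozenset({"molli_mag", "molli_psir"})


@dataclass(frozen=True)
class SignalModel:
    """One signal model row together with its fit variant (2p or 3p)."""

    model_id: str
    n_params: int  # 2 or 3
    family: str  # "t1" or "t2"
    magnitude: bool  # prediction wrapped in |.|
    signed: bool  # input data may be negative (PSIR)
    needs_look_locker: bool
    ideal_b: float  # B under ideal preparation efficiency (0 for T2 rows)

    @property
    def variant(self) -> str:
        return f"{self.n_params}p"

    @property
    def signal_convention(self) -> str:
        return "signed" if self.signed else "magnitude"

    @property
    def offset_constrained(self) -> bool:
        """True for 3-parameter T2 rows, where the offset B must be >= 0."""
        return self.family == "t2" and self.n_params == 3

    @property
    def full_id(self) -> str:
        return f"{self.model_id}_{self.variant}"


def get_model(model_id: str, variant: str = "3p") -> SignalModel:
    """Resolve a model identifier (optionally suffixed ``_2p``/``_3p``).

    >>> get_model("sr_bssfp", "2p").full_id
    'sr_bssfp_2p'
    >>> get_model("se_t2_3p").offset_constrained
    True
    """
    if model_id.endswith(("_2p", "_3p")):
        model_id, variant = model_id[:-3], model_id[-2:]
    if model_id not in _MODEL_TABLE:
        raise ConfigurationError(
            f"unknown model {model_id!r}; choose from {', '.join(MODEL_IDS)}"
        )
    if variant not in ("2p", "3p"):
        raise ConfigurationError(f"unknown fit variant {variant!r}; use '2p' or '3p'")
    if variant == "2p" and model_id in _NO_2P:
        raise ConfigurationError(f"{model_id} has no 2-parameter variant")
    row = _MODEL_TABLE[model_id]
    return SignalModel(
        model_id=model_id,
        n_params=2 if variant == "2p" else 3,
        family=row["family"],
        magnitude=row["magnitude"],
        signed=row["signed"],
        needs_look_locker=row["look_locker"],
        ideal_b=row["ideal_b"],
    )


@dataclass
class ModelParams:
    """Parameters of one fitted curve.

    A      signal amplitude (arbitrary units)
    B      recovery/efficiency factor (T1 rows) or additive offset in signal
           units (T2 3-parameter rows); for 2-parameter variants B holds the
           fixed ideal value
    tau    time constant in ms (T1, T1* or T2)
    """

    A: float
    B: float
    tau: float

    def validate(self, model: SignalModel) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if model.offset_constrained and self.B < 0:
            raise ValueError(f"offset B must be >= 0 for {model.full_id}, got {self.B}")


def predict_signal(model: SignalModel, params: ModelParams, t):
    """Evaluate the model's predicted signal at preparation time(s) ``t`` (ms).

    ``t`` may be a scalar or array; times must be non-negative.  Magnitude
    rows apply the absolute value exactly as written in the model table.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("preparation times must be non-negative")
    if model.family == "t1":
        s = params.A * (1.0 - params.B * np.exp(-t / params.tau))
        if model.magnitude:
            s = np.abs(s)
    else:
        s = params.A * np.exp(-t / params.tau)
        if model.n_params == 3:
            s = s + params.B
    return s if s.ndim else float(s)


def look_locker_correct(t1_star: float, B: float) -> float:
    """Look-Locker correction of the apparent MOLLI T1*: ``T1 = T1* (B - 1)``.

    ``B <= 1`` yields a non-physical (non-positive) T1 and raises; callers
    flag such pixels for exclusion instead of emitting a silent value.
    """
    if not t1_star > 0:
        raise ValueError(f"t1_star must be positive, got {t1_star}")
    if B <= 1.0:
        raise ValueError(
            f"Look-Locker correction undefined for B <= 1 (got B={B}); flag the pixel"
        )
    return t1_star * (B - 1.0)


def sr_anchor_prediction(model: SignalModel, params: ModelParams) -> float:
    """Predicted signal of the saturation-recovery anchor sample.

    The anchor is an SR-prepared image appended to a T2-prepared series to
    stabilise the offset of the 3-parameter fit.  It is treated as a sample of
    the decay curve at infinite preparation duration, so its model prediction
    is the asymptote ``B``.
    """
    if not model.offset_constrained:
        raise ConfigurationError(
            f"SR anchor applies only to 3-parameter T2 models, not {model.full_id}"
        )
    return float(params.B)


def _exp_term(t: np.ndarray, tau: float) -> np.ndarray:
    """exp(-t/tau) with the tau -> 0+ limit (1 at t=0, 0 for t>0)."""
    if tau <= 0.0:
        return (t == 0.0).astype(float)
    return np.exp(-t / tau)


def t1_candidate_curve(times: np.ndarray, tau: float, B: float, magnitude: bool) -> np.ndarray:
    """Unit-amplitude ideal-efficiency recovery curve used by the lookup search."""
    s = 1.0 - B * _exp_term(times, tau)
    return np.abs(s) if magnitude else s


def predict_scalar(model: SignalModel, A: float, B: float, tau: float, t: float) -> float:
    """Fast scalar prediction used in inner fitting loops (no validation)."""
    if model.family == "t1":
        s = A * (1.0 - B * math.exp(-t / tau))
        return abs(s) if model.magnitude else s
    s = A * math.exp(-t / tau)
    return s + B if model.n_params == 3 else s
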