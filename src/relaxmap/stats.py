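"""Modified Bland-Altman agreement analysis.

The modified analysis plots the difference between a candidate measurement
and the reference standard against the *reference* (not the pair mean), and
summarises agreement as bias (mean difference), variability (sample SD of
the differences) and 95 % limits of agreement (bias ± 1.96 SD).  Percentage
forms divide each difference by its reference value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import RelaxationMap

__all__ = ["AgreementStats", "bland_altman", "per_vial_means", "plot_bland_altman",
           "agreement_report"]

_LOA_FACTOR = 1.96  # 95 % limits of agreement


@dataclass(frozen=True)
class AgreementStats:
    """Bias, variability and 95 % limits of agreement, in ms and percent."""

    bias_ms: float
    sd_ms: float
    loa_low_ms: float
    loa_high_ms: float
    bias_pct: float
    sd_pct: float
    loa_low_pct: float
    loa_high_pct: float
    n: int

    def __str__(self) -> str:  # "0.8 ± 8 ms (0.2 ± 1.2 %)" style
        return (f"{self.bias_ms:.1f} ± {self.sd_ms:.1f} ms "
                f"({self.bias_pct:.1f} ± {self.sd_pct:.1f} %), n={self.n}")


def bland_altman(measured, reference) -> AgreementStats:
    """Modified Bland-Altman statistics of measured vs reference values (ms).

    Differences are measured − reference; percentage forms are the per-pair
    differences divided by the reference values.  SD is the sample (n−1)
    standard deviation and requires at least two pairs.
    """
    measured = np.asarray(measured, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if measured.shape != reference.shape or measured.ndim != 1:
        raise ValueError("measured and reference must be matching 1-D vectors")
    if measured.size < 2:
        raise ValueError("need at least two pairs for the SD")
    if np.any(reference <= 0):
        raise ValueError("reference values must be positive")
    d = measured - reference
    p = d / reference * 100.0
    bias, sd = float(d.mean()), float(d.std(ddof=1))
    bias_p, sd_p = float(p.mean()), float(p.std(ddof=1))
    return AgreementStats(
        bias_ms=bias, sd_ms=sd,
        loa_low_ms=bias - _LOA_FACTOR * sd, loa_high_ms=bias + _LOA_FACTOR * sd,
        bias_pct=bias_p, sd_pct=sd_p,
        loa_low_pct=bias_p - _LOA_FACTOR * sd_p, loa_high_pct=bias_p + _LOA_FACTOR * sd_p,
        n=int(measured.size),
    )


def per_vial_means(
    rmap: RelaxationMap | np.ndarray,
    references,
    masks,
    refined_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Mean map value over the refined pixels of each vial, paired with its
    reference.

    ``masks`` is either a sequence of boolean masks or an integer label image
    (labels 1..n matching the order of ``references``).  Vials without any
    refined pixel are dropped with a warning.  Returns (measured, reference,
    kept vial indices).
    """
    if isinstance(rmap, RelaxationMap):
        tau, refined = rmap.tau_map, rmap.refined_mask
    else:
        tau = np.asarray(rmap, dtype=float)
        refined = refined_mask if refined_mask is not None else np.ones_like(tau, bool)
    references = np.asarray(references, dtype=float)
    if isinstance(masks, np.ndarray) and masks.ndim == 2 and masks.dtype != bool:
        masks = [masks == k for k in range(1, references.size + 1)]
    if len(masks) != references.size:
        raise ValueError("one mask per reference value required")
    measured, refs, kept = [], [], []
    for i, mask in enumerate(masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != tau.shape:
            raise ValueError("vial mask shape does not match the map")
        sel = mask & refined
        if not sel.any():
            warnings.warn(f"vial {i + 1} has no refined pixels; pair dropped", stacklevel=2)
            continue
        measured.append(float(tau[sel].mean()))
        refs.append(float(references[i]))
        kept.append(i)
    return np.array(measured), np.array(refs), kept


def agreement_report(measured, reference, kept=None) -> pd.DataFrame:
    """Tidy per-pair table of the agreement analysis (for CSV export)."""
    measured = np.asarray(measured, dtype=float)
    reference = np.asarray(reference, dtype=float)
    vial = (np.asarray(kept) + 1) if kept is not None else np.arange(1, measured.size + 1)
    return pd.DataFrame({
        "vial": vial,
        "measured_ms": measured,
        "reference_ms": reference,
        "difference_ms": measured - reference,
        "difference_pct": (measured - reference) / reference * 100.0,
    })


def plot_bland_altman(measured, reference, path=None, ax=None, title=None):
    """Difference-vs-reference plot with bias and 95 % limits of agreement."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    stats = bland_altman(measured, reference)
    measured = np.asarray(measured, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(reference, measured - reference, color="k", s=18)
    ax.axhline(stats.bias_ms, ls=":", color="tab:blue", label=f"bias {stats.bias_ms:.1f} ms")
    for loa in (stats.loa_low_ms, stats.loa_high_ms):
        ax.axhline(loa, ls="--", color="tab:red")
    ax.set_xlabel("reference (ms)")
    ax.set_ylabel("measured − reference (ms)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
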