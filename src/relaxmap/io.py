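"""Reading image series (DICOM, NIfTI + JSON sidecar) and writing maps.

Preparation times are resolved from standard DICOM tags only (Inversion
Time, Echo Time, Trigger Time as a MOLLI fallback); vendor private headers
are out of scope, but a JSON sidecar always overrides whatever the DICOM
tags say, so any vendor's data remains usable.  Times are milliseconds
everywhere; sidecars declaring other units are rejected, never converted
silently.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mapping import ImageSeries, RelaxationMap

__all__ = [
    "SeriesManifest",
    "MetadataError",
    "read_dicom_series",
    "read_volume_with_sidecar",
    "write_series",
    "write_map",
    "read_map",
    "write_png_preview",
    "read_roi",
    "write_roi",
]


class MetadataError(ValueError):
    """Timing metadata could not be resolved from the input files."""


@dataclass
class SeriesManifest:
    """Provenance of a loaded series: files, resolved times and their origin."""

    files: list[str]
    times_ms: list[float]
    time_source: str  # DICOM tag name or "sidecar"
    convention: str
    model_hint: str | None = None
    extras: dict = field(default_factory=dict)


_SIGNED_HINTS = {"psir", "molli_psir"}
# priority order for resolving the per-frame preparation time
_TIME_TAGS = ("InversionTime", "EchoTime", "TriggerTime")


def read_dicom_series(paths, model_hint: str | None = None):
    """Load a co-registered DICOM series, resolving per-frame times.

    ``paths`` is a directory or an iterable of file paths.  The preparation
    time is taken from the first standard tag (Inversion Time, Echo Time,
    Trigger Time) that is present on every frame and varies across frames;
    frames are then sorted by time.  Returns ``(ImageSeries,
    SeriesManifest)``.
    """
    import pydicom

    if isinstance(paths, (str, os.PathLike)):
        root = Path(paths)
        paths = sorted(p for p in root.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
        if not paths:
            paths = sorted(p for p in root.iterdir() if p.is_file())
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no DICOM files found")
    dsets = [pydicom.dcmread(str(p)) for p in paths]

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in dsets}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame geometries in series: {sorted(shapes)}")

    times, source = _resolve_times(dsets, paths)
    frames = []
    for ds in dsets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        frames.append(arr * slope + intercept)
    order = np.argsort(times, kind="stable")
    frames = np.stack([frames[i] for i in order])
    times = [times[i] for i in order]
    paths = [paths[i] for i in order]

    convention = "signed" if model_hint in _SIGNED_HINTS else "magnitude"
    extras = {}
    for key in ("MagneticFieldStrength", "SequenceName", "SeriesDescription"):
        val = getattr(dsets[0], key, None)
        if val is not None:
            extras[key] = str(val)
    series = ImageSeries(frames=frames, times=np.array(times), convention=convention,
                         model_hint=model_hint)
    manifest = SeriesManifest(
        files=[str(p) for p in paths], times_ms=list(map(float, times)),
        time_source=source, convention=convention, model_hint=model_hint, extras=extras,
    )
    return series, manifest


def _resolve_times(dsets, paths):
    diagnostics = []
    for tag in _TIME_TAGS:
        present = [getattr(ds, tag, None) is not None for ds in dsets]
        if not any(present):
            diagnostics.append(f"{tag}: absent on all frames")
            continue
        if not all(present):
            missing = [str(p) for p, ok in zip(paths, present) if not ok]
            raise MetadataError(f"tag {tag} missing on frames: {', '.join(missing)}")
        values = [float(getattr(ds, tag)) for ds in dsets]
        if len(dsets) > 1 and len(set(values)) == 1:
            diagnostics.append(f"{tag}: constant ({values[0]} ms) — not a varying preparation time")
            continue
        return values, tag
    per_file = "; ".join(diagnostics) or "no candidate tags found"
    raise MetadataError(f"no resolvable preparation times ({per_file})")


def read_volume_with_sidecar(volume_path, sidecar_path) -> ImageSeries:
    """Load a NIfTI frame stack plus its JSON timing sidecar.

    The sidecar lists one time (ms) per frame under ``times_ms`` (``null``
    marks the SR anchor frame, optionally cross-checked against
    ``anchor_index``), an optional ``convention`` and an optional ``units``
    key that must be ``"ms"``.
    """
    import nibabel as nib

    with open(sidecar_path) as fh:
        meta = json.load(fh)
    units = meta.get("units", "ms")
    if units != "ms":
        raise ValueError(f"sidecar times must be in ms, got units={units!r}")
    if "times_ms" not in meta:
        raise ValueError("sidecar must contain a 'times_ms' list")
    raw_times = meta["times_ms"]
    times = np.array([math.nan if t is None else float(t) for t in raw_times])

    vol = np.asanyarray(nib.load(str(volume_path)).dataobj).astype(float)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D volume (height, width, frames), got {vol.shape}")
    frames = np.transpose(vol, (2, 0, 1))
    if frames.shape[0] != times.size:
        raise ValueError(
            f"sidecar lists {times.size} times for {frames.shape[0]} frames"
        )
    anchor = meta.get("anchor_index")
    nan_pos = np.nonzero(~np.isfinite(times))[0]
    if anchor is None and nan_pos.size == 1:
        anchor = int(nan_pos[0])
    if anchor is not None and nan_pos.size and int(anchor) not in nan_pos:
        raise ValueError("anchor_index does not match the null entry in times_ms")
    return ImageSeries(
        frames=frames, times=times,
        convention=meta.get("convention", "magnitude"),
        model_hint=meta.get("model_hint"),
        sr_anchor_index=None if anchor is None else int(anchor),
    )


def write_series(series: ImageSeries, volume_path, sidecar_path) -> None:
    """Write an ImageSeries as a NIfTI volume plus JSON sidecar (round-trips
    through :func:`read_volume_with_sidecar`)."""
    import nibabel as nib

    vol = np.transpose(series.frames, (1, 2, 0))
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(volume_path))
    times = [None if not math.isfinite(t) else float(t) for t in series.times]
    meta = {
        "times_ms": times,
        "units": "ms",
        "convention": series.convention,
        "model_hint": series.model_hint,
        "anchor_index": series.sr_anchor_index,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# Relaxation map output

_MAP_ARRAYS = {
    "tau": ("tau_map", float),
    "residual": ("residual_map", float),
    "tau_fit": ("tau_fit_map", float),
    "amplitude": ("a_map", float),
    "offset": ("b_map", float),
    "refined_mask": ("refined_mask", np.uint8),
    "excluded_mask": ("excluded_mask", np.uint8),
}


def write_map(rmap: RelaxationMap, out_dir) -> dict[str, str]:
    """Write a relaxation map losslessly (float64 NIfTI per array) plus a
    provenance JSON; returns the written paths."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, (attr, dtype) in _MAP_ARRAYS.items():
        arr = np.asarray(getattr(rmap, attr)).astype(dtype)
        path = out_dir / f"{name}.nii"
        nib.save(nib.Nifti1Image(arr, np.eye(4)), str(path))
        written[name] = str(path)
    meta = {"provenance": rmap.provenance, "diagnostics": rmap.diagnostics}
    meta_path = out_dir / "provenance.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, default=float)
    written["provenance"] = str(meta_path)
    return written


def read_map(map_dir) -> RelaxationMap:
    """Read back a map written by :func:`write_map` (lossless round trip)."""
    import nibabel as nib

    map_dir = Path(map_dir)
    arrays = {}
    for name, (attr, dtype) in _MAP_ARRAYS.items():
        arr = np.asanyarray(nib.load(str(map_dir / f"{name}.nii")).dataobj)
        arrays[attr] = arr.astype(bool) if dtype is np.uint8 else arr.astype(float)
    with open(map_dir / "provenance.json") as fh:
        meta = json.load(fh)
    return RelaxationMap(provenance=meta.get("provenance", {}),
                         diagnostics=meta.get("diagnostics", {}), **arrays)


def write_png_preview(rmap: RelaxationMap, path, window: tuple[float, float] = (0.0, 2000.0)):
    """16-bit PNG preview of the tau map with a fixed window.

    The scale factor (map ms per PNG unit) is documented in a JSON file next
    to the image; the PNG is for inspection only, the NIfTI is authoritative.
    """
    import imageio.v3 as iio

    lo, hi = window
    if not hi > lo:
        raise ValueError("window must be increasing")
    scaled = np.clip((rmap.tau_map - lo) / (hi - lo), 0.0, 1.0)
    img = (scaled * 65535).astype(np.uint16)
    iio.imwrite(path, img)
    scale_doc = {"window_ms": [lo, hi], "ms_per_unit": (hi - lo) / 65535.0}
    with open(str(path) + ".json", "w") as fh:
        json.dump(scale_doc, fh, indent=1)
    return scale_doc


# ---------------------------------------------------------------------------
# ROI masks: binary PNG or run-length text

def read_roi(path) -> np.ndarray:
    """Read a binary ROI mask from PNG (nonzero = inside) or run-length text."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        img = iio.imread(path)
        if img.ndim == 3:
            img = img[..., 0]
        return img > 0
    return _read_rle(path)


def write_roi(mask: np.ndarray, path) -> None:
    mask = np.asarray(mask, dtype=bool)
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, (mask * 255).astype(np.uint8))
    else:
        _write_rle(mask, path)


def _write_rle(mask: np.ndarray, path) -> None:
    """Run-length text: 'H W' header, then alternating run lengths of the
    flattened mask starting with a (possibly zero) run of False."""
    flat = mask.ravel()
    runs = []
    current, count = False, 0
    for v in flat:
        if v == current:
            count += 1
        else:
            runs.append(count)
            current, count = v, 1
    runs.append(count)
    with open(path, "w") as fh:
        fh.write(f"{mask.shape[0]} {mask.shape[1]}\n")
        fh.write(" ".join(map(str, runs)) + "\n")


def _read_rle(path) -> np.ndarray:
    with open(path) as fh:
        h, w = map(int, fh.readline().split())
        runs = list(map(int, fh.readline().split()))
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for run in runs:
        flat[pos:pos + run] = val
        pos += run
        val = not val
    if pos != h * w:
        raise ValueError("run lengths do not cover the mask")
    return flat.reshape(h, w)
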