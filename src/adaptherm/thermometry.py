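"""Temperature-map data model and acquisition I/O.

A :class:`TemperatureMap` is one 2D grid of absolute temperatures (°C) on a
rotated slice frame at one acquisition time, together with a validity mask
that is False inside the applicator-artifact band and other corrupted pixels.

Series are stored on disk as per-image CSV grids (or NIfTI) plus a JSON
manifest carrying the acquisition order, frame geometry and baseline.
Phase images can be converted to temperature with the standard proton
resonance frequency shift (PRFS) relation

    dT = d_phi / (gamma * alpha * B0 * TE)

with gamma the proton gyromagnetic ratio (rad/s/T), alpha the PRF thermal
coefficient (about -0.01 ppm/°C) and B0 the field strength.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .geometry import SliceFrame

__all__ = [
    "GAMMA_PROTON",
    "TemperatureMap",
    "phase_to_temperature",
    "mask_applicator_band",
    "read_series",
    "write_series",
]

#: proton gyromagnetic ratio, rad / (s * T)
GAMMA_PROTON = 2.0 * np.pi * 42.576e6

#: PRF thermal coefficient, ppm / °C (literature standard)
DEFAULT_PRF_COEFF = -0.01


@dataclass
class TemperatureMap:
    """One 2D absolute-temperature image on a rotated frame."""

    values: np.ndarray
    frame: SliceFrame
    time_index: int = 0
    baseline_T0: float = 21.0
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.frame.matrix):
            raise ValueError("values shape must equal frame.matrix")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise ValueError("valid_mask shape must equal values shape")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("values must be finite where valid_mask is true")

    def copy(self) -> "TemperatureMap":
        return replace(self, values=self.values.copy(),
                       valid_mask=self.valid_mask.copy())


def phase_to_temperature(
    phase_diff: np.ndarray,
    echo_time_ms: float,
    field_strength: float,
    thermal_coeff: float = DEFAULT_PRF_COEFF,
    baseline_T0: float = 21.0,
    frame: SliceFrame | None = None,
    time_index: int = 0,
) -> TemperatureMap:
    """PRFS conversion of a phase-difference image (radians) to °C.

    ``thermal_coeff`` is in ppm/°C; ``echo_time_ms`` in milliseconds.
    """
    if echo_time_ms <= 0:
        raise ValueError("echo_time must be positive")
    if field_strength <= 0:
        raise ValueError("field_strength must be positive")
    if thermal_coeff == 0:
        raise ValueError("thermal_coeff must be non-zero")
    phase_diff = np.asarray(phase_diff, float)
    dT = phase_diff / (
        GAMMA_PROTON * thermal_coeff * 1e-6 * field_strength * echo_time_ms * 1e-3
    )
    if frame is None:
        frame = SliceFrame(angle=0.0, matrix=phase_diff.shape)
    return TemperatureMap(
        values=baseline_T0 + dT,
        frame=frame,
        time_index=time_index,
        baseline_T0=baseline_T0,
    )


def mask_applicator_band(tmap: TemperatureMap, half_width: int = 2) -> TemperatureMap:
    """Invalidate the corrupted band of +-``half_width`` columns around the axis.

    The applicator erases or distorts thermal information around its own
    axis; those pixels must not feed the isotherm filter.  ``half_width = 0``
    leaves the map unchanged.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    out = tmap.copy()
    if half_width == 0:
        return out
    ncols = out.values.shape[1]
    c0 = int(round(out.frame.axis_column))
    lo = max(0, c0 - half_width)
    hi = min(ncols, c0 + half_width + 1)
    out.valid_mask[:, lo:hi] = False
    return out


# ---------------------------------------------------------------------------
# series I/O: per-image CSV (or NIfTI) + JSON manifest

def write_series(path, maps: list[TemperatureMap], fmt: str = "csv") -> Path:
    """Write an acquisition series; returns the manifest path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for m in maps:
        stem = f"t{m.time_index:04d}"
        if fmt == "csv":
            fn = f"{stem}.csv"
            np.savetxt(path / fn, m.values.astype(np.float32), delimiter=",")
        elif fmt == "nifti":
            import nibabel as nib

            fn = f"{stem}.nii.gz"
            nib.save(nib.Nifti1Image(m.values.astype(np.float32), np.eye(4)),
                     path / fn)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        mfn = f"{stem}.mask.csv"
        np.savetxt(path / mfn, m.valid_mask.astype(np.uint8), delimiter=",",
                   fmt="%d")
        entries.append({
            "file": fn,
            "mask_file": mfn,
            "time_index": int(m.time_index),
            "baseline_T0": float(m.baseline_T0),
            "frame": json.loads(m.frame.to_json()),
        })
    manifest = path / "series.json"
    manifest.write_text(json.dumps({"format": fmt, "images": entries}, indent=1))
    return manifest


def read_series(path) -> list[TemperatureMap]:
    """Read a series written by :func:`write_series`, sorted by time index."""
    path = Path(path)
    manifest = path / "series.json"
    if not manifest.exists():
        if path.is_dir() and not any(path.iterdir()):
            return []
        raise IOError(f"missing series manifest: {manifest}")
    try:
        meta = json.loads(manifest.read_text())
    except json.JSONDecodeError as e:
        raise IOError(f"unreadable manifest {manifest}: {e}") from e
    fmt = meta.get("format", "csv")
    maps = []
    for entry in meta["images"]:
        f = path / entry["file"]
        if not f.exists():
            raise IOError(f"missing series file: {f}")
        if fmt == "csv":
            values = np.loadtxt(f, delimiter=",", ndmin=2)
        elif fmt == "nifti":
            import nibabel as nib

            values = np.asanyarray(nib.load(f).dataobj)
        elif fmt == "dicom_phase":
            # phase-difference DICOMs: rescale to radians, then PRFS-convert
            # using the acquisition parameters recorded in the manifest
            import pydicom

            ds = pydicom.dcmread(f)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            phase = ds.pixel_array.astype(np.float64) * slope + intercept
            prfs = meta.get("prfs", {})
            values = phase_to_temperature(
                phase,
                echo_time_ms=float(prfs.get("echo_time_ms", 3.69)),
                field_strength=float(prfs.get("field_strength", 1.5)),
                thermal_coeff=float(prfs.get("thermal_coeff",
                                             DEFAULT_PRF_COEFF)),
                baseline_T0=float(entry["baseline_T0"]),
            ).values
        else:
            raise IOError(f"unknown series format {fmt!r}")
        mask = None
        if entry.get("mask_file"):
            mf = path / entry["mask_file"]
            if mf.exists():
                mask = np.loadtxt(mf, delimiter=",", ndmin=2).astype(bool)
        try:
            frame = SliceFrame.from_json(json.dumps(entry["frame"]))
        except (KeyError, TypeError) as e:
            raise ValueError(f"missing frame metadata in manifest: {e}") from e
        maps.append(TemperatureMap(
            values=values, frame=frame,
            time_index=int(entry["time_index"]),
            baseline_T0=float(entry["baseline_T0"]),
            valid_mask=mask,
        ))
    maps.sort(key=lambda m: m.time_index)
    return maps
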