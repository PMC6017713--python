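"""File I/O: frame stacks and complex images as 32-bit float TIFF with JSON
sidecars, metrics as CSV, and provenance records."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .lockin import MetricsRecord, ThermalFrameStack
from .model import ComplexSurfaceImage

__all__ = [
    "write_frame_stack", "read_frame_stack",
    "write_complex_image", "read_complex_image",
    "write_metrics_csv", "provenance_record",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_frame_stack(path: str | Path, stack: ThermalFrameStack) -> Path:
    """Multi-page float32 TIFF plus a JSON sidecar with rate and pitch."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    _sidecar(path).write_text(json.dumps({
        "frame_rate_hz": stack.frame_rate,
        "pixel_pitch_m": stack.pixel_pitch,
        "n_frames": stack.n_frames,
    }, indent=2))
    return path


def read_frame_stack(path: str | Path) -> ThermalFrameStack:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    frames = tifffile.imread(path).astype(np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    return ThermalFrameStack(frames, meta["frame_rate_hz"], meta["pixel_pitch_m"])


def write_complex_image(prefix: str | Path, image: ComplexSurfaceImage) -> tuple[Path, Path]:
    """Paired magnitude/phase float32 TIFFs (``<prefix>_mag.tiff`` etc.)."""
    prefix = Path(prefix)
    mag_path = prefix.with_name(prefix.name + "_mag.tiff")
    ph_path = prefix.with_name(prefix.name + "_phase.tiff")
    tifffile.imwrite(mag_path, image.magnitude.astype(np.float32))
    tifffile.imwrite(ph_path, image.phase.astype(np.float32))
    _sidecar(mag_path).write_text(json.dumps({
        "pixel_pitch_m": [image.dx, image.dy],
        "frequency_hz": image.frequency,
    }, indent=2))
    return mag_path, ph_path


def read_complex_image(prefix: str | Path) -> ComplexSurfaceImage:
    prefix = Path(prefix)
    mag_path = prefix.with_name(prefix.name + "_mag.tiff")
    ph_path = prefix.with_name(prefix.name + "_phase.tiff")
    meta = json.loads(_sidecar(mag_path).read_text())
    mag = tifffile.imread(mag_path).astype(np.float64)
    phase = tifffile.imread(ph_path).astype(np.float64)
    dx, dy = meta["pixel_pitch_m"]
    return ComplexSurfaceImage(mag * np.exp(1j * phase), dx, dy,
                               meta["frequency_hz"])


def write_metrics_csv(path: str | Path, records: dict[str, MetricsRecord]) -> Path:
    """One row per labelled scene; FWHM lists joined with ';'."""
    rows = []
    for label, rec in records.items():
        d = asdict(rec)
        d["fwhm_mm"] = ";".join(f"{f:.6g}" for f in rec.fwhm_mm)
        rows.append({"label": label, **d})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def provenance_record(config_hash: str, seed: int | None) -> dict:
    import numpy
    import scipy

    from . import __version__

    return {
        "config_hash": config_hash,
        "seed": seed,
        "versions": {
            "thermolock": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }
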