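"""File formats for stacks, fields, series, and patch metadata.

Stacks are stored as multi-page TIFF (frame order = ascending theta)
with the theta list in a sidecar JSON, or as a numbered PNG series.
Tables (Sigma fields, intensity series, counts, spectra) are CSV with
header.  All angles are degrees.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .synthgen import EyeshineStack

#: Acquisition geometry of the eyeshine protocol: 21-deg patches at four
#: elevations along one of two azimuths.
ELEVATIONS_DEG = (-30, 0, 30, 60)
AZIMUTHS_DEG = (10, 15)


@dataclass(frozen=True)
class PatchMetadata:
    """Specimen and acquisition metadata carried through the pipeline."""

    individual_id: str
    sex: str
    elevation_deg: float
    azimuth_deg: float
    patch_angle_deg: float = 21.0

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.elevation_deg not in ELEVATIONS_DEG:
            warnings.warn(
                f"elevation {self.elevation_deg} outside the standard "
                f"acquisition set {ELEVATIONS_DEG}",
                stacklevel=2,
            )
        if self.azimuth_deg not in AZIMUTHS_DEG:
            warnings.warn(
                f"azimuth {self.azimuth_deg} outside the standard "
                f"acquisition set {AZIMUTHS_DEG}",
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return asdict(self)


def write_stack_tiff(stack: EyeshineStack, path: str | Path) -> None:
    """Multi-page TIFF (one page per theta) plus a `.json` sidecar with
    thetas, channel, and lattice geometry."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32))
    sidecar = {
        "thetas_deg": list(map(float, stack.thetas)),
        "channel": stack.channel,
        "pixel_scale": stack.pixel_scale,
        "origin": list(stack.origin),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_stack_tiff(path: str | Path) -> EyeshineStack:
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return EyeshineStack(
        thetas=np.asarray(meta["thetas_deg"], dtype=float),
        frames=frames,
        channel=meta.get("channel", "mono"),
        pixel_scale=float(meta.get("pixel_scale", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
    )


def write_stack_png_series(stack: EyeshineStack, directory: str | Path,
                           prefix: str = "frame") -> None:
    """Numbered 16-bit PNG series plus sidecar JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = np.asarray(stack.frames, dtype=float)
    peak = frames.max() if frames.max() > 0 else 1.0
    for i, frame in enumerate(frames):
        scaled = np.clip(frame / peak * 65535.0, 0, 65535).astype(np.uint16)
        iio.imwrite(directory / f"{prefix}_{i:03d}.png", scaled)
    sidecar = {
        "thetas_deg": list(map(float, stack.thetas)),
        "channel": stack.channel,
        "pixel_scale": stack.pixel_scale,
        "origin": list(stack.origin),
        "intensity_scale": float(peak / 65535.0),
    }
    (directory / f"{prefix}_meta.json").write_text(json.dumps(sidecar, indent=1))


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
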