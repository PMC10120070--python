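"""ROI-grid photometry of registered eyeshine image stacks.

A hexagonal grid of circular regions of interest, one per ommatidium, is
placed over the stack; the mean pixel intensity inside each ROI is read
out frame by frame, giving one intensity-versus-theta series per
ommatidium.  Stacks are assumed registered (no inter-frame shift).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .lattice import axial_to_pixel, coord_label
from .synthgen import EyeshineStack

Coord = tuple[int, int]


@dataclass(frozen=True)
class HexROIGrid:
    """Circular ROIs on a pointy-top hexagonal lattice.

    ``centers`` maps axial coordinates to pixel positions ``(x, y)``;
    ``radius`` is the common ROI radius in pixels.  ROIs must be pairwise
    non-overlapping and lie fully inside the reference image.
    """

    centers: Mapping[Coord, tuple[float, float]]
    radius: float
    labels: Mapping[Coord, str] | None = None

    def __post_init__(self):
        pts = list(self.centers.values())
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        arr = np.asarray(pts, dtype=float)
        if len(arr) > 1:
            d2 = np.sum((arr[:, None, :] - arr[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            if np.sqrt(d2.min()) < 2.0 * self.radius - 1e-9:
                raise ValueError(
                    "ROI circles overlap: nearest centre distance "
                    f"{np.sqrt(d2.min()):.3f} px < 2*radius"
                )


def build_roi_grid(
    reference_image: np.ndarray,
    spacing: float,
    radius: float,
    origin: tuple[float, float],
    n_rows: int,
    n_cols: int,
) -> HexROIGrid:
    """Lay a rows x cols rhombic hex grid of circular ROIs over an image.

    Raises if ``radius >= spacing / 2`` (overlapping circles) or if any
    centre comes closer than ``radius`` to the image border.
    """
    if radius >= spacing / 2.0:
        raise ValueError(
            f"radius {radius} >= spacing/2 = {spacing / 2}: ROIs would overlap"
        )
    img = np.asarray(reference_image)
    h, w = img.shape[:2]
    centers: dict[Coord, tuple[float, float]] = {}
    out_of_bounds = []
    for r in range(n_rows):
        for q in range(n_cols):
            x, y = axial_to_pixel(q, r, spacing, origin)
            if not (radius <= x <= w - 1 - radius and radius <= y <= h - 1 - radius):
                out_of_bounds.append((q, r))
            centers[(q, r)] = (x, y)
    if out_of_bounds:
        raise ValueError(
            f"ROI centres out of image bounds at coordinates {out_of_bounds}"
        )
    labels = {c: coord_label(*c) for c in centers}
    return HexROIGrid(centers=centers, radius=radius, labels=labels)


def grid_from_stack(stack: EyeshineStack, radius: float,
                    n_rows: int, n_cols: int) -> HexROIGrid:
    """ROI grid inheriting the lattice geometry a synthetic stack was
    rendered with (spacing and origin)."""
    ref = stack.frames[0] if stack.frames.ndim == 3 else stack.frames[0, ..., 0]
    return build_roi_grid(
        ref, stack.pixel_scale, radius, stack.origin, n_rows, n_cols
    )


@dataclass(frozen=True)
class IntensitySeries:
    """Mean ROI intensity of one ommatidium as a function of theta."""

    coordinate: Coord
    thetas: np.ndarray
    values: np.ndarray
    channel: str = "mono"

    def __post_init__(self):
        thetas = np.asarray(self.thetas, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if thetas.shape != values.shape:
            raise ValueError("thetas and values must have the same length")
        if np.any(values < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "thetas", thetas)
        object.__setattr__(self, "values", values)


def _roi_mask(shape: tuple[int, int], center: tuple[float, float],
              radius: float) -> np.ndarray:
    # pixel-centre inclusion: a pixel belongs to the ROI iff its centre
    # lies within `radius` of the ROI centre (no partial-pixel weighting)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def extract_intensity_series(
    stack: EyeshineStack,
    grid: HexROIGrid,
    channel: str = "mono",
) -> dict[Coord, IntensitySeries]:
    """One intensity-versus-theta series per ROI.

    The per-frame value is the arithmetic mean over pixels whose centres
    lie inside the circular ROI.
    """
    frames = stack.frame_channel(channel)
    shape = frames.shape[1:3]
    out: dict[Coord, IntensitySeries] = {}
    for coord, center in grid.centers.items():
        mask = _roi_mask(shape, center, grid.radius)
        if not mask.any():
            raise ValueError(f"ROI at {coord} covers no pixels")
        values = frames[:, mask].mean(axis=1)
        out[coord] = IntensitySeries(
            coordinate=coord,
            thetas=stack.thetas,
            values=values,
            channel=channel,
        )
    return out


def bleaching_ratio(first_frame: np.ndarray, control_frame: np.ndarray,
                    grid: HexROIGrid) -> float:
    """Before/after mean-intensity ratio over all ROIs.

    A control frame retaken at the initial theta after the acquisition
    series quantifies photo-bleaching; no correction is applied.
    """
    shape = np.asarray(first_frame).shape[:2]
    masks = [_roi_mask(shape, c, grid.radius) for c in grid.centers.values()]
    before = np.mean([np.asarray(first_frame)[m].mean() for m in masks])
    after = np.mean([np.asarray(control_frame)[m].mean() for m in masks])
    if before == 0:
        raise ValueError("zero mean intensity in first frame ROIs")
    return float(after / before)


def series_to_frame(
    series: Mapping[Coord, IntensitySeries], patch_id: str = "patch0"
) -> pd.DataFrame:
    """Long-format table (patch_id, q, r, channel, theta_deg, intensity)."""
    records = []
    for (q, r), s in sorted(series.items()):
        for th, v in zip(s.thetas, s.values):
            records.append(
                {
                    "patch_id": patch_id,
                    "q": q,
                    "r": r,
                    "channel": s.channel,
                    "theta_deg": th,
                    "intensity": v,
                }
            )
    return pd.DataFrame(records)


def series_from_frame(frame: pd.DataFrame) -> dict[Coord, IntensitySeries]:
    """Inverse of :func:`series_to_frame` (single patch, single channel)."""
    out: dict[Coord, IntensitySeries] = {}
    for (q, r), grp in frame.groupby(["q", "r"]):
        grp = grp.sort_values("theta_deg")
        out[(int(q), int(r))] = IntensitySeries(
            coordinate=(int(q), int(r)),
            thetas=grp["theta_deg"].to_numpy(),
            values=grp["intensity"].to_numpy(),
            channel=str(grp["channel"].iloc[0]),
        )
    return out
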