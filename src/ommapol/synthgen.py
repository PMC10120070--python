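"""Synthetic inputs for the eyeshine / polarization-vision pipeline.

Everything the downstream analysis consumes can be generated here with a
fixed seed: per-ommatidium principal-axis (Sigma) fields on a hexagonal
lattice, depolarized-eyeshine image stacks over eye roll angle theta,
polarization image pairs of known degree of polarization, Gaussian-peaked
wing reflectance spectra, photoreceptor sensitivity templates, and
per-site behavioural approach counts.

The eyeshine intensity law is phenomenological: depolarized eyeshine of an
ommatidium with principal axis Sigma illuminated at roll angle theta is

    I(theta) = background + baseline + amplitude * sin^2(2 * (theta - Sigma))

which has zeros of the modulated term at theta = Sigma (mod 90 deg) and
maxima at Sigma + 45 (mod 90), i.e. minima separated by 90 deg with the
maxima halfway between — the qualitative signature of rhabdomeric
birefringence in straight rhabdoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lattice import axial_to_pixel, coord_label, rhombic_coords

Coord = tuple[int, int]

# Signed per-cell axial offsets (deg) and weights for the "fig3d" mixture.
# The weights are solved so that the axial difference of two independent
# draws reproduces the published adjacent-pair dissimilarity fractions:
# 22% exactly aligned, 50% within +-5 deg, 30% >= 15 deg, 15% >= 20 deg.
FIG3D_OFFSETS_DEG = (0.0, 2.5, -2.5, 7.5, -7.5, 16.0, -16.0, 30.0, -30.0)
_FIG3D_W = (
    0.4081858160100128,
    0.26021898377427094,
    0.12953568292395987,
    0.13153584227295134,
    0.07052367502097845,
)
FIG3D_WEIGHTS = (
    _FIG3D_W[0],
    _FIG3D_W[1] / 2, _FIG3D_W[1] / 2,
    _FIG3D_W[2] / 2, _FIG3D_W[2] / 2,
    _FIG3D_W[3] / 2, _FIG3D_W[3] / 2,
    _FIG3D_W[4] / 2, _FIG3D_W[4] / 2,
)

#: Default acquisition grid: one frame every 5 deg from 0 to 180 inclusive.
DEFAULT_THETAS = tuple(float(t) for t in range(0, 185, 5))

#: Relative modulation amplitude per colour channel.  Depolarized eyeshine
#: is predominantly red; green and blue are rendered at reduced contrast.
CHANNEL_AMPLITUDE_SCALE = {"R": 1.0, "G": 0.5, "B": 0.25, "mono": 1.0}


@dataclass(frozen=True)
class SigmaField:
    """Per-ommatidium principal axis Sigma on a hexagonal lattice.

    Parameters
    ----------
    rows, cols : int
        Extent of the rhombic axial patch the field lives on.
    sigma : mapping (q, r) -> float
        Principal axis in degrees, each value in [0, 90).
    measured : mapping (q, r) -> bool
        Whether the ommatidium lies inside the illuminated patch and has a
        usable Sigma.  Every coordinate carrying a sigma value is measured.
    """

    rows: int
    cols: int
    sigma: Mapping[Coord, float]
    measured: Mapping[Coord, bool] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.measured is None:
            object.__setattr__(
                self, "measured", {c: True for c in self.sigma}
            )
        for c, s in self.sigma.items():
            if not (0.0 <= s < 90.0):
                raise ValueError(f"sigma at {c} is {s}, outside [0, 90)")
            if not self.measured.get(c, False):
                raise ValueError(f"coordinate {c} has sigma but is not measured")

    def measured_coords(self) -> list[Coord]:
        return [c for c, m in self.measured.items() if m]

    def to_frame(self, patch_id: str = "patch0") -> pd.DataFrame:
        """Long-format table with one row per measured ommatidium."""
        rows = [
            {
                "patch_id": patch_id,
                "q": q,
                "r": r,
                "col_label": f"C{q + 1}",
                "row_label": f"R{r + 1}",
                "sigma_deg": self.sigma[(q, r)],
                "measured": True,
            }
            for (q, r) in sorted(self.sigma)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "patch_id", "q", "r", "col_label", "row_label",
                "sigma_deg", "measured",
            ],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SigmaField":
        frame = frame[frame.get("measured", True) == True]  # noqa: E712
        sigma = {
            (int(row.q), int(row.r)): float(row.sigma_deg)
            for row in frame.itertuples()
        }
        rows = max((r for _, r in sigma), default=-1) + 1
        cols = max((q for q, _ in sigma), default=-1) + 1
        return cls(rows=rows, cols=cols, sigma=sigma)


@dataclass(frozen=True)
class AlignmentParams:
    """Parameters of the Sigma-field generator.

    ``p_align`` is the probability that a newly assigned ommatidium copies
    the axis of an already-assigned neighbour (plus axial Gaussian jitter
    of ``jitter_sd`` degrees); otherwise it draws Sigma ~ Uniform[0, 90).
    If ``mixture`` is given (pairs of signed offset, probability), the
    field is instead built from a random global axis plus i.i.d. per-cell
    offsets drawn from that categorical distribution.
    """

    p_align: float = 0.7
    jitter_sd: float = 2.0
    mixture: Sequence[tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_align <= 1.0):
            raise ValueError(f"p_align must be in [0, 1], got {self.p_align}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.mixture is not None:
            probs = np.array([p for _, p in self.mixture], dtype=float)
            if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
                raise ValueError("mixture probabilities must be >= 0 and sum to 1")

    @classmethod
    def fig3d(cls, seed: int = 0) -> "AlignmentParams":
        """Mixture calibrated to the published adjacent-pair dissimilarity
        fractions of a real ommatidial patch (22% exactly aligned, 50%
        within +-5 deg, 30% >= 15 deg, 15% >= 20 deg)."""
        return cls(
            mixture=tuple(zip(FIG3D_OFFSETS_DEG, FIG3D_WEIGHTS)), seed=seed
        )


@dataclass(frozen=True)
class OpticsParams:
    """Rendering parameters for synthetic eyeshine stacks.

    All intensities are in detector counts.  ``beam_half_angle`` documents
    the angular radius of the illuminating cone (default 10.5 deg, a
    21-deg cone); ommatidia outside the beam are rendered with zero
    modulation amplitude.
    """

    baseline: float = 200.0
    amplitude: float = 600.0
    spot_sigma: float = 2.0
    noise_sd: float = 0.0
    beam_half_angle: float = 10.5
    background: float = 50.0
    saturation: float | None = None

    def __post_init__(self):
        for name in ("baseline", "amplitude", "spot_sigma", "noise_sd",
                     "beam_half_angle", "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.saturation is not None:
            peak = self.background + self.baseline + self.amplitude + 5 * self.noise_sd
            if peak > self.saturation:
                raise ValueError(
                    f"peak intensity {peak} exceeds saturation {self.saturation}"
                )


@dataclass(frozen=True)
class EyeshineStack:
    """Ordered eyeshine frames over roll angles theta.

    ``frames`` has shape ``(n_theta, H, W)`` for mono stacks or
    ``(n_theta, H, W, 3)`` for RGB.  ``pixel_scale`` is the lattice
    spot spacing in pixels; ``origin`` the pixel position of axial (0, 0).
    """

    thetas: np.ndarray
    frames: np.ndarray
    channel: str = "mono"
    pixel_scale: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        thetas = np.asarray(self.thetas, dtype=float)
        object.__setattr__(self, "thetas", thetas)
        if len(thetas) != len(self.frames):
            raise ValueError("one frame per theta required")
        if np.any(np.diff(thetas) <= 0):
            raise ValueError("thetas must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.thetas)

    def frame_channel(self, channel: str) -> np.ndarray:
        """All frames of one colour channel, shape (n_theta, H, W)."""
        if self.frames.ndim == 3:
            if channel not in ("mono", self.channel):
                raise KeyError(f"channel {channel!r} absent from mono stack")
            return self.frames
        idx = {"R": 0, "G": 1, "B": 2}.get(channel)
        if idx is None:
            raise KeyError(f"channel {channel!r} absent from RGB stack")
        return self.frames[..., idx]


def eyeshine_intensity(
    theta_deg: np.ndarray | float,
    sigma_deg: float,
    optics: OpticsParams,
    amplitude_scale: float = 1.0,
) -> np.ndarray:
    """Noiseless spot-centre intensity at roll angle theta."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float) - sigma_deg)
    return (
        optics.background
        + optics.baseline
        + amplitude_scale * optics.amplitude * np.sin(2.0 * th) ** 2
    )


def generate_sigma_field(
    rows: int, cols: int, params: AlignmentParams
) -> SigmaField:
    """Generate a synthetic Sigma field on a rows x cols rhombic patch.

    Two generating processes are available (see :class:`AlignmentParams`):
    a sweep-order copy-with-jitter process that produces spatially
    correlated, locally aligned mosaics, and a calibrated offset-mixture
    process whose adjacent-pair axial differences match published
    dissimilarity fractions.  Deterministic for a fixed seed.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    rng = np.random.default_rng(params.seed)
    coords = rhombic_coords(rows, cols)

    if params.mixture is not None:
        offsets = np.array([v for v, _ in params.mixture], dtype=float)
        probs = np.array([p for _, p in params.mixture], dtype=float)
        probs = probs / probs.sum()
        sigma0 = rng.uniform(0.0, 90.0)
        draws = rng.choice(offsets, size=len(coords), p=probs)
        sigma = {
            c: float((sigma0 + d) % 90.0) for c, d in zip(coords, draws)
        }
        return SigmaField(rows=rows, cols=cols, sigma=sigma)

    sigma: dict[Coord, float] = {}
    for (q, r) in coords:
        assigned = [
            sigma[(q + dq, r + dr)]
            for dq, dr in ((-1, 0), (0, -1), (1, -1))
            if (q + dq, r + dr) in sigma
        ]
        if assigned and rng.random() < params.p_align:
            base = assigned[rng.integers(len(assigned))]
            jitter = rng.normal(0.0, params.jitter_sd) if params.jitter_sd else 0.0
            sigma[(q, r)] = float((base + jitter) % 90.0)
        else:
            sigma[(q, r)] = float(rng.uniform(0.0, 90.0))
    return SigmaField(rows=rows, cols=cols, sigma=sigma)


def render_eyeshine_stack(
    field: SigmaField,
    thetas: Sequence[float] = DEFAULT_THETAS,
    optics: OpticsParams = OpticsParams(),
    seed: int = 0,
    spacing: float = 20.0,
    margin: float = 12.0,
    rgb: bool = False,
    amplitude_scale: Mapping[Coord, float] | None = None,
) -> EyeshineStack:
    """Render a registered eyeshine image stack from a Sigma field.

    Each measured ommatidium becomes a Gaussian spot whose centre
    intensity follows the sin^2 eyeshine law for its Sigma; additive
    Gaussian noise of ``optics.noise_sd`` counts is applied per pixel.
    ``amplitude_scale`` optionally modulates per-ommatidium amplitude
    (e.g. zero for ommatidia outside the illumination cone).
    """
    coords = field.measured_coords()
    if not coords:
        raise ValueError("field has no measured ommatidia")
    thetas = np.asarray(list(thetas), dtype=float)
    if thetas.size == 0:
        raise ValueError("at least one theta required")
    if spacing < 3.0 * optics.spot_sigma:
        warnings.warn(
            f"spot spacing {spacing} < 3*spot_sigma "
            f"{3 * optics.spot_sigma}: spots overlap",
            stacklevel=2,
        )

    origin = (margin, margin)
    xy = np.array([axial_to_pixel(q, r, spacing, origin) for q, r in coords])
    w = int(np.ceil(xy[:, 0].max() + margin)) + 1
    h = int(np.ceil(xy[:, 1].max() + margin)) + 1
    yy, xx = np.mgrid[0:h, 0:w]

    channels = ("R", "G", "B") if rgb else ("mono",)
    rng = np.random.default_rng(seed)
    frames = np.zeros((len(thetas), h, w, len(channels)), dtype=float)
    for ci, ch in enumerate(channels):
        ch_scale = CHANNEL_AMPLITUDE_SCALE[ch]
        for (c, (x, y)) in zip(coords, xy):
            scale = ch_scale * (
                1.0 if amplitude_scale is None else amplitude_scale.get(c, 1.0)
            )
            profile = np.exp(
                -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * optics.spot_sigma**2)
            )
            mod = (
                optics.baseline
                + scale * optics.amplitude
                * np.sin(2.0 * np.deg2rad(thetas - field.sigma[c])) ** 2
            )
            frames[:, :, :, ci] += mod[:, None, None] * profile[None, :, :]
        frames[:, :, :, ci] += optics.background
    if optics.noise_sd > 0:
        frames = frames + rng.normal(0.0, optics.noise_sd, size=frames.shape)
        frames = np.clip(frames, 0.0, None)
    if optics.saturation is not None and frames.max() > optics.saturation:
        raise ValueError("rendered stack exceeds saturation")
    if not rgb:
        frames = frames[..., 0]
    return EyeshineStack(
        thetas=thetas,
        frames=frames,
        channel="R" if rgb else "mono",
        pixel_scale=spacing,
        origin=origin,
    )


def generate_polarization_image_pair(
    dop: float,
    total_intensity: float = 1000.0,
    shape: tuple[int, int] = (64, 64),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Image pair (I_H, I_V) whose mean intensities realise a known DoP.

    The pair satisfies mean(I_H) + mean(I_V) = ``total_intensity`` and
    |mean(I_H) - mean(I_V)| / sum = ``dop`` before noise, with the excess
    assigned to the horizontal channel.
    """
    if not (0.0 <= dop <= 1.0):
        raise ValueError(f"dop must be in [0, 1], got {dop}")
    rng = np.random.default_rng(seed)
    mean_h = total_intensity * (1.0 + dop) / 2.0
    mean_v = total_intensity * (1.0 - dop) / 2.0
    i_h = np.full(shape, mean_h, dtype=float)
    i_v = np.full(shape, mean_v, dtype=float)
    if noise_sd > 0:
        i_h = np.clip(i_h + rng.normal(0.0, noise_sd, shape), 0.0, None)
        i_v = np.clip(i_v + rng.normal(0.0, noise_sd, shape), 0.0, None)
    return i_h, i_v


# Default reflectance templates for dorsal forewings: females are
# blue-shifted (peak 521 nm) relative to males (peak 545 nm).
FEMALE_FOREWING_PEAK_NM = 521.0
MALE_FOREWING_PEAK_NM = 545.0


def generate_reflectance_spectrum(
    peak_nm: float,
    fwhm_nm: float = 120.0,
    amplitude: float = 0.35,
    pedestal: float = 0.05,
    range_nm: tuple[float, float] = (350.0, 700.0),
    step_nm: float = 1.0,
) -> pd.DataFrame:
    """Gaussian-peaked reflectance spectrum on a wavelength grid.

    Returns a two-column table (wavelength_nm, reflectance).  The argmax
    of the sampled spectrum equals ``peak_nm`` whenever the peak lies on
    the grid and inside the range.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be > 0")
    lo, hi = range_nm
    if not (lo <= peak_nm <= hi):
        raise ValueError(f"peak {peak_nm} nm outside range {range_nm}")
    wl = np.arange(lo, hi + step_nm / 2, step_nm)
    sd = fwhm_nm / np.sqrt(8.0 * np.log(2.0))
    refl = pedestal + amplitude * np.exp(-0.5 * ((wl - peak_nm) / sd) ** 2)
    return pd.DataFrame({"wavelength_nm": wl, "reflectance": refl})


def female_forewing_spectrum(**kw) -> pd.DataFrame:
    """Default synthetic female dorsal-forewing reflectance (peak 521 nm)."""
    return generate_reflectance_spectrum(FEMALE_FOREWING_PEAK_NM, **kw)


def male_forewing_spectrum(**kw) -> pd.DataFrame:
    """Default synthetic male dorsal-forewing reflectance (peak 545 nm)."""
    return generate_reflectance_spectrum(MALE_FOREWING_PEAK_NM, **kw)


def generate_sensitivity_templates(
    peaks_nm: Sequence[float] = (360.0, 450.0, 520.0, 600.0),
    fwhm_nm: float = 80.0,
    range_nm: tuple[float, float] = (350.0, 700.0),
    step_nm: float = 1.0,
) -> pd.DataFrame:
    """Gaussian stand-ins for the four photoreceptor sensitivity curves.

    Synthetic fixtures, not estimates of real opsin spectra: one
    unit-peak Gaussian per receptor class (u < s < m < l), columns
    (wavelength_nm, u, s, m, l).
    """
    peaks = list(peaks_nm)
    if len(peaks) != 4 or len(set(peaks)) != 4 or sorted(peaks) != peaks:
        raise ValueError("peaks_nm must be four distinct increasing wavelengths")
    wl = np.arange(range_nm[0], range_nm[1] + step_nm / 2, step_nm)
    sd = fwhm_nm / np.sqrt(8.0 * np.log(2.0))
    out = {"wavelength_nm": wl}
    for name, peak in zip(("u", "s", "m", "l"), peaks):
        out[name] = np.exp(-0.5 * ((wl - peak) / sd) ** 2)
    return pd.DataFrame(out)


def generate_behavior_counts(
    n_sites: int,
    p_depol: float,
    totals_per_site: Sequence[int],
    seed: int = 0,
    treatment: str = "blue",
) -> pd.DataFrame:
    """Per-site approach counts to polarized vs depolarized wing models.

    Depolarized counts are Binomial(total, p_depol) per site; the
    remainder of each site's total goes to the polarized model.
    """
    if not (0.0 <= p_depol <= 1.0):
        raise ValueError("p_depol must be in [0, 1]")
    totals = np.asarray(list(totals_per_site), dtype=int)
    if len(totals) != n_sites:
        raise ValueError("one total per site required")
    if np.any(totals <= 0):
        raise ValueError("totals must be positive")
    rng = np.random.default_rng(seed)
    n_depol = rng.binomial(totals, p_depol)
    return pd.DataFrame(
        {
            "site_id": [f"site{i + 1}" for i in range(n_sites)],
            "treatment": treatment,
            "n_polarized": totals - n_depol,
            "n_depolarized": n_depol,
        }
    )


def outside_beam(field: SigmaField, coords: Sequence[Coord]) -> dict[Coord, float]:
    """Amplitude-scale map flagging the given ommatidia as outside the
    illumination cone (zero modulation)."""
    scale = {c: 1.0 for c in field.measured_coords()}
    for c in coords:
        scale[c] = 0.0
    return scale


def replace_optics(optics: OpticsParams, **kw) -> OpticsParams:
    """Convenience: dataclasses.replace for OpticsParams."""
    return replace(optics, **kw)
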