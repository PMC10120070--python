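"""Wing polarization and colour photometry.

Degree of polarization (DoP) of reflected light is measured from image
pairs taken through a horizontal and a vertical analyser,
DoP = |I_H - I_V| / (I_H + I_V) over total masked intensity, as a
function of "angular contrast" — the sum of the incidence angle theta
and detection angle phi.  Reflectance spectra are summarised by their
peak wavelength and projected into a tetrachromatic (tetrahedral) colour
space via quantum catches of four receptor classes under ideal (flat)
illumination; colour differences are unweighted Euclidean distances in
that space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

Image = np.ndarray

# Regular tetrahedron with centroid at the origin and centre-to-vertex
# distance 3/4: the standard tetrachromat chromaticity diagram, with the
# UV vertex on the +z axis and the s/m/l vertices in the base plane.
TETRA_VERTICES = {
    "u": np.array([0.0, 0.0, 0.75]),
    "s": np.array([-np.sqrt(6.0) / 4.0, -np.sqrt(2.0) / 4.0, -0.25]),
    "m": np.array([np.sqrt(6.0) / 4.0, -np.sqrt(2.0) / 4.0, -0.25]),
    "l": np.array([0.0, np.sqrt(2.0) / 2.0, -0.25]),
}
_TETRA_MATRIX = np.column_stack(
    [TETRA_VERTICES[k] for k in ("u", "s", "m", "l")]
)


def compute_dop(i_h_total: float, i_v_total: float) -> float:
    """Degree of polarization |I_H - I_V| / (I_H + I_V), in [0, 1]."""
    total = i_h_total + i_v_total
    if total <= 0:
        raise ValueError("total intensity must be positive")
    if i_h_total < 0 or i_v_total < 0:
        raise ValueError("intensities must be non-negative")
    return abs(i_h_total - i_v_total) / total


@dataclass(frozen=True)
class PolarizationImagePair:
    """Orthogonally analysed image pair of one viewing geometry.

    ``i_h`` is the horizontally polarized component (perpendicular to the
    plane of incidence), ``i_v`` the vertical (parallel) component;
    ``mask`` restricts the photometry to wing pixels.
    """

    i_h: Image
    i_v: Image
    mask: Image | None = None

    def __post_init__(self):
        i_h = np.asarray(self.i_h, dtype=float)
        i_v = np.asarray(self.i_v, dtype=float)
        if i_h.shape != i_v.shape:
            raise ValueError("i_h and i_v must have the same shape")
        if np.any(i_h < 0) or np.any(i_v < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "i_h", i_h)
        object.__setattr__(self, "i_v", i_v)
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != i_h.shape:
                raise ValueError("mask shape mismatch")
            object.__setattr__(self, "mask", mask)


def image_pair_dop(pair: PolarizationImagePair) -> tuple[float, str]:
    """DoP of an image pair plus the dominant channel ('H' or 'V').

    Channel totals are sums over masked pixels; H dominates on ties.
    """
    mask = pair.mask if pair.mask is not None else np.ones(pair.i_h.shape, bool)
    if not mask.any():
        raise ValueError("empty mask")
    total_h = float(pair.i_h[mask].sum())
    total_v = float(pair.i_v[mask].sum())
    return compute_dop(total_h, total_v), ("H" if total_h >= total_v else "V")


@dataclass(frozen=True)
class ViewingGeometry:
    """Incidence and detection angles of one polarization acquisition."""

    theta_inc_deg: float
    phi_det_deg: float

    def __post_init__(self):
        if not (abs(self.theta_inc_deg) < self.phi_det_deg):
            raise ValueError(
                "acquisition requires |theta_inc| < phi_det "
                f"(got {self.theta_inc_deg}, {self.phi_det_deg})"
            )

    @property
    def angular_contrast_deg(self) -> float:
        return self.theta_inc_deg + self.phi_det_deg


def dop_sweep(
    pairs: dict[ViewingGeometry, PolarizationImagePair]
) -> pd.DataFrame:
    """DoP per viewing geometry over a sweep of angular contrasts.

    One row per geometry: (theta_inc_deg, phi_det_deg,
    angular_contrast_deg, dop, dominant).
    """
    if not pairs:
        raise ValueError("at least one geometry required")
    rows = []
    for geom in sorted(
        pairs, key=lambda g: (g.theta_inc_deg, g.phi_det_deg)
    ):
        dop, dominant = image_pair_dop(pairs[geom])
        rows.append(
            {
                "theta_inc_deg": geom.theta_inc_deg,
                "phi_det_deg": geom.phi_det_deg,
                "angular_contrast_deg": geom.angular_contrast_deg,
                "dop": dop,
                "dominant": dominant,
            }
        )
    return pd.DataFrame(rows)


def _orthogonal_poly(x: np.ndarray, order: int) -> np.ndarray:
    # orthonormal polynomial basis (constant column excluded), as in
    # regression on poly(x, order): QR of the centred Vandermonde
    x = np.asarray(x, dtype=float)
    v = np.vander(x - x.mean(), order + 1, increasing=True)
    q, r = np.linalg.qr(v)
    if np.linalg.matrix_rank(v) < order + 1:
        raise ValueError("rank-deficient design: too few distinct contrasts")
    return q[:, 1:]


def fit_dop_trend(sweep: pd.DataFrame, order: int = 2):
    """OLS polynomial trend of DoP versus angular contrast.

    Fits DoP on an orthogonalized polynomial basis of the angular
    contrast (order 2 or 3) and returns the statsmodels results object
    (coefficients, residual variance, R^2, AIC for comparing orders).
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    if len(sweep) < order + 2:
        raise ValueError(f"need >= {order + 2} rows for an order-{order} fit")
    x = sweep["angular_contrast_deg"].to_numpy(dtype=float)
    y = sweep["dop"].to_numpy(dtype=float)
    design = sm.add_constant(_orthogonal_poly(x, order))
    return sm.OLS(y, design).fit()


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Reflectance relative to a unit standard on a wavelength grid."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        if wl.shape != rf.shape:
            raise ValueError("wavelength and reflectance lengths differ")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(rf < 0):
            raise ValueError("reflectance must be non-negative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", rf)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReflectanceSpectrum":
        return cls(
            wavelengths_nm=frame["wavelength_nm"].to_numpy(),
            reflectance=frame["reflectance"].to_numpy(),
        )


@dataclass(frozen=True)
class SpectralPeak:
    wavelength_nm: float
    tie: bool
    on_boundary: bool


def spectral_peak(spec: ReflectanceSpectrum) -> SpectralPeak:
    """Wavelength of maximum reflectance.

    Ties resolve to the smallest wavelength with ``tie=True``;
    ``on_boundary`` flags a maximum at the grid edge (possible
    truncation of the true peak).
    """
    rf = spec.reflectance
    if np.ptp(rf) == 0:
        raise ValueError("constant spectrum has no peak")
    idx = int(np.argmax(rf))
    tie = bool(np.sum(rf == rf[idx]) > 1)
    return SpectralPeak(
        wavelength_nm=float(spec.wavelengths_nm[idx]),
        tie=tie,
        on_boundary=idx in (0, len(rf) - 1),
    )


@dataclass(frozen=True)
class QuantumCatch:
    """Quantum catches of the four receptor classes (u, s, m, l)."""

    u: float
    s: float
    m: float
    l: float  # noqa: E741

    def __post_init__(self):
        vals = (self.u, self.s, self.m, self.l)
        if any(v < 0 for v in vals):
            raise ValueError("catches must be non-negative")
        if sum(vals) <= 0:
            raise ValueError("all catches are zero")

    @property
    def relative(self) -> np.ndarray:
        raw = np.array([self.u, self.s, self.m, self.l])
        return raw / raw.sum()

    @property
    def xyz(self) -> np.ndarray:
        return tetra_coordinates(self)


def resample_spectrum(
    wavelengths: np.ndarray,
    values: np.ndarray,
    grid: np.ndarray,
) -> np.ndarray:
    """Linear interpolation onto a shared wavelength grid (zero outside)."""
    return np.interp(grid, wavelengths, values, left=0.0, right=0.0)


def quantum_catches(
    spec: ReflectanceSpectrum,
    sensitivities: pd.DataFrame,
    range_nm: tuple[float, float] = (350.0, 700.0),
    step_nm: float = 1.0,
) -> QuantumCatch:
    """Receptor quantum catches of a reflectance spectrum.

    catch_i = integral of R(lambda) * S_i(lambda) over the truncated
    350-700 nm range, with a flat (ideal) illuminant and background.
    Sensitivities are a table with columns (wavelength_nm, u, s, m, l);
    both inputs are resampled to the common grid by linear interpolation.
    """
    grid = np.arange(range_nm[0], range_nm[1] + step_nm / 2, step_nm)
    refl = resample_spectrum(spec.wavelengths_nm, spec.reflectance, grid)
    catches = {}
    for name in ("u", "s", "m", "l"):
        sens = resample_spectrum(
            sensitivities["wavelength_nm"].to_numpy(dtype=float),
            sensitivities[name].to_numpy(dtype=float),
            grid,
        )
        catches[name] = float(np.trapezoid(refl * sens, grid))
    return QuantumCatch(**catches)


def tetra_coordinates(catch: QuantumCatch) -> np.ndarray:
    """Cartesian coordinates of a colour in tetrahedral colour space.

    Linear map of the relative catches onto the fixed regular
    tetrahedron: xyz = V @ (u, s, m, l)_relative with V the 3x4 vertex
    matrix.  Equal catches (achromatic) map to the origin; a pure catch
    maps to its vertex at distance 0.75 from the origin.
    """
    return _TETRA_MATRIX @ catch.relative


def color_distance(a: QuantumCatch, b: QuantumCatch) -> float:
    """Unweighted Euclidean distance between two colours in tetrahedral
    colour space."""
    return float(np.linalg.norm(tetra_coordinates(a) - tetra_coordinates(b)))
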