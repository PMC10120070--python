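"""Two-channel polarization-opponent model and second-order summation.

Each ommatidium carries two orthogonal microvillar channels.  A receptor
with microvillar axis alpha and polarization sensitivity PS responds to
partially linearly polarized light (intensity I, degree of polarization
d, angle of polarization phi) with the two-mechanism Malus law

    R = I * [ (1 - d) * (PS + 1) / 2  +  d * (PS cos^2(phi - alpha) + sin^2(phi - alpha)) ].

A first-order opponent interneuron normalises the difference of the
orthogonal pair, O = (R_par - R_perp) / (R_par + R_perp), which is
intensity independent and reduces to

    O = d * (PS - 1) / (PS + 1) * cos 2(phi - alpha).

O vanishes at phi - alpha = 45 deg whatever d: a single opponent unit is
polarization blind there.  A second-order neuron that sums rectified
first-order outputs from a pair of adjacent ommatidia with sufficiently
different axes (axial difference >= 20 deg) responds at every phi — the
robust polarization detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import delta_sigma

DEFAULT_PS = 10.0


@dataclass(frozen=True)
class PolarizedStimulus:
    """Partially linearly polarized stimulus: intensity, DoP, AoP (deg)."""

    intensity: float = 1.0
    dop: float = 1.0
    aop_deg: float = 0.0

    def __post_init__(self):
        if self.intensity <= 0:
            raise ValueError("intensity must be > 0")
        if not (0.0 <= self.dop <= 1.0):
            raise ValueError("dop must be in [0, 1]")


@dataclass(frozen=True)
class ReceptorConfig:
    """Microvillar axis (deg, mod 180) and polarization sensitivity."""

    axis_deg: float = 0.0
    ps: float = DEFAULT_PS

    def __post_init__(self):
        if self.ps < 1.0:
            raise ValueError("polarization sensitivity must be >= 1")


def receptor_response(stim: PolarizedStimulus, cfg: ReceptorConfig) -> float:
    """Two-mechanism Malus response to partially polarized light."""
    rel = np.deg2rad(stim.aop_deg - cfg.axis_deg)
    polarized = cfg.ps * np.cos(rel) ** 2 + np.sin(rel) ** 2
    unpolarized = (cfg.ps + 1.0) / 2.0
    return float(
        stim.intensity * ((1.0 - stim.dop) * unpolarized + stim.dop * polarized)
    )


def opponent_response(stim: PolarizedStimulus, cfg: ReceptorConfig) -> float:
    """Normalised-difference output of the orthogonal channel pair.

    Computed from the two receptor responses; algebraically equal to
    d * (PS - 1) / (PS + 1) * cos 2(phi - alpha), hence independent of
    intensity and bounded by d * (PS - 1) / (PS + 1).
    """
    r_par = receptor_response(stim, cfg)
    r_perp = receptor_response(
        stim, ReceptorConfig(axis_deg=cfg.axis_deg + 90.0, ps=cfg.ps)
    )
    return (r_par - r_perp) / (r_par + r_perp)


def opponent_gain(ps: float, dop: float = 1.0) -> float:
    """Peak opponent amplitude d * (PS - 1) / (PS + 1)."""
    return dop * (ps - 1.0) / (ps + 1.0)


@dataclass(frozen=True)
class StateSpaceLocus:
    """Joint opponent responses of two neighbouring ommatidia over AoP."""

    delta_sigma_deg: float
    phi_deg: np.ndarray
    points: np.ndarray  # shape (n, 2): (O_1, O_2)
    dop: float


def state_space_locus(
    axis1_deg: float,
    axis2_deg: float,
    ps: float = DEFAULT_PS,
    dop: float = 1.0,
    phi_deg: np.ndarray | None = None,
) -> StateSpaceLocus:
    """Locus (O_1(phi), O_2(phi)) in polarization state space.

    For identical axes the locus degenerates to a segment on the
    identity line; for orthogonal-pair extremes (axial difference 45 deg,
    d = 1) it is the circle of radius (PS - 1) / (PS + 1).  The sampled
    extent grows with the axial difference of the two axes.
    """
    if phi_deg is None:
        phi_deg = np.arange(-90.0, 90.0, 1.0)
    phi_deg = np.asarray(phi_deg, dtype=float)
    pts = np.empty((phi_deg.size, 2))
    for i, phi in enumerate(phi_deg):
        stim = PolarizedStimulus(dop=dop, aop_deg=float(phi))
        pts[i, 0] = opponent_response(stim, ReceptorConfig(axis1_deg, ps))
        pts[i, 1] = opponent_response(stim, ReceptorConfig(axis2_deg, ps))
    return StateSpaceLocus(
        delta_sigma_deg=delta_sigma(axis1_deg, axis2_deg),
        phi_deg=phi_deg,
        points=pts,
        dop=dop,
    )


def locus_extent(locus: StateSpaceLocus) -> float:
    """Enclosed state-space area of a locus (shoelace on the phi grid).

    For the cosine-pair opponent the closed locus is an ellipse of area
    pi * g^2 * |sin 2*delta| with g the opponent gain, so the extent is 0
    for aligned pairs and maximal for a 45-deg axial difference.
    """
    x, y = locus.points[:, 0], locus.points[:, 1]
    return float(
        0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    )


def second_order_response(
    stim: PolarizedStimulus,
    axis1_deg: float,
    axis2_deg: float,
    ps: float = DEFAULT_PS,
    rectified: bool = True,
) -> float:
    """Second-order summation of two first-order opponent outputs.

    The default is the rectified sum |O_1| + |O_2|, the minimal
    nonlinearity for which a pair with sufficient axial difference is
    never polarization blind; ``rectified=False`` gives the signed sum
    O_1 + O_2 for comparison (itself a cosine of phi, hence blind at some
    AoP whatever the pair).  Period 90 deg in phi.
    """
    o1 = opponent_response(stim, ReceptorConfig(axis1_deg, ps))
    o2 = opponent_response(stim, ReceptorConfig(axis2_deg, ps))
    if rectified:
        return abs(o1) + abs(o2)
    return o1 + o2


def robustness(
    axis1_deg: float,
    axis2_deg: float,
    ps: float = DEFAULT_PS,
    dop: float = 1.0,
    phi_step_deg: float = 0.1,
    rectified: bool = True,
) -> float:
    """Worst-case second-order response over all angles of polarization.

    Minimum over a dense phi grid of the second-order response; for the
    rectified sum this equals d * (PS-1)/(PS+1) * sin(2 * delta_sigma),
    strictly increasing in the pair's axial difference on [0, 45] deg.
    A pair is a robust polarization detector when this minimum is
    substantial — in practice when the axial difference reaches 20 deg.
    """
    phis = np.arange(-90.0, 90.0 + phi_step_deg / 2.0, phi_step_deg)

    def _opponent(axis):
        rel = np.deg2rad(phis - axis)
        unpol = (ps + 1.0) / 2.0
        r_par = (1.0 - dop) * unpol + dop * (
            ps * np.cos(rel) ** 2 + np.sin(rel) ** 2
        )
        r_perp = (1.0 - dop) * unpol + dop * (
            ps * np.sin(rel) ** 2 + np.cos(rel) ** 2
        )
        return (r_par - r_perp) / (r_par + r_perp)

    o1 = _opponent(axis1_deg)
    o2 = _opponent(axis2_deg)
    if rectified:
        s = np.abs(o1) + np.abs(o2)
    else:
        s = o1 + o2
    return float(s.min())
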