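"""Neighbour analysis on the hexagonal ommatidial lattice.

Classifies the mosaic of principal axes into the two functional
sub-populations of the robust polarization-vision model:

* edge-detector (ED) chains — collinear runs of three or more ommatidia
  whose axes deviate from parallel by no more than +-5 deg, suited to
  edge and motion detection;
* polarization-detector (PD) pairs — adjacent ommatidia whose axial
  difference is at least 20 deg, whose summed opponent outputs are never
  polarization blind.

Patch-level percentages are computed over interior ommatidia: those all
six of whose hexagonal neighbours were measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import delta_sigma
from .lattice import AXIAL_NEIGHBOR_OFFSETS
from .synthgen import SigmaField

Coord = tuple[int, int]

DEFAULT_PD_THRESHOLD = 20.0
DEFAULT_ED_TOL = 5.0
DEFAULT_MIN_CHAIN = 3
#: An adjacent pair is "exactly aligned" when the estimated axial
#: difference is below this (exact zero is measure-zero on estimates).
DEFAULT_EXACT_TOL = 0.5

#: One direction per lattice axis (the opposite offsets span the same axis).
CHAIN_AXES: tuple[Coord, ...] = ((1, 0), (0, 1), (1, -1))


@dataclass(frozen=True)
class AdjacentPair:
    """An unordered pair of adjacent measured ommatidia."""

    a: Coord
    b: Coord
    delta_sigma_deg: float
    is_pd: bool


@dataclass(frozen=True)
class EdChain:
    """A maximal collinear run of mutually aligned ommatidia."""

    axis: Coord
    members: tuple[Coord, ...]
    spread_deg: float


def neighbors(coord: Coord, field: SigmaField) -> set[Coord]:
    """Measured nearest neighbours of a coordinate (subset of the six
    axial offsets)."""
    q, r = coord
    return {
        (q + dq, r + dr)
        for dq, dr in AXIAL_NEIGHBOR_OFFSETS
        if field.measured.get((q + dq, r + dr), False)
    }


def interior_ommatidia(field: SigmaField) -> set[Coord]:
    """Measured ommatidia all six of whose neighbours are measured."""
    if not field.sigma:
        raise ValueError("empty field")
    return {
        c for c in field.measured_coords() if len(neighbors(c, field)) == 6
    }


def adjacent_pairs(
    field: SigmaField,
    pd_threshold: float = DEFAULT_PD_THRESHOLD,
    restrict_interior: bool = False,
) -> list[AdjacentPair]:
    """Every unordered pair of adjacent measured ommatidia, once.

    With ``restrict_interior`` only pairs with at least one interior
    member are kept (the denominator used for patch-level dissimilarity
    distributions).
    """
    coords = field.measured_coords()
    if len(coords) < 2:
        raise ValueError("need at least two measured ommatidia")
    interior = interior_ommatidia(field) if restrict_interior else None
    pairs: list[AdjacentPair] = []
    for c in sorted(coords):
        for n in sorted(neighbors(c, field)):
            if n <= c:  # count each unordered pair once
                continue
            if interior is not None and c not in interior and n not in interior:
                continue
            d = delta_sigma(field.sigma[c], field.sigma[n])
            pairs.append(AdjacentPair(c, n, d, d >= pd_threshold))
    return pairs


def _line_runs(field: SigmaField, axis: Coord):
    """Maximal contiguous runs of measured cells along one lattice axis."""
    dq, dr = axis
    measured = set(field.measured_coords())
    runs = []
    for c in sorted(measured):
        prev = (c[0] - dq, c[1] - dr)
        if prev in measured:
            continue  # not a run start
        run = [c]
        nxt = (c[0] + dq, c[1] + dr)
        while nxt in measured:
            run.append(nxt)
            nxt = (nxt[0] + dq, nxt[1] + dr)
        runs.append(run)
    return runs


def _axial_spread(sigmas: list[float]) -> float:
    return max(
        delta_sigma(a, b) for i, a in enumerate(sigmas) for b in sigmas[i:]
    )


def find_ed_chains(
    field: SigmaField,
    ed_tol: float = DEFAULT_ED_TOL,
    min_len: int = DEFAULT_MIN_CHAIN,
) -> list[EdChain]:
    """Maximal aligned runs of >= ``min_len`` ommatidia along lattice axes.

    A window of contiguous collinear cells qualifies when the maximum
    pairwise axial difference among its members is at most ``2 * ed_tol``
    (every member within +-ed_tol of the run's axial midpoint); reported
    windows are maximal: extending them along the axis in either
    direction breaks the condition.
    """
    if not field.sigma:
        raise ValueError("empty field")
    chains: list[EdChain] = []
    for axis in CHAIN_AXES:
        for run in _line_runs(field, axis):
            sig = [field.sigma[c] for c in run]
            n = len(run)
            # two-pointer scan over maximal qualifying windows
            j_prev = -1
            for i in range(n):
                j = max(i, j_prev)
                while (
                    j + 1 < n
                    and _axial_spread(sig[i : j + 2]) <= 2.0 * ed_tol + 1e-9
                ):
                    j += 1
                if j > j_prev and j - i + 1 >= min_len:
                    chains.append(
                        EdChain(
                            axis=axis,
                            members=tuple(run[i : j + 1]),
                            spread_deg=_axial_spread(sig[i : j + 1]),
                        )
                    )
                j_prev = j
    return chains


@dataclass(frozen=True)
class PatchMetrics:
    """Patch-level classification summary over interior ommatidia."""

    n_interior: int
    pct_ed: float
    pct_pd: float
    pct_ed_only: float
    pct_pd_only: float
    delta_sigma_summary: dict
    n_pairs: int
    pair_fraction_pd: float

    def to_dict(self) -> dict:
        return {
            "n_interior": self.n_interior,
            "pct_ed": self.pct_ed,
            "pct_pd": self.pct_pd,
            "pct_ed_only": self.pct_ed_only,
            "pct_pd_only": self.pct_pd_only,
            "delta_sigma_summary": dict(self.delta_sigma_summary),
            "n_pairs": self.n_pairs,
            "pair_fraction_pd": self.pair_fraction_pd,
        }


def delta_sigma_distribution(
    pairs: list[AdjacentPair],
    exact_tol: float = DEFAULT_EXACT_TOL,
    pd_threshold: float = DEFAULT_PD_THRESHOLD,
) -> dict:
    """Cumulative dissimilarity fractions over a set of adjacent pairs.

    Reports the fractions published for real patches: exactly aligned
    (ΔΣ < ``exact_tol``), within +-5 deg, >= 15 deg, and >= the PD
    threshold (default 20 deg).
    """
    if not pairs:
        raise ValueError("no pairs supplied")
    d = np.array([p.delta_sigma_deg for p in pairs])
    return {
        "exact": float(np.mean(d < exact_tol)),
        "within_5": float(np.mean(d <= 5.0)),
        "ge_15": float(np.mean(d >= 15.0)),
        "ge_20": float(np.mean(d >= pd_threshold)),
    }


def patch_metrics(
    field: SigmaField,
    ed_tol: float = DEFAULT_ED_TOL,
    min_len: int = DEFAULT_MIN_CHAIN,
    pd_threshold: float = DEFAULT_PD_THRESHOLD,
    exact_tol: float = DEFAULT_EXACT_TOL,
) -> PatchMetrics:
    """Percentages of interior ommatidia suited to edge detection and to
    robust polarization detection.

    An interior ommatidium counts as ED when it is a member of at least
    one aligned chain (chain mates may be non-interior), and as PD when
    at least one of its six adjacent pairs reaches the PD threshold (the
    partner may be non-interior).  The dissimilarity summary is taken
    over pairs with at least one interior member.
    """
    interior = interior_ommatidia(field)
    if not interior:
        raise ValueError(
            "no interior ommatidia (all cells touch the patch boundary); "
            "use a larger patch"
        )
    chains = find_ed_chains(field, ed_tol=ed_tol, min_len=min_len)
    chain_members = {c for ch in chains for c in ch.members}
    pairs_all = adjacent_pairs(field, pd_threshold=pd_threshold)
    pd_members = set()
    for p in pairs_all:
        if p.is_pd:
            pd_members.add(p.a)
            pd_members.add(p.b)

    n = len(interior)
    ed = {c for c in interior if c in chain_members}
    pd_ = {c for c in interior if c in pd_members}
    interior_pairs = [
        p for p in pairs_all if p.a in interior or p.b in interior
    ]
    summary = delta_sigma_distribution(
        interior_pairs, exact_tol=exact_tol, pd_threshold=pd_threshold
    )
    return PatchMetrics(
        n_interior=n,
        pct_ed=100.0 * len(ed) / n,
        pct_pd=100.0 * len(pd_) / n,
        pct_ed_only=100.0 * len(ed - pd_) / n,
        pct_pd_only=100.0 * len(pd_ - ed) / n,
        delta_sigma_summary=summary,
        n_pairs=len(interior_pairs),
        pair_fraction_pd=float(
            np.mean([p.is_pd for p in interior_pairs])
        ),
    )


def pairs_to_frame(pairs: list[AdjacentPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "q_a": p.a[0], "r_a": p.a[1],
                "q_b": p.b[0], "r_b": p.b[1],
                "delta_sigma_deg": p.delta_sigma_deg,
                "is_pd": p.is_pd,
            }
            for p in pairs
        ]
    )


def chains_to_frame(chains: list[EdChain]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "axis_dq": ch.axis[0], "axis_dr": ch.axis[1],
                "length": len(ch.members),
                "spread_deg": ch.spread_deg,
                "members": ";".join(f"{q},{r}" for q, r in ch.members),
            }
            for ch in chains
        ]
    )
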