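"""Axial hexagonal-lattice geometry shared by the generator and photometry.

Ommatidia sit on a triangular (hexagonally packed) lattice addressed by
axial coordinates ``(q, r)`` with 0-based integers.  The rendered layout is
"pointy-top": moving one step in ``q`` shifts right by one lattice spacing,
moving one step in ``r`` shifts down one row and right by half a spacing,
so every cell has six equidistant nearest neighbours.

The column/row labels used on published eyeshine figures (``C2R4`` style)
map to axial coordinates as ``C{q+1}R{r+1}``.
"""

from __future__ import annotations

import math

#: The six axial offsets of nearest neighbours on the hex lattice.
AXIAL_NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (1, 0),
    (-1, 0),
    (0, 1),
    (0, -1),
    (1, -1),
    (-1, 1),
)


def axial_to_pixel(
    q: int, r: int, spacing: float, origin: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, float]:
    """Pixel position ``(x, y)`` of axial coordinate ``(q, r)``.

    ``spacing`` is the centre-to-centre distance between nearest
    neighbours, in pixels; ``origin`` is the pixel position of ``(0, 0)``.
    """
    x = origin[0] + spacing * (q + r / 2.0)
    y = origin[1] + spacing * (math.sqrt(3.0) / 2.0) * r
    return x, y


def rhombic_coords(rows: int, cols: int) -> list[tuple[int, int]]:
    """All axial coordinates of a rows x cols rhombic patch, row-major."""
    return [(q, r) for r in range(rows) for q in range(cols)]


def coord_label(q: int, r: int) -> str:
    """Column/row label of an axial coordinate (``C1R1`` for the origin)."""
    return f"C{q + 1}R{r + 1}"


def rhombic_edge_count(rows: int, cols: int) -> int:
    """Number of nearest-neighbour pairs in a full rows x cols rhombic patch.

    Counts edges along the three lattice axes: ``rows*(cols-1)`` +
    ``(rows-1)*cols`` + ``(rows-1)*(cols-1)``.
    """
    n, m = rows, cols
    return 3 * n * m - 2 * n - 2 * m + 1
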