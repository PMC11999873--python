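"""Cluster labeling, oriented zero-vorticity contour tracing, and chordal
explorer traces.

Contours are traced on the dual lattice of the binary sign field: trace
vertices sit on cell corners at half-integer grid coordinates, every step has
unit length ``h``, and the walk direction always keeps cells of positive
vorticity (value 1) on its right-hand side.

Two saddle conventions are supported for the ambiguous marching-squares cell
(diagonal pair of 1s):

``"square"``
    the positive phase is kept 4-connected (diagonal 1s are *not* joined, the
    negative phase is 8-connected) — the convention for vorticity fields;
``"triangular"``
    sites are adjacent along one fixed diagonal (here +row/+col) in addition
    to the 4-neighbours, the standard square-grid embedding of the triangular
    lattice where site percolation is critical at p = 1/2. Saddles whose 1s
    lie on that diagonal are joined; the complementary phase uses the same
    adjacency, so the construction is self-matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .fields import BinaryVorticityField

__all__ = [
    "ClusterLabeling",
    "ContourTrace",
    "ChordalTrace",
    "label_clusters",
    "trace_contours",
    "accessible_perimeter",
    "extract_chordal_traces",
    "export_traces",
]

# direction codes: 0=N (+y), 1=E (+x), 2=S, 3=W
_DROW = (1, 0, -1, 0)
_DCOL = (0, 1, 0, -1)


@dataclass
class ClusterLabeling:
    """Connected components of the 1-phase.

    ``labels`` uses 0 for background; positive labels are assigned in
    raster-scan first-contact order. ``sizes[k]`` is the site count of label
    ``k + 1``.
    """

    labels: np.ndarray
    n_clusters: int
    sizes: np.ndarray
    connectivity: str = "4"


@dataclass
class ContourTrace:
    """Oriented polyline on the dual lattice, in physical coordinates."""

    vertices: np.ndarray  # (n, 2) float array of (x, y)
    closed: bool
    kind: str = "complete"  # complete | accessible
    label: Optional[int] = None
    orientation_ok: bool = True
    spacing: float = 1.0

    @property
    def length(self) -> float:
        """Perimeter measured as vertex-step count times the grid step."""
        return (len(self.vertices) - 1) * self.spacing

    @property
    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))

    @property
    def is_outer(self) -> bool:
        # walking with the 1-phase on the right is clockwise (y up) around
        # filled regions, hence negative signed area for outer boundaries
        return self.signed_area < 0


@dataclass
class ChordalTrace:
    """Curve in the closed upper half-plane starting at the origin."""

    points: np.ndarray  # complex array, points[0] == 0, Im >= 0
    axis_offset: float = 0.0  # physical y of the chosen real axis
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=complex)
        if self.points.size and self.points[0] != 0:
            raise ValueError("chordal traces must start at the origin")
        if self.points.size and self.points.imag.min() < -1e-9:
            raise ValueError("chordal traces may not enter the lower half-plane")

    def __len__(self) -> int:
        return len(self.points)


_STRUCTS = {
    "4": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
    "8": np.ones((3, 3), bool),
    # +row/+col diagonal added: the triangular-lattice embedding
    "triangular": np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], bool),
}


def label_clusters(binary: BinaryVorticityField | np.ndarray, connectivity: str | int = 4) -> ClusterLabeling:
    """Label 1-clusters under 4-, 8- or triangular connectivity.

    Labels are renumbered into raster-scan first-contact order so the result
    is deterministic and implementation-independent.
    """
    sign = binary.sign if isinstance(binary, BinaryVorticityField) else np.asarray(binary)
    key = str(connectivity)
    if key not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
    labels, n = ndimage.label(sign, structure=_STRUCTS[key])
    if n:
        flat = labels.ravel()
        nz = np.flatnonzero(flat)
        first = np.full(n + 1, flat.size, dtype=np.int64)
        # first occurrence of each label in raster order
        np.minimum.at(first, flat[nz], nz)
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[1 + order] = np.arange(1, n + 1)
        labels = remap[labels]
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return ClusterLabeling(labels=labels, n_clusters=int(n), sizes=sizes, connectivity=key)


# ---------------------------------------------------------------------------
# Oriented marching-squares tracer
# ---------------------------------------------------------------------------

def _next_direction(d: int, lf: int, rf: int, triangular: bool) -> int:
    """Turn decision at a corner given the left-front / right-front cells."""
    if rf and not lf:
        return d  # straight
    if rf and lf:
        return (d - 1) % 4  # left turn (N->W->S->E)
    if not rf and not lf:
        return (d + 1) % 4  # right turn
    # saddle: 1s on a diagonal. For d in {E, W} the 1s lie on the +r/+c
    # diagonal; join them (turn left) only in triangular mode.
    if triangular and d in (1, 3):
        return (d - 1) % 4
    return (d + 1) % 4


def _walk_cycle(cells: np.ndarray, iy: int, ix: int, d: int, triangular: bool,
                vvis: np.ndarray) -> np.ndarray:
    """Follow one oriented boundary cycle starting from corner (iy, ix) with
    direction d. ``cells`` is the binary field padded by one zero ring, so
    corner (iy, ix) has NE cell ``cells[iy+1, ix+1]``.

    Returns the corner sequence (m, 2) as (iy, ix) rows, first == last.
    """
    out = [(iy, ix)]
    iy0, ix0, d0 = iy, ix, d
    while True:
        # mark traversed vertical edges; every cycle holds at least one, so
        # enumerating unvisited vertical edges discovers each cycle once
        if d == 0:
            vvis[iy + 1, ix] = True
        elif d == 2:
            vvis[iy, ix] = True
        iy += _DROW[d]
        ix += _DCOL[d]
        out.append((iy, ix))
        ne = cells[iy + 1, ix + 1]
        nw = cells[iy + 1, ix]
        se = cells[iy, ix + 1]
        sw = cells[iy, ix]
        if d == 0:
            lf, rf = nw, ne
        elif d == 1:
            lf, rf = ne, se
        elif d == 2:
            lf, rf = se, sw
        else:
            lf, rf = sw, nw
        d = _next_direction(d, lf, rf, triangular)
        if iy == iy0 and ix == ix0 and d == d0:
            break
    return np.asarray(out, dtype=np.int64)


def trace_contours(binary: BinaryVorticityField | np.ndarray, mode: str = "square",
                   min_length: int = 0, labeling: Optional[ClusterLabeling] = None) -> list[ContourTrace]:
    """Trace every closed zero-vorticity contour of a binary field.

    One closed trace is produced per cluster boundary; outer boundaries and
    hole boundaries are traced separately. Every trace keeps 1-cells on its
    right. ``min_length`` drops traces with fewer steps (0 keeps all).
    When a ``labeling`` is supplied, each trace records the label of the
    1-cluster it bounds.
    """
    if isinstance(binary, BinaryVorticityField):
        sign, h, origin = binary.sign, binary.spacing, binary.origin
    else:
        sign, h, origin = np.asarray(binary, dtype=np.uint8), 1.0, (0.0, 0.0)
    triangular = {"square": False, "triangular": True}[mode]
    ny, nx = sign.shape
    cells = np.zeros((ny + 2, nx + 2), dtype=np.uint8)
    cells[1:-1, 1:-1] = sign
    # vertical boundary edges: between cells (r, ix-1) and (r, ix) in padded
    # coords; the walk starts northward where the east cell is 1.
    east = cells[:, 1:]
    west = cells[:, :-1]
    vedge = east != west  # shape (ny+2, nx+1): edge between corners (r-1,ix)-(r,ix)
    vvis = np.zeros_like(vedge, dtype=bool)

    traces: list[ContourTrace] = []
    rs, cs = np.nonzero(vedge)
    for r, ix in zip(rs, cs):
        if vvis[r, ix]:
            continue
        if east[r, ix]:  # northward edge, base corner (r-1, ix)
            corners = _walk_cycle(cells, r - 1, ix, 0, triangular, vvis)
        else:  # southward edge, base corner (r, ix)
            corners = _walk_cycle(cells, r, ix, 2, triangular, vvis)
        n_steps = len(corners) - 1
        if n_steps < min_length:
            continue
        verts = np.empty((len(corners), 2))
        verts[:, 0] = origin[0] + (corners[:, 1] - 0.5) * h
        verts[:, 1] = origin[1] + (corners[:, 0] - 0.5) * h
        label = None
        if labeling is not None:
            # cell on the right of the first edge
            iy, ix0 = corners[0]
            d = _dir_of(corners[0], corners[1])
            rr, cc = _right_cell(iy, ix0, d)
            if 0 <= rr < ny and 0 <= cc < nx:
                lab = int(labeling.labels[rr, cc])
                label = lab if lab > 0 else None
        traces.append(ContourTrace(vertices=verts, closed=True, kind="complete",
                                   label=label, spacing=h))
    return traces


def _dir_of(a, b) -> int:
    dy, dx = int(b[0] - a[0]), int(b[1] - a[1])
    return {(1, 0): 0, (0, 1): 1, (-1, 0): 2, (0, -1): 3}[(dy, dx)]


def _right_cell(iy: int, ix: int, d: int) -> tuple[int, int]:
    """Cell (row, col) on the right of the edge leaving corner (iy, ix) with
    direction d, in unpadded cell coordinates."""
    if d == 0:
        return iy, ix  # east cell
    if d == 1:
        return iy - 1, ix  # south cell
    if d == 2:
        return iy - 1, ix - 1  # west cell
    return iy, ix - 1  # north cell


def accessible_perimeter(labeling: ClusterLabeling, label: int, spacing: float = 1.0,
                         origin: tuple[float, float] = (0.0, 0.0)) -> ContourTrace:
    """Accessible external perimeter of one cluster.

    The cluster is dilated by one iteration of a 3x3 square structuring
    element, which seals fjords narrower than one lattice unit; the outer
    contour of the dilated set is traced with the same oriented
    marching-squares walk.
    """
    if not (1 <= label <= labeling.n_clusters):
        raise KeyError(f"no cluster with label {label}")
    mask = labeling.labels == label
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    r0, c0 = sl[0].start, sl[1].start
    sub = np.zeros((sl[0].stop - r0 + 4, sl[1].stop - c0 + 4), dtype=np.uint8)
    sub[2:-2, 2:-2] = mask[sl]
    dil = ndimage.binary_dilation(sub, structure=np.ones((3, 3), bool))
    traces = trace_contours(dil.astype(np.uint8), mode="square")
    outer = min(traces, key=lambda t: t.signed_area)  # most negative = outer
    verts = outer.vertices.copy()
    verts[:, 0] = origin[0] + (verts[:, 0] + c0 - 2) * spacing
    verts[:, 1] = origin[1] + (verts[:, 1] + r0 - 2) * spacing
    return ContourTrace(vertices=verts, closed=True, kind="accessible",
                        label=label, spacing=spacing)


# ---------------------------------------------------------------------------
# Chordal explorer traces
# ---------------------------------------------------------------------------

def extract_chordal_traces(binary: BinaryVorticityField | np.ndarray,
                           axis_row: Optional[int] = None, mode: str = "square",
                           min_length: int = 16) -> list[ChordalTrace]:
    """Explorer walks from each contour/axis intersection.

    A horizontal real axis is drawn along the dual-lattice line just below
    cell row ``axis_row`` (default: the middle row). At every up-crossing of
    a zero-vorticity contour an explorer starts at that origin and follows
    the contour keeping positive vorticity on its right; whenever it returns
    to the axis it travels along it, preserving its orientation, until it can
    re-enter the upper half-plane. The walk ends at the domain boundary.

    Internally the axis condition is realised exactly like the chordal
    boundary condition of a percolation exploration: a virtual boundary row
    below the axis is coloured positive to the right of the origin and
    negative to the left, and the ordinary oriented tracing rules are applied
    to the augmented field — axis sliding then emerges from the same
    right-hand rule that governs the bulk walk.
    """
    if isinstance(binary, BinaryVorticityField):
        sign, h = binary.sign, binary.spacing
    else:
        sign, h = np.asarray(binary, dtype=np.uint8), 1.0
    ny, nx = sign.shape
    if axis_row is None:
        axis_row = ny // 2
    if not 2 <= axis_row <= ny - 2:
        raise ValueError("axis_row must be at least 2 rows from the field edge")
    triangular = {"square": False, "triangular": True}[mode]
    F = sign[axis_row:, :]
    H, W = F.shape

    starts = [c for c in range(W) if F[0, c] == 1 and (c == 0 or F[0, c - 1] == 0)]
    traces: list[ChordalTrace] = []
    for c0 in starts:
        # padded cell array: ring of zeros, then a virtual boundary row that
        # is 1 for columns >= c0 (positive phase attached to the right of the
        # origin) and 0 to the left.
        cells = np.zeros((H + 3, W + 2), dtype=np.uint8)
        cells[2:-1, 1:-1] = F
        cells[1, 1 + c0:-1] = 1
        corners = _explore(cells, c0, triangular)
        # the final vertex may dip one step below the axis when the walk
        # exits through the virtual boundary row; trim it
        while len(corners) and corners[-1, 0] < 1:
            corners = corners[:-1]
        if len(corners) - 1 < min_length:
            continue
        z = (corners[:, 1] - c0) * h + 1j * (corners[:, 0] - 1) * h
        traces.append(ChordalTrace(points=z, axis_offset=(axis_row - 0.5) * h, spacing=h))
    return traces


def _explore(cells: np.ndarray, c0: int, triangular: bool) -> np.ndarray:
    """Directed walk through the augmented field from the axis origin.

    Corner (iy, ix) has its NE cell at ``cells[iy + 1, ix + 1]``; the axis is
    the corner row iy = 1 and the start corner is (1, c0) heading north.
    """
    ny, nx = cells.shape  # padded
    iy, ix, d = 1, c0, 0
    out = [(iy, ix)]
    max_steps = 8 * cells.size
    for _ in range(max_steps):
        iy += _DROW[d]
        ix += _DCOL[d]
        out.append((iy, ix))
        # stop on the domain edge: top corner row (above the last cell row),
        # lateral corner columns, or back below the axis
        if iy <= 0 or iy >= ny - 2 or ix <= 0 or ix >= nx - 2:
            break
        ne = cells[iy + 1, ix + 1]
        nw = cells[iy + 1, ix]
        se = cells[iy, ix + 1]
        sw = cells[iy, ix]
        if d == 0:
            lf, rf = nw, ne
        elif d == 1:
            lf, rf = ne, se
        elif d == 2:
            lf, rf = se, sw
        else:
            lf, rf = sw, nw
        d = _next_direction(d, lf, rf, triangular)
    return np.asarray(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_traces(traces, path_tsv, path_manifest=None) -> None:
    """Write traces as delimited text (trace id, vertex index, x, y) plus an
    optional JSON manifest with per-trace metadata."""
    import json

    with open(path_tsv, "w") as fh:
        fh.write("trace_id\tvertex\tx\ty\n")
        for tid, tr in enumerate(traces):
            pts = tr.vertices if hasattr(tr, "vertices") else np.c_[tr.points.real, tr.points.imag]
            for j, (x, y) in enumerate(pts):
                fh.write(f"{tid}\t{j}\t{x:.9g}\t{y:.9g}\n")
    if path_manifest is not None:
        meta = []
        for tid, tr in enumerate(traces):
            if hasattr(tr, "vertices"):
                meta.append(dict(trace_id=tid, kind=tr.kind, closed=bool(tr.closed),
                                 label=tr.label, length=tr.length))
            else:
                meta.append(dict(trace_id=tid, kind="chordal", closed=False,
                                 label=None, length=float(len(tr.points) - 1) * tr.spacing))
        with open(path_manifest, "w") as fh:
            json.dump(meta, fh, indent=1)
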