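"""Gridded 2D velocity fields, vorticity, and sign binarization.

Velocity fields live on a regular square lattice. The array convention
throughout the package is ``arr[row, col]`` with *physical y increasing with
the row index* and physical x increasing with the column index, so that the
right-handed vorticity :math:`\\omega = \\partial_x u_y - \\partial_y u_x`
keeps its usual sign and the downstream "positive vorticity on the right"
contour-tracing rule is reproducible.

Two on-disk dialects are supported:

``table``
    Delimited text with columns ``x y u v`` (PIV-export style), one node per
    row, comma- or whitespace-separated, ``#`` comments allowed. The rows may
    appear in any order but must cover a complete regular grid.
``grid``
    A NumPy ``.npz`` container with named arrays ``u_x``, ``u_y`` plus
    ``spacing`` and ``origin`` metadata (and optionally ``mask``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "VelocityField",
    "VorticityField",
    "BinaryVorticityField",
    "FieldFormatError",
    "read_velocity_field",
    "write_velocity_field",
    "write_vorticity_field",
    "read_vorticity_field",
    "compute_vorticity",
    "binarize_vorticity",
]


class FieldFormatError(ValueError):
    """Raised for malformed field files (irregular grids, missing nodes)."""


@dataclass
class VelocityField:
    """Regular-grid 2D vector field.

    Attributes
    ----------
    u_x, u_y:
        2D arrays of the velocity components, shape ``(ny, nx)``.
    spacing:
        Grid step ``h`` (same units as the coordinates).
    origin:
        Physical ``(x, y)`` coordinate of grid node ``[0, 0]``.
    mask:
        Optional boolean validity flags (True = valid node).
    """

    u_x: np.ndarray
    u_y: np.ndarray
    spacing: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        if self.u_x.shape != self.u_y.shape:
            raise ValueError("u_x and u_y must have identical shapes")
        if self.u_x.ndim != 2 or min(self.u_x.shape) < 2:
            raise ValueError("velocity grids need at least 2 nodes per axis")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.u_x.shape:
                raise ValueError("mask shape must match the velocity grids")
        valid = self.mask if self.mask is not None else np.ones_like(self.u_x, bool)
        if not (np.isfinite(self.u_x[valid]).all() and np.isfinite(self.u_y[valid]).all()):
            raise ValueError("unmasked velocity values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u_x.shape


@dataclass
class VorticityField:
    """Scalar vorticity grid with the region where the stencil is defined.

    ``valid_slice`` is the (row, col) slice pair of the interior region for
    cropped boundaries, or the full grid for periodic ones.
    """

    omega: np.ndarray
    spacing: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    valid_slice: tuple[slice, slice] = field(
        default_factory=lambda: (slice(None), slice(None))
    )

    @property
    def valid(self) -> np.ndarray:
        """The interior vorticity values."""
        return self.omega[self.valid_slice]

    @property
    def valid_origin(self) -> tuple[float, float]:
        r0 = self.valid_slice[0].start or 0
        c0 = self.valid_slice[1].start or 0
        return (self.origin[0] + c0 * self.spacing, self.origin[1] + r0 * self.spacing)


@dataclass
class BinaryVorticityField:
    """Sign field: 1 where vorticity is strictly positive, else 0."""

    sign: np.ndarray
    spacing: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.sign = np.asarray(self.sign)
        if not np.isin(self.sign, (0, 1)).all():
            raise ValueError("binary field entries must be 0 or 1")
        self.sign = self.sign.astype(np.uint8)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_table(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 4:
                raise FieldFormatError(f"{path}: need 4 columns (x y u v), got {line!r}")
            rows.append([float(p) for p in parts[:4]])
    if not rows:
        raise FieldFormatError(f"{path}: no data rows")
    return np.asarray(rows)


def _regular_axis(values: np.ndarray, name: str, rtol: float = 1e-6) -> np.ndarray:
    axis = np.unique(values)
    if axis.size < 2:
        raise FieldFormatError(f"degenerate {name} axis")
    steps = np.diff(axis)
    h = steps.mean()
    if np.any(np.abs(steps - h) > rtol * max(abs(h), 1e-300)):
        raise FieldFormatError(f"irregular {name} coordinate step")
    return axis


def read_velocity_field(path, dialect: str = "table", allow_missing: bool = False) -> VelocityField:
    """Read a velocity field from disk.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"table"`` for delimited ``x y u v`` text, ``"grid"`` for the npz
        grid container written by :func:`write_velocity_field`.
    allow_missing:
        For the table dialect, accept grids with missing nodes and mark them
        in the mask instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "grid":
        with np.load(path) as npz:
            mask = npz["mask"] if "mask" in npz.files else None
            return VelocityField(
                u_x=npz["u_x"],
                u_y=npz["u_y"],
                spacing=float(npz["spacing"]),
                origin=tuple(np.atleast_1d(npz["origin"]).astype(float)),
                mask=mask,
            )
    if dialect != "table":
        raise ValueError(f"unknown dialect {dialect!r}")

    data = _parse_table(path)
    x, y, u, v = data.T
    xs = _regular_axis(x, "x")
    ys = _regular_axis(y, "y")
    hx, hy = np.diff(xs).mean(), np.diff(ys).mean()
    if abs(hx - hy) > 1e-6 * max(hx, hy):
        raise FieldFormatError("anisotropic grid spacing is not supported")
    nx, ny = xs.size, ys.size
    ci = np.searchsorted(xs, x)
    ri = np.searchsorted(ys, y)
    u_x = np.full((ny, nx), np.nan)
    u_y = np.full((ny, nx), np.nan)
    u_x[ri, ci] = u
    u_y[ri, ci] = v
    missing = ~np.isfinite(u_x)
    if missing.any() and not allow_missing:
        raise FieldFormatError(f"{missing.sum()} missing grid nodes")
    mask = ~missing if missing.any() else None
    if mask is not None:
        u_x[missing] = 0.0
        u_y[missing] = 0.0
    return VelocityField(u_x, u_y, spacing=float(hx), origin=(float(xs[0]), float(ys[0])), mask=mask)


def write_velocity_field(fld: VelocityField, path) -> None:
    """Write a velocity field in the grid (npz) dialect."""
    payload = dict(u_x=fld.u_x, u_y=fld.u_y, spacing=fld.spacing, origin=np.asarray(fld.origin))
    if fld.mask is not None:
        payload["mask"] = fld.mask
    np.savez(path, **payload)


def write_vorticity_field(vort: VorticityField, path) -> None:
    np.savez(
        path,
        omega=vort.omega,
        spacing=vort.spacing,
        origin=np.asarray(vort.origin),
        valid=np.asarray(
            [
                vort.valid_slice[0].start or 0,
                vort.valid_slice[0].stop if vort.valid_slice[0].stop is not None else vort.omega.shape[0],
                vort.valid_slice[1].start or 0,
                vort.valid_slice[1].stop if vort.valid_slice[1].stop is not None else vort.omega.shape[1],
            ]
        ),
    )


def read_vorticity_field(path) -> VorticityField:
    with np.load(path) as npz:
        r0, r1, c0, c1 = (int(v) for v in npz["valid"])
        return VorticityField(
            omega=npz["omega"],
            spacing=float(npz["spacing"]),
            origin=tuple(np.atleast_1d(npz["origin"]).astype(float)),
            valid_slice=(slice(r0, r1), slice(c0, c1)),
        )


# ---------------------------------------------------------------------------
# Vorticity
# ---------------------------------------------------------------------------

def _deriv5(f: np.ndarray, axis: int, h: float, periodic: bool) -> np.ndarray:
    """Fourth-order five-point central derivative (f-2 - 8f-1 + 8f+1 - f+2)/12h."""
    if periodic:
        fm2, fm1 = np.roll(f, 2, axis), np.roll(f, 1, axis)
        fp1, fp2 = np.roll(f, -1, axis), np.roll(f, -2, axis)
        return (fm2 - 8.0 * fm1 + 8.0 * fp1 - fp2) / (12.0 * h)
    out = np.full_like(f, np.nan)
    sl = [slice(None)] * f.ndim

    def shifted(k):
        s = list(sl)
        s[axis] = slice(2 + k, f.shape[axis] - 2 + k if f.shape[axis] - 2 + k != 0 else None)
        return f[tuple(s)]

    interior = list(sl)
    interior[axis] = slice(2, -2)
    out[tuple(interior)] = (
        shifted(-2) - 8.0 * shifted(-1) + 8.0 * shifted(1) - shifted(2)
    ) / (12.0 * h)
    return out


def compute_vorticity(fld: VelocityField, boundary: str = "crop") -> VorticityField:
    """Vorticity via the fourth-order five-point stencil.

    With ``boundary="crop"`` the outer two-node frame (where the stencil is
    undefined) is excluded from the valid region; with ``boundary="periodic"``
    the stencil wraps and the full grid is valid.
    """
    if boundary not in ("crop", "periodic"):
        raise ValueError("boundary must be 'crop' or 'periodic'")
    ny, nx = fld.shape
    if min(ny, nx) < 5:
        raise ValueError("grid too small for the five-point stencil")
    periodic = boundary == "periodic"
    # axis 1 = x (columns), axis 0 = y (rows)
    duy_dx = _deriv5(fld.u_y, axis=1, h=fld.spacing, periodic=periodic)
    dux_dy = _deriv5(fld.u_x, axis=0, h=fld.spacing, periodic=periodic)
    omega = duy_dx - dux_dy
    if periodic:
        valid = (slice(None), slice(None))
    else:
        valid = (slice(2, ny - 2), slice(2, nx - 2))
    if fld.mask is not None:
        bad = ~fld.mask
        # nodes whose stencil touches a masked node are themselves invalid
        grow = bad.copy()
        for ax in (0, 1):
            for k in (1, 2):
                grow |= np.roll(bad, k, axis=ax) | np.roll(bad, -k, axis=ax)
        omega[grow] = np.nan
    if not np.isfinite(omega[valid]).all():
        raise ValueError("non-finite vorticity inside the valid region")
    return VorticityField(omega, spacing=fld.spacing, origin=fld.origin, valid_slice=valid)


def binarize_vorticity(vort: VorticityField) -> BinaryVorticityField:
    """Binary sign field over the valid region: 1 iff omega > 0 strictly."""
    sign = (vort.valid > 0).astype(np.uint8)
    return BinaryVorticityField(sign, spacing=vort.spacing, origin=vort.valid_origin)
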