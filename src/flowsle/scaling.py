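"""Gyration radii, fractal-dimension fits, duality product, and
winding-angle statistics.

The fractal dimension D of a contour ensemble is the slope of log perimeter
against log gyration radius, ``l ~ R_g^D``; the complete perimeter of the
critical-percolation / SLE_6 class has D = 7/4 and the accessible external
perimeter D* = 4/3, linked by the duality relation 4(D-1)(D*-1) = 1.

The winding angle theta_j of a curve is the cumulative sum of its local
turning angles; for conformally invariant curves it is Gaussian at fixed
arclength s with variance Var(theta) = a + [2*kappa/(8+kappa)] * log(s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .contours import ChordalTrace, ClusterLabeling, ContourTrace, accessible_perimeter, trace_contours

__all__ = [
    "ClusterGeometry",
    "ScalingFit",
    "WindingStatistics",
    "gyration_radius",
    "cluster_geometries",
    "fit_fractal_dimension",
    "duality_product",
    "winding_angles",
    "winding_variance_fit",
    "kappa_from_alpha",
    "alpha_from_kappa",
    "resample_arclength",
]


@dataclass
class ClusterGeometry:
    """Per-cluster scalars, lengths in units of the grid step h."""

    label: int
    size: int
    gyration_radius: float
    perimeter_complete: float
    perimeter_accessible: float


@dataclass
class ScalingFit:
    exponent: float
    intercept: float
    stderr: float
    fit_range: tuple[float, float]
    n_points: int
    normalization: float  # R_g of the largest cluster (R_g,max)


@dataclass
class WindingStatistics:
    arclengths: np.ndarray
    variances: np.ndarray
    slope_alpha: float
    intercept_a: float
    stderr: float
    kappa_from_alpha: float
    gaussian: dict = field(default_factory=dict)  # s -> moment/KS diagnostics


# ---------------------------------------------------------------------------
# Cluster geometry
# ---------------------------------------------------------------------------

def gyration_radius(sites: np.ndarray, spacing: float = 1.0) -> float:
    """Root-mean-square displacement of a site set from its centroid.

    Equals ``sqrt((1/(2 N^2)) * sum_{n,m} |r_n - r_m|^2)``; a single site has
    R_g = 0.
    """
    pts = np.atleast_2d(np.asarray(sites, dtype=float))
    if pts.size == 0:
        raise ValueError("empty site set")
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1)))) * spacing


def cluster_geometries(labeling: ClusterLabeling, min_size: int = 2,
                       mode: Optional[str] = None,
                       with_accessible: bool = True) -> list[ClusterGeometry]:
    """Geometry table for every cluster with at least ``min_size`` sites.

    ``mode`` selects the tracing convention and defaults to the labeling
    connectivity ("triangular" stays triangular, 4/8 trace as "square").
    Perimeters are in units of h (unit steps); the complete perimeter is the
    outer boundary of the cluster, the accessible one the outer boundary of
    its 3x3 dilation.
    """
    if mode is None:
        mode = "triangular" if labeling.connectivity == "triangular" else "square"
    out: list[ClusterGeometry] = []
    objects = ndimage.find_objects(labeling.labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None or labeling.sizes[lab - 1] < min_size:
            continue
        sub = labeling.labels[sl] == lab
        rows, cols = np.nonzero(sub)
        rg = gyration_radius(np.c_[cols, rows])
        mask = np.zeros((sub.shape[0] + 2, sub.shape[1] + 2), dtype=np.uint8)
        mask[1:-1, 1:-1] = sub
        traces = trace_contours(mask, mode=mode)
        outer = min(traces, key=lambda t: t.signed_area)
        l_acc = np.nan
        if with_accessible:
            dil = ndimage.binary_dilation(
                np.pad(mask, 1), structure=np.ones((3, 3), bool)
            ).astype(np.uint8)
            acc_traces = trace_contours(dil, mode="square")
            l_acc = min(acc_traces, key=lambda t: t.signed_area).length
        out.append(
            ClusterGeometry(
                label=lab,
                size=int(labeling.sizes[lab - 1]),
                gyration_radius=rg,
                perimeter_complete=outer.length,
                perimeter_accessible=float(l_acc),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fractal-dimension fit
# ---------------------------------------------------------------------------

def fit_fractal_dimension(geometries: Sequence[ClusterGeometry], kind: str = "complete",
                          fit_range: Optional[tuple[float, float]] = None,
                          bins_per_decade: int = 12, min_per_bin: int = 5) -> ScalingFit:
    """Least-squares slope of log l versus log R_g over log-binned medians.

    The default fit window excludes the smallest decade of R_g (the lattice
    regime, where tracing and dilation operate at the scale of single sites)
    and radii above 0.35 R_g,max (the finite-size regime, where the largest
    clusters feel the domain boundary). Perimeter and radius are normalized
    by R_g,max before fitting, which leaves the slope unchanged but makes
    exported axes comparable across systems.
    """
    if kind not in ("complete", "accessible"):
        raise ValueError("kind must be 'complete' or 'accessible'")
    rg = np.array([g.gyration_radius for g in geometries], dtype=float)
    ell = np.array(
        [g.perimeter_complete if kind == "complete" else g.perimeter_accessible
         for g in geometries], dtype=float)
    ok = (rg > 0) & (ell > 0) & np.isfinite(ell)
    rg, ell = rg[ok], ell[ok]
    if rg.size < 10:
        raise ValueError("need at least 10 clusters with positive R_g and perimeter")
    rg_max = rg.max()
    if fit_range is None:
        hi = 0.35 * rg_max    # exclude the finite-size regime
        # exclude the smallest decade (lattice regime); small (smoke-scale)
        # ensembles keep at least 0.6 decades of fit range instead
        lo = min(rg.min() * 10.0, hi / 4.0)
        fit_range = (lo, hi)
    lo, hi = fit_range
    if hi / max(lo, 1e-300) < 10.0**0.5:
        raise ValueError(
            f"insufficient dynamic range for a scaling fit: [{lo:.3g}, {hi:.3g}]")
    sel = (rg >= lo) & (rg <= hi)
    x = np.log10(rg[sel] / rg_max)
    y = np.log10(ell[sel] / rg_max)
    # logarithmically binned medians
    edges = np.arange(np.floor(x.min() * bins_per_decade),
                      np.ceil(x.max() * bins_per_decade) + 1) / bins_per_decade
    idx = np.digitize(x, edges)
    # sparse (smoke-scale) ensembles: relax the per-bin occupancy rather
    # than fail outright, the stderr reflects the extra scatter
    for occupancy in sorted({min_per_bin, 3, 2, 1}, reverse=True):
        if occupancy > min_per_bin:
            continue
        bx, by = [], []
        for b in np.unique(idx):
            m = idx == b
            if m.sum() >= occupancy:
                bx.append(np.median(x[m]))
                by.append(np.median(y[m]))
        if len(bx) >= 4:
            break
    if len(bx) < 4:
        raise ValueError("too few populated bins for a scaling fit")
    res = stats.linregress(bx, by)
    return ScalingFit(exponent=float(res.slope), intercept=float(res.intercept),
                      stderr=float(res.stderr), fit_range=(float(lo), float(hi)),
                      n_points=len(bx), normalization=float(rg_max))


def duality_product(D: float, D_star: float) -> float:
    """The conformal-duality combination 4(D-1)(D*-1), equal to 1 for dual
    pairs such as (7/4, 4/3)."""
    if D <= 1 or D_star <= 1:
        raise ValueError("fractal dimensions of fractal curves must exceed 1")
    return 4.0 * (D - 1.0) * (D_star - 1.0)


# ---------------------------------------------------------------------------
# Winding angles
# ---------------------------------------------------------------------------

def _as_complex(trace) -> np.ndarray:
    if isinstance(trace, ChordalTrace):
        return trace.points
    if isinstance(trace, ContourTrace):
        return trace.vertices[:, 0] + 1j * trace.vertices[:, 1]
    arr = np.asarray(trace)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0] + 1j * arr[:, 1]
    return arr.astype(complex)


def winding_angles(trace) -> np.ndarray:
    """Cumulative winding angle theta_j along a polyline.

    theta_0 = 0 at the first segment; each increment is the signed turning
    angle in (-pi, pi] between consecutive segments. A polyline with n
    vertices yields n - 1 values (one per segment).
    """
    z = _as_complex(trace)
    if len(z) < 3:
        raise ValueError("winding angles need at least 3 vertices")
    seg = np.diff(z)
    if np.any(seg == 0):
        raise ValueError("degenerate (repeated) vertices in trace")
    turns = np.angle(seg[1:] / seg[:-1])
    return np.concatenate([[0.0], np.cumsum(turns)])


def alpha_from_kappa(kappa: float) -> float:
    return 2.0 * kappa / (8.0 + kappa)


def kappa_from_alpha(alpha: float) -> float:
    """Invert alpha = 2 kappa / (8 + kappa)."""
    return 8.0 * alpha / (2.0 - alpha)


def resample_arclength(trace, ds: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arclength step ds.

    Needed before winding-angle statistics of curves sampled non-uniformly
    in arclength (e.g. Loewner-time-sampled traces).
    """
    z = _as_complex(trace)
    s = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(z)))])
    n = max(int(s[-1] / ds), 2)
    si = np.linspace(0.0, s[-1], n + 1)
    return np.interp(si, s, z.real) + 1j * np.interp(si, s, z.imag)


def winding_variance_fit(traces: Sequence, s_grid: Optional[np.ndarray] = None,
                         fit_range: Optional[tuple[float, float]] = None,
                         gaussian_s: Sequence[int] = (64, 512)) -> WindingStatistics:
    """Ensemble winding-angle variance versus arclength and its log fit.

    For each arclength s (in vertex steps) every trace is cut into
    non-overlapping segments of s steps; within each segment the winding
    angles are measured relative to the segment's average angle and pooled
    across segments and traces. The pooled variance is fitted as
    Var(theta) = a + alpha * ln(s), and kappa is recovered from
    alpha = 2 kappa / (8 + kappa).

    Gaussianity is assessed at the arclengths in ``gaussian_s`` by
    standardized skewness / excess kurtosis and a KS distance to the unit
    normal.
    """
    if len(traces) < 50:
        raise ValueError("need at least 50 traces for winding statistics")
    thetas = []
    for tr in traces:
        z = _as_complex(tr)
        if len(z) >= 3:
            thetas.append(winding_angles(z))
    lengths = np.array([len(t) - 1 for t in thetas])
    l_ref = np.quantile(lengths, 0.25)
    if s_grid is None:
        smax = l_ref / 2.0
        s_grid = np.unique((2.0 ** np.arange(3, 1 + np.floor(np.log2(smax))))).astype(int)
    s_grid = np.asarray(s_grid, dtype=int)
    if s_grid.min() < 8:
        raise ValueError("arclengths below 8 steps are lattice-dominated")

    samples: dict[int, np.ndarray] = {}
    variances = []
    for s in s_grid:
        vals = []
        for th in thetas:
            nwin = (len(th) - 1) // s
            for k in range(nwin):
                w = th[k * s:(k + 1) * s]
                vals.append(w - w.mean())
        v = np.concatenate(vals) if vals else np.array([])
        samples[int(s)] = v
        variances.append(v.var() if v.size > 1 else np.nan)
    variances = np.asarray(variances)
    ok = np.isfinite(variances)
    if fit_range is None:
        hi = max(l_ref / 4.0, 64.0)
        # prefer dropping the lattice-affected small-s points, but keep at
        # least three grid points for short-trace (smoke-scale) ensembles
        for lo in (32.0, 16.0, 8.0):
            fit_range = (lo, hi)
            if (ok & (s_grid >= lo) & (s_grid <= hi)).sum() >= 3:
                break
    sel = ok & (s_grid >= fit_range[0]) & (s_grid <= fit_range[1])
    if sel.sum() < 3:
        raise ValueError("too few arclength points inside the fit range")
    res = stats.linregress(np.log(s_grid[sel]), variances[sel])
    alpha = float(res.slope)

    gauss = {}
    for s in gaussian_s:
        s = int(s)
        v = samples.get(s)
        if v is None and s <= s_grid.max():
            continue
        if v is None or v.size < 100:
            continue
        std = v.std()
        if std == 0:
            continue
        u = (v - v.mean()) / std
        gauss[s] = dict(
            n=int(v.size),
            skew=float(stats.skew(u)),
            excess_kurtosis=float(stats.kurtosis(u)),
            ks=float(stats.kstest(u, "norm").statistic),
        )
    return WindingStatistics(
        arclengths=s_grid.astype(float), variances=variances,
        slope_alpha=alpha, intercept_a=float(res.intercept),
        stderr=float(res.stderr), kappa_from_alpha=float(kappa_from_alpha(alpha)),
        gaussian=gauss,
    )
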