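"""Schramm-Loewner-evolution inference: left-passage probability and
Loewner driving-function extraction.

Chordal SLE_kappa curves run from 0 to infinity in the upper half-plane H
and are generated by the Loewner equation

    d g_t(z) / dt = 2 / (g_t(z) - U_t),      g_0(z) = z,

with a Brownian driving function of variance Var(U_t) = kappa * t. Two
independent estimators of kappa are implemented:

* **left-passage**: the probability that the curve passes to the left of a
  point z = rho * exp(i*phi) depends only on phi (Schramm's formula); kappa
  is the minimizer of a weighted mean-square deviation between empirical and
  analytic passage probabilities.
* **driving function**: the curve is "unzipped" by iterating the vertical
  slit map, reading off the driving values U_{t_k}; kappa is the slope of
  the ensemble variance of U_t against Loewner time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .contours import ChordalTrace

__all__ = [
    "PassageGrid",
    "DrivingFunction",
    "KappaEstimate",
    "schramm_probability",
    "default_passage_points",
    "empirical_left_passage",
    "estimate_kappa_lpp",
    "slit_map",
    "inverse_slit_map",
    "compute_driving_function",
    "fit_kappa_driving",
    "driving_autocorrelation",
]


@dataclass
class PassageGrid:
    """Empirical left-passage tallies on a fixed point set in H."""

    points: np.ndarray  # complex sample points
    counts_left: np.ndarray  # per-point tallies
    n_samples: np.ndarray  # per-point eligible trace counts

    @property
    def probabilities(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_samples > 0, self.counts_left / self.n_samples, np.nan)


@dataclass
class DrivingFunction:
    """Loewner times t_k (increasing from 0) and driving values U_{t_k}."""

    times: np.ndarray
    values: np.ndarray
    trace_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("Loewner times must increase strictly from 0")
        if not np.isfinite(self.values).all():
            raise ValueError("driving values must be finite")

    @property
    def capacity(self) -> float:
        return float(self.times[-1])

    def at(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-constant interpolation (the zipper's stepwise driving)."""
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, len(self.values) - 1)
        return self.values[idx]


@dataclass
class KappaEstimate:
    kappa: float
    stderr: float
    method: str  # left_passage | driving_variance | winding
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Schramm's formula and the left-passage estimator
# ---------------------------------------------------------------------------

def schramm_probability(phi, kappa: float):
    """Probability that a chordal SLE_kappa trace passes to the left of a
    point with polar angle phi in (0, pi); independent of the radius.

    P_kappa(phi) = 1/2 + Gamma(4/k)/(sqrt(pi) Gamma((8-k)/(2k)))
                   * cot(phi) * 2F1(1/2, 4/k; 3/2; -cot^2(phi)).
    """
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr <= 0.0) or np.any(phi_arr >= np.pi):
        raise ValueError("phi must lie strictly inside (0, pi)")
    if not (0.0 < kappa < 8.0):
        raise ValueError("kappa must lie strictly inside (0, 8)")
    c = special.gamma(4.0 / kappa) / (np.sqrt(np.pi) * special.gamma((8.0 - kappa) / (2.0 * kappa)))
    ct = 1.0 / np.tan(phi_arr)
    p = 0.5 + c * ct * special.hyp2f1(0.5, 4.0 / kappa, 1.5, -(ct**2))
    return p if p.ndim else float(p)


def default_passage_points(traces: Sequence[ChordalTrace | np.ndarray],
                           n_radii: int = 5, n_angles: int = 9,
                           radial_window: tuple[float, float] = (0.04, 0.15)) -> np.ndarray:
    """Point set S: n_radii logarithmic radii between the given fractions of
    the median trace extent, crossed with n_angles angles pi/10 ... 9pi/10.

    The radial window sits well inside the median extent: the analytic
    left-passage law assumes a curve running to infinity, and points whose
    radius is not small compared to the observed trace length acquire a
    truncation bias that systematically lowers the fitted diffusivity.
    """
    extents = np.array([np.abs(np.asarray(getattr(t, "points", t))).max() for t in traces])
    med = np.median(extents)
    radii = np.geomspace(radial_window[0] * med, radial_window[1] * med, n_radii)
    angles = np.linspace(np.pi / (n_angles + 1), n_angles * np.pi / (n_angles + 1), n_angles)
    return (radii[:, None] * np.exp(1j * angles[None, :])).ravel()


def _passes_left(z: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Boolean per point: does the directed curve z pass to the left of it?

    Decided by the total angle subtended at the point: the cumulative
    continuous change of arg(z_j - p) is negative when p lies to the right
    of the curve (the curve passes to its left). Robust for curves that
    touch the real axis.
    """
    dz = z[1:, None] - points[None, :]
    dz0 = z[:-1, None] - points[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ang = np.angle(dz / dz0)
    return np.nansum(ang, axis=0) < 0.0


def empirical_left_passage(traces: Sequence[ChordalTrace | np.ndarray],
                           points: Optional[np.ndarray] = None) -> PassageGrid:
    """Tally left passages of an ensemble of chordal traces at a point set.

    A trace is eligible for a point only if it extends beyond the point's
    radius; ineligible traces are excluded from that point's tally.
    """
    if points is None:
        points = default_passage_points(traces)
    points = np.asarray(points, dtype=complex)
    if np.any(points.imag <= 0):
        raise ValueError("passage points must lie strictly in the upper half-plane")
    counts = np.zeros(points.size)
    nelig = np.zeros(points.size)
    rho = np.abs(points)
    for tr in traces:
        z = np.asarray(getattr(tr, "points", tr), dtype=complex)
        if len(z) < 2:
            continue
        elig = np.abs(z).max() >= rho
        if not elig.any():
            continue
        # guard: a sample point exactly on a vertex makes the angle undefined
        d = np.abs(z[:, None] - points[None, :]).min(axis=0)
        elig &= d > 1e-12
        left = _passes_left(z, points)
        counts[elig] += left[elig]
        nelig[elig] += 1
    return PassageGrid(points=points, counts_left=counts, n_samples=nelig)


def lpp_objective(grid: PassageGrid, kappa: float) -> float:
    """Weighted mean-square deviation Q(kappa) between empirical and analytic
    left-passage probabilities."""
    P = grid.probabilities
    usable = (grid.n_samples > 1) & (P > 0) & (P < 1)
    P = P[usable]
    n = grid.n_samples[usable]
    phi = np.angle(grid.points[usable])
    Pk = schramm_probability(phi, kappa)
    return float(np.mean((n - 1.0) * (P - Pk) ** 2 / (P * (1.0 - P))))


def estimate_kappa_lpp(grid: PassageGrid, bracket: tuple[float, float] = (0.5, 7.9),
                       xatol: float = 1e-4) -> KappaEstimate:
    """kappa as the minimizer of Q(kappa) over the bracket.

    The standard error is taken from the curvature of Q at the minimum
    (Q behaves like a chi-square in kappa near its minimum).
    """
    P = grid.probabilities
    usable = (grid.n_samples > 1) & (P > 0) & (P < 1)
    if usable.sum() < 5:
        raise ValueError("need at least 5 points with non-degenerate passage frequencies")
    res = optimize.minimize_scalar(lambda k: lpp_objective(grid, k),
                                   bounds=bracket, method="bounded",
                                   options={"xatol": xatol})
    k0 = float(res.x)
    h = 1e-2
    q0, qm, qp = (lpp_objective(grid, k) for k in (k0, k0 - h, k0 + h))
    curv = (qm - 2.0 * q0 + qp) / h**2
    stderr = float(np.sqrt(2.0 / curv)) if curv > 0 else float("nan")
    return KappaEstimate(kappa=k0, stderr=stderr, method="left_passage",
                         diagnostics=dict(Q_min=float(res.fun), n_points=int(usable.sum()),
                                          n_samples=float(np.median(grid.n_samples[usable]))))


# ---------------------------------------------------------------------------
# Vertical slit map and the zipper
# ---------------------------------------------------------------------------

def _sqrt_upper(w: np.ndarray, re_ref: np.ndarray) -> np.ndarray:
    """Square root branch mapping into the closed upper half-plane, with the
    sign of the real part following ``re_ref`` on the real axis."""
    s = np.sqrt(w.astype(complex))
    sign = np.where(s.imag > 0, 1.0, np.where(s.imag < 0, -1.0, np.where(re_ref >= 0, 1.0, -1.0)))
    return s * sign


def slit_map(z, delta: float, Delta: float):
    """The vertical slit map g(z) = sqrt((z-delta)^2 + 4*Delta) + delta.

    Removes the slit from delta to delta + 2i*sqrt(Delta) and maps
    H minus the slit onto H; the slit tip maps to its base delta.
    """
    if Delta <= 0:
        raise ValueError("Delta must be positive")
    z_arr = np.asarray(z, dtype=complex)
    if np.any(z_arr.imag < -1e-12):
        raise ValueError("slit map is defined on the closed upper half-plane")
    w = z_arr - delta
    inside = (np.abs(w.real) < 1e-14) & (w.imag < 2.0 * np.sqrt(Delta) * (1 - 1e-12))
    if np.any(inside):
        raise ValueError("point lies strictly inside the slit")
    out = _sqrt_upper(w**2 + 4.0 * Delta, w.real) + delta
    return out if out.ndim else complex(out)


def inverse_slit_map(w, delta: float, Delta: float):
    """Inverse of :func:`slit_map`: f(w) = sqrt((w-delta)^2 - 4*Delta) + delta,
    opening a vertical slit at delta."""
    w_arr = np.asarray(w, dtype=complex)
    v = w_arr - delta
    out = _sqrt_upper(v**2 - 4.0 * Delta, v.real) + delta
    return out if out.ndim else complex(out)


def compute_driving_function(trace: ChordalTrace | np.ndarray,
                             max_points: Optional[int] = 1200,
                             trace_id: Optional[int] = None,
                             im_tol: float = 1e-6) -> DrivingFunction:
    """Extract the Loewner driving function of a chordal trace by the
    vertical-slit zipper.

    At step k the first unmapped point w = x + iy fixes delta_k = x and
    Delta_k = y^2/4; U_{t_k} = delta_k is recorded at t_k = t_{k-1} +
    Delta_k and the slit map is applied to all remaining points. Points that
    lie on the real axis carry no half-plane capacity and are skipped.

    ``max_points`` caps the number of zipper steps by uniform subsampling
    (the zipper is O(n^2) in the trace length).
    """
    z = np.asarray(getattr(trace, "points", trace), dtype=complex).copy()
    if len(z) < 10:
        raise ValueError("trace too short for driving-function extraction")
    if z[0] != 0:
        raise ValueError("chordal traces must start at the origin")
    if z.imag.min() < -1e-9:
        raise ValueError("trace leaves the closed upper half-plane")
    if max_points is not None and len(z) > max_points:
        stride = int(np.ceil(len(z) / max_points))
        z = np.concatenate([z[::stride], z[-1:]]) if (len(z) - 1) % stride else z[::stride]
    scale = max(np.abs(z).max(), 1e-30)
    times = [0.0]
    values = [0.0]
    t = 0.0
    k = 1  # z[0] == 0 is the base point
    while k < len(z):
        w = z[k]
        if w.imag < -im_tol * scale:
            raise ArithmeticError(
                f"zipper instability at step {k}: Im = {w.imag:.3g}")
        y = max(w.imag, 0.0)
        delta = w.real
        Delta = 0.25 * y * y
        if Delta <= (1e-13 * scale) ** 2 or t + Delta == t:
            k += 1
            continue  # axis point (or sub-roundoff capacity): no slit to open
        t += Delta
        times.append(t)
        values.append(delta)
        rest = z[k + 1:] - delta
        mapped = _sqrt_upper(rest**2 + 4.0 * Delta, rest.real) + delta
        # roundoff can push points marginally below the axis
        mapped = np.where(mapped.imag < 0, mapped.real + 0j, mapped)
        z[k + 1:] = mapped
        k += 1
    if len(times) < 2:
        raise ValueError("trace has no interior points above the axis")
    return DrivingFunction(times=np.asarray(times), values=np.asarray(values),
                           trace_id=trace_id)


# ---------------------------------------------------------------------------
# Driving-function statistics
# ---------------------------------------------------------------------------

def lattice_driving_window(half_width: float, t_min: float = 800.0,
                           saturation: float = 0.025) -> Optional[tuple[float, float]]:
    """Loewner-time fit window for driving functions of lattice curves.

    Ensemble variance profiles Var(U_t)/t of critical lattice interfaces
    show three regimes: a sub-scaling excess at small t (the curve is not
    yet fractal at lattice scales; boundary excursions near the origin are
    O(1) in lattice units), a plateau at the universal diffusivity, and a
    suppression once the driving has diffused across a finite domain of
    lateral half-width W (|U| cannot exceed the domain). The window
    [max(t_min, t_sat/8), t_sat] with t_sat = saturation * W^2 brackets the
    plateau. Returns None when the domain is too small to have one.
    """
    t_sat = saturation * half_width**2
    lo = max(t_min, t_sat / 8.0)
    if t_sat <= 1.5 * lo:
        return None
    return (lo, t_sat)


def fit_kappa_driving(dfs: Sequence[DrivingFunction],
                      t_grid: Optional[np.ndarray] = None,
                      n_grid: int = 64,
                      collapse_times: Sequence[float] = (0.25, 0.75)) -> KappaEstimate:
    """kappa from the linear growth Var(U_t) = kappa * t.

    U is interpolated onto a common Loewner-time grid (piecewise-constant,
    matching the zipper's stepwise driving) and the ensemble variance is
    fitted linearly through the origin over the grid. All traces are
    truncated at the common capacity horizon T = ``t_grid[-1]`` (traces that
    never reach it are dropped), so Loewner times rescaled by T lie in
    [0, 1] uniformly across the ensemble. The diagnostics carry the
    rescaled distributions U_{t}/sqrt(kappa*t) at the fractions
    ``collapse_times`` of T, with KS distances to the unit normal.

    For lattice curves the default grid starts above zero: the smallest
    Loewner times probe sub-lattice structure where the curve is not yet
    in the scaling regime.
    """
    if len(dfs) < 50:
        raise ValueError("need at least 50 driving functions")
    caps = np.array([d.capacity for d in dfs])
    if t_grid is None:
        t_end = np.quantile(caps, 0.05)
        t_grid = np.linspace(0.0, t_end, n_grid + 1)[1:]
    t_grid = np.asarray(t_grid, dtype=float)
    keep = [d for d in dfs if d.capacity >= t_grid[-1]]
    if len(keep) < 50:
        raise ValueError("too few driving functions reach the end of the time grid")
    U = np.stack([d.at(t_grid) for d in keep])
    var = U.var(axis=0)
    kappa = float(np.sum(var * t_grid) / np.sum(t_grid**2))
    resid = var - kappa * t_grid
    stderr = float(np.sqrt(np.sum(resid**2) / max(len(t_grid) - 1, 1) / np.sum(t_grid**2)))
    # finite-ensemble error floor: Var estimates at each t have relative
    # s.d. sqrt(2/(n-1)); the grid points are strongly correlated in t, so
    # use the single-time bound as a conservative component
    stderr = float(np.hypot(stderr, kappa * np.sqrt(2.0 / (len(keep) - 1))))

    T_end = float(t_grid[-1])
    collapse = {}
    for frac in collapse_times:
        t_c = frac * T_end
        vals = np.array([d.at(np.array([t_c]))[0] for d in keep]) / np.sqrt(kappa * t_c)
        collapse[frac] = dict(
            samples=vals,
            ks=float(stats.kstest(vals, "norm").statistic),
            n=int(vals.size),
        )
    return KappaEstimate(kappa=kappa, stderr=stderr, method="driving_variance",
                         diagnostics=dict(t_grid=t_grid, var=var, n_traces=len(keep),
                                          collapse=collapse))


def driving_autocorrelation(dfs: Sequence[DrivingFunction],
                            t: Optional[float | np.ndarray] = None,
                            taus: Optional[np.ndarray] = None,
                            n_grid: int = 64,
                            t_window: Optional[tuple[float, float]] = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson autocorrelation C(t; tau) of driving-function increments.

    Increments are formed on a common uniform grid of ``n_grid`` steps over
    ``t_window`` (default [0, T] with T the 5th-percentile capacity). With
    scalar ``t`` the correlation at that time origin is returned for each
    lag; with ``t`` None (or an array of origins) the estimate is averaged
    over origins, which is the curve a Markov/Brownian diagnostic reports.

    Returns ``(taus, C)`` with taus in grid-step units.
    """
    caps = np.array([d.capacity for d in dfs])
    if t_window is None:
        t_window = (0.0, float(np.quantile(caps, 0.05)))
    t0, T = t_window
    grid = np.linspace(t0, T, n_grid + 1)
    keep = [d for d in dfs if d.capacity >= T]
    dU = np.diff(np.stack([d.at(grid) for d in keep]), axis=1)  # (n_traces, n_grid)
    n_tr, m = dU.shape
    sd = dU.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance increments: correlation undefined")
    if taus is None:
        taus = np.arange(0, min(m, 17))
    taus = np.asarray(taus, dtype=int)
    if t is None:
        origins = np.arange(m)
    else:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        origins = np.clip(((t_arr - t0) / ((T - t0) / m)).astype(int), 0, m - 1)
    C = np.empty(taus.shape, dtype=float)
    for i, tau in enumerate(taus):
        js = origins[origins + tau < m]
        if js.size == 0:
            C[i] = np.nan
            continue
        a = dU[:, js]
        b = dU[:, js + tau]
        am = a - a.mean(axis=0)
        bm = b - b.mean(axis=0)
        corr = (am * bm).mean(axis=0) / (a.std(axis=0) * b.std(axis=0))
        C[i] = corr.mean()
    return taus, C
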