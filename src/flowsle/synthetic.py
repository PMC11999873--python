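"""Synthetic ground-truth generators.

Three generators with exactly known statistics feed the analysis pipeline:

* **critical-percolation interfaces** — site percolation at p = 1/2 on the
  triangular lattice (hexagonal cells), explored chordally from a boundary
  point; the exploration path converges to SLE_6 (kappa = 6, D = 7/4,
  winding slope alpha = 6/7);
* **forward SLE_kappa traces** — discrete Loewner evolution driven by
  Brownian motion of variance kappa*t, for any kappa in (0, 8);
* **active-nematic velocity fields** — a minimal incompressible active
  nematic (Q-tensor) model producing statistically stationary vortical flow
  ("active turbulence") with vortices at the active length sqrt(K/zeta),
  solved by a finite-difference order-parameter update coupled to a D2Q9
  lattice-kinetic flow step in the low-Reynolds limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .contours import ChordalTrace
from .fields import VelocityField

__all__ = [
    "PercolationField",
    "SimulationParams",
    "NematicState",
    "percolation_interface",
    "sample_percolation_field",
    "sample_sle_trace",
    "init_nematic",
    "step_active_nematic",
    "run_simulation",
    "elastic_free_energy",
]


# ---------------------------------------------------------------------------
# Critical percolation on the triangular lattice
# ---------------------------------------------------------------------------

SQRT3 = np.sqrt(3.0)

# explorer directions at angles 30 + 60*d degrees; positions are stored as
# integers (p, q) with x = p*sqrt(3)/2 and y = q/2 (honeycomb vertices)
_DXP = (1, 0, -1, -1, 0, 1)
_DYQ = (1, 2, 1, -1, -2, -1)


@dataclass
class PercolationField:
    """Site colours of the triangular lattice in axial storage.

    ``sign[b, j]`` is the colour (1 = positive phase) of the hexagonal cell
    in row b; the cell with axial coordinates (a, b) sits at column
    ``j = a + a_offset`` and physical centre
    x = sqrt(3)*(0.5 + a + b/2), y = 0.5 + 1.5*b. The boundary row below the
    real axis is coloured by the sign of x (positive to the right of the
    origin), which forces a single chordal interface.
    """

    sign: np.ndarray
    a_offset: int
    p: float = 0.5
    seed: Optional[int] = None


def _explore_hex(colors: np.ndarray, a_off: int, width: int, height: int,
                 max_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Chordal exploration walk on the honeycomb; returns vertex arrays p, q.

    Cells in the boundary row below the real axis are fixed by the sign of
    x (positive to the right of the origin, negative to the left); the walk
    starts on the edge shared by the two forced cells that meet at the
    origin, so the interface invariant — positive cells on the right,
    negative on the left — holds from the first step. At each vertex the
    hexagon straight ahead decides the turn: left if it is positive (keeping
    it on the right), right otherwise.
    """
    q_top = 3 * height - 2
    ps = np.empty(max_steps + 1, dtype=np.int64)
    qs = np.empty(max_steps + 1, dtype=np.int64)
    # start edge: between the forced boundary cells at x = -sqrt(3) (colour
    # 0) and x = 0 (colour 1); its upper vertex is (-1, -1), half a unit
    # below the axis, which becomes the chordal origin.
    p, q = -1, -3
    d = 1  # straight up
    n = 0
    dxp, dyq = _DXP, _DYQ
    while n <= max_steps:
        p += dxp[d]
        q += dyq[d]
        ps[n] = p
        qs[n] = q
        n += 1
        if p >= width or p <= -width or q >= q_top:
            break
        ph = p + dxp[d]
        qh = q + dyq[d]
        b = (qh - 1) // 3
        if b < 0:
            c = 1 if ph >= 0 else 0
        else:
            c = colors[b, ((ph - 1 - b) >> 1) + a_off]
        d = (d + 1) % 6 if c else (d - 1) % 6
    return ps[:n], qs[:n]


try:  # optional acceleration; the pure-Python walk is the reference
    from numba import njit as _njit

    _explore_hex_fast = _njit(cache=False)(_explore_hex)
except Exception:  # pragma: no cover - numba is optional
    _explore_hex_fast = None


def percolation_interface(width: int = 128, height: int = 128,
                          seed: Optional[int] = None,
                          rng: Optional[np.random.Generator] = None
                          ) -> tuple[ChordalTrace, PercolationField]:
    """One chordal critical-percolation interface.

    Site percolation at p = 1/2 on a triangular lattice of ``width`` cell
    columns and ``height`` cell rows above the real axis, with the boundary
    row split at the origin. The exploration path starts at the origin and
    is returned as a :class:`ChordalTrace` (unit-length steps); it ends at
    the lattice boundary. Fixing the seed reproduces the trace exactly.
    """
    if width < 8 or height < 8:
        raise ValueError("lattice must be at least 8 x 8 cells")
    if rng is None:
        rng = np.random.default_rng(seed)
    ncols = width + height // 2 + 8
    a_off = (width + height) // 2 + 4
    colors = rng.integers(0, 2, size=(height, ncols), dtype=np.uint8)
    max_steps = 16 * width * height
    walker = _explore_hex_fast if _explore_hex_fast is not None else _explore_hex
    ps, qs = walker(colors, a_off, width, height, max_steps)
    # the real axis sits at the level of the start vertex (-1, -1); every
    # later vertex has q >= -1, so the trace stays in the closed upper
    # half-plane with unit steps throughout
    z = (ps + 1) * (SQRT3 / 2.0) + 1j * ((qs + 1) * 0.5)
    trace = ChordalTrace(points=z)
    return trace, PercolationField(sign=colors, a_offset=a_off, p=0.5, seed=seed)


def sample_percolation_field(shape: tuple[int, int], seed: Optional[int] = None,
                             rng: Optional[np.random.Generator] = None,
                             p: float = 0.5) -> np.ndarray:
    """I.i.d. site field on the square grid for triangular-adjacency cluster
    analysis (two extra diagonal neighbours per site; critical at p = 1/2)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return (rng.random(shape) < p).astype(np.uint8)


# ---------------------------------------------------------------------------
# Loop-erased random walk (exact SLE_2 class)
# ---------------------------------------------------------------------------

def _lerw_walk(rand: np.ndarray, width: int, height: int,
               px: np.ndarray, py: np.ndarray, visited: np.ndarray) -> int:
    """Half-plane excursion random walk with online loop erasure.

    The walk is the simple random walk on Z^2 conditioned to stay in the
    upper half-plane (Doob h-transform with h = y), whose loop erasure
    converges to chordal SLE_2. Returns the loop-erased path length, or -1
    if the random buffer is exhausted.
    """
    x, y = 0, 1
    px[0], py[0] = 0, 0
    px[1], py[1] = 0, 1
    visited[width, 1] = 2
    n = 2
    for k in range(rand.shape[0]):
        u = rand[k] * (4.0 * y)
        if u < y + 1.0:
            nx, ny = x, y + 1
        elif u < 2.0 * y:
            nx, ny = x, y - 1
        elif u < 3.0 * y:
            nx, ny = x - 1, y
        else:
            nx, ny = x + 1, y
        if ny > height or nx > width or nx < -width:
            px[n], py[n] = nx, ny
            return n + 1
        idx = visited[nx + width, ny]
        if idx > 0:
            for j in range(idx, n):
                visited[px[j] + width, py[j]] = 0
            n = idx
        else:
            px[n], py[n] = nx, ny
            visited[nx + width, ny] = n + 1
            n += 1
        x, y = nx, ny
    return -1


try:
    from numba import njit as _njit_lerw

    _lerw_walk_fast = _njit_lerw(cache=False)(_lerw_walk)
except Exception:  # pragma: no cover
    _lerw_walk_fast = None


def loop_erased_walk(width: int = 200, height: int = 200,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None) -> ChordalTrace:
    """One chordal loop-erased-random-walk trace (SLE_2 universality class).

    The underlying walk starts on the real axis, is conditioned to stay in
    the upper half-plane, and is absorbed at height ``height`` or at
    |x| = ``width``; loops are erased on the fly. The loop-erased path is
    the exact lattice curve whose scaling limit is chordal SLE_2
    (winding-variance slope 2*kappa/(8+kappa) = 0.4), useful as a second
    ground-truth ensemble that is fully resolved at the lattice scale.
    """
    if width < 8 or height < 8:
        raise ValueError("domain must be at least 8 x 8")
    if rng is None:
        rng = np.random.default_rng(seed)
    walker = _lerw_walk_fast if _lerw_walk_fast is not None else _lerw_walk
    cap = 4 * (width + height) * height + 4
    px = np.empty(cap, dtype=np.int64)
    py = np.empty(cap, dtype=np.int64)
    visited = np.zeros((2 * width + 1, height + 2), dtype=np.int64)
    n_rand = 60 * height * height
    while True:
        rand = rng.random(n_rand)
        n = walker(rand, width, height, px, py, visited)
        if n > 0:
            break
        visited[:] = 0  # exhausted the buffer (rare): retry longer
        n_rand *= 2
    z = px[:n] + 1j * py[:n].astype(float)
    return ChordalTrace(points=z)


# ---------------------------------------------------------------------------
# Forward SLE
# ---------------------------------------------------------------------------

def sample_sle_trace(kappa: float, n_steps: int = 1000, dt: float = 1e-3,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None) -> ChordalTrace:
    """Forward chordal SLE_kappa trace from Brownian driving.

    The driving function is piecewise constant on steps of size ``dt`` with
    Gaussian increments of variance kappa*dt; trace points are obtained by
    composing inverse vertical slit maps in reverse order (discrete Loewner
    evolution). kappa -> 0 yields the straight vertical trace
    gamma(t) = 2i*sqrt(t).
    """
    from .sle import _sqrt_upper

    if not 0.0 <= kappa < 8.0:
        raise ValueError("kappa must lie in [0, 8)")
    if n_steps < 100:
        raise ValueError("need at least 100 steps")
    if rng is None:
        rng = np.random.default_rng(seed)
    dU = np.sqrt(kappa * dt) * rng.standard_normal(n_steps)
    # driving value on interval k is U at its left endpoint
    delta = np.concatenate([[0.0], np.cumsum(dU)[:-1]])
    w = delta.astype(complex)  # tip of slit k in its own frame maps from delta_k
    for j in range(n_steps - 1, -1, -1):
        v = w[j:] - delta[j]
        w[j:] = _sqrt_upper(v * v - 4.0 * dt, v.real) + delta[j]
    pts = np.concatenate([[0.0 + 0.0j], w])
    pts = np.where(pts.imag < 0, pts.real + 0j, pts)
    return ChordalTrace(points=pts)


# ---------------------------------------------------------------------------
# Active nematic continuum model
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Parameters of the active nematic model, in lattice units
    (lattice spacing and time step are unity).

    The defaults are the production parameter set (Gamma = 0.05, K = 0.05,
    mu = 1, lambda = 1, zeta = 0.1) rescaled for the scaled-down lattice:
    at 256^2 the production active length sqrt(K/zeta) = 0.7 lattice units
    is unresolvable, so the pair (K, zeta) is moved along the line that
    roughly preserves the production velocity scale zeta*sqrt(K/zeta)/mu
    (~0.05-0.07, keeping the kinetic flow solver in its low-Mach regime)
    while enlarging sqrt(K/zeta) to 3 lattice units — the smallest
    resolvable value, which maximises the scaling range between the active
    length and the box. Exponent estimates are insensitive to the
    elasticity itself (they change by less than 1% under a 500-fold change
    of K).
    """

    Gamma: float = 0.05     # rotational diffusivity
    K: float = 0.15         # Frank elastic constant (production value: 0.05)
    mu: float = 1.0         # dynamic viscosity
    lambda_align: float = 1.0  # flow-alignment parameter (rod-like > 0)
    zeta: float = 0.15 / 9  # activity, extensile > 0 (production value: 0.1)
    lattice: tuple[int, int] = (256, 256)
    n_steps: int = 6000     # post-warm-up steps
    seed: Optional[int] = None
    snapshot_interval: int = 300
    force_cap: float = 0.05  # per-node body-force cap (keeps Mach low)
    n_sub: Optional[int] = None  # order-parameter sub-steps per kinetic step
    grid_filter: float = 0.02  # biharmonic damping of sub-lattice Q modes
    S_max: float = 1.25  # soft cap on the scalar order parameter 2|Q|; with
    # no bulk free energy the magnitude is bounded only dynamically, and a
    # rare local overshoot would otherwise run away through the cubic
    # flow-alignment terms (the stationary turbulent state sits near S ~ 1)
    force_cutoff: float = 0.4  # spectral low-pass on the body force, as a
    # fraction of the Nyquist wavenumber; scales below ~5 lattice units do
    # not force the flow. This dealiasing of the stress divergence is what
    # keeps the coupled explicit scheme dissipative (checked by the
    # passive free-energy-descent test; the admissible cutoff grows as K
    # shrinks); the physical bend-instability forcing lives at
    # ~2*pi*sqrt(K/zeta) ~ 19 lattice units, well inside the passband.

    @property
    def q_substeps(self) -> int:
        """Sub-steps of the explicit Q update per unit time step.

        The molecular-field diffusivity is 2*Gamma*K; explicit Euler with
        the 5-point Laplacian requires dt * 2*Gamma*K < 1/4, and a further
        factor ~4 of headroom absorbs the nonlinear terms.
        """
        if self.n_sub is not None:
            return self.n_sub
        return max(1, int(np.ceil(32.0 * self.Gamma * self.K)))

    def __post_init__(self) -> None:
        if min(self.Gamma, self.K, self.mu) <= 0:
            raise ValueError("Gamma, K and mu must be positive")
        if self.zeta > 0 and np.sqrt(self.K / self.zeta) < 3.0:
            raise ValueError("active length sqrt(K/zeta) must be >= 3 lattice units")

    @property
    def active_length(self) -> float:
        return float(np.sqrt(self.K / abs(self.zeta))) if self.zeta else np.inf

    @property
    def tau(self) -> float:
        """BGK relaxation time: nu = c_s^2 (tau - 1/2) with c_s^2 = 1/3."""
        return 3.0 * self.mu + 0.5


# D2Q9 velocity set
_CX = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1])
_CY = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1])
_W = np.array([4 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 36, 1 / 36, 1 / 36, 1 / 36])


@dataclass
class NematicState:
    """Order parameter, kinetic populations and derived flow fields.

    Q is stored through its two independent components (Q_xx, Q_xy);
    tracelessness and symmetry are therefore exact by construction.
    """

    Qxx: np.ndarray
    Qxy: np.ndarray
    f: np.ndarray          # populations, shape (9, ny, nx)
    ux: np.ndarray
    uy: np.ndarray
    rho: np.ndarray
    step: int = 0


def _dx(a: np.ndarray) -> np.ndarray:
    return 0.5 * (np.roll(a, -1, axis=1) - np.roll(a, 1, axis=1))


def _dy(a: np.ndarray) -> np.ndarray:
    return 0.5 * (np.roll(a, -1, axis=0) - np.roll(a, 1, axis=0))


def _lap(a: np.ndarray) -> np.ndarray:
    return (np.roll(a, 1, 0) + np.roll(a, -1, 0) + np.roll(a, 1, 1)
            + np.roll(a, -1, 1) - 4.0 * a)


def _upwind_adv(ux: np.ndarray, uy: np.ndarray, a: np.ndarray) -> np.ndarray:
    """First-order upwind u . grad(a); the explicit Euler update is unstable
    with centred advection at the low molecular diffusivities used here."""
    dxm = a - np.roll(a, 1, 1)   # backward differences
    dxp = np.roll(a, -1, 1) - a  # forward differences
    dym = a - np.roll(a, 1, 0)
    dyp = np.roll(a, -1, 0) - a
    return (np.maximum(ux, 0.0) * dxm + np.minimum(ux, 0.0) * dxp
            + np.maximum(uy, 0.0) * dym + np.minimum(uy, 0.0) * dyp)


def _feq(rho: np.ndarray, ux: np.ndarray, uy: np.ndarray) -> np.ndarray:
    cu = _CX[:, None, None] * ux[None] + _CY[:, None, None] * uy[None]
    usq = ux**2 + uy**2
    return _W[:, None, None] * rho[None] * (1.0 + 3.0 * cu + 4.5 * cu**2 - 1.5 * usq[None])


def init_nematic(params: SimulationParams, mode: str = "random",
                 amplitude: float = 0.01,
                 uniform_Q: tuple[float, float] = (0.0, 0.0)) -> NematicState:
    """Initial state: small random traceless Q (or a uniform Q plus noise),
    zero flow, populations at equilibrium.

    The random perturbation is smoothed at the scale of the active length
    so that the initial elastic stresses are small: orientation structure
    below the coherence length is unphysical and would kick the flow solver
    with O(K) forces on the first steps.
    """
    from scipy.ndimage import gaussian_filter

    ny, nx = params.lattice
    rng = np.random.default_rng(params.seed)

    def noise() -> np.ndarray:
        raw = rng.standard_normal((ny, nx))
        sigma = max(params.active_length / 2.0, 1.0) if params.zeta else 2.0
        sm = gaussian_filter(raw, sigma=sigma, mode="wrap")
        sm /= max(np.abs(sm).max(), 1e-300)
        return amplitude * sm

    if mode == "random":
        Qxx = noise()
        Qxy = noise()
    elif mode == "uniform+noise":
        Qxx = uniform_Q[0] + (noise() if amplitude else 0.0)
        Qxy = uniform_Q[1] + (noise() if amplitude else 0.0)
    else:
        raise ValueError("mode must be 'random' or 'uniform+noise'")
    Qxx = np.asarray(Qxx, dtype=float) * np.ones((ny, nx))
    Qxy = np.asarray(Qxy, dtype=float) * np.ones((ny, nx))
    rho = np.ones((ny, nx))
    zero = np.zeros((ny, nx))
    f = _feq(rho, zero, zero)
    return NematicState(Qxx=Qxx, Qxy=Qxy, f=f, ux=zero.copy(), uy=zero.copy(), rho=rho)


def elastic_free_energy(state: NematicState, params: SimulationParams) -> float:
    """Total distortion free energy K * (d_k Q_ij)^2 summed over the lattice."""
    g = ((_dx(state.Qxx))**2 + (_dy(state.Qxx))**2
         + (_dx(state.Qxy))**2 + (_dy(state.Qxy))**2)
    return float(params.K * 2.0 * g.sum())


def _body_force(Qxx: np.ndarray, Qxy: np.ndarray, params: SimulationParams
                ) -> tuple[np.ndarray, np.ndarray]:
    """Divergence of the elastic plus active stress (pressure and viscous
    parts are carried by the kinetic solver itself)."""
    K, lam, zeta = params.K, params.lambda_align, params.zeta
    Hxx = 2.0 * K * _lap(Qxx)
    Hxy = 2.0 * K * _lap(Qxy)
    QH2 = Qxx * Hxx + Qxy * Hxy  # = Tr(Q H)/2
    dxQxx, dyQxx = _dx(Qxx), _dy(Qxx)
    dxQxy, dyQxy = _dx(Qxy), _dy(Qxy)
    Gxx = 2.0 * (dxQxx**2 + dxQxy**2)
    Gxy = 2.0 * (dxQxx * dyQxx + dxQxy * dyQxy)
    Gyy = 2.0 * (dyQxx**2 + dyQxy**2)
    anti = 2.0 * (Qxx * Hxy - Qxy * Hxx)  # (QH - HQ)_xy
    Pxx = 4.0 * lam * QH2 * (Qxx + 0.5) - lam * (2.0 * QH2 + Hxx) - 2.0 * K * Gxx - zeta * Qxx
    Pyy = 4.0 * lam * QH2 * (0.5 - Qxx) - lam * (2.0 * QH2 - Hxx) - 2.0 * K * Gyy + zeta * Qxx
    Psym = 4.0 * lam * QH2 * Qxy - lam * Hxy - 2.0 * K * Gxy - zeta * Qxy
    Pxy = Psym + anti
    Pyx = Psym - anti
    Fx = _dx(Pxx) + _dy(Pxy)
    Fy = _dx(Pyx) + _dy(Pyy)
    if params.force_cutoff:
        # spectral low-pass: the centred stencils of the stress divergence
        # and of the velocity gradients disagree at sub-lattice scales, and
        # unfiltered high-k forcing closes an anti-dissipative feedback
        # loop through the flow-alignment coupling
        ny, nx = Fx.shape
        ky = np.fft.fftfreq(ny)[:, None]  # in cycles per node; Nyquist 0.5
        kx = np.fft.rfftfreq(nx)[None, :]
        keep = (ky**2 + kx**2) <= (0.5 * params.force_cutoff) ** 2
        Fx = np.fft.irfft2(np.fft.rfft2(Fx) * keep, s=Fx.shape)
        Fy = np.fft.irfft2(np.fft.rfft2(Fy) * keep, s=Fy.shape)
    cap = params.force_cap
    mag = np.sqrt(Fx**2 + Fy**2)
    over = mag > cap
    if over.any():
        s = np.where(over, cap / np.maximum(mag, 1e-300), 1.0)
        Fx, Fy = Fx * s, Fy * s
    return Fx, Fy


def step_active_nematic(state: NematicState, params: SimulationParams) -> NematicState:
    """One coupled update (in place) of order parameter and flow.

    (i) Q advances by an explicit finite-difference Euler step of the
    Beris-Edwards equation with the full co-rotational term and molecular
    field H = 2K lap(Q); (ii) the flow advances by one forced D2Q9 BGK step
    with Guo forcing from the divergence of the elastic + active stress.
    Tracelessness and symmetry of Q are exact because only (Q_xx, Q_xy) are
    stored.
    """
    Qxx, Qxy, f = state.Qxx, state.Qxy, state.f
    lam, Gamma = params.lambda_align, params.Gamma

    Fx, Fy = _body_force(Qxx, Qxy, params)

    rho = f.sum(axis=0)
    ux = (np.einsum("i,ijk->jk", _CX.astype(float), f) + 0.5 * Fx) / rho
    uy = (np.einsum("i,ijk->jk", _CY.astype(float), f) + 0.5 * Fy) / rho

    # --- order parameter update -------------------------------------------
    dxux, dyux = _dx(ux), _dy(ux)
    dxuy, dyuy = _dx(uy), _dy(uy)
    Exx, Eyy = dxux, dyuy
    Exy = 0.5 * (dxuy + dyux)
    Oxy = 0.5 * (dxuy - dyux)  # Omega_xy; Omega_xx = 0
    # A = lam*E + Omega, B = lam*E - Omega (fixed over the sub-steps)
    Axx, Axy, Ayx, Ayy = lam * Exx, lam * Exy + Oxy, lam * Exy - Oxy, lam * Eyy
    Bxx, Bxy, Byx, Byy = lam * Exx, lam * Exy - Oxy, lam * Exy + Oxy, lam * Eyy
    trdu = Qxx * (dxux - dyuy) + Qxy * (dxuy + dyux)  # recomputed below

    n_sub = params.q_substeps
    dt = 1.0 / n_sub
    Qxx_new, Qxy_new = Qxx, Qxy
    for _ in range(n_sub):
        Mxx, Mxy, Myy = Qxx_new + 0.5, Qxy_new, 0.5 - Qxx_new
        AMxx = Axx * Mxx + Axy * Mxy
        AMxy = Axx * Mxy + Axy * Myy
        AMyx = Ayx * Mxx + Ayy * Mxy
        AMyy = Ayx * Mxy + Ayy * Myy
        MBxx = Mxx * Bxx + Mxy * Byx
        MBxy = Mxx * Bxy + Mxy * Byy
        MByx = Mxy * Bxx + Myy * Byx
        MByy = Mxy * Bxy + Myy * Byy
        trQdu = Qxx_new * (dxux - dyuy) + Qxy_new * (dxuy + dyux)
        Sxx = AMxx + MBxx - 2.0 * lam * Mxx * trQdu
        Sxy = AMxy + MBxy - 2.0 * lam * Mxy * trQdu
        Syx = AMyx + MByx - 2.0 * lam * Mxy * trQdu
        Syy = AMyy + MByy - 2.0 * lam * Myy * trQdu
        # traceless symmetric part (Q update preserves Tr Q = 0 exactly)
        Sxx_t = 0.5 * (Sxx - Syy)
        Sxy_t = 0.5 * (Sxy + Syx)
        Hxx = 2.0 * params.K * _lap(Qxx_new)
        Hxy = 2.0 * params.K * _lap(Qxy_new)
        adv_xx = _upwind_adv(ux, uy, Qxx_new)
        adv_xy = _upwind_adv(ux, uy, Qxy_new)
        Qxx_new = Qxx_new + dt * (-adv_xx + Sxx_t + Gamma * Hxx)
        Qxy_new = Qxy_new + dt * (-adv_xy + Sxy_t + Gamma * Hxy)
    # biharmonic grid filter: the centred force/gradient stencils are blind
    # to the chequerboard mode, which the stress-flow feedback would
    # otherwise pump; damping ~ eps*k^4 removes it while leaving structures
    # at the active length nearly untouched
    eps = params.grid_filter
    if eps:
        Qxx_new = Qxx_new - eps * _lap(_lap(Qxx_new))
        Qxy_new = Qxy_new - eps * _lap(_lap(Qxy_new))
    if params.S_max:
        S = 2.0 * np.sqrt(Qxx_new**2 + Qxy_new**2)
        over = S > params.S_max
        if over.any():
            shrink = np.where(over, params.S_max / np.maximum(S, 1e-300), 1.0)
            Qxx_new = Qxx_new * shrink
            Qxy_new = Qxy_new * shrink

    # --- kinetic flow update ----------------------------------------------
    tau = params.tau
    feq = _feq(rho, ux, uy)
    cu = _CX[:, None, None] * ux[None] + _CY[:, None, None] * uy[None]
    guo = (1.0 - 0.5 / tau) * _W[:, None, None] * (
        3.0 * ((_CX[:, None, None] - ux[None]) * Fx[None]
               + (_CY[:, None, None] - uy[None]) * Fy[None])
        + 9.0 * cu * (_CX[:, None, None] * Fx[None] + _CY[:, None, None] * Fy[None])
    )
    f = f - (f - feq) / tau + guo
    for i in range(9):
        f[i] = np.roll(f[i], (int(_CY[i]), int(_CX[i])), axis=(0, 1))
    if not np.isfinite(f).all() or not np.isfinite(Qxx_new).all():
        raise ArithmeticError(
            f"solver divergence at step {state.step}: max|Q| = "
            f"{np.nanmax(np.abs(Qxx_new)):.3g}")

    state.Qxx, state.Qxy, state.f = Qxx_new, Qxy_new, f
    state.ux, state.uy, state.rho = ux, uy, rho
    state.step += 1
    return state


def run_simulation(params: SimulationParams, warmup: Optional[int] = None,
                   init_mode: str = "random") -> list[VelocityField]:
    """Warm up past the transient, then emit velocity snapshots.

    With ``warmup=None`` the transient is detected from the RMS velocity:
    the flow is considered statistically stationary once the RMS changes by
    < 2% across consecutive 200-step windows three times in a row, after
    which the same duration again is discarded as safety margin (capped at
    20000 steps). Snapshots are then taken every ``snapshot_interval`` steps
    for ``n_steps`` steps.
    """
    state = init_nematic(params, mode=init_mode)
    if warmup is None:
        calm = 0
        prev = None
        spent = 0
        while calm < 3 and spent < 20000:
            for _ in range(200):
                step_active_nematic(state, params)
            spent += 200
            rms = float(np.sqrt(np.mean(state.ux**2 + state.uy**2)))
            if prev is not None and prev > 0 and abs(rms - prev) / prev < 0.02:
                calm += 1
            else:
                calm = 0
            prev = rms
        margin = min(spent, 20000 - spent)
        for _ in range(max(margin, 0)):
            step_active_nematic(state, params)
    else:
        for _ in range(warmup):
            step_active_nematic(state, params)

    snaps: list[VelocityField] = []
    for k in range(params.n_steps):
        step_active_nematic(state, params)
        if (k + 1) % params.snapshot_interval == 0:
            snaps.append(VelocityField(u_x=state.ux.copy(), u_y=state.uy.copy(),
                                       spacing=1.0))
    return snaps
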