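"""Expected joint SFS under two-population divergence models A/B/C.

The density phi(x, y, t) of derived-allele frequencies in the (wild,
cultivated) frequency square evolves under the Wright-Fisher diffusion

    dphi/dt = sum_axes [ -d/dx ( M(x) phi ) + 1/2 d^2/dx^2 ( V(x) phi ) ],

with time in units of 2*N_ref generations, V(x) = x(1-x)/nu and migration
drift M(x) = m_in * (x_other - x), m scaled by 2*N_ref.  New mutations enter
at low frequency at rate theta0/2 per axis.  The three divergence models
share one integration kernel:

* Model A — split at scaled time T in the past; the wild lineage takes size
  nu_wild_current at the split, the cultivated lineage is founded at
  nu_cult_founder and changes exponentially to nu_cult_current; no gene flow.
* Model B — Model A plus symmetric migration m_sym in both directions.
* Model C — Model A plus independent directional rates m_w_to_c, m_c_to_w.

Spatial discretization is a conservative finite-volume scheme on a grid
crowded near the absorbing boundaries, with Chang-Cooper interface weighting
for the advective flux; each time step is an alternating-direction implicit
(ADI) sweep.  Spectra are computed on several grid sizes and extrapolated
cell-wise (quadratic in the boundary grid spacing) to the infinite-grid
limit, so leading discretization errors cancel.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import gammaln

DEFAULT_GRIDS = (40, 50, 60)
DEFAULT_DT_FAC = 5e-3


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------
@dataclass
class DemographicParams:
    """Dimensionless parameters of one divergence model.

    Sizes are relative to the ancestral reference N_ref; T is the scaled
    divergence time (units of 2*N_ref generations); migration rates are
    population-scaled (2*N_ref per generation, receiving-population
    convention).  theta = 4*N_ref*mu*L multiplies the expected spectrum.
    """

    model: str
    nu_wild_current: float
    nu_cult_founder: float
    nu_cult_current: float
    T: float
    m_sym: float = 0.0
    m_w_to_c: float = 0.0
    m_c_to_w: float = 0.0
    theta: float = 1.0

    def __post_init__(self):
        if self.model not in ("A", "B", "C"):
            raise ValueError("model must be 'A', 'B' or 'C'")
        for name in ("nu_wild_current", "nu_cult_founder", "nu_cult_current"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.T < 0:
            raise ValueError("T must be non-negative")
        if min(self.m_sym, self.m_w_to_c, self.m_c_to_w) < 0:
            raise ValueError("migration rates must be non-negative")
        if self.model == "A" and (self.m_sym or self.m_w_to_c or self.m_c_to_w):
            raise ValueError("model A has no migration parameters")
        if self.model == "B" and (self.m_w_to_c or self.m_c_to_w):
            raise ValueError("model B uses m_sym only")
        if self.model == "C" and self.m_sym:
            raise ValueError("model C uses directional rates only")

    @property
    def migration_into_wild(self) -> float:
        return self.m_sym if self.model == "B" else self.m_c_to_w

    @property
    def migration_into_cult(self) -> float:
        return self.m_sym if self.model == "B" else self.m_w_to_c

    # -- free-parameter vector interface (optimizer order) -----------------
    @staticmethod
    def free_param_names(model: str):
        base = ["nu_wild_current", "nu_cult_founder", "nu_cult_current", "T"]
        if model == "A":
            return base
        if model == "B":
            return base + ["m_sym"]
        return base + ["m_w_to_c", "m_c_to_w"]

    @classmethod
    def from_vector(cls, model: str, vec, theta: float = 1.0):
        names = cls.free_param_names(model)
        if len(vec) != len(names):
            raise ValueError(f"model {model} expects {len(names)} parameters")
        return cls(model=model, theta=theta, **dict(zip(names, map(float, vec))))

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n)
                         for n in self.free_param_names(self.model)])

    @property
    def k(self) -> int:
        """Free demographic parameter count (theta excluded)."""
        return len(self.free_param_names(self.model))


@dataclass
class DiffusionState:
    """Frequency grid, density and elapsed scaled time."""

    grid: np.ndarray
    phi: np.ndarray
    time: float = 0.0


def cult_size_trajectory(params: DemographicParams, tau: float) -> float:
    """Relative cultivated size at scaled time tau since the split.

    Exponential interpolation between the founding and current sizes;
    endpoints exact.  Degenerate T = 0 returns the current size.
    """
    if not 0 <= tau <= max(params.T, 0):
        raise ValueError("tau must lie in [0, T]")
    if params.T == 0:
        return params.nu_cult_current
    nf, nc = params.nu_cult_founder, params.nu_cult_current
    return nf * (nc / nf) ** (tau / params.T)


# ---------------------------------------------------------------------------
# grid, equilibrium, sampling
# ---------------------------------------------------------------------------
def make_grid(pts: int, crwd: float = 8.0) -> np.ndarray:
    """Frequency grid on [0, 1], logistically crowded near both boundaries."""
    if pts < 3:
        raise ValueError("grid needs at least 3 points")
    unif = np.linspace(0.0, 1.0, pts)
    grid = 1.0 / (1.0 + np.exp(-crwd * (unif - 0.5)))
    return (grid - grid[0]) / (grid[-1] - grid[0])


def equilibrium_phi_1d(grid: np.ndarray, theta0: float = 1.0) -> DiffusionState:
    """Stationary neutral density of an equilibrium population (nu = 1).

    phi(x) = theta0/x solves the neutral diffusion with mutational influx
    theta0/2; its sampled spectrum is E[xi_i] = theta0/i.  The x = 0 entry is
    a finite placeholder (the sampling weights vanish there).
    """
    phi = np.empty_like(grid)
    phi[1:] = theta0 / grid[1:]
    phi[0] = phi[1]
    return DiffusionState(grid=grid, phi=phi, time=0.0)


def phi_1d_to_2d(grid: np.ndarray, phi1: np.ndarray) -> np.ndarray:
    """Place a 1D density on the diagonal of the 2D frequency square.

    The split is instantaneous: immediately afterwards both daughter
    populations share the ancestral allele frequency, i.e. phi2(x, y) =
    phi1(x) * delta(x - y), discretized with the local diagonal measure.
    """
    L = len(grid)
    phi2 = np.zeros((L, L))
    for i in range(L):
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, L - 1)]
        phi2[i, i] = phi1[i] * 2.0 / (hi - lo)
    return phi2


def _trapz_weights(grid: np.ndarray) -> np.ndarray:
    w = np.zeros_like(grid)
    dx = np.diff(grid)
    w[:-1] += dx / 2
    w[1:] += dx / 2
    return w


def _binom_weights(n: int, grid: np.ndarray) -> np.ndarray:
    """Matrix B[i, j] = C(n, i) x_j^i (1 - x_j)^(n - i)."""
    i = np.arange(n + 1)[:, None]
    x = grid[None, :]
    logc = (gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        logw = logc + i * np.log(x) + (n - i) * np.log1p(-x)
    w = np.exp(logw)
    # 0^0 = 1 at the boundary columns
    w[:, 0] = 0.0
    w[0, 0] = 1.0
    w[:, -1] = 0.0
    w[-1, -1] = 1.0
    return w


def sample_phi_1d(grid, phi, n: int) -> np.ndarray:
    """Expected 1D SFS (classes 0..n) by binomial sampling of the density."""
    return _binom_weights(n, grid) @ (_trapz_weights(grid) * phi)


def sample_phi_2d(grid, phi2, n1: int, n2: int) -> np.ndarray:
    w = _trapz_weights(grid)
    b1 = _binom_weights(n1, grid) * w[None, :]
    b2 = _binom_weights(n2, grid) * w[None, :]
    return b1 @ phi2 @ b2.T


def extrapolate_to_zero(values, xs) -> np.ndarray:
    """Lagrange-polynomial extrapolation of grid results to spacing 0.

    ``values`` are arrays computed at grid-spacing parameters ``xs`` (the
    first interior grid point of each grid); with three grids this is the
    quadratic (Richardson-style) limit.
    """
    xs = np.asarray(xs, dtype=float)
    if len(values) != len(xs) or len(xs) < 2:
        raise ValueError("need matching values/xs with at least two grids")
    out = np.zeros_like(np.asarray(values[0], dtype=float))
    for i, v in enumerate(values):
        li = 1.0
        for j in range(len(xs)):
            if j != i:
                li *= (0.0 - xs[j]) / (xs[i] - xs[j])
        out = out + li * np.asarray(v, dtype=float)
    return out


# ---------------------------------------------------------------------------
# numba integration kernel
# ---------------------------------------------------------------------------
@njit(cache=True)
def _interface_coeffs(grid, nu, m, other_axis_vals):
    """Per-interface flux coefficients A, B for one sweep direction.

    Flux at interface k (between nodes k, k+1) for the row with the other
    axis at value y: J_k = A[r, k] * phi_k + B[r, k] * phi_{k+1}; r indexes
    rows (values of the other axis).  The advective term is weighted by an
    exponential-fitting (Chang-Cooper style) factor delta that tends to 1/2
    where diffusion dominates and to full upwinding where drift dominates,
    keeping the implicit scheme stable and positivity-preserving at strong
    migration; the boundary cells (V = 0) trap absorbed density, which
    represents sites fixed or lost on that axis and keeps evolving on the
    other axis.
    """
    L = grid.shape[0]
    R = other_axis_vals.shape[0]
    A = np.empty((R, L - 1))
    B = np.empty((R, L - 1))
    V = grid * (1.0 - grid) / nu
    for r in range(R):
        y = other_axis_vals[r]
        for k in range(L - 1):
            dx = grid[k + 1] - grid[k]
            xm = 0.5 * (grid[k] + grid[k + 1])
            M = m * (y - xm)
            if k == 0:
                # Boundary cells trap absorbed density (V = 0 there).  The
                # trap stands in for the integrable y^(beta-1) boundary layer
                # of the continuum solution (beta = 2*M(0)*nu): its exchange
                # with the first interior node is calibrated so the zero-flux
                # layer profile is a discrete equilibrium.  Drift toward the
                # boundary makes the trap a pure (upwinded) absorber.
                m0 = m * y  # drift at the boundary node x = 0
                if m0 > 0.0:
                    A[r, k] = 0.5 * m0
                    B[r, k] = -0.5 * V[k + 1] / dx
                else:
                    A[r, k] = 0.0
                    B[r, k] = M - 0.5 * V[k + 1] / dx
            elif k == L - 2:
                m1 = m * (y - 1.0)  # drift at the boundary node x = 1
                if m1 < 0.0:
                    A[r, k] = 0.5 * V[k] / dx
                    B[r, k] = 0.5 * m1
                else:
                    A[r, k] = M + 0.5 * V[k] / dx
                    B[r, k] = 0.0
            else:
                vint = 0.5 * (V[k] + V[k + 1])
                if M == 0.0 or vint <= 0.0:
                    delta = 0.5
                else:
                    z = 2.0 * M * dx / vint
                    if z > 40.0:
                        delta = 1.0 - 1.0 / z
                    elif z < -40.0:
                        delta = -1.0 / z
                    else:
                        delta = 1.0 / (-np.expm1(-z)) - 1.0 / z
                A[r, k] = M * delta + 0.5 * V[k] / dx
                B[r, k] = M * (1.0 - delta) - 0.5 * V[k + 1] / dx
    return A, B


@njit(cache=True)
def _factorize(A, B, winv, dt):
    """Thomas factorization of (I + dt*Op) for every row.

    Returns (low, dinv, cp): per-row lower coefficients, inverse pivots and
    normalized upper coefficients, so each step reduces to forward/backward
    substitution.
    """
    R = A.shape[0]
    L = A.shape[1] + 1
    low = np.empty((R, L))
    dinv = np.empty((R, L))
    cp = np.empty((R, L))
    for r in range(R):
        for i in range(L):
            fac = dt * winv[i]
            diag = 1.0
            lo = 0.0
            up = 0.0
            if i < L - 1:
                diag += fac * A[r, i]
                up = fac * B[r, i]
            if i > 0:
                diag -= fac * B[r, i - 1]
                lo = -fac * A[r, i - 1]
            if i == 0:
                piv = diag
            else:
                piv = diag - lo * cp[r, i - 1]
            dinv[r, i] = 1.0 / piv
            cp[r, i] = up * dinv[r, i]
            low[r, i] = lo
    return low, dinv, cp


@njit(cache=True)
def _solve_batch(phi, low_t, dinv_t, cp_t, work):
    """In-place pre-factorized tridiagonal solves, vectorized across systems.

    ``phi`` has shape (L_along, n_batch) with the tridiagonal direction on
    axis 0; coefficient arrays share that layout (transposed relative to
    :func:`_factorize` output), so the inner loops run over the contiguous
    batch axis and SIMD-vectorize.
    """
    L, R = phi.shape
    for r in range(R):
        work[0, r] = phi[0, r] * dinv_t[0, r]
    for i in range(1, L):
        for r in range(R):
            work[i, r] = (phi[i, r] - low_t[i, r] * work[i - 1, r]) \
                * dinv_t[i, r]
    for r in range(R):
        phi[L - 1, r] = work[L - 1, r]
    for i in range(L - 2, -1, -1):
        for r in range(R):
            phi[i, r] = work[i, r] - cp_t[i, r] * phi[i + 1, r]


@njit(cache=True)
def _integrate_two_pop(phi, grid, T, nu1, nu2_start, nu2_end, m12, m21,
                       theta0, dt_fac):
    """Integrate the 2D diffusion from the split to time T (in place).

    Axis 0 is population 1 (constant size nu1), axis 1 population 2 whose
    size moves exponentially from nu2_start to nu2_end.  m12 is migration
    into population 1 from 2; m21 the reverse.  The exponential cultivated
    trajectory is quantized into piecewise-constant epochs so that every
    implicit sweep uses a pre-factorized tridiagonal solve.
    """
    L = grid.shape[0]
    w = np.empty(L)
    w[0] = 0.5 * (grid[1] - grid[0])
    w[L - 1] = 0.5 * (grid[L - 1] - grid[L - 2])
    for i in range(1, L - 1):
        w[i] = 0.5 * (grid[i + 1] - grid[i - 1])
    winv = 1.0 / w

    if T <= 0.0:
        return phi
    nu2_min = min(nu2_start, nu2_end)
    max_vm = max(0.25 / nu1, 0.25 / nu2_min)
    max_vm = max(max_vm, m12 + m21)
    # Step counts are rounded up to a geometric ladder: within a rung the
    # count is constant, so the likelihood is a smooth function of the
    # parameters there (integer step-count jumps otherwise put small cliffs
    # on the surface that stall simplex optimizers).  The cap bounds runtime
    # at extreme parameter corners (tiny nu with long T); the implicit
    # scheme stays stable, only accuracy there degrades.
    ideal = T * max_vm / dt_fac
    n_steps = 12
    while n_steps < ideal and n_steps < 1200:
        n_steps = min(2 * n_steps, 1200)
    dt = T / n_steps

    # x-operator is time-constant (nu1, m12 fixed): factorize once; the
    # solver wants the along-axis first, so coefficients are transposed
    A1, B1 = _interface_coeffs(grid, nu1, m12, grid)
    l1, d1, c1 = _factorize(A1, B1, winv, dt)
    lo1, di1, cp1 = l1.T.copy(), d1.T.copy(), c1.T.copy()

    # quantize the nu2 trajectory into epochs, factorize per epoch
    n_epochs = min(48, n_steps)
    growth = np.log(nu2_end / nu2_start)
    lo2 = np.empty((n_epochs, L, L))
    di2 = np.empty((n_epochs, L, L))
    cp2 = np.empty((n_epochs, L, L))
    for e in range(n_epochs):
        tau_mid = (e + 0.5) / n_epochs
        nu2 = nu2_start * np.exp(growth * tau_mid)
        A2, B2 = _interface_coeffs(grid, nu2, m21, grid)
        l2, d2, c2 = _factorize(A2, B2, winv, dt)
        lo2[e], di2[e], cp2[e] = l2.T.copy(), d2.T.copy(), c2.T.copy()

    inj1 = 0.5 * theta0 / grid[1] * 4.0 / ((grid[2] - grid[0]) * grid[1])
    inj2 = inj1  # same grid on both axes

    phit = np.empty((L, L))
    work = np.empty((L, L))
    for s in range(n_steps):
        # mutation influx at low frequency on each axis
        phi[1, 0] += dt * inj1
        phi[0, 1] += dt * inj2
        # implicit x-sweep: tridiagonal along axis 0, batched over y
        _solve_batch(phi, lo1, di1, cp1, work)
        # implicit y-sweep on the transpose with the epoch's cultivated size
        for i in range(L):
            for j in range(L):
                phit[j, i] = phi[i, j]
        e = min(s * n_epochs // n_steps, n_epochs - 1)
        _solve_batch(phit, lo2[e], di2[e], cp2[e], work)
        for i in range(L):
            for j in range(L):
                phi[i, j] = phit[j, i]
    return phi


# ---------------------------------------------------------------------------
# public model surface
# ---------------------------------------------------------------------------
def _raw_model_sfs(params: DemographicParams, sample_sizes, pts: int,
                   dt_fac: float) -> np.ndarray:
    """Expected (theta0 = 1) joint SFS on a single grid size."""
    grid = make_grid(pts)
    phi1 = equilibrium_phi_1d(grid).phi
    phi = phi_1d_to_2d(grid, phi1)
    _integrate_two_pop(
        phi, grid, params.T,
        params.nu_wild_current,
        params.nu_cult_founder, params.nu_cult_current,
        params.migration_into_wild, params.migration_into_cult,
        1.0, dt_fac,
    )
    n1, n2 = sample_sizes
    return sample_phi_2d(grid, phi, n1, n2)


def expected_sfs(params: DemographicParams, sample_sizes,
                 grids=DEFAULT_GRIDS, dt_fac=DEFAULT_DT_FAC):
    """Expected unfolded joint SFS, extrapolated to the infinite-grid limit.

    Returns a :class:`helipop.sfs.JointSFS` whose unmasked entries are the
    expected site counts (scaled by ``params.theta``); small negative
    extrapolation artifacts are clipped to zero.  ``grids`` must contain at
    least two point counts, all larger than both sample sizes.
    """
    from .sfs import JointSFS

    n1, n2 = sample_sizes
    if n1 < 2 or n2 < 2:
        raise ValueError("sample sizes must be at least 2 haplotypes")
    if len(grids) < 2:
        raise ValueError("need at least two grid sizes for extrapolation")
    if min(grids) <= max(n1, n2):
        raise ValueError("grid sizes should exceed the sample sizes")
    results, spacings = [], []
    for pts in grids:
        results.append(_raw_model_sfs(params, sample_sizes, pts, dt_fac))
        spacings.append(make_grid(pts)[1])
    out = extrapolate_to_zero(results, spacings)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("diffusion integration did not converge; "
                                 "non-finite expected SFS entries")
    np.clip(out, 0.0, None, out=out)
    return JointSFS(params.theta * out, pop_ids=("wild", "cultivated"))


def expected_sfs_1d_equilibrium(n: int, theta: float = 1.0,
                                grids=DEFAULT_GRIDS) -> np.ndarray:
    """Extrapolated 1D equilibrium spectrum; analytic value is theta/i."""
    results, spacings = [], []
    for pts in grids:
        grid = make_grid(pts)
        results.append(sample_phi_1d(grid, equilibrium_phi_1d(grid).phi, n))
        spacings.append(grid[1])
    return theta * extrapolate_to_zero(results, spacings)
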