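"""Discretized reaction–diffusion model of CXCL13.

The chemokine is secreted at stromal-cell positions, diffuses on a regular
3D lattice, decays first-order, and can reversibly bind extracellular-matrix
components (an immobilized pool that does not diffuse). Two canonical
parameterizations are provided: model 1 (low diffusivity / fast decay —
short, sharp immobilized gradients around secreting cells) and model 2
(high diffusivity / slow decay — a nearly homogeneous soluble field), with
secretion scaled so both steady states carry the same total chemokine mass.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve

from .network import ReticularNetwork


class StabilityError(ValueError):
    """Raised when the requested time step violates the explicit-scheme bound."""

    def __init__(self, dt: float, dt_max: float):
        super().__init__(
            f"dt={dt:g}s unstable for explicit update; use dt <= {dt_max:g}s"
        )
        self.suggested_dt = dt_max


class ConvergenceError(RuntimeError):
    """Raised when steady state is not reached within max_t."""


@dataclass
class FieldParams:
    """Reaction–diffusion rates. All nonnegative.

    D: soluble diffusion coefficient, µm²·s⁻¹. lam: first-order decay, s⁻¹.
    k_on_ecm / k_off_ecm: reversible ECM immobilization rates, s⁻¹.
    secretion_fdc / secretion_rc: per-node secretion, concentration·s⁻¹.
    lam_immobilized: decay of the bound pool (defaults to lam).
    """

    D: float = 1.0
    lam: float = 1e-3
    k_on_ecm: float = 0.0
    k_off_ecm: float = 0.0
    secretion_fdc: float = 1.0
    secretion_rc: float = 0.5
    lam_immobilized: float | None = None

    def __post_init__(self) -> None:
        for name in ("D", "lam", "k_on_ecm", "k_off_ecm",
                     "secretion_fdc", "secretion_rc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def lam_i(self) -> float:
        return self.lam if self.lam_immobilized is None else self.lam_immobilized


@dataclass
class ChemokineGrid:
    """Lattice fields: soluble + immobilized concentration and secretion source."""

    spacing: float  # µm
    shape: tuple[int, int, int]
    params: FieldParams = field(default_factory=FieldParams)
    boundary: str = "reflective"
    soluble: np.ndarray | None = None
    immobilized: np.ndarray | None = None
    source: np.ndarray | None = None
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.boundary not in ("reflective", "absorbing"):
            raise ValueError("boundary must be 'reflective' or 'absorbing'")
        self.shape = tuple(int(s) for s in self.shape)
        for name in ("soluble", "immobilized", "source"):
            arr = getattr(self, name)
            if arr is None:
                arr = np.zeros(self.shape)
            arr = np.asarray(arr, float)
            if arr.shape != self.shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {self.shape}")
            if (arr < 0).any():
                raise ValueError(f"{name} has negative values")
            setattr(self, name, arr)

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def total_mass(self) -> float:
        """Total chemokine amount (soluble + immobilized) · voxel volume."""
        return float((self.soluble.sum() + self.immobilized.sum()) * self.voxel_volume)

    def copy(self) -> "ChemokineGrid":
        return ChemokineGrid(
            spacing=self.spacing,
            shape=self.shape,
            params=self.params,
            boundary=self.boundary,
            soluble=self.soluble.copy(),
            immobilized=self.immobilized.copy(),
            source=self.source.copy(),
            origin=self.origin,
        )

    def max_stable_dt(self) -> float:
        """Largest dt keeping the explicit update positive and stable."""
        p = self.params
        rate = 6 * p.D / self.spacing**2 + p.lam + p.k_on_ecm
        rate = max(rate, p.k_off_ecm + p.lam_i)
        return 1.0 / rate if rate > 0 else np.inf


def make_grid_for_network(
    net: ReticularNetwork,
    spacing: float = 5.0,
    params: FieldParams | None = None,
    boundary: str = "reflective",
) -> ChemokineGrid:
    """Build an empty grid covering the network's bounding box."""
    lo, hi = np.asarray(net.bounds[0]), np.asarray(net.bounds[1])
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    return ChemokineGrid(
        spacing=spacing,
        shape=shape,
        params=params or FieldParams(),
        boundary=boundary,
        origin=tuple(lo),
    )


def rasterize_sources(
    net: ReticularNetwork, grid: ChemokineGrid, rates: str = "params"
) -> ChemokineGrid:
    """Deposit each node's secretion rate into its nearest voxel.

    With ``rates="params"`` the subtype-specific rates from
    ``grid.params`` are used; with ``rates="nodes"`` each node's own
    ``secretion_rate`` is deposited. Total deposited rate equals the sum of
    node rates exactly.
    """
    out = grid.copy()
    origin = np.asarray(grid.origin)
    p = grid.params
    rate_of = {"FDC": p.secretion_fdc, "CD21neg_RC": p.secretion_rc}
    src = np.zeros(grid.shape)
    for node in net.nodes:
        idx = np.round((node.position - origin) / grid.spacing).astype(int)
        if (idx < 0).any() or (idx >= np.array(grid.shape)).any():
            raise ValueError(f"node {node.id} at {node.position} outside grid")
        rate = rate_of[node.subtype] if rates == "params" else node.secretion_rate
        src[tuple(idx)] += rate
    out.source = src
    return out


def _neighbor_sum(c: np.ndarray, boundary: str) -> np.ndarray:
    """Sum of the six lattice neighbours with the given boundary condition."""
    mode = "edge" if boundary == "reflective" else "constant"
    p = np.pad(c, 1, mode=mode)
    return (
        p[:-2, 1:-1, 1:-1] + p[2:, 1:-1, 1:-1]
        + p[1:-1, :-2, 1:-1] + p[1:-1, 2:, 1:-1]
        + p[1:-1, 1:-1, :-2] + p[1:-1, 1:-1, 2:]
    )


def step(grid: ChemokineGrid, dt: float) -> ChemokineGrid:
    """One forward-time central-space update of both pools."""
    dt_max = grid.max_stable_dt()
    if dt > dt_max:
        raise StabilityError(dt, dt_max)
    p = grid.params
    s, im = grid.soluble, grid.immobilized
    lap = (_neighbor_sum(s, grid.boundary) - 6 * s) / grid.spacing**2
    s_new = s + dt * (
        p.D * lap + grid.source - (p.lam + p.k_on_ecm) * s + p.k_off_ecm * im
    )
    i_new = im + dt * (p.k_on_ecm * s - (p.k_off_ecm + p.lam_i) * im)
    out = grid.copy()
    out.soluble = np.maximum(s_new, 0.0)
    out.immobilized = np.maximum(i_new, 0.0)
    return out


def run_to_steady_state(
    grid: ChemokineGrid,
    tol: float = 1e-5,
    max_t: float = 1e6,
    dt: float | None = None,
) -> tuple[ChemokineGrid, float]:
    """Time-step until the max relative field change per second drops below tol.

    Returns (converged grid, elapsed simulated time). Requires a sink
    (decay, immobilization with decay, or an absorbing boundary).
    """
    p = grid.params
    if p.lam + p.k_on_ecm <= 0 and grid.boundary != "absorbing":
        raise ValueError("no steady state: need decay/immobilization or absorbing boundary")
    if dt is None:
        dt = 0.9 * grid.max_stable_dt()
    g = grid
    t = 0.0
    while t < max_t:
        g2 = step(g, dt)
        t += dt
        scale = max(g2.soluble.max(), g2.immobilized.max(), 1e-300)
        change = max(
            np.abs(g2.soluble - g.soluble).max(),
            np.abs(g2.immobilized - g.immobilized).max(),
        )
        g = g2
        if change / (scale * dt) < tol:
            return g, t
    raise ConvergenceError(
        f"not converged after {max_t:g}s (residual {change / (scale * dt):.3g}/s)"
    )


def _laplacian_1d(n: int, boundary: str) -> sparse.spmatrix:
    main = -2.0 * np.ones(n)
    off = np.ones(n - 1)
    m = sparse.diags([off, main, off], [-1, 0, 1], format="lil")
    if boundary == "reflective":
        m[0, 0] = -1.0
        m[-1, -1] = -1.0
    return m.tocsr()


def steady_state_direct(grid: ChemokineGrid) -> ChemokineGrid:
    """Solve the linear steady state exactly with a sparse solver.

    Substituting the immobilized-pool balance i = k_on·s/(k_off + lam_i)
    into the soluble equation gives a screened Poisson problem with
    effective decay lam_eff = lam + k_on·lam_i/(k_off + lam_i).
    """
    p = grid.params
    if p.k_off_ecm + p.lam_i > 0:
        ratio = p.k_on_ecm / (p.k_off_ecm + p.lam_i)
    else:
        if p.k_on_ecm > 0:
            raise ValueError("immobilized pool has no sink; no steady state")
        ratio = 0.0
    lam_eff = p.lam + p.k_on_ecm - p.k_off_ecm * ratio
    if lam_eff <= 0 and grid.boundary != "absorbing":
        raise ValueError("no steady state: effective decay must be positive")
    nx_, ny, nz = grid.shape
    h2 = grid.spacing**2
    Ix, Iy, Iz = (sparse.identity(n, format="csr") for n in (nx_, ny, nz))
    lap = (
        sparse.kron(sparse.kron(_laplacian_1d(nx_, grid.boundary), Iy), Iz)
        + sparse.kron(sparse.kron(Ix, _laplacian_1d(ny, grid.boundary)), Iz)
        + sparse.kron(sparse.kron(Ix, Iy), _laplacian_1d(nz, grid.boundary))
    ) / h2
    A = (-p.D * lap + lam_eff * sparse.identity(nx_ * ny * nz, format="csr")).tocsr()
    # the operator is symmetric positive definite: conjugate gradients
    s, info = cg(A, grid.source.ravel(), rtol=1e-12, atol=0.0, maxiter=20000)
    if info != 0:
        s = spsolve(A.tocsc(), grid.source.ravel())
    out = grid.copy()
    out.soluble = np.maximum(s.reshape(grid.shape), 0.0)
    out.immobilized = ratio * out.soluble
    return out


def model_parameterization(
    model_id: int,
    reference_mass: float,
    net: ReticularNetwork | None = None,
    two_pool: bool = False,
    spacing: float = 5.0,
) -> FieldParams:
    """Canonical parameters for the two competing gradient hypotheses.

    Model 1: ECM-constrained chemokine — low diffusivity (0.19 µm²·s⁻¹, the
    measured median in untreated tissue), fast decay giving a ~15 µm
    screening length; with ``two_pool`` an explicit immobilized pool is
    added. Model 2: freely soluble chemokine — high diffusivity
    (1.6 µm²·s⁻¹, the heparinase-treated median), slow decay, screening
    length larger than the follicle, hence a nearly homogeneous field.

    If ``net`` is given, secretion rates are rescaled so the steady-state
    total mass equals ``reference_mass`` (the two models are compared at
    fixed overall chemokine amount).
    """
    if reference_mass <= 0:
        raise ValueError("reference_mass must be > 0")
    if model_id == 1:
        D, screening = 0.19, 15.0  # µm²/s, µm
        lam = D / screening**2
        p = FieldParams(D=D, lam=lam, secretion_fdc=1.0, secretion_rc=0.5)
        if two_pool:
            p = replace(p, k_on_ecm=1e-2, k_off_ecm=1e-3)
    elif model_id == 2:
        D = 1.6
        lam = 5e-5  # screening length ~179 µm, exceeds the follicle radius
        p = FieldParams(D=D, lam=lam, secretion_fdc=1.0, secretion_rc=0.5)
    else:
        raise ValueError("model_id must be 1 or 2")
    if net is not None:
        subtypes = net.subtypes()
        total = (
            p.secretion_fdc * (subtypes == "FDC").sum()
            + p.secretion_rc * (subtypes == "CD21neg_RC").sum()
        )
        # steady total mass (reflective boundary) = secretion · voxel volume / lam
        scale = reference_mass * p.lam / (total * spacing**3)
        p = replace(
            p,
            secretion_fdc=p.secretion_fdc * scale,
            secretion_rc=p.secretion_rc * scale,
        )
    return p
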