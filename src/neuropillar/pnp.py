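"""Exterior Poisson-Nernst-Planck electrodiffusion around a cylindrical axon.

The action potential is frozen into the co-moving frame (xi = z - vt), which
turns the time-dependent, axisymmetric 3D problem into a steady 2D problem on
(r, xi):

    Poisson:           eps*eps0 div(grad V) = -rho = -F (c+ - c-)
    Nernst-Planck:     div( -D_s [grad c_s + z_s (e/kT) c_s grad V] - v c_s e_xi ) = 0

for two effective monovalent species (the physiological cations grouped into
one species, the anions into another).  The axon interior is not meshed: it
enters only through the membrane boundary data derived from the
Hodgkin-Huxley traveling wave — a surface charge density sigma(xi) (Neumann
condition for V, via Gauss' law) and prescribed rest-referenced molar fluxes
for the two species.

Discretization is cell-centered finite volume on a tensor-product mesh that is
geometrically graded in r (sub-Angstrom first cell, resolving the ~0.8 nm
Debye layer) and uniform in xi.  Face fluxes use the Scharfetter-Gummel
exponential scheme, with the frame advection -v folded into the axial drift;
the coupled system is solved by a fully coupled damped Newton iteration (a
segregated Gummel sweep stalls on this geometry; see ``solve_pnp``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    EPS0,
    FARADAY,
    thermal_voltage,
)
from .hh import APWaveform, resting_currents

__all__ = [
    "IonSpecies",
    "EffectiveSpeciesPair",
    "AxonGeometry",
    "MeshSpec",
    "Mesh",
    "MembraneBC",
    "SolverOptions",
    "PNPField",
    "PNPConvergenceError",
    "debye_length",
    "build_mesh",
    "membrane_boundary",
    "solve_pnp",
    "gouy_chapman_potential",
]


def debye_length(ionic_strength: float, eps: float = 80.0, T: float = 310.0) -> float:
    """Debye screening length (m) of a symmetric 1:1 electrolyte.

    ``ionic_strength`` in mol/m^3 (numerically equal to mM).
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be positive")
    return float(
        np.sqrt(
            eps * EPS0 * BOLTZMANN * T
            / (2.0 * ELEMENTARY_CHARGE**2 * AVOGADRO * ionic_strength)
        )
    )


@dataclass(frozen=True)
class IonSpecies:
    """A (possibly effective) ion species."""

    name: str
    z: int
    D: float  # m^2/s
    c_inf: float  # bulk concentration, mol/m^3

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("diffusion constant must be positive")
        if self.c_inf < 0:
            raise ValueError("bulk concentration must be non-negative")


# free-solution diffusion constants, m^2/s
D_NA, D_K, D_CL, D_OA = 1.33e-9, 1.96e-9, 2.03e-9, 0.5e-9


@dataclass(frozen=True)
class EffectiveSpeciesPair:
    """Two effective monovalent species: the grouped cations (Na+, K+) and the
    grouped anions (Cl-, organic anions), each with the mean diffusion
    constant of its constituents and the summed bulk concentration."""

    cation: IonSpecies = IonSpecies("cation(Na,K)", +1, (D_NA + D_K) / 2, 150.0)
    anion: IonSpecies = IonSpecies("anion(Cl,OA)", -1, (D_CL + D_OA) / 2, 150.0)

    def __post_init__(self):
        if self.cation.z != 1 or self.anion.z != -1:
            raise ValueError("effective pair must be monovalent (+1/-1)")
        if not np.isclose(self.cation.c_inf, self.anion.c_inf):
            raise ValueError("bulk electroneutrality requires equal bulk concentrations")

    @property
    def ionic_strength(self) -> float:
        return self.cation.c_inf


@dataclass(frozen=True)
class AxonGeometry:
    """Exterior solution domain: annulus a <= r <= R_max, |xi| <= half_length."""

    a: float = 500e-9
    R_max: float = 3e-6
    half_length: float = 3e-3
    eps: float = 80.0

    def __post_init__(self):
        if self.R_max <= self.a:
            raise ValueError("R_max must exceed the membrane radius")
        if self.eps <= 1:
            raise ValueError("relative permittivity must exceed 1")


@dataclass(frozen=True)
class MeshSpec:
    """Radial grading and node counts.

    If ``growth_ratio`` is None it is solved so that ``n_r`` cells starting at
    ``first_cell`` exactly span the annulus; if given, the first-cell size is
    rescaled to fit (ratio 1.0 means uniform spacing).
    """

    n_r: int = 250
    n_xi: int = 400
    first_cell: float = 1.5e-10
    growth_ratio: float | None = None
    debye: float = field(default_factory=lambda: debye_length(150.0))


@dataclass
class Mesh:
    r_faces: np.ndarray
    xi_faces: np.ndarray

    @property
    def r_centers(self):
        return 0.5 * (self.r_faces[:-1] + self.r_faces[1:])

    @property
    def xi_centers(self):
        return 0.5 * (self.xi_faces[:-1] + self.xi_faces[1:])

    @property
    def n_r(self):
        return len(self.r_faces) - 1

    @property
    def n_xi(self):
        return len(self.xi_faces) - 1

    @property
    def dxi(self):
        return self.xi_faces[1] - self.xi_faces[0]


def _geometric_faces(a, extent, n, h0=None, g=None):
    if g is None:
        # solve (g^n - 1)/(g - 1) = extent/h0 for g >= 1
        target = extent / h0
        if target <= n:
            g = 1.0
            h0 = extent / n
        else:
            from scipy.optimize import brentq

            f = lambda x: (x**n - 1) / (x - 1) - target
            g = brentq(f, 1.0 + 1e-12, 10.0)
    else:
        h0 = extent / n if g == 1.0 else extent * (g - 1) / (g**n - 1)
    steps = h0 * g ** np.arange(n)
    faces = a + np.concatenate(([0.0], np.cumsum(steps)))
    faces[-1] = a + extent
    return faces, h0, g


def build_mesh(geom: AxonGeometry, grading: MeshSpec = MeshSpec()) -> Mesh:
    """Geometrically graded radial nodes, uniform axial nodes.

    Refuses meshes whose first radial cell exceeds half the Debye length
    (the double layer would be unresolved).
    """
    extent = geom.R_max - geom.a
    faces, h0, g = _geometric_faces(
        geom.a, extent, grading.n_r, grading.first_cell, grading.growth_ratio
    )
    if h0 > grading.debye / 2:
        raise ValueError(
            f"first radial cell ({h0:.2e} m) exceeds half the Debye length "
            f"({grading.debye:.2e} m): the screening layer would be unresolved"
        )
    if h0 > grading.debye / 5:
        warnings.warn("first radial cell exceeds Debye/5; accuracy may suffer")
    xi_faces = np.linspace(-geom.half_length, geom.half_length, grading.n_xi + 1)
    return Mesh(r_faces=faces, xi_faces=xi_faces)


@dataclass
class MembraneBC:
    """Membrane boundary data on the waveform's xi grid.

    ``sigma``: surface charge density (C/m^2) seen by the exterior solution —
    the resting capacitor charge plus the co-moving line charge I(xi)/v spread
    over the circumference.  ``F_plus``/``F_minus``: outward (into the
    exterior) molar fluxes of the effective cation/anion (mol m^-2 s^-1),
    referenced to rest so that the resting state is a true equilibrium.
    """

    xi: np.ndarray
    sigma: np.ndarray
    F_plus: np.ndarray
    F_minus: np.ndarray

    def interp(self, xi_new):
        return MembraneBC(
            xi=np.asarray(xi_new),
            sigma=np.interp(xi_new, self.xi, self.sigma),
            F_plus=np.interp(xi_new, self.xi, self.F_plus),
            F_minus=np.interp(xi_new, self.xi, self.F_minus),
        )


DEFAULT_SIGMA_CAPACITANCE = 5.2e-3  # F/m^2, calibrated charge-coupling capacitance


def membrane_boundary(
    waveform: APWaveform,
    C_m: float = DEFAULT_SIGMA_CAPACITANCE,
    leak_assignment: dict | None = None,
) -> MembraneBC:
    """Build PNP membrane boundary data from the traveling-wave AP.

    sigma(xi) = C_m V_rest + I(xi) / (2 pi a v); the Na and K channel currents
    (rest-subtracted) are carried by the effective cation, the leak current by
    the effective anion (overridable through ``leak_assignment``, a mapping
    channel -> 'cation' | 'anion').
    """
    if waveform.I is None:
        raise ValueError("waveform is missing the axial current profile")
    assignment = {"Na": "cation", "K": "cation", "L": "anion"}
    if leak_assignment:
        assignment.update(leak_assignment)
    p = waveform.params
    jNa0, jK0, jL0 = resting_currents(p)
    deltas = {
        "Na": waveform.j_Na - jNa0,
        "K": waveform.j_K - jK0,
        "L": waveform.j_L - jL0,
    }
    F_plus = np.zeros_like(waveform.xi)
    F_minus = np.zeros_like(waveform.xi)
    for ch, dj in deltas.items():
        tgt = assignment[ch]
        if tgt == "cation":
            F_plus = F_plus + dj / FARADAY  # z = +1
        elif tgt == "anion":
            F_minus = F_minus - dj / FARADAY  # z = -1
        else:
            raise ValueError(f"unknown species target {tgt!r}")
    sigma = C_m * (p.V_rest * 1e-3) + waveform.I / (
        2 * np.pi * waveform.a * waveform.v
    )
    return MembraneBC(xi=waveform.xi, sigma=sigma, F_plus=F_plus, F_minus=F_minus)


@dataclass(frozen=True)
class SolverOptions:
    tol: float = 1e-8
    max_iter: int = 200
    relax: float = 0.5
    verbose: bool = False


class PNPConvergenceError(RuntimeError):
    def __init__(self, msg, history):
        super().__init__(msg)
        self.history = history


@dataclass
class PNPField:
    """Converged exterior solution on the (r, xi) mesh.

    ``V`` in volts, concentrations in mol/m^3, arrays shaped (n_r, n_xi)."""

    mesh: Mesh
    V: np.ndarray
    c_plus: np.ndarray
    c_minus: np.ndarray
    ions: EffectiveSpeciesPair
    bc: MembraneBC
    v: float
    T: float
    eps: float
    converged: bool
    iterations: int
    residual_history: list

    def charge_density(self) -> np.ndarray:
        """rho = F (c+ - c-), C/m^3."""
        return FARADAY * (self.c_plus - self.c_minus)

    @property
    def sigma(self) -> np.ndarray:
        """Membrane surface charge on the mesh's xi centers."""
        return self.bc.sigma

    def membrane_E(self) -> np.ndarray:
        """Radial electric field at r = a+ (V/m), from the Gauss-law BC."""
        return self.bc.sigma / (self.eps * EPS0)


def _bernoulli(x):
    """B(x) = x / (exp(x) - 1), overflow-safe and continuous at 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    pos = (x >= 0) & ~small
    neg = (x < 0) & ~small
    out[small] = 1.0 - x[small] / 2.0
    xp = x[pos]
    out[pos] = xp * np.exp(-xp) / (-np.expm1(-xp))
    xn = x[neg]
    out[neg] = xn / np.expm1(xn)
    return out


def _dbernoulli(x):
    """B'(x), overflow-safe.  B'(0) = -1/2; B'(-inf) = -1; B'(+inf) = 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-6
    big_pos = x > 40.0
    big_neg = x < -40.0
    mid = ~(small | big_pos | big_neg)
    out[small] = -0.5 + x[small] / 6.0
    out[big_pos] = (1.0 - x[big_pos]) * np.exp(-x[big_pos])
    out[big_neg] = -1.0
    xm = x[mid]
    em = np.expm1(xm)  # e^x - 1
    out[mid] = (em - xm * (em + 1.0)) / em**2
    return out


class _FVGrid:
    """Precomputed finite-volume geometry (per radian of azimuth)."""

    def __init__(self, mesh: Mesh):
        rf, xf = mesh.r_faces, mesh.xi_faces
        self.mesh = mesh
        self.nr, self.nx = mesh.n_r, mesh.n_xi
        self.rc = mesh.r_centers
        self.xc = mesh.xi_centers
        self.dx = mesh.dxi
        self.ring = 0.5 * (rf[1:] ** 2 - rf[:-1] ** 2)  # per-cell annulus area
        self.vol = self.ring[:, None] * self.dx * np.ones((1, self.nx))
        # radial faces 0..nr; areas per radian
        self.A_r = rf * self.dx
        # distances center-to-center (interior) and center-to-face (boundaries)
        self.d_r = np.empty(self.nr + 1)
        self.d_r[1:-1] = np.diff(self.rc)
        self.d_r[0] = self.rc[0] - rf[0]
        self.d_r[-1] = rf[-1] - self.rc[-1]
        self.A_x = self.ring  # axial face area per radian, per r-cell
        self.idx = np.arange(self.nr * self.nx).reshape(self.nr, self.nx)


def _poisson_matrix(g: _FVGrid, eps_eff: float):
    """SPD matrix for  -div(eps grad V) = rho, Neumann at membrane,
    V=0 at R_max, zero-flux at the xi ends."""
    nr, nx = g.nr, g.nx
    rows, cols, vals = [], [], []
    diag = np.zeros((nr, nx))
    # interior radial faces j = 1..nr-1 between cells (j-1,k) and (j,k)
    w_r = eps_eff * g.A_r[1:-1] / g.d_r[1:-1]  # (nr-1,)
    for j in range(1, nr):
        w = w_r[j - 1]
        p, n = g.idx[j - 1], g.idx[j]
        rows += [p, n, p, n]
        cols += [n, p, p, n]
        vals += [np.full(nx, -w), np.full(nx, -w), np.full(nx, w), np.full(nx, w)]
    # outer Dirichlet face
    w_out = eps_eff * g.A_r[-1] / g.d_r[-1]
    diag[-1, :] += w_out
    # axial faces between (j,k-1) and (j,k)
    w_x = eps_eff * g.A_x / g.dx  # (nr,)
    p = g.idx[:, :-1].ravel()
    n = g.idx[:, 1:].ravel()
    w = np.repeat(w_x, nx - 1)
    rows += [p, n, p, n]
    cols += [n, p, p, n]
    vals += [-w, -w, w, w]
    rows.append(g.idx.ravel())
    cols.append(g.idx.ravel())
    vals.append(diag.ravel())
    rows = np.concatenate([np.asarray(r).ravel() for r in rows])
    cols = np.concatenate([np.asarray(c).ravel() for c in cols])
    vals = np.concatenate([np.asarray(v).ravel() for v in vals])
    A = sp.coo_matrix((vals, (rows, cols)), shape=(nr * nx, nr * nx)).tocsc()
    return A


def _poisson_rhs(g: _FVGrid, rho, sigma):
    b = rho * g.vol
    b[0, :] += sigma * g.A_r[0]
    return b.ravel()


def _transport_system(g: _FVGrid, V, z, D, v, Vt, c_inf, F_mem, c=None):
    """Assemble the species conservation system at potential ``V``.

    Returns ``(M, b)`` with the flux-balance equations ``M c = b``; if the
    current concentration iterate ``c`` is supplied, additionally returns the
    Jacobian block ``K = d(M(V) c - b)/dV`` needed by the coupled Newton
    solve (the sensitivity of the Scharfetter-Gummel face fluxes to the
    potential differences that drive them).
    """
    nr, nx = g.nr, g.nx
    rows, cols, vals = [], [], []
    krows, kcols, kvals = [], [], []
    diag = np.zeros((nr, nx))
    kdiag = np.zeros((nr, nx))
    b = np.zeros((nr, nx))
    want_K = c is not None

    def add_face(p_idx, n_idx, coef, pe):
        """SG flux P->N through a face: J = coef*(B(-pe) c_P - B(pe) c_N),
        coef = D*A/h, pe the (drift + advection) Peclet number.  Adds
        outward-flux contributions to both cells, and (optionally) the
        dJ/dV entries using dpe/dV_P = +z/Vt, dpe/dV_N = -z/Vt."""
        Bm = _bernoulli(-pe)
        Bp = _bernoulli(pe)
        rows.extend([p_idx, p_idx, n_idx, n_idx])
        cols.extend([p_idx, n_idx, p_idx, n_idx])
        vals.extend([coef * Bm, -coef * Bp, -coef * Bm, coef * Bp])
        if want_K:
            cP = c.ravel()[p_idx]
            cN = c.ravel()[n_idx]
            dJdpe = coef * (-_dbernoulli(-pe) * cP - _dbernoulli(pe) * cN)
            gz = dJdpe * z / Vt
            krows.extend([p_idx, p_idx, n_idx, n_idx])
            kcols.extend([p_idx, n_idx, p_idx, n_idx])
            kvals.extend([gz, -gz, -gz, gz])

    # interior radial faces
    for j in range(1, nr):
        coef = D * g.A_r[j] / g.d_r[j]
        pe = -z * (V[j] - V[j - 1]) / Vt
        add_face(g.idx[j - 1], g.idx[j], np.full(nx, coef), pe)
    # membrane face: prescribed molar influx F_mem (mol/m^2/s, into domain)
    b[0, :] += F_mem * g.A_r[0]
    # outer Dirichlet face: ghost value c_inf at V = 0 (V Dirichlet there too)
    coef = D * g.A_r[-1] / g.d_r[-1]
    pe = -z * (0.0 - V[-1]) / Vt
    diag[-1, :] += coef * _bernoulli(-pe)
    b[-1, :] += coef * _bernoulli(pe) * c_inf
    if want_K:
        dJdpe = coef * (-_dbernoulli(-pe) * c[-1] - _dbernoulli(pe) * c_inf)
        kdiag[-1, :] += dJdpe * z / Vt
    # axial interior faces: drift = electric + frame advection (-v)
    coef = D * g.A_x / g.dx  # (nr,)
    dV = V[:, 1:] - V[:, :-1]
    pe = -z * dV / Vt + (-v) * g.dx / D
    add_face(
        g.idx[:, :-1].ravel(),
        g.idx[:, 1:].ravel(),
        np.repeat(coef, nx - 1),
        pe.ravel(),
    )
    # xi ends: advective only.  k=0 face is the outflow (frame velocity -v),
    # upwinded on the cell; k=nx-1 face is the inflow, fed with bulk fluid.
    if v > 0:
        diag[:, 0] += v * g.A_x
        b[:, -1] += v * g.A_x * c_inf
    rows = np.concatenate([np.asarray(r).ravel() for r in rows] + [g.idx.ravel()])
    cols = np.concatenate([np.asarray(cc).ravel() for cc in cols] + [g.idx.ravel()])
    vals = np.concatenate([np.asarray(v_).ravel() for v_ in vals] + [diag.ravel()])
    n = nr * nx
    M = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    if not want_K:
        return M, b.ravel()
    krows = np.concatenate(
        [np.asarray(r).ravel() for r in krows] + [g.idx.ravel()]
    )
    kcols = np.concatenate(
        [np.asarray(cc).ravel() for cc in kcols] + [g.idx.ravel()]
    )
    kvals = np.concatenate(
        [np.asarray(v_).ravel() for v_ in kvals] + [kdiag.ravel()]
    )
    K = sp.coo_matrix((kvals, (krows, kcols)), shape=(n, n)).tocsc()
    return M, b.ravel(), K


def solve_pnp(
    mesh: Mesh,
    ions: EffectiveSpeciesPair,
    bc: MembraneBC,
    v: float,
    opts: SolverOptions = SolverOptions(),
    eps: float = 80.0,
    T: float = 310.0,
) -> PNPField:
    """Solve the coupled Poisson/Nernst-Planck system to steady state in the
    co-moving frame by a fully coupled Newton iteration.

    The unknown vector stacks (V, c+, c-).  The residual comprises the
    discrete Poisson balance and the two species flux balances; the Jacobian
    couples them through the charge density (Poisson rows) and through the
    potential-dependence of the Scharfetter-Gummel fluxes (transport rows).
    A segregated (Gummel) sweep stalls here: the electrolyte's screening
    response has near-unity loop gain on a domain thousands of Debye lengths
    wide, which the coupled Jacobian captures exactly.  The iteration starts
    from the linearized (Debye-Hueckel) screened state; steps that would
    drive concentrations negative are damped by ``opts.relax``.

    Returns a :class:`PNPField`; raises :class:`PNPConvergenceError` with the
    residual history if the relative residual does not reach ``opts.tol``
    within ``opts.max_iter`` Newton steps.
    """
    if v < 0:
        raise ValueError("v must be non-negative")
    g = _FVGrid(mesh)
    Vt = thermal_voltage(T)
    bc_m = bc if len(bc.xi) == g.nx and np.allclose(bc.xi, g.xc) else bc.interp(g.xc)
    sigma = bc_m.sigma
    c_inf = ions.ionic_strength
    n = g.nr * g.nx
    A = _poisson_matrix(g, eps * EPS0)
    # screened (Debye-Hueckel) initial state: linearized Boltzmann response
    S = 2.0 * FARADAY * c_inf / Vt * g.vol.ravel()
    V = spla.spsolve(
        (A + sp.diags(S)).tocsc(), _poisson_rhs(g, np.zeros((g.nr, g.nx)), sigma)
    ).reshape(g.nr, g.nx)
    cp = ions.cation.c_inf * np.exp(-np.clip(V / Vt, -50, 50))
    cm = ions.anion.c_inf * np.exp(+np.clip(V / Vt, -50, 50))
    # residual scales: Gauss-law boundary term for Poisson, largest face flux
    # (membrane or outer-diffusive) for each species
    scale_V = max(np.abs(sigma).max() * g.A_r[0], 1e-30)
    flux_out = ions.cation.D * g.A_r[-1] / g.d_r[-1] * c_inf

    def flux_scale(F_mem):
        # peak membrane flux when driven, floored by a characteristic bulk
        # face flux: the membrane flux can sit many orders below the
        # cancelling screening-layer fluxes, where double precision cannot
        # resolve residuals anyway
        return max(np.abs(F_mem).max() * g.A_r[0], 1e-3 * flux_out)

    scales = np.concatenate(
        [
            np.full(n, scale_V),
            np.full(n, flux_scale(bc_m.F_plus)),
            np.full(n, flux_scale(bc_m.F_minus)),
        ]
    )
    species = (
        (+1, ions.cation.D, bc_m.F_plus),
        (-1, ions.anion.D, bc_m.F_minus),
    )
    rho_coef = FARADAY * g.vol.ravel()
    b_V = _poisson_rhs(g, np.zeros((g.nr, g.nx)), sigma)
    history = []
    converged = False
    it = 0
    lu = None
    for it in range(1, opts.max_iter + 1):
        Mp, bp, Kp = _transport_system(
            g, V, +1, species[0][1], v, Vt, c_inf, species[0][2], c=cp
        )
        Mm, bm, Km = _transport_system(
            g, V, -1, species[1][1], v, Vt, c_inf, species[1][2], c=cm
        )
        R = np.concatenate(
            [
                A @ V.ravel() - rho_coef * (cp.ravel() - cm.ravel()) - b_V,
                Mp @ cp.ravel() - bp,
                Mm @ cm.ravel() - bm,
            ]
        )
        res = np.abs(R / scales).max()
        history.append(res)
        if opts.verbose:
            print(f"  newton iter {it:3d}: rel residual {res:.3e}")
        if res < opts.tol:
            converged = True
            break
        # modified Newton: the Jacobian changes only through the ~1% SG
        # nonlinearity, so one factorization is reused until the residual
        # reduction stalls
        stalled = len(history) >= 2 and res > 0.3 * history[-2]
        if lu is None or stalled:
            D_rho = sp.diags(rho_coef)
            J = sp.bmat(
                [
                    [A, -D_rho, D_rho],
                    [Kp, Mp, None],
                    [Km, None, Mm],
                ],
                format="csc",
            )
            lu = spla.splu(J)
        delta = lu.solve(-R)
        dV = delta[:n].reshape(g.nr, g.nx)
        dcp = delta[n : 2 * n].reshape(g.nr, g.nx)
        dcm = delta[2 * n :].reshape(g.nr, g.nx)
        # damp steps that would drive a concentration negative
        alpha = 1.0
        for c_arr, dc in ((cp, dcp), (cm, dcm)):
            neg = dc < 0
            if np.any(c_arr[neg] + dc[neg] <= 0):
                lim = np.min(c_arr[neg] / -dc[neg])
                alpha = min(alpha, max(opts.relax * lim, 1e-3))
        V = V + alpha * dV
        cp = np.maximum(cp + alpha * dcp, 0.0)
        cm = np.maximum(cm + alpha * dcm, 0.0)
    if not converged:
        raise PNPConvergenceError(
            f"PNP Newton iteration did not reach tol={opts.tol} in "
            f"{opts.max_iter} iterations (last residual {history[-1]:.3e})",
            history,
        )
    return PNPField(
        mesh=mesh, V=V, c_plus=cp, c_minus=cm, ions=ions, bc=bc_m,
        v=v, T=T, eps=eps, converged=converged, iterations=it,
        residual_history=history,
    )


def gouy_chapman_potential(x, sigma, c_inf, eps=80.0, T=310.0):
    """Closed-form planar double-layer potential (V) at distance x from a
    charged plane with surface charge ``sigma`` (C/m^2) in a symmetric 1:1
    electrolyte of bulk concentration ``c_inf`` (mol/m^3).

    Grahame's equation gives the surface potential; the full (nonlinear)
    Gouy-Chapman profile is then evaluated at x.
    """
    lam = debye_length(c_inf, eps, T)
    Vt = thermal_voltage(T)
    pref = np.sqrt(8 * eps * EPS0 * BOLTZMANN * T * AVOGADRO * c_inf)
    psi0 = 2 * Vt * np.arcsinh(sigma / pref)
    gamma = np.tanh(psi0 / (4 * Vt))
    gx = gamma * np.exp(-np.asarray(x) / lam)
    return 2 * Vt * np.log((1 + gx) / (1 - gx))
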