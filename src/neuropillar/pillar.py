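"""Laplace solutions for the electric field inside a diamond nanopillar.

When a neurite touches the pillar it displaces the screening ions over the
contact patch, so the unscreened membrane field enters the diamond there; on
every other part of the diamond surface the Debye layer pins the potential to
zero.  Inside the (charge-free) pillar the potential then satisfies Laplace's
equation with mixed boundary conditions:

* contact patch — uniform normal field E0 (Neumann), the membrane field
  delivered by the electrodiffusion stage;
* everywhere else on the surface — V = 0 (Dirichlet), except that in the
  on-side geometry the top disc defaults to flux-free: the neurite body
  (radius ~5x the pillar's) overhangs the tip and displaces the screening
  ions there as well (``grounded_top`` restores the grounded variant).

Two contact geometries are supported.  ``on-top`` (neurite lying across the
full circular top disc) has a classical separable solution

    V(r, z) = sum_n A_n J0(j0n 2r/d) exp(-j0n 2z/d),

z measured downward from the disc, whose slowest mode decays with constant
2 j01 / d ≈ 4.81/d.  ``on-side`` (neurite against the lateral wall near the
tip, square patch of area equal to the top disc) has no separable solution
and is solved by a cell-centered finite-volume discretization in cylindrical
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import j0, j1, jn_zeros

__all__ = [
    "PillarGeometry",
    "OnTopSolution",
    "OnSideSolution",
    "GridSpec",
    "ontop_series",
    "onside_numeric",
    "decay_constant",
    "field_at",
]


@dataclass(frozen=True)
class PillarGeometry:
    """Cylindrical diamond pillar and its neuron contact.

    ``E0`` is the normal electric field (V/m) imposed over the contact patch;
    ``contact`` selects the geometry.  The on-side patch is a square of side
    sqrt(pi d^2/4) (same area as the top disc) wrapped onto the lateral
    surface with its upper edge at the tip.  ``dielectric_contrast``
    optionally scales E0 by a normal-field jump factor (eps_water/eps_diamond
    would be 80/5.7); the default 1.0 applies no amplification.
    """

    diameter: float = 200e-9
    height: float = 1e-6
    contact: Literal["on-top", "on-side"] = "on-top"
    E0: float = 3.3e6
    dirichlet_value: float | None = None  # alternative: fix V on the patch
    dielectric_contrast: float = 1.0
    # on-side only: the overhanging neurite body covers the tip of a pillar
    # much thinner than itself, so by default the top disc is treated as
    # screening-free (zero normal flux) rather than grounded
    grounded_top: bool = False

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.height <= self.diameter / 4:
            raise ValueError("pillar height must exceed d/4")
        if self.contact not in ("on-top", "on-side"):
            raise ValueError(f"unknown contact mode {self.contact!r}")
        if self.contact == "on-side":
            s = self.patch_side
            if s > self.height:
                raise ValueError("wrapped square patch does not fit on the pillar")
            if s > np.pi * self.diameter:
                raise ValueError("wrapped square patch overlaps itself")

    @property
    def radius(self) -> float:
        return self.diameter / 2

    @property
    def patch_side(self) -> float:
        """Side of the on-side square patch: sqrt(pi d^2 / 4)."""
        return float(np.sqrt(np.pi) * self.diameter / 2)

    @property
    def drive(self) -> float:
        return self.E0 * self.dielectric_contrast


def decay_constant(pillar: PillarGeometry) -> float:
    """Dominant axial decay rate (1/m) of the on-top solution: 2 j01 / d."""
    if pillar.contact != "on-top":
        raise ValueError("decay constant is defined for the on-top series")
    j01 = float(jn_zeros(0, 1)[0])
    return 2.0 * j01 / pillar.diameter


@dataclass
class OnTopSolution:
    """Bessel-series solution for on-top contact.

    Coordinates: z >= 0 measured downward from the contact disc into the
    pillar, r the cylindrical radius.  ``V(r, z)`` in volts, fields in V/m.
    """

    pillar: PillarGeometry
    modes: np.ndarray  # Bessel zeros j0n
    A_n: np.ndarray  # series coefficients (V)

    @property
    def decay_constant(self) -> float:
        return 2.0 * float(self.modes[0]) / self.pillar.diameter

    def _check(self, r, z):
        r = np.asarray(r, dtype=float)
        z = np.asarray(z, dtype=float)
        if np.any(z < 0) or np.any(z > self.pillar.height) or np.any(
            np.abs(r) > self.pillar.radius
        ):
            raise ValueError("evaluation point outside the pillar")
        return r, z

    def V(self, r, z):
        r, z = self._check(r, z)
        k = 2.0 * self.modes / self.pillar.diameter  # (n,)
        rad = j0(np.multiply.outer(r, k))
        ax = np.exp(-np.multiply.outer(z, k))
        return np.einsum("...n,...n,n->...", rad, ax, self.A_n)

    def E(self, r, z):
        """(E_r, E_z) = -grad V."""
        r, z = self._check(r, z)
        k = 2.0 * self.modes / self.pillar.diameter
        ax = np.exp(-np.multiply.outer(z, k))
        E_r = np.einsum(
            "...n,...n,n->...", j1(np.multiply.outer(r, k)), ax, self.A_n * k
        )
        E_z = np.einsum(
            "...n,...n,n->...", j0(np.multiply.outer(r, k)), ax, self.A_n * k
        )
        return E_r, E_z

    def E_axis(self, z):
        """|E| on the axis (r = 0), where only E_z survives."""
        _, E_z = self.E(0.0, z)
        return np.abs(E_z)


def ontop_series(pillar: PillarGeometry, n_modes: int = 200) -> OnTopSolution:
    """Analytic on-top solution with ``n_modes`` Bessel modes.

    The Neumann contact condition dV/dz(r, 0) = -E0 over the disc fixes
    A_n = E0 d / (j0n^2 J1(j0n)); the Dirichlet variant (V = V0 on the disc)
    gives A_n = 2 V0 / (j0n J1(j0n)).
    """
    if n_modes < 1:
        raise ValueError("need at least one mode")
    if pillar.contact != "on-top":
        raise ValueError("ontop_series requires contact='on-top'")
    zeros = jn_zeros(0, n_modes)
    if pillar.dirichlet_value is not None:
        A_n = 2.0 * pillar.dirichlet_value / (zeros * j1(zeros))
    else:
        A_n = pillar.drive * pillar.diameter / (zeros**2 * j1(zeros))
    return OnTopSolution(pillar=pillar, modes=zeros, A_n=A_n)


@dataclass(frozen=True)
class GridSpec:
    """Resolution of the on-side finite-volume solve."""

    n_r: int = 40
    n_phi: int = 96
    n_z: int = 140
    tol: float = 1e-8


@dataclass
class OnSideSolution:
    """Finite-volume solution for on-side contact.

    Cell-centered grid in (r, phi, z); z measured downward from the tip.
    The patch is centered at phi = 0 with its top edge at z = 0.
    """

    pillar: PillarGeometry
    r: np.ndarray
    phi: np.ndarray
    z: np.ndarray
    V_grid: np.ndarray  # (n_r, n_phi, n_z), volts
    residual: float
    patch_center_z: float

    def V(self, x, y, z):
        """Trilinear interpolation of V at Cartesian points inside the pillar
        (patch center lies in the +x direction)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        z = np.asarray(z, float)
        r = np.hypot(x, y)
        if np.any(r > self.pillar.radius) or np.any(z < 0) or np.any(
            z > self.pillar.height
        ):
            raise ValueError("evaluation point outside the pillar")
        phi = np.arctan2(y, x)  # (-pi, pi], matching the grid convention
        from scipy.interpolate import RegularGridInterpolator

        nphi = len(self.phi)
        # extend across the axis with the phi+pi ring so interpolation below
        # the first ring stays linear through r = 0
        mirror = np.roll(self.V_grid, nphi // 2, axis=1)[[0], :, :]
        Vr = np.concatenate((mirror, self.V_grid), axis=0)
        r_pad = np.concatenate(([-self.r[0]], self.r))
        # periodic phi padding
        phi_pad = np.concatenate(
            ([self.phi[-1] - 2 * np.pi], self.phi, [self.phi[0] + 2 * np.pi])
        )
        Vp = np.concatenate((Vr[:, [-1], :], Vr, Vr[:, [0], :]), axis=1)
        interp = RegularGridInterpolator(
            (r_pad, phi_pad, self.z), Vp, method="linear", bounds_error=False,
            fill_value=None,
        )
        pts = np.stack(
            [np.broadcast_arrays(r, phi, z)[i].ravel() for i in range(3)], axis=-1
        )
        out = interp(pts)
        return out.reshape(np.broadcast(x, y, z).shape)

    def E(self, x, y, z, h: float = 1e-9):
        """-grad V by central differences of the interpolant."""
        Ex = -(self.V(x + h, y, z) - self.V(x - h, y, z)) / (2 * h)
        Ey = -(self.V(x, y + h, z) - self.V(x, y - h, z)) / (2 * h)
        zp = np.minimum(z + h, self.pillar.height)
        zm = np.maximum(z - h, 0.0)
        Ez = -(self.V(x, y, zp) - self.V(x, y, zm)) / (zp - zm)
        return Ex, Ey, Ez

    def E_mag(self, x, y, z, h: float = 1e-9):
        Ex, Ey, Ez = self.E(x, y, z, h)
        return np.sqrt(Ex**2 + Ey**2 + Ez**2)


def onside_numeric(
    pillar: PillarGeometry, grid: GridSpec = GridSpec()
) -> OnSideSolution:
    """3D finite-volume Laplace solve for on-side contact.

    Cell-centered cylindrical grid; the axis needs no boundary condition
    (zero face area).  Patch faces carry the uniform inward normal field
    ``E0``; all other surface faces are Dirichlet V = 0.  The SPD system is
    solved by Jacobi-preconditioned conjugate gradients.
    """
    if pillar.contact != "on-side":
        raise ValueError("onside_numeric requires contact='on-side'")
    R = pillar.radius
    H = pillar.height
    s = pillar.patch_side
    nr, nphi, nz = grid.n_r, grid.n_phi, grid.n_z
    half_arc = s / (2 * R)  # patch half-width in phi
    if nphi * half_arc / np.pi < 10 or nz * s / H < 10:
        raise ValueError("grid does not resolve the contact patch")
    dr = R / nr
    dphi = 2 * np.pi / nphi
    dz = H / nz
    r_f = np.arange(nr + 1) * dr
    r_c = 0.5 * (r_f[:-1] + r_f[1:])
    phi_c = (np.arange(nphi) + 0.5) * dphi - np.pi  # patch centered at phi=0
    z_c = (np.arange(nz) + 0.5) * dz

    idx = np.arange(nr * nphi * nz).reshape(nr, nphi, nz)
    rows, cols, vals = [], [], []
    diag = np.zeros((nr, nphi, nz))
    b = np.zeros((nr, nphi, nz))

    def couple(p, n, w):
        rows.extend([p, n])
        cols.extend([n, p])
        vals.extend([-w, -w])
        np.add.at(diag.reshape(-1), p, w)
        np.add.at(diag.reshape(-1), n, w)

    # radial faces j = 1..nr-1 (face area r_f dphi dz, distance dr)
    for j in range(1, nr):
        w = r_f[j] * dphi * dz / dr
        couple(idx[j - 1].ravel(), idx[j].ravel(), np.full(nphi * nz, w))
    # azimuthal faces (area dr dz, arc distance r_c dphi), periodic
    for j in range(nr):
        w = dr * dz / (r_c[j] * dphi)
        p = idx[j, :, :].ravel()
        nb = np.roll(idx[j, :, :], -1, axis=0).ravel()
        couple(p, nb, np.full(nphi * nz, w))
    # vertical faces (area r_c dr dphi, distance dz)
    w_z = r_c * dr * dphi / dz
    for j in range(nr):
        couple(idx[j, :, :-1].ravel(), idx[j, :, 1:].ravel(),
               np.full(nphi * (nz - 1), w_z[j]))
    # bottom (z=H) grounded; top (z=0) grounded only if requested (the
    # default leaves it flux-free beneath the overhanging neurite)
    for j in range(nr):
        w = r_c[j] * dr * dphi / (dz / 2)
        if pillar.grounded_top:
            diag[j, :, 0] += w
        diag[j, :, -1] += w
    # lateral surface r = R: patch (Neumann, inward E0) or Dirichlet 0.
    # Faces cut by the patch edge are area-weighted: the patch fraction of the
    # face carries the Neumann drive, the rest stays grounded.
    def overlap(lo, hi, a_, b_):
        return np.clip(np.minimum(hi, b_) - np.maximum(lo, a_), 0.0, None) / (hi - lo)

    f_phi = overlap(phi_c - dphi / 2, phi_c + dphi / 2, -half_arc, half_arc)
    f_z = overlap(z_c - dz / 2, z_c + dz / 2, 0.0, s)
    frac = f_phi[:, None] * f_z[None, :]
    w_lat = r_f[-1] * dphi * dz / (dr / 2)
    diag[-1, :, :] += (1.0 - frac) * w_lat
    # FV balance: sum of outward -dV/dn * area = 0; a patch face contributes
    # outward normal gradient dV/dn_out = +dV/dr = E0 (field -E0 r_hat inward)
    b[-1, :, :] += frac * pillar.drive * r_f[-1] * dphi * dz

    n_cells = nr * nphi * nz
    rows = np.concatenate([np.asarray(r).ravel() for r in rows] + [idx.ravel()])
    cols = np.concatenate([np.asarray(c).ravel() for c in cols] + [idx.ravel()])
    vals = np.concatenate([np.asarray(v).ravel() for v in vals] + [diag.ravel()])
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n_cells, n_cells)).tocsr()
    rhs = b.ravel()

    dinv = 1.0 / A.diagonal()
    M = spla.LinearOperator(A.shape, lambda u: dinv * u)
    x, info = spla.cg(A, rhs, rtol=grid.tol, maxiter=20000, M=M)
    resid = float(np.linalg.norm(A @ x - rhs) / np.linalg.norm(rhs))
    if info != 0 or resid > 100 * grid.tol:
        raise RuntimeError(
            f"on-side Laplace solve did not converge (info={info}, "
            f"relative residual {resid:.2e})"
        )
    return OnSideSolution(
        pillar=pillar,
        r=r_c,
        phi=phi_c,
        z=z_c,
        V_grid=x.reshape(nr, nphi, nz),
        residual=resid,
        patch_center_z=min(s / 2, H),
    )


def field_at(solution, point):
    """|E| and components at a Cartesian point strictly inside the pillar.

    ``solution`` may be an :class:`OnTopSolution` (point = (r, z) or
    (x, y, z)) or an :class:`OnSideSolution` (point = (x, y, z)).
    Returns ``(magnitude, components)``.
    """
    if isinstance(solution, OnTopSolution):
        if len(point) == 2:
            r, z = point
        else:
            x, y, z = point
            r = float(np.hypot(x, y))
        E_r, E_z = solution.E(r, z)
        mag = float(np.sqrt(E_r**2 + E_z**2))
        return mag, (float(E_r), float(E_z))
    if isinstance(solution, OnSideSolution):
        x, y, z = point
        Ex, Ey, Ez = solution.E(x, y, z)
        mag = float(np.sqrt(Ex**2 + Ey**2 + Ez**2))
        return mag, (float(Ex), float(Ey), float(Ez))
    raise TypeError(f"unsupported solution type {type(solution)!r}")
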