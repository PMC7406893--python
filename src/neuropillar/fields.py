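"""Electric field, charge, current and magnetic-field maps from a PNP solution.

This module turns a converged exterior electrodiffusion solution into the
observable fields:

* ``E = -grad V`` (quasi-static),
* charge density ``rho = F (c+ - c-)``,
* drift-diffusion current density
  ``j = F sum_i z_i ( -D_i [grad c_i + z_i (e/kT) c_i grad V] )``,
* azimuthal magnetic field from the integral form of Ampere's law,
  ``B_phi(r) = mu0/r [ I(xi)/(2 pi) + int_a^r j_xi r' dr' ]`` — the internal
  axial current plus the (small) exterior current it drags along.

It also provides the micron-scale core-conductor comparator (line-source
extracellular potential and wire magnetic field), radial profile extraction at
the AP peak, and a 1/r amplitude fit.

Field components are stored in SI (V/m, A/m^2, C/m^3, T); the ``*_report``
helpers convert to the presentation units (mV/m, mA/m^2, nT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import EPS0, FARADAY, MU0, thermal_voltage
from .hh import APWaveform
from .pnp import AxonGeometry, PNPField

__all__ = [
    "FieldMaps",
    "derive_fields",
    "magnetic_field",
    "radial_peak_profile",
    "fit_inverse_r",
    "cc_comparator",
]


def _grad_nonuniform(f, x, axis):
    """Second-order centered gradient on a non-uniform grid."""
    return np.gradient(f, x, axis=axis, edge_order=2)


@dataclass
class FieldMaps:
    """Derived fields on the PNP mesh (shapes (n_r, n_xi), SI units).

    ``E_r_membrane`` is the Gauss-law boundary value sigma/(eps eps0) at
    r = a+, exact on the discrete level; the cell-centered maps start at the
    first cell center.
    """

    field: PNPField
    E_r: np.ndarray
    E_xi: np.ndarray
    rho: np.ndarray
    j_r: np.ndarray
    j_xi: np.ndarray
    B_phi: np.ndarray | None = None

    @property
    def mesh(self):
        return self.field.mesh

    @property
    def E_r_membrane(self) -> np.ndarray:
        return self.field.membrane_E()

    def peak_xi_index(self) -> int:
        """xi index of the maximum membrane radial field (ties -> smaller xi)."""
        return int(np.argmax(self.E_r_membrane))

    def rest_xi_index(self) -> int:
        """xi index representing rest: the leading domain end, far ahead of
        the wave."""
        return self.mesh.n_xi - 1


def derive_fields(field: PNPField) -> FieldMaps:
    """Differentiate the PNP solution into E, rho and j maps.

    Refuses a non-converged input: finite differences of an unconverged
    iterate are meaningless.
    """
    if not field.converged:
        raise ValueError("PNP solution is not converged; refusing to derive fields")
    mesh = field.mesh
    r = mesh.r_centers
    xi = mesh.xi_centers
    V, cp, cm = field.V, field.c_plus, field.c_minus
    E_r = -_grad_nonuniform(V, r, axis=0)
    E_xi = -_grad_nonuniform(V, xi, axis=1)
    rho = field.charge_density()
    Vt = thermal_voltage(field.T)
    Dp, Dm = field.ions.cation.D, field.ions.anion.D
    # molar fluxes J_i = -D_i (grad c_i + z_i c_i grad V / Vt); j = F sum z_i J_i
    jr = FARADAY * (
        Dp * (-_grad_nonuniform(cp, r, axis=0) + cp * E_r / Vt)
        + Dm * (_grad_nonuniform(cm, r, axis=0) + cm * E_r / Vt)
    )
    jxi = FARADAY * (
        Dp * (-_grad_nonuniform(cp, xi, axis=1) + cp * E_xi / Vt)
        + Dm * (_grad_nonuniform(cm, xi, axis=1) + cm * E_xi / Vt)
    )
    return FieldMaps(field=field, E_r=E_r, E_xi=E_xi, rho=rho, j_r=jr, j_xi=jxi)


def magnetic_field(maps: FieldMaps, I: np.ndarray) -> np.ndarray:
    """Azimuthal magnetic field B_phi(r, xi) in tesla via Ampere's law.

    ``I``: internal axial current (A) on the mesh's xi centers.  The enclosed
    current at radius r is I(xi) plus the exterior axial current integrated
    over the annulus [a, r] (cumulative trapezoid, with the membrane-face
    value taken from the first cell row).
    """
    mesh = maps.mesh
    I = np.asarray(I, dtype=float)
    if I.shape != (mesh.n_xi,):
        raise ValueError("axial-current profile must live on the mesh xi centers")
    r = np.concatenate(([mesh.r_faces[0]], mesh.r_centers))
    jxi = np.vstack([maps.j_xi[0, :], maps.j_xi])  # extend to the membrane face
    integrand = jxi * r[:, None]
    from scipy.integrate import cumulative_trapezoid

    enclosed_ext = cumulative_trapezoid(integrand, r, axis=0, initial=0.0)
    B = MU0 / r[:, None] * (I[None, :] / (2 * np.pi) + enclosed_ext)
    maps.B_phi = B[1:, :]  # on cell centers
    maps._B_membrane = B[0, :]
    return B[1:, :]


def membrane_B(maps: FieldMaps, I: np.ndarray) -> np.ndarray:
    """B_phi exactly at the membrane radius r = a (tesla)."""
    if getattr(maps, "_B_membrane", None) is None:
        magnetic_field(maps, I)
    return maps._B_membrane


_QUANTITIES = {
    "E_r": ("E_r", "E_r_membrane"),
    "E_xi": ("E_xi", None),
    "rho": ("rho", None),
    "j_r": ("j_r", None),
    "j_xi": ("j_xi", None),
    "B_phi": ("B_phi", "_B_membrane"),
    "V": (None, None),
}


def radial_peak_profile(maps: FieldMaps, quantity: str, xi_index: int | None = None):
    """1D radial profile (r, values) of ``quantity`` at the xi of peak
    membrane field (or an explicit ``xi_index``).

    The membrane point r = a is prepended when a boundary-consistent value
    exists (E_r from the Gauss BC, B_phi from the enclosed current).
    """
    if quantity not in _QUANTITIES:
        raise KeyError(
            f"unknown quantity {quantity!r}; choose from {sorted(_QUANTITIES)}"
        )
    k = maps.peak_xi_index() if xi_index is None else xi_index
    mesh = maps.mesh
    if quantity == "V":
        arr = maps.field.V
        mem_val = None
    else:
        attr, mem_attr = _QUANTITIES[quantity]
        arr = getattr(maps, attr)
        if arr is None:
            raise ValueError(f"{quantity} has not been computed yet")
        mem_val = None
        if mem_attr == "E_r_membrane":
            mem_val = maps.E_r_membrane[k]
        elif mem_attr == "_B_membrane":
            mem_val = getattr(maps, "_B_membrane", None)
            mem_val = None if mem_val is None else mem_val[k]
    r = mesh.r_centers
    vals = arr[:, k]
    if mem_val is not None:
        r = np.concatenate(([mesh.r_faces[0]], r))
        vals = np.concatenate(([mem_val], vals))
    return r, vals


def fit_inverse_r(r, y):
    """Least-squares amplitude A of the model y = A/r.

    Returns ``(A, rel_rms_residual)``.  Raises on a degenerate (all-zero)
    profile or fewer than 3 points.
    """
    r = np.asarray(r, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(r) < 3:
        raise ValueError("need at least 3 points to fit A/r")
    if not np.any(y):
        raise ValueError("degenerate all-zero profile")
    basis = 1.0 / r
    A = float(np.dot(y, basis) / np.dot(basis, basis))
    resid = y - A * basis
    rel = float(np.sqrt(np.mean(resid**2)) / np.sqrt(np.mean(y**2)))
    return A, rel


def cc_comparator(
    waveform: APWaveform,
    geom: AxonGeometry,
    sigma_e: float = 1.5,
    r: np.ndarray | None = None,
):
    """Core-conductor (micron-scale) comparator fields.

    The classic volume-conductor description treats the axon as a line source
    in a homogeneous medium of conductivity ``sigma_e`` (S/m): membrane
    current per unit length i_m = -dI/dxi feeds

        V_e(r, xi) = 1/(4 pi sigma_e) * int i_m(xi') / sqrt(r^2 + (xi-xi')^2) dxi'

    and the magnetic field is that of the internal current alone,
    B_cc = mu0 I(xi) / (2 pi r).  Valid for r >> Debye length, where ion
    densities are effectively stationary.

    Returns ``(r, V_e, B_cc)`` with shapes (n_r,), (n_r, n_xi), (n_r, n_xi).
    """
    if sigma_e <= 0:
        raise ValueError("extracellular conductivity must be positive")
    if waveform.I is None:
        raise ValueError("waveform is missing the axial current profile")
    xi = waveform.xi
    I = waveform.I
    if r is None:
        r = np.geomspace(geom.a, geom.R_max, 64)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    i_m = -np.gradient(I, xi, edge_order=2)  # A/m
    dxi = np.gradient(xi)
    # V_e[j, k] = sum_k' i_m[k'] dxi[k'] / (4 pi sigma_e sqrt(r_j^2 + (xi_k - xi_k')^2))
    V_e = np.empty((len(r), len(xi)))
    w = i_m * dxi
    for j, rj in enumerate(r):
        kern = 1.0 / np.sqrt(rj**2 + (xi[:, None] - xi[None, :]) ** 2)
        V_e[j] = kern @ w / (4 * np.pi * sigma_e)
    B_cc = MU0 * I[None, :] / (2 * np.pi * r[:, None])
    return r, V_e, B_cc
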