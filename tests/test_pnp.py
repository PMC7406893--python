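"""Exterior electrodiffusion: boundary data, meshing, and the coupled solve."""

import numpy as np
import pytest

from neuropillar.constants import EPS0, FARADAY
from neuropillar.hh import resting_currents, simulate_membrane_ap, to_traveling_wave
from neuropillar.pnp import (
    AxonGeometry,
    EffectiveSpeciesPair,
    IonSpecies,
    MembraneBC,
    MeshSpec,
    SolverOptions,
    build_mesh,
    debye_length,
    gouy_chapman_potential,
    membrane_boundary,
    solve_pnp,
)

SMALL_GEOM = AxonGeometry(half_length=50e-6)


def small_mesh(n_r=80, n_xi=16):
    return build_mesh(SMALL_GEOM, MeshSpec(n_r=n_r, n_xi=n_xi))


def rest_bc(mesh, sigma):
    xi = mesh.xi_centers
    z = np.zeros_like(xi)
    return MembraneBC(xi=xi, sigma=np.full_like(xi, sigma), F_plus=z, F_minus=z)


# ---------------------------------------------------------------- debye length

def test_debye_length_closed_form():
    lam = debye_length(150.0, eps=80.0, T=310.0)
    from neuropillar.constants import AVOGADRO, BOLTZMANN, ELEMENTARY_CHARGE

    expected = np.sqrt(
        80 * EPS0 * BOLTZMANN * 310
        / (2 * ELEMENTARY_CHARGE**2 * AVOGADRO * 150.0)
    )
    assert lam == pytest.approx(expected, rel=1e-12)
    assert 0.75e-9 < lam < 0.85e-9
    # physiological value lies within a factor 1.3 of 1 nm
    assert 1e-9 / 1.3 < lam < 1.3e-9


def test_debye_length_dilution_scaling():
    assert debye_length(150.0 / 4) == pytest.approx(2 * debye_length(150.0))
    with pytest.raises(ValueError):
        debye_length(0.0)


# --------------------------------------------------------------------- meshing

def test_uniform_mesh_counts_and_spacing():
    # a coarse bookkeeping-only mesh: relax the screening-resolution guard
    mesh = build_mesh(
        SMALL_GEOM, MeshSpec(n_r=10, n_xi=10, growth_ratio=1.0, debye=1e-6)
    )
    assert mesh.n_r == 10 and mesh.n_xi == 10
    dr = np.diff(mesh.r_faces)
    assert np.allclose(dr, dr[0])
    assert mesh.r_faces[0] == SMALL_GEOM.a
    assert mesh.r_faces[-1] == pytest.approx(SMALL_GEOM.R_max)


def test_default_grading_resolves_debye_layer():
    mesh = build_mesh(AxonGeometry(), MeshSpec())
    first = mesh.r_faces[1] - mesh.r_faces[0]
    assert first <= debye_length(150.0) / 5
    # graded: spacing increases monotonically
    assert np.all(np.diff(np.diff(mesh.r_faces)) >= -1e-20)


def test_unresolved_debye_layer_refused():
    # uniform cells of ~25 nm >> Debye/2
    with pytest.raises(ValueError, match="[Dd]ebye|unresolved|screening"):
        build_mesh(SMALL_GEOM, MeshSpec(n_r=100, n_xi=8, growth_ratio=1.0))


# ------------------------------------------------------------------ membrane BC

@pytest.fixture(scope="module")
def ap_waveform():
    series = simulate_membrane_ap(duration=40.0)
    xi = np.linspace(-3e-3, 3e-3, 400)
    return to_traveling_wave(series, v=0.17, xi_grid=xi)


def test_resting_waveform_gives_capacitor_charge_and_zero_flux():
    series = simulate_membrane_ap(duration=20.0)
    from neuropillar.hh import StimulusPulse

    quiet = simulate_membrane_ap(
        stimulus=StimulusPulse(amplitude=0.0), duration=20.0
    )
    xi = np.linspace(-1e-3, 1e-3, 64)
    wf = to_traveling_wave(quiet, v=0.2, xi_grid=xi)
    wf.V_m[:] = wf.params.V_rest
    wf.dVdt[:] = 0.0
    jNa0, jK0, jL0 = resting_currents(wf.params)
    wf.j_Na[:], wf.j_K[:], wf.j_L[:] = jNa0, jK0, jL0
    from neuropillar.hh import axial_current

    wf.I = axial_current(wf)
    bc = membrane_boundary(wf, C_m=5.2e-3)
    assert np.allclose(bc.sigma, 5.2e-3 * (-68e-3), rtol=1e-12)
    assert np.abs(bc.F_plus).max() == 0.0
    assert np.abs(bc.F_minus).max() == 0.0


def test_flux_charge_identity(ap_waveform):
    """e*N_A*(F+ - F-) equals the rest-referenced total ionic current."""
    bc = membrane_boundary(ap_waveform)
    p = ap_waveform.params
    jNa0, jK0, jL0 = resting_currents(p)
    j_total = (
        ap_waveform.j_Na + ap_waveform.j_K + ap_waveform.j_L
        - (jNa0 + jK0 + jL0)
    )
    assert np.allclose(FARADAY * (bc.F_plus - bc.F_minus), j_total, atol=1e-12)


def test_sigma_sign_flips_at_ap_peak(ap_waveform):
    """Resting sigma is negative; at the AP peak the upstroke line charge
    flips it positive (positive membrane field)."""
    bc = membrane_boundary(ap_waveform)
    assert bc.sigma[-1] < 0  # leading end: rest
    assert bc.sigma.max() > 0


# ------------------------------------------------------------------- PNP solve

def test_neutral_boundary_gives_trivial_solution():
    mesh = small_mesh()
    f = solve_pnp(mesh, EffectiveSpeciesPair(), rest_bc(mesh, 0.0), v=0.17)
    assert np.abs(f.V).max() == 0.0
    assert np.abs(f.c_plus - 150.0).max() < 1e-9
    assert np.abs(f.c_minus - 150.0).max() < 1e-9


@pytest.fixture(scope="module")
def rest_double_layer():
    mesh = small_mesh()
    sigma = 5.2e-3 * (-0.068)
    f = solve_pnp(mesh, EffectiveSpeciesPair(), rest_bc(mesh, sigma), v=0.0)
    return mesh, sigma, f


def test_equilibrium_matches_gouy_chapman(rest_double_layer):
    """v=0 rest solve vs the planar closed-form double layer (a >> lambda_D)."""
    mesh, sigma, f = rest_double_layer
    x = mesh.r_centers - SMALL_GEOM.a
    V_num = f.V[:, mesh.n_xi // 2]
    V_gc = gouy_chapman_potential(x, sigma, 150.0, eps=80.0, T=310.0)
    layer = x < 5 * debye_length(150.0)
    err = np.abs(V_num[layer] - V_gc[layer]).max() / np.abs(V_gc[0])
    assert err < 0.02


def test_equilibrium_is_axially_invariant(rest_double_layer):
    mesh, sigma, f = rest_double_layer
    xi_var = np.abs(f.V - f.V[:, [mesh.n_xi // 2]]).max()
    assert xi_var < 1e-6 * np.abs(f.V).max()


def test_rest_signs(rest_double_layer):
    """Resting membrane field negative; Debye layer charge positive."""
    mesh, sigma, f = rest_double_layer
    assert f.membrane_E().max() < 0
    rho = f.charge_density()
    assert rho[0, :].min() > 0  # counter-ion (cation) excess at the wall


def test_far_field_neutral_and_grounded(rest_double_layer):
    mesh, sigma, f = rest_double_layer
    rho = f.charge_density()
    assert np.abs(rho[-1, :]).max() < 1e-6 * np.abs(rho[0, :]).max()
    assert np.abs(f.V[-1, :]).max() < 1e-6


def test_discrete_species_conservation(rest_double_layer):
    """Net co-moving species flux out of every interior cell vanishes
    relative to the dominant face flux (direct residual of the FV system)."""
    from neuropillar.pnp import _FVGrid, _transport_system
    from neuropillar.constants import thermal_voltage

    mesh, sigma, f = rest_double_layer
    g = _FVGrid(mesh)
    Vt = thermal_voltage(310.0)
    for z, sp in ((1, f.ions.cation), (-1, f.ions.anion)):
        M, b = _transport_system(
            g, f.V, z, sp.D, f.v, Vt, 150.0, np.zeros(g.nx)
        )
        c = (f.c_plus if z == 1 else f.c_minus).ravel()
        resid = np.abs(M @ c - b).max()
        flux_scale = sp.D * g.A_r[-1] / g.d_r[-1] * 150.0
        assert resid < 1e-8 * flux_scale
        # per-cell: net flux tiny against the cell's gross flux turnover
        gross = np.abs(M) @ np.abs(c) + np.abs(b)
        assert (np.abs(M @ c - b) / gross).max() < 1e-8


def test_nonconvergence_raises_with_history():
    from neuropillar.pnp import PNPConvergenceError

    mesh = small_mesh(n_r=40)
    with pytest.raises(PNPConvergenceError) as exc:
        solve_pnp(
            mesh,
            EffectiveSpeciesPair(),
            rest_bc(mesh, 5.2e-3 * (-0.068)),
            v=0.0,
            opts=SolverOptions(tol=1e-30, max_iter=3),
        )
    assert len(exc.value.history) == 3


def test_validation_errors():
    with pytest.raises(ValueError):
        IonSpecies("x", 1, -1e-9, 150.0)
    with pytest.raises(ValueError):
        EffectiveSpeciesPair(
            cation=IonSpecies("c", 1, 1e-9, 150.0),
            anion=IonSpecies("a", -1, 1e-9, 100.0),
        )
    with pytest.raises(ValueError):
        AxonGeometry(a=1e-6, R_max=0.5e-6)


# ------------------------------------------------- driven solve on a small mesh

@pytest.fixture(scope="module")
def gaussian_pulse_solution():
    """Gaussian surface-charge pulse riding on the resting layer: a cheap
    stand-in for the AP with the same structure (sign flip, screening)."""
    geom = AxonGeometry(half_length=200e-6)
    mesh = build_mesh(geom, MeshSpec(n_r=120, n_xi=60))
    xi = mesh.xi_centers
    sigma = 5.2e-3 * (-0.068) + 2.7e-3 * np.exp(-(xi**2) / (2 * (30e-6) ** 2))
    z = np.zeros_like(xi)
    bc = MembraneBC(xi=xi, sigma=sigma, F_plus=z, F_minus=z)
    f = solve_pnp(mesh, EffectiveSpeciesPair(), bc, v=0.17)
    return geom, mesh, f


def test_pulse_sign_structure(gaussian_pulse_solution):
    """Membrane field negative at rest, positive under the pulse; exterior
    charge negative under the pulse, positive in the resting layer."""
    geom, mesh, f = gaussian_pulse_solution
    E_m = f.membrane_E()
    assert E_m[0] < 0 and E_m[-1] < 0
    assert E_m.max() > 0
    rho = f.charge_density()
    k_pk = int(np.argmax(E_m))
    assert rho[0, k_pk] < 0
    assert rho[0, 0] > 0


def test_pulse_screened_within_nanometres(gaussian_pulse_solution):
    """The AP-induced field change dies to <5% within a few Debye lengths."""
    geom, mesh, f = gaussian_pulse_solution
    from neuropillar.fields import derive_fields, radial_peak_profile

    maps = derive_fields(f)
    k_pk = maps.peak_xi_index()
    r, E_pk = radial_peak_profile(maps, "E_r", xi_index=k_pk)
    _, E_rest = radial_peak_profile(maps, "E_r", xi_index=mesh.n_xi - 1)
    dE = E_pk - E_rest
    dist = r[np.argmax(np.abs(dE) < 0.05 * abs(dE[0]))] - r[0]
    assert 1e-9 < dist < 5e-9


def test_mesh_refinement_stability():
    """Halving the mesh spacings changes the membrane peak field by <2% and
    the near-membrane solution only slightly."""
    geom = AxonGeometry(half_length=100e-6)

    def solve(n_r, n_xi):
        mesh = build_mesh(geom, MeshSpec(n_r=n_r, n_xi=n_xi))
        xi = mesh.xi_centers
        sigma = 5.2e-3 * (-0.068) + 2.7e-3 * np.exp(
            -(xi**2) / (2 * (20e-6) ** 2)
        )
        z = np.zeros_like(xi)
        bc = MembraneBC(xi=xi, sigma=sigma, F_plus=z, F_minus=z)
        f = solve_pnp(mesh, EffectiveSpeciesPair(), bc, v=0.17)
        return mesh, f

    m1, f1 = solve(80, 24)
    m2, f2 = solve(160, 48)
    assert f1.membrane_E().max() == pytest.approx(
        f2.membrane_E().max(), rel=0.02
    )
    # potential at the membrane line (physical, not BC-imposed)
    V1 = f1.V[0, m1.n_xi // 2]
    V2 = f2.V[0, m2.n_xi // 2]
    assert V1 == pytest.approx(V2, rel=0.05)
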