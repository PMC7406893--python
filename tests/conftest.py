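import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from neuropillar.hh import (
    HHParams,
    StimulusPulse,
    simulate_membrane_ap,
    to_traveling_wave,
)


@pytest.fixture(scope="session")
def default_series():
    """Default-stimulus membrane trajectory, shared across tests."""
    return simulate_membrane_ap(duration=40.0)


@pytest.fixture(scope="session")
def default_waveform(default_series):
    xi = np.linspace(-3e-3, 3e-3, 400)
    return to_traveling_wave(default_series, v=0.17, xi_grid=xi)


@pytest.fixture(scope="session")
def oracle_solution():
    """High-accuracy reference integration of the same membrane equations.

    Independent of the package's fixed-step RK4: scipy's adaptive RK45 at
    tight tolerance on an independently coded right-hand side.
    """
    from scipy.integrate import solve_ivp

    p = HHParams()
    stim = StimulusPulse(amplitude=10.0, t_start=1.0, duration=1.0)

    def rates(u):
        am = (
            0.1 * (25.0 - u) / np.expm1((25.0 - u) / 10.0)
            if abs(25.0 - u) > 1e-9
            else 1.0
        )
        bm = 4.0 * np.exp(-u / 18.0)
        ah = 0.07 * np.exp(-u / 20.0)
        bh = 1.0 / (np.exp((30.0 - u) / 10.0) + 1.0)
        an = (
            0.01 * (10.0 - u) / np.expm1((10.0 - u) / 10.0)
            if abs(10.0 - u) > 1e-9
            else 0.1
        )
        bn = 0.125 * np.exp(-u / 80.0)
        return am, bm, ah, bh, an, bn

    def rhs(t, y):
        V, m, h, n = y
        u = V - p.V_rest
        am, bm, ah, bh, an, bn = rates(u)
        jNa = p.g_Na * m**3 * h * (V - p.E_Na) * 1e-3
        jK = p.g_K * n**4 * (V - p.E_K) * 1e-3
        jL = p.g_L * (V - p.E_L) * 1e-3
        dV = (stim(t) - jNa - jK - jL) / p.C_m
        return [dV, am * (1 - m) - bm * m, ah * (1 - h) - bh * h,
                an * (1 - n) - bn * n]

    am, bm, ah, bh, an, bn = rates(0.0)
    y0 = [p.V_rest, am / (am + bm), ah / (ah + bh), an / (an + bn)]
    t_eval = np.arange(0, 25.0, 0.01)
    sol = solve_ivp(
        rhs, (0, 25.0), y0, t_eval=t_eval, rtol=1e-10, atol=1e-12,
        method="RK45", max_step=0.1,
    )
    assert sol.success
    return sol, stim, p
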