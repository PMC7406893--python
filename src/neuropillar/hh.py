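"""Hodgkin-Huxley membrane dynamics and the frozen traveling-wave action potential.

The membrane is the classic squid-axon conductance model (channels Na, K and
leak with gating variables m, h, n), with all voltages rigidly shifted so that
the resting potential sits at -68 mV, the value appropriate for a mammalian
neurite.  Rate constants may be temperature-scaled with a Q10 factor relative
to the model's original calibration temperature of 6.3 degC; by default no
scaling is applied, because the unscaled kinetics produce the upstroke rate
(and hence axial current and field magnitudes) that the downstream
electrodiffusion stage is calibrated against.

A simulated membrane trajectory is mapped onto a co-moving axial coordinate
xi = -v (t - t_peak) (the wave travels in +z with constant velocity v, and the
voltage peak sits at xi = 0).  The internal axial current follows from the
cable relation I(xi) = (pi a^2 / (rho_i v)) dV_m/dt.

Unit conventions in this module: potentials in mV, time in ms, current
densities in A/m^2, conductances in S/m^2, capacitance in F/m^2.  Note the
happy accident that mV/ms and V/s are numerically identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "HHParams",
    "StimulusPulse",
    "MembraneSeries",
    "APWaveform",
    "SolverDivergence",
    "simulate_membrane_ap",
    "to_traveling_wave",
    "axial_current",
    "rate_constants",
    "resting_gates",
    "resting_currents",
]

T_REF = 279.45  # K, 6.3 degC: calibration temperature of the rate functions


class SolverDivergence(RuntimeError):
    """Raised when the membrane integrator produces a non-finite state."""


@dataclass(frozen=True)
class HHParams:
    """Membrane parameters.

    Conductances in S/m^2, capacitance in F/m^2, potentials in mV.
    ``T`` is the temperature (K) used for Q10 rate scaling relative to 6.3 degC;
    with ``q10 = 1`` (or ``T = 279.45``) the classic kinetics are used unscaled.
    """

    C_m: float = 0.01
    g_Na: float = 1200.0
    g_K: float = 360.0
    g_L: float = 3.0
    V_rest: float = -68.0
    E_Na: float = None  # type: ignore[assignment]
    E_K: float = None  # type: ignore[assignment]
    E_L: float = None  # type: ignore[assignment]
    T: float = T_REF
    q10: float = 3.0

    def __post_init__(self):
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        for name in ("g_Na", "g_K", "g_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        # classic reversal offsets relative to rest
        if self.E_Na is None:
            object.__setattr__(self, "E_Na", self.V_rest + 115.0)
        if self.E_K is None:
            object.__setattr__(self, "E_K", self.V_rest - 12.0)
        if self.E_L is None:
            object.__setattr__(self, "E_L", self.V_rest + 10.613)

    @property
    def rate_scale(self) -> float:
        """Q10 multiplier applied to all gating rates."""
        return float(self.q10 ** ((self.T - T_REF) / 10.0))


@dataclass(frozen=True)
class StimulusPulse:
    """Rectangular stimulus current density pulse (A/m^2, outward-negative
    convention: a positive amplitude depolarizes)."""

    amplitude: float = 1.0
    t_start: float = 1.0  # ms
    duration: float = 0.3  # ms

    def __call__(self, t):
        return np.where(
            (t >= self.t_start) & (t < self.t_start + self.duration),
            self.amplitude,
            0.0,
        )


def _safe_exp_ratio(x):
    """x / expm1(x), continuous through x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    out = np.where(small, 1.0 - x / 2.0, x / np.expm1(np.where(small, 1.0, x)))
    return out


def rate_constants(u):
    """Classic gating rates (1/ms) as functions of u = V - V_rest in mV."""
    u = np.asarray(u, dtype=float)
    alpha_m = 0.1 * 10.0 * _safe_exp_ratio((25.0 - u) / 10.0)
    beta_m = 4.0 * np.exp(-u / 18.0)
    alpha_h = 0.07 * np.exp(-u / 20.0)
    beta_h = 1.0 / (np.exp((30.0 - u) / 10.0) + 1.0)
    alpha_n = 0.01 * 10.0 * _safe_exp_ratio((10.0 - u) / 10.0)
    beta_n = 0.125 * np.exp(-u / 80.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def resting_gates(params: HHParams):
    """Steady-state (m, h, n) at the resting potential."""
    am, bm, ah, bh, an, bn = rate_constants(0.0)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def channel_currents(params: HHParams, V, m, h, n):
    """Per-channel current densities (A/m^2, outward positive); V in mV."""
    j_Na = params.g_Na * m**3 * h * (V - params.E_Na) * 1e-3
    j_K = params.g_K * n**4 * (V - params.E_K) * 1e-3
    j_L = params.g_L * (V - params.E_L) * 1e-3
    return j_Na, j_K, j_L


def resting_currents(params: HHParams):
    """Per-channel current densities at rest (A/m^2)."""
    m0, h0, n0 = resting_gates(params)
    return channel_currents(params, params.V_rest, m0, h0, n0)


@dataclass
class MembraneSeries:
    """Membrane trajectory on a uniform time grid (ms)."""

    t: np.ndarray
    V_m: np.ndarray  # mV
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    j_Na: np.ndarray  # A/m^2, outward positive
    j_K: np.ndarray
    j_L: np.ndarray
    j_stim: np.ndarray
    dVdt: np.ndarray  # V/s (== mV/ms)
    params: HHParams

    @property
    def j_cap(self) -> np.ndarray:
        """Capacitive current density C_m dV/dt (A/m^2)."""
        return self.params.C_m * self.dVdt

    def spike_times(self, threshold: float = 0.0) -> np.ndarray:
        """Times (ms) of V_m maxima above ``threshold`` mV."""
        V = self.V_m
        above = V > threshold
        interior = np.zeros_like(above)
        interior[1:-1] = above[1:-1] & (V[1:-1] >= V[:-2]) & (V[1:-1] > V[2:])
        return self.t[interior]


def _rhs(params: HHParams, stim: Callable, t, state):
    V, m, h, n = state
    u = V - params.V_rest
    am, bm, ah, bh, an, bn = rate_constants(u)
    phi = params.rate_scale
    j_Na, j_K, j_L = channel_currents(params, V, m, h, n)
    dV = (stim(t) - j_Na - j_K - j_L) / params.C_m * 1e-3 * 1e3  # -> mV/ms
    return np.array(
        [
            dV,
            phi * (am * (1 - m) - bm * m),
            phi * (ah * (1 - h) - bh * h),
            phi * (an * (1 - n) - bn * n),
        ]
    )


def simulate_membrane_ap(
    params: HHParams = HHParams(),
    stimulus: StimulusPulse | Callable = StimulusPulse(),
    duration: float = 25.0,
    dt: float = 0.005,
) -> MembraneSeries:
    """Integrate the membrane equations with fixed-step RK4 (4th order).

    ``duration`` and ``dt`` in ms.  The default step (0.005 ms) resolves the
    fastest gating time constant by more than an order of magnitude.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt * params.rate_scale > 0.05:
        raise ValueError(
            f"dt = {dt} ms does not resolve the gating kinetics at "
            f"rate scale {params.rate_scale:.2f} (need dt*scale <= 0.05 ms)"
        )
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps + 1) * dt
    m0, h0, n0 = resting_gates(params)
    state = np.array([params.V_rest, m0, h0, n0])
    traj = np.empty((n_steps + 1, 4))
    dV = np.empty(n_steps + 1)
    for i in range(n_steps + 1):
        traj[i] = state
        k1 = _rhs(params, stimulus, t[i], state)
        dV[i] = k1[0]
        if i == n_steps:
            break
        k2 = _rhs(params, stimulus, t[i] + dt / 2, state + dt / 2 * k1)
        k3 = _rhs(params, stimulus, t[i] + dt / 2, state + dt / 2 * k2)
        k4 = _rhs(params, stimulus, t[i] + dt, state + dt * k3)
        state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise SolverDivergence(
                f"membrane integrator diverged at t = {t[i] + dt:.4f} ms"
            )
        # clip round-off excursions; dynamics keep gates in [0, 1]
        state[1:] = np.clip(state[1:], 0.0, 1.0)
    V, m, h, n = traj.T
    j_Na, j_K, j_L = channel_currents(params, V, m, h, n)
    stim_vals = np.broadcast_to(np.asarray(stimulus(t), dtype=float), t.shape).copy()
    return MembraneSeries(
        t=t, V_m=V, m=m, h=h, n=n,
        j_Na=j_Na, j_K=j_K, j_L=j_L, j_stim=stim_vals, dVdt=dV,
        params=params,
    )


@dataclass
class APWaveform:
    """Frozen co-moving action potential on an axial grid xi (m).

    The wave propagates in +z with velocity ``v`` (m/s); xi = 0 is anchored at
    the V_m peak, positive xi is ahead of the wave.  ``I`` is the internal
    axial current (A, positive in +z), ``a`` the axon exterior radius (m) and
    ``rho_i`` the axoplasm resistivity (Ohm m).
    """

    xi: np.ndarray
    v: float
    V_m: np.ndarray  # mV
    j_Na: np.ndarray  # A/m^2
    j_K: np.ndarray
    j_L: np.ndarray
    dVdt: np.ndarray  # V/s
    a: float = 500e-9
    rho_i: float = 1.0
    params: HHParams = field(default_factory=HHParams)
    I: np.ndarray | None = None

    @property
    def j_ion(self) -> np.ndarray:
        return self.j_Na + self.j_K + self.j_L


def to_traveling_wave(
    series: MembraneSeries,
    v: float,
    xi_grid: np.ndarray,
    a: float = 500e-9,
    rho_i: float = 1.0,
    rest_tol: float = 1.0,
) -> APWaveform:
    """Resample a membrane trajectory onto the co-moving axial coordinate.

    xi = -v (t - t_peak), so later times map to more negative xi (the tail of
    the wave).  Samples outside the simulated window are filled with the
    resting values.  Raises ``ValueError`` if the grid is too short to contain
    the AP footprint (V_m more than ``rest_tol`` mV from rest at either end).
    """
    if v <= 0:
        raise ValueError("conduction velocity must be positive")
    xi_grid = np.asarray(xi_grid, dtype=float)
    i_pk = int(np.argmax(series.V_m))
    t_pk = series.t[i_pk]
    # xi decreasing in t: interpolate on t(xi) = t_pk - xi/v  (seconds -> ms)
    t_of_xi = t_pk - xi_grid / v * 1e3
    p = series.params
    m0, h0, n0 = resting_gates(p)
    jNa0, jK0, jL0 = channel_currents(p, p.V_rest, m0, h0, n0)

    def interp(y, rest):
        return np.interp(t_of_xi, series.t, y, left=rest, right=rest)

    # A steadily propagating AP is stimulus-free: the waveform carries the
    # free membrane response only, C_m dV/dt|free = -(j_Na + j_K + j_L).
    # Keeping the injected pulse in dV/dt would freeze its square edges into
    # the axial-current profile as unphysical discontinuities.
    dVdt_free = series.dVdt - series.j_stim / p.C_m
    # left of the time window (= far ahead in xi) and right (= far behind)
    V = interp(series.V_m, p.V_rest)
    wf = APWaveform(
        xi=xi_grid,
        v=v,
        V_m=V,
        j_Na=interp(series.j_Na, jNa0),
        j_K=interp(series.j_K, jK0),
        j_L=interp(series.j_L, jL0),
        dVdt=interp(dVdt_free, 0.0),
        a=a,
        rho_i=rho_i,
        params=p,
    )
    for end in (0, -1):
        if abs(wf.V_m[end] - p.V_rest) > rest_tol:
            raise ValueError(
                "xi grid too short to contain the AP footprint: "
                f"V_m at grid end = {wf.V_m[end]:.2f} mV "
                f"(rest {p.V_rest:.2f} mV, tol {rest_tol} mV)"
            )
    wf.I = axial_current(wf)
    return wf


def axial_current(waveform: APWaveform) -> np.ndarray:
    """Internal axial current I(xi) = (pi a^2 / (rho_i v)) dV_m/dt, in A.

    Positive I flows in +z (the propagation direction).
    """
    if waveform.rho_i <= 0 or waveform.a <= 0 or waveform.v <= 0:
        raise ValueError("a, rho_i and v must all be positive")
    return (
        np.pi * waveform.a**2 / (waveform.rho_i * waveform.v) * waveform.dVdt
    )
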