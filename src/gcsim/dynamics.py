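"""Deterministic core of the germinal-center model.

Each subclone i carries four coupled compartments -- centroblasts CB_i,
centrocytes CC_i, memory M_i and plasma P_i -- governed by

    dCB_i/dt = rho_CB * D(CB_tot) * CB_i + eta_CC->CB * CC_i
               - (1 - S_d_i) * eta_CB->CC * CB_i
    dCC_i/dt = (1 - S_d_i) * eta_CB->CC * CB_i - eta_CC->CB * CC_i
               - (1 - S_a_i) * mu_CC * CC_i - eta_CC->M * CC_i
               - eta_CC->P * sigma_i * CC_i
    dM_i/dt  = eta_CC->M * CC_i - mu_M * M_i
    dP_i/dt  = eta_CC->P * sigma_i * CC_i - mu_P * P_i

with the density factor D(x) = A^h / (x^h + A^h) modelling non-specific
resource competition, and the survival signals S_d, S_a sigmoidal in the
subclone's *relative* affinity (absolute affinity scaled by the current
population maximum).  Plasma output scales with the *absolute* affinity.

Signals are evaluated once per 6-h division interval and held fixed while the
ODEs are integrated (affinities only change at discrete SHM events, and the
population composition is frozen within an interval by construction).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .params import ModelParams, RateParams, SignalParams
from .state import EmptyPopulationError, GCState

__all__ = [
    "relative_affinities",
    "survival_signal",
    "density_factor",
    "compute_signals",
    "derivatives",
    "integrate_interval",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """ODE solver failure, annotated with population size and time."""


def relative_affinities(sigma) -> np.ndarray:
    """Scale absolute affinities by the population maximum.

    Returns sigma_i / max_j sigma_j, so values lie in (0, 1] and the current
    best binder sits exactly at 1.  The arrival of a higher-affinity subclone
    therefore pushes every existing subclone to a lower relative affinity.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.size == 0:
        raise EmptyPopulationError("relative affinities need >= 1 subclone")
    return sigma / sigma.max()


def survival_signal(sigma_rel, k: float, n: float) -> np.ndarray | float:
    """Sigmoidal signal S(x) = x^n / (k^n + x^n); S(k) = 1/2 exactly."""
    x = np.asarray(sigma_rel, dtype=float)
    xn = x ** n
    out = xn / (k ** n + xn)
    return out if out.ndim else float(out)


def density_factor(cb_total: float, capacity: float, hill_h: float) -> float:
    """Density-limited proliferation factor A^h / (x^h + A^h).

    Computed as a logistic in log space, 1 / (1 + exp(h*(log x - log A))),
    which is exact and immune to overflow (A^20 with A = 8000 exceeds float
    range in the naive form).
    """
    if cb_total <= 0:
        return 1.0
    return float(expit(-hill_h * (np.log(cb_total) - np.log(capacity))))


def compute_signals(state: GCState, signals: SignalParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-subclone (S_d, S_a) at the start of an interval.

    During the monoclonal-expansion phase (time < clamp_days) both signals
    are pinned to ``clamp_value`` for every subclone; afterwards they follow
    the sigmoid of the relative affinity.
    """
    n = state.n_subclones
    if state.time < signals.clamp_days:
        s = np.full(n, signals.clamp_value)
        return s, s.copy()
    rel = relative_affinities(state.sigma)
    s_d = np.asarray(survival_signal(rel, signals.k_d, signals.n_d))
    s_a = np.asarray(survival_signal(rel, signals.k_a, signals.n_a))
    return s_d, s_a


def derivatives(
    cb: np.ndarray,
    cc: np.ndarray,
    mem: np.ndarray,
    plasma: np.ndarray,
    sigma: np.ndarray,
    s_d: np.ndarray,
    s_a: np.ndarray,
    rates: RateParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Right-hand side of the four compartment equations, vectorized."""
    dens = density_factor(float(cb.sum()), rates.capacity, rates.hill_h)
    diff_cb_cc = (1.0 - s_d) * rates.eta_cb_cc * cb
    plasma_in = rates.eta_cc_p * sigma * cc
    d_cb = rates.rho_cb * dens * cb + rates.eta_cc_cb * cc - diff_cb_cc
    d_cc = (diff_cb_cc - rates.eta_cc_cb * cc - (1.0 - s_a) * rates.mu_cc * cc
            - rates.eta_cc_m * cc - plasma_in)
    d_m = rates.eta_cc_m * cc - rates.mu_m * mem
    d_p = plasma_in - rates.mu_p * plasma
    return d_cb, d_cc, d_m, d_p


def integrate_interval(
    state: GCState,
    dt: float,
    rates: RateParams,
    s_d: np.ndarray,
    s_a: np.ndarray,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> GCState:
    """Advance all compartments by ``dt`` days with signals held fixed.

    Mutates ``state`` in place (compartment arrays and time) and returns it.
    Small integrator undershoots below zero are clipped; the solver is an
    adaptive Runge-Kutta pair at the configured tolerances (the per-interval
    system, with rates of order 1-10 per day over a 0.25-day interval, is not
    stiff).
    """
    n = state.n_subclones
    if n == 0 or dt == 0:
        state.time += dt
        return state
    if dt < 0:
        raise ValueError("dt must be positive")
    y0 = np.concatenate([state.cb, state.cc, state.mem, state.plasma])
    sigma = state.sigma

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        cb, cc, mem, plasma = y[:n], y[n:2 * n], y[2 * n:3 * n], y[3 * n:]
        return np.concatenate(derivatives(cb, cc, mem, plasma, sigma, s_d, s_a, rates))

    sol = solve_ivp(rhs, (0.0, dt), y0, method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed at t={state.time:g} d with "
            f"{n} subclones: {sol.message}")
    y = np.clip(sol.y[:, -1], 0.0, None)
    state.cb, state.cc = y[:n].copy(), y[n:2 * n].copy()
    state.mem, state.plasma = y[2 * n:3 * n].copy(), y[3 * n:].copy()
    state.time += dt
    return state
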