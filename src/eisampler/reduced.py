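"""Analytic reductions of the network dynamics.

For fixed contrast z the noise-free network collapses, component by
component, to an undamped harmonic oscillator around the posterior mean with
stiffness equal to the posterior precision; its frequency gives the
contrast--frequency law. Substituting the instantaneous contrast estimate
z ~ x/(A u) yields a one-dimensional nonlinear oscillator whose first
excursion reproduces the stimulus-onset transient.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "reduced_accel_fixed_z",
    "oscillation_frequency",
    "reduced_accel_inferred_z",
    "simulate_reduced",
    "initial_excursion",
]


def _check_params(tau: float, sigma_x_sq: float) -> None:
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not (0.0 < sigma_x_sq < 1.0):
        raise ValueError("sigma_x_sq must lie in (0, 1)")


def reduced_accel_fixed_z(u, u_bar, z: float, tau: float, sigma_x_sq: float):
    """u'' = -(1/tau^2) (z^2/sigma_x^2 + 1/(1 - sigma_x^2)) (u - u_bar).

    The bracket is the (whitened) posterior precision; each component of u
    evolves independently. Accepts scalars or arrays.
    """
    _check_params(tau, sigma_x_sq)
    stiffness = z**2 / sigma_x_sq + 1.0 / (1.0 - sigma_x_sq)
    return -(stiffness / tau**2) * (np.asarray(u) - np.asarray(u_bar))


def oscillation_frequency(z: float, tau: float, sigma_x_sq: float) -> float:
    """f(z) = (1/2 pi tau) sqrt(z^2/sigma_x^2 + 1/(1 - sigma_x_sq)), in Hz."""
    _check_params(tau, sigma_x_sq)
    return math.sqrt(z**2 / sigma_x_sq + 1.0 / (1.0 - sigma_x_sq)) / (
        2.0 * math.pi * tau
    )


def reduced_accel_inferred_z(
    u, x: float, A: float, u_bar: float, tau: float, sigma_x_sq: float,
    eps_rel: float = 1e-3,
):
    """u'' with the contrast inferred instantaneously, z ~ x / (A u).

    Stiffness x^2/(sigma_x^2 A^2 u^2) + 1/(1 - sigma_x_sq): very stiff for
    small |u|, soft for large |u|. |u| is floored at eps_rel * |u_bar| to
    guard the division.
    """
    _check_params(tau, sigma_x_sq)
    u = np.asarray(u, dtype=float)
    floor = eps_rel * abs(u_bar)
    u_eff = np.where(np.abs(u) < floor, floor, np.abs(u))
    stiffness = x**2 / (sigma_x_sq * A**2 * u_eff**2) + 1.0 / (1.0 - sigma_x_sq)
    return -(stiffness / tau**2) * (u - u_bar)


def simulate_reduced(
    model: str,
    u0,
    u_dot0,
    duration: float,
    dt: float = 1e-5,
    *,
    u_bar=1.0,
    tau: float = 0.010,
    sigma_x_sq: float = 0.1,
    z: float | None = None,
    x: float | None = None,
    A: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Velocity-Verlet integration of a reduced model.

    ``model`` is 'fixed_z' (requires z) or 'inferred_z' (requires x).
    Returns (times, u(t), u_dot(t)).
    """
    if model == "fixed_z":
        if z is None:
            raise ValueError("fixed_z model requires z")
        accel = lambda u: reduced_accel_fixed_z(u, u_bar, z, tau, sigma_x_sq)
    elif model == "inferred_z":
        if x is None:
            raise ValueError("inferred_z model requires x")
        accel = lambda u: reduced_accel_inferred_z(u, x, A, u_bar, tau, sigma_x_sq)
    else:
        raise ValueError("model must be 'fixed_z' or 'inferred_z'")
    n_steps = int(round(duration / dt))
    u = np.asarray(u0, dtype=float).copy()
    ud = np.asarray(u_dot0, dtype=float).copy()
    us = np.empty((n_steps + 1,) + u.shape)
    uds = np.empty_like(us)
    us[0], uds[0] = u, ud
    a = accel(u)
    for k in range(n_steps):
        u = u + ud * dt + 0.5 * a * dt * dt
        a_new = accel(u)
        ud = ud + 0.5 * (a + a_new) * dt
        a = a_new
        us[k + 1], uds[k + 1] = u, ud
        if not np.all(np.isfinite(u)):
            raise RuntimeError(f"reduced integration blew up at t = {(k+1)*dt:.5f} s")
    times = np.arange(n_steps + 1) * dt
    return times, us, uds


def initial_excursion(
    times: np.ndarray, u: np.ndarray, u_bar: float
) -> dict:
    """Quantify the first excursion of a reduced trajectory above u_bar.

    Finds the *first local maximum* of u above u_bar, then the first return
    to u_bar after it. (A global argmax is wrong for a conservative
    oscillator: tiny integrator energy drift can make a later cycle's peak
    marginally higher.) Returns peak value, time of peak, and excursion
    duration (onset to the return crossing), all in the units of ``times``.
    """
    u = np.asarray(u)
    above = u > u_bar
    if not above.any():
        return {"peak": float(u.max()), "t_peak": float(times[int(u.argmax())]),
                "duration": float("nan"), "found": False}
    # First local maximum while above u_bar.
    i = int(np.argmax(above))  # first index above
    j = i
    while j + 1 < len(u) and u[j + 1] >= u[j]:
        j += 1
    peak, t_peak = float(u[j]), float(times[j])
    # First return to u_bar after the peak.
    k = j
    while k + 1 < len(u) and u[k + 1] > u_bar:
        k += 1
    if k + 1 >= len(u):
        return {"peak": peak, "t_peak": t_peak, "duration": float("nan"),
                "found": False}
    # Linear interpolation of the crossing time.
    t_cross = times[k] + (times[k + 1] - times[k]) * (u[k] - u_bar) / (
        u[k] - u[k + 1]
    )
    return {"peak": peak, "t_peak": t_peak, "duration": float(t_cross),
            "found": True}
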