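"""The sampler dynamics: three continuous-time stochastic samplers.

Modes:
- ``hamiltonian``: the full EI network. Excitatory cells u and inhibitory
  cells v implement Hamiltonian dynamics over the GSM posterior; a scalar
  (z, v_z) subsystem infers the contrast jointly, with a reflecting boundary
  at z = 0.
- ``hamiltonian_fixed_z``: same u, v network with z clamped (z-subsystem
  frozen).
- ``langevin``: the control sampler; no auxiliary populations, drift
  I_input / tau_L, matched noise.

Integration is Euler-Maruyama with a shared batched core, so a single
trajectory and a many-repetition experiment use identical code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gsm import GSMParams, input_current, sample_stimulus, z_input_current
from .parameters import NetworkParams

__all__ = [
    "NetworkState",
    "SimulationProtocol",
    "Trajectory",
    "IntegrationError",
    "drift_hamiltonian",
    "drift_hamiltonian_pure",
    "drift_z",
    "drift_z_pure",
    "drift_langevin",
    "simulate",
    "simulate_batch",
    "apply_offset",
    "OffsetModel",
    "linearized_drift_matrix",
    "stationary_covariance_target",
    "stationary_covariance_lyapunov",
]

MODES = ("hamiltonian", "langevin", "hamiltonian_fixed_z")


class IntegrationError(RuntimeError):
    """The state became non-finite during integration."""


@dataclass(frozen=True)
class NetworkState:
    """Instantaneous network state (u, v, z, v_z)."""

    u: np.ndarray
    v: np.ndarray
    z: float
    v_z: float

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError("z must be nonnegative")
        if not (
            np.all(np.isfinite(self.u))
            and np.all(np.isfinite(self.v))
            and np.isfinite(self.z)
            and np.isfinite(self.v_z)
        ):
            raise ValueError("state entries must be finite")


@dataclass(frozen=True)
class SimulationProtocol:
    """Stimulus-onset simulation protocol.

    ``t_pre`` seconds of no-stimulus (z_gen = 0 draw) equilibration, then
    ``t_post`` seconds with a z_gen draw. ``init='prior'`` starts each run
    from a prior draw; with t_pre = 0 the stimulus is on from t = 0.
    """

    t_pre: float = 1.0
    t_post: float = 2.0
    z_gen: float = 1.0
    dt: float = 5e-5
    mode: str = "hamiltonian"
    z_fixed: float | None = None
    noise_seed: int = 0
    record_every: int = 10
    init: str = "prior"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "hamiltonian_fixed_z" and self.z_fixed is None:
            raise ValueError("hamiltonian_fixed_z requires z_fixed")
        if self.dt <= 0 or self.dt > 5e-4:
            raise ValueError("dt must be positive and much smaller than tau")
        if self.t_pre < 0 or self.t_post <= 0:
            raise ValueError("t_pre must be >= 0 and t_post > 0")
        if self.z_gen < 0:
            raise ValueError("z_gen must be nonnegative")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.init != "prior":
            raise ValueError("init must be 'prior'")


@dataclass(frozen=True)
class Trajectory:
    """A recorded run: times (s), state stacks, and the onset index."""

    times: np.ndarray
    u_t: np.ndarray
    v_t: np.ndarray | None
    z_t: np.ndarray
    v_z_t: np.ndarray | None
    onset_index: int
    protocol: SimulationProtocol

    @property
    def fs(self) -> float:
        """Sampling rate of the recorded points, Hz."""
        return 1.0 / (self.protocol.dt * self.protocol.record_every)


# ---------------------------------------------------------------------------
# Drift functions (single-state, used directly in tests and diagnostics)
# ---------------------------------------------------------------------------

def drift_hamiltonian(
    state: NetworkState, net: NetworkParams, gsm: GSMParams, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """du/dt and dv/dt of the EI network (diffusion sqrt(2/tau_L) on both)."""
    Iin = input_current(gsm, state.u, state.z, x)
    r = net.tau / net.tau_L
    du = (net.W_uu @ state.u - net.W_uv @ state.v + r * Iin) / net.tau
    dv = (net.W_vu @ state.u - net.W_vv @ state.v - Iin) / net.tau
    return du, dv


def drift_z(
    state: NetworkState, net: NetworkParams, gsm: GSMParams, x: np.ndarray
) -> tuple[float, float]:
    """dz/dt and dv_z/dt of the scalar contrast subsystem (B = M = 1)."""
    Iz = z_input_current(gsm, state.u, state.z, x)
    w_zz, w_zv, w_vz, w_vv = net.z_weights
    r = net.tau / net.tau_L
    dz = (w_zz * state.z - w_zv * state.v_z + r * Iz) / net.tau
    dv_z = (w_vz * state.z - w_vv * state.v_z - Iz) / net.tau
    return dz, dv_z


def drift_hamiltonian_pure(
    state: NetworkState, net: NetworkParams, gsm: GSMParams, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """The frictionless (energy-conserving) component of the EI drift.

    Drops the tau/tau_L terms of the weight matrices and the tau/tau_L
    injection of I_input into u; what remains conserves the joint log-density
    (potential plus momentum terms) exactly in continuous time.
    """
    Iin = input_current(gsm, state.u, state.z, x)
    MB = net.M @ net.B
    du = (net.B.T @ net.M @ (net.B @ state.u) - net.B.T @ (net.M @ state.v)) / net.tau
    dv = (MB @ state.u - net.M @ state.v - Iin) / net.tau
    return du, dv


def drift_z_pure(
    state: NetworkState, net: NetworkParams, gsm: GSMParams, x: np.ndarray
) -> tuple[float, float]:
    """Frictionless component of the z-subsystem drift (B = M = 1)."""
    Iz = z_input_current(gsm, state.u, state.z, x)
    dz = (state.z - state.v_z) / net.tau
    dv_z = (state.z - state.v_z - Iz) / net.tau
    return dz, dv_z


def drift_langevin(
    state: NetworkState, net: NetworkParams, gsm: GSMParams, x: np.ndarray
) -> np.ndarray:
    """du/dt of the Langevin control sampler (no v population)."""
    return input_current(gsm, state.u, state.z, x) / net.tau_L


# ---------------------------------------------------------------------------
# Batched Euler-Maruyama core
# ---------------------------------------------------------------------------

def _init_batch(
    gsm: GSMParams, net: NetworkParams, n_batch: int, rng: np.random.Generator,
    mode: str, z_fixed: float | None,
):
    n = gsm.n_features
    Lc = np.linalg.cholesky(gsm.C)
    u = rng.standard_normal((n_batch, n)) @ Lc.T
    if mode == "langevin":
        v = None
    else:
        Lm = np.linalg.cholesky(np.linalg.inv(net.M))
        v = u @ net.B.T + rng.standard_normal((n_batch, n)) @ Lm.T
    if z_fixed is not None:
        z = np.full(n_batch, float(z_fixed))
        v_z = z.copy()
    else:
        z = np.abs(rng.standard_normal(n_batch))
        v_z = z + rng.standard_normal(n_batch)
    return u, v, z, v_z


def simulate_batch(
    protocol: SimulationProtocol,
    net: NetworkParams,
    gsm: GSMParams,
    X_pre: np.ndarray,
    X_post: np.ndarray,
    record: tuple[str, ...] = ("u", "v", "z", "v_z"),
) -> dict:
    """Integrate ``n_batch`` independent runs sharing a protocol.

    ``X_pre`` and ``X_post`` are (n_batch, n_pixels) stimulus arrays (rows may
    repeat a shared stimulus). Returns a dict with 'times', 'onset_index' and
    the requested recorded stacks of shape (n_times, n_batch, ...).
    """
    if X_pre.shape != X_post.shape or X_pre.ndim != 2:
        raise ValueError("X_pre and X_post must be matching 2-D arrays")
    n_batch = X_post.shape[0]
    n = gsm.n_features
    dt = protocol.dt
    rng = np.random.default_rng(protocol.noise_seed)
    mode = protocol.mode
    z_fixed = protocol.z_fixed
    fixed_z = z_fixed is not None

    u, v, z, v_z = _init_batch(gsm, net, n_batch, rng, mode, z_fixed)

    n_pre = int(round(protocol.t_pre / dt))
    n_post = int(round(protocol.t_post / dt))
    n_steps = n_pre + n_post
    rec_idx = np.arange(0, n_steps + 1, protocol.record_every)
    times = rec_idx * dt - protocol.t_pre
    onset_index = int(np.searchsorted(times, 0.0))

    out: dict[str, list] = {k: [] for k in record}
    r = net.tau / net.tau_L
    amp = np.sqrt(2.0 / net.tau_L * dt)
    Ci = gsm.C_inv
    G = gsm.A.T @ gsm.A
    ATX_pre = X_pre @ gsm.A
    ATX_post = X_post @ gsm.A
    w_zz, w_zv, w_vz, w_vv = net.z_weights
    sx2 = gsm.sigma_x_sq

    def _record():
        if "u" in record:
            out["u"].append(u.copy())
        if "v" in record and v is not None:
            out["v"].append(v.copy())
        if "z" in record:
            out["z"].append(z.copy())
        if "v_z" in record:
            out["v_z"].append(v_z.copy())

    _record()
    for step in range(n_steps):
        ATx = ATX_pre if step < n_pre else ATX_post
        Gu = u @ G.T
        Iin = (z[:, None] / sx2) * (ATx - z[:, None] * Gu) - u @ Ci.T
        if mode == "langevin":
            u_new = u + (Iin / net.tau_L) * dt + amp * rng.standard_normal((n_batch, n))
            if not fixed_z:
                uATx = np.einsum("ri,ri->r", u, ATx)
                uGu = np.einsum("ri,ri->r", u, Gu)
                Iz = (uATx - z * uGu) / sx2 - z
                z = z + (Iz / net.tau_L) * dt + amp * rng.standard_normal(n_batch)
                z = np.abs(z)
            u = u_new
        else:
            du = (u @ net.W_uu.T - v @ net.W_uv.T + r * Iin) / net.tau
            dv = (u @ net.W_vu.T - v @ net.W_vv.T - Iin) / net.tau
            u_new = u + du * dt + amp * rng.standard_normal((n_batch, n))
            v = v + dv * dt + amp * rng.standard_normal((n_batch, n))
            if not fixed_z:
                uATx = np.einsum("ri,ri->r", u, ATx)
                uGu = np.einsum("ri,ri->r", u, Gu)
                Iz = (uATx - z * uGu) / sx2 - z
                dz = (w_zz * z - w_zv * v_z + r * Iz) / net.tau
                dv_z = (w_vz * z - w_vv * v_z - Iz) / net.tau
                z = z + dz * dt + amp * rng.standard_normal(n_batch)
                v_z = v_z + dv_z * dt + amp * rng.standard_normal(n_batch)
                neg = z < 0
                if neg.any():
                    z[neg] = -z[neg]
                    v_z[neg] = -v_z[neg]
            u = u_new
        if (step + 1) % protocol.record_every == 0:
            _record()
        if (step + 1) % 4000 == 0 and not np.all(np.isfinite(u)):
            raise IntegrationError(
                f"non-finite state at t = {(step + 1) * dt - protocol.t_pre:.4f} s "
                f"(dt = {dt:g})"
            )
    if not np.all(np.isfinite(u)):
        raise IntegrationError(f"non-finite state at end of run (dt = {dt:g})")

    result = {
        "times": times[: len(out[record[0]])],
        "onset_index": onset_index,
    }
    for k in record:
        if out[k]:
            result[k] = np.array(out[k])
        else:
            result[k] = None
    return result


def simulate(
    protocol: SimulationProtocol,
    net: NetworkParams,
    gsm: GSMParams,
    x_post: np.ndarray | None = None,
    x_pre: np.ndarray | None = None,
) -> Trajectory:
    """Run one trajectory under the stimulus-onset protocol.

    Stimuli not supplied are drawn from the generative model (a z = 0 draw
    for the pre epoch, a z_gen draw for the post epoch) using a stream
    derived from ``protocol.noise_seed``, so a protocol fully determines the
    run.
    """
    stim_rng = np.random.default_rng(np.random.SeedSequence(protocol.noise_seed).spawn(1)[0])
    if x_pre is None:
        x_pre = sample_stimulus(gsm, 0.0, stim_rng).x
    if x_post is None:
        x_post = sample_stimulus(gsm, protocol.z_gen, stim_rng).x
    res = simulate_batch(
        protocol, net, gsm, x_pre[None, :], x_post[None, :],
        record=("u", "z") if protocol.mode == "langevin" else ("u", "v", "z", "v_z"),
    )
    return Trajectory(
        times=res["times"],
        u_t=res["u"][:, 0, :],
        v_t=None if protocol.mode == "langevin" else res["v"][:, 0, :],
        z_t=res["z"][:, 0],
        v_z_t=None if protocol.mode == "langevin" else res["v_z"][:, 0],
        onset_index=res["onset_index"],
        protocol=protocol,
    )


# ---------------------------------------------------------------------------
# Stationary-law oracles (fixed z)
# ---------------------------------------------------------------------------

def linearized_drift_matrix(net: NetworkParams, sigma_inv: np.ndarray) -> np.ndarray:
    """Drift matrix F of the fixed-z (u, v) fluctuations around the mean.

    d(du, dv)/dt = F (du, dv) with diffusion sqrt(2/tau_L) on every
    coordinate.
    """
    n = net.n
    F = np.empty((2 * n, 2 * n))
    F[:n, :n] = net.W_uu - (net.tau / net.tau_L) * sigma_inv
    F[:n, n:] = -net.W_uv
    F[n:, :n] = net.W_vu + sigma_inv
    F[n:, n:] = -net.W_vv
    return F / net.tau


def stationary_covariance_target(net: NetworkParams, sigma: np.ndarray) -> np.ndarray:
    """Block-Gaussian stationary covariance of (u, v) for fixed z.

    [[Sigma, Sigma B^T], [B Sigma, M^-1 + B Sigma B^T]] — u marginally follows
    the posterior, v tracks B u with M^-1 momentum noise.
    """
    B = net.B
    top = np.hstack([sigma, sigma @ B.T])
    bottom = np.hstack([B @ sigma, net.M_inv + B @ sigma @ B.T])
    return np.vstack([top, bottom])


def stationary_covariance_lyapunov(
    net: NetworkParams, sigma_inv: np.ndarray
) -> np.ndarray:
    """Brute-force OU stationary covariance via the Lyapunov equation."""
    from scipy import linalg as sla

    F = linearized_drift_matrix(net, sigma_inv)
    Q = (2.0 / net.tau_L) * np.eye(2 * net.n)
    return sla.solve_continuous_lyapunov(F, -Q)


# ---------------------------------------------------------------------------
# Offset (positivity) transformation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OffsetModel:
    """A GSM with prior mean b: u ~ N(b, C), x ~ N(z A (u - b), sigma_x^2 I).

    The data distribution P(x) and the dynamics are unchanged; u-trajectories
    and posterior means are shifted by b.
    """

    base: GSMParams
    b: np.ndarray

    def sample_stimulus(self, z_gen: float, rng) -> "Stimulus":
        from .gsm import Stimulus

        s = sample_stimulus(self.base, z_gen, rng)
        return Stimulus(x=s.x, z_gen=s.z_gen, u_gen=s.u_gen + self.b, seed=s.seed)

    def posterior_u(self, x: np.ndarray, z: float):
        from .gsm import PosteriorSummary, posterior_u

        p = posterior_u(self.base, x, z)
        return PosteriorSummary(mean=p.mean + self.b, cov=p.cov, z=p.z)

    def input_current(self, u: np.ndarray, z: float, x: np.ndarray) -> np.ndarray:
        return input_current(self.base, u - self.b, z, x)


def apply_offset(gsm: GSMParams, b: np.ndarray) -> OffsetModel:
    """Shift the prior mean to b without changing P(x) or the dynamics."""
    b = np.asarray(b, dtype=float)
    if b.shape != (gsm.n_features,) or not np.all(np.isfinite(b)):
        raise ValueError("b must be a finite n_features vector")
    return OffsetModel(base=gsm, b=b)
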