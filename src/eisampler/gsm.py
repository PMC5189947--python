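"""The Gaussian scale mixture (GSM) generative model and its exact posteriors.

Generative model: u ~ N(0, C), z ~ TruncNormal(0, 1, z >= 0),
x | u, z ~ N(z A u, sigma_x^2 I). Conditional posterior over u given (x, z)
is Gaussian; the marginal posterior over (u, z) given x is computed by 1-D
quadrature over z. Also provides the joint log-density (energy) and the
gradient currents that drive the sampler network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .parameters import GSMParams, NetworkParams

__all__ = [
    "Stimulus",
    "PosteriorSummary",
    "MarginalPosterior",
    "sample_stimulus",
    "posterior_u",
    "marginal_posterior",
    "log_joint",
    "total_energy",
    "input_current",
    "z_input_current",
]


@dataclass(frozen=True)
class Stimulus:
    """A generated image patch with its generative latent variables."""

    x: np.ndarray
    z_gen: float
    u_gen: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.z_gen < 0:
            raise ValueError("z_gen must be nonnegative")


@dataclass(frozen=True)
class PosteriorSummary:
    """Exact conditional posterior over u given (x, z): N(mean, cov)."""

    mean: np.ndarray
    cov: np.ndarray
    z: float


@dataclass(frozen=True)
class MarginalPosterior:
    """Marginal posterior moments given x (z integrated out by quadrature)."""

    mean_u: np.ndarray
    var_u: np.ndarray
    mean_z: float
    sd_z: float
    z_grid: np.ndarray
    z_pdf: np.ndarray


def sample_stimulus(
    params: GSMParams, z_gen: float, rng: np.random.Generator | int
) -> Stimulus:
    """Draw u_gen ~ N(0, C) and x ~ N(z_gen A u_gen, sigma_x^2 I)."""
    if z_gen < 0:
        raise ValueError("z_gen must be nonnegative")
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    u_gen = rng.multivariate_normal(np.zeros(params.n_features), params.C,
                                    method="cholesky")
    x = z_gen * params.A @ u_gen + np.sqrt(params.sigma_x_sq) * rng.standard_normal(
        params.n_pixels
    )
    return Stimulus(x=x, z_gen=float(z_gen), u_gen=u_gen, seed=seed)


def posterior_u(params: GSMParams, x: np.ndarray, z: float) -> PosteriorSummary:
    """Sigma(z) = (C^-1 + z^2/sigma_x^2 A^T A)^-1; u_bar = z/sigma_x^2 Sigma A^T x."""
    if z < 0:
        raise ValueError("z must be nonnegative")
    gram = params.A.T @ params.A
    precision = params.C_inv + (z**2 / params.sigma_x_sq) * gram
    try:
        cf = sla.cho_factor((precision + precision.T) / 2.0)
    except sla.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"posterior precision not PD (condition number "
            f"{np.linalg.cond(precision):.3e})"
        ) from exc
    cov = sla.cho_solve(cf, np.eye(params.n_features))
    cov = (cov + cov.T) / 2.0
    mean = (z / params.sigma_x_sq) * (cov @ (params.A.T @ x))
    return PosteriorSummary(mean=mean, cov=cov, z=float(z))


def marginal_posterior(
    params: GSMParams, x: np.ndarray, z_max: float = 6.0, n_grid: int = 801
) -> MarginalPosterior:
    """Marginal posterior moments of (u, z) given x via a 1-D z-grid.

    Works in the n-dimensional feature subspace (QR reduction of A) so the
    per-gridpoint likelihood is an O(n) eigen-reweighting.
    """
    A, C, sx2 = params.A, params.C, params.sigma_x_sq
    n = params.n_features
    Q, R = np.linalg.qr(A)
    y = Q.T @ x
    resid_sq = float(x @ x - y @ y)  # component of x orthogonal to range(A)
    S = R @ C @ R.T
    w, V = np.linalg.eigh((S + S.T) / 2.0)
    yt = V.T @ y

    zs = np.linspace(0.0, z_max, n_grid)
    # Truncated-normal prior T(z; 0, 1, z>=0): density ∝ exp(-z^2/2) on z >= 0.
    log_post = np.empty_like(zs)
    for i, z in enumerate(zs):
        d = z * z * w + sx2
        log_post[i] = (
            -0.5 * np.sum(yt * yt / d)
            - 0.5 * np.sum(np.log(d))
            - 0.5 * resid_sq / sx2
            - 0.5 * z * z
        )
    log_post -= log_post.max()
    pdf = np.exp(log_post)
    norm = np.trapezoid(pdf, zs)
    pdf /= norm

    mean_z = float(np.trapezoid(pdf * zs, zs))
    var_z = float(np.trapezoid(pdf * zs * zs, zs)) - mean_z**2
    sd_z = float(np.sqrt(max(var_z, 0.0)))

    # Conditional moments on the grid, mixed over P(z | x).
    Rinv = np.linalg.inv(R)
    means = np.empty((n_grid, n))
    second = np.zeros((n_grid, n))
    for i, z in enumerate(zs):
        d = z * z * w + sx2
        # Sigma(z) = Rinv V diag(sx2 * w / d) V^T Rinv^T ; u_bar per the
        # conditional-posterior formula expressed in the reduced coordinates.
        core = (z * w / d) * yt
        means[i] = Rinv @ (V @ core)
        diag_cov = (Rinv @ V) ** 2 @ (sx2 * w / d)
        second[i] = means[i] ** 2 + diag_cov
    mean_u = np.trapezoid(pdf[:, None] * means, zs, axis=0)
    e2 = np.trapezoid(pdf[:, None] * second, zs, axis=0)
    var_u = np.maximum(e2 - mean_u**2, 1e-300)
    return MarginalPosterior(
        mean_u=mean_u, var_u=var_u, mean_z=mean_z, sd_z=sd_z, z_grid=zs, z_pdf=pdf
    )


def log_joint(
    gsm: GSMParams,
    net: NetworkParams,
    u: np.ndarray,
    v: np.ndarray,
    z: float,
    x: np.ndarray,
) -> float:
    """log P(u | x, z) + log N(v; B u, M^-1), up to additive constants."""
    resid = x - z * (gsm.A @ u)
    lp = -0.5 * (resid @ resid) / gsm.sigma_x_sq
    lp += -0.5 * u @ (gsm.C_inv @ u)
    dv = v - net.B @ u
    lp += -0.5 * dv @ (net.M @ dv)
    return float(lp)


def total_energy(
    gsm: GSMParams,
    net: NetworkParams,
    u: np.ndarray,
    v: np.ndarray,
    z: float,
    v_z: float,
    x: np.ndarray,
) -> float:
    """Full conserved quantity of the noise-free Hamiltonian flow.

    log P(u, z | x) + log N(v; B u, M^-1) + log N(v_z; z, 1), up to constants.
    """
    lp = log_joint(gsm, net, u, v, z, x)
    lp += -0.5 * z * z  # truncated-normal prior on z (z >= 0)
    lp += -0.5 * (v_z - z) ** 2
    return float(lp)


def input_current(
    gsm: GSMParams, u: np.ndarray, z: float, x: np.ndarray
) -> np.ndarray:
    """I_input = z/sigma_x^2 A^T (x - z A u) - C^-1 u = Sigma(z)^-1 (u_bar - u)."""
    return (z / gsm.sigma_x_sq) * (gsm.A.T @ (x - z * (gsm.A @ u))) - gsm.C_inv @ u


def z_input_current(
    gsm: GSMParams, u: np.ndarray, z: float, x: np.ndarray
) -> float:
    """I_z = 1/sigma_x^2 (A u)^T (x - z A u) - z (prior gradient -z on z > 0)."""
    Au = gsm.A @ u
    return float((Au @ (x - z * Au)) / gsm.sigma_x_sq - z)
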