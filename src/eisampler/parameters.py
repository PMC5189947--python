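"""Model and network parameter construction.

Builds every constant of the Gaussian-scale-mixture (GSM) image model and of
the Hamiltonian excitatory-inhibitory (EI) sampler network from first
principles: the Gabor filter bank, the whitened prior covariance, the
Dale's-law-compatible mass and weight matrices, and the biophysical estimates
behind the two time constants.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaborBankSpec",
    "GSMParams",
    "NetworkParams",
    "BiophysEstimate",
    "DegenerateBasisError",
    "DalesLawError",
    "default_gabor_spec",
    "build_gabor_bank",
    "build_prior_covariance",
    "build_mass_matrix",
    "build_weights",
    "build_z_weights",
    "estimate_sigma_x",
    "estimate_tau_L",
    "propagate_lognormal",
    "default_model",
]


class DegenerateBasisError(ValueError):
    """The filter bank's Gram matrix is singular or the clipped mass matrix is not PD."""


class DalesLawError(ValueError):
    """A constructed weight matrix has a negative element."""


# ---------------------------------------------------------------------------
# Gabor bank
# ---------------------------------------------------------------------------

def _default_locations() -> tuple[tuple[float, float], ...]:
    # Center plus four corners, 1/6 image-width in from each edge
    # (offset measured to the envelope center).
    e = 1.0 / 6.0
    return ((0.5, 0.5), (e, e), (e, 1 - e), (1 - e, e), (1 - e, 1 - e))


@dataclass(frozen=True)
class GaborBankSpec:
    """Geometry of the Gabor filter bank (all lengths in image-width units)."""

    image_side: int = 24
    orientations: tuple[float, ...] = (0.0, math.pi / 3, 2 * math.pi / 3)
    locations: tuple[tuple[float, float], ...] = field(default_factory=_default_locations)
    minor_axis_sd: float = 0.1
    major_axis_sds: tuple[float, ...] = tuple(np.linspace(0.1, 0.5, 15))
    wavelength: float = 0.13
    phase: float = 0.0
    normalize: str = "global"  # {"global", "none"}

    def __post_init__(self) -> None:
        if self.image_side < 1:
            raise ValueError("image_side must be a positive integer")
        n = len(self.orientations) * len(self.locations)
        if len(self.major_axis_sds) != n:
            raise ValueError(
                f"need one major-axis sd per filter: got {len(self.major_axis_sds)}, "
                f"expected {n}"
            )
        if self.minor_axis_sd <= 0 or self.wavelength <= 0:
            raise ValueError("geometric quantities must be positive")
        if any(s <= 0 for s in self.major_axis_sds):
            raise ValueError("geometric quantities must be positive")
        for (cx, cy) in self.locations:
            if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
                raise ValueError("locations must lie inside the unit square")
        if self.normalize not in ("global", "none"):
            raise ValueError("normalize must be 'global' or 'none'")

    @property
    def n_filters(self) -> int:
        return len(self.orientations) * len(self.locations)


def default_gabor_spec(image_side: int = 24) -> GaborBankSpec:
    """The default 15-filter bank: 3 orientations x 5 locations."""
    return GaborBankSpec(image_side=image_side)


def build_gabor_bank(spec: GaborBankSpec) -> np.ndarray:
    """Return the basis matrix A, shape (image_side**2, n_filters).

    Columns are ordered location-major, orientation-minor. Filters are
    even-symmetric (cosine-phase) Gabors; the envelope minor axis lies along
    the wave vector and the major axis along the wavefront. Deterministic.
    """
    side = spec.image_side
    # Pixel centers in image-width units.
    coords = (np.arange(side) + 0.5) / side
    X, Y = np.meshgrid(coords, coords, indexing="xy")
    cols = []
    k = 0
    for (cx, cy) in spec.locations:
        for theta in spec.orientations:
            sd_major = spec.major_axis_sds[k]
            k += 1
            dx = X - cx
            dy = Y - cy
            # s: along the wave vector; t: along the wavefront.
            s = dx * math.cos(theta) + dy * math.sin(theta)
            t = -dx * math.sin(theta) + dy * math.cos(theta)
            envelope = np.exp(
                -(s**2) / (2 * spec.minor_axis_sd**2) - (t**2) / (2 * sd_major**2)
            )
            carrier = np.cos(2 * math.pi * s / spec.wavelength + spec.phase)
            cols.append((envelope * carrier).ravel())
    A = np.column_stack(cols)
    if spec.normalize == "global":
        # One global rescale so that the Gram matrix is O(1) on average
        # (mean eigenvalue of A^T A equal to 1). A global rescale leaves all
        # dynamics and observables invariant; see docs/methods.md.
        scale = math.sqrt(np.trace(A.T @ A) / A.shape[1])
        A = A / scale
    gram = A.T @ A
    if np.linalg.matrix_rank(gram) < A.shape[1]:
        raise DegenerateBasisError("A^T A is singular for this bank spec")
    return A


# ---------------------------------------------------------------------------
# GSM parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GSMParams:
    """Generative-model constants: basis, prior covariance, noise level."""

    A: np.ndarray
    C: np.ndarray
    sigma_x_sq: float

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma_x_sq < 1.0):
            raise ValueError("sigma_x_sq must lie in (0, 1)")
        C = self.C
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("C must be symmetric")
        if np.linalg.eigvalsh((C + C.T) / 2).min() <= 0:
            raise ValueError("C must be positive definite")

    @property
    def K(self) -> float:
        """Prior scale: C = K (A^T A)^{-1} with K = 1 - sigma_x_sq."""
        return 1.0 - self.sigma_x_sq

    @property
    def n_features(self) -> int:
        return self.A.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.A.shape[0]

    @property
    def C_inv(self) -> np.ndarray:
        return (self.A.T @ self.A) / self.K


def build_prior_covariance(A: np.ndarray, sigma_x_sq: float) -> np.ndarray:
    """C = (1 - sigma_x_sq) (A^T A)^{-1}, symmetrized."""
    if not (0.0 < sigma_x_sq < 1.0):
        raise ValueError("sigma_x_sq must lie in (0, 1)")
    gram = A.T @ A
    try:
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise DegenerateBasisError("A^T A is singular") from exc
    if np.linalg.cond(gram) > 1e12:
        raise DegenerateBasisError("A^T A is numerically singular")
    C = (1.0 - sigma_x_sq) * gram_inv
    return (C + C.T) / 2.0


# ---------------------------------------------------------------------------
# Network parameters
# ---------------------------------------------------------------------------

def build_mass_matrix(A: np.ndarray) -> np.ndarray:
    """M_ij = max(0, [(A^T A)^{-1}]_ij); verified positive definite."""
    gram_inv = np.linalg.inv(A.T @ A)
    M = np.maximum(0.0, (gram_inv + gram_inv.T) / 2.0)
    M = (M + M.T) / 2.0
    eigs = np.linalg.eigvalsh(M)
    if eigs.min() <= -1e-10 * max(eigs.max(), 1.0):
        raise DegenerateBasisError(
            f"clipped mass matrix is not positive definite "
            f"(smallest eigenvalue {eigs.min():.3e})"
        )
    return M


def build_weights(
    M: np.ndarray, B: np.ndarray, tau: float, tau_L: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """The four EI weight matrices; raises DalesLawError on any negative element."""
    if tau >= tau_L:
        raise ValueError("tau must be smaller than tau_L")
    r = tau / tau_L
    W_uu = B.T @ M @ B - r * M @ B
    W_uv = B.T @ M - r * M
    W_vu = M @ B + r * B.T @ M @ B
    W_vv = M + r * B.T @ M
    for name, W in (("W_uu", W_uu), ("W_uv", W_uv), ("W_vu", W_vu), ("W_vv", W_vv)):
        if W.min() < -1e-12:
            raise DalesLawError(
                f"Dale's law violated: {name} has negative element {W.min():.3e}"
            )
    return W_uu, W_uv, W_vu, W_vv


def build_z_weights(tau: float, tau_L: float) -> tuple[float, float, float, float]:
    """Scalar weights of the z-subsystem (B = M = 1): (W_zz, W_zv, W_vz, W_vv)."""
    if tau >= tau_L:
        raise ValueError("tau must be smaller than tau_L")
    r = tau / tau_L
    w = (1.0 - r, 1.0 - r, 1.0 + r, 1.0 + r)
    if min(w) < 0:
        raise DalesLawError("Dale's law violated in the z-subsystem weights")
    return w


@dataclass(frozen=True)
class NetworkParams:
    """Sampler constants: time constants, coupling, mass and weight matrices."""

    tau: float
    tau_L: float
    B: np.ndarray
    M: np.ndarray
    W_uu: np.ndarray
    W_uv: np.ndarray
    W_vu: np.ndarray
    W_vv: np.ndarray
    z_weights: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not (0 < self.tau < self.tau_L):
            raise ValueError("need 0 < tau < tau_L")
        eigs = np.linalg.eigvalsh((self.M + self.M.T) / 2.0)
        if eigs.min() <= 0:
            raise ValueError("M must be positive definite")
        for name, W in (
            ("W_uu", self.W_uu),
            ("W_uv", self.W_uv),
            ("W_vu", self.W_vu),
            ("W_vv", self.W_vv),
        ):
            if W.min() < -1e-12:
                raise DalesLawError(f"{name} has a negative element")

    @property
    def rho_sq(self) -> float:
        """Noise-injection rate: rho^2 = 2 / tau_L (so rho_sq * tau_L == 2)."""
        return 2.0 / self.tau_L

    @property
    def n(self) -> int:
        return self.M.shape[0]

    @property
    def M_inv(self) -> np.ndarray:
        return np.linalg.inv(self.M)

    @classmethod
    def from_mass(cls, M: np.ndarray, tau: float = 0.010, tau_L: float = 0.150,
                  B: np.ndarray | None = None) -> "NetworkParams":
        if B is None:
            B = np.eye(M.shape[0])
        W = build_weights(M, B, tau, tau_L)
        return cls(tau=tau, tau_L=tau_L, B=B, M=M, W_uu=W[0], W_uv=W[1],
                   W_vu=W[2], W_vv=W[3], z_weights=build_z_weights(tau, tau_L))


def default_model(
    image_side: int = 24,
    sigma_x_sq: float = 0.1,
    tau: float = 0.010,
    tau_L: float = 0.150,
) -> tuple[GSMParams, NetworkParams]:
    """Build the default 15-filter model and its sampler network."""
    spec = default_gabor_spec(image_side=image_side)
    A = build_gabor_bank(spec)
    C = build_prior_covariance(A, sigma_x_sq)
    gsm = GSMParams(A=A, C=C, sigma_x_sq=sigma_x_sq)
    M = build_mass_matrix(A)
    net = NetworkParams.from_mass(M, tau=tau, tau_L=tau_L)
    return gsm, net


# ---------------------------------------------------------------------------
# Biophysical estimates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiophysEstimate:
    """A lognormal uncertainty summary: central value and 95% range."""

    central: float
    low: float
    high: float
    log_mu: float
    log_sigma: float

    @classmethod
    def from_range(cls, low: float, high: float) -> "BiophysEstimate":
        if not (0 < low < high):
            raise ValueError("need 0 < low < high")
        log_mu = 0.5 * (math.log(low) + math.log(high))
        log_sigma = 0.25 * (math.log(high) - math.log(low))
        return cls(central=math.exp(log_mu), low=low, high=high,
                   log_mu=log_mu, log_sigma=log_sigma)


def estimate_sigma_x(N: float, r: float, dt: float) -> float:
    """sigma_x = 1 / sqrt(N r dt): coefficient of variation of Poisson input counts."""
    if N <= 0 or r <= 0 or dt <= 0:
        raise ValueError("all inputs must be positive")
    return 1.0 / math.sqrt(N * r * dt)


def estimate_tau_L(sigma: float, s: float, r: float, v: float) -> float:
    """tau_L = 2 sigma^2 / (s r v), in seconds for SI inputs."""
    if sigma <= 0 or s <= 0 or r <= 0 or v <= 0:
        raise ValueError("all inputs must be positive")
    return 2.0 * sigma**2 / (s * r * v)


def propagate_lognormal(
    sigma_range: tuple[float, float],
    s_range: tuple[float, float],
    r_range: tuple[float, float],
    v_range: tuple[float, float],
) -> BiophysEstimate:
    """Exact lognormal propagation of tau_L = 2 sigma^2/(s r v).

    Each input is a (low, high) 95% range; the result is the induced lognormal
    on tau_L (log-domain sum of component log-parameters).
    """
    e_sigma = BiophysEstimate.from_range(*sigma_range)
    e_s = BiophysEstimate.from_range(*s_range)
    e_r = BiophysEstimate.from_range(*r_range)
    e_v = BiophysEstimate.from_range(*v_range)
    log_mu = math.log(2.0) + 2 * e_sigma.log_mu - e_s.log_mu - e_r.log_mu - e_v.log_mu
    log_sigma = math.sqrt(
        (2 * e_sigma.log_sigma) ** 2
        + e_s.log_sigma**2
        + e_r.log_sigma**2
        + e_v.log_sigma**2
    )
    return BiophysEstimate(
        central=math.exp(log_mu),
        low=math.exp(log_mu - 2 * log_sigma),
        high=math.exp(log_mu + 2 * log_sigma),
        log_mu=log_mu,
        log_sigma=log_sigma,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def params_to_dict(gsm: GSMParams, net: NetworkParams, spec: GaborBankSpec | None = None) -> dict:
    """Flat scalar configuration (matrices are rebuilt from it, not stored)."""
    d = {
        "tau_ms": net.tau * 1e3,
        "tau_L_ms": net.tau_L * 1e3,
        "sigma_x_sq": gsm.sigma_x_sq,
        "n_features": gsm.n_features,
    }
    if spec is not None:
        d.update(
            image_side=spec.image_side,
            n_orientations=len(spec.orientations),
            n_locations=len(spec.locations),
            minor_axis_sd=spec.minor_axis_sd,
            wavelength=spec.wavelength,
        )
    return d


def params_from_dict(d: dict) -> tuple[GSMParams, NetworkParams]:
    return default_model(
        image_side=int(d.get("image_side", 24)),
        sigma_x_sq=float(d.get("sigma_x_sq", 0.1)),
        tau=float(d.get("tau_ms", 10.0)) * 1e-3,
        tau_L=float(d.get("tau_L_ms", 150.0)) * 1e-3,
    )
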