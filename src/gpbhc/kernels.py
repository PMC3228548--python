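"""Covariance functions and the block-structured cluster Gram matrix.

Within a cluster of ``G`` genes observed at ``T`` shared time points, all
genes share one latent curve, so the full ``GT x GT`` covariance of the
time-major stacked observations is

    K = Sigma_T (x) J_G + noise_var * I,

where ``Sigma_T`` is the noise-free ``T x T`` kernel matrix, ``J_G`` the
all-ones matrix and ``(x)`` the Kronecker product.  ``J_G`` has one
eigenvalue ``G`` (the per-time gene mean) and ``G - 1`` zeros (residuals),
so every determinant, solve, and trace reduces to work on the ``T x T``
matrix ``A = G * Sigma_T + noise_var * I`` — the matrix-inversion-lemma
shortcut that makes cluster likelihood evaluations cheap.

Two covariance functions are provided: the squared exponential (smooth
stationary dynamics; hyperparameters signal variance, length scale, noise
variance) and the cubic spline (integrated-Wiener-process dynamics pinned
at the time origin; no length scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

NOISE_FLOOR = 1e-10
JITTER_START = 1e-10
JITTER_MAX = 1e-6


class NumericalError(RuntimeError):
    """Raised when a covariance factorization fails beyond repair."""


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of a cluster covariance function.

    ``kind`` is ``"SE"`` (squared exponential: signal_var, length_scale,
    noise_var) or ``"CS"`` (cubic spline: signal_var, noise_var).
    """

    kind: str
    signal_var: float
    noise_var: float
    length_scale: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("SE", "CS"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.signal_var < 0 or self.noise_var <= 0:
            raise ValueError("variances must be positive")
        if self.kind == "SE":
            if self.length_scale is None or self.length_scale <= 0:
                raise ValueError("SE kernel needs a positive length scale")
        elif self.length_scale is not None:
            raise ValueError("CS kernel has no length scale")

    # log-parameterization used by the unconstrained optimizer
    def to_log_vector(self) -> np.ndarray:
        if self.kind == "SE":
            return np.log([self.signal_var, self.length_scale, self.noise_var])
        return np.log([self.signal_var, self.noise_var])

    @classmethod
    def from_log_vector(cls, kind: str, v: np.ndarray) -> "KernelParams":
        v = np.exp(np.asarray(v, dtype=float))
        if kind == "SE":
            return cls("SE", signal_var=v[0], length_scale=v[1], noise_var=v[2])
        return cls("CS", signal_var=v[0], noise_var=v[1])

    @property
    def names(self) -> tuple[str, ...]:
        if self.kind == "SE":
            return ("signal_var", "length_scale", "noise_var")
        return ("signal_var", "noise_var")

    def with_noise(self, noise_var: float) -> "KernelParams":
        return replace(self, noise_var=noise_var)


def se_kernel(t_i: float, t_j: float, p: KernelParams) -> float:
    """Noise-free squared-exponential covariance between two times."""
    if p.kind != "SE":
        raise ValueError("se_kernel requires SE params")
    d = t_i - t_j
    return p.signal_var * np.exp(-(d * d) / (2.0 * p.length_scale**2))


def cs_kernel(t_i: float, t_j: float, p: KernelParams) -> float:
    """Noise-free cubic-spline covariance; times must be nonnegative."""
    if p.kind != "CS":
        raise ValueError("cs_kernel requires CS params")
    if t_i < 0 or t_j < 0:
        raise ValueError("cubic-spline kernel is defined for nonnegative times")
    v = min(t_i, t_j)
    return p.signal_var * (abs(t_i - t_j) * v * v / 2.0 + v**3 / 3.0)


def kernel_matrix(times: np.ndarray, p: KernelParams) -> np.ndarray:
    """Noise-free T x T kernel matrix over a time grid (vectorized)."""
    t = np.asarray(times, dtype=float)
    if p.kind == "SE":
        d = t[:, None] - t[None, :]
        return p.signal_var * np.exp(-(d * d) / (2.0 * p.length_scale**2))
    if (t < 0).any():
        raise ValueError("cubic-spline kernel is defined for nonnegative times")
    v = np.minimum(t[:, None], t[None, :])
    absd = np.abs(t[:, None] - t[None, :])
    return p.signal_var * (absd * v * v / 2.0 + v**3 / 3.0)


@dataclass
class GramStructure:
    """Block representation of a cluster covariance K = Sigma_T (x) J_G + s2 I."""

    Sigma_T: np.ndarray
    G: int
    noise_var: float
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.noise_var < NOISE_FLOOR:
            raise NumericalError(
                f"noise variance {self.noise_var:.3e} below floor {NOISE_FLOOR:.0e}; "
                "the block structure is degenerate"
            )
        self._chol_A: np.ndarray | None = None

    @property
    def T(self) -> int:
        return self.Sigma_T.shape[0]

    @property
    def N(self) -> int:
        return self.G * self.T

    def dense(self) -> np.ndarray:
        """Materialize the full GT x GT covariance (time-major ordering)."""
        J = np.ones((self.G, self.G))
        return np.kron(self.Sigma_T, J) + self.noise_var * np.eye(self.N)

    def chol_A(self) -> np.ndarray:
        """Cholesky factor of A = G * Sigma_T + noise_var * I with jitter escalation."""
        if self._chol_A is None:
            A = self.G * self.Sigma_T + self.noise_var * np.eye(self.T)
            jitter = 0.0
            while True:
                try:
                    self._chol_A = linalg.cholesky(
                        A + jitter * np.eye(self.T), lower=True
                    )
                    break
                except linalg.LinAlgError:
                    jitter = JITTER_START if jitter == 0.0 else jitter * 10.0
                    if jitter > JITTER_MAX:
                        raise NumericalError(
                            "Cholesky of the T-level factor failed at max jitter "
                            f"{JITTER_MAX:.0e} (T={self.T}, G={self.G}, "
                            f"noise_var={self.noise_var:.3e})"
                        ) from None
                    logger.warning("escalating Cholesky jitter to %.0e", jitter)
        return self._chol_A

    def split(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split a time-major vector into per-time gene means and residuals."""
        Y = np.asarray(y, dtype=float).reshape(self.T, self.G)
        m = Y.mean(axis=1)
        r = Y - m[:, None]
        return m, r


def build_gram(times: np.ndarray, G: int, p: KernelParams) -> GramStructure:
    """Assemble the block Gram structure for G genes over a time grid."""
    if G < 1:
        raise ValueError("G must be at least 1")
    return GramStructure(
        Sigma_T=kernel_matrix(times, p), G=G,
        noise_var=p.noise_var, times=np.asarray(times, dtype=float),
    )


def fast_logdet_solve(
    gram: GramStructure, y: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """log|K|, K^-1 y and y^T K^-1 y via the T x T reduction.

    ``y`` must be time-major (all genes at t_1, then t_2, ...).  Using the
    eigenstructure of J_G:

        log|K| = log|A| + (G - 1) T log(noise_var),  A = G Sigma_T + s2 I
        K^-1 y = (A^-1 m) broadcast over genes + residuals / s2

    where ``m`` is the per-time gene mean of ``y``.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (gram.N,):
        raise ValueError(f"y must have length N = {gram.N}")
    L = gram.chol_A()
    logdet = 2.0 * float(np.sum(np.log(np.diag(L)))) + (
        (gram.G - 1) * gram.T * np.log(gram.noise_var)
    )
    m, r = gram.split(y)
    Ainv_m = linalg.cho_solve((L, True), m)
    Kinv_y = (Ainv_m[:, None] + r / gram.noise_var).ravel()
    quad = gram.G * float(m @ Ainv_m) + float((r * r).sum()) / gram.noise_var
    return logdet, Kinv_y, quad


def gram_gradients(
    gram: GramStructure, p: KernelParams
) -> dict[str, np.ndarray | str]:
    """Elementwise derivatives of K in block form, per hyperparameter.

    For the signal hyperparameters the derivative is ``D_T (x) J_G`` and the
    T x T matrix ``D_T`` is returned; the noise-variance derivative is the
    identity, returned as the sentinel string ``"identity"``.
    """
    t = gram.times
    grads: dict[str, np.ndarray | str] = {}
    if p.kind == "SE":
        d = t[:, None] - t[None, :]
        E = np.exp(-(d * d) / (2.0 * p.length_scale**2))
        grads["signal_var"] = E
        grads["length_scale"] = p.signal_var * E * (d * d) / p.length_scale**3
    else:
        v = np.minimum(t[:, None], t[None, :])
        absd = np.abs(t[:, None] - t[None, :])
        grads["signal_var"] = absd * v * v / 2.0 + v**3 / 3.0
    grads["noise_var"] = "identity"
    return grads
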