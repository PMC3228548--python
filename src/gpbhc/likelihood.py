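"""GP marginal likelihoods, MAP hyperparameter fits, and the outlier mixture.

The marginal likelihood of a cluster's stacked observations ``y`` under a
shared latent curve is the zero-mean Gaussian density N(y; 0, K) with the
block covariance from :mod:`gpbhc.kernels`.  Hyperparameters are fit by
maximizing the log marginal likelihood plus (optionally) a Gamma prior on
the noise variance, using analytic gradients

    d/d theta_j log P = 1/2 tr((gamma gamma^T - K^-1) dK/dtheta_j),
    gamma = K^-1 y,

chain-ruled onto log-parameters for unconstrained quasi-Newton ascent.

The outlier-robust likelihood replaces the per-observation Gaussian with a
two-component mixture: weight ``a`` on the Gaussian and ``1 - a`` on a
constant density ``B = 1 / Range``.  Expanding the product over
observations and dropping terms with two or more outliers gives the
first-order marginal

    P(y) ~= a^N V1 + a^{N-1} (1 - a) V2,
    V1 = N(y; 0, K),   V2 = sum_n B * N(y_{-n}; 0, K_{-n}),

and the weight maximizing it has the closed form
a_max = (1 - N) V2 / (N (V1 - V2)), clamped to 1 outside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from scipy.special import logsumexp

from .kernels import (
    GramStructure,
    KernelParams,
    NumericalError,
    build_gram,
    fast_logdet_solve,
    gram_gradients,
)
from .preprocess import NoisePrior

LOG2PI = np.log(2.0 * np.pi)


def log_marginal(y: np.ndarray, gram: GramStructure) -> float:
    """Log N(y; 0, K) through the fast block log-determinant/solve."""
    logdet, _, quad = fast_logdet_solve(gram, y)
    return -0.5 * (gram.N * LOG2PI + logdet + quad)


def _objective_and_gradient(
    log_v: np.ndarray,
    y: np.ndarray,
    times: np.ndarray,
    G: int,
    kind: str,
    prior: NoisePrior,
) -> tuple[float, np.ndarray]:
    """Log posterior and its gradient in log-parameters.

    All trace/quadratic terms reduce to T x T work: for a signal
    hyperparameter with dK = D (x) J_G,

        tr(K^-1 dK) = G tr(A^-1 D),   gamma^T dK gamma = G^2 x^T D x

    with A = G Sigma_T + s2 I and x = A^-1 m (m the per-time gene means);
    for the noise derivative (dK = I),

        tr(K^-1) = tr(A^-1) + (G-1) T / s2,
        gamma^T gamma = G x^T x + r^T r / s2^2.
    """
    p = KernelParams.from_log_vector(kind, log_v)
    gram = build_gram(times, G, p)
    L = gram.chol_A()
    logdet = 2.0 * float(np.sum(np.log(np.diag(L)))) + (
        (G - 1) * gram.T * np.log(gram.noise_var)
    )
    m, r = gram.split(y)
    x = linalg.cho_solve((L, True), m)
    rss = float((r * r).sum())
    quad = G * float(m @ x) + rss / gram.noise_var
    obj = -0.5 * (gram.N * LOG2PI + logdet + quad)

    Ainv = linalg.cho_solve((L, True), np.eye(gram.T))
    grads = gram_gradients(gram, p)
    g = np.empty(len(p.names))
    for j, name in enumerate(p.names):
        D = grads[name]
        if isinstance(D, str):  # noise: dK = I
            tr_term = float(np.trace(Ainv)) + (G - 1) * gram.T / gram.noise_var
            quad_term = G * float(x @ x) + rss / gram.noise_var**2
        else:
            tr_term = G * float(np.sum(Ainv * D))
            quad_term = G * G * float(x @ D @ x)
        g[j] = 0.5 * (quad_term - tr_term)

    if not prior.flat:
        s2 = p.noise_var
        obj += prior.log_density(s2)
        g[p.names.index("noise_var")] += (prior.alpha - 1.0) / s2 - prior.beta
    # chain rule onto log-parameters
    g *= np.exp(log_v)
    return obj, g


def log_posterior_gradient(
    y: np.ndarray,
    p: KernelParams,
    times: np.ndarray,
    G: int,
    prior: NoisePrior,
) -> np.ndarray:
    """Gradient of the log posterior at ``p``, on the log-parameter scale."""
    _, g = _objective_and_gradient(p.to_log_vector(), y, times, G, p.kind, prior)
    return g


@dataclass(frozen=True)
class OptimizerOptions:
    n_restarts: int = 3
    gtol: float = 1e-6
    maxiter: int = 200


def _initial_params(
    y: np.ndarray, times: np.ndarray, G: int, kind: str, prior: NoisePrior
) -> KernelParams:
    """Moment-based heuristic initial point."""
    T = len(times)
    m = y.reshape(T, G).mean(axis=1)
    var_y = max(float(np.var(y)), 1e-3)
    sig0 = max(float(np.var(m)), 0.25 * var_y, 1e-3)
    noise0 = prior.mode if not prior.flat else max(0.25 * var_y, 0.02)
    if kind == "SE":
        span = float(times[-1] - times[0])
        return KernelParams("SE", signal_var=sig0,
                            length_scale=max(span / 4.0, 1e-2),
                            noise_var=noise0)
    scale = float(np.mean(np.asarray(times) ** 3) / 3.0) + 1e-6
    return KernelParams("CS", signal_var=max(sig0 / scale, 1e-6),
                        noise_var=noise0)


def optimize_hyperparameters(
    y: np.ndarray,
    times: np.ndarray,
    G: int,
    kind: str,
    prior: NoisePrior,
    opts: OptimizerOptions | None = None,
    init: KernelParams | None = None,
) -> tuple[KernelParams, float]:
    """MAP fit of the kernel hyperparameters for one cluster.

    Deterministic: restarts perturb the moment-based initial point by
    fixed factors of e (no randomness).  Returns the best
    ``(params, achieved log posterior)`` over restarts.
    """
    opts = opts or OptimizerOptions()
    y = np.asarray(y, dtype=float)
    times = np.asarray(times, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observations to fit hyperparameters")
    base = (init or _initial_params(y, times, G, kind, prior)).to_log_vector()
    offsets = [0.0, 1.0, -1.0, 2.0, -2.0][: max(opts.n_restarts, 1)]

    best: tuple[float, np.ndarray] | None = None
    failures = []
    for off in offsets:
        x0 = base + off
        try:
            res = optimize.minimize(
                lambda v: tuple(
                    -t for t in _objective_and_gradient(v, y, times, G, kind, prior)
                ),
                x0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": opts.maxiter, "gtol": opts.gtol},
                bounds=[(-12.0, 12.0)] * len(x0),
            )
        except (NumericalError, linalg.LinAlgError) as exc:
            failures.append(str(exc))
            continue
        if not np.isfinite(res.fun):
            failures.append("non-finite objective")
            continue
        if best is None or -res.fun > best[0]:
            best = (-res.fun, res.x)
    if best is None:
        raise NumericalError(
            "hyperparameter optimization failed on all restarts: "
            + "; ".join(failures)
        )
    return KernelParams.from_log_vector(kind, best[1]), best[0]


# ---------------------------------------------------------------------------
# leave-one-out terms and the outlier mixture
# ---------------------------------------------------------------------------


@dataclass
class LikelihoodWorkspace:
    """Per-cluster quantities shared by the mixture computation."""

    gamma_vec: np.ndarray          # K^-1 y
    logdet: float                  # log|K|
    full_logml: float              # log N(y; 0, K)
    loo_logpdfs: np.ndarray        # log N(y_{-n}; 0, K_{-n}) for each n

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.loo_logpdfs)):
            bad = int(np.flatnonzero(~np.isfinite(self.loo_logpdfs))[0])
            raise NumericalError(f"non-finite leave-one-out term at n={bad}")


def leave_one_out_terms(
    y: np.ndarray, gram: GramStructure, method: str = "downdate"
) -> LikelihoodWorkspace:
    """log N(y_{-n}; 0, K_{-n}) for every observation n.

    ``method="downdate"`` (default) uses the Gaussian factorization
    p(y) = p(y_{-n}) p(y_n | y_{-n}): with Kinv = K^-1 and gamma = Kinv y,
    the conditional has variance 1/Kinv[n,n] and mean
    y_n - gamma_n / Kinv[n,n], so each term costs O(1) after one O(N^3)
    factorization.  ``method="dense"`` refactorizes K_{-n} per n; the two
    paths agree and the dense one serves as the reference in tests.
    """
    y = np.asarray(y, dtype=float)
    N = gram.N
    if N < 2:
        raise ValueError("leave-one-out terms need at least 2 observations")
    K = gram.dense()
    if method == "dense":
        loo = np.empty(N)
        for n in range(N):
            idx = np.delete(np.arange(N), n)
            Kn = K[np.ix_(idx, idx)]
            yn = y[idx]
            try:
                c, low = linalg.cho_factor(Kn, lower=True)
            except linalg.LinAlgError as exc:
                raise NumericalError(f"leave-one-out factorization failed at n={n}") from exc
            quad = float(yn @ linalg.cho_solve((c, low), yn))
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            loo[n] = -0.5 * ((N - 1) * LOG2PI + logdet + quad)
        logdet_full, gamma, quad_full = fast_logdet_solve(gram, y)
        full = -0.5 * (N * LOG2PI + logdet_full + quad_full)
        return LikelihoodWorkspace(gamma, logdet_full, full, loo)
    if method != "downdate":
        raise ValueError(f"unknown method {method!r}")
    try:
        c, low = linalg.cho_factor(K, lower=True)
    except linalg.LinAlgError as exc:
        raise NumericalError("full covariance factorization failed") from exc
    Kinv = linalg.cho_solve((c, low), np.eye(N))
    gamma = Kinv @ y
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    full = -0.5 * (N * LOG2PI + logdet + float(y @ gamma))
    d = np.diag(Kinv)
    # conditional log-density of y_n given the rest
    cond = -0.5 * (LOG2PI - np.log(d)) - gamma**2 / (2.0 * d)
    return LikelihoodWorkspace(gamma, logdet, full, full - cond)


@dataclass(frozen=True)
class MixtureModel:
    """First-order outlier mixture for one cluster.

    ``log_v1``/``log_v2`` are the no-outlier and summed single-outlier
    terms; ``a`` weights the regular Gaussian component and ``1 - a`` the
    constant outlier density ``B = 1 / data_range``.
    """

    a: float
    data_range: float
    log_v1: float
    log_v2: float
    N: int

    @property
    def b(self) -> float:
        return 1.0 - self.a

    @property
    def B(self) -> float:
        return 1.0 / self.data_range


def optimal_outlier_fraction(log_v1: float, log_v2: float, N: int) -> float:
    """Closed-form weight a maximizing a^N V1 + a^{N-1}(1-a) V2.

    a_max = (1 - N) V2 / (N (V1 - V2)); returned as-is when inside (0, 1),
    otherwise 1.  Computed stably from the log-space terms:
    a_max = (1 - N) / (N expm1(log V1 - log V2)).
    """
    if N < 2:
        raise ValueError("mixture weight undefined for N < 2")
    if not (np.isfinite(log_v1) and np.isfinite(log_v2)):
        raise ValueError("non-finite mixture terms")
    diff = log_v1 - log_v2
    if diff == 0.0:
        return 1.0
    a_max = (1.0 - N) / (N * np.expm1(diff))
    return float(a_max) if 0.0 < a_max < 1.0 else 1.0


def mixture_log_marginal(
    y: np.ndarray,
    gram: GramStructure,
    data_range: float,
    a: float | None = None,
    workspace: LikelihoodWorkspace | None = None,
) -> MixtureModel:
    """Fit/evaluate the first-order outlier-mixture marginal likelihood.

    With ``a=None`` the weight is set to its closed-form optimum; a
    supplied ``a`` is used as given (``a=1`` reduces exactly to the plain
    marginal).  Returns the :class:`MixtureModel`; use
    :func:`mixture_objective` for the resulting log marginal value.
    """
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    N = gram.N
    if N < 2 and (a is None or a < 1.0):
        raise ValueError("outlier mixture needs at least 2 observations")
    if workspace is None:
        workspace = leave_one_out_terms(y, gram)
    log_v1 = workspace.full_logml
    log_v2 = float(logsumexp(-np.log(data_range) + workspace.loo_logpdfs))
    if a is None:
        a = optimal_outlier_fraction(log_v1, log_v2, N)
    return MixtureModel(a=float(a), data_range=float(data_range),
                        log_v1=log_v1, log_v2=log_v2, N=N)


def mixture_objective(mix: MixtureModel, a: float | None = None) -> float:
    """log[a^N V1 + a^{N-1}(1-a) V2] for the mixture's terms."""
    a = mix.a if a is None else a
    if a >= 1.0:
        return mix.log_v1
    return float(logsumexp([
        mix.N * np.log(a) + mix.log_v1,
        (mix.N - 1) * np.log(a) + np.log1p(-a) + mix.log_v2,
    ]))
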