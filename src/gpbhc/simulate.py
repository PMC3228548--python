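"""Synthetic replicated time-course data from Gaussian-process cluster models.

Each cluster is defined by a noise-free kernel and a noise level.  One
latent curve f is drawn per cluster (all genes in a cluster share the same
underlying function), each gene's averaged observation adds iid Gaussian
noise to f, and each replicate adds further iid measurement noise around
the gene's observation:

    f ~ GP(0, kernel),  ybar_g(t) = f(t) + N(0, noise_sd^2),
    y_{r,g}(t) = ybar_g(t) + N(0, replicate_sd^2).

This mirrors the generative model the clustering assumes, so simulated
datasets provide ground truth for cluster-recovery and noise-recovery
experiments.  The round trip fit_cluster_gp -> simulate_dataset lets
models inferred from a clustering generate fresh data with matched noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import TimeSeriesDataset
from .kernels import KernelParams, kernel_matrix
from .likelihood import OptimizerOptions, optimize_hyperparameters
from .preprocess import NoisePrior

_SIM_JITTER = 1e-10


@dataclass(frozen=True)
class GPClusterModel:
    """Generative model of one cluster: latent kernel + observation noise."""

    kernel: KernelParams      # noise-free part: signal_var (and length_scale)
    noise_sd: float
    n_genes: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be at least 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of one synthetic dataset."""

    clusters: tuple[GPClusterModel, ...]
    times: tuple[float, ...]
    n_replicates: int = 1
    replicate_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if not all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def default_spec(
    seed: int = 0,
    n_clusters: int = 3,
    genes_per_cluster: int = 10,
    n_times: int = 12,
    noise_sd: float = 0.3,
    n_replicates: int = 1,
    replicate_sd: float = 0.0,
) -> SimulationSpec:
    """Well-separated squared-exponential cluster models.

    Length scales span 1-4 time units on a unit-spaced grid, with unit
    signal variance, so independent latent draws are distinct relative to
    the default noise level.
    """
    length_scales = np.geomspace(1.0, 4.0, num=max(n_clusters, 2))[:n_clusters]
    clusters = tuple(
        GPClusterModel(
            kernel=KernelParams("SE", signal_var=1.0,
                                length_scale=float(l), noise_var=1.0),
            noise_sd=noise_sd, n_genes=genes_per_cluster,
            label=f"cluster{i}",
        )
        for i, l in enumerate(length_scales)
    )
    return SimulationSpec(
        clusters=clusters, times=tuple(float(t) for t in range(n_times)),
        n_replicates=n_replicates, replicate_sd=replicate_sd, seed=seed,
    )


def simulate_dataset(spec: SimulationSpec) -> tuple[TimeSeriesDataset, np.ndarray]:
    """Draw a dataset from a :class:`SimulationSpec`; returns (dataset, labels).

    Deterministic given ``spec.seed``.  Latent curves are drawn once per
    cluster and shared by all its genes.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.times, dtype=float)
    T = len(times)
    G = sum(c.n_genes for c in spec.clusters)
    R = spec.n_replicates
    raw = np.empty((R, G, T))
    labels = np.empty(G, dtype=int)
    g0 = 0
    for ci, cm in enumerate(spec.clusters):
        cov = kernel_matrix(times - times.min() if cm.kernel.kind == "CS" else times,
                            cm.kernel)
        f = rng.multivariate_normal(
            np.zeros(T), cov + _SIM_JITTER * np.eye(T), method="cholesky"
        )
        for g in range(g0, g0 + cm.n_genes):
            ybar = f + rng.normal(0.0, cm.noise_sd, size=T)
            raw[:, g, :] = ybar[None, :] + rng.normal(
                0.0, spec.replicate_sd, size=(R, T)
            )
            labels[g] = ci
        g0 += cm.n_genes
    gene_ids = [f"g{idx:04d}" for idx in range(G)]
    return TimeSeriesDataset(gene_ids=gene_ids, times=times, raw=raw), labels


def fit_cluster_gp(
    profiles: np.ndarray,
    times: np.ndarray,
    kind: str = "SE",
    opts: OptimizerOptions | None = None,
    label: str = "",
) -> GPClusterModel:
    """Infer a generative cluster model from observed profiles.

    Fits MAP kernel hyperparameters (flat noise prior) on the pooled
    profiles; the fitted noise-free part becomes the latent kernel and
    sqrt(noise_var) the observation noise.  Enables the round trip
    cluster -> fit -> resimulate.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValueError("need a (genes >= 2) x times profile matrix")
    times = np.asarray(times, dtype=float)
    if kind == "CS":
        times = times - times.min()
    y = profiles.T.ravel()  # time-major
    params, _ = optimize_hyperparameters(
        y, times, profiles.shape[0], kind, NoisePrior.make_flat(), opts=opts,
    )
    latent = KernelParams(
        kind, signal_var=params.signal_var,
        length_scale=params.length_scale, noise_var=1.0,
    )
    return GPClusterModel(kernel=latent, noise_sd=float(np.sqrt(params.noise_var)),
                          n_genes=profiles.shape[0], label=label)


def inject_outliers(
    dataset: TimeSeriesDataset,
    fraction: float,
    magnitude_sd: float,
    seed: int,
    cells: list[tuple[int, int]] | None = None,
) -> tuple[TimeSeriesDataset, list[dict]]:
    """Displace a few (gene, time) cells by +/- magnitude_sd in all replicates.

    ``fraction`` of the G*T cells are chosen at random (or ``cells`` can
    pin them explicitly); each is shifted by ``magnitude_sd`` with a random
    sign.  Returns a new dataset plus a log of the ground-truth
    corruptions.
    """
    if not (0.0 <= fraction <= 0.1):
        raise ValueError("fraction must lie in [0, 0.1]")
    rng = np.random.default_rng(seed)
    raw = dataset.raw.copy()
    if cells is None:
        n_cells = int(round(fraction * dataset.G * dataset.T))
        flat = rng.choice(dataset.G * dataset.T, size=n_cells, replace=False)
        cells = [(int(k // dataset.T), int(k % dataset.T)) for k in flat]
    log = []
    for g, t in cells:
        delta = float(magnitude_sd * rng.choice([-1.0, 1.0]))
        raw[:, g, t] += delta
        log.append({"gene": int(g), "time_index": int(t), "delta": delta})
    corrupted = TimeSeriesDataset(
        gene_ids=list(dataset.gene_ids), times=dataset.times.copy(), raw=raw,
    )
    return corrupted, log
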