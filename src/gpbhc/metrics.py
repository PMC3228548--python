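"""Cluster-quality scores: shape coherence and biological homogeneity.

Two pairwise scores are provided.  The average Pearson correlation
coefficient (PCC) measures how similar the expression shapes within each
cluster are: it is the mean, over all within-cluster gene pairs pooled
across clusters, of the Pearson correlation of the two profiles.

The Biological Homogeneity Index (BHI) asks whether co-clustered annotated
genes share an annotation term: each within-cluster pair of annotated
genes scores 1 if their term sets intersect, else 0.  Two weightings are
offered — the headline statistic pools all pairs across clusters, and a
variant averages the per-cluster pair means equally over clusters — since
either convention appears in practice.

Standard errors come from a seeded nonparametric bootstrap over the pooled
pair scores (1000 resamples for BHI, 100 for PCC by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd


class UndefinedScoreError(ValueError):
    """Raised when no within-cluster pair exists to score."""


@dataclass
class PartitionScore:
    name: str
    value: float
    stderr: float
    n_boot: int
    seed: int
    pair_scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        assert np.isclose(self.value, float(np.mean(self.pair_scores))) or \
            self.name.endswith("cluster_mean")


def _clusters_from_partition(partition: pd.DataFrame) -> dict[int, list[str]]:
    return {
        int(cid): list(sub["gene_id"])
        for cid, sub in partition.groupby("cluster_id")
    }


def average_pcc(
    partition: pd.DataFrame,
    profiles: pd.DataFrame | np.ndarray,
    gene_ids: list[str] | None = None,
    n_boot: int = 100,
    seed: int = 0,
) -> PartitionScore:
    """Mean within-cluster pairwise Pearson correlation of profiles.

    ``profiles`` is a gene x time matrix (DataFrame indexed by gene id, or
    an array with ``gene_ids`` giving row names).  Singleton clusters
    contribute no pairs.
    """
    if isinstance(profiles, pd.DataFrame):
        table = profiles
    else:
        if gene_ids is None:
            raise ValueError("gene_ids required with an array of profiles")
        table = pd.DataFrame(np.asarray(profiles, dtype=float), index=gene_ids)
    scores = []
    for _, members in _clusters_from_partition(partition).items():
        for ga, gb in combinations(members, 2):
            xa = table.loc[ga].to_numpy()
            xb = table.loc[gb].to_numpy()
            scores.append(float(np.corrcoef(xa, xb)[0, 1]))
    if not scores:
        raise UndefinedScoreError("no within-cluster pair to correlate")
    pair_scores = np.asarray(scores)
    return PartitionScore(
        name="average_pcc", value=float(pair_scores.mean()),
        stderr=bootstrap_stderr(pair_scores, n_boot, seed),
        n_boot=n_boot, seed=seed, pair_scores=pair_scores,
    )


def bhi(
    partition: pd.DataFrame,
    annotations: dict[str, set[str]],
    variant: str = "pooled",
    n_boot: int = 1000,
    seed: int = 0,
) -> PartitionScore:
    """Biological Homogeneity Index of a partition.

    ``annotations`` maps gene id -> set of annotation terms; genes absent
    from the mapping (or with empty term sets) are ignored.  With
    ``variant="pooled"`` (headline) the indicator pairs are pooled across
    clusters; ``variant="cluster_mean"`` averages per-cluster means
    equally over clusters that contain at least one annotated pair.
    """
    if variant not in ("pooled", "cluster_mean"):
        raise ValueError(f"unknown BHI variant {variant!r}")
    per_cluster: list[np.ndarray] = []
    for _, members in _clusters_from_partition(partition).items():
        annotated = [g for g in members if annotations.get(g)]
        pairs = [
            1.0 if annotations[ga] & annotations[gb] else 0.0
            for ga, gb in combinations(annotated, 2)
        ]
        if pairs:
            per_cluster.append(np.asarray(pairs))
    if not per_cluster:
        raise UndefinedScoreError("no annotated within-cluster pair")
    pooled = np.concatenate(per_cluster)
    if variant == "pooled":
        value = float(pooled.mean())
    else:
        value = float(np.mean([c.mean() for c in per_cluster]))
    return PartitionScore(
        name=f"bhi_{variant}" if variant != "pooled" else "bhi",
        value=value, stderr=bootstrap_stderr(pooled, n_boot, seed),
        n_boot=n_boot, seed=seed, pair_scores=pooled,
    )


def bootstrap_stderr(pair_scores: np.ndarray, n_boot: int, seed: int) -> float:
    """Bootstrap standard error of the mean of the pooled pair scores."""
    pair_scores = np.asarray(pair_scores, dtype=float)
    if pair_scores.size < 2:
        return 0.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pair_scores.size, size=(n_boot, pair_scores.size))
    means = pair_scores[idx].mean(axis=1)
    return float(means.std(ddof=1))
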