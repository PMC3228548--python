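"""Agglomerative Bayesian hierarchical clustering over GP cluster models.

Every gene starts in its own cluster.  A Dirichlet-process mixture supplies
the prior probability pi_k that two clusters share one latent curve, via
the weight recursion

    d_leaf = alpha,   d_k = alpha Gamma(n_k) + d_i d_j,
    pi_k = alpha Gamma(n_k) / d_k,

and Bayes' rule gives the merge posterior

    r_k = pi_k P(y | H1_k) / P(y | T_k),
    P(y | T_k) = pi_k P(y | H1_k) + (1 - pi_k) P(y | T_i) P(y | T_j),

where P(y | H1_k) is the GP marginal likelihood of the pooled cluster data
at its MAP hyperparameters (optionally the outlier-mixture marginal).  The
pair with the highest r_k is merged at each step until one root remains;
the r < threshold rule is applied afterwards to cut the tree into the
reported partition, so one run yields both the dendrogram and the
partition.  All probabilities are carried in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .config import CRP_ALPHA_GRID, RunConfig
from .dataset import TimeSeriesDataset
from .kernels import KernelParams, build_gram
from .likelihood import (
    OptimizerOptions,
    leave_one_out_terms,
    log_marginal,
    mixture_log_marginal,
    mixture_objective,
    optimize_hyperparameters,
)
from .preprocess import NoisePrior, preprocess

logger = logging.getLogger(__name__)


def log1mexp(x: float) -> float:
    """log(1 - exp(x)) for x <= 0, stable near both ends."""
    if x >= 0.0:
        return -np.inf
    if x > -np.log(2.0):
        return float(np.log(-np.expm1(x)))
    return float(np.log1p(-np.exp(x)))


@dataclass
class ClusterNode:
    """A dendrogram node: a gene set with its merge statistics."""

    members: tuple[int, ...]
    children: tuple["ClusterNode", "ClusterNode"] | None
    log_d: float
    log_pi: float          # 0.0 (log 1) at leaves
    log_mlh: float         # log P(y | H1)
    log_tree: float        # log P(y | T)
    r: float
    params: KernelParams
    a: float = 1.0         # regular-observation weight of the mixture

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Dendrogram:
    """Complete merge tree plus the trace of the agglomeration."""

    root: ClusterNode
    merge_trace: list[dict]
    crp_alpha: float
    kernel: str
    gene_ids: list[str]
    mixture_on: bool = False

    @property
    def root_log_tree(self) -> float:
        """Root log P(y | T): the model-comparison score of the run."""
        return self.root.log_tree

    def to_newick(self) -> str:
        """Label-only Newick: leaves are gene ids, internal labels are r."""
        def render(node: ClusterNode) -> str:
            if node.is_leaf:
                return _newick_safe(self.gene_ids[node.members[0]])
            left, right = node.children
            return f"({render(left)},{render(right)}){node.r:.4f}"
        return render(self.root) + ";"


def _newick_safe(label: str) -> str:
    if any(c in label for c in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class _Context:
    """Shared state for one clustering pass."""

    dataset: TimeSeriesDataset
    times: np.ndarray
    prior: NoisePrior
    kind: str
    mixture_on: bool
    data_range: float
    opts: OptimizerOptions
    fit_cache: dict = field(default_factory=dict)

    def fit_cluster(
        self, members: tuple[int, ...], init: KernelParams | None = None
    ) -> tuple[KernelParams, float, float]:
        """MAP hyperparameters, outlier weight, and log P(y|H1) for a gene set."""
        if members in self.fit_cache:
            return self.fit_cache[members]
        y = self.dataset.profile_vector(list(members))
        params, _ = optimize_hyperparameters(
            y, self.times, len(members), self.kind, self.prior,
            opts=self.opts, init=init,
        )
        gram = build_gram(self.times, len(members), params)
        if self.mixture_on:
            ws = leave_one_out_terms(y, gram)
            mix = mixture_log_marginal(y, gram, self.data_range, workspace=ws)
            a, log_mlh = mix.a, mixture_objective(mix)
        else:
            a, log_mlh = 1.0, log_marginal(y, gram)
        self.fit_cache[members] = (params, a, log_mlh)
        return params, a, log_mlh


def make_leaf(gene: int, crp_alpha: float, ctx: _Context) -> ClusterNode:
    """Singleton cluster: d = alpha, P(y|T) = P(y|H1)."""
    params, a, log_mlh = ctx.fit_cluster((gene,))
    return ClusterNode(
        members=(gene,), children=None,
        log_d=float(np.log(crp_alpha)), log_pi=0.0,
        log_mlh=log_mlh, log_tree=log_mlh, r=1.0, params=params, a=a,
    )


def dpm_prior_merge(
    left: ClusterNode, right: ClusterNode, crp_alpha: float
) -> tuple[float, float]:
    """(log d_k, log pi_k) for merging two disjoint clusters."""
    if set(left.members) & set(right.members):
        raise ValueError("cannot merge overlapping clusters")
    n_k = left.size + right.size
    log_num = float(np.log(crp_alpha) + gammaln(n_k))
    log_d = float(np.logaddexp(log_num, left.log_d + right.log_d))
    log_pi = log_num - log_d
    if not np.isfinite(log_d):
        raise FloatingPointError("non-finite DPM weight")
    return log_d, log_pi


def evaluate_merge(
    left: ClusterNode, right: ClusterNode, crp_alpha: float, ctx: _Context
) -> ClusterNode:
    """Score the merged-cluster hypothesis for a candidate pair."""
    members = tuple(sorted(left.members + right.members))
    log_d, log_pi = dpm_prior_merge(left, right, crp_alpha)
    warm = (left if left.size >= right.size else right).params
    params, a, log_mlh = ctx.fit_cluster(members, init=warm)
    merged = log_pi + log_mlh
    apart = log1mexp(log_pi) + left.log_tree + right.log_tree
    log_tree = float(np.logaddexp(merged, apart))
    r = float(np.clip(np.exp(merged - log_tree), 0.0, 1.0))
    return ClusterNode(
        members=members, children=(left, right),
        log_d=log_d, log_pi=log_pi, log_mlh=log_mlh,
        log_tree=log_tree, r=r, params=params, a=a,
    )


def _pair_key(a: ClusterNode, b: ClusterNode, gene_ids: list[str]):
    """Deterministic, permutation-stable ordering key for a candidate pair."""
    ka = tuple(sorted(gene_ids[g] for g in a.members))
    kb = tuple(sorted(gene_ids[g] for g in b.members))
    return min(ka, kb), max(ka, kb)


def run_bhc(
    dataset: TimeSeriesDataset,
    config: RunConfig | None = None,
    prior: NoisePrior | None = None,
) -> Dendrogram:
    """Cluster a dataset; returns the full dendrogram.

    Preprocesses the dataset in place if needed.  With
    ``config.crp_alpha == "grid"`` the concentration is chosen from a small
    grid by the root tree log marginal likelihood.
    """
    config = config or RunConfig()
    if dataset.profiles is None or prior is None:
        prior = preprocess(
            dataset, omega=config.omega,
            use_replicate_prior=config.use_replicate_prior,
        )
    if isinstance(config.crp_alpha, str):
        best = None
        for alpha in CRP_ALPHA_GRID:
            dend = _run_bhc_fixed_alpha(dataset, config, prior, alpha)
            logger.info("crp_alpha=%g -> root log P(y|T) = %.3f",
                        alpha, dend.root_log_tree)
            if best is None or dend.root_log_tree > best.root_log_tree:
                best = dend
        return best
    return _run_bhc_fixed_alpha(dataset, config, prior, float(config.crp_alpha))


def _run_bhc_fixed_alpha(
    dataset: TimeSeriesDataset,
    config: RunConfig,
    prior: NoisePrior,
    crp_alpha: float,
) -> Dendrogram:
    times = np.asarray(dataset.times, dtype=float)
    if config.kernel == "CS":
        shift = float(times.min())
        if shift != 0.0:
            logger.info("shifting times by %+g so the spline origin is 0", -shift)
        times = times - shift
    ctx = _Context(
        dataset=dataset, times=times, prior=prior, kind=config.kernel,
        mixture_on=config.mixture_on,
        data_range=dataset.value_range if config.mixture_on else 1.0,
        opts=OptimizerOptions(n_restarts=config.n_restarts,
                              gtol=config.gtol, maxiter=config.maxiter),
    )
    active = [make_leaf(g, crp_alpha, ctx) for g in range(dataset.G)]
    merge_trace: list[dict] = []
    candidates: dict = {}

    def ensure_candidate(a: ClusterNode, b: ClusterNode) -> None:
        key = _pair_key(a, b, dataset.gene_ids)
        if key not in candidates:
            candidates[key] = (evaluate_merge(a, b, crp_alpha, ctx), a, b)

    while len(active) > 1:
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                ensure_candidate(active[i], active[j])
        # highest r wins; ties broken by the smallest lexicographic pair key
        best_key = min(
            candidates, key=lambda k: (-candidates[k][0].r, k)
        )
        merged, left, right = candidates.pop(best_key)
        merge_trace.append({
            "left": [dataset.gene_ids[g] for g in left.members],
            "right": [dataset.gene_ids[g] for g in right.members],
            "r": merged.r,
            "log_tree": merged.log_tree,
        })
        active = [n for n in active if n is not left and n is not right]
        stale = {
            k for k, (_, a, b) in candidates.items()
            if a in (left, right) or b in (left, right)
        }
        for k in stale:
            del candidates[k]
        active.append(merged)

    return Dendrogram(
        root=active[0], merge_trace=merge_trace, crp_alpha=crp_alpha,
        kernel=config.kernel, gene_ids=list(dataset.gene_ids),
        mixture_on=config.mixture_on,
    )


def extract_partition(dend: Dendrogram, threshold: float = 0.5) -> pd.DataFrame:
    """Cut the dendrogram into the reported flat clustering.

    Descends from the root, emitting a node as a cluster when it is a leaf
    or its merge posterior exceeds ``threshold``; otherwise its children
    are visited.  Returns one row per gene: gene_id, cluster_id,
    cluster_size, cluster_r.
    """
    clusters: list[ClusterNode] = []

    def descend(node: ClusterNode) -> None:
        if node.is_leaf or node.r > threshold:
            clusters.append(node)
        else:
            descend(node.children[0])
            descend(node.children[1])

    descend(dend.root)
    rows = []
    for cid, node in enumerate(clusters):
        for g in sorted(node.members):
            rows.append({
                "gene_id": dend.gene_ids[g],
                "cluster_id": cid,
                "cluster_size": node.size,
                "cluster_r": node.r,
            })
    return pd.DataFrame(rows, columns=["gene_id", "cluster_id",
                                       "cluster_size", "cluster_r"])


def tree_likelihood_by_enumeration(
    root: ClusterNode, crp_alpha: float, max_leaves: int = 6
) -> float:
    """Reference log P(y|T) by summing over tree-consistent partitions.

    A partition is tree-consistent when each of its blocks is a node of
    the tree.  Each partition V is weighted by the Dirichlet-process mass
    implied by the d-recursion,

        w(V) = alpha^{|V|} prod_c Gamma(n_c) / d_root,

    and contributes w(V) * prod_c P(y_c | H1_c), reusing the per-node
    marginals stored in the tree.  Equals the recursive log_tree; intended
    for validation on small trees.
    """
    n_leaves = root.size
    if n_leaves > max_leaves:
        raise ValueError(f"enumeration oracle limited to {max_leaves} leaves")
    log_alpha = float(np.log(crp_alpha))

    def partitions(node: ClusterNode) -> list[list[ClusterNode]]:
        if node.is_leaf:
            return [[node]]
        out = [[node]]
        left, right = node.children
        for pl in partitions(left):
            for pr in partitions(right):
                out.append(pl + pr)
        return out

    terms = []
    for part in partitions(root):
        log_w = len(part) * log_alpha - root.log_d
        log_w += sum(float(gammaln(c.size)) for c in part)
        terms.append(log_w + sum(c.log_mlh for c in part))
    return float(logsumexp(terms))
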