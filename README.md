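# gpbhc

Bayesian hierarchical clustering of gene-expression time courses with
Gaussian-process cluster likelihoods.

## What problem this solves

Time-course transcriptomics experiments measure many genes over a handful
of (often unevenly spaced) time points, frequently with replicates.
Grouping genes with similar temporal profiles suggests co-regulation, but
distance-based clustering ignores the time ordering, gives no principled
number of clusters, and is easily derailed by single outlier measurements.
`gpbhc` addresses all three: it clusters profiles under a generative model
that respects time, learns the number of clusters from the data, models a
small fraction of observations as outliers, and uses replicate scatter to
inform the noise level.

## The method in brief

Each gene starts as its own cluster.  A cluster's data are modelled as one
latent curve f ~ GP(0, Σ) shared by its genes plus iid Gaussian noise, so
the cluster marginal likelihood is N(y; 0, Σ_T ⊗ J_G + σ²_ε I), with a
squared-exponential or cubic-spline kernel.  A Dirichlet process mixture
supplies the prior π_k that two clusters share a curve, and Bayes' rule
gives the merge posterior

    r_k = π_k P(y|H1_k) / P(y|T_k),
    P(y|T_k) = π_k P(y|H1_k) + (1 − π_k) P(y|T_i) P(y|T_j).

The pair with the highest r_k merges at each step; afterwards the tree is
cut wherever r drops below 0.5, which simultaneously fixes the number of
clusters.  Optionally the per-observation likelihood is a mixture of the
Gaussian and a constant outlier density 1/Range (first-order
approximation, with a closed-form optimal outlier weight), and with
replicates a Gamma prior on σ²_ε is calibrated from the measurement-error
variance.  The block structure Σ_T ⊗ J_G + σ²_ε I reduces all linear
algebra to a single T × T factorization per likelihood evaluation.

See `docs/methods.md` for the full model, parameter meanings, and
limitations.

## Worked example

```sh
python examples/cluster_simulated_timecourses.py
```

simulates 30 genes from three Gaussian processes (length scales 1, 2 and
4 time units, noise sd 0.3), clusters them and prints:

```
recovered clusters : 3  (planted: 3)
adjusted Rand index: 1.000
average within-cluster PCC: 0.871 +/- 0.006
root merge posterior r = 0.0000 (< 0.5 means the top-level split is real)
root log P(y|T) = -206.9
```

The algorithm found exactly the three planted clusters (adjusted Rand
index 1 against the simulation truth), the clusters are internally
coherent (mean within-cluster Pearson correlation 0.87), and the root's
merge posterior near 0 says the top-level split is strongly supported —
the data should not be one cluster.

Other examples: `outlier_rescue.py` (a gene with one corrupted time point
stays with its cluster only under the mixture likelihood),
`replicate_noise_prior.py` (replicate-informed prior improves noise
recovery), `score_partition.py` (average PCC and Biological Homogeneity
Index with bootstrap errors).

A thin CLI wraps the same pipeline:

```sh
gpbhc simulate --outdir sim --seed 1
gpbhc cluster --input sim/expression.tsv --sidecar sim/times.yaml \
              --outdir out --kernel SE --mixture
gpbhc score --partition out/partition.tsv --input sim/expression.tsv \
            --sidecar sim/times.yaml
```

`cluster` writes a Newick dendrogram (internal labels are merge
posteriors), a partition TSV, a scores TSV and a JSON run report.

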