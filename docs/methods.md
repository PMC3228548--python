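# Methods

## Model

`gpbhc` clusters gene-expression time courses by Bayesian hierarchical
clustering (BHC): greedy agglomeration in which each candidate merge is
scored by a posterior probability rather than a distance.  The
probabilistic ingredients are:

**Cluster likelihood.**  All genes in a cluster are assumed to share one
latent curve f drawn from a zero-mean Gaussian process; each observation is
y_g(t) = f(t) + ε with iid Gaussian noise ε ~ N(0, σ²_ε).  Stacking the G
genes' profiles over the T time points (time-major), the marginal
likelihood of the cluster is the Gaussian density

    P(y | θ) = N(y; 0, K),    K = Σ_T ⊗ J_G + σ²_ε I,

where Σ_T is the noise-free T × T kernel matrix and J_G the all-ones
matrix.  Two kernels are provided: squared exponential
k(t,t') = σ²_f exp(−(t−t')²/2l²) for smooth stationary dynamics, and cubic
spline k(t,t') = σ²_f (|t−t'| v²/2 + v³/3), v = min(t,t'), which encodes
integrated-Wiener dynamics pinned at the time origin and has no length
scale.  Hyperparameters are fitted per evaluated cluster by maximizing the
log marginal likelihood (plus the noise prior below) with L-BFGS on
log-parameters, using the analytic gradient
½ tr((γγᵀ − K⁻¹) ∂K/∂θ), γ = K⁻¹y.

**Merge prior and posterior.**  A Dirichlet process mixture with
concentration α supplies the prior π_k that two clusters belong together,
through the weight recursion d_leaf = α, d_k = αΓ(n_k) + d_i d_j,
π_k = αΓ(n_k)/d_k.  The merge posterior is
r_k = π_k P(y|H1_k) / P(y|T_k) with the tree likelihood
P(y|T_k) = π_k P(y|H1_k) + (1−π_k) P(y|T_i) P(y|T_j).  The pair with the
highest r_k is merged at each step; the full tree is always built and the
partition is read off afterwards by descending from the root and emitting
any node whose r exceeds the threshold (default 0.5).  The root's
P(y|T) doubles as a model-comparison score between kernels.

**Outlier mixture.**  Optionally each observation is modelled as a mixture
of the regular Gaussian component (weight a) and a constant outlier
density B = 1/Range, with Range the spread of all normalized observations
in the dataset.  Expanding the likelihood product and keeping terms with
at most one outlier gives

    P(y|θ) ≈ a^N V1 + a^{N−1}(1−a) V2,
    V1 = N(y; 0, K),   V2 = Σ_n B · N(y_{−n}; 0, K_{−n}),

and after the hyperparameters are fitted with a = 1, the weight is set to
the closed-form maximizer a_max = (1−N)V2 / (N(V1−V2)), clamped to 1
outside (0, 1).  Higher-order outlier terms are deliberately dropped; the
truncation error is bounded by the neglected mass and checked against
exact subset enumeration in the tests.

**Replicate-informed noise prior.**  Profiles are replicate means, each
gene normalized to mean 0 and sample (n−1) sd 1.  With R ≥ 2 replicates,
the replicate scatter around the means estimates the measurement-error
variance of an averaged observation,

    σ²_m = Σ_{t,g,r} (y_{r,g,t} − ȳ_{g,t})² / (R (GRT − 1)),

computed once over the whole dataset on the normalized scale (replicates
are transformed by the same per-gene affine map as the profiles).  A
Gamma(α, β) prior on σ²_ε is then calibrated so its density is equal at
σ²_m and at 1 (the approximate post-normalization data variance) and its
mode, which the equal-density constraint pins at (1−σ²_m)/(−log σ²_m), is
Ω = 100 times higher than that common density.  These two constraints have
an exact closed-form solution (the second is linear in α−1), so no
iterative root find is needed.  Without replicates the prior is flat.

## Fast linear algebra

Because genes in a cluster are exchangeable, J_G has one eigenvalue G (the
per-time gene mean) and G−1 zeros (residuals), so every determinant,
solve, trace and gradient term reduces to the T × T matrix
A = G Σ_T + σ²_ε I:

    log|K| = log|A| + (G−1) T log σ²_ε,
    K⁻¹y  = (A⁻¹ m) ⊗ 1_G + r / σ²_ε,

with m the per-time means and r the residuals.  This is what makes
per-merge hyperparameter fits cheap.  Leave-one-out terms for the mixture
use the conditional factorization p(y) = p(y_{−n}) p(y_n | y_{−n}): after
one dense factorization of K, each term costs O(1) via
Var(y_n | y_{−n}) = 1/(K⁻¹)_{nn}.  A per-n dense refactorization path is
retained as the reference implementation.

## Parameters that matter

- `crp_alpha` (default 1e-3): DPM concentration; smaller values favour
  merging.  The value is not identified by theory alone, so `"grid"`
  selects from {1e-3, 1e-2, 1e-1, 1} by root log P(y|T).
- `omega` (default 100): density ratio between the noise prior's mode and
  its anchors; larger values sharpen the prior around the mode.
- `partition_threshold` (default 0.5): posterior level at which a subtree
  is reported as one cluster; 0.5 is the point where merging becomes more
  likely than not.
- Optimizer: 3 deterministic restarts (moment-based initial point shifted
  by ±1, ±2 in log space), gradient tolerance 1e-6, at most 200
  iterations, log-parameters bounded to ±12 to keep factorizations sane.
- Jitter: T-level Cholesky failures escalate a diagonal jitter from 1e-10
  by factors of 10 up to 1e-6; the noise variance has a hard floor of
  1e-10 below which the block structure is declared degenerate.
- Times are used in their native units (the SE length scale is in user
  time units); for the cubic-spline kernel the time axis is shifted so the
  earliest observation sits at the origin, since the kernel presumes one.

## Synthetic data

The simulator draws one latent curve per cluster (shared by its genes,
matching the model), adds per-gene observation noise, and per-replicate
measurement noise.  Default study conditions are three well-separated
squared-exponential clusters — unit signal variance, length scales
geometrically spaced over 1–4 time units — with 10 genes each, 12
unit-spaced time points and observation noise sd 0.3; replicate
experiments use R = 4 with replicate sd 0.4 and observation sd 0.2, and
outlier experiments displace one (gene, time) cell by 4 observation-noise
sd in a 2 × 8-gene, T = 10, sd 0.25 design.  What this does **not**
emulate: heavy-tailed or multiplicative microarray noise, missing cells,
probe-level artefacts, and correlated biological variation between genes
beyond the shared curve.  Passing the recovery tests therefore shows the
algorithm is correct under its own generative assumptions, not that real
microarray clusterings will be equally clean.

A note on identifiability: because each cluster's genes share a single
latent realization, the cluster signal variance σ²_f is informed by one GP
draw no matter how many genes are present; its sampling error is
irreducibly large (roughly √(2/k) relative, with k the number of
effective independent points of the draw).  Length scale and noise
variance are well identified.  Tests assert tight recovery only for the
identifiable parameters.

## Numerical and design choices

- All probabilities (d, π, tree likelihoods, mixture terms) are carried in
  log space; r is an exp of a log-ratio clamped to [0, 1].
- Merge ties are broken by the lexicographically smallest pair of member
  gene-id tuples, which makes runs deterministic and partition output
  invariant to input gene order.
- Hyperparameters are fitted once per evaluated gene set and cached; a
  candidate merge warms its fit from the larger child's parameters.
- The outlier weight a is recomputed for every evaluated cluster (the
  alternative — freezing a after a cluster first forms — was rejected so
  that merge scores stay comparable).
- σ²_m is computed globally rather than per cluster so that a single prior
  applies to every merge score; with ragged replicate counts the balanced
  formula generalizes by replacing R with the mean replicate count and GRT
  with the total measurement count (the balanced case is recovered
  exactly, which is unit-tested).
- Degenerate inputs: constant genes are rejected by name before
  normalization; missing values are accepted only as whole replicate
  columns and are dropped with a warning; a measurement-error estimate
  outside (0, 1) falls back to the flat prior with a warning.

## Known limitations

- Greedy agglomeration commits to merges; no tree search or
  reclassification pass is performed.
- The outlier mixture is first order — two simultaneous outliers within
  one cluster are outside the model.
- The cubic-spline kernel forces zero variance at the (shifted) time
  origin, so the first time point is explained entirely by noise.
- Run time is dominated by the O(G²) candidate hyperparameter fits;
  datasets of a few hundred genes are practical, thousands are not.
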