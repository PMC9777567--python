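# Methods

## Scope and units

Every information quantity in the package is reported in **bits** (log base
2); all public functions accept a `base` argument where another base is
meaningful. Inputs are samples-by-variables matrices
(`TimeSeriesMatrix`); rows are time points, columns named channels/regions.

## Exact oracles

Two families of closed forms anchor the test suite and are exposed as
library functions:

* **Discrete joints** (`DiscreteJoint`): entropy, mutual information, Total
  Correlation (both the sum-of-entropies and the KL form, cross-checked),
  conditional TC, and the latent-factor decomposition identity
  TC(X) − TC(X|Y) = Σᵢ I(Xᵢ;Y) − I(X;Y), whose two sides are computed
  independently; the residual is below 1e-10 on every valid joint and is
  verified on 1000 seeded Dirichlet(1) random joints.
* **Gaussian models**: TC(Σ) = ½·log₂(Πᵢσᵢᵢ / det Σ); for two variables
  with correlation ρ this is −½·log₂(1−ρ²).

## Sample estimators

* **Binned plug-in**: equal-frequency bins per column (ordinal-rank ties,
  exactly balanced counts), empirical joint, discrete TC. The plug-in bias
  is ≈ (Πkᵢ − Σkᵢ + d − 1)/(2N ln 2) bits and positive, so the bin count
  must keep the joint histogram populated; the estimator-comparison runner
  sizes bins by k = max(2, ⌊(N/10)^(1/d)⌋) (cells ≈ N/10), a rule fixed a
  priori from the bias formula. With d = 3 and the module default of 8 bins
  the bias alone is ≈ 0.35 bits at N = 1000 — the discrete-Shannon baseline
  genuinely needs large samples.
* **Gaussian copula**: average ranks → (r−½)/n → standard-normal quantile →
  empirical correlation → Gaussian closed form. Single-pass member of the
  Gaussianisation family; exactly invariant to monotone marginal
  transforms; captures only Gaussian-copula dependence.
* **Matrix-based Rényi α-entropy** (α = 1.01 default): per variable a
  trace-normalised Gaussian-kernel Gram matrix, S_α from its eigenvalues;
  joint entropy from the trace-normalised Hadamard product; TC = ΣS_α(Xᵢ) −
  S_α(X). Kernel width = per-variable median pairwise distance (floored at
  1e-6); negative eigenvalues from rounding are clipped at zero with a
  warning. Gram matrices are n×n, so inputs longer than `max_samples`
  (default 2000) are evenly strided down before estimation.

## The CorEx optimiser

Per layer with m factors of `n_states` discrete states (default 2), on
z-scored columns:

1. **E-step**: log p(yⱼ=s|x) ∝ log p(yⱼ=s) + Σᵢ α_ij·[log p(xᵢ|yⱼ=s) −
   log p(xᵢ)], normalised per factor; p(xᵢ|yⱼ=s) is a univariate Gaussian
   per state (variance floored at 1e-4 after z-scoring) and p(xᵢ) the
   factor's own state-mixture — a continuous-margin model chosen because
   fMRI inputs are continuous while the factors stay discrete.
2. **M-step**: state priors and per-state means/variances from soft counts.
3. **MI step**: plug-in I(Xᵢ;Yⱼ) = E_q[log p(xᵢ|yⱼ) − log p(xᵢ)] and
   I(Yⱼ;X) = E_q[log q(yⱼ|x) − log p(yⱼ)], both clipped at 0.
4. **α step**: α* = exp(γ(I_ij − maxⱼ I_ij)), α ← (1−λ)α + λα*, with
   λ = 0.3 (smooth trajectories) and γ = 10 (sharply peaked competition);
   both exposed in `CorexConfig`.

Three numerical choices deserve emphasis because the bare recipe above does
not determine them:

* **Initialisation / symmetry breaking.** The uniform posterior is a fixed
  point of the updates, so random per-state means (sd 0.5) seed the first
  E-step. The per-column random streams are keyed to a hash of the column
  *content*, which makes fits equivariant under column permutations up to
  floating-point reordering noise (measured: identical cluster partitions,
  bounds agreeing to ~1e-5). α starts at 1/m plus 1e-3 jitter.
* **Bound accounting.** The reported bound Σⱼ[Σᵢ α_ij·I(Xᵢ;Yⱼ) − I(Yⱼ;X)]
  uses α row-normalised to sum ≤ 1, so a variable's dependence is never
  credited to two factors simultaneously while they compete for it; the α
  *dynamics* are the unnormalised update above (capping the dynamics
  instead destroys the factors' ability to recruit variables).
* **Incumbent tracking.** The optimiser is a hill-climber on the accounted
  bound: the best iterate seen is retained and returned, `bound_history`
  records the incumbent bound per iteration (hence non-decreasing by
  construction), and convergence is declared when the incumbent improves by
  less than `tol` = 1e-5 bits over a 10-iteration window (cap 200
  iterations). Raw iterate trajectories show transient dips of up to ~0.1
  bits while two factors contend for the same block; the incumbent is never
  worse than the final iterate. Best of `n_restarts` = 3 seeded restarts is
  returned; restart r uses seed + 1000·r.

**Hierarchy**: layer k is fit on layer k−1's per-sample posterior mean of
the state index (continuous; MAP labels are available via
`representation(map_states=True)`), so upper layers reuse the same
Gaussian-margin machinery; the total bound is the sum of layer bounds.
Constant upper-layer columns (dead factors) are zeroed rather than
rejected. **Clustering**: variable i → argmaxⱼ α_ij·I(Xᵢ;Yⱼ), ties to the
lowest factor index, variables below ε = 1e-4 bits labelled unclustered;
note that the finite-sample noise floor of the MI table is ~1e-3 bits at
n = 500, so weakly attached variables generally clear ε.

Models serialise to versioned JSON (`tcnet-corex-1`): α, MI tables, priors,
marginal parameters, bound histories and config round-trip bit-exactly;
per-sample posteriors are not stored.

## Connectivity and graphs

Pearson (unit diagonal), pairwise MI in bits (zero diagonal; binned or
copula), and partial correlation −P_ij/√(P_ii·P_jj) from the precision
matrix P (trace-scaled ridge 1e-6 on singular covariances). Thresholding
keeps edges ≥ τ, on |w| for correlation methods and raw w for MI; pairwise
clusters are the connected components of the thresholded graph (isolated
nodes are singletons). The CorEx tree graph links each child to its
strongest parent only (guaranteeing a forest), drops edges below 0.16 bits
by default for legibility, and normalises node sizes (TC explained) to a
maximum of 1. Export: GraphML and a JSON node/edge schema.

## Synthetic study conditions

* **Independent Gaussians** — n_vars i.i.d. N(0,1) columns; TC = 0 exactly.
  The null benchmark uses 3 variables, n = 1000, 20 seeds.
* **Dependent/independent mixture** — X₁..X₃ i.i.d. N(0,1); Y₁ ~ N(0,1),
  Y₂ = Y₁+ε₂, Y₃ = Y₂+ε₃, ε ~ N(0, 0.5²); columns z-scored; ground truth
  {{X₁},{X₂},{X₃},{Y₁,Y₂,Y₃}}. The chain noise sd 0.5 makes the Y chain
  strong (ρ(Y₁,Y₂) = 1/√1.25 ≈ 0.894) while spurious X edges remain
  possible at the default n = 500. Benchmark thresholds: Pearson 0.1,
  binned MI 0.4 bits, partial correlation at the ≈2-standard-error rule
  2/√n (a literal zero threshold always yields one component), CorEx
  layer_sizes [2,1]; medians over 20 seeds.
* **Modular blocks** — one latent factor per block,
  xᵢ = √ρ·factor + √(1−ρ)·noise; within-block population correlation
  exactly ρ; block TC has the equicorrelation closed form. Recovery
  benchmark: 3 blocks × 4 variables, ρ = 0.6, n = 2000.
* **Labeled image** — contiguous integer-labelled voxel blocks sharing a
  planted course plus voxel noise; label 0 is background. Exercises the
  §ROI pipeline: per-region uniform voxel mean (the "weighted average" with
  uniform weights — a weight-volume hook is the natural extension), z-score
  normalisation, integer-factor subsampling, subject averaging.

These generators emulate second-order (Gaussian) dependence with exact
ground truth; they do not emulate haemodynamic autocorrelation, non-Gaussian
margins beyond what the copula transform removes, or between-subject
variability — so passing tests demonstrate correctness of the estimators
and optimiser under known conditions, not performance on real BOLD data.

## Purity and its conventions

Purity(X,Y) = (1/N)·Σᵢ maxⱼ |Xᵢ∩Yⱼ| over clusters X and classes Y. Two
degeneracies matter and are deliberately documented: an all-singleton
clustering is maximally pure, and with the mixture's ground-truth classes
the minimum attainable purity is 0.5 (a single mega-cluster). Consequently
pairwise methods that correctly isolate the independent variables as
singletons score 1.0 on the mixture benchmark, and CorEx — whose two
factors absorb the independent variables at noise-floor weights — typically
scores 2/3. Reported comparisons in parts of the connectivity literature
appear to follow a stricter counting (consistent with purity =
n_clusters/N, i.e. all-singleton classes); `run_experiment2` reports the
standard metric above, per-seed, so either convention can be recomputed
from its table.

## Known limitations

* The CorEx bound is a sample estimate of a lower bound: with few samples
  and many states it can overfit upward; the benchmarks use n ≥ 500.
* Factor count per layer is user-chosen; there is no automatic model
  selection, and thresholds for graph legibility are fixed constants, not
  optimised for modularity.
* The Rényi estimator's O(n²) memory bounds it to ~2000 samples per call
  (strided subsampling beyond); the binned estimator is limited by the
  curse of dimensionality through its joint histogram.
* Directed measures (transfer entropy), k-NN MI estimators and full
  iterative Gaussianisation (rotation + marginal Gaussianisation) are out
  of scope.
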