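# tcnet — Total-Correlation functional connectivity

`tcnet` infers **multivariate** statistical dependence among many
simultaneously recorded signals — typically fMRI BOLD time series averaged
over atlas-defined brain regions — using **Total Correlation** (TC,
multi-information) instead of purely pairwise measures, and explains that
dependence with a hierarchy of discrete latent factors (**Correlation
Explanation**, CorEx). It is aimed at researchers building functional
connectomes who want dependence structure *beyond* what Pearson correlation
or pairwise mutual information can express.

## The quantities at its core

For variables X = (X₁, …, Xₙ), Total Correlation is

    TC(X) = Σᵢ H(Xᵢ) − H(X₁, …, Xₙ) = D_KL( p(x) ‖ Πᵢ p(xᵢ) )

in bits; it is zero iff the variables are jointly independent, and reduces
to mutual information I(X₁;X₂) for n = 2. CorEx searches for m discrete
latent factors Y = (Y₁..Y_m) with a factorised posterior
p(y|x) = Πⱼ p(yⱼ|x) that maximise the tractable lower bound

    TC(X) ≥ Σⱼ [ Σᵢ α_ij I(Xᵢ;Yⱼ) − I(Yⱼ;X) ],   α_ij ∈ [0, 1],

with the exponential competition update
α* = exp(γ(I(Xᵢ;Yⱼ) − maxⱼ I(Xᵢ;Yⱼ))), α ← (1−λ)α + λα*. Stacking layers
(each fit on the layer below's factor representation) tightens the bound
additively and yields an interpretable tree: edge weight α_ij·I(Xᵢ;Yⱼ),
node size proportional to the TC a factor explains about its children, and
variable clusters from argmaxⱼ α_ij·I(Xᵢ;Yⱼ).

The package also provides the standard baselines around that core: exact
entropies/MI/TC on small discrete joints and Gaussian models (the test
oracles), sample TC estimators (equal-frequency binned plug-in,
Gaussian-copula, matrix-based Rényi α-entropy), pairwise connectivity
(Pearson, mutual information, partial correlation from the precision
matrix), graph thresholding with connected-component clustering, purity
evaluation, seeded synthetic generators, and ROI extraction from 4D NIfTI
images.

## Worked example

Twelve "regions" in three independent blocks of four, within-block
correlation 0.6 (the generating model's closed-form TC is 3.7205 bits —
the bound must stay below it):

```python
from tcnet import Corex
from tcnet.synthetic import gen_modular_blocks

ts, truth = gen_modular_blocks((4, 4, 4), within_rho=0.6, n_samples=2000, seed=0)
res = Corex(ts, layer_sizes=[3, 1], seed=0).fit()
print(res.summary())
```

```
CorEx Total Correlation lower bound
====================================================
Observed variables: 12
Layer sizes:        [3, 1]
Total bound:        2.3820 bits
----------------------------------------------------
Layer 0: m=3, bound=2.3801 bits, 49 iterations
  factor 0: TC explained 0.7671 bits; children: B2V2 (0.412), B2V3 (0.385), B2V1 (0.371), B2V4 (0.347)
  factor 1: TC explained 0.7965 bits; children: B3V3 (0.435), B3V2 (0.384), B3V4 (0.383), B3V1 (0.358)
  factor 2: TC explained 0.8164 bits; children: B1V4 (0.409), B1V3 (0.407), B1V2 (0.390), B1V1 (0.377)
----------------------------------------------------
Layer 1: m=1, bound=0.0019 bits, 54 iterations
  factor 0: TC explained 0.0019 bits; children: L1F0 (0.819), L1F2 (0.002), L1F1 (0.000)
```

Each first-layer factor claims exactly one planted block (the numbers in
parentheses are the edge weights α_ij·I(Xᵢ;Yⱼ) in bits), the 2.38-bit bound
sits below the 3.72-bit ground truth, and the near-zero second-layer bound
says the three blocks are mutually independent — all three facts match how
the data were generated. `res.clusters()` recovers the block partition
exactly, and `res.save("model.json")` writes a versioned model file.

The same workflow is available from the shell:

```sh
tcnet simulate --kind modular_blocks --n 2000 --seed 0 --out ts.tsv
tcnet corex --input ts.tsv --layers 3,1 --seed 0 --out model.json
tcnet graph --input model.json --from-model --tau 0.16 --out tree.graphml
tcnet exp2 --seeds 20 --out exp2.tsv     # four-method purity comparison
```

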