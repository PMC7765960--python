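# gdcoxs — set-wise differential interaction of copy-number alterations and gene expression

Copy-number alterations (CNAs) drive cancer progression partly through
their effect on transcription. Whether the *coupling* between a pathway's
CNAs and its expression profile differs between two clinical conditions
(say, survivors vs non-survivors) is a question that single-gene
correlation tests answer poorly: gene-level effects are small, the tests
are many, and the coupling is a property of the gene set, not of any one
gene.

`gdcoxs` implements a set-wise differential-interaction screen for
integrative CNA × expression analysis. It is aimed at computational
biologists working with gene-level thresholded copy-number calls
(GISTIC-style, {−1, 0, +1}), a matched expression matrix, and a pathway
collection in GMT format.

## The method

For one gene set with `d` member genes and one condition with `n`
samples, each data type's sub-matrix is modelled as a multivariate normal
whose covariance Σ is estimated with Schäfer–Strimmer shrinkage (sample
correlations shrunk toward the identity with an analytic intensity
λ* ∈ [0, 1], rescaled by the sample variances), so Σ is positive definite
and invertible even when `n < d`. The distance between two samples is the
Rényi quadratic divergence, estimated as the log density ratio

    D₂(Sᵢ‖Sⱼ) = log f̂(Sᵢ) − log f̂(Sⱼ)
              = −½ [(xᵢ−µ)ᵀΣ⁻¹(xᵢ−µ) − (xⱼ−µ)ᵀΣ⁻¹(xⱼ−µ)],

the Gaussian normalising constants cancelling exactly. The **interaction
score (IAS)** of the set in that condition is the Pearson correlation
between the upper-triangle entries of the CNA and the expression
divergence matrices:

    IAS = corr( {D₂ᶜ(Sᵢ‖Sⱼ)}ᵢ<ⱼ , {D₂ᴳ(Sᵢ‖Sⱼ)}ᵢ<ⱼ ).

The **differential interaction** between conditions a and b is contrasted
on the Fisher-z scale,

    diffIAS = [atanh(IASₐ) − atanh(IAS_b)] / √(1/(mₐ−3) + 1/(m_b−3)),

with `m = n(n−1)/2` sample pairs per group, and its significance comes
from a label-permutation null (group sizes preserved, the CNA/expression
pairing of every sample kept, everything recomputed per permutation),
with Bonferroni correction over the gene-set family. Comparators are
included: the product-kernel density baseline (dCoxS) and differential
Mantel tests with Euclidean/Manhattan/Mahalanobis distances.

## Worked example

```python
import numpy as np
from gdcoxs.io import ConditionLabels, GeneSetCollection, MatrixKind, OmicsMatrix
from gdcoxs.model import SetwiseDifferentialInteraction
from gdcoxs.simulate import simulate_cna

rng = np.random.default_rng(7)
n = 60  # samples per condition

# 24 genes; in the first set expression tracks copy number only in group A
cna = simulate_cna(2 * n, 24, rng=rng)
ge_values = simulate_cna(2 * n, 24, rng=rng).values + 0.3 * rng.standard_normal((24, 2 * n))
ge_values[:12, :n] = cna.values[:12, :n] + 0.3 * rng.standard_normal((12, n))
ge = OmicsMatrix(ge_values, cna.gene_ids, cna.sample_ids, MatrixKind.GE)

labels = ConditionLabels({s: ("A" if j < n else "B") for j, s in enumerate(cna.sample_ids)})
sets = GeneSetCollection({
    "COUPLED": ("demo", cna.gene_ids[:12]),
    "NULL": ("demo", cna.gene_ids[12:]),
})

model = SetwiseDifferentialInteraction(cna, ge, labels, sets)
results = model.fit(n_permutations=999, alpha=0.05, seed=1)
print(results.summary())
```

which prints:

```
Set-wise differential interaction (CNA x GE)
============================================================
method:            gdcoxs
groups:            A (reference) vs B
samples:           120 (A: 60, B: 60)
gene sets tested:  2
permutations:      999   seed: 1
alpha:             0.05   Bonferroni per-test threshold: 0.025
significant sets:  1 (diffIAS > 0: 1, diffIAS < 0: 0)
------------------------------------------------------------
set_name  n_cna  n_exp  ias_group_a  ias_group_b  diff_ias  p_value  significant
 COUPLED     12     12       0.7291      -0.1331     31.53    0.001         True
    NULL     12     12      -0.1694       0.0816    -7.514    0.264        False
```

The coupled set's interaction score is high in group A (0.73, expression
distances track copy-number distances) and near zero in group B; the
Fisher-z contrast is large and the permutation p-value bottoms out at
1/(B+1) = 0.001, significant after Bonferroni correction. The null set's
scores are near zero in both groups. The same screen is available from
the shell (`gdcoxs run --cna ... --ge ... --labels ... --gmt ...`), with
`gdcoxs simulate` and `gdcoxs benchmark` for the simulation studies and
comparator methods.

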