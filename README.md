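# smbpls — sparse multi-block PLS for multi-omics module discovery

Gene expression is shaped simultaneously by copy-number variation (CNV),
DNA methylation (DM) and microRNA expression (ME).  Multi-dimensional
genomic datasets profile all of these layers on the same cohort of samples,
and the question becomes: which *subsets* of regulatory variables from the
different layers jointly explain the expression of which *subsets* of
genes, across which *subsets* of samples?  Such a coordinated group — a
sample set, a variable set per input omics block, and a gene set — is a
multi-dimensional regulatory module (MDRM).

`smbpls` implements sparse Multi-Block Partial Least Squares regression for
discovering these modules, for computational biologists working with
matched multi-omics matrices.  Given centered input blocks X_1..X_R and a
response block Y on the same K samples, one component maximizes the sample
covariance

    cov(t, u),   t = [X_1 w_1, ..., X_R w_R] b,   u = Y q,

over unit-norm loadings w_i, q and block weights b, subject to lasso
penalties that keep only a requested number of nonzero entries (the
"degree of sparsity") in each loading — and optionally in the latent
variables t_i and u themselves, which selects samples.  Penalties are
applied by soft thresholding, sign(x)·max(|x| − λ, 0), with λ induced from
the degree via an order statistic.  The nonzero supports of the converged
component are the module; deflating the fitted signal out of every block
and refitting extracts modules one by one.  The package also ships the
classic (non-sparse) MBPLS solver, the two-step top-|loading| baseline
built on it, a single-merged-block sparse PLS baseline, L-fold
cross-validation for degree selection, a planted-module simulator, and
hypergeometric overlap statistics for scoring modules against each other
or against a planted truth.

## Worked example

Estimators follow scikit-learn conventions (`fit`, fitted attributes with a
trailing underscore, `get_params`/`set_params`); `MultiBlockDataset` or
plain arrays are accepted.

```python
import dataclasses
from smbpls import (SparseMBPLS, block_weight_significance, default_scenario,
                    preprocess, recovery_report, simulate_dataset)

config = dataclasses.replace(default_scenario("benchmark"),
                             latent_scale=1.0, seed=7)
dataset, truth = simulate_dataset(config)          # 100 samples; CNV/DM/ME 200 vars each; 200 genes
dataset = preprocess(dataset, scale=False, cv_filter_threshold=0.0)

est = SparseMBPLS(loading_degrees=(30, 30, 30), response_degree=30,
                  sample_degree=20, max_modules=1).fit(dataset)
module = est.modules_[0]

print(f"objective (cov of t and u): {est.objective_:.3f}")
print("block weights: " + ", ".join(
    f"{n}={w:.3f}" for n, w in zip(dataset.block_names, module.block_weights)))
print(f"selected: {len(module.sample_ids)} samples, "
      + ", ".join(f"{len(module.selected_variables[n])} {n}" for n in dataset.block_names)
      + f", {len(module.selected_response)} genes")
report = recovery_report(est.result_, truth)
print(f"recovered fraction vs planted truth: {report.recovered_fraction:.2f}")
row = report.table.iloc[0]
print("per-dimension Jaccard vs truth: " + ", ".join(
    f"{d}={row['jaccard_' + d]:.2f}" for d in ["CNV", "DM", "ME", "response", "samples"]))
for name, (r, p) in block_weight_significance(est.fits_[0]).items():
    print(f"latent correlation {name} vs GE: r={r:.3f}, p={p:.2e}")
```

prints

```
objective (cov of t and u): 4.217
block weights: CNV=0.538, DM=0.617, ME=0.575
selected: 17 samples, 30 CNV, 30 DM, 30 ME, 30 genes
recovered fraction vs planted truth: 1.00
per-dimension Jaccard vs truth: CNV=0.67, DM=0.88, ME=0.71, response=0.88, samples=0.61
latent correlation CNV vs GE: r=0.960, p=1.05e-09
latent correlation DM vs GE: r=0.956, p=2.26e-09
latent correlation ME vs GE: r=0.968, p=2.20e-10
```

The component's covariance objective is 4.217; the block weights say all
three omics layers contribute comparably to it.  The module selects 17 of
the 100 samples and 30 variables per dimension; `recovery_report` confirms
a statistically significant overlap with the planted module in every
dimension (hypergeometric test, Bonferroni-corrected), and
`block_weight_significance` (last three lines) shows each block's latent
variable tracks the gene-expression latent on the module's samples.

The same pipeline runs from the shell on tab-separated matrices:

```
smbpls simulate --scenario noiseless --seed 1 --out-dir data/
smbpls fit --block data/CNV.tsv --block data/DM.tsv --block data/ME.tsv \
           --response data/GE.tsv --degrees 30,30,30 --response-degree 30 \
           --sample-degree 20 --no-scale --out modules.json
smbpls evaluate --modules modules.json --truth data/truth.json --out report.tsv
```

`smbpls tune` cross-validates a YAML grid of degree combinations.

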