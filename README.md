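# chemcca

Regularized canonical correlation analysis (rCCA) linking **chemical descriptor
space** to **genome-wide drug-response space**.

Given a compound library measured in two views — a descriptor table `X`
(compounds × chemical descriptors, e.g. 3D molecular-field descriptors) and a
biological activation table `Y` (compounds × gene sets, signed GSEA-derived
activations in [−1, 1]) — the package decomposes the relationship between the
two spaces into correlated components, validates them by drug-similarity
retrieval against external annotations (protein targets / therapeutic class
codes), assesses their significance by permutation, and characterizes each
component's chemistry and biology. Intended users are computational chemists
and systems biologists running chemical-systems-biology analyses on
transcriptional drug-response compendia.

## The model

rCCA seeks projection pairs (w_s, v_s) maximizing the ridge-penalized
correlation of the canonical variates,

```
P_s = max  w'C_xy v / sqrt( (w'C_xx w + λ₁‖w‖²) (v'C_yy v + λ₂‖v‖²) ),
```

subject to var(Xwₛ) = var(Yvₛ) = 1 and uncorrelatedness between components,
where C_xx = X'X/(n−1), C_yy, C_xy are centered feature-space (cross-)
covariances. The solution is the symmetric eigenproblem of
`(C_xx+λ₁I)^{-1/2} C_xy (C_yy+λ₂I)^{-1} C_yx (C_xx+λ₁I)^{-1/2}`; ridge
penalties keep it well-posed when features are collinear or outnumber
compounds. λ₁, λ₂ are chosen by cross-validated retrieval performance (mean
average precision of recovering functionally similar compounds in the fused
component space), component significance by permuting the compound pairing
between the two views, and each significant component is split into `A`
(positive canonical score) and `B` (negative) subcomponents that drive the
response pattern in opposite directions.

Around the core model the package provides the full pipeline:

| stage | module | what it does |
|---|---|---|
| synthetic data | `chemcca.synth` | planted-structure generators for every input |
| preprocessing | `chemcca.preprocess` | control consolidation (outlier-control removal), differential expression, control-variance gene filter, strongest-instance selection |
| activation | `chemcca.genesets` | weighted running-sum gene-set enrichment, FDR q-values, signed activation `sign × (1 − q)` |
| model | `chemcca.rcca` | rCCA fit, projection, CV model selection, permutation significance, A/B split |
| validation | `chemcca.retrieval` | correlation similarities, average precision, MAP curves, four-space comparison |
| characterization | `chemcca.characterize` | top gene sets/compounds, moderated-t gene lists, term over-representation, Tanimoto component similarity, target-enrichment resampling |
| orchestration | `chemcca.pipeline` / `chemcca.cli` | end-to-end runs with manifests and byte-reproducible outputs |

## Worked example

```python
import numpy as np
from chemcca import synth, rcca, retrieval as rtv

# two views sharing a 4-dimensional latent signal, mostly-noise features
x, y, truth = synth.simulate_joint_data(
    n=300, p=30, q=40, k=4,
    correlations=(0.9, 0.85, 0.8, 0.75), noise_sd=1.0, seed=0,
)
model = rcca.fit_rcca(x, y, l1=0.01, l2=0.01)
print("planted:", truth.planted_correlations)
print("fitted :", model.correlations[:5].round(3))

p, _ = rcca.permutation_significance(x, y, 0.01, 0.01, n_components=4,
                                     n_perm=199, seed=1)
print("perm p :", p.round(3))

ann = synth.simulate_annotations(list(x.index), 4, truth, alignment=0.9, seed=2)
curves = rtv.compare_spaces(x, y, None, model, ann, ks=(10,), retained=[0, 1, 2, 3])
for c in curves:
    print(f"MAP@10 {c.space:9s} {c.map_values[0]:.3f}")
```

Output:

```
planted: (0.9, 0.85, 0.8, 0.75)
fitted : [0.877 0.837 0.78  0.744 0.564]
perm p : [0.005 0.005 0.005 0.005]
MAP@10 cca       0.613
MAP@10 chemical  0.524
MAP@10 gene_set  0.480
```

The four planted correlations are recovered, all four components reach the
minimum attainable permutation p-value (1/200), and retrieval of functionally
similar compounds in the fused component space beats either view alone — the
model extracts the shared signal and discards view-specific noise.

The same analysis runs from the shell on TSV/GMT files:

```bash
chemcca run-all --seed 3 --outdir runs/demo          # synthetic end-to-end demo
chemcca fit --descriptors X.tsv --activation Y.tsv --out model.json --l1 0.01 --l2 0.01
```

`run-all` writes the response matrix, activation matrix, model archive,
retrieval curves, per-subcomponent reports (top compounds, gene sets, genes,
terms, targets) and a manifest of checksums; identical config + seed
reproduces every file byte for byte.

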