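# decontpro

Decontamination of droplet-based single-cell surface-protein (ADT)
counts.

CITE-seq and related assays measure cell-surface proteins through
antibody-derived tags (ADTs), but ADT counts carry substantial
background: ambient antibody material from the cell suspension, plus
a low-level non-specific component (debris "spongelet" droplets,
non-specific binding) that shows up as the lower peak of the typical
bimodal per-ADT distributions. Both contaminate every cell cluster
with markers it does not express and blur downstream clustering.
`decontpro` is for analysts of CITE-seq / Total-seq data who want to
quantify and remove that contamination before interpretation.

## The model

For droplet *i* (cluster *k<sub>i</sub>*, library size *L<sub>i</sub>*)
and ADT *j*, counts follow

> x<sub>ij</sub> | L ∼ Poisson(λ<sub>ij</sub> · L<sub>i</sub>)
>
> λ<sub>ij</sub> = (1 − β<sub>ij</sub>) θ<sub>ij</sub> η<sub>j</sub> + (1 − β<sub>ij</sub>)(1 − θ<sub>ij</sub>) φ<sub>k<sub>i</sub>j</sub> + β<sub>ij</sub>

where φ<sub>k</sub> is the native expression profile of cluster *k*
(a simplex), η the ambient profile (a fixed plug-in estimated from
ambient empty droplets or from the cell average), θ<sub>ij</sub> the
ambient rate with prior TruncNormal(δ<sub>i</sub>, τ₁) on (0, 1), and
β<sub>ij</sub> the background rate with prior
TruncNormal(μ<sub>j</sub>, τ₂) on (0, 0.5). The model is fitted by
variational inference and each count is then split across the three
sources in proportion to the three λ terms, so the native, ambient
and background matrices sum exactly to the input.

The package also ships the surrounding workflow: raw-droplet triage
(classifying "empty" droplets into mislabeled cells, spongelets and
true ambient droplets by k-means on log library sizes), ambient
profile estimation, a generative simulator with exact ground-truth
count splits, and decontamination quality metrics (marker
Positive/Negative/Combined scores, CLR-based silhouette deltas).
See `docs/methods.md` for assumptions, defaults and known
limitations — in particular the identifiability convention behind
the ambient/background mean split.

## Worked example

```python
import numpy as np
from decontpro import DecontPro, SimConfig, simulate_cells

cfg = SimConfig(I=500, J=12, K=3, seed=0)
counts, labels, truth = simulate_cells(cfg)

model = DecontPro(random_state=0).fit(counts, labels)
decomp = model.decompose()          # .native / .ambient / .background
df, summary = model.contamination_summary()

print(f"converged: {model.converged_} after {model.n_iter_} iterations")
for source in ("native", "ambient", "background"):
    s = summary[source]
    print(f"{source:>10}: median {100*s['median']:.1f}%  "
          f"range {100*s['min']:.1f}-{100*s['max']:.1f}%")
true_native = np.median(truth.component_counts["native"].sum(1)
                        / counts.library_sizes())
print(f"true median native fraction: {100*true_native:.1f}%")
```

prints

```
converged: True after 10800 iterations
    native: median 94.8%  range 92.6-95.7%
   ambient: median 0.1%  range 0.1-0.2%
background: median 5.0%  range 4.2-7.2%
true median native fraction: 93.1%
```

The estimator recovers the simulated contamination level (~7% of
counts; estimated ~5%, attributed to the background channel) and
`decomp.native` is the matrix to carry into downstream analysis.
`model.transform()` returns it directly, and the estimator follows
scikit-learn conventions (`get_params`/`set_params`, trailing
underscore fitted attributes), so it composes with sklearn tooling.

## Command line

```bash
decontpro simulate --seed 0 --out sim/
decontpro triage --raw sim/raw --filtered sim/filtered --out triage/
decontpro fit --counts sim/filtered --labels sim/labels.tsv --from-cells --out fit/
decontpro decompose --fit fit/ --out decomp/
decontpro score --counts sim/filtered --labels sim/labels.tsv \
    --markers markers.tsv --out report.json
decontpro run --config run.json     # the full chain, one config file
```

Exit codes: 0 ok, 2 configuration error, 3 data error, 4 inference
divergence.

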