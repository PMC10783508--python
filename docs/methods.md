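# Methods

## The decontamination model

Droplet-based surface-protein (ADT) counts mix three sources: the
native expression of the droplet's cell, ambient antibody material
from the cell suspension, and a low-level non-specific background
(sponge-like debris droplets, non-specific antibody binding) that
manifests as the lower peak of the typically bimodal per-ADT count
distributions. `decontpro` models a cell-containing count matrix
`X = [x_ij]` (I droplets x J ADTs, cluster label `k_i` per droplet,
library size `L_i = sum_j x_ij`) as

```
x_ij | L ~ Poisson(lambda_ij * L_i)
lambda_ij = (1 - beta_ij) * theta_ij * eta_j                 (ambient)
          + (1 - beta_ij) * (1 - theta_ij) * phi[k_i, j]     (native)
          + beta_ij                                          (background)
```

with

- `phi_k` — native expression profile of cluster k (a point on the
  J-simplex), free per cluster with a flat Dirichlet(1) prior;
- `eta` — the ambient profile (J-simplex), a fixed plug-in estimated
  upstream, never inferred: from the empirical profile of ambient
  empty droplets when a raw matrix is available, otherwise from the
  average of the cell droplets;
- `theta_ij ~ TruncNormal(delta_i, tau1)` on (0, 1) — per-entry
  ambient contamination rate, shrunk toward a per-droplet level
  `delta_i`;
- `beta_ij ~ TruncNormal(mu_j, tau2)` on (0, 0.5) — per-entry
  background rate, shrunk toward a per-ADT level `mu_j`; the upper
  bound encodes the assumption that background never exceeds half of
  an entry's rate;
- `delta_i`, `mu_j` — flat priors on their supports.

After fitting, every count is split across the three sources in
proportion to the three terms of `lambda_ij`, so the native, ambient
and background matrices sum to the input exactly (to floating-point
rounding); per-droplet source fractions summarize contamination.

## Parameters and defaults

| parameter | meaning | default | notes |
|---|---|---|---|
| `tau1` | scale (sd) of the theta prior | 2e-5 | per-droplet shrinkage; dataset-specific values in the 2e-5..5e-5 range are typical |
| `tau2` | scale (sd) of the beta prior | 2e-6 | per-ADT shrinkage |
| `beta_upper` | background truncation | 0.5 | model assumption |
| `init_theta` / `init_beta` | optimization initial values | 1e-4 / 1e-2 | part of the attribution convention (below) |
| `init_delta` / `init_mu` | hyper-mean initial values | 0.01 | unstated upstream; chosen once |
| `max_iter` | optimizer cap | 50000 | |
| `elbo_rel_tol` | windowed-ELBO relative stop | 1e-4 | window 100 iterations |
| detection threshold | count > t counts as expressed | 1 | strictly greater; 5 for normalized outputs on other scales |

## Inference

Fitting is mean-field variational inference implemented natively:
bounded scalars map to the real line through logit-type bijections
(`theta = sigmoid(z)`, `beta = 0.5*sigmoid(z)`, ...), each `phi` row
maps through an additive-log-ratio bijection, and a fully factorized
Gaussian over the unconstrained coordinates is optimized by Adam
(step 0.05, 1/sqrt decay after 2000 iterations) with single-sample
reparameterized ELBO gradients derived analytically. Truncated-normal
normalizers and their derivatives use stable `ndtr`-based forms.
Optimization stops when the mean ELBO over consecutive 100-iteration
windows changes by less than `elbo_rel_tol` in relative terms, or at
`max_iter`. Posterior means of constrained parameters are Monte-Carlo
averages (256 draws) under the fitted variational law. Identical seed
and inputs give bitwise-identical results.

### Identifiability and the attribution convention

Droplet-level contamination *variation* is well identified: a droplet
with an elevated ambient load deviates from its cluster's profile
toward `eta` in a way no other parameter can mimic. The *mean-level*
attribution is not: because `phi_k` is a free simplex per cluster,
any cluster-uniform contamination component (the average ambient load
`delta-bar * eta_j`, and the entire background `mu_j`) can be folded
into the native profiles with negligible likelihood cost. Worse, the
truncated-normal normalizers mildly favor the degenerate
`delta = mu = 0` all-native solution, which optimizers that truly
converge do reach: both a non-centered stochastic optimizer and a
deterministic fixed-draw (sample-average) ELBO driven by L-BFGS — the
latter is available as `optimizer="saa"` — end at ~100% native on any
input. A decontamination tool that never removes anything is useless,
so the method resolves the ridge by *convention*: the stated initial
values (`theta = 1e-4`, `beta = 1e-2`) anchor the fit, and the tight
couplings make the default stochastic optimizer settle where the
likelihood-identified structure is fit while the mean-level
attribution remains near the anchor — background at the scale the
data demands of it, ambient kept small unless droplet-level variation
demands more. Real marker structure (ADTs absent from some clusters)
turns much of the convention into genuine identification, which is
why marker-structured data recovers cleanly. Two consequences users
should know:

- on data that is truly contamination-free and has unstructured
  profiles, the fit still attributes a few percent of counts to
  background (the anchor, not evidence);
- the split between "ambient" and "background" is softer than either
  component's sum; interpret the two jointly unless the data has
  strong droplet-level ambient variation.

### Small-instance oracle

An independent Metropolis-within-Gibbs sampler (tests/_mcmc.py;
vectorized per-entry updates, joint shift moves for the coupled
(delta, theta-row) and (mu, beta-column) pairs, adaptive proposal
scales) serves as a long-run posterior reference. The comparison runs
on 20-droplet, 3-ADT, 2-cluster instances with marker-structured
profiles (each ADT near-absent in some cluster) and modest
contamination: only there does the small-sample posterior concentrate
enough that a point summary is meaningful; in diffuse regimes the
posterior spreads along the attribution ridge and no variational
point matches it. Variational and MCMC per-droplet native fractions
agree within 0.05 absolute under those conditions.

## The simulator

`simulate_cells` draws from exactly the generative process above,
emitting each count as the sum of three independent Poisson draws
(one per source); by Poisson superposition the marginal law is
unchanged while the true per-entry split is recorded for recovery
tests. Default study conditions: `L_i ~ LogNormal(log 3000, 0.4)`,
`delta_i ~ Beta(2, 38)` (mean 0.05), `mu_j ~ 0.5 * Beta(2, 398)`
(mean 0.0025 — background accrues per ADT, so this yields ~5% of a
droplet's counts over the default 20-ADT panel; a per-ADT mean of
0.05 would make background half the library), Dirichlet(1) profiles.
This lands the median native fraction near 90%, the regime reported
for real PBMC panels.

`simulate_raw` appends planted empty-droplet classes to emulate a raw
matrix: mislabeled cells (cell-like ADT profiles at high totals,
ambient-level RNA), spongelets (one shared non-specific profile at
medium totals) and ambient droplets (the ambient profile at low
totals), at class means 5168 / 268 / 20 ADT counts and with spongelet
and ambient droplets outnumbering mislabeled cells by more than an
order of magnitude, mirroring real raw-matrix geometry. The RNA side
is minimal (one fixed gene profile, two total-count laws) — enough
for triage testing only.

What the simulator does not emulate: overdispersion beyond Poisson,
doublets, batch effects, cluster-label errors, antibody-specific
binding kinetics, or any dependence of the ambient profile on the
cell population (eta is an independent Dirichlet draw). Passing
recovery tests therefore shows correctness of the inference under the
model's own assumptions, not robustness to real-data violations.

## Droplet triage

Empty droplets are raw-matrix barcodes absent from the filtered
(cell-called) matrix; droplets with zero ADT+RNA totals are excluded
entirely. K-means (k = 3, 10 restarts, seeded) clusters the empties
on `log10(total + 1)` ADT and RNA library sizes; the two features are
used on their common decades scale *without* per-feature
standardization — rescaling an uninformative axis to unit variance
makes k-means split large classes along noise instead of separating
the (ADT-driven) class structure. Classes are named by descending
mean ADT total: mislabeled cell > spongelet > ambient; cells come
from the filtered barcode set, never from k-means. Background-peak
profiles accept manual per-ADT cutoffs (the curated route); the
automatic mode places each cutoff at the deepest kernel-density
valley between the two highest modes of `log1p(count)` (Scott's-rule
bandwidth), falling back to the global median for unimodal ADTs, and
is flagged as an extension in reports.

Preprocessing of cell droplets before fitting: drop hashing/isotype
features (name contains HTO, Hashtag, isotype or IgG,
case-insensitive, overridable), drop droplets outside the [1%, 99%]
library-size quantiles of either modality (inclusive bounds, linear
empirical quantiles), drop droplets with mitochondrial RNA fraction
>= 15% (gene names prefixed MT-/mt-).

## Scores and silhouettes

Detection is strictly `value > threshold` (default 1), applied
identically to integer and real-valued decontaminated matrices. The
Positive (native markers detected in their own cluster) and Negative
(non-native markers detected) scores average per-(cluster, marker)
percentages with equal weight per pair within a cluster, then equal
weight per cluster; Combined = Positive - Negative. Silhouette widths
use Euclidean distances on CLR-normalized matrices (`log1p` counts
centered per droplet), no PCA by default (`n_pca` optional), with
per-cluster means before/after decontamination and their deltas;
singleton clusters are flagged undefined.

## Pipeline configuration

`decontpro run --config FILE` takes one JSON object. Keys: `filtered`
(triplet matrix directory, required), `labels` (TSV: barcode TAB
cluster, required), `output` (directory, required), `raw` (triplet
directory; enables triage and `eta_mode="empties"`), `markers`
(TSV with columns cluster / native / non_native, comma-separated
marker lists; enables before/after scoring), `eta_mode` (`cells`,
`empties` or `file` via `eta_file`), `tau1`, `tau2`, `max_iter`,
`threshold`, `k`, `seed`. All stages derive their randomness from the
single seed; the provenance JSON written alongside the outputs is
sufficient to reproduce the run.

## Numerical choices

- Sparse matrices are CSR internally; the model densifies the cell
  matrix (I x J with J of order tens — small) while triage stays
  sparse for raw matrices.
- MTX indices convert between 1-based (on disk) and 0-based
  (in memory) at the boundary; the CellRanger orientation (features
  as MTX rows) is assumed, with a flag for the transposed dialect.
- Decomposition outputs are real-valued; an optional seeded
  multinomial rounding mode returns integer components that still sum
  to the input exactly.
- Rates are floored at 1e-300 before logs; log-jacobians of sigmoid
  transforms use softplus forms stable at extreme arguments.
- Ties in triage class naming break toward the lower k-means cluster
  index.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script simulations use I = 2000
droplets x J = 20 ADTs x K = 4 clusters for recovery, I = 1000 for
scoring, ~12000 raw droplets for triage, and 20 x 3 x 2 for the MCMC
oracle comparison — sizes at which every quantity stabilizes while
the full pipeline runs in minutes on one CPU.

## Known limitations

- The ambient/background mean split is a convention (see above); only
  their sum and its droplet-to-droplet variation are robustly
  data-driven on unstructured data.
- `eta` is a plug-in; uncertainty in the ambient profile is not
  propagated.
- Cluster labels are trusted as given; label errors leak native
  signal into the contamination channels.
- The Poisson likelihood has no overdispersion term; strongly
  overdispersed ADTs will inflate the background estimate.
- Mean-field variational posteriors understate uncertainty; the
  package reports point decompositions, not credible intervals.
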