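# proteonet

Staged-cohort TMT proteomics analysis: reference-channel normalization,
multi-pass empirical-Bayes batch harmonization, signed weighted
co-expression networks, module statistics, cross-network projection,
and marker-based cell-type deconvolution — with a synthetic-data
generator that makes every stage verifiable at desk scale.

## The problem

Multiplexed isobaric-label (TMT) proteomics of postmortem brain cohorts
measures thousands of proteins across samples spread over many labeling
batches, two instrument platforms, and two brain regions, with
diagnosis groups on an ordered severity continuum (control, four
disease stages, an exaggerated-phenotype endpoint). Before any biology
can be read out, the technical structure must be removed without
touching the biological structure; then co-expression modules, their
severity trajectories, and their cell-type composition carry the
scientific signal. `proteonet` is for computational biologists who want
that whole chain as tested, composable Python.

The core machinery:

* **Harmonization** — the parametric empirical-Bayes location/scale
  batch model: per protein, `y = alpha + X_protected beta + gamma_batch
  + delta_batch eps`; batch locations and scales are shrunk toward
  moment-matched normal / inverse-gamma priors and removed, protected
  covariates (diagnosis, region, sex) restored. Orchestrated as the
  four-pass recipe (per-platform batch passes, a platform pass, a
  region pass), anchored by pooled-reference (GIS) channels, followed
  by within-group bootstrap regression of age and PMI.
* **Networks** — signed weighted co-expression analysis: biweight
  midcorrelation, adjacency `a_ij = ((1+cor_ij)/2)^beta` (beta = 7),
  topological overlap `TOM_ij = (l_ij + a_ij)/(mean(k_i,k_j) + 1 -
  a_ij)`, average-linkage clustering with an adaptive (dynamic-hybrid
  style) cut, module eigenproteins (first principal component of the
  standardized members), kME membership, conservative merging and
  kME-based reassignment.
* **Statistics** — ANOVA + Tukey HSD differential abundance,
  covariate-adjusted module-trait F tests, hypergeometric module
  overlap, synthetic eigengene projection across datasets, Fisher /
  hypergeometric enrichment with Benjamini-Hochberg control, and
  digital-sorting-style nonnegative deconvolution of cell-type
  proportions.

Estimators follow sklearn conventions (`fit`/`transform`,
`get_params`, fitted attributes with trailing underscores) and compose
with sklearn pipelines; module-level functions wrap them in the
proteins x samples orientation used on disk.

## Worked example

```python
import proteonet as pn

# a synthetic cohort: 10 batches x (9 samples + 2 GIS), two platforms,
# two regions, five planted modules with severity trajectories
ab, meta, truth = pn.generate_dataset(pn.SyntheticConfig(seed=1))

ab = pn.normalize_to_gis(ab, meta)            # anchor to pooled reference
ab = pn.filter_complete_proteins(ab, meta)    # no-missingness filter
ab, removed = pn.remove_connectivity_outliers(ab, meta)
meta = meta.loc[ab.columns]
print(f"{ab.shape[0]} complete proteins x {ab.shape[1]} samples; "
      f"{len(removed)} outliers removed")

harm = pn.run_harmonization_plan(ab, meta)    # four EB passes, drops GIS
mb = meta.loc[harm.columns]
vp = pn.variance_partition(harm, mb, ["group", "platform", "batch", "region"],
                           method="excess")
print("residual technical variance (%):",
      {f: round(100 * vp[f].mean(), 2) for f in ("batch", "platform", "region")})
reg = pn.regress_covariates_bootstrap(harm, mb, n_boot=200, seed=1)

net = pn.CoexpressionNetwork().fit(reg.T)     # samples x proteins
sizes = net.labels_[net.labels_ != "grey"].value_counts()
print("modules:", {f"{net.aliases_[c]}-{c}": int(n) for c, n in sizes.items()})
print(pn.module_trait_significance(net.eigenproteins_, mb).round(4))
```

This prints (seed 1):

```
1320 complete proteins x 110 samples; 0 outliers removed
residual technical variance (%): {'batch': 0.02, 'platform': 0.15, 'region': 0.09}
modules: {'M1-turquoise': 52, 'M2-blue': 45, 'M3-brown': 39, 'M4-yellow': 34, 'M5-green': 28}
                 F       p  p_kruskal
module
turquoise  16.3361  0.0000     0.0000
blue       10.9834  0.0000     0.0000
brown      16.9753  0.0000     0.0000
yellow     17.8701  0.0000     0.0000
green       0.7324  0.6013     0.7122
```

Reading it: 180 of 1500 proteins were dropped by the batch-completeness
filter; after the four-pass harmonization, less than 0.2% of per-protein
variance is attributable to any technical factor beyond chance. The
network recovers the five planted modules at their planted sizes
(members lost only to the missingness filter), and the
covariate-adjusted group test flags the four trajectory-carrying
modules at p < 1e-7 while the flat module is correctly null (p = 0.60).
The detected sizes match `truth.module_of_protein` exactly (adjusted
Rand index 1.0).

A CLI mirrors the stages (`proteonet simulate / prep / harmonize /
network / stats / crossnet / celltype / run-all / validate`); `run-all`
drives the whole pipeline from a YAML config and writes every
intermediate plus a hashed manifest, so identical config + seed gives
byte-identical outputs.

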