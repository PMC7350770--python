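# asymmorph

Mirror-based quantification of cranial (bilateral) asymmetry on 3D landmark
configurations, plus the downstream phylogenetic comparative machinery for
analysing how asymmetry evolves across a clade.

The package implements, as a tested reusable pipeline:

- **Landmark I/O** (`asymmorph.io`): long/wide CSV landmark tables with a
  `-9999` missing sentinel, bilateral scheme files (paired left/right +
  midline landmarks with region labels), specimen metadata, validation.
- **Symmetry geometry** (`asymmorph.geometry`): total-least-squares
  midsagittal plane fitting, mirroring of left-side landmarks to build a
  perfectly symmetric reference, 3D thin-plate-spline estimation of missing
  landmarks, full generalized Procrustes analysis (proper rotations only),
  and transfer of each specimen's Procrustes transform to its mirror.
- **Asymmetry metrics** (`asymmorph.metrics`): per-landmark displacement
  radii (rho, phi, theta) between the focal and mirrored configurations,
  per-specimen summed radii, group means, per-landmark group means,
  rankings, region fractions, region dropping (e.g. rostrum-removed
  sensitivity), and PCA of the aligned coordinates.
- **Trees** (`asymmorph.trees`): Newick/NEXUS I/O (via dendropy), polytomy
  resolution with zero-length branches, pruning, deterministic regime
  painting (clade rules or tip states), and phylogenetic covariance matrices
  with per-regime components.
- **Discrete models** (`asymmorph.discrete`): Mk likelihoods (pruning
  algorithm) and ML fits for ER / SYM / ARD transition structures.
- **Continuous models** (`asymmorph.continuous`): ML fitting and AIC ranking
  of BM, BM+trend, BM with separate regime means, multi-rate BM, OU, and
  multi-optimum OU over painted trees.
- **rjMCMC** (`asymmorph.rjmcmc`): reversible-jump MCMC over relaxed
  Brownian motion with branch rate shifts (Poisson(log 2) shift-count
  prior, Half-Cauchy(25) scalars) and the combined model with trait jumps;
  shift/jump posterior summaries, ESS and Gelman-Rubin diagnostics.
- **Phylogenetic ANOVA** (`asymmorph.anova`): GLS with a Pagel's-lambda
  correlation structure, F tests against the intercept-only model,
  Benjamini-Hochberg control across scenarios.
- **Synthetic data** (`asymmorph.synthetic`): stylised symmetric skull
  templates, planted directional asymmetry, missingness/noise degradation,
  random trees (birth-death / coalescent, optional fossil tips), and
  continuous/discrete trait simulation with planted shifts and jumps.
- **Pipeline + CLI** (`asymmorph.pipeline`, `asymmorph.cli`): config-driven
  orchestration with manifests, plus sensitivity re-runs (no fossils, no
  rostrum, matrix-only tree).

## CLI

All stages read a flat YAML config naming the inputs:

```yaml
landmarks: data/landmarks.csv   # specimen_id,landmark,x,y,z (long form)
scheme: data/scheme.csv         # landmark,side,partner,region
metadata: data/metadata.csv     # specimen_id,species,group,regime,...
tree: data/tree.nwk             # rooted, branch lengths in My
seed: 1
```

```sh
asymmorph quantify --config config.yaml --outdir out/    # radii + summaries + PCA
asymmorph fit      --config config.yaml --outdir out/    # BM/OU model ranking
asymmorph mcmc     --config config.yaml --outdir out/    # rjMCMC shifts/jumps
asymmorph anova    --config config.yaml --outdir out/    # lambda-GLS ANOVA + BH
asymmorph all      --config config.yaml --outdir out/
asymmorph sensitivity --config config.yaml --outdir out/ --mode no-rostrum
```

Outputs are CSV/JSON (radii.csv, asymmetry_summary.csv, pca_scores.csv,
model_ranking.csv, shifts.csv, jumps.csv, anova.csv, mcmc_diagnostics.json)
plus a `manifest.json` with config snapshot, stage timings, warnings, and
file checksums.

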