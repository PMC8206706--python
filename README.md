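# traitwalk

Simulate adaptive walks of microbial populations whose individuals carry both
trait values and heritable pairwise trait–trait correlations, on a
low-dimensional PCA trait landscape anchored in empirical trait data.

The pipeline has five stages:

1. **Landscape** (`traitwalk.scape`) — standardize the evolved rows of a
   long-format trait table, fit PCA axes, project ancestral phenotypes onto
   the evolved axes, and fix the start (ancestral centroid) and end
   (evolved centroid, the high-fitness coordinate) of the walk.
2. **Simulation** (`traitwalk.sim`) — per generation, 90% of individuals
   receive a Gaussian trait perturbation propagated through their own
   correlations and 10% receive a joint correlation + trait perturbation;
   selection resamples the population with replacement weighted by
   `exp(-z²/2)`, where `z` is the retained-axis distance to the endpoint.
   Starting correlations can be fully random (`mixed`), pinned to ranked
   empirical ancestral/evolved values (`A1..A4` / `E1..E4`), or zeroed with
   propagation disabled (`uncorrelated` control).
3. **Census** (`traitwalk.census`) — summarize each replicate by its mean
   final correlation vector, cluster replicates (UPGMA + silhouette model
   selection) into emergent population types, and report each type's
   accessibility (fraction of replicates) and adaptation rate (1 / the
   generation reaching 95% of the fitness plateau).
4. **Meta-analysis** (`traitwalk.msboot`) — from-scratch multiscale
   bootstrap hierarchical clustering: feature dimensions are resampled at a
   ladder of scale factors, per-node bootstrap proportions are fitted with
   the two-parameter probit model `BP_r = 1 − Φ(v√r + c/√r)`, and
   approximately unbiased support is reported as `AU = 1 − Φ(v − c)`.
   Includes a centred PCA view with per-cluster convex hulls.
5. **Workbench** (`traitwalk.workbench`) — the 9-mode study grid,
   alternative equidistant/multi-subpopulation starts, pooled signature
   tables and reproducible manifests.

`traitwalk.fixtures` generates synthetic multi-genotype trait tables from
multivariate Gaussians with user-specified (PSD-repaired) correlation
targets, plus a packaged 5-genotype / 4-trait reference fixture with ranked
ancestral/evolved correlation tables, so the whole pipeline is testable
without any external data.

## CLI

```sh
# synthetic inputs
traitwalk synth --reference --out table.csv --corr-out corr.csv

# fit the landscape
traitwalk scape --table table.csv --focal G1 --out scape.json --coords coords.csv

# run the engine (config is flat YAML with SimConfig keys)
printf 'n_individuals: 250\ngenerations: 500\nreplicates: 30\nmode: mixed\nbase_seed: 1\n' > run.yaml
traitwalk simulate --config run.yaml --scape scape.json --corr corr.csv --out runs/

# emergent population types
traitwalk census --runs runs/ --kmax 8 --out census.csv --membership members.csv

# multiscale-bootstrap meta-analysis of signature vectors
traitwalk cluster --signatures sigs.csv --nboot 1000 --out cluster/

# the full 9-mode study grid
traitwalk study --scape scape.json --corr corr.csv --out study/ --base-seed 1
```

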