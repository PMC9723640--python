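# bficomm

Catchment-scale analysis of the microbial communities that cycle nitrogen
and carbon in river sediments, driven by a single hydrological predictor:
the **base flow index** (BFI), the fraction of river flow fed by delayed
groundwater. BFI ranges from 0 (no groundwater contribution) to 1 (fully
groundwater-fed) and integrates catchment permeability — clay catchments
sit near the low end, chalk-gravel catchments near the top.

`bficomm` is for microbial ecologists who want to test whether such a
landscape-scale variable predicts the structure of functional-gene
communities (ammonia oxidisers assayed by *amoA*, anammox bacteria by
*hzo*, nitrite reducers by *nirS*, methanogens by *mcrA*, …). It provides
the full chain from in-frame functional-gene amplicons to fitted models,
plus a synthetic-study generator with known ground truth so every
estimator can be validated by parameter recovery.

## What it computes

* **Community units.** Nucleotide reads are collapsed two ways: into
  **amino acid variants** (AAVs — clusters of nucleotide sequences sharing
  an identical translated protein, so all within-cluster variation is
  synonymous) and into **OTUs** (greedy centroid clustering at 97%
  pairwise identity). Per-gene length filters and per-sample library-size
  filters are applied first.
* **β diversity.** Pairwise Sørensen dissimilarity
  βsor = (b + c) / (2a + b + c), partitioned into spatial turnover
  (Simpson dissimilarity βsim = min(b,c)/(a + min(b,c))) and the
  nestedness-resultant remainder βsne = βsor − βsim.
* **Distance decay.** Community similarity S = 1 − βsor is modelled
  against the pairwise BFI distance d as a negative exponential,
  E[S] = exp(β₀ + β₁·d), a Gaussian GLM with log link fitted by IRLS.
  Goodness of fit is a deviance-based pseudo-R²; significance comes from
  permuting BFI labels across whole sites (1000 permutations); AAV and
  OTU decay rates are compared by a cluster bootstrap over sites.
* **Sequence properties.** Per feature: GC content, codon adaptation
  index (geometric mean of codon relative-adaptiveness values), GRAVY
  (mean Kyte–Doolittle hydropathy) and Henderson–Hasselbalch net charge at
  pH 7 under the Lehninger pKa scale; abundance-weighted per-sample means
  are regressed on BFI.
* **Group models.** Richness is modelled with negative-binomial GLMs
  (explained deviance as adjusted D²); qPCR-derived group proportions
  (e.g. the archaeal share of the ammonia-oxidising community) with beta
  regressions, coefficients reported on the odds scale.

## Worked example

```python
from bficomm.synthetic_data import (
    SimulationConfig, generate_sites, generate_communities, sites_to_metadata)
from bficomm.community_structure import (
    drop_single_sample_features, rarefy, pairwise_dissimilarity)
from bficomm.distance_decay import attach_delta_bfi, fit_negative_exponential

cfg = SimulationConfig(seed=1)          # 9 sites, BFI 0.23-0.95, 54 samples
sites = generate_sites(cfg)
meta = sites_to_metadata(sites)
com = generate_communities(sites, cfg)  # true decay rate = 3.0 per unit BFI

m = drop_single_sample_features(com.counts)
m = rarefy(m, int(m.sum().min()), seed=1)
pairs = attach_delta_bfi(pairwise_dissimilarity(m), meta)
fit = fit_negative_exponential(1 - pairs["beta_sor"], pairs["delta_bfi"])
print(f"decay rate {fit.rate:.2f}, pseudo-R2 {fit.pseudo_r2:.2f}")
```

prints

```
decay rate -3.10, pseudo-R2 0.90
```

— the fitted similarity-decay slope per unit ΔBFI (the generator's true
rate is 3.0; communities at opposite ends of the gradient share few
species) and the fraction of deviance the decay model explains relative
to an intercept-only null.

The same analysis, end to end with all intermediate tables, via the CLI:

```bash
bficomm run-all --outdir my_run --seed 1
bficomm validate --outdir my_run
```

which writes community matrices, pairwise tables, fit records and a
`manifest.json` with seeds, settings and file checksums sufficient to
reproduce the run bit for bit.

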