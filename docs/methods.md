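# Methods

This note describes the models implemented in `bficomm`, the assumptions
behind them, the synthetic study the package generates to validate them,
and the numerical and design choices that were genuinely open.

## The study design being emulated

The analysis targets a survey of nine river sites spanning a base flow
index (BFI) gradient from 0.23 (clay catchments) to 0.95 (chalk), grouped
into three geology classes by BFI tercile. Amplicon sequencing of
functional genes covers two seasons (winter, summer) with three replicate
sediment cores per site — 54 samples; qPCR gene-copy tables cover four
seasons — 108 samples. The synthetic generator
(`bficomm.synthetic_data`) reproduces this layout with known ground
truth, so every downstream estimator is testable by parameter recovery.

## Community units

**AAVs.** An amino acid variant is the set of nucleotide sequences whose
standard-code translation is identical; there is no similarity threshold,
and all within-AAV nucleotide variation is synonymous by construction.
Records with internal stop codons are flagged, logged, and excluded
(rather than truncated): a conservative choice, since an in-frame read
with a premature stop is most plausibly an artefact.

**OTUs.** Greedy centroid clustering at a pairwise-identity threshold
(default 0.97). Candidates are visited in order of decreasing total
abundance, ties broken lexicographically by sequence, and each joins the
first centroid (in founding order) at or above the threshold. Pairwise
identity is computed from a global end-to-end alignment with unit
mismatch and gap costs (Levenshtein) as matching columns divided by total
alignment columns. Published centroid clusterers do not pin down either
the identity definition or the tie-breaking, so both are stated here
explicitly and the greedy result is verified against an exhaustive
brute-force clustering oracle in the tests. When several minimal-edit
alignments of different column counts exist, the alignment backtrace of
the edlib library decides; this is deterministic.

**Filters.** Per-gene length windows (inclusive bounds) and per-sample
library-size thresholds (strictly "fewer than" discards) mirror the
standard amplicon QC for these loci; removed samples are logged, and
removing every sample is an error.

## Normalisation and β diversity

Features occurring in only one sample are discarded, then each table is
rarefied — a single multivariate-hypergeometric draw per table, without
replacement, to the table's own minimum sample depth, with the seed
recorded in the output metadata. AAV and OTU tables are rarefied to their
own minima independently and never forced to a common depth.

Pairwise Sørensen dissimilarity is partitioned as

    beta_sor = (b + c) / (2a + b + c)
    beta_sim = min(b, c) / (a + min(b, c))      (turnover / Simpson)
    beta_sne = beta_sor - beta_sim              (nestedness-resultant)

where a is the shared-feature count and b, c the features unique to each
sample. The identity beta_sor = beta_sim + beta_sne holds exactly and is
enforced to 1e-12 in the tests. A pair of two empty communities has no
defined dissimilarity and is flagged as missing rather than assigned 0
or 1.

## Distance decay of similarity

Similarity S = 1 − beta_sor is modelled against pairwise BFI distance d
as E[S] = exp(b0 + b1 d), a Gaussian-variance GLM with log link fitted by
iteratively reweighted least squares (working weights μ², starting values
from a log-linear regression on S floored away from zero). Goodness of
fit is the deviance-based pseudo-R² = 1 − residual/null deviance, which
for this family reduces to 1 − RSS/TSS of the nonlinear fit; it is
clamped to [0, 1]. Zero-similarity pairs are retained — the log link
constrains the mean, not the data. The Gaussian/log choice is recorded in
the fit record so a binomial-variance variant could be swapped in; on
noise-free exponential data the fit reproduces the generating parameters
to 1e-6.

Sample pairs sharing a site are not independent, so:

* **Significance** comes from permuting BFI values across whole sites
  (not pairs), refitting per permutation, and
  p = (1 + #{permuted pseudo-R² ≥ observed}) / (n_perm + 1). Fewer than
  four distinct sites leaves too small a permutation space and is an
  error. Type-I calibration of this test is checked over 200 null
  datasets in the acceptance suite.
* **Slope comparisons** between two datasets on the same sites (AAV vs
  OTU) use a cluster bootstrap: sites resampled with replacement, all
  sample pairs among the resampled sites entering each refit, percentile
  95% CIs, and a two-sided bootstrap p for the rate difference. The two
  datasets share each site resample, keeping the comparison paired.
  Resamples with fewer than three distinct sites are redrawn.

The two resampling schemes (permutation for significance, bootstrap for
interval estimation) are deliberately both provided; they answer
different questions and are not interchangeable.

Seasons can be analysed separately (the amplicon design has two) or
pooled; the pipeline's default fits pool both seasons of the rarefied
table, with within-site pairs across seasons entering at d = 0.

## Sequence properties

* **GC content**: (G+C)/length of the nucleotide sequence.
* **CAI**: for each amino acid, a codon's relative adaptiveness w is its
  reference-set count divided by the count of its commonest synonym
  (zero counts replaced by a 0.5 pseudocount before normalising); the CAI
  of a gene is the geometric mean of w over its codons, excluding ATG,
  TGG and stop codons, which carry no usage information. A sequence with
  no informative codons has undefined CAI (NaN). The reference set is
  unspecified in most field studies; the default here is the top decile
  of features by total abundance in the analysed table (self-contained
  and overridable by explicit codon counts or a reference FASTA-derived
  count table). When the strictness is relaxed, amino acids absent from
  the reference get uniform w = 1.
* **GRAVY**: mean Kyte–Doolittle hydropathy per residue; the scale ships
  as a packaged, versioned data file and is cross-checked against an
  independent implementation in the tests.
* **Net charge** at pH 7 (intracellular) under the Lehninger pKa scale
  (packaged data file): the sum of Henderson–Hasselbalch fractional
  charges, basic groups (K, R, H, amino terminus) as n/(1+10^(pH−pKa)),
  acidic groups (D, E, C, Y, carboxyl terminus) as −n/(1+10^(pKa−pH)),
  termini counted once each. Cysteine and tyrosine are treated as
  deprotonatable acidic groups because the scale assigns them pKa values.
  Net charge is strictly non-increasing in pH; a lone group evaluated at
  its own pKa contributes exactly ±0.5.

Per-feature DNA properties (GC, CAI) are computed on the OTU centroid or
an AAV representative nucleotide sequence; protein properties on the AAV
protein. Community-weighted means Σ pᵢxᵢ (pᵢ the relative abundance in a
sample) are regressed on BFI by ordinary least squares.

## Group-level models

Richness (features per sample after rarefaction) is modelled with
negative-binomial GLMs (log link), dispersion estimated by full maximum
likelihood; near-Poisson data push the dispersion to its boundary, where
a tiny-gradient solution is accepted as converged. Explained deviance is
D² = 1 − residual/null deviance with the adjustment
adj-D² = 1 − [(n−1)/(n−p)](1−D²).

qPCR group proportions — each ammonia-oxidising group's share of the
AOA + AOB + anammox total, and each functional gene's copies relative to
bacterial 16S rRNA — are modelled with beta regression: logit mean link,
constant precision φ (no precision covariates, since single-coefficient
effects are the target), maximum likelihood. Exact 0/1 proportions are
squeezed by (p(n−1)+0.5)/n, and only when boundary values actually
occur. Mean coefficients are reported exponentiated ("odds scale"). D²
for beta fits measures deviance against the saturated model (μᵢ = yᵢ) at
the fitted φ. Technical qPCR triplicates are collapsed by arithmetic
mean before modelling. Season terms are user-configurable; nested fits
with and without season are compared by deviance drop, ΔAIC and the
ratio of explained deviances.

## The synthetic generator

**Communities** follow a niche model: each of `gamma_richness` species
(default 400) has a Gaussian occupancy curve on the BFI axis,
p(occupied) = exp(−(bfi−μ)²/2σ²), with optima uniform over the BFI range
extended by 3σ on each side (so edge sites are not artificially poor)
and lognormal abundance heterogeneity (σ_log = 0.5). Presence is a
Bernoulli draw per sample; counts are multinomial over present species
with per-sample depths uniform on [0.7, 1]×1000, giving the unequal
library sizes rarefaction exists for.

The similarity decay emerging from this model is not exactly
exponential, so the niche width σ is **calibrated numerically**: for a
candidate σ the expected pairwise similarities over the actual
sample-pair design (within-site replicate pairs included, each site pair
with its sample multiplicity) are computed by numerical integration and
fitted with the same negative-exponential GLM; root finding on σ makes
the fitted rate equal the configured `decay_rate`. The default
decay_rate of 3.0 per unit ΔBFI is a design choice representing strong
turnover — communities at opposite ends of the 0.72-wide gradient share
few species — comparable to the steep decay seen in permeability
gradients in the field; it is not a measured constant. Recovery of the
rate by the full pipeline is within a few percent averaged over seeds.

**Sequences.** Each species receives an in-frame nucleotide sequence
(default 100 codons, no stops) whose GC content, GRAVY and net charge
trend linearly with the species' BFI optimum. Ionizable residues are
chosen first by greedy repair against the charge target; remaining
positions are filled greedily for the per-residue hydropathy deficit
with a usage penalty that keeps composition diverse and a pull toward
residues whose synonymous codons can realise the GC target; codons are
then chosen greedily against the cumulative GC target. All choices are
deterministic with alphabetical tie-breaks. Targets outside what the
genetic code can realise raise an explicit infeasibility error. About
30% of species also emit one synonymous nucleotide variant, exercising
AAV collapsing; species with near-identical optima can legitimately
converge to the same protein, so the AAV count is bounded by — not equal
to — the species count. Default trend slopes (GC −0.08, GRAVY −0.07,
charge −0.08 per unit BFI around intercepts 0.55, 0.30, −1.0) mirror the
direction and order of magnitude of the field observations for archaeal
ammonia oxidisers. Charge targets are met to roughly ±0.03 (the lattice
of Henderson–Hasselbalch step sizes), so the recovered charge slope is
mildly attenuated relative to truth.

**qPCR tables.** The archaeal share of the ammonia-oxidising community
is a beta draw with logit(mean) = 2.1 − 3.5·BFI and precision φ = 30 —
the slope is the log of the field estimate's odds-scale coefficient
(0.03), and the intercept puts the archaeal/bacterial transition near
BFI 0.6. The anammox share of the non-archaeal remainder uses
logit(mean) = −2.48 + 1.62·BFI (slope from the field odds coefficient
5.06; intercept chosen so the anammox share of the total
ammonia-oxidiser community averages ≈ 21.7% at BFI 0.95). Shares are
scaled by lognormal totals into copy numbers; 16S copies decline gently
with BFI and nirS/mcrA are beta-distributed fractions of them.

**Determinism.** Every generator is a pure function of its inputs and
the config seed; each stage draws from its own fixed-offset stream, so
regenerating any one stage reproduces it exactly.

## What the synthetic data do and do not show

The generator produces the statistical structure the estimators assume:
presence-based turnover decaying with ΔBFI, linear property trends,
logit-linear proportions. It does not simulate sequencing error,
chimeras, frameshifts, primer bias, spatial autocorrelation beyond the
BFI axis, or phylogenetic structure among species. Passing recovery
tests therefore demonstrates that the estimators are correct and
calibrated under their own assumptions — not that those assumptions hold
for any particular field dataset, and not that upstream read QC
(out of scope here) is handled.

## Numerical choices and degenerate inputs

* IRLS: linear predictor clipped to ±30, convergence on coefficient and
  deviance change, explicit error with diagnostics after 200 iterations;
  all-zero similarity vectors rejected.
* Rarefaction depth above any column total is an error naming the
  sample; a column exactly at depth passes through unchanged.
* Empty community pairs, zero-total samples in weighted means, and zero
  qPCR denominators are flagged missing, never silently imputed.
* Permutations that fail to fit (degenerate distance structure) count as
  non-exceeding rather than aborting the test.
* Pseudo-R² and D² are clamped to [0, 1]; adjusted D² may be negative.

## Problem sizes

Default analyses run the full survey scale (54/108 samples, 400-species
pool). Recovery summaries average 10–50 replicate surveys; permutation
tests use 999 permutations in the acceptance script and 199 in the
repeated calibration study (200 null datasets), sizes chosen to keep the
whole validation suite comfortably within desk time while leaving
Monte-Carlo error well below the tolerances being checked.

## Known limitations

* The negative-exponential GLM uses Gaussian variance; similarities are
  bounded in [0, 1] and a binomial-variance variant may be preferable
  near the boundaries.
* Greedy OTU clustering is order-dependent by construction; it matches
  the brute-force oracle exactly but is not a global optimum of any
  objective.
* The within-dataset CAI reference makes CAI values comparable inside a
  run, not across studies with different references.
* The bootstrap p-value for slope differences is percentile-based;
  studentised intervals would be more accurate at small site counts.
* The charge-target lattice quantises per-feature net charge (±0.03),
  mildly attenuating recovered charge slopes.
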