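"""Synthetic study generator: sites, communities, sequences, qPCR tables.

Emulates a catchment-scale survey of river-sediment functional-gene
communities along a base flow index (BFI) gradient: nine sites spanning
BFI 0.23–0.95 across three geology classes (clay, greensand, chalk), two
amplicon seasons with three replicate sediment samples each, per-sample
in-frame nucleotide reads for a functional gene, and a qPCR gene-copy
table over four seasons.

The community model is niche-based: each of ``gamma_richness`` species has
a Gaussian occupancy curve on the BFI axis centred at a uniform-random
optimum with common width ``niche_breadth``.  Presence in a sample is a
Bernoulli draw from the occupancy curve and counts are a multinomial draw
over present species, so pairwise Sørensen similarity declines with BFI
distance.  The niche width is calibrated numerically so that a
negative-exponential GLM fitted to the noise-free expected similarities
returns exactly ``decay_rate`` — making the decay rate an emergent but
recoverable quantity.

Sequences are built per species so that GC content, protein hydropathy
(GRAVY) and net charge at pH 7 trend linearly with the species' BFI
optimum (slopes from the config); synonymous nucleotide variants are
emitted for a fraction of species to exercise AAV collapsing.  qPCR group
proportions follow a logit-linear-in-BFI beta model with constant
precision.

Every generator is a pure function of its inputs and the config seed; each
stage draws from its own fixed-offset stream.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .distance_decay import fit_negative_exponential
from .sequence_properties import KYTE_DOOLITTLE, LEHNINGER, _SYNONYMS
from .sequence_units import SequenceSet

__all__ = [
    "Site",
    "SimulationConfig",
    "Community",
    "generate_sites",
    "generate_communities",
    "feature_sequences",
    "generate_sequences",
    "generate_qpcr_table",
    "sites_to_metadata",
    "calibrate_niche_breadth",
    "FOUR_SEASONS",
]

GEOLOGY_CLASSES = ("clay", "greensand", "chalk")
FOUR_SEASONS = ("winter", "spring", "summer", "autumn")

# fixed per-stage offsets from config.seed (stage-level reproducibility)
_STREAM_COMMUNITIES = 1
_STREAM_SEQUENCES = 2
_STREAM_QPCR = 3


@dataclass(frozen=True)
class Site:
    """One sampling unit: a river site in one season, one replicate core."""

    site_id: str
    bfi: float
    geology: str
    season: str
    replicate: int

    def __post_init__(self) -> None:
        if not 0 <= self.bfi <= 1:
            raise ValueError(f"bfi {self.bfi} outside [0, 1]")
        if self.geology not in GEOLOGY_CLASSES:
            raise ValueError(f"unknown geology {self.geology!r}")

    @property
    def sample_id(self) -> str:
        return f"{self.site_id}_{self.season}_R{self.replicate}"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with survey-scale defaults.

    ``decay_rate`` is the true similarity-decay rate per unit ΔBFI
    (positive; communities decay as exp(-decay_rate * d)); when
    ``niche_breadth`` is None it is derived from ``decay_rate`` by the
    numerical calibration in :func:`calibrate_niche_breadth`.
    ``beta_coefs`` are the logit-scale (intercept, BFI-slope) coefficients
    of the AOA share of the ammonia-oxidising community;
    ``anammox_coefs`` play the same role for the anammox share of the
    non-AOA remainder.
    """

    n_sites: int = 9
    bfi_range: tuple[float, float] = (0.23, 0.95)
    seasons: tuple[str, ...] = ("winter", "summer")
    n_replicates: int = 3
    gamma_richness: int = 400
    decay_rate: float = 3.0
    niche_breadth: float | None = None
    depth: int = 1000
    abundance_sigma: float = 0.5
    gc_slope: float = -0.08
    gravy_slope: float = -0.07
    charge_slope: float = -0.08
    gc_intercept: float = 0.55
    gravy_intercept: float = 0.30
    charge_intercept: float = -1.0
    protein_length: int = 100
    synonymous_fraction: float = 0.3
    beta_coefs: tuple[float, ...] = (2.1, -3.5)
    anammox_coefs: tuple[float, ...] = (-2.48, 1.62)
    precision_phi: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_replicates", "gamma_richness", "depth",
                     "protein_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.bfi_range
        if not (0 <= lo <= 1 and 0 <= hi <= 1):
            raise ValueError("bfi_range must lie within [0, 1]")
        if self.precision_phi <= 0:
            raise ValueError("precision_phi must be positive")
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be positive")
        if self.niche_breadth is not None and self.niche_breadth <= 0:
            raise ValueError("niche_breadth must be positive")


def generate_sites(config: SimulationConfig) -> list[Site]:
    """Sites evenly spread over the BFI range, geology by BFI tercile.

    One :class:`Site` entry is produced per (site, season, replicate)
    combination.  The layout is deterministic (the seed is recorded but no
    randomness is needed for an evenly spaced design).
    """
    if config.n_sites < 2:
        raise ValueError("need at least two sites")
    lo, hi = config.bfi_range
    if hi <= lo:
        raise ValueError(f"degenerate bfi_range {config.bfi_range}")
    bfis = np.linspace(lo, hi, config.n_sites)
    # terciles of the range position assign the geology class
    tercile = np.minimum(((bfis - lo) / (hi - lo) * 3).astype(int), 2)
    sites = []
    for k, (bfi, terc) in enumerate(zip(bfis, tercile)):
        site_id = f"S{k + 1:02d}"
        for season in config.seasons:
            for rep in range(1, config.n_replicates + 1):
                sites.append(
                    Site(
                        site_id=site_id,
                        bfi=float(round(bfi, 6)),
                        geology=GEOLOGY_CLASSES[terc],
                        season=season,
                        replicate=rep,
                    )
                )
    return sites


def sites_to_metadata(sites: list[Site]) -> pd.DataFrame:
    """Sample metadata table (sample_id, site_id, bfi, geology, season, replicate)."""
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "site_id": s.site_id,
                "bfi": s.bfi,
                "geology": s.geology,
                "season": s.season,
                "replicate": s.replicate,
            }
            for s in sites
        ]
    )


def _expected_similarity(bfi_a, bfi_b, sigma, lo, hi):
    """Noise-free expected Sørensen similarity between two BFI positions.

    Large-richness expectation under Bernoulli occupancy with Gaussian
    curves of width ``sigma`` and optima uniform on [lo - 3σ, hi + 3σ],
    evaluated by numerical integration (so range truncation is accounted
    for).
    """
    grid = np.linspace(lo - 3 * sigma, hi + 3 * sigma, 801)
    pa = np.exp(-((bfi_a - grid) ** 2) / (2 * sigma**2))
    pb = np.exp(-((bfi_b - grid) ** 2) / (2 * sigma**2))
    a = np.trapezoid(pa * pb, grid)
    occ_a = np.trapezoid(pa, grid)
    occ_b = np.trapezoid(pb, grid)
    return 2 * a / (occ_a + occ_b)


def calibrate_niche_breadth(
    decay_rate: float, bfi_values: np.ndarray, bfi_range: tuple[float, float]
) -> float:
    """Niche width whose emergent similarity decay matches ``decay_rate``.

    For a candidate width σ the expected pairwise similarities over the
    actual *sample*-pair ΔBFI design — including within-site replicate
    pairs at zero distance, with the multiplicity each site pair has among
    the samples — are computed noise-free, a negative-exponential GLM is
    fitted to them, and σ is adjusted by root finding until the fitted
    rate equals -decay_rate.  Fitting the design the estimator will
    actually see matters because the niche model's expected decay curve is
    not exactly exponential, so the best-fit rate is design-weighted.
    Deterministic.
    """
    bfi_values = np.asarray(bfi_values, dtype=float)
    if len(np.unique(bfi_values)) < 2:
        raise ValueError("need at least two distinct BFI values")
    pairs = list(itertools.combinations(range(len(bfi_values)), 2))
    lo, hi = bfi_range
    # expected similarity depends on the pair's (bfi_i, bfi_j) only
    uniq_pairs = sorted(
        {tuple(sorted((bfi_values[i], bfi_values[j]))) for i, j in pairs}
    )
    multiplicity = {}
    for i, j in pairs:
        key = tuple(sorted((bfi_values[i], bfi_values[j])))
        multiplicity[key] = multiplicity.get(key, 0) + 1

    def fitted_rate(sigma: float) -> float:
        sims, dists = [], []
        for key in uniq_pairs:
            s = _expected_similarity(key[0], key[1], sigma, lo, hi)
            sims.extend([s] * multiplicity[key])
            dists.extend([key[1] - key[0]] * multiplicity[key])
        return fit_negative_exponential(sims, dists).rate

    def objective(sigma: float) -> float:
        return fitted_rate(sigma) + decay_rate

    lo_s, hi_s = 0.01, 5.0
    if objective(lo_s) * objective(hi_s) > 0:
        raise ValueError(
            f"decay_rate {decay_rate} not attainable for niche widths in "
            f"[{lo_s}, {hi_s}] on this BFI design"
        )
    return float(brentq(objective, lo_s, hi_s, xtol=1e-5))


@dataclass
class Community:
    """Counts matrix plus the per-species truth used to generate it."""

    counts: pd.DataFrame
    feature_optima: pd.Series
    feature_heterogeneity: pd.Series = field(repr=False, default=None)
    niche_breadth: float = float("nan")


def generate_communities(
    sites: list[Site], config: SimulationConfig
) -> Community:
    """Draw a feature × sample count matrix from the niche model.

    Species optima are uniform on the BFI range extended by three niche
    widths each side (so edge sites are not artificially depauperate);
    species abundances carry lognormal heterogeneity.  Presence is
    Bernoulli per sample from the Gaussian occupancy curve; counts are a
    multinomial draw over present species with a per-sample depth drawn
    uniformly from [0.7, 1.0] x ``depth`` (unequal library sizes, so
    rarefaction has work to do).
    """
    if config.gamma_richness < 10:
        raise ValueError("gamma_richness must be at least 10")
    bfis = np.array([s.bfi for s in sites])
    lo, hi = config.bfi_range
    sigma = config.niche_breadth
    if sigma is None:
        # calibrate against the full sample-pair design, replicates included
        sigma = calibrate_niche_breadth(config.decay_rate, bfis, config.bfi_range)
    rng = np.random.default_rng(config.seed + _STREAM_COMMUNITIES)
    R = config.gamma_richness
    optima = rng.uniform(lo - 3 * sigma, hi + 3 * sigma, R)
    hetero = rng.lognormal(0.0, config.abundance_sigma, R)
    features = [f"SP{k + 1:05d}" for k in range(R)]
    cols = {}
    for s in sites:
        occ_p = np.exp(-((s.bfi - optima) ** 2) / (2 * sigma**2))
        z = rng.random(R) < occ_p
        counts = np.zeros(R, dtype=np.int64)
        if z.any():
            w = np.where(z, hetero, 0.0)
            depth = int(rng.integers(int(0.7 * config.depth), config.depth + 1))
            counts = rng.multinomial(depth, w / w.sum())
        cols[s.sample_id] = counts
    m = pd.DataFrame(cols, index=features)
    m.index.name = "feature"
    m.columns.name = "sample"
    return Community(
        counts=m,
        feature_optima=pd.Series(optima, index=features, name="optimum"),
        feature_heterogeneity=pd.Series(hetero, index=features, name="heterogeneity"),
        niche_breadth=float(sigma),
    )


# ---------------------------------------------------------------------------
# sequence construction

# per-residue net-charge contribution of side chains at pH 7 (Lehninger)
def _side_chain_charge(aa: str, ph: float = 7.0) -> float:
    pka = LEHNINGER.side_chain.get(aa)
    if pka is None:
        return 0.0
    if aa in LEHNINGER.basic:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    return -1.0 / (1.0 + 10.0 ** (pka - ph))


_AA_GRAVY = dict(KYTE_DOOLITTLE)
_AA_CHARGE = {aa: _side_chain_charge(aa) for aa in _AA_GRAVY}
_GC_COUNT = {
    codon: codon.count("G") + codon.count("C")
    for codons in _SYNONYMS.values()
    for codon in codons
}


# mean GC fraction over a residue's synonymous codons (its "GC capability")
def _mean_codon_gc(aa: str) -> float:
    codons = _SYNONYMS[aa]
    return sum(_GC_COUNT[c] for c in codons) / (3 * len(codons))


def _greedy_protein(
    length: int, gravy_target: float, charge_target: float, gc_target: float
) -> str:
    """Choose residues so hydropathy, net charge and GC room hit targets.

    Ionizable residues are selected first by greedy repair: the residue
    (D, E, K, R, H or C) whose Henderson-Hasselbalch charge at pH 7 most
    reduces the remaining charge deficit is added until the deficit is
    below the finest available step.  The remaining positions are filled
    with neutral residues chosen greedily for the per-residue hydropathy
    deficit, with a usage penalty that keeps the composition diverse and a
    pull toward residues whose synonymous codons can realise the GC target
    (a two-residue protein would leave no synonymous room to steer GC).
    Charged residues are interleaved at evenly spaced positions.  Every
    choice breaks ties alphabetically, so the construction is
    deterministic.
    """
    if not -4.5 <= gravy_target <= 4.5:
        raise ValueError(
            f"gravy target {gravy_target:.3f} outside the Kyte-Doolittle "
            "range [-4.5, 4.5]; property combination infeasible"
        )
    if abs(charge_target) > length:
        raise ValueError(
            f"charge target {charge_target:.3f} infeasible for length {length}"
        )
    ionizable = {aa: _AA_CHARGE[aa] for aa in "DEKRHC"}
    charged: list[str] = []
    residual = charge_target
    finest = min(abs(v) for v in ionizable.values())
    while len(charged) < length // 2 and abs(residual) > finest / 2:
        best = min(
            sorted(ionizable),
            key=lambda aa: abs(residual - ionizable[aa]),
        )
        if abs(residual - ionizable[best]) >= abs(residual):
            break
        charged.append(best)
        residual -= ionizable[best]
    n_fill = length - len(charged)
    neutral = sorted(set(_AA_GRAVY) - set("DEKRHCY"))
    g = np.array([_AA_GRAVY[a] for a in neutral])
    gc_mid = np.array([_mean_codon_gc(a) for a in neutral])
    gravy_budget = gravy_target * length - sum(_AA_GRAVY[a] for a in charged)
    fill: list[str] = []
    counts = np.zeros(len(neutral))
    G = 0.0
    for pos in range(n_fill):
        r = n_fill - pos
        dg = (gravy_budget - G) / r
        usage = counts / (pos + 1)
        score = (g - dg) ** 2 + 8.0 * usage + 12.0 * (gc_mid - gc_target) ** 2
        k = int(np.argmin(score))  # argmin takes the first (alphabetical) tie
        fill.append(neutral[k])
        counts[k] += 1
        G += g[k]
    # interleave charged residues at evenly spaced positions
    seq = list(fill)
    for i, aa in enumerate(charged):
        seq.insert(
            min(len(seq), int((i + 1) * length / (len(charged) + 1))), aa
        )
    return "".join(seq)


def _greedy_codons(protein: str, gc_target: float) -> str:
    """Pick synonymous codons so cumulative GC tracks the target fraction."""
    min_gc = sum(min(_GC_COUNT[c] for c in _SYNONYMS[aa]) for aa in protein)
    max_gc = sum(max(_GC_COUNT[c] for c in _SYNONYMS[aa]) for aa in protein)
    L = 3 * len(protein)
    if not min_gc / L <= gc_target <= max_gc / L:
        raise ValueError(
            f"GC target {gc_target:.3f} outside the attainable range "
            f"[{min_gc / L:.3f}, {max_gc / L:.3f}] for this protein; "
            "property combination infeasible"
        )
    codons = []
    gc = 0
    for i, aa in enumerate(protein):
        options = sorted(_SYNONYMS[aa])
        want = gc_target * 3 * (i + 1)
        best = min(options, key=lambda c: (abs(gc + _GC_COUNT[c] - want), c))
        codons.append(best)
        gc += _GC_COUNT[best]
    return "".join(codons)


def _synonymous_variant(nt: str) -> str | None:
    """A copy of ``nt`` with one codon swapped for a synonym, or None."""
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        aa = None
        for cand_aa, codons in _SYNONYMS.items():
            if codon in codons:
                aa = cand_aa
                break
        options = [c for c in sorted(_SYNONYMS[aa]) if c != codon]
        if options:
            # prefer a synonym with the same GC count to keep GC on target
            options.sort(key=lambda c: (abs(_GC_COUNT[c] - _GC_COUNT[codon]), c))
            return nt[:i] + options[0] + nt[i + 3 :]
    return None


def feature_sequences(
    community: Community, config: SimulationConfig
) -> dict[str, list[str]]:
    """True nucleotide variant(s) per species.

    Each species gets a nucleotide sequence whose GC content, encoded
    GRAVY and net charge trend linearly with its BFI optimum (slopes and
    intercepts from the config); a random ``synonymous_fraction`` of
    species carries a second, synonymous variant.
    """
    rng = np.random.default_rng(config.seed + _STREAM_SEQUENCES)
    variants: dict[str, list[str]] = {}
    for feat in community.counts.index:
        mu = float(community.feature_optima[feat])
        gc_target = config.gc_intercept + config.gc_slope * mu
        protein = _greedy_protein(
            config.protein_length,
            config.gravy_intercept + config.gravy_slope * mu,
            config.charge_intercept + config.charge_slope * mu,
            gc_target,
        )
        nt = _greedy_codons(protein, gc_target)
        seqs = [nt]
        if rng.random() < config.synonymous_fraction:
            var = _synonymous_variant(nt)
            if var is not None:
                seqs.append(var)
        variants[feat] = seqs
    return variants


def generate_sequences(
    community: Community, config: SimulationConfig, gene: str = "sim_gene"
) -> SequenceSet:
    """Emit per-sample in-frame reads realising the community counts.

    Sequences come from :func:`feature_sequences`; a species' reads are
    split evenly between its synonymous variants, so AAV collapsing has
    real work to do while OTU clustering sees near-identical pairs.
    """
    m = community.counts
    if m.shape[0] == 0 or m.to_numpy().sum() == 0:
        raise ValueError("community is empty")
    variants = feature_sequences(community, config)
    rows = []
    for sample in m.columns:
        col = m[sample]
        r = 0
        for feat in m.index[col.to_numpy() > 0]:
            count = int(col[feat])
            seqs = variants[feat]
            # split reads evenly across synonymous variants
            base, extra = divmod(count, len(seqs))
            for v, nt in enumerate(seqs):
                for _ in range(base + (1 if v < extra else 0)):
                    rows.append((sample, f"read{r:06d}", nt))
                    r += 1
    records = pd.DataFrame(rows, columns=["sample_id", "seq_id", "nt"])
    return SequenceSet(gene=gene, records=records)


def generate_qpcr_table(
    sites: list[Site], config: SimulationConfig
) -> pd.DataFrame:
    """Long-format qPCR copy table (sample_id, gene, copies).

    The AOA share of the ammonia-oxidising community (aoa_amoA + aob_amoA
    + hzo copies) is a beta draw with logit(mean) = beta_coefs · (1, bfi)
    and precision ``precision_phi``; the anammox share of the non-AOA
    remainder follows ``anammox_coefs`` the same way.  Shares are scaled
    by a lognormal total to give copies; bacterial 16S rRNA copies decline
    modestly with BFI and nirS/mcrA are beta-distributed fractions of
    them.
    """
    if len(config.beta_coefs) != 2:
        raise ValueError("beta_coefs must be (intercept, bfi_slope)")
    if config.precision_phi <= 0:
        raise ValueError("precision_phi must be positive")
    rng = np.random.default_rng(config.seed + _STREAM_QPCR)
    phi = config.precision_phi
    b0, b1 = config.beta_coefs
    a0, a1 = config.anammox_coefs

    def beta_draw(logit_mu: float) -> float:
        mu = 1.0 / (1.0 + math.exp(-logit_mu))
        return float(rng.beta(mu * phi, (1.0 - mu) * phi))

    rows = []
    for s in sites:
        total_ao = float(rng.lognormal(math.log(1e5), 0.3))
        p_aoa = beta_draw(b0 + b1 * s.bfi)
        p_anx = beta_draw(a0 + a1 * s.bfi)
        aoa = p_aoa * total_ao
        hzo = (1.0 - p_aoa) * p_anx * total_ao
        aob = (1.0 - p_aoa) * (1.0 - p_anx) * total_ao
        bac = float(rng.lognormal(math.log(1e8) - 0.4 * s.bfi, 0.3))
        nirs = beta_draw(-4.0 + 0.8 * s.bfi) * bac
        mcra = beta_draw(-5.0 - 0.5 * s.bfi) * bac
        for gene, copies in [
            ("aoa_amoA", aoa),
            ("aob_amoA", aob),
            ("hzo", hzo),
            ("nirS", nirs),
            ("mcrA", mcra),
            ("bac_16S", bac),
        ]:
            rows.append((s.sample_id, gene, copies))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "copies"])


def qpcr_sites(config: SimulationConfig) -> list[Site]:
    """Site list for the qPCR design: the full four-season survey."""
    return generate_sites(replace(config, seasons=FOUR_SEASONS))
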