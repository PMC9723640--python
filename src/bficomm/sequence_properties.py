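"""DNA and protein sequence properties and their community-weighted means.

Four per-feature properties drive the downstream regressions against base
flow index:

* **GC content** of the nucleotide sequence, (G+C)/length.
* **CAI** (codon adaptation index): the geometric mean of codon relative
  adaptiveness values over the informative codons of a gene, where a
  codon's relative adaptiveness w is its frequency in a reference set
  divided by the frequency of the commonest synonymous codon.  Methionine
  (ATG), tryptophan (TGG) and stop codons are uninformative (w = 1 by
  definition) and are excluded from the mean.
* **GRAVY**: grand average of hydropathy — the mean Kyte-Doolittle
  hydropathy of the residues of the translated protein.
* **Net charge** at a given pH: the sum of Henderson-Hasselbalch
  fractional charges of all ionizable groups (basic side chains K/R/H and
  the amino terminus; acidic side chains D/E/C/Y and the carboxyl
  terminus) under a pKa scale; the packaged default is the Lehninger
  textbook scale evaluated at intracellular pH 7.

Community-weighted means multiply each feature's value by its relative
abundance in a sample, giving one value per sample to regress on BFI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .sequence_units import (
    _CODON_TABLE,
    _STOP_CODONS,
    InternalStopError,
    TranslationError,
)

__all__ = [
    "PkaScale",
    "CodonWeights",
    "KYTE_DOOLITTLE",
    "LEHNINGER",
    "gc_content",
    "relative_adaptiveness",
    "cai",
    "gravy",
    "net_charge",
    "community_weighted_mean",
    "property_vs_bfi",
    "sequence_property_table",
    "reference_codon_counts",
]

_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# codons grouped by encoded amino acid (stop codons excluded)
_SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    _SYNONYMS.setdefault(_aa, []).append(_codon)

# codons that carry no codon-usage information for CAI
_UNINFORMATIVE = {"ATG", "TGG"} | _STOP_CODONS


def _load_data(name: str) -> dict:
    with resources.files("bficomm.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class PkaScale:
    """pKa values for ionizable groups of a peptide.

    ``side_chain`` maps one-letter residue codes to side-chain pKa;
    ``amino_terminus``/``carboxyl_terminus`` are the terminal pKas,
    counted once per peptide.  ``basic`` groups gain a positive fractional
    charge below their pKa, ``acidic`` groups a negative one above it.
    """

    name: str
    side_chain: dict[str, float]
    amino_terminus: float
    carboxyl_terminus: float
    basic: frozenset[str] = frozenset("RHK")
    acidic: frozenset[str] = frozenset("DECY")

    def __post_init__(self) -> None:
        for pka in [*self.side_chain.values(), self.amino_terminus,
                    self.carboxyl_terminus]:
            if not 0 < pka < 14:
                raise ValueError(f"pKa {pka} outside (0, 14)")


def _load_lehninger() -> PkaScale:
    d = _load_data("lehninger_pka.json")
    return PkaScale(
        name=d["name"],
        side_chain=d["side_chain"],
        amino_terminus=d["amino_terminus"],
        carboxyl_terminus=d["carboxyl_terminus"],
        basic=frozenset(d["basic"]),
        acidic=frozenset(d["acidic"]),
    )


KYTE_DOOLITTLE: dict[str, float] = _load_data("kyte_doolittle.json")["values"]
LEHNINGER: PkaScale = _load_lehninger()


@dataclass(frozen=True)
class CodonWeights:
    """Relative adaptiveness w of every sense codon, in [0, 1].

    For each amino acid the commonest synonymous codon of the reference
    set has w = 1.
    """

    w: dict[str, float]
    reference: str = "unspecified"

    def __post_init__(self) -> None:
        for codon, val in self.w.items():
            if not 0 < val <= 1:
                raise ValueError(f"w[{codon}] = {val} outside (0, 1]")


def gc_content(nt: str) -> float:
    """Fraction of G and C bases in a nucleotide string."""
    if not nt:
        raise ValueError("empty sequence")
    if not set(nt) <= set("ACGT"):
        raise ValueError(f"non-ACGT symbol(s) {sorted(set(nt) - set('ACGT'))}")
    return (nt.count("G") + nt.count("C")) / len(nt)


def relative_adaptiveness(
    reference_codon_counts: dict[str, float], require_complete: bool = True
) -> CodonWeights:
    """Codon relative adaptiveness from reference codon counts.

    w(codon) = count(codon) / max count among its synonyms, after replacing
    zero counts by a 0.5 pseudocount so rare codons never zero out the
    geometric mean.  By default every amino acid must be observed at least
    once; with ``require_complete=False`` an entirely unobserved amino acid
    instead gets uniform weights w = 1 for all its synonyms (its codons
    carry no usage information and then contribute nothing to a CAI).
    """
    counts = {c: float(reference_codon_counts.get(c, 0.0)) for c in _CODON_TABLE}
    w: dict[str, float] = {}
    for aa, codons in _SYNONYMS.items():
        if all(counts[c] == 0 for c in codons):
            if require_complete:
                raise ValueError(f"amino acid {aa} never observed in reference")
            for c in codons:
                w[c] = 1.0
            continue
        adj = {c: (counts[c] if counts[c] > 0 else 0.5) for c in codons}
        top = max(adj.values())
        for c in codons:
            w[c] = adj[c] / top
    return CodonWeights(w=w, reference="user-supplied codon counts")


def cai(nt: str, weights: CodonWeights) -> float:
    """Codon adaptation index: geometric mean of w over informative codons.

    ATG, TGG and a terminal stop codon are skipped; an internal stop is an
    error.  A sequence with no informative codon has an undefined CAI and
    returns NaN.
    """
    if len(nt) % 3 != 0:
        raise TranslationError(f"length {len(nt)} is not a multiple of 3")
    n_codons = len(nt) // 3
    logs = []
    for k in range(n_codons):
        codon = nt[3 * k : 3 * k + 3]
        if codon in _STOP_CODONS:
            if k != n_codons - 1:
                raise InternalStopError(f"stop codon at codon {k + 1}")
            continue
        if codon in _UNINFORMATIVE:
            continue
        if codon not in weights.w:
            raise ValueError(f"no adaptiveness weight for codon {codon}")
        logs.append(np.log(weights.w[codon]))
    if not logs:
        return float("nan")
    return float(np.exp(np.mean(logs)))


def gravy(protein: str) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value per residue)."""
    if not protein:
        raise ValueError("empty protein")
    try:
        return sum(KYTE_DOOLITTLE[aa] for aa in protein) / len(protein)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


def net_charge(protein: str, ph: float = 7.0, scale: PkaScale = LEHNINGER) -> float:
    """Net charge of a peptide at a given pH under a pKa scale.

    Z = sum over basic groups of n/(1 + 10^(pH - pKa))
      - sum over acidic groups of n/(1 + 10^(pKa - pH)),
    with the two termini each counted once.
    """
    if not protein:
        raise ValueError("empty protein")
    if not 0 < ph < 14:
        raise ValueError("pH must be in (0, 14)")
    unknown = set(protein) - _AMINO_ACIDS
    if unknown:
        raise ValueError(f"unknown residue(s) {sorted(unknown)}")
    z = 1.0 / (1.0 + 10.0 ** (ph - scale.amino_terminus))
    z -= 1.0 / (1.0 + 10.0 ** (scale.carboxyl_terminus - ph))
    for aa, pka in scale.side_chain.items():
        n = protein.count(aa)
        if n == 0:
            continue
        if aa in scale.basic:
            z += n / (1.0 + 10.0 ** (ph - pka))
        elif aa in scale.acidic:
            z -= n / (1.0 + 10.0 ** (pka - ph))
    return z


def community_weighted_mean(values: pd.Series, m: pd.DataFrame) -> pd.Series:
    """Abundance-weighted mean of a per-feature value, per sample.

    ``values`` is indexed by feature; every feature with nonzero abundance
    in ``m`` must have a value.  Samples with zero total count get NaN.
    """
    present = m.index[(m > 0).any(axis=1)]
    missing = present.difference(values.index)
    if len(missing):
        raise ValueError(
            f"no property value for feature(s): {', '.join(map(str, missing[:5]))}"
        )
    vals = values.reindex(m.index).to_numpy(dtype=float)
    counts = m.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        weighted = np.where(
            totals > 0,
            np.nansum(counts * vals[:, None], axis=0) / totals,
            np.nan,
        )
    return pd.Series(weighted, index=m.columns, name=values.name)


@dataclass
class PropertyFit:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def property_vs_bfi(values: pd.Series, meta: pd.DataFrame) -> PropertyFit:
    """OLS regression of a per-sample property mean on BFI.

    ``values`` is indexed by sample_id; ``meta`` maps sample_id to bfi.
    NaN samples (e.g. empty communities) are dropped before fitting.
    """
    bfi = meta.set_index("sample_id")["bfi"].reindex(values.index)
    keep = values.notna() & bfi.notna()
    y = values[keep].to_numpy(dtype=float)
    x = bfi[keep].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least three samples with values")
    if np.ptp(x) == 0:
        raise ValueError("BFI is constant across samples; slope undefined")
    if np.ptp(y) == 0:
        # constant response: flat line fits exactly, nothing explained
        return PropertyFit(slope=0.0, intercept=float(y[0]), r2=0.0,
                           p_value=1.0, n=len(y))
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return PropertyFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=len(y),
    )


def reference_codon_counts(
    nt_by_feature: pd.Series, m: pd.DataFrame, top_fraction: float = 0.1
) -> dict[str, int]:
    """Codon counts of the most abundant features, for a CAI reference.

    The default reference set is the top ``top_fraction`` of features by
    total abundance in the analysed table (at least one feature).
    """
    totals = m.sum(axis=1).sort_values(ascending=False)
    n_top = max(1, int(np.ceil(top_fraction * len(totals))))
    counts: dict[str, int] = {}
    for feat in totals.index[:n_top]:
        nt = nt_by_feature[feat]
        for k in range(len(nt) // 3):
            codon = nt[3 * k : 3 * k + 3]
            if codon in _STOP_CODONS:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def sequence_property_table(
    nt_by_feature: pd.Series,
    m: pd.DataFrame,
    weights: CodonWeights | None = None,
    ph: float = 7.0,
    scale: PkaScale = LEHNINGER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature properties and their community-weighted per-sample means.

    ``nt_by_feature`` maps every feature of ``m`` to its representative
    in-frame nucleotide sequence (the OTU centroid or an AAV member).  If
    no codon ``weights`` are supplied the reference set defaults to the top
    decile of features by total abundance.

    Returns ``(per_feature, per_sample)`` tables with columns gc, cai,
    gravy, charge.
    """
    from .sequence_units import translate

    if weights is None:
        weights = relative_adaptiveness(
            reference_codon_counts(nt_by_feature, m), require_complete=False
        )
    feats = list(m.index)
    rows = []
    for feat in feats:
        nt = nt_by_feature[feat]
        protein = translate(nt)
        rows.append(
            {
                "feature": feat,
                "gc": gc_content(nt),
                "cai": cai(nt, weights),
                "gravy": gravy(protein),
                "charge": net_charge(protein, ph=ph, scale=scale),
            }
        )
    per_feature = pd.DataFrame(rows).set_index("feature")
    per_sample = pd.DataFrame(
        {
            col: community_weighted_mean(per_feature[col], m)
            for col in ("gc", "cai", "gravy", "charge")
        }
    )
    per_sample.index.name = "sample"
    return per_feature, per_sample
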