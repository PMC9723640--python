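"""From in-frame nucleotide reads to AAV and OTU community matrices.

Input sequences are assumed frameshift-corrected and in frame +1; this
module applies per-gene length filters and per-sample library-size filters,
translates with the standard genetic code, and builds two kinds of
community units:

* **AAV** (amino acid variant): a cluster of nucleotide sequences sharing
  an identical translated protein.  There is no similarity threshold — any
  nucleotide variation within an AAV is synonymous by construction.
* **OTU**: greedy centroid clustering of nucleotide sequences at a
  pairwise-identity threshold (default 97%).  Candidates are processed in
  decreasing total-abundance order (ties broken lexicographically by
  sequence); a candidate joins the first centroid with identity >= the
  threshold, else founds a new cluster.  Identity is computed from a
  global (end-to-end) alignment with unit mismatch/gap costs as
  matches / alignment columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import edlib
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceSet",
    "FilterConfig",
    "AAVCluster",
    "OtuCluster",
    "TranslationError",
    "InternalStopError",
    "filter_by_length",
    "filter_by_library_size",
    "translate",
    "build_aav_matrix",
    "cluster_otus",
    "pairwise_identity",
]

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


class TranslationError(ValueError):
    """Sequence cannot be translated (bad frame or alphabet)."""


class InternalStopError(TranslationError):
    """Translation hit a stop codon before the final codon."""


@dataclass
class SequenceSet:
    """Per-sample in-frame nucleotide sequences for one functional gene.

    ``records`` has columns ``sample_id``, ``seq_id``, ``nt``; one row per
    read, so per-sample abundance is row multiplicity.
    """

    gene: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "seq_id", "nt"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(required)}")
        if len(self.records) and (self.records["nt"].str.len() == 0).any():
            raise ValueError("empty nucleotide sequences are not allowed")
        dup = self.records.duplicated(subset=["sample_id", "seq_id"])
        if dup.any():
            raise ValueError("seq_id must be unique within each sample")

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class FilterConfig:
    """Length and library-size thresholds for one gene.

    ``min_len``/``max_len`` are inclusive bounds in bases (None disables a
    bound); samples with fewer than ``min_library`` reads are discarded.
    """

    min_len: int | None = None
    max_len: int | None = None
    min_library: int = 0

    def __post_init__(self) -> None:
        if (
            self.min_len is not None
            and self.max_len is not None
            and self.min_len > self.max_len
        ):
            raise ValueError("min_len must not exceed max_len")
        if self.min_library < 0:
            raise ValueError("min_library must be non-negative")


@dataclass
class AAVCluster:
    aav_id: str
    protein: str
    member_nt: set[str] = field(default_factory=set)
    per_sample_count: dict[str, int] = field(default_factory=dict)


@dataclass
class OtuCluster:
    otu_id: str
    centroid_nt: str
    identity_threshold: float
    per_sample_count: dict[str, int] = field(default_factory=dict)
    member_nt: set[str] = field(default_factory=set)


def filter_by_length(seqs: SequenceSet, cfg: FilterConfig) -> SequenceSet:
    """Keep records whose length satisfies min_len <= l <= max_len."""
    lengths = seqs.records["nt"].str.len()
    mask = pd.Series(True, index=seqs.records.index)
    if cfg.min_len is not None:
        mask &= lengths >= cfg.min_len
    if cfg.max_len is not None:
        mask &= lengths <= cfg.max_len
    dropped = int((~mask).sum())
    if dropped:
        logger.info("%s: length filter removed %d of %d records",
                    seqs.gene, dropped, len(seqs.records))
    return replace(seqs, records=seqs.records.loc[mask].reset_index(drop=True))


def filter_by_library_size(seqs: SequenceSet, cfg: FilterConfig) -> SequenceSet:
    """Discard whole samples with fewer than ``min_library`` records.

    The comparison is strict ("fewer than"), so a sample holding exactly the
    threshold count is retained.  Raises if nothing survives.
    """
    sizes = seqs.records.groupby("sample_id").size()
    removed = sizes[sizes < cfg.min_library].index.tolist()
    if removed:
        logger.info("%s: library-size filter (< %d) removed samples: %s",
                    seqs.gene, cfg.min_library, ", ".join(map(str, removed)))
    kept = seqs.records[~seqs.records["sample_id"].isin(removed)]
    if len(kept) == 0 and len(seqs.records) > 0:
        raise ValueError(
            f"{seqs.gene}: library-size threshold {cfg.min_library} "
            "removed every sample"
        )
    return replace(seqs, records=kept.reset_index(drop=True))


def translate(nt: str) -> str:
    """Translate an in-frame (frame +1) nucleotide string, standard code.

    A single stop codon at the very end is tolerated and stripped; a stop
    anywhere else raises :class:`InternalStopError`.
    """
    if len(nt) % 3 != 0:
        raise TranslationError(f"length {len(nt)} is not a multiple of 3")
    if not set(nt) <= set("ACGT"):
        bad = sorted(set(nt) - set("ACGT"))
        raise TranslationError(f"non-ACGT symbol(s) {bad} in sequence")
    aas = []
    n_codons = len(nt) // 3
    for k in range(n_codons):
        codon = nt[3 * k : 3 * k + 3]
        if codon in _STOP_CODONS:
            if k == n_codons - 1:
                break
            raise InternalStopError(f"stop codon {codon} at codon {k + 1}")
        aas.append(_CODON_TABLE[codon])
    return "".join(aas)


def build_aav_matrix(
    seqs: SequenceSet,
) -> tuple[list[AAVCluster], pd.DataFrame]:
    """Collapse reads into amino acid variants.

    Every translatable record is assigned to the cluster of its protein
    string; records with internal stop codons are logged and excluded.
    Returns the clusters (ordered by decreasing total abundance, protein
    lexicographic tie-break) and a feature × sample count matrix whose
    total equals the number of translatable input records.
    """
    if len(seqs.records) == 0:
        return [], pd.DataFrame()
    proteins = {}
    flagged = 0
    for nt in seqs.records["nt"].unique():
        try:
            proteins[nt] = translate(nt)
        except InternalStopError:
            proteins[nt] = None
            flagged += 1
    if flagged:
        logger.warning("%s: excluded %d unique sequences with internal stops",
                       seqs.gene, flagged)
    rec = seqs.records.assign(protein=seqs.records["nt"].map(proteins))
    rec = rec.dropna(subset=["protein"])
    if len(rec) == 0:
        return [], pd.DataFrame()
    counts = (
        rec.groupby(["protein", "sample_id"]).size().unstack(fill_value=0)
    )
    order = sorted(
        counts.index, key=lambda prot: (-counts.loc[prot].sum(), prot)
    )
    counts = counts.loc[order]
    members = rec.groupby("protein")["nt"].agg(set)
    clusters = []
    ids = []
    for i, protein in enumerate(counts.index):
        aav_id = f"AAV{i + 1:05d}"
        ids.append(aav_id)
        clusters.append(
            AAVCluster(
                aav_id=aav_id,
                protein=protein,
                member_nt=members[protein],
                per_sample_count={
                    s: int(v) for s, v in counts.loc[protein].items() if v > 0
                },
            )
        )
    matrix = counts.set_axis(ids, axis=0)
    matrix.index.name = "feature"
    matrix.columns.name = "sample"
    return clusters, matrix


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two nucleotide strings.

    The alignment minimises unit-cost edits (Levenshtein, end-to-end);
    identity = matching columns / total alignment columns
    = 1 - edit_distance / alignment_length.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    res = edlib.align(a, b, mode="NW", task="path")
    cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            cols += int(num)
            num = ""
    return 1.0 - res["editDistance"] / cols


def cluster_otus(
    seqs: SequenceSet, threshold: float = 0.97
) -> tuple[list[OtuCluster], pd.DataFrame]:
    """Greedy centroid clustering of nucleotide sequences.

    Unique sequences are visited in decreasing total-abundance order
    (lexicographic tie-break) and each joins the first existing centroid —
    in founding order — whose identity is >= ``threshold``, otherwise it
    founds a new cluster.  The centroid is therefore always the most
    abundant member of its cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if len(seqs.records) == 0:
        return [], pd.DataFrame()
    counts = (
        seqs.records.groupby(["nt", "sample_id"]).size().unstack(fill_value=0)
    )
    order = sorted(counts.index, key=lambda nt: (-counts.loc[nt].sum(), nt))
    clusters: list[OtuCluster] = []
    for nt in order:
        home = None
        for cl in clusters:
            if pairwise_identity(nt, cl.centroid_nt) >= threshold:
                home = cl
                break
        if home is None:
            home = OtuCluster(
                otu_id=f"OTU{len(clusters) + 1:05d}",
                centroid_nt=nt,
                identity_threshold=threshold,
            )
            clusters.append(home)
        home.member_nt.add(nt)
        for sample, v in counts.loc[nt].items():
            if v > 0:
                home.per_sample_count[sample] = (
                    home.per_sample_count.get(sample, 0) + int(v)
                )
    samples = list(counts.columns)
    matrix = pd.DataFrame(
        [[cl.per_sample_count.get(s, 0) for s in samples] for cl in clusters],
        index=[cl.otu_id for cl in clusters],
        columns=samples,
    )
    matrix.index.name = "feature"
    matrix.columns.name = "sample"
    return clusters, matrix
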