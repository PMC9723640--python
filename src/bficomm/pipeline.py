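"""End-to-end orchestration: simulate → cluster → normalise → analyse.

The pipeline reads a single YAML config (or a :class:`RunConfig`) and runs
the stages in order, writing every intermediate table under the output
directory plus a ``manifest.json`` recording inputs, seeds, settings and a
SHA-256 checksum of every file written — enough to reproduce a run
bit-for-bit.  Each stage can also be invoked on its own through
:mod:`bficomm.cli`.

Directory layout of a full run::

    outdir/
      simulated/        metadata.tsv, qpcr.tsv, sim_config.yaml,
                        <gene>/<sample>.fasta
      cluster/          aav_matrix.tsv, otu_matrix.tsv,
                        aav_proteins.fasta, otu_centroids.fasta
      normalise/        aav_rarefied.tsv, otu_rarefied.tsv
      betadiv/          aav_pairs.tsv, otu_pairs.tsv
      decay/            aav_decay.json, otu_decay.json, slope_comparison.json
      seqprops/         aav_properties.tsv, aav_sample_means.tsv,
                        property_fits.tsv
      models/           richness_fits.json, qpcr_fits.json
      manifest.json
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import community_structure as cs
from . import distance_decay as dd
from . import group_models as gm
from . import sequence_properties as sp
from . import sequence_units as su
from . import synthetic_data as syn

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "validate_inputs", "run_pipeline"]


@dataclass
class RunConfig:
    """Settings for a pipeline run.

    ``simulation`` holds :class:`~bficomm.synthetic_data.SimulationConfig`
    overrides; ``filters`` per-gene length/library thresholds;
    ``rarefaction_seed`` the (recorded) seed of the single rarefaction
    draw; resampling counts must be at least 99.
    """

    outdir: str = "bficomm_run"
    gene: str = "sim_gene"
    simulation: dict = field(default_factory=dict)
    filters: dict = field(default_factory=dict)
    otu_threshold: float = 0.97
    rarefaction_seed: int = 17
    n_perm: int = 1000
    n_boot: int = 1000
    permutation_seed: int = 23
    bootstrap_seed: int = 29

    def __post_init__(self) -> None:
        if self.n_perm < 99 or self.n_boot < 99:
            raise ValueError("resampling counts must be at least 99")

    def sim_config(self) -> syn.SimulationConfig:
        return syn.SimulationConfig(**self.simulation)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, cfg: RunConfig):
        self.outdir = outdir
        self.record = {
            "config": dataclasses.asdict(cfg),
            "stages": {},
        }

    def add(self, stage: str, files: list[Path], **settings) -> None:
        self.record["stages"][stage] = {
            "settings": settings,
            "files": {
                str(p.relative_to(self.outdir)): _sha256(p) for p in files
            },
        }

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.record, fh, indent=2, sort_keys=True)
        return path


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def _read_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict[str, Path]:
    """Generate the synthetic study and write all of its raw inputs."""
    sim = cfg.sim_config()
    simdir = outdir / "simulated"
    simdir.mkdir(parents=True, exist_ok=True)
    sites = syn.generate_sites(sim)
    meta = syn.sites_to_metadata(sites)
    community = syn.generate_communities(sites, sim)
    seqs = syn.generate_sequences(community, sim, gene=cfg.gene)
    qpcr = syn.generate_qpcr_table(syn.qpcr_sites(sim), sim)

    paths = {}
    paths["metadata"] = _write_tsv(meta, simdir / "metadata.tsv", index=False)
    paths["qpcr"] = _write_tsv(qpcr, simdir / "qpcr.tsv", index=False)
    genedir = simdir / cfg.gene
    genedir.mkdir(exist_ok=True)
    for sample, group in seqs.records.groupby("sample_id"):
        recs = [
            SeqRecord(Seq(nt), id=f"{sample}.{sid}", description="")
            for sid, nt in zip(group["seq_id"], group["nt"])
        ]
        SeqIO.write(recs, genedir / f"{sample}.fasta", "fasta")
        paths[f"fasta:{sample}"] = genedir / f"{sample}.fasta"
    with open(simdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(sim), fh, sort_keys=True)
    paths["sim_config"] = simdir / "sim_config.yaml"
    return paths


def read_fasta_dir(genedir: Path, gene: str) -> su.SequenceSet:
    """Load per-sample FASTA files (``<sample>.fasta``) into a SequenceSet."""
    rows = []
    for fa in sorted(genedir.glob("*.fasta")):
        sample = fa.stem
        for rec in SeqIO.parse(str(fa), "fasta"):
            seq_id = rec.id.removeprefix(f"{sample}.")
            rows.append((sample, seq_id, str(rec.seq)))
    if not rows:
        raise FileNotFoundError(f"no FASTA records under {genedir}")
    return su.SequenceSet(
        gene=gene, records=pd.DataFrame(rows, columns=["sample_id", "seq_id", "nt"])
    )


def stage_cluster(cfg: RunConfig, outdir: Path) -> dict[str, Path]:
    """Filter reads, then build the AAV and OTU matrices and FASTAs."""
    seqs = read_fasta_dir(outdir / "simulated" / cfg.gene, cfg.gene)
    fcfg = su.FilterConfig(**cfg.filters)
    seqs = su.filter_by_length(seqs, fcfg)
    seqs = su.filter_by_library_size(seqs, fcfg)
    aavs, aav_m = su.build_aav_matrix(seqs)
    otus, otu_m = su.cluster_otus(seqs, threshold=cfg.otu_threshold)
    cldir = outdir / "cluster"
    cldir.mkdir(parents=True, exist_ok=True)
    paths = {
        "aav_matrix": _write_tsv(aav_m, cldir / "aav_matrix.tsv"),
        "otu_matrix": _write_tsv(otu_m, cldir / "otu_matrix.tsv"),
    }
    SeqIO.write(
        [SeqRecord(Seq(a.protein), id=a.aav_id, description="") for a in aavs],
        cldir / "aav_proteins.fasta",
        "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(o.centroid_nt), id=o.otu_id, description="") for o in otus],
        cldir / "otu_centroids.fasta",
        "fasta",
    )
    # one representative in-frame nucleotide sequence per AAV, for DNA props
    SeqIO.write(
        [
            SeqRecord(Seq(sorted(a.member_nt)[0]), id=a.aav_id, description="")
            for a in aavs
        ],
        cldir / "aav_representatives.fasta",
        "fasta",
    )
    paths["aav_proteins"] = cldir / "aav_proteins.fasta"
    paths["otu_centroids"] = cldir / "otu_centroids.fasta"
    paths["aav_representatives"] = cldir / "aav_representatives.fasta"
    return paths


def stage_normalise(cfg: RunConfig, outdir: Path) -> dict[str, Path]:
    """Singleton-sample filter then independent rarefaction per table."""
    ndir = outdir / "normalise"
    ndir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind in ("aav", "otu"):
        m = _read_matrix(outdir / "cluster" / f"{kind}_matrix.tsv")
        m = cs.drop_single_sample_features(m)
        depth = int(m.sum(axis=0).min())
        m = cs.rarefy(m, depth, seed=cfg.rarefaction_seed)
        paths[kind] = _write_tsv(m, ndir / f"{kind}_rarefied.tsv")
    return paths


def stage_betadiv(cfg: RunConfig, outdir: Path) -> dict[str, Path]:
    """Pairwise Sørensen partitions joined with pairwise ΔBFI."""
    meta = pd.read_csv(outdir / "simulated" / "metadata.tsv", sep="\t")
    bdir = outdir / "betadiv"
    bdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind in ("aav", "otu"):
        m = _read_matrix(outdir / "normalise" / f"{kind}_rarefied.tsv")
        pairs = dd.attach_delta_bfi(cs.pairwise_dissimilarity(m), meta)
        paths[kind] = _write_tsv(pairs, bdir / f"{kind}_pairs.tsv", index=False)
    return paths


def stage_decay(cfg: RunConfig, outdir: Path) -> dict[str, Path]:
    """Distance-decay fits with permutation p and AAV-vs-OTU slope comparison."""
    meta = pd.read_csv(outdir / "simulated" / "metadata.tsv", sep="\t")
    ddir = outdir / "decay"
    ddir.mkdir(parents=True, exist_ok=True)
    paths = {}
    pair_tabs = {}
    for kind in ("aav", "otu"):
        pairs = pd.read_csv(outdir / "betadiv" / f"{kind}_pairs.tsv", sep="\t")
        pairs["similarity"] = 1.0 - pairs["beta_sor"]
        pair_tabs[kind] = pairs
        fit = dd.permutation_significance(
            pairs, meta, n_perm=cfg.n_perm, seed=cfg.permutation_seed
        )
        record = dataclasses.asdict(fit)
        record["n_permutations"] = cfg.n_perm
        record["seed"] = cfg.permutation_seed
        path = ddir / f"{kind}_decay.json"
        with open(path, "w") as fh:
            json.dump(record, fh, indent=2)
        paths[kind] = path
    comp = dd.bootstrap_compare_slopes(
        pair_tabs["aav"], pair_tabs["otu"], meta,
        n_boot=cfg.n_boot, seed=cfg.bootstrap_seed,
    )
    path = ddir / "slope_comparison.json"
    with open(path, "w") as fh:
        json.dump(
            {
                "rate_aav": comp.rate_a,
                "rate_otu": comp.rate_b,
                "ci_aav": list(comp.ci_a),
                "ci_otu": list(comp.ci_b),
                "p_value": comp.p_value,
                "n_boot": comp.n_boot,
                "seed": cfg.bootstrap_seed,
            },
            fh,
            indent=2,
        )
    paths["comparison"] = path
    return paths


def stage_seqprops(cfg: RunConfig, outdir: Path) -> dict[str, Path]:
    """Per-AAV sequence properties, community-weighted means, BFI fits."""
    meta = pd.read_csv(outdir / "simulated" / "metadata.tsv", sep="\t")
    m = _read_matrix(outdir / "normalise" / "aav_rarefied.tsv")
    reps = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(
            str(outdir / "cluster" / "aav_representatives.fasta"), "fasta"
        )
    }
    nt_by_feature = pd.Series(reps).reindex(m.index)
    per_feature, per_sample = sp.sequence_property_table(nt_by_feature, m)
    fits = []
    for prop in ("gc", "cai", "gravy", "charge"):
        fit = sp.property_vs_bfi(per_sample[prop], meta)
        fits.append(
            {
                "property": prop,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "p_value": fit.p_value,
                "n": fit.n,
            }
        )
    pdir = outdir / "seqprops"
    pdir.mkdir(parents=True, exist_ok=True)
    return {
        "per_feature": _write_tsv(per_feature, pdir / "aav_properties.tsv"),
        "per_sample": _write_tsv(per_sample, pdir / "aav_sample_means.tsv"),
        "fits": _write_tsv(
            pd.DataFrame(fits), pdir / "property_fits.tsv", index=False
        ),
    }


def _fit_record(fit: gm.GroupModelFit) -> dict:
    return {
        "family": fit.family,
        "coefficients": fit.coefficients,
        "odds_scale": fit.odds_scale,
        "dispersion": fit.dispersion,
        "d2": fit.d2,
        "adj_d2": fit.adj_d2,
        "z_values": fit.z_values,
        "p_values": fit.p_values,
        "n": fit.n,
        "terms": list(fit.terms),
    }


def stage_models(cfg: RunConfig, outdir: Path) -> dict[str, Path]:
    """Richness NB GLMs and beta regressions on qPCR group proportions."""
    meta = pd.read_csv(outdir / "simulated" / "metadata.tsv", sep="\t")
    mdir = outdir / "models"
    mdir.mkdir(parents=True, exist_ok=True)
    richness_fits = {}
    for kind in ("aav", "otu"):
        m = _read_matrix(outdir / "normalise" / f"{kind}_rarefied.tsv")
        rich = cs.richness(m)
        sub = meta.set_index("sample_id").loc[rich.index].reset_index()
        richness_fits[kind] = _fit_record(
            gm.fit_negbin(rich.to_numpy(), sub, terms=("bfi", "geology"))
        )
    p1 = mdir / "richness_fits.json"
    with open(p1, "w") as fh:
        json.dump(richness_fits, fh, indent=2)

    qpcr = pd.read_csv(outdir / "simulated" / "qpcr.tsv", sep="\t")
    props = gm.compute_group_proportions(qpcr)
    qmeta = pd.DataFrame(
        {"sample_id": props.index}
    )
    # qPCR samples follow the same naming scheme; recover bfi via site id
    site_bfi = meta.drop_duplicates("site_id").set_index("site_id")["bfi"]
    qmeta["site_id"] = qmeta["sample_id"].str.split("_").str[0]
    qmeta["bfi"] = qmeta["site_id"].map(site_bfi)
    qmeta["season"] = qmeta["sample_id"].str.split("_").str[1]
    qpcr_fits = {}
    for col in ("p_aoa", "p_anammox"):
        y = props[col]
        keep = y.notna()
        data = qmeta.set_index("sample_id").loc[y.index[keep]]
        qpcr_fits[col] = _fit_record(
            gm.fit_beta(y[keep].to_numpy(), data, terms=("bfi",))
        )
    p2 = mdir / "qpcr_fits.json"
    with open(p2, "w") as fh:
        json.dump(qpcr_fits, fh, indent=2)
    return {"richness": p1, "qpcr": p2}


_STAGES = [
    ("simulate", stage_simulate),
    ("cluster", stage_cluster),
    ("normalise", stage_normalise),
    ("betadiv", stage_betadiv),
    ("decay", stage_decay),
    ("seqprops", stage_seqprops),
    ("models", stage_models),
]


def validate_inputs(cfg: RunConfig, outdir: str | Path | None = None) -> list[str]:
    """Report (without aborting) problems in a run's raw inputs.

    Checks FASTA parseability, metadata completeness (every FASTA sample
    has bfi/geology/season; BFI within [0, 1]) and the qPCR table schema.
    A clean run returns an empty list.
    """
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    report: list[str] = []
    simdir = outdir / "simulated"
    meta_path = simdir / "metadata.tsv"
    meta = None
    if not meta_path.exists():
        report.append(f"missing metadata table {meta_path}")
    else:
        meta = pd.read_csv(meta_path, sep="\t")
        for col in ("sample_id", "site_id", "bfi", "geology", "season"):
            if col not in meta.columns:
                report.append(f"metadata lacks column {col!r}")
                meta = None
                break
    if meta is not None:
        bad = meta[(meta["bfi"] < 0) | (meta["bfi"] > 1)]
        for sid in bad["sample_id"]:
            report.append(f"sample {sid}: bfi outside [0, 1]")
        genedir = simdir / cfg.gene
        if not genedir.is_dir():
            report.append(f"missing FASTA directory {genedir}")
        else:
            known = set(meta["sample_id"])
            for fa in sorted(genedir.glob("*.fasta")):
                try:
                    n = sum(1 for _ in SeqIO.parse(str(fa), "fasta"))
                    if n == 0:
                        report.append(f"{fa.name}: no FASTA records")
                except Exception as exc:  # pragma: no cover
                    report.append(f"{fa.name}: unparseable FASTA ({exc})")
                if fa.stem not in known:
                    report.append(f"sample {fa.stem} present in FASTA but absent "
                                  "from metadata")
    qpath = simdir / "qpcr.tsv"
    if not qpath.exists():
        report.append(f"missing qPCR table {qpath}")
    else:
        q = pd.read_csv(qpath, sep="\t")
        missing = {"sample_id", "gene", "copies"} - set(q.columns)
        if missing:
            report.append(f"qPCR table lacks column(s) {sorted(missing)}")
        elif (q["copies"] < 0).any():
            report.append("qPCR table contains negative copy numbers")
    return report


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages (all, by default) and write the manifest.

    Any stage error aborts the run with the stage name attached.  Returns
    the manifest path.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, cfg)
    wanted = set(stages) if stages is not None else {s for s, _ in _STAGES}
    unknown = wanted - {s for s, _ in _STAGES}
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    for name, fn in _STAGES:
        if name not in wanted:
            continue
        logger.info("stage %s starting", name)
        try:
            paths = fn(cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.add(name, sorted(set(paths.values())),
                     seed=cfg.sim_config().seed)
        logger.info("stage %s wrote %d files", name, len(paths))
    return manifest.write()
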