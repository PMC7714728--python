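"""End-to-end orchestration: simulate -> map -> call -> filter -> merge -> detect.

Configuration is a flat ``key = value`` text file with CLI overrides (CLI
wins).  Every run writes a machine-readable provenance block (config hash,
seed, package version) and logs the observation counts at each filter stage
so attrition is auditable.  Re-running with identical inputs and seed yields
byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .bhb_detector import MotifParams, detect
from .junction_caller import (
    call_junctions,
    clusters_to_bed,
    clusters_to_frame,
    filter_junctions,
    map_split_reads,
    merge_junctions,
    observations_from_sam,
)
from .synthetic_data import (
    LocusSpec,
    ReadSimConfig,
    build_genome,
    demo_locus_set,
    file_sha256,
    simulate_reads,
    write_fasta,
    write_fastq,
    write_truth_gff3,
    write_truth_tsv,
)

logger = logging.getLogger("bhbscan")

__all__ = ["PipelineConfig", "run_simulation", "run_discovery"]


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; see ``from_file`` for the text format."""

    outdir: str = "bhbscan_out"
    genome: str = ""
    reads: tuple[str, ...] = ()
    sam: tuple[str, ...] = ()
    # generator
    background_len: int = 30000
    loci: list[LocusSpec] = field(default_factory=demo_locus_set)
    read_len: int = 75
    per_junction_depth: tuple[int, ...] = (10, 10, 10)
    linear_background_depth: float = 1.0
    error_rate: float = 0.0
    circular_enrichment: float = 1.0
    # junction calling
    min_seed: int = 12
    min_coverage: int = 2
    n_replicates: int = 3
    merge_dist: int = 10
    # motif detection
    flank_len: int = 25
    strict_hbhbh: bool = True
    helix_len: int = 4
    bulge_len: int = 3
    h_len: int = 4
    hprime_len: int = 4
    allow_wobble: bool = True
    energy_engine: str = "internal"
    # bookkeeping
    seed: int = 0
    log_level: str = "INFO"

    _SIMPLE = {
        "outdir": str, "genome": str, "background_len": int, "read_len": int,
        "linear_background_depth": float, "error_rate": float,
        "circular_enrichment": float, "min_seed": int, "min_coverage": int,
        "n_replicates": int, "merge_dist": int, "flank_len": int,
        "helix_len": int, "bulge_len": int, "h_len": int, "hprime_len": int,
        "energy_engine": str, "seed": int, "log_level": str,
    }

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat key = value config.  Lists are comma-separated;
        booleans are true/false.  Unknown keys raise."""
        cfg = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (x.strip() for x in line.split("=", 1))
            if key in cls._SIMPLE:
                setattr(cfg, key, cls._SIMPLE[key](val))
            elif key in ("reads", "sam"):
                setattr(cfg, key, tuple(v.strip() for v in val.split(",") if v.strip()))
            elif key == "per_junction_depth":
                cfg.per_junction_depth = tuple(int(v) for v in val.split(","))
            elif key in ("strict_hbhbh", "allow_wobble"):
                cfg.__setattr__(key, val.lower() in ("1", "true", "yes"))
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg

    @property
    def motif(self) -> MotifParams:
        return MotifParams(
            helix_len=self.helix_len,
            bulge_len=self.bulge_len,
            h_len=self.h_len,
            hprime_len=self.hprime_len,
            allow_wobble=self.allow_wobble,
        )

    def config_hash(self) -> str:
        d = asdict(self)
        d["loci"] = [
            (l.locus_id, l.kind, l.exon5_len, l.intron_len, l.exon3_len,
             None if l.motif is None else asdict(l.motif))
            for l in self.loci
        ]
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _setup_logging(cfg: PipelineConfig, outdir: Path) -> None:
    logger.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    for h in list(logger.handlers):
        logger.removeHandler(h)
        h.close()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(fmt)
    logger.addHandler(fh)
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)


def _provenance(cfg: PipelineConfig) -> dict:
    return {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
    }


def run_simulation(config: PipelineConfig) -> dict:
    """Generate the fixture bundle: genome, truth, per-replicate FASTQ.

    Returns a manifest with paths and sha256 checksums (deterministic for a
    fixed seed and config)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, outdir)
    genome, truth, gff = build_genome(config.loci, config.background_len, config.seed)
    sim = ReadSimConfig(
        n_replicates=config.n_replicates,
        read_len=config.read_len,
        per_junction_depth=config.per_junction_depth,
        linear_background_depth=config.linear_background_depth,
        error_rate=config.error_rate,
        circular_enrichment=config.circular_enrichment,
        seed=config.seed,
    )
    files = {"genome": outdir / "genome.fasta", "truth_gff3": outdir / "truth.gff3",
             "truth_tsv": outdir / "truth.tsv"}
    write_fasta(files["genome"], "synth1", genome)
    write_truth_gff3(files["truth_gff3"], gff)
    write_truth_tsv(files["truth_tsv"], truth)
    if config.loci:
        reads, provenance = simulate_reads(genome, truth, sim)
        for rep, rr in reads.items():
            p = outdir / f"reads_rep{rep}.fastq"
            write_fastq(p, rr)
            files[f"reads_rep{rep}"] = p
        prov_path = outdir / "read_provenance.tsv"
        provenance.to_csv(prov_path, sep="\t", index=False)
        files["read_provenance"] = prov_path
    manifest = {
        "files": {k: str(v) for k, v in files.items()},
        "checksums": {k: file_sha256(v) for k, v in files.items()},
        "n_loci": len(config.loci),
        "n_truth_junctions": len(truth),
        **_provenance(config),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("simulated %d loci into %s", len(config.loci), outdir)
    return manifest


def run_discovery(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Run junction calling and motif detection, write the substrate report.

    Report columns mirror the circRNA result table (left site, right site,
    intron length, folding energy) plus topology, coverage and verdict; the
    summary counts observations at each stage, split by topology.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, outdir)
    genome = str(next(SeqIO.parse(config.genome, "fasta")).seq).upper()

    observations = []
    if config.sam:
        for rep, path in enumerate(config.sam, start=1):
            observations.extend(observations_from_sam(path, replicate_id=rep))
    elif config.reads:
        for rep, path in enumerate(config.reads, start=1):
            recs = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fastq")]
            alns = map_split_reads(recs, genome, min_seed=config.min_seed)
            observations.extend(call_junctions(alns, replicate_id=rep))
    else:
        raise ValueError("config must provide reads or sam inputs")
    logger.info("junction observations: %d", len(observations))

    filtered = filter_junctions(
        observations,
        min_coverage=config.min_coverage,
        n_replicates=config.n_replicates,
    )
    logger.info("junctions after coverage/replicate filter: %d", len(filtered))
    clusters = merge_junctions(filtered, max_dist=config.merge_dist)
    logger.info("junction clusters after %d-nt merge: %d", config.merge_dist, len(clusters))

    if not clusters:
        logger.warning("no junctions survived filtering; writing empty report")
    report = detect(
        genome,
        clusters,
        motif=config.motif,
        flank_len=config.flank_len,
        strict_hbhbh=config.strict_hbhbh,
        engine=config.energy_engine,
    )
    n_candidates = int((report["verdict"] == "SE-substrate-candidate").sum()) if len(report) else 0

    (outdir / "junctions.bed").write_text("\n".join(clusters_to_bed(clusters)) + "\n")
    clusters_to_frame(clusters).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    report.to_csv(outdir / "substrates.tsv", sep="\t", index=False)
    _write_substrates_gff3(outdir / "substrates.gff3", genome, report)

    by_topo = lambda df, topo: int((df["topology"] == topo).sum()) if len(df) else 0
    summary = {
        "n_observations": len(observations),
        "n_filtered_junctions": len(filtered),
        "n_clusters": len(clusters),
        "n_candidates": n_candidates,
        "clusters_linear": sum(c.topology == "linear" for c in clusters),
        "clusters_circular": sum(c.topology == "circular" for c in clusters),
        "candidates_circular": by_topo(
            report[report["verdict"] == "SE-substrate-candidate"], "circular"
        ) if len(report) else 0,
        **_provenance(config),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("substrate candidates: %d / %d clusters", n_candidates, len(clusters))
    return report, summary


def _write_substrates_gff3(path, genome: str, report: pd.DataFrame) -> None:
    lines = ["##gff-version 3"]
    for k, row in report.iterrows():
        if row["verdict"] != "SE-substrate-candidate":
            continue
        s, e = row["left_site"] + 1, row["right_site"]
        attrs = (
            f"ID=substrate{k};topology={row['topology']};"
            f"energy={row['energy']};layout={row['layout']}"
        )
        lines.append(f"synth1\tbhbscan\tBHB_substrate\t{s}\t{e}\t.\t+\t.\t{attrs}")
    Path(path).write_text("\n".join(lines) + "\n")
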