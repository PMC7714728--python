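"""Synthetic genomes with planted BHB-flanked introns and circRNA-seq reads.

The generator emulates what the circular-RNA sequencing experiment sees in an
intron-bearing archaeal genome: loci (tRNA-like, rRNA-like, mRNA-5'UTR-like)
whose intron is flanked by a designed hBHBh' motif, excised by the splicing
endonuclease and circularized by the ligase.  Reads sampled across the
circular intron's ligation point ("back-junction reads") map back to the
genome as two segments in reversed order, which is the signal the junction
caller detects.  Every planted locus is recorded in a :class:`TruthSet` that
downstream recovery tests use as their oracle.

Background sequence is i.i.d. uniform over ACGT -- the simplest null that
rarely forms long helices by chance.  All randomness flows through one seeded
generator, so identical seeds give byte-identical FASTQ output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .bhb_detector import MotifParams

__all__ = [
    "LocusSpec",
    "ReadSimConfig",
    "TruthLocus",
    "TruthSet",
    "Read",
    "build_genome",
    "simulate_reads",
    "demo_locus_set",
    "write_fasta",
    "write_fastq",
    "write_truth_gff3",
    "write_truth_tsv",
]

BASES = np.array(list("ACGT"))
WC_DNA = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class LocusSpec:
    """One locus to plant: exon5 -- intron -- exon3.

    ``motif=None`` plants a decoy: a junction-producing intron with no
    designed BHB around its splice sites.
    """

    locus_id: str
    kind: str  # tRNA | rRNA | mRNA_5UTR
    exon5_len: int
    intron_len: int
    exon3_len: int
    motif: MotifParams | None = dc_field(default_factory=MotifParams)

    def __post_init__(self) -> None:
        if self.kind not in ("tRNA", "rRNA", "mRNA_5UTR"):
            raise ValueError(f"unknown locus kind {self.kind!r}")
        if self.intron_len < 16:
            raise ValueError("intron_len must be >= 16")
        if self.exon5_len < 1 or self.exon3_len < 1:
            raise ValueError("exon lengths must be positive")

    @property
    def total_len(self) -> int:
        return self.exon5_len + self.intron_len + self.exon3_len


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation parameters.

    per_junction_depth
        Back-junction reads emitted per circular intron in each replicate
        (before the ``circular_enrichment`` multiplier).
    linear_background_depth
        Mean genome-wide coverage of plain (unspliced) reads per replicate.
    circular_enrichment
        Sampling-weight multiplier on circular templates, emulating
        RNase-R-style depletion of linear RNA.
    min_overhang
        Minimum bases a back-junction read keeps on each side of the
        ligation point (must allow split mapping).
    """

    n_replicates: int = 3
    read_len: int = 75
    per_junction_depth: tuple[int, ...] = (10, 10, 10)
    linear_background_depth: float = 1.0
    error_rate: float = 0.0
    circular_enrichment: float = 1.0
    seed: int = 0
    min_overhang: int = 15
    quality_char: str = "I"

    def __post_init__(self) -> None:
        if self.read_len < 20:
            raise ValueError("read_len must be >= 20")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must be in [0, 0.1]")
        if len(self.per_junction_depth) != self.n_replicates:
            raise ValueError("per_junction_depth needs one entry per replicate")
        if any(x < 0 for x in self.per_junction_depth):
            raise ValueError("depths must be >= 0")
        if self.circular_enrichment < 1.0:
            raise ValueError("circular_enrichment must be >= 1")
        if self.min_overhang * 2 > self.read_len:
            raise ValueError("read_len too short for the requested overhang")


@dataclass(frozen=True)
class TruthLocus:
    """Ground truth for one planted locus (1-based genomic coordinates)."""

    locus_id: str
    kind: str
    intron_start: int
    intron_end: int
    left_site: int
    right_site: int
    topology: str
    strand: str
    has_motif: bool

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start + 1


@dataclass
class TruthSet:
    loci: list[TruthLocus]
    genome_len: int
    seed: int

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def junctions(self) -> list[tuple[int, int]]:
        return [(t.left_site, t.right_site) for t in self.loci]


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    quality: str


def _rand_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(BASES[rng.integers(0, 4, size=n)])


def _draw_not(rng: np.random.Generator, forbidden: str, pool: str = "AC") -> str:
    choices = [b for b in pool if b != forbidden]
    return choices[rng.integers(0, len(choices))]


def _plant_motif(
    g: list[str], s0: int, e0: int, motif: MotifParams, rng: np.random.Generator
) -> None:
    """Overwrite bases around intron [s0, e0] (0-based incl.) with an hBHBh'.

    Layout (genomic coordinates, B = bulge_len, H = helix_len):
      upstream bulge   : exon5[-(B-2):] + intron[:2]        (unpaired)
      central helix    : intron[2 : 2+H]  x  exon3[2 : 2+H]
      outer helix h    : exon5 side       x  exon3 side
      outer helix h'   : intron[2+H : 2+H+hp] x intron 3' end
      downstream bulge : intron[-1:] + exon3[:2]            (unpaired)
    With the default cut rule (between bulge nts 2 and 3 counted from the
    central-helix-proximal side) both cuts land exactly on the exon|intron
    bonds, so cleavage excises precisely [s0, e0].
    """
    H, B = motif.helix_len, motif.bulge_len
    hl, hp = motif.h_len, motif.hprime_len
    n = len(g)
    # Feasibility: upstream exon needs (B-2)+hl bases, intron needs
    # (2+H+hp) at its 5' end plus (B-2)+hp... at its 3' end, downstream
    # exon needs 2+H+hl bases.
    need_intron = (2 + H + hp) + (hp + (B - 2) + 1)
    if e0 - s0 + 1 < need_intron:
        raise ValueError("intron too short to accommodate the motif layout")
    if s0 - ((B - 2) + hl) < 0 or e0 + 2 + H + hl >= n:
        raise ValueError("exon flanks too short to accommodate the motif layout")

    def put_pair(a: int, b: int) -> None:
        base = "ACGT"[rng.integers(0, 4)]
        g[a] = base
        g[b] = WC_DNA[base]

    # central helix: intron 5' x exon3
    for k in range(H):
        put_pair(s0 + 2 + k, e0 + 2 + H - k)
    # outer helix h: exon5 x exon3
    for t in range(hl):
        put_pair(s0 - (B - 2) - 1 - t, e0 + 3 + H + t)
    # outer helix h': intron 5' x intron 3'
    for t in range(hp):
        put_pair(s0 + 2 + H + t, e0 - (B - 2) - t)
    # bulges: drawn from {A, C} so the two bulges cannot pair with each
    # other, then adjusted so that exact prefix/suffix mapping across the
    # ligation point cannot extend past the true junction.
    bulge_positions = (
        [s0 - t for t in range(1, B - 1)] + [s0, s0 + 1]
        + [e0 - t for t in range(B - 2)] + [e0 + 1, e0 + 2]
    )
    for p in bulge_positions:
        g[p] = "AC"[rng.integers(0, 2)]
    # Force the bulges: one nucleotide per bulge must not pair with the base
    # it would face if the bulge zipped onto the central-helix diagonal
    # (A pairs only T/U, C pairs only G, so a choice always exists).
    def unpairable_with(partner: str) -> str:
        if partner == "T":
            return "C"
        if partner == "G":
            return "A"
        return "AC"[rng.integers(0, 2)]

    if s0 + 4 + H < n:
        g[e0] = unpairable_with(g[s0 + 4 + H])
    if e0 + 4 + H < n:
        g[s0] = unpairable_with(g[e0 + 4 + H])
    g[e0 + 1] = _draw_not(rng, g[s0])          # +1 shift guard
    g[e0 + 2] = _draw_not(rng, g[s0 + 1])      # +2 shift guard
    g[s0 - 1] = _draw_not(rng, g[e0])          # -1 shift guard


def build_genome(
    loci: list[LocusSpec], background_len: int, seed: int
) -> tuple[str, TruthSet, list[str]]:
    """Generate a genome with the given loci planted at evenly spaced sites.

    Returns the genome sequence (DNA, single chromosome named ``synth1``),
    the :class:`TruthSet` of planted introns/junctions, and GFF3 annotation
    lines.  Loci are laid out left to right in input order; raises if they
    cannot be placed without overlap.
    """
    ids = [l.locus_id for l in loci]
    if len(set(ids)) != len(ids):
        raise ValueError("locus_id values must be unique")
    rng = np.random.default_rng(seed)
    g = _rand_seq(rng, background_len)
    total = sum(l.total_len for l in loci)
    n = len(loci)
    spacer = (background_len - total) // (n + 1) if n else background_len
    if n and spacer < 1:
        raise ValueError("planted loci overlap: background_len too small")

    truth_loci: list[TruthLocus] = []
    gff: list[str] = ["##gff-version 3", f"##sequence-region synth1 1 {background_len}"]
    pos = spacer  # 0-based start of next locus block
    for spec in loci:
        s0 = pos + spec.exon5_len            # 0-based intron start
        e0 = s0 + spec.intron_len - 1        # 0-based intron end
        for p in range(pos, pos + spec.total_len):
            g[p] = "ACGT"[rng.integers(0, 4)]
        if spec.motif is not None:
            m = spec.motif
            if spec.exon5_len < (m.bulge_len - 2) + m.h_len or spec.exon3_len < (
                2 + m.helix_len + m.h_len
            ):
                raise ValueError(f"{spec.locus_id}: exons too short for the motif")
            _plant_motif(g, s0, e0, spec.motif, rng)
        else:
            # Decoy junction: keep it split-mappable without ambiguity.
            g[e0 + 1] = _draw_not(rng, g[s0], pool="ACGT")
            g[e0 + 2] = _draw_not(rng, g[s0 + 1], pool="ACGT")
            g[s0 - 1] = _draw_not(rng, g[e0], pool="ACGT")
        s, e = s0 + 1, e0 + 1  # 1-based
        truth_loci.append(
            TruthLocus(
                locus_id=spec.locus_id,
                kind=spec.kind,
                intron_start=s,
                intron_end=e,
                left_site=s - 1,
                right_site=e,
                topology="circular",
                strand="+",
                has_motif=spec.motif is not None,
            )
        )
        attrs = f"ID={spec.locus_id};kind={spec.kind}"
        gff.append(
            f"synth1\tbhbscan\tgene\t{pos + 1}\t{pos + spec.total_len}\t.\t+\t.\t{attrs}"
        )
        gff.append(
            f"synth1\tbhbscan\texon\t{pos + 1}\t{s - 1}\t.\t+\t.\t"
            f"ID={spec.locus_id}.exon5;Parent={spec.locus_id}"
        )
        gff.append(
            f"synth1\tbhbscan\tintron\t{s}\t{e}\t.\t+\t.\t"
            f"ID={spec.locus_id}.intron;Parent={spec.locus_id}"
        )
        gff.append(
            f"synth1\tbhbscan\texon\t{e + 1}\t{pos + spec.total_len}\t.\t+\t.\t"
            f"ID={spec.locus_id}.exon3;Parent={spec.locus_id}"
        )
        gff.append(
            f"synth1\tbhbscan\tsplice_junction\t{s - 1}\t{e}\t.\t+\t.\t"
            f"ID={spec.locus_id}.junction;Parent={spec.locus_id};topology=circular"
        )
        pos += spec.total_len + spacer

    return "".join(g), TruthSet(truth_loci, background_len, seed), gff


def simulate_reads(
    genome: str, truth: TruthSet, config: ReadSimConfig
) -> tuple[dict[int, list[Read]], pd.DataFrame]:
    """Simulate per-replicate circRNA-seq read sets with known provenance.

    For every circular intron in ``truth``, each replicate receives
    ``per_junction_depth[r] * circular_enrichment`` back-junction reads whose
    sequence crosses the intron-3'-end -> intron-5'-start ligation point with
    at least ``min_overhang`` bases on both sides.  Reads from a circular
    template are capped at the circle's circumference (fragmentation-limited
    insert).  Linear background reads are sampled uniformly from the genome.
    Sequencing errors are i.i.d. substitutions at ``error_rate``.

    Returns ``{replicate_id: [Read, ...]}`` (replicates numbered from 1) and
    a provenance table mapping each read to its template and junction.
    """
    rng = np.random.default_rng(config.seed)
    if config.read_len > len(genome):
        raise ValueError("read_len exceeds genome length")
    reads: dict[int, list[Read]] = {}
    prov_rows = []

    def apply_errors(seq: str) -> str:
        if config.error_rate == 0:
            return seq
        arr = list(seq)
        hits = np.nonzero(rng.random(len(arr)) < config.error_rate)[0]
        for k in hits:
            arr[k] = _draw_not(rng, arr[k], pool="ACGT")
        return "".join(arr)

    for rep in range(1, config.n_replicates + 1):
        out: list[Read] = []
        depth = int(round(config.per_junction_depth[rep - 1] * config.circular_enrichment))
        for t in truth:
            if t.topology != "circular":
                continue
            circle = genome[t.intron_start - 1 : t.intron_end]
            circ_len = len(circle)
            rl = min(config.read_len, circ_len)
            if rl < 2 * config.min_overhang:
                raise ValueError(
                    f"circular template {t.locus_id} too short for min_overhang"
                )
            for i in range(depth):
                # k bases 5'-of-junction (from the intron 3' end), the rest
                # from the intron 5' start.
                k = int(rng.integers(config.min_overhang, rl - config.min_overhang + 1))
                seq = circle[circ_len - k :] + circle[: rl - k]
                seq = apply_errors(seq)
                rid = f"rep{rep}.bj.{t.locus_id}.{i}"
                out.append(Read(rid, seq, config.quality_char * len(seq)))
                prov_rows.append(
                    {
                        "read_id": rid,
                        "replicate": rep,
                        "template": "circular_intron",
                        "locus_id": t.locus_id,
                        "left_site": t.left_site,
                        "right_site": t.right_site,
                        "junction_spanning": True,
                    }
                )
        n_bg = int(round(config.linear_background_depth * len(genome) / config.read_len))
        for i in range(n_bg):
            p = int(rng.integers(0, len(genome) - config.read_len + 1))
            seq = apply_errors(genome[p : p + config.read_len])
            rid = f"rep{rep}.bg.{i}"
            out.append(Read(rid, seq, config.quality_char * len(seq)))
            prov_rows.append(
                {
                    "read_id": rid,
                    "replicate": rep,
                    "template": "linear_genome",
                    "locus_id": "",
                    "left_site": 0,
                    "right_site": 0,
                    "junction_spanning": False,
                }
            )
        reads[rep] = out

    provenance = pd.DataFrame(
        prov_rows,
        columns=[
            "read_id", "replicate", "template", "locus_id",
            "left_site", "right_site", "junction_spanning",
        ],
    )
    provenance.attrs["seed"] = config.seed
    return reads, provenance


def demo_locus_set() -> list[LocusSpec]:
    """The stock demonstration locus set: three tRNA-like introns, two
    rRNA-like processing stems and one mRNA 5'UTR intron, with intron
    lengths spanning the biologically observed range (31-2979 nt)."""
    return [
        LocusSpec("tRNA-Trp", "tRNA", 30, 103, 30),
        LocusSpec("tRNA-Met", "tRNA", 30, 75, 30),
        LocusSpec("tRNA-Gln", "tRNA", 30, 31, 30),
        LocusSpec("rRNA-16S", "rRNA", 40, 1658, 40),
        LocusSpec("rRNA-23S", "rRNA", 40, 2979, 40),
        LocusSpec("UTR-1309", "mRNA_5UTR", 30, 46, 30),
    ]


# ---------------------------------------------------------------------------
# plain-text writers


def write_fasta(path, name: str, seq: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for k in range(0, len(seq), width):
            fh.write(seq[k : k + width] + "\n")


def write_fastq(path, reads: list[Read]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_truth_gff3(path, gff_lines: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")


def write_truth_tsv(path, truth: TruthSet) -> None:
    df = pd.DataFrame(
        [
            {
                "locus_id": t.locus_id,
                "kind": t.kind,
                "intron_start": t.intron_start,
                "intron_end": t.intron_end,
                "left_site": t.left_site,
                "right_site": t.right_site,
                "intron_length": t.intron_length,
                "topology": t.topology,
                "strand": t.strand,
                "has_motif": t.has_motif,
            }
            for t in truth
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
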