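"""Splice-junction detection from split alignments.

A pair of splice sites (left, right) describes the location of an intron:
the intron occupies [left+1, right] (1-based inclusive), so its length is
right - left.  Reads split into two genomic segments report a junction; the
segment order distinguishes topology:

linear
    segments in genomic order (5' segment upstream): an ordinary spliced or
    exon-ligation read skipping the intron.
circular
    segments in reversed genomic order: a back-junction read across the
    ligation point of a circularized intron.

Junctions are filtered by per-replicate coverage, then merged by
single-linkage clustering with a Chebyshev distance cutoff on the two
coordinates (sites differing by a few bases in either endpoint collapse to
one cluster whose representative is the highest-coverage member).

Split alignments come either from the internal exact split mapper
(:func:`map_split_reads`, intended for synthetic data) or from a SAM file
with supplementary alignments and/or 'N' CIGAR operations
(:func:`observations_from_sam`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .bhb_detector import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "SplitAlignment",
    "JunctionObservation",
    "FilteredJunction",
    "JunctionCluster",
    "IntronRecord",
    "map_split_reads",
    "call_junctions",
    "observations_from_sam",
    "filter_junctions",
    "merge_junctions",
    "intron_from_cluster",
    "clusters_to_bed",
    "clusters_to_frame",
]


@dataclass(frozen=True)
class Segment:
    """One aligned piece of a read; reference coordinates 1-based inclusive,
    query coordinates 0-based half-open in original read orientation."""

    ref_start: int
    ref_end: int
    strand: str
    query_start: int
    query_end: int


@dataclass
class SplitAlignment:
    read_id: str
    status: str  # unsplit | split | unmapped
    segments: list[Segment]


@dataclass(frozen=True)
class JunctionObservation:
    left_site: int
    right_site: int
    replicate_id: int
    topology: str  # linear | circular
    read_id: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.left_site >= self.right_site:
            raise ValueError("left_site must be < right_site")


@dataclass(frozen=True)
class FilteredJunction:
    left_site: int
    right_site: int
    topology: str
    strand: str
    coverage_per_replicate: tuple[int, ...]

    @property
    def total_coverage(self) -> int:
        return sum(self.coverage_per_replicate)


@dataclass
class JunctionCluster:
    representative_left: int
    representative_right: int
    members: list[tuple[int, int]]
    coverage_per_replicate: tuple[int, ...]
    topology: str
    strand: str = "+"

    @property
    def intron_length(self) -> int:
        return self.representative_right - self.representative_left


@dataclass(frozen=True)
class IntronRecord:
    start: int  # 1-based inclusive
    end: int
    length: int
    topology: str


# ---------------------------------------------------------------------------
# internal split mapper


def _longest_prefix_in(genome: str, read: str) -> int:
    """Longest p such that read[:p] occurs in genome (p is monotone)."""
    lo, hi = 0, len(read)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if genome.find(read[:mid]) >= 0:
            lo = mid
        else:
            hi = mid - 1
    return lo


def _try_split(genome: str, read: str, min_seed: int) -> tuple[int, int, int] | None:
    """Find an exact two-segment decomposition (split point, pos1, pos2).

    Prefers the maximal-prefix split, falling back to the maximal-suffix
    split; both segments must be at least ``min_seed`` long."""
    L = len(read)
    p = _longest_prefix_in(genome, read)
    if min_seed <= p < L and L - p >= min_seed:
        pos2 = genome.find(read[p:])
        if pos2 >= 0:
            return p, genome.find(read[:p]), pos2
    rev_best = _longest_prefix_in(genome[::-1], read[::-1])
    p = L - rev_best
    if min_seed <= p < L and L - p >= min_seed and p != _longest_prefix_in(genome, read):
        if genome.find(read[:p]) >= 0:
            pos2 = genome.find(read[p:])
            if pos2 >= 0:
                return p, genome.find(read[:p]), pos2
    return None


def map_split_reads(reads, genome: str, min_seed: int = 12) -> list[SplitAlignment]:
    """Exact split mapper for synthetic reads.

    Each read is reported as a single contiguous match, an exact two-segment
    split (both segments >= ``min_seed``), or unmapped; both strands are
    tried.  ``reads`` is an iterable of (read_id, sequence) pairs or objects
    with ``read_id``/``sequence`` attributes.  Deterministic for fixed input.
    """
    if not genome:
        raise ValueError("empty genome")
    if min_seed < 12:
        raise ValueError("min_seed must be >= 12")
    out: list[SplitAlignment] = []
    for item in reads:
        if isinstance(item, tuple):
            rid, seq = item
        else:
            rid, seq = item.read_id, item.sequence
        L = len(seq)
        aln = None
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            pos = genome.find(s)
            if pos >= 0:
                aln = SplitAlignment(
                    rid, "unsplit", [Segment(pos + 1, pos + L, strand, 0, L)]
                )
                break
            hit = _try_split(genome, s, min_seed)
            if hit is not None:
                p, pos1, pos2 = hit
                segs = [
                    Segment(pos1 + 1, pos1 + p, strand, 0, p),
                    Segment(pos2 + 1, pos2 + L - p, strand, p, L),
                ]
                if strand == "-":
                    # report in original read order
                    segs = [
                        Segment(pos2 + 1, pos2 + L - p, "-", 0, L - p),
                        Segment(pos1 + 1, pos1 + p, "-", L - p, L),
                    ]
                aln = SplitAlignment(rid, "split", segs)
                break
        out.append(aln if aln is not None else SplitAlignment(rid, "unmapped", []))
    return out


# ---------------------------------------------------------------------------
# junction calling


def _junction_from_segments(
    s1: Segment, s2: Segment
) -> tuple[int, int, str] | None:
    """Classify a two-segment alignment given segments in genome-forward
    read order.  Returns (left, right, topology) or None."""
    if s1.ref_end < s2.ref_start:
        return s1.ref_end, s2.ref_start - 1, "linear"
    if s2.ref_start <= s1.ref_start and s2.ref_end < s1.ref_end:
        return s2.ref_start - 1, s1.ref_end, "circular"
    return None


def call_junctions(
    alignments: list[SplitAlignment], replicate_id: int = 1
) -> list[JunctionObservation]:
    """Turn split alignments into junction observations.

    Alignments with more than two segments are skipped with a warning (the
    count is logged); unsplit or unmapped reads contribute nothing.  Both
    strands are handled symmetrically by normalising '-' alignments to
    genome-forward segment order before classification.
    """
    obs: list[JunctionObservation] = []
    skipped = 0
    for aln in alignments:
        if aln.status != "split":
            continue
        if len(aln.segments) != 2:
            skipped += 1
            continue
        segs = list(aln.segments)
        strand = segs[0].strand
        if strand == "-":
            segs = segs[::-1]
        hit = _junction_from_segments(*segs)
        if hit is None:
            skipped += 1
            continue
        left, right, topology = hit
        obs.append(
            JunctionObservation(left, right, replicate_id, topology, aln.read_id, strand)
        )
    if skipped:
        logger.warning("skipped %d alignments without a clean 2-segment split", skipped)
    return obs


def observations_from_sam(path, replicate_id: int = 1) -> list[JunctionObservation]:
    """Extract junction observations from a SAM/BAM file.

    Supplementary alignments (chimeric reads) are grouped by query name and
    ordered by their offset in the original read; 'N' CIGAR operations in a
    single alignment are reported directly as linear junctions.
    """
    import pysam

    obs: list[JunctionObservation] = []
    by_name: dict[str, list] = {}
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            # spliced alignment: each N gap is a linear junction
            ref = rec.reference_start + 1
            for op, ln in rec.cigartuples or []:
                if op in (0, 7, 8, 2):  # M/=/X/D consume reference
                    ref += ln
                elif op == 3:  # N
                    obs.append(
                        JunctionObservation(
                            ref - 1,
                            ref + ln - 1,
                            replicate_id,
                            "linear",
                            rec.query_name,
                            "-" if rec.is_reverse else "+",
                        )
                    )
                    ref += ln
            if rec.has_tag("SA") or rec.is_supplementary:
                by_name.setdefault(rec.query_name, []).append(rec)
    for name, recs in by_name.items():
        if len(recs) != 2:
            skipped += 1
            continue
        segs = []
        for rec in recs:
            cig = rec.cigartuples or []
            clip5 = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            clip3 = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
            qlen = rec.infer_read_length() or (
                clip5 + rec.query_alignment_length + clip3
            )
            qstart = clip5 if not rec.is_reverse else qlen - clip5 - rec.query_alignment_length
            segs.append(
                Segment(
                    rec.reference_start + 1,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    qstart,
                    qstart + rec.query_alignment_length,
                )
            )
        segs.sort(key=lambda s: s.query_start)
        strand = segs[0].strand
        if any(s.strand != strand for s in segs):
            skipped += 1
            continue
        ordered = segs if strand == "+" else segs[::-1]
        hit = _junction_from_segments(*ordered)
        if hit is None:
            skipped += 1
            continue
        left, right, topology = hit
        obs.append(JunctionObservation(left, right, replicate_id, topology, name, strand))
    if skipped:
        logger.warning("skipped %d chimeric reads without a clean 2-segment split", skipped)
    return obs


# ---------------------------------------------------------------------------
# filtering and merging


def filter_junctions(
    observations: list[JunctionObservation],
    min_coverage: int = 2,
    n_replicates: int = 3,
    require_per_replicate: bool = True,
) -> list[FilteredJunction]:
    """Keep junctions supported in all replicates.

    Default (strict) reading: per-replicate coverage >= ``min_coverage`` in
    every one of ``n_replicates`` replicates.  With
    ``require_per_replicate=False`` the laxer reading applies: present
    (>= 1) in every replicate and total coverage >= ``min_coverage``.
    Output is sorted by coordinates.
    """
    if not observations:
        return []
    reps_present = {o.replicate_id for o in observations}
    if n_replicates > len(reps_present):
        raise ValueError(
            f"n_replicates={n_replicates} but only {len(reps_present)} replicates present"
        )
    counts: dict[tuple, list[int]] = {}
    for o in observations:
        if not (1 <= o.replicate_id <= n_replicates):
            continue
        key = (o.left_site, o.right_site, o.topology, o.strand)
        counts.setdefault(key, [0] * n_replicates)[o.replicate_id - 1] += 1
    kept = []
    for (left, right, topo, strand), cov in counts.items():
        if require_per_replicate:
            ok = all(c >= min_coverage for c in cov)
        else:
            ok = all(c >= 1 for c in cov) and sum(cov) >= min_coverage
        if ok:
            kept.append(FilteredJunction(left, right, topo, strand, tuple(cov)))
    kept.sort(key=lambda j: (j.left_site, j.right_site, j.topology))
    return kept


def merge_junctions(
    junctions: list[FilteredJunction], max_dist: int = 10
) -> list[JunctionCluster]:
    """Single-linkage merge of nearby junctions.

    Two junctions link iff their topologies and strands match and both
    |delta left| <= max_dist and |delta right| <= max_dist.  The cluster
    representative is the member with the highest total coverage (ties:
    smaller left, then smaller right); per-replicate coverages are summed
    over members.
    """
    n = len(junctions)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            ja, jb = junctions[a], junctions[b]
            if ja.topology != jb.topology or ja.strand != jb.strand:
                continue
            if (
                abs(ja.left_site - jb.left_site) <= max_dist
                and abs(ja.right_site - jb.right_site) <= max_dist
            ):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    groups: dict[int, list[FilteredJunction]] = {}
    for a in range(n):
        groups.setdefault(find(a), []).append(junctions[a])
    clusters = []
    for members in groups.values():
        rep = min(
            members,
            key=lambda j: (-j.total_coverage, j.left_site, j.right_site),
        )
        n_reps = len(members[0].coverage_per_replicate)
        cov = tuple(
            sum(m.coverage_per_replicate[r] for m in members) for r in range(n_reps)
        )
        clusters.append(
            JunctionCluster(
                representative_left=rep.left_site,
                representative_right=rep.right_site,
                members=[(m.left_site, m.right_site) for m in members],
                coverage_per_replicate=cov,
                topology=rep.topology,
                strand=rep.strand,
            )
        )
    clusters.sort(key=lambda c: (c.representative_left, c.representative_right))
    return clusters


def intron_from_cluster(cluster: JunctionCluster) -> IntronRecord:
    """Intron interval implied by a cluster's representative sites: the
    intron occupies [left+1, right], length = right - left."""
    length = cluster.representative_right - cluster.representative_left
    if length <= 0:
        raise ValueError("non-positive intron length")
    return IntronRecord(
        start=cluster.representative_left + 1,
        end=cluster.representative_right,
        length=length,
        topology=cluster.topology,
    )


def clusters_to_bed(clusters: list[JunctionCluster], chrom: str = "synth1") -> list[str]:
    """BED6 lines for cluster representatives (0-based half-open intron
    intervals; name = topology, score = total coverage capped at 1000)."""
    lines = []
    for c in clusters:
        score = min(1000, sum(c.coverage_per_replicate))
        lines.append(
            f"{chrom}\t{c.representative_left}\t{c.representative_right}\t"
            f"{c.topology}\t{score}\t{c.strand}"
        )
    return lines


def clusters_to_frame(clusters: list[JunctionCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "representative_left": c.representative_left,
                "representative_right": c.representative_right,
                "intron_length": c.intron_length,
                "topology": c.topology,
                "strand": c.strand,
                "n_members": len(c.members),
                "coverage_per_replicate": ",".join(map(str, c.coverage_per_replicate)),
                "coverage_total": sum(c.coverage_per_replicate),
            }
            for c in clusters
        ],
        columns=[
            "representative_left", "representative_right", "intron_length",
            "topology", "strand", "n_members", "coverage_per_replicate",
            "coverage_total",
        ],
    )
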