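"""Bulge-helix-bulge (hBHBh') motif detection on glued splice-site contexts.

The archaeal splicing endonuclease recognises a structural element formed
between the two strands of the stem that presents an intron: a 4-bp central
helix flanked by two 3-nt bulges on opposite strands, each bulge bounded
distally by an outer helix (h and h').  The two cleavage sites sit inside the
bulges.  Because the motif is structural rather than sequence-based, detection
is done with an explicit layout grammar: the exon flanks around the two splice
sites are glued together with the bulk of the intron treated as an insert, and
every placement of the helix/bulge layout with complementary (Watson-Crick,
optionally G:U) inter-arm pairs is enumerated.

Coordinate conventions
----------------------
Genomic coordinates are 1-based inclusive.  A splice-site pair (left, right)
delimits an intron occupying [left+1, right], so intron length = right - left.
Within a :class:`GluedContext`, arm positions are 0-based and a splice site is
the phosphodiester bond *after* the recorded index.

Energies
--------
The internal engine sums nearest-neighbor stacking free energies (Turner 2004
parameters at 37 degC, Watson-Crick and G:U steps) over consecutive pairs
within each helix.  No loop or terminal terms are included: the score is a
relative stability measure (more negative = more stable), not a full minimum
free energy.  The external engine delegates the two arms to RNAcofold.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MotifParams",
    "GluedContext",
    "BHBMatch",
    "extract_context",
    "match_bhb",
    "check_splice_in_bulge",
    "score_energy",
    "duplex_stacking_energy",
    "parse_layout",
    "detect",
]

RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
DNA_TO_RNA = str.maketrans("ACGTacgt", "ACGUACGU")
DNA_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")

WC_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

# Nearest-neighbor stack free energies, kcal/mol at 37 degC (Turner 2004 set,
# as tabulated by ViennaRNA).  Key "XY/WZ" is the step with pair X:Y stacked
# 5'-side of pair W:Z, both read along the same strand.
STACK_DG37 = {
    "AU/AU": -0.9, "AU/UA": -1.1, "AU/CG": -2.2, "AU/GC": -2.1,
    "AU/GU": -0.6, "AU/UG": -1.4,
    "UA/AU": -1.3, "UA/UA": -0.9, "UA/CG": -2.4, "UA/GC": -2.1,
    "UA/GU": -1.0, "UA/UG": -1.3,
    "CG/AU": -2.1, "CG/UA": -2.1, "CG/CG": -3.3, "CG/GC": -2.4,
    "CG/GU": -1.4, "CG/UG": -2.1,
    "GC/AU": -2.4, "GC/UA": -2.2, "GC/CG": -3.4, "GC/GC": -3.3,
    "GC/GU": -1.5, "GC/UG": -2.5,
    "GU/AU": -1.3, "GU/UA": -1.4, "GU/CG": -2.5, "GU/GC": -2.1,
    "GU/GU": -0.5, "GU/UG": 1.3,
    "UG/AU": -1.0, "UG/UA": -0.6, "UG/CG": -1.5, "UG/GC": -1.4,
    "UG/GU": 0.3, "UG/UG": -0.5,
}


def _is_pair(x: str, y: str, allow_wobble: bool) -> bool:
    p = (x, y)
    return p in WC_PAIRS or (allow_wobble and p in WOBBLE_PAIRS)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence."""
    return seq.translate(DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifParams:
    """Geometry of the hBHBh' layout.

    helix_len
        Central helix length in base pairs (4 in the canonical motif).
    bulge_len
        Length of each unpaired bulge in nucleotides (3 canonically).
    h_len, hprime_len
        Minimum length of the outer helices bounding the bulges distally.
        Only enforced in strict hBHBh' mode; the alpha2-type enzyme of
        Haloferax volcanii requires both.
    allow_wobble
        Accept G:U pairs in helices in addition to Watson-Crick pairs.
    """

    helix_len: int = 4
    bulge_len: int = 3
    h_len: int = 4
    hprime_len: int = 4
    allow_wobble: bool = True

    def __post_init__(self) -> None:
        if self.helix_len < 1:
            raise ValueError("helix_len must be >= 1")
        if self.bulge_len < 1:
            raise ValueError("bulge_len must be >= 1")
        if self.h_len < 0 or self.hprime_len < 0:
            raise ValueError("outer helix lengths must be >= 0")


@dataclass(frozen=True)
class GluedContext:
    """The two splice-site neighbourhoods glued with the intron as an insert.

    ``upstream_arm`` holds the 5' exon flank followed by the first bases of
    the intron; ``downstream_arm`` holds the last bases of the intron followed
    by the 3' exon flank.  The excised middle of the intron is not part of
    either arm.  ``splice_site_up``/``splice_site_down`` record each splice
    site as the bond after that 0-based arm index.  ``insert_marker`` gives
    (index in upstream arm where intronic sequence begins, index in downstream
    arm where it ends).
    """

    upstream_arm: str
    downstream_arm: str
    flank_len: int
    intron_head: int
    intron_tail: int
    splice_site_up: int
    splice_site_down: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.upstream_arm or not self.downstream_arm:
            raise ValueError("context arms must be non-empty")
        for arm in (self.upstream_arm, self.downstream_arm):
            if set(arm) - set("ACGU"):
                raise ValueError("arms must be RNA over {A,C,G,U}")
        if not (0 <= self.splice_site_up < len(self.upstream_arm)):
            raise ValueError("upstream splice site outside arm")
        if not (0 <= self.splice_site_down < len(self.downstream_arm)):
            raise ValueError("downstream splice site outside arm")

    @property
    def insert_marker(self) -> tuple[int, int]:
        return (self.flank_len, self.intron_tail - 1)

    @property
    def splice_site_positions(self) -> tuple[int, int]:
        return (self.splice_site_up, self.splice_site_down)


@dataclass
class BHBMatch:
    """One concrete hBHBh' layout on a glued context.

    Helices are lists of (upstream index, downstream index) pairs ordered
    along the upstream arm; bulges are 0-based inclusive intervals.  Outer
    helices are reported at their maximal contiguous extent.
    """

    central_helix: list[tuple[int, int]]
    bulge_up: tuple[int, int]
    bulge_down: tuple[int, int]
    outer_helix_h: list[tuple[int, int]]
    outer_helix_hprime: list[tuple[int, int]]
    splice_in_bulge: tuple[bool, bool] = (False, False)
    energy: float = 0.0
    layout_string: str = ""

    @property
    def substrate_consistent(self) -> bool:
        return self.splice_in_bulge[0] and self.splice_in_bulge[1]


def extract_context(
    genome: str,
    intron: tuple[int, int],
    flank_len: int = 25,
    strand: str = "+",
) -> GluedContext:
    """Extract the glued context around an intron's splice sites.

    ``intron`` is the 1-based inclusive genomic interval of the intron.  Each
    arm carries ``flank_len`` exonic nucleotides plus up to ``flank_len``
    intronic nucleotides; for introns shorter than twice the flank the
    intronic parts are truncated at the intron midpoint so they never overlap.
    For '-' strand introns the context is built on the reverse-complement
    transcript of the same genomic interval.
    """
    start, end = intron
    n = len(genome)
    if not (1 <= start <= end <= n):
        raise ValueError(f"intron interval {intron} outside genome of length {n}")
    if start - flank_len < 1 or end + flank_len > n:
        raise ValueError("insufficient flanking sequence at genome edge")
    length = end - start + 1
    head = min(flank_len, (length + 1) // 2)
    tail = min(flank_len, length - head)
    if strand == "+":
        up = genome[start - 1 - flank_len : start - 1 + head]
        down = genome[end - tail : end + flank_len]
    elif strand == "-":
        # The transcript runs right-to-left: its 5' exon flank is the genomic
        # sequence after `end`, reverse complemented.
        up = reverse_complement(genome[end : end + flank_len] )
        up += reverse_complement(genome[end - head : end])
        down = reverse_complement(genome[start - 1 : start - 1 + tail])
        down += reverse_complement(genome[start - 1 - flank_len : start - 1])
    else:
        raise ValueError(f"unknown strand {strand!r}")
    return GluedContext(
        upstream_arm=up.translate(DNA_TO_RNA),
        downstream_arm=down.translate(DNA_TO_RNA),
        flank_len=flank_len,
        intron_head=head,
        intron_tail=tail,
        splice_site_up=flank_len - 1,
        splice_site_down=tail - 1,
        strand=strand,
    )


def _maximal_run(
    u: str, d: str, iu: int, jd: int, du: int, dd: int, allow_wobble: bool
) -> int:
    """Length of the maximal contiguous paired run starting at (iu, jd),
    stepping du along the upstream and dd along the downstream arm."""
    run = 0
    while 0 <= iu < len(u) and 0 <= jd < len(d) and _is_pair(u[iu], d[jd], allow_wobble):
        run += 1
        iu += du
        jd += dd
    return run


def _build_layout_string(match: BHBMatch, context: GluedContext) -> str:
    u = ["."] * len(context.upstream_arm)
    d = ["."] * len(context.downstream_arm)
    for i, j in match.outer_helix_h + match.central_helix + match.outer_helix_hprime:
        u[i] = "("
        d[j] = ")"
    for k in range(match.bulge_up[0], match.bulge_up[1] + 1):
        u[k] = "b"
    for k in range(match.bulge_down[0], match.bulge_down[1] + 1):
        d[k] = "b"
    return "".join(u) + "&" + "".join(d)


def parse_layout(layout: str) -> dict:
    """Re-parse a layout string into helix/bulge intervals.

    Returns a dict with keys ``h``, ``central``, ``hprime`` (pair lists) and
    ``bulge_up``, ``bulge_down`` (inclusive intervals).  On the upstream arm
    the central helix and h' are contiguous (the downstream bulge interrupts
    only the downstream arm), and vice versa for h; the two arms together
    disambiguate the three helices.
    """
    u_str, d_str = layout.split("&")

    def runs(s: str, ch: str) -> list[tuple[int, int]]:
        out, start = [], None
        for k, c in enumerate(s + "\x00"):
            if c == ch and start is None:
                start = k
            elif c != ch and start is not None:
                out.append((start, k - 1))
                start = None
        return out

    u_runs = runs(u_str, "(")
    d_runs = runs(d_str, ")")
    bulge_up = runs(u_str, "b")
    bulge_down = runs(d_str, "b")
    if len(bulge_up) != 1 or len(bulge_down) != 1:
        raise ValueError("layout must contain exactly one bulge per arm")
    # Upstream runs 5'->3': [h][bulge][central+hprime]; downstream runs
    # 5'->3': [hprime][bulge][central+h].
    if len(u_runs) == 2:
        h_run, chp_run = u_runs
        h_len = h_run[1] - h_run[0] + 1
    elif len(u_runs) == 1:
        h_run, chp_run = None, u_runs[0]
        h_len = 0
    else:
        raise ValueError("unexpected paired-run structure on upstream arm")
    if len(d_runs) == 2:
        hp_run, ch_run = d_runs
        hp_len = hp_run[1] - hp_run[0] + 1
    elif len(d_runs) == 1:
        hp_run, ch_run = None, d_runs[0]
        hp_len = 0
    else:
        raise ValueError("unexpected paired-run structure on downstream arm")
    central_len = (chp_run[1] - chp_run[0] + 1) - hp_len
    if central_len != (ch_run[1] - ch_run[0] + 1) - h_len:
        raise ValueError("inconsistent central helix length between arms")

    central_d_top = ch_run[1] - h_len
    central = [(chp_run[0] + k, central_d_top - k) for k in range(central_len)]
    h = []
    if h_len:
        h = [(h_run[0] + t, ch_run[1] - t) for t in range(h_len)]
    hprime = []
    if hp_len:
        hprime = [
            (i, j)
            for i, j in zip(
                range(chp_run[0] + central_len, chp_run[1] + 1),
                range(hp_run[1], hp_run[0] - 1, -1),
            )
        ]
    return {
        "h": h,
        "central": central,
        "hprime": hprime,
        "bulge_up": bulge_up[0],
        "bulge_down": bulge_down[0],
    }


def check_splice_in_bulge(match: BHBMatch, context: GluedContext) -> tuple[bool, bool]:
    """Whether each splice site falls inside its bulge.

    A splice site (the bond after arm index p) lies inside a bulge [s, e]
    iff both flanking nucleotides belong to the bulge, i.e. s <= p < e.
    """
    if match.bulge_up[1] >= len(context.upstream_arm) or match.bulge_down[1] >= len(
        context.downstream_arm
    ):
        raise ValueError("match does not belong to this context")
    p_up, p_down = context.splice_site_positions
    s, e = match.bulge_up
    up_ok = s <= p_up < e
    s, e = match.bulge_down
    down_ok = s <= p_down < e
    return (up_ok, down_ok)


def _helix_stack_sum(pairs: list[tuple[int, int]], u: str, d: str) -> float:
    total = 0.0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        total += STACK_DG37[f"{u[i1]}{d[j1]}/{u[i2]}{d[j2]}"]
    return round(total, 10)


def duplex_stacking_energy(top: str, bottom: str) -> float:
    """Stacking score of a fully paired antiparallel duplex.

    ``top`` and ``bottom`` are both 5'->3'; top[k] pairs bottom[-1-k].
    """
    if len(top) != len(bottom):
        raise ValueError("duplex strands must have equal length")
    total = 0.0
    for k in range(len(top) - 1):
        total += STACK_DG37[
            f"{top[k]}{bottom[-1 - k]}/{top[k + 1]}{bottom[-2 - k]}"
        ]
    return round(total, 10)


def _cofold_mfe(seq_a: str, seq_b: str) -> float:
    """Minimum free energy of cofolding two strands (ViennaRNA)."""
    try:
        import RNA  # ViennaRNA python bindings

        fc = RNA.fold_compound(f"{seq_a}&{seq_b}")
        _, mfe = fc.mfe_dimer()
        return float(mfe)
    except ImportError:
        pass
    if shutil.which("RNAcofold") is None:
        raise RuntimeError("external energy engine requires ViennaRNA (RNAcofold)")
    out = subprocess.run(
        ["RNAcofold", "--noPS"],
        input=f"{seq_a}&{seq_b}\n",
        capture_output=True,
        text=True,
        check=True,
    ).stdout
    last = out.strip().splitlines()[-1]
    return float(last.rsplit("(", 1)[1].rstrip(" )"))


def score_energy(match: BHBMatch, context: GluedContext, engine: str = "internal") -> float:
    """Stability score of a match in kcal/mol.

    internal
        Sum of nearest-neighbor stacking terms over consecutive pairs within
        each of the three helices (no loop terms; relative score).
    external
        Minimum free energy of cofolding the two arms (RNAcofold / Turner
        model), independent of the matched layout.
    """
    u, d = context.upstream_arm, context.downstream_arm
    if engine == "internal":
        return round(
            _helix_stack_sum(match.outer_helix_h, u, d)
            + _helix_stack_sum(match.central_helix, u, d)
            + _helix_stack_sum(match.outer_helix_hprime, u, d),
            10,
        )
    if engine == "external":
        return _cofold_mfe(u, d)
    raise ValueError(f"unknown energy engine {engine!r}")


def match_bhb(
    context: GluedContext,
    motif: MotifParams | None = None,
    strict_hbhbh: bool = True,
) -> list[BHBMatch]:
    """Enumerate all hBHBh' layouts on a glued context.

    A layout places a ``helix_len`` central helix of inter-arm pairs flanked
    by a ``bulge_len`` unpaired bulge on the upstream arm (5' of the helix)
    and one on the downstream arm, each bulge bounded distally by an outer
    helix.  With ``strict_hbhbh`` the outer helices must reach ``h_len`` /
    ``hprime_len`` pairs (the strict substrate requirement of the Haloferax
    enzyme); otherwise a bare BHB suffices.  A bulge must be forced: if all
    its nucleotides could pair on the continuation of the central-helix
    diagonal the layout is rejected, since such a "bulge" would fold as an
    uninterrupted helix.  Matches with a positive internal stacking score
    are not reported.  Returned sorted by energy ascending,
    then leftmost central helix, then longest outer helices.
    """
    motif = motif or MotifParams()
    u, d = context.upstream_arm, context.downstream_arm
    H, B = motif.helix_len, motif.bulge_len
    wob = motif.allow_wobble

    def absorbable(iu0: int, jd0: int, du: int, dd: int) -> bool:
        # A bulge is only a bulge if it cannot zip onto the continuation of
        # the central-helix diagonal; a fully pairable "bulge" would fold as
        # an uninterrupted helix instead (cheap surrogate for the cofold
        # verification of the predicted structure).
        for t in range(B):
            iu, jd = iu0 + du * t, jd0 + dd * t
            if not (0 <= iu < len(u) and 0 <= jd < len(d)):
                return False
            if not _is_pair(u[iu], d[jd], wob):
                return False
        return True

    matches: list[BHBMatch] = []
    # i: upstream index of the first central-helix nt;
    # j: downstream index of the central helix's highest-index nt
    # (central pairs are (i+k, j-k), k = 0..H-1).
    for i in range(B, len(u) - H + 1):
        for j in range(H + B - 1, len(d)):
            if not all(_is_pair(u[i + k], d[j - k], wob) for k in range(H)):
                continue
            if absorbable(i - 1, j + 1, -1, +1) or absorbable(i + H, j - H, +1, -1):
                continue
            # Outer helix h: pairs (i-B-1-t, j+1+t), exon-side.
            h_run = _maximal_run(u, d, i - B - 1, j + 1, -1, +1, wob)
            # Outer helix h': pairs (i+H+t, j-H-B-t), intron-side.
            hp_run = _maximal_run(u, d, i + H, j - H - B, +1, -1, wob)
            if strict_hbhbh and (h_run < motif.h_len or hp_run < motif.hprime_len):
                continue
            m = BHBMatch(
                central_helix=[(i + k, j - k) for k in range(H)],
                bulge_up=(i - B, i - 1),
                bulge_down=(j - H - B + 1, j - H),
                outer_helix_h=[(i - B - h_run + t, j + h_run - t) for t in range(h_run)],
                outer_helix_hprime=[(i + H + t, j - H - B - t) for t in range(hp_run)],
            )
            m.energy = score_energy(m, context, engine="internal")
            if m.energy > 0:
                continue
            m.splice_in_bulge = check_splice_in_bulge(m, context)
            m.layout_string = _build_layout_string(m, context)
            matches.append(m)
    matches.sort(
        key=lambda m: (
            m.energy,
            m.central_helix[0][0],
            -(len(m.outer_helix_h) + len(m.outer_helix_hprime)),
            -m.central_helix[0][1],
        )
    )
    return matches


def detect(
    genome: str,
    clusters,
    motif: MotifParams | None = None,
    flank_len: int = 25,
    strict_hbhbh: bool = True,
    engine: str = "internal",
) -> pd.DataFrame:
    """Screen junction clusters for SE-substrate candidates.

    For each cluster the glued context around its representative splice sites
    is extracted, hBHBh' layouts are enumerated, and the best
    substrate-consistent match (both splice sites inside bulges) decides the
    verdict.  Returns one row per cluster with coordinates, intron length,
    verdict, energy and layout string.
    """
    motif = motif or MotifParams()
    rows = []
    for cl in clusters:
        left, right = cl.representative_left, cl.representative_right
        ctx = extract_context(genome, (left + 1, right), flank_len=flank_len)
        hits = [m for m in match_bhb(ctx, motif, strict_hbhbh) if m.substrate_consistent]
        best = hits[0] if hits else None
        energy = best.energy if best is not None else float("nan")
        if best is not None and engine == "external":
            energy = score_energy(best, ctx, engine="external")
        rows.append(
            {
                "left_site": left,
                "right_site": right,
                "intron_length": right - left,
                "topology": cl.topology,
                "coverage_total": sum(cl.coverage_per_replicate),
                "verdict": "SE-substrate-candidate" if best else "no-motif",
                "energy": energy,
                "engine": engine if best else "",
                "layout": best.layout_string if best else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "left_site", "right_site", "intron_length", "topology",
            "coverage_total", "verdict", "energy", "engine", "layout",
        ],
    )
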