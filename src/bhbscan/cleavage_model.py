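"""Splicing-endonuclease cleavage and downstream ligation.

The enzyme cuts a precursor twice, once inside each bulge of its hBHBh'
substrate, releasing three fragments in 5'->3' order.  A ligase then joins
the two outer fragments (exon ligation) and circularizes the middle fragment
(the excised intron) -- the species circRNA-seq observes.  Cleavage chemistry
(2',3'-cyclic phosphate / 5'-OH ends) is carried as metadata labels only.

The nucleotide-level scissile position within a 3-nt bulge is a configurable
convention (``cut_rule``): the default cuts between bulge nucleotides 2 and 3
counted from the central-helix-proximal side, which for the planted motif
layout reproduces the exon|intron bonds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PrecursorSubstrate",
    "CleavageResult",
    "CUT_RULES",
    "cleave",
    "ligate",
    "canonical_rotation",
    "substrate_from_planted_locus",
]

CUT_RULES = ("after1", "after2", "after3")


@dataclass(frozen=True)
class PrecursorSubstrate:
    """An RNA precursor with an annotated BHB.

    ``bulge5``/``bulge3`` are 0-based inclusive intervals in ``sequence``;
    for both bulges the central-helix-proximal end is the 3' (higher-index)
    end, as in the planted motif layout.
    """

    sequence: str
    bulge5: tuple[int, int]
    bulge3: tuple[int, int]
    label: str = ""
    end_chemistry: dict = field(
        default_factory=lambda: {"cut_5p": "5'-OH", "cut_3p": "2',3'-cyclic phosphate"}
    )

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for lo, hi in (self.bulge5, self.bulge3):
            if not (0 <= lo <= hi < n):
                raise ValueError("bulge interval outside precursor")
        if self.bulge5[1] >= self.bulge3[0]:
            raise ValueError("bulges must be disjoint and ordered 5' before 3'")


@dataclass
class CleavageResult:
    fragment5: str
    fragment_mid: str
    fragment3: str
    cut_positions: tuple[int, int]  # bond after this 0-based index
    ligated_exons: str = ""
    circular_intron: str = ""  # canonical rotation of fragment_mid


def _cut_after(bulge: tuple[int, int], rule: str) -> int:
    """0-based index after which the bond is cut, for a bulge whose
    helix-proximal end is bulge[1].  afterK cuts distal of the K-th
    nucleotide counted from the proximal side."""
    if rule not in CUT_RULES:
        raise ValueError(f"unknown cut_rule {rule!r}")
    k = int(rule[-1])
    pos = bulge[1] - k
    if pos < bulge[0] - 1:
        raise ValueError(f"cut_rule {rule} falls outside bulge {bulge}")
    return pos


def cleave(precursor: PrecursorSubstrate, cut_rule: str = "after2") -> CleavageResult:
    """Cut the precursor inside both bulges, yielding three fragments.

    Fragment lengths always sum to the precursor length; raises if the two
    cut positions coincide, invert, or touch the precursor ends (an empty
    fragment would not be a cleavage product).
    """
    seq = precursor.sequence
    cut1 = _cut_after(precursor.bulge5, cut_rule)
    cut2 = _cut_after(precursor.bulge3, cut_rule)
    if not (0 <= cut1 < cut2 < len(seq) - 1):
        raise ValueError(f"invalid cut positions ({cut1}, {cut2})")
    f5 = seq[: cut1 + 1]
    mid = seq[cut1 + 1 : cut2 + 1]
    f3 = seq[cut2 + 1 :]
    assert len(f5) + len(mid) + len(f3) == len(seq)
    result = CleavageResult(f5, mid, f3, (cut1, cut2))
    result.ligated_exons, result.circular_intron = ligate(result)
    return result


def ligate(result: CleavageResult) -> tuple[str, str]:
    """Join the outer fragments and circularize the middle one.

    Returns (ligated exons, canonical rotation of the circular intron).
    The canonical rotation -- the lexicographically minimal one -- gives a
    well-defined serialization of the rotation-equivalence class.
    """
    if not result.fragment_mid:
        raise ValueError("cannot circularize an empty intron fragment")
    return result.fragment5 + result.fragment3, canonical_rotation(result.fragment_mid)


def canonical_rotation(s: str) -> str:
    """Lexicographically minimal rotation of ``s`` (idempotent and invariant
    under rotation of the input)."""
    if not s:
        return s
    doubled = s + s
    n = len(s)
    return min(doubled[i : i + n] for i in range(n))


def substrate_from_planted_locus(
    genome: str,
    intron: tuple[int, int],
    bulge_len: int = 3,
    pad: int = 30,
    label: str = "",
) -> PrecursorSubstrate:
    """Build a precursor around a planted intron using the generator's motif
    layout: the 5' bulge ends one base inside the intron's second position
    and the 3' bulge two bases into the 3' exon.  With cut_rule='after2' the
    cleavage products are exactly (5' exon pad, intron, 3' exon pad)."""
    s, e = intron
    lo = max(1, s - pad)
    hi = min(len(genome), e + pad)
    seq = genome[lo - 1 : hi].translate(_DNA_TO_RNA)
    off = lo - 1  # genome 1-based -> precursor 0-based shift is (pos-1-off)
    b5 = (s - (bulge_len - 2) - 1 - off, s + 1 - 1 - off)
    b3 = (e - (bulge_len - 2) - off, e + 2 - 1 - off)
    return PrecursorSubstrate(seq, b5, b3, label=label)


_DNA_TO_RNA = str.maketrans("ACGTacgt", "ACGUACGU")
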