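"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results from first principles
(exhaustive enumeration, direct rule application) so the tests check the
implementation against an independent route, not against itself.
"""

from __future__ import annotations

import numpy as np
import pytest

from bhbscan import LocusSpec, MotifParams, build_genome

WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOBBLE = {("G", "U"), ("U", "G")}


def pairs(x: str, y: str, wobble: bool = True) -> bool:
    return (x, y) in WC or (wobble and (x, y) in WOBBLE)


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_filter(counts_by_junction: dict, min_coverage: int, n_replicates: int):
    """Direct application of the replicate/coverage rule to per-junction
    coverage vectors: kept iff every replicate reaches min_coverage."""
    kept = []
    for key, cov in counts_by_junction.items():
        if len(cov) == n_replicates and all(c >= min_coverage for c in cov):
            kept.append(key)
    return sorted(kept)


def oracle_single_linkage(points: list[tuple[int, int]], max_dist: int) -> list[set]:
    """O(n^2) single-linkage clustering by repeated merging until fixpoint."""
    clusters = [{k} for k in range(len(points))]
    changed = True
    while changed:
        changed = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                if any(
                    abs(points[i][0] - points[j][0]) <= max_dist
                    and abs(points[i][1] - points[j][1]) <= max_dist
                    for i in clusters[a]
                    for j in clusters[b]
                ):
                    clusters[a] |= clusters[b]
                    del clusters[b]
                    changed = True
                    break
            if changed:
                break
    return clusters


def oracle_match_bhb(u: str, d: str, motif: MotifParams, strict: bool):
    """Exhaustive enumeration of hBHBh' layouts over all legal pairings.

    Returns a set of canonical tuples (central start i, central D top j,
    h run length, h' run length) for every layout the grammar admits."""
    H, B = motif.helix_len, motif.bulge_len
    wob = motif.allow_wobble
    out = set()
    for i in range(len(u)):
        for j in range(len(d)):
            if i - B < 0 or i + H - 1 >= len(u):
                continue
            if j - H - B + 1 < 0 or j >= len(d):
                continue
            ok = True
            for k in range(H):
                if not pairs(u[i + k], d[j - k], wob):
                    ok = False
            if not ok:
                continue
            # bulge forcedness: not all bulge nts may zip onto the
            # central-helix diagonal continuation
            up_zip = True
            for t in range(B):
                iu, jd = i - 1 - t, j + 1 + t
                if not (0 <= iu < len(u) and 0 <= jd < len(d)) or not pairs(
                    u[iu], d[jd], wob
                ):
                    up_zip = False
            down_zip = True
            for t in range(B):
                iu, jd = i + H + t, j - H - t
                if not (0 <= iu < len(u) and 0 <= jd < len(d)) or not pairs(
                    u[iu], d[jd], wob
                ):
                    down_zip = False
            if up_zip or down_zip:
                continue
            h_run = 0
            iu, jd = i - B - 1, j + 1
            while 0 <= iu < len(u) and jd < len(d) and pairs(u[iu], d[jd], wob):
                h_run += 1
                iu -= 1
                jd += 1
            hp_run = 0
            iu, jd = i + H, j - H - B
            while iu < len(u) and 0 <= jd and pairs(u[iu], d[jd], wob):
                hp_run += 1
                iu += 1
                jd -= 1
            if strict and (h_run < motif.h_len or hp_run < motif.hprime_len):
                continue
            out.add((i, j, h_run, hp_run))
    return out


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def single_locus_world():
    """A genome with one planted tRNA-like locus (103-nt intron)."""
    loci = [LocusSpec("tRNA-103", "tRNA", 30, 103, 30)]
    genome, truth, gff = build_genome(loci, 3000, seed=7)
    return genome, truth, gff


@pytest.fixture(scope="session")
def seven_plus_decoys():
    """Seven BHB-flanked loci mirroring the biologically observed intron
    lengths plus three motif-free decoy junctions."""
    return [
        LocusSpec("UTR-46", "mRNA_5UTR", 30, 46, 30),
        LocusSpec("tRNA-75", "tRNA", 30, 75, 30),
        LocusSpec("tRNA-103", "tRNA", 30, 103, 30),
        LocusSpec("rRNA-16S-a", "rRNA", 40, 1658, 40),
        LocusSpec("rRNA-16S-b", "rRNA", 40, 1658, 40),
        LocusSpec("rRNA-23S-a", "rRNA", 40, 2979, 40),
        LocusSpec("rRNA-23S-b", "rRNA", 40, 2980, 40),
        LocusSpec("decoy-1", "tRNA", 30, 120, 30, motif=None),
        LocusSpec("decoy-2", "rRNA", 30, 200, 30, motif=None),
        LocusSpec("decoy-3", "mRNA_5UTR", 30, 350, 30, motif=None),
    ]


def random_context_arms(rng: np.random.Generator, max_len: int = 20):
    nu = int(rng.integers(8, max_len + 1))
    nd = int(rng.integers(8, max_len + 1))
    u = "".join("ACGU"[k] for k in rng.integers(0, 4, nu))
    d = "".join("ACGU"[k] for k in rng.integers(0, 4, nd))
    return u, d
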