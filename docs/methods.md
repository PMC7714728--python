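# Methods

## Coordinate conventions

Genomic coordinates are 1-based inclusive. A splice-site pair `(left, right)`
is stored so that the intron occupies `[left + 1, right]`: `left` is the last
exonic base before the intron, `right` the last intronic base, and intron
length = `right − left`. This convention matches six of the seven published
circRNA coordinate/length rows that motivated it; the seventh (one of the two
16S rRNA rows) is internally inconsistent by one base under *any* fixed
convention, so it is documented rather than asserted. BED output applies the
usual 0-based half-open transform; GFF3 output stays 1-based inclusive.
Within a glued context, arm positions are 0-based and a splice site is the
phosphodiester bond *after* the recorded index.

## Junction calling

A read split into two exact genomic segments reports a junction. Segments in
genomic order (5′ segment upstream) give a **linear** junction
(`left = end of segment 1`, `right = start of segment 2 − 1`); segments in
reversed order give a **circular** junction spanning
`[start of segment 2, end of segment 1]` — the geometry of a read across the
ligation point of a circularized intron. Minus-strand alignments are
normalised to genome-forward segment order first. Reads with more than two
segments are skipped and counted in the log.

The internal split mapper is an exact matcher intended for synthetic data:
it binary-searches the longest mappable prefix (occurrence is monotone in
prefix length), then requires the exact remainder to map as well, with both
segments at least `min_seed = 12` nt. It makes no attempt at mismatch
tolerance or repeat resolution; real data should arrive as SAM with
supplementary alignments (SA-tag chimeras) or spliced `N`-CIGAR alignments,
both of which are ingested through pysam.

**Filter.** A junction is kept iff its per-replicate coverage reaches
`min_coverage` (default 2) in *every* one of `n_replicates` (default 3)
replicates. The published rule ("coverage of at least two that appear in all
three replicates") admits a laxer reading — total ≥ 2 plus presence in all
replicates — which is available via `require_per_replicate=False`; the strict
reading is the default because it is reproducible and conservative.

**Merge.** Junctions whose left *and* right coordinates each differ by at
most `merge_dist = 10` nt (per-coordinate Chebyshev distance) and whose
topologies match are merged by single linkage. The representative is the
member with the highest total coverage (ties: smaller left, then smaller
right); per-replicate coverages are summed over members. Single linkage
makes cluster count monotone non-increasing in `merge_dist`.

## The hBHBh′ layout grammar

The motif search glues the two splice-site neighbourhoods: the upstream arm
is `flank_len` exonic nt before the intron plus the first `flank_len`
intronic nt; the downstream arm is the mirror image. For introns shorter
than two flanks the intronic parts truncate at the intron midpoint and never
overlap. `flank_len` defaults to 25 nt — enough to hold the outer helix,
bulge and central helix with margin while keeping the search space small.

A match places, along the antiparallel inter-arm duplex:

    h (≥ h_len pairs) — 3-nt bulge (upstream arm) — 4-bp central helix —
    3-nt bulge (downstream arm) — h′ (≥ hprime_len pairs)

Each bulge interrupts only its own strand; the opposite strand is contiguous
across it (that is what distinguishes a bulge from an internal loop). In
each arm's own 5′→3′ direction both bulges lie 5′ of the central helix —
the layout is dyad-symmetric, as expected for a substrate of a homodimeric
enzyme. Pairing is Watson-Crick plus G:U wobble by default (`allow_wobble`);
the motif is conserved structurally, not by sequence. Outer helices are
reported at their maximal contiguous extent. With `strict_hbhbh=False` the
outer-helix requirement is dropped, admitting bare BHB layouts (the relaxed
substrate spectrum of (αβ)₂-type enzymes).

Two semantic constraints replace the covariance-model machinery that this
grammar supersedes:

* **Splice-in-bulge.** A candidate is substrate-consistent only if each
  splice site (a bond) falls strictly inside its 3-nt bulge, i.e. between
  two bulge nucleotides.
* **Forced bulges.** A layout is rejected if all nucleotides of a bulge
  could pair on the continuation of the central-helix diagonal: such a
  "bulge" would fold as an uninterrupted helix. This is a deterministic
  surrogate for verifying with a folding program that the sequence really
  folds into the predicted bulged structure.

Matches with a positive internal stacking score are suppressed, and the
returned list is sorted by energy, then leftmost central helix, then longest
outer helices. Enumeration is exhaustive over all `O(|U|·|D|)` placements;
at the default 50-nt arms this is a few thousand constant-time checks per
junction.

## Energy model

The internal engine sums nearest-neighbor stacking free energies over
consecutive pairs within each helix. The 36-entry stack table (Watson-Crick
and G:U steps, ΔG°37 in kcal/mol) is the Turner 2004 parameter set as
tabulated by ViennaRNA 2.7; it was extracted programmatically from RNAeval's
per-loop output on 2-bp duplexes, so the per-stack terms are exactly
consistent with the external oracle. No duplex-initiation, loop or terminal
penalties are included: the score is a *relative* stability measure (a
single pair scores 0.0; each added stack changes the score by its table
entry), suitable for ranking and sign checks but not comparable to absolute
folding energies of real loci. The optional external engine
(`engine="external"`) cofolds the two arms with RNAcofold and returns its
MFE. `cofold_reference.py` freezes RNAcofold MFEs for 20 designed duplexes;
the internal ranking agrees with them at Spearman ρ ≈ 0.996, and the test
suite requires ρ ≥ 0.9. No energy cutoff is applied to candidates — the
report carries energies and leaves thresholds to the caller, since observed
substrate energies span a range without a published cutoff.

## Cleavage and ligation

Cleavage cuts once inside each bulge. The nucleotide-level scissile position
is not specified by the motif definition, so it is a configurable convention:
`after1`, `after2` (default) or `after3`, cutting distal of the k-th bulge
nucleotide counted from the central-helix-proximal side. Under the planted
layout, `after2` places both cuts exactly on the exon|intron bonds, so the
middle fragment is precisely the annotated intron. Fragment lengths sum to
the precursor length by construction and this is asserted on every call.
Ligation concatenates the outer fragments and circularizes the middle one;
circles are serialized as their lexicographically minimal rotation, which is
idempotent and rotation-invariant, so rotation-equivalent circles compare
equal. Cleavage chemistry (2′,3′-cyclic phosphate / 5′-OH ends) is metadata
only; the 2′-phosphotransferase step some eukaryotes need is out of scope.

## Synthetic data

`build_genome` plants loci on an i.i.d. uniform-ACGT background — the
simplest null that rarely forms long helices by chance. Helix bases of the
designed motif are drawn as random Watson-Crick pairs; bulge bases are drawn
from {A, C} so the two bulges cannot pair with each other, and one
nucleotide per bulge is forced to be unpairable with the base it would face
if the bulge zipped onto the central-helix diagonal, guaranteeing the
forced-bulge constraint holds for every planted locus. Three additional
bases around the ligation point are drawn unequal to the bases that could
extend an exact prefix/suffix match across it, so error-free back-junction
reads split uniquely at the truth coordinates. A locus with `motif=None` is
a decoy: a junction-producing intron with no designed structure.

`simulate_reads` emits, per replicate and per circular intron,
`per_junction_depth × circular_enrichment` back-junction reads crossing the
ligation point with at least `min_overhang = 15` nt on each side, plus
uniform linear background reads at `linear_background_depth` mean coverage.
Substitution errors are i.i.d. at `error_rate`. Reads from a circular
template are capped at the circle's circumference, emulating
fragmentation-limited insert size (a 46-nt circle yields 46-nt reads); the
`read_len`-exceeds-template error applies to linear templates. Enrichment is
a sampling-weight multiplier, not an exonuclease kinetics model, and the
known bias of circRNA-seq against short circles is deliberately *not*
modelled — depth is an explicit per-junction knob instead, so tests state
their coverage assumptions directly. All randomness flows through one seeded
generator; identical seeds give byte-identical FASTQ.

Default study conditions used by the demonstration configs and the
acceptance script: three replicates, 1 × 75 nt reads, per-junction depth 10,
background coverage 0.5–1×, genome 12–30 kb with six (demo) or seven-plus-
three-decoy (acceptance) loci whose intron lengths span 31–2980 nt,
mirroring the biologically observed range. These sizes keep a full
simulate-map-call-detect cycle under a few seconds on one CPU while every
junction retains replicate coverage well above the filter threshold.

What passing tests on these data do **not** show: robustness to alignment
ambiguity in repetitive genomes, indel errors, partial RNase-R digestion,
multi-chromosome chimeras, or expression-level effects — the generator does
not emulate those features of real data.

## Known limitations

* The exact split mapper tolerates no mismatches within a segment; with
  sequencing errors, coverage degrades gracefully (error-free reads still
  map) but individual errored reads are lost rather than rescued.
* The grammar fixes bulge length per search; enzymes with variable-bulge
  substrate spectra are approximated only by `strict_hbhbh=False` plus
  re-running with other `MotifParams`.
* Internal energies are stacking-only and should never be compared with
  published absolute folding energies of real loci; use the external engine
  for that.
* Detection of very short introns is bounded by the midpoint-truncation of
  the glued context: the default layout needs about 10 intronic nt on the 5′
  side and 5 on the 3′ side, so introns shorter than ~19 nt cannot present
  the full motif to the detector.
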