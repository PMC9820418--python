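# Methods

This note documents the models and procedures implemented in `mitorecomb`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic bench does and does not establish
about real data.

## Conformation model

A *conformation* is a set of circular chromosomes, each an ordered list of
oriented segments. `segment_genome` cuts the assembled circles at the
boundaries of the repeat-pair copies; each copy becomes its own segment
tagged with its pair id and with the strand on which the repeat consensus
lies (the second copy of an inverted pair stores the plus-strand sequence
but carries repeat-strand −1). Crossover between the two copies of a pair
is a pure splice of these lists:

- copies on two different circles → **fusion** (if the repeat frames
  disagree, the second circle is flipped first — a whole-circle flip is
  the identity on the molecule);
- direct copies on one circle → **fission** into two circles;
- inverted copies on one circle → **inversion** of the intervening block.

The mode is *derived* from co-circularity and relative repeat-frame
orientation, never user-set. Events never duplicate or delete segments,
so total base content is conserved exactly, and every event is an
involution (applying it twice restores the conformation). Both properties
are asserted in tests on random event walks.

**Mosaic junctions.** A recombinant junction is represented with the full
sequence of whichever copy sits at the splice point. When the copies are
not identical the biological product is a mosaic of the two; for the
junction-support analysis only the flanks discriminate templates, so this
approximation is immaterial at ≥90% copy identity.

**Canonical key.** Distinct conformations are counted via a key invariant
under circle rotation, circle relabeling, and whole-circle strand flip
(minimum over all rotations of the circle and of its reversed,
orientation-flipped form, circles sorted). With the segment registry
supplied, segments are labelled by sequence content up to reverse
complement, which makes the two copies of an identical repeat
interchangeable; tests verify that key equality then coincides exactly
with circular-sequence identity on random event walks.

**Enumeration.** Supported events are applied breadth-first (default
depth 2, the deepest cascade in the system this models: an inversion
acting on a fused product) and deduplicated by canonical key. The event
list is a set of *plans* — pair id, optional required mode, optional
restrict-to-major flag — rather than a bare pair list: a flat list
applied exhaustively would also enumerate composite products (e.g.
fission followed by fusion) that junction evidence alone cannot rank, so
the published-style inventory is driven by an explicit plan, and the
pipeline's default plan applies each supported pair from the major
conformation with its derived mode.

## Junction templates and spanning support

For each pair, four templates are built from the assembled genome: each
copy with its own 1,000 bp flanks (`ref_1`, `ref_2`), and the two
flank-swapped constructs joining one copy's upstream flank to the other
copy's downstream flank (`swap_1`, `swap_2`). For inverted pairs the
second copy's flanks are taken on its own strand; flanks wrap across the
circular origin. Pairs whose flank-extended intervals overlap are
rejected (their templates would share sequence), and pairs with identical
flanks on both copies are flagged unresolvable.

A read supports a template iff the template's *diagnostic core* — the
repeat copy plus `min_anchor` flank bases on each side — aligns within
the read at identity ≥ `min_identity`, and both flank anchors
individually align inside the matched window at that identity. The second
condition is essential: infix edit-distance alignment will otherwise
absorb a missing flank as end insertions and credit reads that do not
actually span the junction. Among the four templates the strictly best
edit distance wins; ties leave the read unassigned (conservative, no
double counting). Reads shorter than the core are counted uninformative.

Defaults: `min_anchor` = 200 bp and `min_identity` = 0.80, chosen so a
360 bp repeat needs a ≥760 bp read and so a 200 bp anchor mismatch
(~50% identity between unrelated flanks) always dominates the ~5%
read-error noise on the shared part; an event is called supported at ≥2
recombinant-junction reads. Alignment is bit-parallel banded edit
distance (edlib) with the distance cap set by the identity floor. On
simulated single-conformation reads at 5% error, false support is
indistinguishable from zero (<1% asserted over ≥300 informative reads),
and 50:50 mixtures are recovered within the 99% binomial interval.

## Repeat census

**SSRs.** Maximal perfect runs of primitive 1–6 bp motifs, reported at
the leftmost phase with whole copies only. Class thresholds default to
mono ≥10, di ≥5, tri ≥4, tetra/penta/hexa ≥3 copies — common organelle
settings; they are fully configurable and no attempt is made to reproduce
any published absolute count, which depends on the source assembly.
Adjacent SSRs are reported separately (no compound merging). With
`circular=True` the scan is repeated on the half-rotated sequence;
origin-spanning runs are reported in original coordinates with `end`
exceeding the sequence length and a `wrapped` flag, and the partial
linear calls they subsume are dropped.

**Tandem repeats.** A simplified tandem-array finder for the 15–27 bp
unit regime: arrays are seeded where the period-lag self-match fraction
over one unit clears the floor (default 78%), extended greedily, then
re-bounded as the maximal-scoring segment of agreement with the
column-majority consensus so boundaries land on consensus-matching bases.
Reported arrays need ≥1.8 unit copies and the percent-match floor;
overlapping calls at different periods resolve by highest percent match,
then longest array. The full statistical machinery of a
maximum-likelihood tandem finder is deliberately out of scope — in this
unit-length regime column-majority consensus scoring reproduces the same
calls.

**Dispersed repeats.** Forward and palindromic pairs ≥30 bp. The
detector is seed-and-extend: exact k-mer anchors select candidate
diagonals; each anchored diagonal is decomposed into *maximal-scoring
segments* of its match/mismatch series under integer scoring (match +1,
mismatch −λ with λ = ⌈(1−f)/f⌉, i.e. λ=9 at the default mismatch ceiling
f=0.1), computed by the divide-and-conquer characterisation (extract the
best segment, recurse on the flanks). A positive score bounds the
mismatch fraction below 1/(λ+1) ≤ f, so the identity floor is enforced by
construction, and segments begin and end on matches.

This locally-optimal-alignment definition was chosen over the naive
alternative — "longest interval whose overall identity stays above the
floor" — deliberately: under the naive rule the mismatch budget grows
with length, so any strong repeat can legally absorb flanking random
sequence and reported boundaries become seed-lottery; under local
optimality a planted 137 bp pair with 12 interior substitutions is
reported at exactly 137 bp and 91.24% identity.

The anchor size defaults to the largest k that provably cannot miss a
reportable segment (pigeonhole: a positive-score segment of length L with
m mismatches contains an exact run of ≥⌈(L−m)/(m+1)⌉; k=7 at min length
30 and f=0.1), capped at 13. Windows around anchor clusters are padded so
a reportable segment cannot extend past its anchors by more than the pad,
and are re-expanded if a substantial segment touches a window edge — so
the windowed computation equals the full-diagonal decomposition, which is
what the brute-force oracle in the test suite computes. Self-trivial
matches and strand/mirror duplicates are excluded; the detector output on
the reverse-complemented genome maps onto the original output
(strand-symmetry test).

Dispersed detectors operate on the linearised circle; origin-spanning
dispersed pairs are not re-scanned under rotation (templates, where the
origin matters for this analysis, do wrap).

**E-value.** REPuter-style expected count for an exact match,
E = N²/4^L, multiplied by C(L,m)·3^m for m mismatches. The mismatch
correction is an approximation (the original tool's internals are not
published); it agrees with the published table's imperfect-repeat entries
to within about an order of magnitude and is monotone in L and N, which
is what the ranking uses. Values below the double-precision floor are
printed as 0.

## MTPT scan

Mito–plastid homology uses the same diagonal engine with the penalty set
from the identity floor (default 70% → λ=3, effective guaranteed floor
75%), minimum length 100 bp, both strands. These thresholds are package
defaults, configurable, not taken from any publication. The anchor here
is a heuristic k=11 (a sensitivity-guaranteed anchor at 70% identity
would be k=4, which degenerates to scanning every diagonal); any
homology with ≤1 difference per 11 bp stretch anchors reliably, far below
the divergence of recent organellar transfers, and planted transfers at
≤5% divergence are recovered with boundaries within 10 bp of truth.

Raw matches are merged by interval union on the mitochondrial axis
(overlapping or book-ended); merged identity is the length-weighted mean
of constituents, and the reported plastid partner is the highest-identity
constituent with alternatives logged. Statistics (fragment count, total
bp, percent of mitogenome to 2 decimals, count >1 kb, longest) are
recomputed from the emitted fragments. Gene containment is strict: a
plastid gene is attached to a fragment only if its full span lies inside
the fragment's plastid interval; a 1 bp overhang excludes it.

## Synthetic-data bench

The generator emulates the study conditions the analysis assumes: two
circular chromosomes (demo: 26,176 + 14,425 bp, one-tenth of the modelled
genome's published lengths) with i.i.d. background at GC 44.43%, four
recombination-active repeat pairs reproducing the published topology and
lengths (982-scaled/360/211/137 bp; the 137 bp pair carries 12
substitutions, identity 91.24%), MISA-class SSRs, 20–25 bp-unit tandem
arrays, and plastid transfers (longest 1,578 bp). Truth tables use
1-based inclusive coordinates.

Reads are log-normal in length (moment-matched to the configured
mean/sd, truncated to [500 bp, circle length]), drawn from a weighted
conformation mixture, reverse-complemented with probability 0.5, with
substitution:insertion:deletion noise at 60:20:20 of the per-base error
rate (only the aggregate rate matters to spanning support). The modelled
study reports no read-length or coverage statistics, so the demo defaults
— mean 3 kb, sd 2 kb, 5% error, 40× coverage — are this package's own
choice of a realistic Nanopore-like regime. FASTQ qualities are a
constant derived from the error rate.

Two generator policies make planted truth *detector-well-defined* rather
than seed-lottery: substitutions between planted repeat copies (and
within transfer fragments) are spread deterministically with an interior
margin of ~λ+1 bases, so end-trimming never pays and the planted
alignment is the unique maximal-scoring segment; and the background bases
immediately flanking a planted feature are forced to mismatch the
feature's continuation, so the planted alignment is maximal. Without
these, truth coordinates would not correspond to any alignment a correct
detector should report.

What the bench does **not** model: base-composition structure beyond
i.i.d. (no codon or strand asymmetry), pore-model-specific error
profiles, homopolymer-length errors, chimeric reads, nuclear
contamination, and assembly uncertainty. Passing tests therefore
establish the correctness of the algorithms under their stated
assumptions, not the field performance of the thresholds on arbitrary
real libraries.

## Numerical and procedural choices

- Tie-breaks in the segment decomposition are fixed (highest score, then
  smallest start, then largest end), making all detectors deterministic.
- Consensus ties in the tandem finder resolve alphabetically.
- Read-template ties (equal best edit distance) discard the read.
- Pipeline stage seeds derive from the config seed (genome = seed,
  plastid = seed+1, reads = seed+2); identical configs give byte-identical
  outputs, asserted in tests.
- Problem sizes in the test suite are desk-scale by design: oracle
  equivalence runs on 100 sequences of 0.2–2 kb against quadratic/cubic
  brute force; support fidelity uses a 20 kb two-circle genome at
  coverage high enough to yield ≥300 informative spanning reads; the
  demo pipeline runs the one-tenth-scale replica.

## Known limitations

- Alignments are ungapped; a dispersed repeat pair whose copies differ by
  an indel is reported as two pairs (or the longer ungapped piece).
  Junction support does tolerate indels (edit distance), so recombination
  detection is unaffected.
- Conformation enumeration ranks nothing: stoichiometry in vivo is out of
  scope beyond the swap-fraction estimate per pair.
- A mitochondrial interval homologous to several plastid loci reports
  only the best partner (alternatives are logged, and the raw match count
  is emitted alongside the merged count).
- E-values for imperfect repeats are approximate (see above).
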