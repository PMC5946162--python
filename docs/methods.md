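# Methods

## Problem and model

A cis-natural antisense transcript (cis-NAT) pair is two transcripts from
opposite strands of overlapping adjacent loci, complementary over the
overlap. The package treats discovery as a purely coordinate-based
decision problem over gene loci — no sequence is read at any stage. All
internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted only at I/O boundaries, so every overlap length is
plain `end − start` arithmetic.

### Pair detection

A candidate pair must satisfy three criteria: (1) the two genes lie on
opposite strands of the same chromosome; (2) their spans overlap by at
least `min_overlap` bp (default 22 — "larger than 21 nt" read strictly,
because the smallest NAT-siRNA class is 21 nt; the threshold is a config
key for users who prefer ≥ 21); (3) both genes are protein-coding. A gene
counts as protein-coding when the annotation's biotype attribute says so,
or, absent such an attribute, when the locus has at least one CDS feature.
The gene span is the union span over all isoforms, introns included
(default); an exon-level span mode exists as a stricter refinement. UTR-only
isoforms extend the union like any other isoform.

Detection is a per-chromosome sweep over start-sorted genes with an active
set pruned by end coordinate — O(n log n + k). An O(n²) all-pairs scanner
is kept in the package (`pairs.brute_force_pairs`) purely as an
independent oracle for tests.

### Orientation classification

Orientation is decided by a single **nearest-ends rule**: compare the
genomic distance between the two 3′ ends (`|plus.end − minus.start|`)
against the distance between the two 5′ ends (`|plus.start − minus.end|`);
the smaller names the class — `three_prime` (tail-to-tail, convergent) or
`five_prime` (head-to-head, divergent) — with ties going to `three_prime`.
For partially overlapping pairs this provably reduces to the familiar
arrangement rule (for a convergent pair the 3′-end distance *is* the
overlap length, necessarily smaller than the union-length 5′ distance),
so one rule also covers containment pairs — one span fully inside the
other — which still receive a class this way. The containment convention
is this package's own deterministic choice; identical spans classify as
containment, `three_prime`.

Genes participating in exactly two pairs spanning three distinct genes
form a triplet set; chains of ≥ 4 genes yield one set per consecutive
triple, and a pair inside such a chain carries both set ids
(comma-joined).

### Boundary extension and novel pairs

Annotated gene ends are often shorter than the transcribed unit (missing
UTR sequence), hiding real overlaps. The package replaces visual
inspection of coverage in a genome browser with an explicit walk: from
each annotated end, move outward while per-base read depth ≥ `min_depth`
(default 2), tolerating sub-threshold runs up to `max_gap` bp (default
50), stopping at the first longer gap or at `max_extension` bp (default
2000; never past position 0). The extension endpoint is the furthest base
with qualifying depth, so a trailing tolerated gap is not included.
Extensions apply to both ends regardless of 5′/3′ identity. The three
parameters are config keys; the walk is the minimal deterministic
formalization of "the RNA-seq shows the transcript continuing".

Pair detection is rerun on the extended spans under identical criteria;
pairs absent from the annotation-derived set are emitted with
`source=rnaseq_extended`. Because extension only grows spans, every
annotation pair remains detectable on extended spans, making the novel
set a clean set difference.

Coverage is unstranded by default (the strandedness of a given RNA-seq
protocol is often unknown); a stranded mode assigns reads to per-strand
tracks. Note that with unstranded coverage any antisense-overlapping pair
feeds coverage across the overlap into both genes, which extends each
through its partner; stranded libraries avoid this and are strongly
preferable when boundary extension matters. The synthetic fixture is
therefore generated and analysed stranded (see below).

### Expression gate

RPM = read count × 10⁶ / total mapped reads, no pseudocounts, no length
correction; the denominator is all mapped reads in the library, not the
per-gene sum. A read counts toward every gene whose whole-locus span it
overlaps by ≥ 1 bp (strand-matched in stranded mode); reads overlapping
two genes count for both — the simplest deterministic rule for antisense
overlaps, where fractional assignment would be arbitrary. Expressed ⇔
RPM ≥ 1.0, inclusive. Pairs fall into `both_low`, `one_expressed`, or
`both_expressed` (`unknown` when a gene lacks a record); the gate keeps
one-expressed pairs because sperm transcripts are heavily diluted in
whole-pollen RNA and a sperm-specific partner can fall below the
threshold while still being co-expressed in sperm.

### Cell assignment

Inputs are per-gene detection calls (Present/Absent/Marginal) with signal
intensities for pollen and sperm. Sperm expression is the sperm call
itself (P ⇒ expressed). Vegetative-cell expression exploits the fact that
the vegetative cell contributes most pollen RNA: a gene is VC-expressed
iff pollen is P and either sperm is A, or both are P with pollen/sperm
signal ratio strictly > 3 (`ratio_threshold`, config). A sperm signal of
exactly 0 with both calls P satisfies the ratio (treated as +∞). Marginal
calls default to Absent — conservative, since the decision rules only
reference P and A — with a config flag to treat them as Present. The
intensities are consumed as given; whether they are normalized is the
array provider's concern. Assignment is evaluated on the pairs that pass
the expression gate, in keeping with the pipeline's funnel order;
non-evaluated pairs are reported as `not_evaluated`, distinct from
`unknown` (≥ 1 gene missing from the array table).

### Small-RNA evidence

Alignments are filtered to 21–24 nt, the canonical plant siRNA window
(configurable; the 21 nt floor matches the smallest NAT-siRNA class). A
gene "has sRNA" when ≥ 1 filtered alignment overlaps its span by ≥ 1 bp on
either strand — either strand because NAT-siRNAs arise from both strands
of the duplex. Overlap-region evidence requires, by default, full
containment of the read within the pair's overlap interval ("from the
overlapping region" read as origin inside the region); an `intersect`
policy is available. Hit counts are abundance-weighted, since collapsed
sRNA tables carry an abundance per distinct read. Gene-level intersection
uses the RNA-seq-extended spans — the same transcript models pair
detection used — which guarantees structurally that overlap evidence
implies gene evidence even for novel pairs whose overlap lies outside the
annotated spans.

## Synthetic data: what it emulates, and what it does not

The generator plants, on one synthetic chromosome, a configurable census
of pair geometries (default: 20 tail-to-tail, 5 head-to-head, 3
containment alternating their class, 2 triplet chains contributing 4
pairs, 5 novel pairs whose annotated spans are truncated to a 10–30 bp gap
while the true transcripts overlap by 150–250 bp) and negative controls
(5 same-strand overlaps, 5 antisense overlaps with a non-coding partner,
5 sub-threshold antisense overlaps, the first at exactly 21 bp; plus 19 nt
and 30 nt sRNA reads inside otherwise empty overlaps). Gene lengths
(800–1600 bp), intergenic gaps (200–400 bp) and overlap widths (40–200 bp)
are drawn per seed; unit geometry is verified at generation time against
the brute-force scanner, so a planted class can never silently disagree
with its label.

Expression designs cycle `both_expressed / one_expressed / both_low`
across pairs (novel-pair genes are always expressed — they must produce
the coverage that reveals them); expressed genes target 300–800 RPM, low
genes 0–3 RPM. Cell patterns cycle through six per-pair combinations of
`sperm_only / vc_only / both_cells / silent`, with array signals drawn
log-normally around pattern means and ratios for Present/Present genes
kept in [0.5, 2.5], safely inside the > 3 boundary; one pair's second gene
is omitted from the array table to plant an `unknown`. sRNA designs cycle
`in_overlap / outside_overlap / none`, with in-overlap reads centered in
the overlap and outside reads kept ≥ 5 bp clear of every planted overlap.

Two regimes:

* **noise-free (default)** — read counts are `round(target_rpm ×
  library_size / 10⁶)` and read starts are tiled evenly over the true
  transcript span (novel-pair genes get enough reads that tiling spacing
  ≤ read_length/2, i.e. depth ≥ 2 across the span). Recovery of the
  planted truth is then exact for *any* seed, which is what the end-to-end
  tests and the acceptance script assert.
* **stochastic** (`noise_free=False`) — Poisson counts with uniform read
  placement, for calibration studies.

The generated reads carry their gene's strand and the emitted pipeline
config analyses them stranded. This is deliberate: with unstranded
coverage every planted antisense overlap would extend both genes through
each other (see above), turning sub-threshold decoys into spurious novel
pairs and making noise-free recovery ill-posed. The module default for
user data remains unstranded.

The truth manifest's expression flags and sRNA flags are *realized*: after
emitting reads the generator recomputes, with independent naive loops,
which genes clear RPM ≥ 1 against the annotated spans and which reads hit
which spans, so the manifest is consistent with the files byte for byte.

What the simulation does **not** model: splicing (reads are contiguous;
extension is contiguous-coverage only, so spliced UTRs would be
under-extended on real data), sequencing error and mapping bias,
multi-mapping, biological count overdispersion beyond Poisson, more than
one chromosome per dataset, and array probe effects (signals are drawn
directly from the pattern, not from probe models). Passing the recovery
tests therefore demonstrates the correctness of the decision logic, not
robustness to alignment noise on real libraries.

## Numerical and scale choices

* All thresholds are strict or inclusive exactly as the decision rules
  state: overlap qualifies at ≥ 22 bp, RPM at ≥ 1.0, the VC ratio at
  > 3.0; the orientation tie-break is `three_prime`; degenerate inputs
  (empty alignment sets, genes on chromosomes absent from coverage,
  zero-length extension budgets) all resolve to the zero/empty case rather
  than erroring.
* The default fixture (~100 genes, ~4000 reads) keeps the full test suite
  under a few seconds; the acceptance script's problem sizes (100 random
  genomes of ≤ 200 genes for scanner parity, 1000 random tracks for the
  extension oracle, 100 × 50 Poisson draws for gate calibration) were
  chosen as the package's own verification budget and complete in
  seconds.
* Gate calibration is evaluated at a library size of 10⁷ reads — the
  scale of a typical bulk RNA-seq library. This matters: at the RPM ≥ 1
  threshold the gate is equivalent to `count ≥ library_size/10⁶`, and the
  binary classification of genes 3× away from the threshold concentrates
  (> 99% correct) only once that count threshold is ≳ 10. The calibration
  samples counts directly from the Poisson model rather than materializing
  10⁷ alignment rows.

## Known limitations

* The containment-pair orientation convention (nearest ends) is a
  package convention; other tools may fold fully-overlapping pairs into a
  separate class entirely.
* Whole-locus read counting (introns included) inflates RPM for genes
  with long introns relative to exon-level counting; an exon span mode
  exists for the annotation but counting is locus-based.
* Boundary extension cannot cross assembly gaps or splice out introns,
  and with unstranded libraries it cannot distinguish a genuine UTR from
  antisense-partner signal; treat novel pairs from unstranded data as
  candidates for manual review.
* The sperm/VC rules depend on detection calls produced upstream
  (MAS5-style P/A/M); the package performs no array preprocessing.
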