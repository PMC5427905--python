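# Methods

## Coordinate model

Exons carry 1-based inclusive genomic coordinates on the plus strand (the
built-in hg19 VEGFA catalog ascends 5′→3′; a `strand` field exists for
generality). BED export converts to 0-based half-open. Several exon pairs
are genomically contiguous and together form one physical exon: 1a|1b,
6a|6b|6c, 7a|7b and the terminal 8a|8b. A junction `donor-acceptor` exists
only when an intron separates the two (acceptor start ≥ donor end + 2);
contiguous neighbours in a transcript chain yield read-through sequence, not
a junction. Exons 1B, 1C and 1D have no published start coordinate and are
omitted from the default catalog; user catalogs may add them.

## Junction probes

A probe is the last `flank` bases of the donor exon plus the first `flank`
bases of the acceptor (default `flank = 11`, 22 bases — long enough to be
unique in the transcriptome context, short enough to fit comfortably inside
a 100-base read). The flank is validated against exon lengths: exon 5
(30 bases) caps it at 30, exon 6b at 18 for the real catalog. Scanning is
exact, contiguous, case-insensitive substring matching against the read and
(by default) its reverse complement; reads containing `N` never match, and a
read contributes at most once per probe (tandem occurrences count once —
reads are counted, not occurrences). A documented mismatch-tolerant mode is
deliberately absent from the default path: exact matching is what makes the
probe route immune to the anchor artifact. Per-million normalization divides
by all reads scanned, including unmatched ones; paired mates are scanned and
counted as two independent reads.

## Shared terminal ambiguity and spliced assignment

For exons *a*, *b*, `shared_terminal_ambiguity` is the longest *s* with the
last *s* bases equal; it is computed from sequence, never assumed (the value
3 for 7b vs 8a is a property of the sequence, real or engineered). For a
junction whose acceptor is abutted genomically by another exon *x* (8a abuts
8b), a spliced placement with donor overhang ≤ `shared_suffix(donor, x)` is
exactly consistent with a contiguous read-through placement — the
misalignment artifact.

Assignment enumerates exact placements of a read (both orientations) in the
locus and in a set of annotation transcripts. A placement crossing a
junction of the selected junction set is a spliced candidate with recorded
donor/acceptor overhangs; all other placements are contiguous. Generating
spliced candidates from annotation transcripts is deliberate: the artifact
arises precisely in annotation-guided alignment, and including/excluding the
b-isoform models from the junction set mirrors including/excluding them from
a `genes.gtf`. Two policies:

* **naive** — accepts spliced candidates with donor overhang ≥ 1 (config-
  urable) and prefers annotated spliced placements over contiguous ones.
  This is a documented emulation of annotation-guided aligner behaviour, not
  a claim about any aligner's internals.
* **ambiguity_aware** — prefers contiguous placements; spliced candidates
  additionally require donor overhang ≥ shared suffix + 1 and acceptor
  overhang ≥ shared prefix + 1 (the acceptor side is handled symmetrically;
  the real artifact is donor-side, but symmetry costs nothing).

Ties between surviving junctions yield the verdict `ambiguous`, never an
arbitrary choice; output ordering is deterministic (by read id). Raising the
minimum overhang can only shrink junction counts. The artifact flag on a
junction assignment is donor-side (overhang ≤ shared suffix), matching the
phenomenon being reproduced; an acceptor-side analogue exists (a read ending
one base into an exon whose first base coincides with the annotated
acceptor's first base can be pulled to the annotated junction under the
naive policy) and is resolved contiguously by the aware policy, but is not
flagged. The audit table reports the full overhang histogram of flagged
assignments rather than assuming they all sit at the maximum ambiguity.

Placement matching is exact (no mismatches, no indels): this isolates the
ambiguity phenomenon from alignment-scoring details. A general spliced
aligner is explicitly out of scope.

## Synthetic data

The toy locus mirrors the VEGFA architecture at ~1/6 scale (total span
2,725 bases): the same 14 exons in the same order and contiguity structure,
exon lengths 24–80 bases except exon 8b (120 bases — kept long because it is
the read-through tail whose real length is 1,880 and acceptor-side overhangs
up to read length − 1 must fit inside it), introns 100–400 bases. Exon 5
keeps its real 30 bases since it caps the probe flank. The generator
rejection-samples (bounded attempts, seeded `numpy` generator, no
hash-order dependence) until:

* the 7b/8a shared terminal suffix equals the requested value **exactly**
  (default 3; configurable, including 0 to switch the artifact off);
* every default probe occurs exactly at its cognate junction and nowhere
  else — on either strand, in the locus or any canonical/b transcript — with
  a Hamming margin ≥ 2, so a single substitution error can never forge a
  probe hit (a property the real locus has that a short random sequence
  would not reliably have);
* no other exon pair shares a terminal suffix as long as the flank.

Transcript models: six canonical chains (VEGFA_121/145/148/165/183/189),
all ending in the contiguous read-through exon 8 (8a+8b), and two b-isoform
chains (VEGFA_121b/165b) splicing directly into 8b. Chain composition
follows the standard isoform architecture (identical for the junctions under
study; interior exon-6 content differs between sources and is immaterial
here).

Reads are drawn by weighted transcript choice, uniform start, random strand
and i.i.d. substitution errors (no indels: the exact-match analyses are
substitution-sensitive, and indel simulation would conflate scanner misses
with simulator artifacts; no PCR-duplicate, GC or quality modelling).
Paired mode emits mates from opposite fragment ends into `/1`–`/2` records
counted as two reads. Every read has exactly one truth record listing the
junctions it spans with per-side overhangs, which is what makes exact
cross-module equality checks possible (probe counts = truth counts =
wide-overhang assignments at error rate 0). Amplicon pools apportion reads
to templates by largest remainder, so truth proportions are exact by
construction. What the toy locus does **not** emulate: expression-level
biases, intron retention, sequencing quality decay — so passing tests
demonstrate the correctness of the counting logic and the artifact
mechanism, not performance on real libraries.

## Amplicon analysis

In-silico PCR locates the forward primer as-is and the reverse primer as its
reverse complement (reverse primers are specified 5′→3′ on the antisense
strand); the product spans both footprints inclusively, and priming must be
unique (multiple sites raise an error listing them). Primer matching is
exact — no thermodynamics, no mismatch tolerance. On real hg19 sequence the
printed primer pairs give 235 bp (7b-8a), 169 bp (7b-8b) and 115 bp
(universal exon 4/5) products; on the toy locus the canonical−b difference
is exactly the 66-base exon 8a, the same structural signature.
Classification assigns a read to the unique junction whose probe it contains
(either strand); multi-probe reads are `ambiguous`, probe-free reads
`unclassified`; classes are conserved and percentages reported to two
decimals. Simulations standardize on 50,000-read pools, the scale of the
per-tissue RT-PCR sequencing.

## Detection limits, ratios, correlation

`one_read_proportion(n) = 100/n` is the headline "what one read would have
meant" statistic; report text rounds it to one significant figure (0.002%
for the 50,230 pooled canonical reads, 0.06% for the 1,807 per-tissue mean —
the per-tissue mean is treated as a given input, since its derivation from
per-sample tables is not reconstructible). It is not a confidence bound, so
the exact zero-observation bound `p = 1 − (1−confidence)^(1/n)` (and the
rule-of-three `3/n` it converges to) is computed alongside and labeled as
such. Isoform ratios are `count(5-8a)/count(7b-8a)` per sample; samples with
a zero denominator are excluded with a log entry. Cross-dataset agreement is
the squared Pearson correlation of per-tissue ratio pairs (scipy), defined
for ≥ 3 points with nonzero variance. Reports are deterministic; Table-style
rows show clean counts with artifact counts bracketed (`0 (24)` style), and
TSVs keep full precision.

## Problem sizes and defaults in the test/acceptance suite

Property checks run at the scale where their statistical contracts are
sharp: 200,000-read mixtures for the specificity/spike-in checks (a 0.1%
spike among junction-spanning reads yields ~30 expected probe hits,
comfortably detectable and testable within 3 binomial SD), 10,000–15,000
reads for assignment and cross-module equality, 50,000-read amplicon pools,
14 tissues × 2,000 junction-spanning reads × 20 replicates for the ratio
R² recovery (median R² ≈ 0.99 > 0.8). All randomness flows through
explicit integer seeds.

## Known limitations

* No BAM/spliced-alignment parsing: raw reads and SJ tables cover both
  quantification routes; BAM support would be additive.
* No GTF/GFF parsing; exon catalogs are the package's own tab format.
* The SJ parser ignores strand/motif codes by design (fixture writers emit
  defaults); only coordinates and unique counts are interpreted.
* Mismatch-tolerant scanning and primer matching are intentionally absent
  from default paths; the analyses modeled are exact-match by construction.
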