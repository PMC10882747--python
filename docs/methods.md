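# Methods

## Model and procedure

`nrskit` treats a pangenome graph as a labeled sequence graph: rGFA
segments carry origin tags (`SN` source name, `SO` 0-based source offset,
`SR` rank), and each assembly is represented as an ordered walk of
*bubbles* — (chromosome, reference interval, oriented segment path)
triples modelled on minigraph's per-genome call output. The backbone
assembly's walk tiles the reference with rank-0 segments in coordinate
order.

**Labeling.** Initial labels come from rank (0 = reference, > 0 =
non-reference). Walk evidence then demotes nodes to *skeptical* under any
of: (a) visited by no walk of any assembly, (b) rank 0 but never visited
by the backbone walk, (c) rank > 0 but visited by the backbone walk.
Rule (c) operationalizes "inconsistent labelling" with the only evidence
available from rank tags plus paths; it is exposed as a switch
(`strict_backbone_consistency`) because a graph producer could in
principle route the backbone through a rank>0 node legitimately.
Orientation does not matter for visitation. Bubbles containing a
skeptical node are excluded from candidate extraction wholesale — the
conservative reading of "excluded from the analysis".

**Extraction.** A candidate NRS is a bubble whose oriented path differs
from the backbone path over the same interval; reverse-orientation steps
contribute reverse-complemented sequence. Identical (chromosome,
interval, path) candidates merge across assemblies, accumulating
supporters. The four retention criteria are strict inequalities: length
> `min_nrs_bp` (500) and NRN fraction > `min_nrn_fraction` (0.5), plus
≥ 1 NRN and ≥ 1 supporter.

**Screens.** Redundancy removal sweeps records in descending length
(ties broken lexicographically by id) and marks a record redundant when it
matches an already-retained record at identity ≥ 0.90 and coverage ≥ 0.90
— retaining the longer of a matching pair. Identity is matches over
alignment columns (gaps included); coverage is the aligned span over the
*shorter* sequence for redundancy and over the NRS itself for the
reference screen (the NRS is always the shorter side there). Both choices
follow common BLAST-style usage; the coverage denominator is exposed as a
documented convention rather than a switch because every decision in the
pipeline composes with it. Reverse-complement matches count in both
screens.

**Alignment engine.** The screens need threshold decisions, not scores,
so the engine is exact 15-mer seeding, diagonal-band chaining (band 32,
adjacent bands merged), and unit-cost alignment of the chained windows
(±30 bp pad) with edlib in infix mode. Pairs sharing no 15-mer score
(0, 0) — for i.i.d. random sequences the expected number of shared
15-mers between two 1 kb sequences is ≈ 10⁶/4¹⁵ ≈ 10⁻³, so unrelated
pairs almost never reach the aligner. The test suite validates the
accept/reject decisions against full Smith–Waterman dynamic programming
(biotite, match +1 / mismatch −2 / gap −2,−1) on identical inputs; the
engine is not a scoring-compatible BLAST reimplementation.

**Classification and anchoring.** cNRS iff the path contains no
reference-labeled node. The anchor is the left breakpoint of the bubble's
reference interval, i.e. deletions of reference sequence inside a pNRS
bubble do not shift the anchor; 1-based coordinates appear only in FASTA
headers and reports. Genomic context classifies the anchor point with
priority CDS > UTR > intron > intergenic, where "intron" means inside a
gene body with no CDS/UTR hit — a breakpoint in a non-coding exon portion
not annotated as UTR would also classify as intron, which is the right
call for the synthetic annotation (exons = CDS ∪ UTR exactly) and a
documented approximation otherwise.

**PAV.** Breadth is the measure of the union of alignment intervals over
the NRS body divided by body length; the 100 bp flanks used as mapping
targets are excluded from both numerator and denominator. Alignment
records with MAPQ < 10 are discarded before profiles are built. Presence
requires breadth > 0.70 (strict). Frequency categories resolve the
published overlapping ranges into a true partition: core f > 0.99,
softcore 0.90 ≤ f ≤ 0.99, shell 0.01 ≤ f < 0.90, cloud 0 < f < 0.01,
skeptical f = 0. PCA mean-centres columns without scaling (booleans share
a scale) and eigendecomposes the sample Gram matrix X_c X_cᵀ/(n−1);
scores equal U·S of the SVD and eigenvalues sum to total column variance.

**Group tests.** The two-sided Fisher p-value uses the probability-mass
convention (sum over tables with the observed margins whose probability
does not exceed the observed table's). It is computed with exact integer
hypergeometric weights C(n₁,x)·C(n₂,k−x) cached per margin triple: the
p-value is one integer ratio, so ties are resolved exactly and the result
is exact to one float rounding. This is numerically stronger than
log-space summation and is what makes the 10⁻¹² oracle agreement in the
tests meaningful. Bonferroni multiplies by the number of NRSs actually
tested (after skeptical removal), capped at 1; significance at adjusted
*P* < 0.01. Equal group frequencies report direction "tie", never a
silently assigned side.

## Synthetic data: what it emulates, and what it does not

The generator plants `n_insertions` insertions (default 12) on a uniform
random genome (default 2 × 100 kb) across 4 assemblies, with lengths from
a mixture straddling the 500 bp cutoff (30% in 300–490, 45% in 520–1500,
25% in 1500–3500) and a 35% chance of embedding a reference-derived
segment whose share puts the NRN fraction in 0.30–0.70, straddling the
50% criterion. Decoys exercise the funnel: one near-duplicate (shorter,
~2% diverged copy of a planted insertion) and one verbatim reference copy
per dataset, plus one orphan node that labeling must call skeptical.
Coverage simulation gives 150 samples (75 + 75) at 21× with 150 bp reads:
carriers get Poisson-tiled read intervals over the insertion body;
non-carriers get at most half a read length of flank spill per end, so
their breadth is bounded below 0.70 by construction for insertions
≥ 300 bp. Two retainable insertions get group-differential carrier
frequencies (0.10 vs 0.70 and 0.80 vs 0.20); all others share one
frequency across groups. About 10% of sample–insertion pairs receive one
MAPQ < 10 interval that the quality screen must drop.

Deliberately absent: repeats and segmental duplication (uniform DNA keeps
the alignment screens unambiguous), sequencing error and read-level
artefacts, SV types other than insertion (deletion walks parse but are
not planted), GC or mappability bias, and linkage between insertions.
Passing tests therefore demonstrate the correctness of the pipeline's
logic and calibration of its thresholds under clean separation — not
robustness to repeat-induced ambiguity, which in real data is handled
upstream by the aligner and by repeat annotation outside this scope.

Problem sizes used by the default test and acceptance runs (2 × 100 kb
genome, 12 + 2 planted insertions, 150 samples, 20 generator seeds) were
chosen so every stage's behaviour is exercised — both sides of every
threshold, every funnel branch, both PAV call outcomes, planted positives
and nulls in the group contrast — while a complete run stays in the
seconds range.

## Numerical choices

- All internal coordinates are 0-based half-open; rGFA `SO` is read as
  0-based per the format definition.
- Strict vs inclusive thresholds follow the wording they implement:
  "greater than 500 bp", "over 50%", "more than 70%", "more than 99%" are
  strict; the 90%/90% screen thresholds are inclusive (≥).
- Greedy redundancy order is descending length with lexicographic id
  tie-break, making byte-identical pairs deterministic ("first id wins").
- `fisher_exact_two_sided` requires positive row margins; an all-zero
  column never reaches it because skeptical NRSs are excluded first.
- PCA eigenvalues are clipped at 0 (Gram eigenvalues are non-negative up
  to rounding) and reported non-increasing.
- Breadth of an empty interval set is 0; an interval exceeding the NRS
  body is an error rather than a silent clip, because the generator and
  any upstream converter are required to pre-trim flank alignments.

## Known limitations

- The walk TSV is this package's own dialect (the upstream caller's
  on-disk schema is not standardized); a converter from minigraph call
  BED is an explicit extension point in `graphio`.
- The seed-and-extend screen can under-call redundancy between sequences
  whose homology is fragmented by indels larger than the chaining band;
  at the divergence levels the screens target (≥ 90% identity) this does
  not occur.
- Genomic-context classification is point-based (the anchor breakpoint),
  not span-based; an NRS whose bubble replaces a long reference interval
  is classified by its left breakpoint only.
- GO/KEGG/QTL enrichment of overlapped genes is out of scope (external
  databases); the pipeline stops at the gene list.
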