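# Methods

## The data model

A mate-pair full-length cDNA tag is a linked pair of sequence tags from the
two ends of one circularised cDNA: the 5' tag marks the base where
transcription started (recognisable because cap replacement leaves the
adaptor signature `CTGCTGCC` at the junction), the 3' tag marks either the
cleavage/poly(A) base (a poly(A)/(T) run at the junction) or, in the
TSS/Random protocol, a random internal position (`CTGCTGGG`).  All
coordinates inside the package are 0-based half-open; a PAS tag's position
is the last transcribed base and its strand is the transcript strand.

Aligned tags are exchanged through the `ENDPAIR v1` TSV dialect
(`library_id, chrom5, pos5, strand5, mapq5, chrom3, pos3, strand3, mapq3,
end3_kind, blocks3_sizes, blocks3_starts`).  At load, rows with mapq < 10
on either end are dropped (configurable); the stricter mapq > 37 rule is
applied only where it matters, in fusion calling.

## End clustering and the ppm screen

TSS and PAS tags are clustered independently on a fixed strand-specific
genomic grid of 500-bp bins.  The fixed grid (rather than greedy merging)
is deterministic and order-independent; its cost — a cluster straddling a
grid boundary is split in two — is accepted and documented.  The
representative position of a cluster is its modal tag position, ties broken
toward the smaller coordinate.

Expression is counts per million mapped pairs of the library (ppm).  The
noise screen keeps clusters exceeding 5 ppm in *at least one* library
(libraries were prepared independently, so evidence in any one suffices).
**Scale caveat:** ppm thresholds are calibrated for deep libraries (the
protocol produces >10⁷ pairs per library, where 5 ppm ≈ 50 tags).  At
desk-scale simulated depths (10⁴–10⁵ pairs) a single tag can exceed 5 ppm
and the screen loses its noise-rejection power; tests that depend on the
screen's logic therefore either use pooled-count thresholds (pairing,
fusions) or evaluate the Poisson significance directly.

Cluster concentration is tested against uniform scatter on the mature mRNA:
with N same-kind tags on a transcript of mature length L, the count in a
window of min(w, L) bp is Poisson with mean `lam = N·min(w, L)/L`, and the
cluster's p-value is the upper tail P(X ≥ k).  L is the exon-length sum,
not the genomic span, because the tags derive from the mRNA.  Note the
structural limit: when L is close to the bin width the window contains the
whole transcript (lam → N) and no concentration is detectable — transcripts
must exceed the bin several-fold for the screen to be informative.

## Cluster-gene association

A TSC is linked to a gene when its bin overlaps the 50-kb window upstream
of the annotated 5' end or the first exon; a PAC symmetrically downstream /
last exon.  Any bin overlap qualifies; signed distances are measured from
the representative position.  Hits in internal exons are returned but
flagged excluded — internal tags are dominated by truncation and internal
priming artifacts.  A cluster may link to several genes.

## Sequence scans

Scans run on the transcript (sense) strand in windows relative to the
representative position (0 = rep, negative = upstream):

- poly(A) signal: perfect `AATAAA` in [−40, 0); the window covers the
  canonical signal placement ~10–35 nt upstream of cleavage.
- internal-priming risk: ≥ 6 consecutive genomic `A` in (0, +20] — a
  downstream A-stretch lets oligo-dT prime internally and fake a PAS.
- TATA box: IUPAC consensus `TATAWAWR` fully inside [−40, −20).  The
  licence-restricted TRANSFAC matrices are deliberately not used; a
  user-supplied matcher callable can replace the consensus.

All windows are configurable; none is fixed by the protocol itself.

## Pairing statistics

For each gene, pairs whose 5' end falls in a linked TSC and whose 3' end
falls in a linked PAC are cross-tabulated into a matrix `o_ij` (pooled over
libraries; per-library counts retained).  Deviation from independent end
selection is scored per cell with the Poisson upper tail at the contingency
expectation `e_ij = T_i·P_j/N`.  This is the natural "random selection"
null stated explicitly so results are reproducible.  Two consequences are
worth knowing:

1. A 1×1 matrix has no alternative pairing; its p-value is 1 by convention.
2. Conditioning on estimated margins makes the test *conservative*: the
   null variance of `o_ij − e_ij` is ≈ `e_ij(1 − T_i/N)(1 − P_j/N)`, not
   `e_ij`.  With 1–3 units per end and a dominant primary unit, the actual
   size at nominal α = 0.05 is well below 1% (measured ≈ 0.3% in
   simulation).  The preferred-pair selection uses the p-value only as one
   of four filters, so this conservatism costs little recall, but the raw
   flag rate under the null should not be expected to reach 5%.

A cell is a **preferred** pair iff all of: pooled ppm > 5 and o > 10 (both
strict); p < 0.05; strict row and column maximum (ties disqualify, for
determinism); and o exceeds half the tags of its TSC or of its PAC.  The
ppm criterion is applied to the pair (pooled count over pooled library
totals); whether the protocol's screen applied it to pair, TSC or PAC is
ambiguous, and the pair is the strictest consistent reading.

Raw p-values are used (the original screen combines p < 0.05 with share and
mutuality filters rather than multiplicity adjustment); Benjamini-Hochberg
is available in `geneset_enrichment` and could be applied to pair p-values
by the caller.

Unit spans (TSC rep → PAC rep) are compared with the Jaccard fraction
|a∩b|/|a∪b| — symmetric and bounded; an overlap/shorter-unit variant is
available by flag.

## Tissue specificity

`z = (x − μ)/σ` with `x = log2(ppm + 1)` across the 18 libraries, using
population moments, so mean(z) = 0 and sd(z) = 1 exactly whenever σ > 0;
σ below 1e−12 (relative) is treated as a constant unit, z ≡ 0.  The 1-ppm
pseudocount keeps zero-count libraries finite.  Switching between two units
is reported as tissue pairs (t₁, t₂) with z₁(t₁) > 2 and z₂(t₂) > 2.

## Connected units and fusions

A TSC of gene A paired with a PAC of a distinct gene B is a *connected*
unit (read-through) when both genes share chromosome and strand, B's 5'
end lies 0–3 Mb downstream of A's 3' end in transcription orientation, and
the pooled pair expression exceeds 5 ppm.  Beyond 3 Mb, on different
chromosomes, or on opposite strands (which requires a rearrangement at any
distance) the pair is a *fusion candidate*, additionally requiring every
supporting tag to have mapq > 37.  Fusion ppm uses pooled counts over
pooled library totals — support concentrated in one cell line is what
matters, and pooling is the conservative denominator.  At desk-scale depth
with skewed expression, 1% chimeric ligation can push highly expressed
distant gene pairs over the pooled 5-ppm line; the default synthetic world
therefore produces chimeric fusion calls alongside the planted ones, which
mirrors the known chimera caveat of the protocol rather than a detector
defect (at matched real depths the same rate stays far below threshold only
for near-uniform expression).

## Tag assembly

Between a TSC and a PAC, a coordinate covered by ≥ 1 aligned tag block is
`transcript`; a coordinate inside the gap of ≥ 1 split tag is `intron`;
direct coverage wins when both apply (coverage is stronger evidence than a
gap).  Integrity is the labeled fraction of the region; maximal transcript
runs are reported as exons (BED12).  Integrity is monotone non-decreasing
in added tags by construction.  Assembly is per TSC-PAC pair, so
alternative-promoter products are assembled separately.  Split tags are not
required to show canonical splice motifs.

## The synthetic world

Defaults (all overridable on `SimConfig`):

| parameter | default | why |
|---|---|---|
| libraries | 18 (14 tissues + 4 cancer lines) | the study design being emulated |
| genes | 200 on 2 chromosomes | two chromosomes make inter-chromosomal fusions plantable |
| mature mRNA length | U(500, 5000) nt | realistic span; note the short-transcript screening limit above |
| exons per gene | 1–8, introns U(200, 2000) | typical compact loci |
| intergenic gap | U(60, 100) kb | keeps the 50-kb windows of neighbours disjoint |
| alternative TSC / PAC probability | 0.25 / 0.20 | minority of genes with 2–3 units, primary unit dominant (0.6–0.65 share) |
| coupling share *s* | 0.9 | strong preferred pairing for planted genes |
| expression | log2-normal: gene sd 1.5, per-library sd 0.5 | wide dynamic range plus tissue scatter |
| depth | 100,000 pairs/library | scaled-down from >10⁷ (runtime); ppm caveat above |
| truncation / internal priming / chimera | 5% / 5% / 1% | the three protocol noise sources |
| poly(A)-signal planting | 72% of PASs | observed canonical-signal frequency |
| dR fractions | 0.5–1, 1–2, 2–5 kb | gel-cut size fractions; uniform insert inside the fraction stands in for the unknown gel profile |

Internal-priming events are emitted only at positions where the synthetic
genome carries a planted A-run, so the QC scan can find exactly the noise
the generator injected.  Tissue-switching unit pairs are planted as a
gene-level boost in two tissues plus a swap of the two units' usage shares
between them; a share boost alone cannot move the dominant unit's log2 ppm
far enough to reach z > 2, because its baseline share is already near 1.
Identical config and seed give byte-identical outputs (all randomness flows
from one seed sequence with fixed spawn order).

What the generator does *not* emulate: base-level sequencing errors, PCR
duplicates, GC bias, mappability structure, overlapping genes, and real
gel size-selection profiles.  A green test on synthetic data therefore
establishes the correctness of the statistical and interval logic under
the stated model, not robustness to alignment artifacts.

Structural consequence of the dR size fractions: mRNA positions closer to
the TSS than (smallest fraction bound − tag length) ≈ 400 nt are never
covered by a random tag, so realistic simulated assemblies plateau around
integrity 0.8–0.95; the assembly logic itself is validated separately with
exhaustive deterministic tilings (`exhaustive_random_tags`), which recover
exon/intron structure base-exactly at integrity 1.0.

## Numerical choices

- Poisson and hypergeometric tails via scipy's survival functions; tests
  verify ≤ 1e−9 relative agreement with independent term-wise summation /
  exact rational oracles.
- Ties: modal cluster position → smallest coordinate; fold-density argmax →
  smallest coordinate; equal row/column maxima → no preferred pair.
- Fold density: per-bin mass normalised by track total, fold =
  (ip + ε)/(input + ε) with ε = 1e−9, bin 50 bp (neither fixed by the
  protocol; ε keeps empty input bins finite and preserves scale
  invariance to < 1e−9).
- Degenerate inputs: empty tag list clusters to an empty list; zero-length
  unit spans and empty assembly regions raise; σ = 0 expression gives z ≡ 0.

## Known limitations

- Fixed-grid clustering splits boundary-straddling clusters.
- The independence test is conservative (margin conditioning, above).
- ppm thresholds lose meaning at scaled-down depths.
- No isoform deconvolution when splice variants share one TSC-PAC region;
  split-tag coverage limits intron recovery near the TSS in size-selected
  random libraries.
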