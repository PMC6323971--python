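# Methods

## Coordinate model

All intervals are 0-based half-open. GTF input (1-based inclusive) is
converted on read; BED input is used natively. Transcript coordinates
always run 5′→3′: for minus-strand transcripts, transcript offset 0 is
the rightmost genomic exonic base. This makes ORF scanning, P-site
arithmetic and quantification strand-free, and confines every strand
flip to two functions (`genome_to_transcript` / `transcript_to_genome`),
which are verified as mutual inverses on every exonic base of randomly
generated multi-exon models.

Two GTF dialects are supported. Gencode-style annotation excludes the
stop codon from CDS records and carries it as a separate `stop_codon`
feature; the `gencode` dialect (default) appends it so that the internal
CDS span is the full annotated ORF, stop included. The `generic` dialect
uses CDS lines as-is. A transcript whose merged CDS spliced length is
not a positive multiple of 3 keeps its exon structure but loses the CDS,
with a logged warning — it then participates only as an unannotated
transcript.

## ORF enumeration and categorization

An ORF is any AUG paired with its nearest downstream in-frame stop
(UAA/UAG/UGA), scanned on the spliced transcript sequence. The scanner
indexes stop positions per frame once and resolves each AUG by
bisection; it is checked against a quadratic all-pairs reference
enumeration on random sequences. Conventions:

- **Length includes the stop codon** (start of AUG through end of stop).
  The 300 nt sORF threshold is applied to this inclusive length; the
  threshold and the minimum length (6 nt = AUG + stop) are parameters.
- AUGs with no downstream in-frame stop on the transcript are discarded
  rather than truncated at the transcript end.
- Codons containing N never match AUG or a stop — conservative, so
  ambiguity never fabricates an ORF.

Categories are assigned per isoform against the transcript's own CDS
(the aORF), not a gene-level consensus, by a fixed-order cascade: no
CDS → *unannotated*; identical interval → *annotated*; same stop
codon → *truncated*/*extended* by start side; any ≥ 1 nt overlap (at
this point necessarily not sharing the stop, i.e. off-frame or
different-stop) → *internal*; else *uORF*/*dORF* by side. The order
makes the seven categories a partition, and places in-frame ORFs lying
wholly upstream of the aORF without sharing its stop in *uORF*. Because
a shared interval end forces a shared frame, *truncated*/*extended*
ORFs are always in the aORF's frame.

## P-site inference and tracks

For each annotated start codon at transcript position *s*, reads whose
5′ end lies within a window upstream of (or on) *s* contribute the
distance *d = s − five_prime*. The offset for read length *L* is the
mode of *d* restricted to 0 ≤ *d* < *L*; ties break toward the smaller
offset so the statistic is deterministic. Defaults: window = 40 nt,
minimum support = 10 reads per length; both are parameters, chosen as
ordinary metagene settings rather than claims about any particular
published pipeline. The mode is robust to a minority of off-peak reads,
which is what the noise-recovery tests exercise (exact recovery under
20% uniform positional noise).

Track construction adds one count at `five_prime + offset(L)` per read;
reads of lengths without an offset entry, or whose P-site would fall
past the 3′ end, are dropped and counted in the log, so the invariant
*track mass = retained read count* is exact, not approximate.

Genomic SAM/BAM alignments are converted to transcript space via the
coordinate maps: a read must be fully exonic in an isoform to count for
it (spliced reads must match the isoform's introns), and its transcript
5′ end is the minimum transcript coordinate of its aligned bases —
which is the genomic leftmost base on + strand isoforms and the
rightmost on − strand. Reads compatible with several isoforms
contribute to each.

Denoising of footprint signal is out of scope: tracks carry a `source`
tag (`raw`/`psite`/`denoised`) and an externally denoised track is
quantified identically to a raw one.

## Quantification

RPKM = count / (length/10³ × library/10⁶), with the library size defined
as the total mass of the respective track set or count table (not raw
sequencing depth). TE = Ribo RPKM / RNA RPKM, NA exactly when the RNA
RPKM is zero (never 0 or ∞). Density = P-site count in [start, end) /
ORF length. A Ribo-seq read counts toward an ORF iff its P-site falls in
the ORF interval — the convention the track construction itself implies.
RNA abundance enters as user-supplied per-transcript counts (the
denominator is transcript-level RPKM); upstream RNA-seq estimation is
out of scope. No pseudocounts by default; an additive pseudocount flag
exists for exploration and is off in all tests.

## Hotspots, elements, intersections

The "precursor" binned by hotspot profiles is the full unspliced gene
span, introns included, because the profile annotates pre-mRNA; bin *k*
covers precursor offsets [20·k, 20·k+20) anchored at the gene's 5′ end
in transcription orientation, final partial bin retained. A bin's count
is the number of distinct RBP names (methods and samples pooled; a flag
switches to (rbp, sample) keys) with a site overlapping the bin by
≥ 1 nt — so duplicated peak records are idempotent by construction.

Element assignment uses a priority list over the elements a site
overlaps across all isoforms, default CDS > 3′UTR > 5′UTR > lncRNA_exon
> other_exon > intron > intergenic; the list is configurable since
mutually exclusive genomic fractions require *some* deterministic rule.
Intersections are tree-based, half-open (abutting intervals do not
pair), with zero-length point features widened to 1 nt; the result is
checked against a quadratic all-vs-all reference.

## Read filters

Quality: a read passes iff strictly more than Q20 in at least 80% of its
bases — "above" is read as strict, "in 80%" as non-strict; both
thresholds are parameters because either inequality sense is defensible.
Length: reads < 13 nt are discarded. Collapse: exact-sequence identity
only (no UMI handling); the representative keeps the first occurrence's
id and qualities and first-occurrence order is preserved. All three are
idempotent and order-independent, which the suite asserts.

## Synthetic data generator

`ribostar.fixtures` emulates the *data model* of a Ribo-seq/CLIP-seq
study, not its error processes: no sequencing errors, fixed read
lengths, single-chromosome genome, uniform base composition. Passing
tests therefore certify the algorithms and conventions above — not
robustness to mapping artifacts, biased nucleotide composition or real
library-preparation noise.

Ground truth is recorded by deliberately naive reference routines that
share no code with the production paths: quadratic ORF enumeration, a
standalone interval categorizer, per-base distinct-RBP unions. One
hand-designed coding transcript plants all ORF categories relative to
its CDS (uORF in the 5′UTR, in-frame upstream start with no intervening
stop → extended, in-frame internal start → truncated, off-frame
start/stop pair inside the CDS → internal, dORF in the 3′UTR, ~170 nt
CDS); a designed non-coding transcript supplies the unannotated class;
remaining transcripts are random with the longest suitable ORF annotated
as CDS for a coding fraction of them.

Generator defaults (all `FixtureSpec` parameters): 12 transcripts of
300–1500 nt, 70% coding, P-site offsets {28→12, 29→13}, 5% uniform
positional noise, 10,000 footprints, 200 binding sites from 12 RBPs,
10,000 FASTQ reads of 10–40 nt with a geometric-tailed duplication
spectrum. Footprint depth per ORF is proportional to TE × RNA level ×
ORF length, with the first coding transcript simulated at TE 2.0 against
a baseline of 1.0 so the TE contrast is recoverable to within binomial
sampling error at this depth. A 10% initiation-peak fraction places
P-sites exactly on the start codon: real ribosome profiling shows strong
initiation enrichment there, and it is this pileup that makes the
per-length metagene mode identifiable — under purely uniform elongation
coverage the distance distribution is flat across in-frame positions
and the mode (hence the offset) would be arbitrary. RNA counts are
emitted at their expectation (proportional to transcript length × RNA
level) rather than resampled, so TE comparisons carry only footprint
sampling noise. All randomness flows through one explicit
`random.Random(seed)` stream per artifact; no hash-order-dependent
iteration is used, so equal seeds give byte-identical files across
platforms and processes.

## Problem sizes in the checks

The bundled verification runs use 1,000 random sequences of 30–3,000 nt
for the scanner/oracle comparison, 100 (tests) or 50 (acceptance
script) simulated replicates for offset recovery, 10⁴ footprints for TE
recovery, 50 random site sets of 200 peaks × 12 RBPs for hotspot
agreement, and 10³ × 10³ records for intersection agreement — sizes at
which the brute-force references remain exact and fast while binomial
sampling error stays well inside the stated recovery tolerances.

## Known limitations

- One CDS per transcript; polycistronic annotation and GFF3 are not
  supported.
- AUG-only starts; near-cognate initiation is out of scope, as are
  translated-ORF calling (3-nt periodicity tests), peak calling, motif
  discovery and genome-build liftover.
- Whether the 300 nt sORF threshold should count the stop codon is an
  annotation-convention choice; it is a single exposed parameter rather
  than a hard-coded truth.
- Multi-isoform read assignment duplicates a read into every compatible
  isoform; no probabilistic assignment is attempted.
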