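# Methods

## Coordinate conventions

All coordinates are 0-based, half-open `[start, end)`. The CDS interval
includes the stop codon, so the stop codon's first nucleotide is
`cds_end − 3`; frame analyses can exclude the final codon via
`frame_distribution(..., include_stop=False)`. Annotations with a CDS
length not divisible by 3 load with a warning, not an error — real
transcriptome annotations contain such cases — and frame is always
`(pos − cds_start) mod 3`. SAM `POS` is 1-based in files and converted
to 0-based on ingest. FASTA records are matched to transcripts by the
token before the first whitespace, case-sensitively.

## Ingestion

Footprint length is the reference span of the alignment (sum of
M/D/N/=/X CIGAR operations), not the SEQ length, so soft-clipped
untemplated additions do not perturb occupancy. Filters run in a fixed
order — unmapped, secondary/supplementary, reverse strand, length
outside the tracked range (default [15, 40]), unknown reference name,
out of transcript bounds — and the first failure is the one counted,
making the filtering statistics deterministic. `accepted` is the
"total mapped and filtered reads" that all CPM normalization divides
by. Secondary and supplementary alignments are dropped so a
multi-mapping read contributes exactly one primary record.

Region assignment and metagene accumulation both use the footprint's
**5′ end**. Metagene windows (default radius 50 nt) that extend beyond
a short transcript simply receive no counts from it; there is no
transcript-level exclusion, which keeps the conservation identity
"region totals per length = accepted reads per length" exact. P-site
corrected re-analysis is available downstream from the stored
per-length coverage.

## The store

HDF5 layout: `/reference/{names,lengths,cds_start,cds_end}` plus a
SHA-256 digest over those tables (the identity check for
cross-experiment comparison; attaching sequences never changes it), and
`/experiments/<name>/{region_counts,metagene_start,metagene_stop}` with
optional `coverage/len_<L>/{indptr,positions,values}` (CSR-style rows
per transcript). All integers are 64-bit with shuffle + deflate; the
region axis order (UTR5, CDS, UTR3) is written as a file attribute so
files are self-describing. Writes go to a temporary sibling file and
are renamed into place, so an interrupted write leaves nothing at the
target path. Opening a store checks shapes only; deep validation
(coverage monotonicity, non-negativity) is behind a flag. Coverage
datasets are read only when explicitly requested, so opening and
attribute access stay fast regardless of store size. This schema is
this package's own dialect; it is not read/write compatible with other
hierarchical ribo-seq containers.

## P-site offset detection

The detector reads the start-codon metagene. For each length L,
candidates are `o ∈ search ∩ [1, L−1]` (default search [3, 18], wide
enough to bracket published offsets of ~11–15 nt with slack);
`score(o) = metagene_start[L, −o]`, the number of 5′ ends exactly o nt
upstream of a start codon. The argmax is the offset; ties break toward
the smaller o (deterministic, biased toward the canonical ~12 nt
geometry). `support` is the summed score over the candidate window;
below `min_count` (default 10) the call falls back to a constant
default (12 nt, clamped below L) with `confident = False` rather than
interpolating from neighbouring lengths — simpler, and the flag lets
reports warn. This rule is a replacement for, not a reconstruction of,
any particular published detector: it assumes the initiation pile-up at
the start codon that real libraries show. Applying offsets shifts
5′-end coverage by `offset(L)`; shifted positions at or beyond the
transcript end go to a reported `clipped` tally so that input mass
always equals output plus clipped. Under the package's own invariants
(offset < L, reads inside the transcript) clipping cannot actually
occur; the tally is a defensive conservation check for hand-edited
offset tables or coverage.

## Comparison

"Gene-level" counts are transcript-level CDS footprint counts over a
selected length range (ribo-seq references conventionally carry one
isoform per gene); an optional transcript→gene map collapses rows by
summation. Spearman rho is computed as average ranks followed by
Pearson on the ranks; zero-variance columns yield explicit NaN entries
with a warning, never a silent 0. The scatter view reports rho on raw
counts, which equals rho on `log10(count + 1)` because the transform is
strictly monotone.

## The simulator

The generator emulates a small monosome ribo-seq library and is the
source of every test fixture. Defaults: 50 transcripts with lengths
uniform on [300, 1200] nt; 5′UTR/3′UTR fractions 0.15/0.25 with the CDS
rounded down to a codon boundary (real transcripts have shorter 5′ than
3′ UTRs); footprint lengths 26–32 nt with a unimodal weight profile
peaked at 28 nt; planted offsets {26:11, 27:11, 28:12, 29:12, 30:13,
31:13, 32:14}; `in_frame_prob = 0.9`; `noise_prob = 0.1` with
background positions uniform over all transcript nucleotides (transcript
drawn proportional to its length), so expected background region
fractions are proportional to region lengths; 20 000 reads.

Signal reads place the P-site on a CDS codon: the start codon with
probability `start_peak_prob = 0.15`, otherwise a uniform codon
(transcript drawn proportional to its codon count). The initiation
pile-up is not optional decoration: with perfectly uniform codon usage
the planted offset is unidentifiable from the start metagene — columns
at −offset, −offset+3, … have equal expectation, so any detector
reading that matrix aliases modulo 3. The pile-up is both the
real-data feature that makes offsets detectable and a hallmark of
actual libraries. Off-frame reads shift the P-site by ±1 nt with equal
probability; draws falling outside the transcript are redrawn.

The ground truth records the analytically expected frame-0 fraction of
P-site-corrected CDS mass, accounting for the one boundary effect of
order `start_peak_prob`: a −1 nt shift from the start codon lands in
the 5′UTR and leaves the CDS frame mass. With `q0` the start-codon
probability of a signal P-site, CDS frame masses are proportional to
`(in_frame, (1−in_frame)/2, (1−in_frame)/2·(1−q0))` for signal plus a
uniform third each of the background CDS mass. Simulated frame-0
fractions agree with this within 3 binomial standard errors at the
default 20 000 reads; smaller boundary effects (background truncation
near transcript ends, +1 shifts from the final codon staying inside the
stop codon) are neglected.

What the simulator does **not** model: sequence-dependent ligation and
digestion bias, codon-specific dwell times, disomes, uneven expression
beyond transcript-length weighting, UMIs/duplicates, spliced
alignments. Passing tests therefore demonstrate the correctness of the
accounting and the detector's behaviour under its stated assumptions,
not robustness to every artefact of real libraries.

## Reports

Reports are a view, never a recomputation: each figure's numbers are
the exact return values of the corresponding library call, embedded in
the HTML as JSON blocks alongside inline-SVG charts. The footprint
length slider re-aggregates embedded per-length series client-side in a
few lines of vanilla JavaScript, mirroring the library's
additivity-over-lengths invariant. Rendering is deterministic: given
identical inputs the output is byte-identical (no timestamps in the
default fixed-metadata mode), which the test suite asserts.

## Problem sizes

Test and acceptance runs use 1 500–20 000 simulated reads for
behavioural checks and 100 000 reads for the storage-efficiency
measurement; these sizes give stable statistics (binomial standard
errors well below the asserted margins) while keeping the full suite
under a minute on one CPU.
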