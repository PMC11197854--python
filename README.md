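# ribolens

Read-length-resolved analysis of ribosome profiling (ribo-seq) data:
a compact HDF5 occupancy store built once from transcriptome-space
alignments, plus the complete QC and comparison suite that runs on it —
footprint length distributions, start/stop metagene profiles, region
counts, automated P-site offset detection and correction, triplet
periodicity, per-transcript coverage, CPM normalization, cross-experiment
Spearman correlation — rendered as a single self-contained interactive
HTML report.

## The problem

Ribosome profiling sequences the ~26–34 nt mRNA fragments protected from
nuclease digestion by translating ribosomes. The footprint *length* is
itself informative (it reflects ribosome conformation and data quality),
so analyses must keep nucleotide **and** length resolution. Working
directly from SAM/BAM makes every plot a full pass over a large
alignment file. `ribolens` separates that preprocessing from
visualization: alignments are ingested once into a small hierarchical
store holding, per experiment and per footprint length *L*:

- `region_counts[L, t, r]` — footprints per transcript *t* and region
  *r* ∈ (5′UTR, CDS, 3′UTR), assigned by the 5′ end against half-open
  0-based CDS bounds `[cds_start, cds_end)` (stop codon included);
- `metagene_start[L, p]`, `metagene_stop[L, p]` — counts of 5′ ends at
  position *p* ∈ [−radius, +radius] relative to the first nucleotide of
  the start codon and of the stop codon (`cds_end − 3`);
- optional sparse per-length 5′-end coverage for transcript-level plots.

The store is typically **orders of magnitude smaller** than its source
alignments (≈ 0.5 % of the SAM bytes in the bundled simulation), and
every analysis afterwards is a cheap array operation.

## P-site correction

A footprint's 5′ end sits a fixed, length-dependent distance upstream of
the ribosomal P-site: `position_P = five_prime + offset(L)`, with
offsets ≈ 11–14 nt. `ribolens` detects offsets automatically from the
start-codon metagene: initiating ribosomes pile up with their P-site on
the start codon, so for each length *L* the candidate offset
*o* ∈ search ∩ [1, L−1] (default search [3, 18]) is scored by
`metagene_start[L, −o]` and the argmax wins (ties toward the smaller
offset; lengths whose candidate support is below `min_count` fall back
to a default of 12 nt and are flagged unconfident). Applying the offsets
shifts coverage to P-site positions; the triplet periodicity of the
corrected CDS signal — the fraction of mass in reading frame
`(x − cds_start) mod 3 = 0` — is the standard evidence of genuine
translation.

## Worked example

The built-in simulator generates a complete test dataset with planted
ground truth — 50 transcripts, 20 000 footprints of 26–32 nt with
P-site offsets {26:11, 27:11, 28:12, 29:12, 30:13, 31:13, 32:14}, 90 %
of signal in the annotated frame and 10 % uniform positional background:

```sh
ribolens simulate --out-dir sim --n-reads 20000 --seed 1
ribolens ingest --sam sim/reads.sam --annotation sim/annotation.tsv \
    --fasta sim/transcripts.fa --min-len 26 --max-len 32 --name WT --out wt.h5
ribolens offsets wt.h5 --exp WT
```

prints the detected offset table:

```
# length  offset  confident  support
26        11      True       178
27        11      True       296
28        12      True       906
29        12      True       756
30        13      True       481
31        13      True       329
32        14      True       162
```

— every planted offset recovered exactly, all calls confident (`support`
is the total start-metagene mass inside each length's candidate
window). `ribolens qc wt.h5 --exp WT` then reports, among other things,
the region occupancy of the 20 000 accepted footprints:

```
regions:  UTR5   CDS    UTR3
counts:   3431   16098  471
percent:  17.2   80.5   2.4
```

The CDS fraction is high because only the 10 % background lands outside
coding regions (plus 5′UTR mass from 5′ ends of start-proximal
footprints, whose P-sites are in the CDS). A full report —

```sh
ribolens report wt.h5 --out report.html --offsets auto --export-json
```

— writes one HTML file viewable offline, with a footprint-length slider,
and (with `--export-json`) every figure's numbers as JSON.
`ribolens compare` adds the cross-experiment Spearman heatmap and
scatter plots when a store holds several experiments
(`ribolens.merge_stores` combines single-experiment stores that share a
reference).

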