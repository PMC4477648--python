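# slqscan

Prediction of **stem-loop-containing quadruplex sequences (SLQS)** — putative
G-quadruplex motifs whose long loops fold back into stable duplex hairpins,
the sequence signature of **quadruplex–duplex hybrid (QDH)** structures — in
genomic DNA.

Classical putative-quadruplex (PQS) scanners cap loop length at 7 nt and so
miss G4 motifs whose loops are long *because* they carry a duplex stem-loop.
`slqscan` is built for researchers studying these hybrid motifs: it scans
FASTA sequence for the grammar

```
G3–6 N1–20 G3–6 N1–20 G3–6 N1–20 G3–6
```

(four tracts of 3–6 consecutive guanines, three loops of 1–20 nt, loops
inclusive of guanines), sub-classifies hits with all loops ≤ 7 nt as
**PQS_L7**, and screens every longer loop with a DNA nearest-neighbor
minimum-free-energy hairpin folder.  A hit is an **SLQS** only if *each* long
loop (> 7 nt), extended with the flanking guanines in excess of three from
its two adjacent tracts (screened lengths 8–26 nt), folds into a stem-loop
with ΔG°₃₇ < 0 whose paired bases cover ≥ 50 % of the loop.

On top of the scanner the package provides:

* **Clustering** of overlapping hits (hits may share up to three identical
  G-tracts; a cluster is a connected component of tract sharing).
* **Genomic annotation** against refGene/BED12 gene models: genic, promoter
  (2 kb upstream of the TSS), exon/intron/CDS/UTR segments, template vs
  non-template strand placement, signed TSS distances, normalized
  TSS-proximity frequency profiles, and ≥ 1-nt-overlap intersection with any
  BED track.
* The **Kolmogorov–Waring (K–W) distribution** for per-gene motif counts —
  the heavy-tailed family defined by `p_{m+1} = θ(a+m)/(b+m+1)·p_m` with
  `b > a > 0`, `0 < θ ≤ 1` and zero-class probability `p₀ = 1 − a/b` at
  θ = 1 — with pmf, doubly truncated form on observed counts 1…J, sampling,
  and constrained maximum-likelihood fitting.
* A **synthetic-genome generator** that plants SLQS, PQS_L7 and decoy motifs
  with exact ground truth for end-to-end validation.
* The fourteen published SLQS oligonucleotides (NMR and mutational studies)
  bundled as fixtures.

## Worked example

The 29-nt MYT1L intronic oligonucleotide `G4ST02001786748`
(`AGGGAGAGGAGAGCTCTGGGTTGGGTGGG`) is the package's canonical example: NMR
showed it folds into a (3+1) G-quadruplex whose first loop forms a
four-base-pair stem closed by a five-nucleotide hairpin loop.  Folding that
13-nt loop:

```
$ slqscan fold AGAGGAGAGCTCT
AGAGGAGAGCTCT
((((.....))))
dG37=-0.51 kcal/mol pairs=4 fraction=0.615 screen=pass
```

The four predicted pairs (loop positions 1·13, 2·12, 3·11, 4·10) are exactly
the NMR-determined Watson–Crick pairs A5·T17, G6·C16, A7·T15 and G8·C14 of
the oligo, and the 5-nt hairpin loop matches the observed G9–G13 loop.  The
motif itself is a single long-loop candidate with loops (13, 2, 1) nt that
classifies as SLQS.

Scanning all ten bundled NMR-study oligos:

```
$ slqscan scan oligos.fa -o t3
records=10 PQS_L20=81 PQS_L7=0 SLQS=71 rejected=10 slqs_clusters=10 \
records_with_slqs=10 n_stemloops={1: 70, 2: 1, 3: 0}
```

All ten oligos are SLQS-positive (the 71 SLQS records are overlapping tract
placements that collapse into 10 clusters, one per oligo).  The MYO9B
mutation-pair fixture behaves as published: the wild type is an SLQS, while
its six-nucleotide deletion mutant retains only three G-runs and yields no
PQS hit at all.

Other subcommands: `simulate` (synthetic genome with ground truth),
`annotate`, `profile-tss`, `intersect` and `kwfit`; see `slqscan --help`.

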