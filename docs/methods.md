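# Methods

## The motif model

An SLQS is a four-G-tract putative quadruplex whose long loops can each fold
into a stable duplex hairpin, making the sequence a candidate for a
quadruplex–duplex hybrid (QDH).  The search proceeds in three stages:

1. **Grammar scan** for `G3–6 N1–20 G3–6 N1–20 G3–6 N1–20 G3–6` on both
   strands (minus-strand motifs appear as C-tracts in the reference and are
   found on the reverse complement, coordinates mapped back).
2. **Sub-classification**: all loops ≤ 7 nt → PQS_L7 (the classical
   short-loop definition); any loop > 7 nt → long-loop candidate.
3. **Stem-loop screen**: each long loop is extracted, extended on both sides
   by the guanines in excess of three from its flanking tracts (a G5 tract
   contributes 2 G; screened sequences are 8–26 nt under default
   parameters), and folded.  The candidate is an SLQS only if *every* long
   loop folds with ΔG°₃₇ < 0 and paired bases covering ≥ 50 % (inclusive) of
   the extended loop.  Rejected candidates are retained with the failing
   loop and reason ("no stable stem-loop" vs composition below 50 %), so the
   three classes {PQS_L7, SLQS, rejected candidate} partition all hits.

### Tract placement and overlap semantics

Hits are permitted to overlap and may share up to three identical G-tracts.
`find_g_runs` reports *maximal* G-runs (runs longer than 6 nt are flagged
with their true length); `enumerate_pqs` then enumerates every admissible
tract placement of 3–6 consecutive guanines *within* those runs.  Guanines
of a run not covered by a chosen tract fall into the adjacent loop (loops
are inclusive of guanines), and one long run may host two tracts separated
by a ≥ 1-nt all-G loop.  This placement semantics is required by real
sequences: one bundled oligo carries its first two tracts inside a single
7-G run and would have no four-tract parse under a
one-tract-per-maximal-run reading.  It also makes the scanner provably
equivalent to a brute-force oracle that tests all 4-interval placements
directly against the grammar (a property exercised in the test suite on
G-rich random sequence).  The cost is redundancy: G-rich regions produce
many overlapping placements, which is why outputs carry cluster assignments
(connected components of tract sharing) and why a configurable cap (default
10 000 quadruples per 10-kb window) guards against pathological regions —
when it triggers, output is truncated with an explicit warning and a flag,
never silently.

Ordering is deterministic everywhere: hits sort by (span start, span end,
strand `+` first, tract coordinates), so identical inputs give byte-identical
outputs.

## The hairpin folder

The screen needs a DNA-parameterized folding engine for 8–26-nt
single-stranded sequences.  The in-package folder predicts the
minimum-free-energy **single hairpin** — one helix with optional bulges and
internal loops closed by one hairpin loop of ≥ 3 nt; no multibranch loops —
under the unified oligonucleotide DNA nearest-neighbor ΔG°₃₇ model at 1 M
Na⁺: the ten Watson–Crick stack free energies, a 0.05 kcal/mol terminal A·T
penalty applied at the outermost pair, and hairpin/bulge/internal-loop
initiation tables with linear interpolation between tabulated sizes and
Jacobson–Stockmayer extrapolation (coefficient 2.44·RT) beyond 30 nt.
Single-nucleotide bulges retain the stack across the bulge; internal loops
carry a 0.48 kcal/mol/nt asymmetry penalty capped at 3.0.  Temperature is
fixed at 37 °C by using ΔG°₃₇ tables directly (no ΔH/ΔS rescaling); there
are no dangling ends or coaxial stacking.  Canonical A·T/G·C pairs only by
default; a G·T wobble toggle admits wobble pairs but scores their stacks at
0 (untabulated), which is deliberately conservative.

Energies are carried as integer centi-kcal so the dynamic program and the
exhaustive brute-force enumerator (`brute_force_fold`, ≤ 15 nt) produce
bit-identical sums; their exact agreement on thousands of random sequences
is a standing test.  Ties are broken deterministically: lower energy, then
more pairs, then lexicographically smallest pair set.  A sequence with no
structure below the open chain returns the open chain with ΔG°₃₇ = 0, so the
returned energy is never positive.

The single-hairpin restriction is appropriate because screened sequences are
at most 26 nt; a `max_length` of 110 nt supports surveys of longer
stem-loops.  The "stable" threshold (ΔG°₃₇ strictly below 0) and the use of
the *extended* loop length as the composition denominator are declared
defaults of this package: the screen runs on the extracted-extended
sequence, and that sequence's 8–26-nt range is the printed one.  Extension
guanines are counted as loop nucleotides only, never double-counted as tract
bases.

This folder is not a reimplementation of any external package, and its MFE
values will not match other engines decimal-for-decimal; the screen,
however, is binary, and all ten bundled NMR-study oligos classify as SLQS
with canonical pairs alone.  Known divergence: the two BMP8A SNP-polymorph
oligos from the mutational-study fixtures fold to 4 pairs on a 19–20-nt
loop (composition 0.40–0.42) and therefore fail the 50 % screen here, even
though they are bundled as SLQS oligos from the mutational study — plausibly
a consequence of wobble-pair counting or a different composition denominator
in the folding tool those predictions came from.

## Annotation conventions

* Coordinates are 0-based half-open internally and in BED; IDs use 1-based
  positions (`G4ST` + 2-digit chromosome code + 9-digit position; chr1–22 →
  01–22, X → 23, Y → 24, M → 25).
* Promoter = 2 kb upstream of the TSS in gene orientation; genic = ≥ 1-nt
  overlap with the transcript; exon/intron/CDS/5′-UTR/3′-UTR by interval
  algebra per transcript, union-reduced to gene symbols for counting so a
  hit touching a gene through several isoforms counts once.
* **Non-template** = hit strand equals gene strand (G-tracts on the sense
  strand), the usual G4-promoter-literature convention.
* TSS distance is the signed offset (negative upstream) of the hit boundary
  nearest the TSS; a hit covering the TSS has distance 0.
* TSS profiles count per-position hit coverage over ±window (default 2 kb)
  around each transcript's TSS, per strand class, normalized to sum to 1;
  an all-zero profile is flagged, not an error.
* Track intersection is the ≥ 1-nt-overlap rule on half-open intervals;
  adjacency does not count.
* Clustering operates within strand and class; whether published
  unique-cluster counts merged across strands is unstated, so this is a
  declared choice.

## The Kolmogorov–Waring model

`p_{m+1} = θ(a+m)/(b+m+1)·p_m` with `b > a > 0`, `0 < θ ≤ 1`.  Since
`p_m/p_0 = θ^m (a)_m/(b+1)_m`, the normalizing constant is the Gauss
hypergeometric value ₂F₁(a, 1; b+1; θ), evaluated with
`scipy.special.hyp2f1`; the normalized p₀ is its reciprocal and reduces
exactly to the closed form p₀ = 1 − a/b at θ = 1 (a direct series summation
with a 10⁻¹² increment cutoff is kept as a fallback, but near θ = 1 the tail
decays only like m^−(b−a) and the analytic form is both faster and exact).
The doubly truncated form `p_m^T = p_m / Σ_{s=1..J} p_s` models count tables
where zero counts and counts beyond the largest observed value J are
undetected; it is the default for fitting because genes with no hits are
absent from hit tables.

Fitting maximizes the multinomial log-likelihood with Nelder–Mead over
(logit θ, log a, log(b−a)) — the constraints hold by construction — from
five fixed starting points, keeping the best.  The parameters are weakly
identifiable (a ridge trades θ against b−a), so fit quality is judged by
total-variation distance between pmfs, not parameter equality; recovery
tests on 10⁵ samples demand TV < 0.01 and self-consistency on exact expected
frequencies demands TV < 10⁻⁴.  Histograms with fewer than three distinct
observed counts raise an "unidentifiable" error.  Sampling is inverse-CDF on
a table covering all but ≤ 10⁻¹² of the mass, seeded and reproducible.

## The synthetic-data generator

The generator emulates exactly the features the pipeline reacts to, with
exact ground truth:

* **Planted SLQS**: four G-tracts with lengths drawn from 3–6 and one to
  three long loops, each carrying a designed complementary stem (≥ 4
  canonical pairs, ≥ 3-nt hairpin loop, randomized offset within the loop)
  sized so paired bases cover ≥ 50 % of the extended loop.  Because a stem
  of 4 pairs plus a 3-nt hairpin loop needs 11 nt, raw long-loop lengths are
  drawn from 11–20 nt (8–10-nt loops cannot satisfy the stem contract).
* **Planted PQS_L7**: four tracts, loops 1–7 nt.
* **Decoys**: (i) long loops of shuffled, complementarity-free content,
  (ii) three-tract near-misses, (iii) C-strand motifs (reverse complements,
  recoverable only on the minus strand).
* **Spacers**: G-poor random background in which every G- or C-run of ≥ 3 nt
  is broken and motif-adjacent bases are forced to T, so planted motifs are
  the only tract sources; with ≥ 30-nt spacing no cross-motif hit is
  possible and recovery is exactly decidable.

Every motif is verified at build time by excising it with 10-nt flanks and
running the actual scanner and classifier (planted PQS_L7 additionally must
produce no SLQS among their overlapping placements); content is resampled on
failure and generation errors out rather than emit unverifiable truth.
Identical seed and configuration give byte-identical genomes.

What passing these tests does **not** show: the background is run-free and
motifs are isolated, so the generator says nothing about behaviour in
G-dense real sequence (tandem G-rich repeats, overlapping motif families,
N-gaps, soft-masked repeats), about folding engines other than this one, or
about genome-scale hit totals.  Whole-genome counts depend on the exact
overlap-enumeration reading and on folding-engine details, and published
totals for a full genome build are not reproduced at the problem sizes this
package validates (oligos, 200-nt random sequences, 1-Mb synthetic genomes
— sizes chosen so the full validation suite runs in seconds).

## Numerical and degenerate-input choices

* Non-ACGT characters terminate G-runs and disqualify any hit whose span
  contains them; lowercase input is uppercased and scanned.
* Sequences shorter than `min_hairpin_loop + 2` fold to the open chain (not
  an error); illegal characters are errors.
* `stemloop_length_distribution` requires `max_len ≥ 8`; empty input gives
  an all-zero histogram with zero cumulative mass.
* `kw_truncated_pmf` rejects m outside 1…J; `KWParams` rejects invalid
  parameter triples at construction.
* Malformed gene models raise errors naming the transcript ID.
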