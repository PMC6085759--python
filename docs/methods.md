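# Methods

## Overview

`isolimits` asks a design question by simulation: given a fixed sequencing
budget, how do library preparation (how much of each transcript is covered)
and depth-per-cell (how a long-read budget is split over cells) bound
isoform-level conclusions in single-cell RNA-seq? Everything runs on a
synthetic transcriptome with known ground truth, with error-free reads and an
exact compatibility oracle in place of an aligner, so the only limits at work
are the structural and depth limits under study. Results are therefore
upper-bound estimates: every real-data complication (sequencing errors,
positional bias, RT artefacts, capture drop-outs beyond sampling noise) can
only push detection down.

## Synthetic transcriptome

Genes are placed sequentially on one synthetic chromosome with 500 nt
inter-gene gaps, never overlapping, strand drawn uniformly. The reference
isoform of each gene has 2 + Poisson(4) exons; exon lengths are log-normal
(median 180 nt, log-sd 0.75, clipped to [30, 3000]) and intron lengths
log-normal (median 300 nt, log-sd 0.8, clipped to [60, 5000]). Genomic
sequence is i.i.d. uniform A/C/G/T — adequate because all downstream logic is
coordinate-based; sequence content never enters compatibility.

The default preset emulates the scale of a published neural PacBio
transcriptome: 7000 genes, of which exactly round(0.45 · 7000) = 3150 are
multi-isoform. Each MIG's isoform count is 1 + T with T truncated-geometric
(P(T=k) ∝ (1−p)^(k−1), k = 1..9, p = 0.525), tuned so the expected transcript
total is ≈13,000 (mean ≈2.9 isoforms per MIG). The per-gene isoform-count
distribution of the reference dataset is not published beyond these totals;
the truncated geometric is this package's choice and is the main free
structural parameter.

Alternative isoforms are derived from the reference by exactly one event,
sampled from {exon skip 0.30, intron retention 0.15, alt 5′ splice site
0.125, alt 3′ splice site 0.125, alt TSS 0.15, alt TTS 0.15}:

* **exon skip** removes one internal exon;
* **intron retention** merges two adjacent exons across their intron;
* **alt 5′/3′ splice site** moves one junction boundary by ≥10 nt (into the
  exon, or into the intron while leaving ≥10 nt of intron), leaving ≥20 nt of
  exon;
* **alt TSS/TTS** trims the transcript terminus by ≥10 nt within the terminal
  exon, leaving ≥20 nt.

Events that are structurally impossible (e.g. exon skip on a 2-exon gene) are
resampled; after 20 collision attempts the gene's isoform count is reduced
and logged. Coordinates are 0-based half-open internally and converted to
GTF's 1-based inclusive convention only at serialization. "5′" and "3′"
always refer to the transcript, not the genomic left/right.

## Expression model

Gene abundance is log-normal (log-mean 0, log-sd 2.1) and shared by both cell
types — gene-level differential expression is deliberately absent so that any
between-cell-type signal is purely isoform switching. The log-sd default puts
roughly 10% of genes below one expected read at a one-million-read depth,
giving a realistic low-expression tail. Within a MIG, isoform proportions are
a symmetric Dirichlet(α = 0.8) draw whose largest share is reassigned to a
uniformly chosen dominant isoform; ties in the maximum are redrawn so
dominance is strict. Profiles are normalised to 10⁶ TPM.

Switches: exactly round(0.14 · n_MIG) MIGs, sampled without replacement, have
the dominant and one random alternative isoform's proportions swapped in the
second cell type. Swapping (rather than redrawing) keeps gene-level output
identical between cell types, isolating the switch signal. The 14% statistic
is counted per MIG. Within a cell type, no cell-to-cell biological
variability is modelled — the simulation assumes the same isoform diversity
at the cell and bulk level, which makes all detection numbers upper bounds.

## Library models and read simulation

A protocol is a coverage template plus a read spec. UMI3/UMI5 cover the
terminal `window` nt of the transcript (the whole transcript when shorter);
SMART and LONGREAD cover everything. Read lengths grow with the window so
coverage stays even: 100/200 nt → 25 nt single-end, 300/500 nt → 50 nt,
1000 nt → 100 nt, full length → 250 nt paired-end with fragment length
N(350, 35²) truncated to the template (the fragment distribution for the
paired-end case is this package's default; typical Illumina insert sizes).
Fixed windows deliberately idealise UMI libraries: covered length does not
vary between molecules, and no UMI deduplication or 3′ coverage decay is
modelled.

The read budget (default 10⁶) is allocated over isoforms by a single
multinomial draw with p_i = TPM_i/10⁶ — multinomial rather than Poisson so
the budget is exact. Fragment starts are uniform over valid placements;
fragments longer than their template are clipped to it.

**Compatibility oracle.** A read is compatible with a candidate isoform iff
its 5′→3′ sequence of genomic positions is a contiguous subsequence of the
candidate's — equivalently, every projected genomic segment is contained in
the candidate's exons and every junction the read crosses matches a candidate
junction exactly. Mates of a pair may straddle candidate-internal gaps. Two
implementations exist: a per-read predicate (projection through the origin's
exon chain) and a vectorised path that enumerates compatible start positions
per (origin, candidate) pair and bins sampled starts directly into
equivalence classes; the test suite checks them against each other and
against an independent position-subsequence oracle. Genes never overlap, so
compatibility is restricted to same-gene candidates by construction.

## Quantification

Per gene, equivalence classes (compatibility set → read count) are quantified
by plain maximum-likelihood EM: a read from isoform i lands on one of ℓ_i
placements uniformly, so a class c has likelihood ∝ Σ_{i∈c} θ_i/ℓ_i; the
E-step distributes class counts ∝ θ_i/ℓ_i, the M-step renormalises. Uniform
initialisation, tolerance max|Δθ| < 1e-8, ≤1000 iterations; estimated counts
conserve the gene's read total at every iteration. No sparse prior and no
credibility intervals are fitted — identifiability behaviour, not any
particular tool's numerics, is what the study exercises.

**Effective length** is ℓ_i = max(1, L_i − f + 1) with L_i the *full*
transcript length and f the protocol's expected fragment length (read length
for single-end). Using the full length — not the trimmed window — reflects
that the emulated quantification step is annotation-based and does not know
which part of the transcript the library covered. This choice also matters
numerically: with per-window lengths all isoforms of a gene would have equal
ℓ, fully ambiguous classes would sit on a symmetric likelihood ridge, EM
would split them evenly from its uniform start, and every isoform would pass
the detection threshold — inverting the window-length effect entirely. With
full-length ℓ the ridge is tilted and unidentifiable mass concentrates, so
"detected" tracks genuine discriminability.

An isoform is **detected** when its estimated read count is ≥ 1 (inclusive;
configurable). The threshold the emulated workflow implicitly used is
unknown, so it is a prominent knob.

## Short-read metrics

Per MIG, resolution = 100 · n_detected / n_reference, capped at 100. The
reference is protocol-dependent: annotated isoform counts for Smart-seq, the
matched Smart-seq-detected counts for UMI runs. MIGs with a zero Smart
reference are excluded from percentages and reported separately. Bins
partition [0,100] as [0,25], (25,50], (50,75], (75,100]; the top bin is the
"near fully resolved" (>75%) class. Because the two conventions put Smart-seq
and UMI runs on different scales, reports also carry every protocol's mean
against the common annotated reference; cross-protocol statements (Smart ≥
UMI) are made on that common scale.

## Long-read trade-off

The long-read budget is split evenly over n ∈ {2, 6, 10, 16, 20} cells (half
per cell type, remainder reads to the first cells), each cell drawn
multinomially from its cell type's TPM (a deterministic proportional mode is
available). One read = one full-length transcript, so counts are isoform
counts and no EM is involved. Reported per scenario: the mean number of MIGs
with ≥2 isoforms at ≥1 read per cell (averaged per cell, not pooled), and the
mean number of true-switch MIGs whose observed dominant isoforms (argmax
count, ties to the smallest id, undefined if the gene has no reads) differ
between the two cells of every cross-type pair. Restricting switch counting
to the MIGs that truly switch in the noiseless profiles scores *recovery* of
real switches; unrestricted counting would also score noise-flipped dominance
in weakly dominant genes and can exceed the reference. Flow-cell budgeting is
ceil(n_cells / 4) at the instrument's 4-cells-per-flow-cell capacity.

## Determinism

A root seed deterministically derives a substream per (stage, protocol, cell
type, replicate) via SHA-256, so adding a protocol or scenario never perturbs
any other stage's randomness, and identical config + seed gives byte-identical
outputs.

## Problem sizes used by the test suite

End-to-end checks run the full preset (7000 genes, 10⁶ reads per protocol
run) for the short-read sweep on three seeds and 20 long-read replicates;
unit and property tests use small generated transcriptomes (12–60 genes) and
a hand-built two-gene fixture whose compatibility structure is enumerable by
hand.

## Known limitations

* Terminal-truncation isoforms (alt TSS/TTS) are genomically nested in their
  reference and have no uniquely compatible reads; their ML estimates are
  unbiased but high-variance, which caps rank-correlation recovery for this
  event class (see the parameter-recovery test) and would equally affect any
  class-based quantifier.
* The positions of discriminating events in this generator are roughly
  uniform along transcripts, whereas real annotations concentrate much
  isoform diversity near the 3′ end; the growth of the near-fully-resolved
  fraction with window length is therefore steeper here than in data whose
  decisive events cluster terminally.
* No sequencing-error, bias, drop-out or UMI-collision models; no overlapping
  or fusion genes; no cell-to-cell variability within a cell type. Passing
  tests demonstrate structural/depth limits under ideal conditions, not
  performance on real libraries.
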