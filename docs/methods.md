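# Methods

`txarch` infers the transcriptome architecture of a bacterial genome from
per-position count tracks: stranded 5′-end counts from differential RNA-seq
(TEX-treated vs untreated), stranded 3′-end counts from Term-seq, and
stranded RNA-seq coverage. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Coordinates and normalization

All internal coordinates are 1-based inclusive (GFF3 convention); BED and
bedGraph are converted at the I/O boundary. The pipeline assumes a single
chromosome and does not model circularity: windows are truncated at the
genome ends and affected records are flagged. Heights are normalized to
reads per million (RPM) using the library's total mapped reads from the
metadata table — not the track sum — so partial tracks normalize correctly.

## End calling

A position is a TSS candidate when, in at least `replicate_min_fraction` of
TEX+/TEX− replicate pairs (paired by replicate index), all of the following
hold:

- TEX+ height ≥ `min_height_rpm` (default 1.5 RPM);
- pseudocounted raw-count ratio (TEX+ + 1)/(TEX− + 1) ≥ `enrichment_min`
  (default 2.0) — the TEX exonuclease degrades processed 5′-monophosphate
  ends, so genuine initiation sites are TEX-enriched and processed sites are
  TEX-depleted;
- the TEX+ height is the strict maximum within ±`local_max_window` nt
  (default 2), with ties broken to the 5′-most position;
- mean RNA-seq coverage over the `downstream_support_len` nt (default 50)
  downstream is ≥ `downstream_support_min_cov` (default 1 RPM).

The coverage-support rule is an automated surrogate for the manual curation
of candidate peaks against coverage profiles that is customary in this kind
of study; its defaults were chosen on synthetic data. TEP calling applies
the same machinery without the enrichment test, with the support window
upstream of the 3′ end, and with ties broken to the 3′-most position.
Enrichment is computed on raw counts (plus pseudocount) rather than RPM so
that the pseudocount has a fixed meaning of one read.

Peak lists from different conditions are merged per strand by transitive
single linkage with a ±5 nt tolerance. The representative position is the
member with the highest height (ties: lower coordinate, then condition
name), so every merged site sits exactly on a member peak. A site observed
in ≥ 2 conditions is labelled constitutive, otherwise
condition-specific. Single-linkage was chosen because the merging rule is
silent about chains (e.g. 100–104–108); it makes the operation idempotent
and order-independent, both of which are tested.

Reproducibility is summarized as the median Pearson r of RPM heights at the
called site positions between replicate pairs (pairs formed within a
condition, pooled across conditions). Height vectors with zero variance are
excluded with a warning. Whole-track correlations would be dominated by the
zeros between sites, which is why site heights are used.

## Site classification

TSS categories relative to the annotation: per gene, TSSs on its strand
within −300/+100 nt of the gene 5′ end are promoter-window sites; the
highest is primary (P), the rest secondary (S) (ties: nearer the gene end,
then 5′-most). A site inside two genes' windows belongs to the gene with
the nearer 5′ end (ties: lower start coordinate). Remaining sites are
internal (I) when inside a sense-strand gene body, antisense (A) when
within a gene body ±100 nt on the opposite strand, else intergenic (N).
Precedence is P/S > I > A > N and every site gets exactly one category, so
category counts always partition the site list.

TEPs use the mirrored scheme with a [0, +300] nt window downstream of gene
3′ ends (chosen to mirror the TSS window depth, since 3′ processing places
TEPs only downstream of stops), plus a cis-regulatory (C)
category — a TEP on the sense strand strictly between a gene's primary TSS
and its start, i.e. premature termination inside the 5′-UTR, the signature
of riboswitch-style attenuation. Precedence P/S > C > I > A > N.

5′-UTR length is the strand-aware distance from a P/S TSS to its gene's 5′
end, clamped at 0 for the (allowed) TSSs up to 100 nt downstream of the
start; transcripts with UTR ≤ 10 nt are counted leaderless. Nucleotide
composition is tabulated at promoter offsets −2, −1, +1, +2 where +1 is the
TSS base itself (promoter numbering has no zero), reverse-complemented on
the minus strand. The RBS scan tests the 20 nt upstream of each start codon
of a leadered (UTR ≥ 10 nt) P/S transcript against an AG-rich
Shine–Dalgarno weight matrix; a hit is a placement with exact p ≤ 1e-3.

## Transcription units

Each TSS is paired with its nearest downstream same-strand TEP within
`max_len_nt` (default 15 kb); a `pairing: all` variant pairs every
downstream TEP. The span becomes a TU when ≥ `min_support_fraction`
(default 0.8) of its positions have coverage ≥ `min_cov_rpm` (default 1 RPM)
and no sub-threshold run exceeds `max_gap_nt` (default 50 nt). All TSS
categories may seed TUs (antisense/intergenic units simply carry no gene
list); gene lists contain sense-strand genes fully inside the span. When
several conditions were profiled, support is evaluated against the
element-wise maximum RPM across condition coverages, so condition-specific
units are judged in the condition where they are expressed. TUs overlapping
by ≥ 1 nt on the same strand form clusters by single linkage (a strandless
variant exists behind a flag); clustering is verified against brute-force
connected components.

## Motif models and scanning

σ-factor promoters are modelled as two position-weight-matrix blocks (−35-
and −10-side) with a categorical spacer-length prior. A hit's score in bits
is the sum of both block log₂-odds plus log₂ of the spacer prior; SigA
additionally gets a +1 bit bonus when TG occupies the 2 nt upstream of the
−10 block (the extended −10 element is treated as part of the SigA motif,
not an independent motif). P-values are exact per-placement tail
probabilities of the block score under a 0-order background, computed by
the discretized dynamic-programming convolution (10⁴ bins) used by
FIMO-style scanners and verified against 4^w word enumeration. The
per-placement convention (rather than a max-over-window null) is the one
FIMO reports and the one under which an exact σ⁵⁴ consensus placement is
significant at p ≤ 1e-4.

Built-in models: SigA (TTGHHW / TATAAT, 17 nt spacer), SigH (AGGA / GAAT,
17–18 nt), SigL (σ⁵⁴, TGGCA / TTGC, 6 nt — the −24/−12 elements handled by
the same bipartite machinery), and B. subtilis-inspired placeholders for
SigF/SigE/SigK with 14–15 nt spacers. Consensus matrices use concentration
0.85 (the consensus base(s) share 85% of the mass). Defaults per model:
score floor 0 bits, p ≤ 1e-4; these cutoffs are declared rather than taken
from any reference, and reported proportions should always be read together
with them. Scanning a TSS set re-estimates the background from the scanned
50-nt upstream windows (inclusive of −1); genome-wide background is a
config option. A promoter may carry hits for several σ factors — models are
scanned independently and proportions are over total hits.

De novo discovery is a ZOOPS (zero-or-one occurrence per sequence) Gibbs
site sampler — a deliberately simple stand-in for MEME-class expectation
maximization, adequate because discovery here is exploratory while the
reported proportions come from scanning. It iterates leave-one-out PWM
estimation and site resampling proportional to the odds, keeps the
best-likelihood state across restarts, applies a greedy ±1–2 nt column-shift
move every 20 iterations (curing the phase ambiguity these samplers are
prone to), and finishes with a deterministic argmax polish. It is
bit-reproducible given a seed. Bipartite discovery runs in two stages:
the −10-side block in the 20 nt nearest the TSS, then, after aligning on
those hits, the −35-side block in the 13–21 nt spacer band; the spacer
prior is the empirical histogram (spacers under 5% frequency dropped).

## Terminator features

For each TEP: the U-tract fraction is the T fraction of the 8 coding-strand
nt ending at the TEP; the stem-loop is the best-scoring hairpin in the
60 nt ending at the TEP by exhaustive enumeration of loop placements
(loop 3–10 nt) with stems extended outward until the first non-pairing
position (no bulges), scored G-C=3, A-T=2, G-T=1, minimum stem 5 bp. This
is a pairing score, not a thermodynamic free-energy model, and is verified
against full enumeration.

## Synthetic data generator

The generator is the package's study-conditions testbed. Defaults: 100 kb
genome at GC 0.474, 80 non-overlapping genes (200–700 bp) on both strands,
two conditions with 30% of genes active in only one, two replicates,
5′-end peak heights ~ NegBin(mean 50 reads, size 10), TEX+/TEX− enrichment
5, Poisson background 0.05 reads/nt/strand, ±2 nt multinomial positional
jitter (σ = 0.5 nt), coverage plateau 15 RPM over each TU, and
total_mapped_reads = 5×10⁶ for every library so one read = 0.2 RPM. At that
scale the 1.5 RPM calling threshold corresponds to ~8 stacked reads, which
the Poisson background essentially never produces, while planted sites
average 10 RPM — the margin was set by that tail calculation.

Each gene gets: a promoter whose block sequences are sampled from its σ
model's PWMs, rejection-resampled (≤50 tries) until the draw is
scanner-detectable at half the model's p-value threshold — mirroring the
fact that annotated motif instances in real studies are precisely the
detected ones; a 5′-UTR from 0.4·U{20..29} + 0.6·U{30..121} (exact discrete
median 45 nt, modal bin 20–29 — note a mixture putting most of its mass on
20–29 cannot have a 45 nt median, so the weights are set by the median
constraint); an AGGAGG RBS 5–9 nt upstream of the start; a 3′-UTR from
20 + Gamma(2.5, 20.3) clipped to [30, 250] (median ≈ 64 nt; the lower clip
reserves room for the terminator and only moves sub-median values, leaving
the median unchanged); and an 8 bp GC-biased stem, 4 nt loop, U₈-tract
terminator ending at the TEP. Planted σ labels are SigA/SigH at 75/25.
Each gene also carries a lognormal abundance factor (σ = 0.8 log-units)
shared by its TSS, TEP and coverage across replicates and conditions;
without it replicate heights would be uncorrelated and the reproducibility
statistic meaningless. TEX-depleted processed 5′ ends (0.2/kb) are planted
with TEX−/TEX+ ratio ≥ 2, making them enrichment-test negatives by
construction.

Randomness: one seed; background noise draws from a separately spawned
stream so that changing the background rate is a common-random-numbers
comparison that leaves the genome, placement and heights untouched. Same
seed ⇒ byte-identical outputs.

Recovery scoring matches called to planted sites greedily (nearest first,
one-to-one, same strand, within ±1 nt by default); precision with zero
calls is reported as 1.0 with a flag. A TU counts as recovered only when
both endpoints matched and a called TU pairs exactly those two sites.
σ-assignment accuracy is the fraction of matched planted promoters whose
top-scoring hit names the planted σ.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: reads and mapping artifacts (tracks are
simulated directly), operonic genes sharing one TU, nested/overlapping gene
structure, sequence-dependent coverage bias, 5′-end micro-heterogeneity
beyond ±2 nt, condition-dependent σ usage, and any correlation between
promoter strength and motif quality. Distribution medians (45/64 nt) are
verified on large draws from the samplers (n = 5000), not on an 80-gene
instance, where sample-median noise alone exceeds the ±3 nt check.

## Problem sizes and defaults used in checks

The end-to-end benchmark runs the default 100 kb / 80-gene dataset (seed 7)
through the full pipeline in a few seconds. Oracle-equivalence checks use
1,000 randomized 10-kb layouts (classification), all 4^w words for widths
≤ 6 (p-values), ≤ 50 random intervals (clustering), and 60-nt windows
(hairpins). Motif-recovery checks use 50–60 sequences of 50–60 nt.

## Known limitations

- No statistical error model for peak calling (thresholds are rule-based,
  as in the lineage of TSS/Term-seq methods this follows); no FDR.
- Replicate handling requires matched replicate indices across TEX states.
- The P-vs-S decision uses height; if two promoter-window TSSs tie in
  height the nearer one is primary. Proximity-based primary assignment is
  not offered.
- Whether detection should be required in all replicates is left as
  `replicate_min_fraction` (default 0.5, i.e. either of two).
- SigF/SigE/SigK models are placeholders pending organism-specific
  refinement; their spacer ranges ({14, 15}) follow B. subtilis-like
  patterns and are flagged as assumptions.
- The hairpin score admits no bulges or mismatches; real terminator stems
  with internal loops are undercalled.
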