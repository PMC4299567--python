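# Methods

This note documents the models implemented in `nuwtscan`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Copy number from read depth

Reads from a line carrying a nuclear endosymbiont insertion (nuwt) are
mapped against two references: the host assembly and the endosymbiont
genome. After coordinate-key duplicate removal, per-base depth is piled up
natively (`depth[i]` = number of retained reads whose half-open span covers
`i`; the identity Σdepth = Σ aligned lengths is enforced by tests).

**Normalization.** Copy number is windowed mean depth divided by the modal
depth of the single-copy host genome, computed over 1 kbp windows every
500 bp. The mode is taken with histogram bin width 1, excluding zero-depth
positions (assembly gaps would otherwise make 0 the mode), with exact ties
broken toward the larger depth (conservative, i.e. lower, copy calls).

Two modal estimators are provided:

* `modal_depth` — the mode of the per-base depth histogram. At an integer
  single-copy rate λ this is intrinsically ambiguous: per-base depth is
  Poisson(λ) and Poisson puts exactly equal mass on λ−1 and λ, so the
  empirical per-base mode at 5× coverage is a coin flip between 4 and 5.
* `windowed_modal_depth` — the mode of 1 kbp windowed mean depths, rounded
  to bin width 1. Window means concentrate tightly around the true
  single-copy depth (sd ≈ 0.45 at 5×), making the mode stable. The
  pipeline normalizes with this estimator, applied to the **host** track.

The host-track choice matters: the endosymbiont track's own mode would sit
at the most common *duplicated* copy class and silently rescale the
profile. Normalizing both references by the host mode anchors copy number
to single-copy host genes.

**Windowing conventions.** Windows start at 0, step, 2·step, …; a terminal
partial window is kept only when its span strictly exceeds half the window
(a 2000 bp reference with 1 kbp/500 bp windows yields starts {0, 500,
1000}; the 500 bp remnant is dropped). Coordinates are 0-based half-open
everywhere; SAM's 1-based positions are converted at the parser boundary.

**Read-fraction statistics.** With *h* host-mapped and *e*
endosymbiont-mapped reads out of *N*, the module reports 100·h/N, 100·e/N
and the ratio 100·e/h at full precision (rounding belongs to
presentation). The implied insertion span is (ratio/100) × genome size: a
tandem array contributing r% of the mapped reads occupies roughly r% of
the genome. Reads mapping to both the endosymbiont and the mitochondrial
reference (shared ancestry) are counted once, flagged multi-reference, and
surfaced by `cross_mapping_audit` rather than silently dropped.

## qPCR dosage model

Relative quantification against single-copy host genes:

    ΔCt = Ct(single-copy reference) − Ct(target),    fold = E^ΔCt

with amplification efficiency E = 2 (perfect doubling) by default,
configurable. The sign convention makes duplicated targets (earlier
amplification, lower Ct) give ΔCt > 0 and fold > 1; the worked dosage
numbers fix this orientation (ΔCt = 1.4 ⇒ fold 2.6). `fold` is a derived
property of ΔCt, never stored, so the identity fold = 2^ΔCt is exact by
construction.

Replicates are aggregated by arithmetic mean of Ct before differencing
(median available). Reference normalization is either *aggregate* (pool
all reference-gene Ct values) or *per-gene* (one ΔCt per gene, averaged);
the two coincide whenever replicate counts are balanced. A warning is
raised when the reference genes span more than 1 Ct, the empirical bound a
well-behaved panel should respect. Targets with no amplification within
the 45-cycle program are flagged undetected; presence/absence calls use a
configurable Ct cutoff (default 40) rather than melt-curve QC, which is
out of scope.

Validation against sequencing regresses sequencing copy number (y) on
qPCR fold (x) by ordinary least squares with a two-sided t-test on the
slope (scipy's `linregress`). When the sequencing copies are constant
across amplicons — an evenly duplicated insertion — no correlation is
expected and the fit is flagged instead of fitted: the scatter then only
shows the assay's random variation.

## Genetic crosses

An F1 of a cross between the insertion-bearing line and a naive line
carries one parental chromosome set: every nuwt amplicon halves
(fold ratio 0.5, ΔCt intercept shift +1 cycle), and — if the parent is
homozygous — every offspring stays PCR-positive for single-copy regions.
The verdict combines:

* mean F1/parent fold ratio over shared amplicons, accepted as "half"
  within [0.35, 0.65];
* the intercept shift between the parental and F1 fits of ΔCt vs
  log2(sequencing copy), accepted as "+1 Ct" within [0.7, 1.3] (the
  observed shift is reported without tolerance in the source assays, so
  the bands bracket it symmetrically);
* the exact binomial probability of the observed number of positive
  offspring under the heterozygous (50% absence) null — exact rather than
  normal-approximate because offspring counts are small (tens): 44/44
  positive has probability 0.5⁴⁴ ≈ 5.7×10⁻¹⁴.

All offspring positive ⇒ homozygous (with a consistency warning if the
dosage did not halve); a mix ⇒ heterozygous; none ⇒ lost. Because
endosymbionts are strictly maternally inherited, F1 infection status
follows the mother: a naive-mother cross sheds the infection in one
generation, so endosymbiont signal persisting in such an F1 is
chromosomal. When the mother was infected the report always carries a
residual-infection caveat.

**Bacterial titer.** In an uncured fly, free bacterial genomes add the
same extra template B to every endosymbiont amplicon (template = c + B,
additive because each bacterial genome contributes an independent copy of
each locus; whether the observed "4-fold shift" is additive or
multiplicative is not settled by the source assays — the additive model is
implemented and is exactly recoverable: under zero noise the least-squares
intercept of fold vs copy equals B and the slope equals 1 to machine
precision). B is reported per haploid host genome ("per chromosome copy").
Dosage bookkeeping is per haploid genome throughout; per-nucleus values
are 2× (8 per haploid ⇒ 16 per nucleus).

## Life stages and replication origins

For a stage whose insertion template is represented at factor u relative
to single-copy genes, qPCR fold is u·c for true copy c. Regressing adult
sequencing copy (y) on stage fold (x) **through the origin** gives slope
Σxy/Σx² = 1/u exactly under the noise-free model — that identity is why
the slope is fit without an intercept; a free-intercept fit is reported
alongside as a diagnostic. Slopes ≥ 2 (the lower edge of the 2–8× range
observed for *dsx*-like heterochromatic controls) are flagged
heterochromatin-like, and the nuwt's fold is called consistent with
heterochromatin when it sits within a factor of two of the flagged
controls. Stage ploidy is not modeled: folds are relative to single-copy
genes in the same individual, which cancels global ploidy.

`origin_spacing` is the literal division genome_size / n_origins under
even placement. Note an arithmetic subtlety in the published discussion of
these numbers: 231 Mbp divided by the 7,329 predicted ORC sites is
~31.5 kbp, although the accompanying prose quotes ~315 kbp (and 293 kbp
for 215 Mbp) — a tenfold discrepancy. The operation implements the literal
division and does not guess which figure was intended; the
underreplication-risk flag therefore uses the independently stated maximum
inter-ORC gap (447 kbp), not the mean spacing, compared with strict
inequality against the total tandem span Σ copies × segment length.

## The synthetic-data generator

The generator's defaults are the study conditions the analysis targets:
~5× single-copy depth, 40 bp reads, paired fragments with ~300 bp inserts,
45-cycle qPCR with efficiency 2 and 0.2-cycle noise, three replicates,
six single-copy reference genes, copy classes {1, 2, 4, 8, 12}, 4-fold
larval underrepresentation (u = 0.25), bacterial titer 4 for uncured
flies, 44 offspring per cross.

**Reads.** Fragment starts are Poisson with per-base rate
(u·c(pos) + B) × depth/(2·read_length); each fragment emits a forward and
a reverse read joined by mate coordinates. Reads are emitted directly as
placed alignment records, not FASTQ through an external aligner: the
inference chain starts at mapped reads, and this keeps the pipeline
desk-scale and aligner-independent (a FASTQ writer exists for
interoperability but is untested against external aligners). Pairing is
load-bearing, not cosmetic: duplicate detection keys on (reference, start,
strand, mate reference, mate start), and with single-end fixed-length
reads coordinate deduplication would collapse independent co-starting
reads — at 12 copies × 5× depth roughly a third of genuine reads share a
start position, which would destroy high-copy recovery. Random insert
sizes make coincidental key collisions negligible, as in real libraries.
PCR duplicates are injected per fragment as exact-coordinate copies;
contaminant (rRNA-like) reads are counted as unmapped total only. A
configurable homology block copied verbatim from the endosymbiont into
the mitochondrial reference produces genuinely cross-mapping reads,
flagged multi-reference.

Copy number is assigned by fragment start, so copy transitions smear over
one insert length (~300 bp) at segment boundaries; recovery tests
therefore evaluate windows at least one insert length inside each
segment, and the default panel places amplicons in the central half of
each segment.

**qPCR.** Ct = C₀ − log_E(template) + N(0, σ), truncated at the 45-cycle
limit (later Cts are recorded as absent, mirroring the instrument);
template 0 never amplifies. With σ = 0 and E = 2 the chain is exact: 2^ΔCt
equals the template ratio to machine precision, which is the oracle the
noise-free tests pin.

**What is not emulated** — and hence what passing tests do not show about
real data: sequence-level realism (indels, quality scores, GC bias,
mapping ambiguity beyond the single homology block), retroelement
insertions inside the array (only span accounting), SNP structure,
mitochondrial high-copy state, batch effects between qPCR plates, and
primer efficiency variation. Recovery results on this generator
demonstrate correctness of the inference arithmetic under the stated
noise model, not robustness to alignment artifacts in real libraries.

## Problem sizes and determinism

Simulated references are tens of kilobases (default 60 kbp host, 20 kbp
endosymbiont, 3 kbp mitochondrial stand-in) — large enough for ~120
windows on the host track and several windows per copy-class segment,
small enough that the full pipeline runs in seconds. Copy-class
recovery holds within ±1 copy for classes ≤ 8 and ±2 at 12 at these
sizes. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); a fixed seed reproduces every output file
byte for byte, and each output carries the seed and a config hash in its
header.

## Known limitations

* The modal-depth normalizer assumes the host assembly is predominantly
  single copy; a highly repetitive host would bias the mode.
* Copy numbers are window averages; breakpoints are localized only to
  window resolution, and short high-copy islands are attenuated.
* The additive bacterial-titer model treats the infection as uniform
  across individuals; titer variance between flies is not modeled.
* The heterozygosity verdict assumes the cross design was executed as
  described; it flags, but cannot correct, a failed cross (fold ratio ≈ 1).
* Stage regressions assume the adult sequencing profile is the fully
  replicated baseline; if adults themselves underreplicate the insertion,
  all slopes are scaled by that common factor.
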