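# Methods

## Coordinate conventions

All positions are 0-based, half-open, transcript-space, 5′→3′. Each
transcript is partitioned totally into 5′UTR / CDS / 3′UTR; the CDS
includes its stop codon, so `cds_len` is a positive multiple of 3.
Structure can come from a 4-column TSV (`transcript_id utr5_len cds_len
utr3_len`) or a BED12 file, whose thickStart/thickEnd are projected
through the block structure (minus-strand records are flipped into
transcript orientation). Transcripts violating the invariants are
dropped with a logged reason, never silently kept; a structured
transcript with no sequence is a hard error. Each transcript id is
treated independently — gene-level isoform collapsing is left to the
caller. N bases are allowed; codons containing N never match a start or
stop codon.

## P-site assignment and RPKM

Footprint tables carry (transcript, position, read length, count) with
positions either raw read 5′ ends or P-sites. The default offset is
+12 nt for read lengths 26–32 (the standard value for
cycloheximide-arrested 80S footprints of those lengths); other lengths
are dropped with a tally, as are reads whose shifted P-site falls off
the transcript. RPKM is count / (region kb × mapped reads in millions)
with the sample's total retained P-sites as the default library size; a
zero-length region yields a missing value, never 0/0. Reading frame is
(position − utr5_len) mod 3 over CDS-mapped P-sites.

## Well-translated filter

Codon index is floor((psite − utr5_len)/3). After excluding the first
15 and last 5 codons, nonoverlapping five-codon windows are tiled left
to right; a trailing partial window is discarded (complete windows
only). The verdict is PASS when the median window read sum is ≥ 2,
TOO_SHORT when no complete window exists (CDS < 25 codons under the
defaults — kept distinct from FAIL so downstream statistics can exclude
rather than count such transcripts), FAIL otherwise. Counts are pooled
across all samples of the experiment by default so that a single
transcript universe feeds the rhythm analysis; a per-sample mode
(pass-everywhere) is available by flag.

## uORF detection and read allocation

A uORF is a start-codon occurrence in the 5′UTR terminated by the
*first* downstream in-frame stop codon still inside the 5′UTR. This
follows standard ORF semantics; an `all_stop_pairs` mode emits one
record per (start, in-frame stop) pair instead, for the literal
"all pairs" reading. The minimal uORF is 6 nt — a bare start–stop pair
encoding a zero-codon peptide, which is exactly the mouse Per2 uORF
(ATGTAA). Canonical starts are {ATG}; near-cognate starts are the nine
single-nucleotide variants of ATG. Starts with no in-frame stop before
the CDS are skipped by default; `allow_cds_overlap` reports them under
a distinct class because CDS-overlapping uORFs act differently.
Overlapping/nested uORFs from distinct starts are all reported.

5′UTR reads are allocated to every uORF whose interval [start, end)
contains their P-site — allocation is per-uORF feature quantification,
not a partition of the library, so a read inside two overlapping uORFs
counts for both; the `n_overlapping` column lets users deduplicate.
uORF RPKM uses the uORF length as denominator.

## Rhythm detection

The primary test compares each time course against cosine reference
templates cos(2π(t − φ)/τ) evaluated at the raw sample times
(replicates at the same t hit the same template value; CT0 and CT24 are
distinct samples whose template values coincide, so no wrap-around
special case is needed). Default grid: τ = 24 h only — with 4-h
sampling over a single day the design tests circadian rhythmicity, not
period estimation (a 20–28 h grid is available) — and one template per
4 h of phase, the sampling interval; finer grids only add tied
templates after rank conversion.

For each template, Kendall's S = Σ_{i<j} sign(y_j − y_i)·sign(c_j − c_i)
and τ_b with tie-corrected denominator. The null distribution of S
against a fixed tie pattern is exact: with template tie-group sizes
g_1..g_m, the concordant-pair count follows the Gaussian-multinomial
distribution ∏_i [(g_1+…+g_i) choose g_i]_q, computed by polynomial
convolution; two-sided p doubles the upper tail (capped at 1). For
n > 25 a normal approximation with continuity correction is used and
flagged. The exact null assumes distinct data ranks (ties only in the
template) — the classical assumption; with heavily tied counts p-values
are approximate.

The reported p is the template minimum with a Bonferroni factor equal
to the number of *sign-distinct* templates (a template and its
anti-phase mirror are the same two-sided test; 3 for the default 6-phase
grid). An uncorrected minimum is markedly anticonservative (realized
type-I ≈ 0.11 at nominal 0.05 on this design), while the corrected
version measures ≈ 0.04 — slightly conservative, the behaviour this
family of rank tests is known for. When the winning template is
anti-correlated (S < 0) the reported peak phase is mirrored by half a
period, so `phase` is always the estimated peak time in [0, τ). Ties
among equally minimal templates break to the smallest phase, then the
smallest period. Family-wise control across features is
Benjamini–Hochberg; the replicate handling default is pooled (14 points
for 7 timepoints × 2), with averaging available upstream if desired.

Amplitude and mesor come from the cosinor fit
y = M + β₁cos(2πt/τ) + β₂sin(2πt/τ): A = √(β₁²+β₂²),
φ = atan2(β₂, β₁)·τ/2π normalized to [0, τ), p from the F-test of
(β₁, β₂) = 0; a singular design (all times equal modulo τ) raises. The
Lomb–Scargle periodogram is the classical normalized form (scipy), with
a 16–32 h default period grid; constant series get zero power.

## Integration

Phase delay is the circular difference (protein phase − ribosome phase)
mod 24 mapped to (−12, +12] (signed delays are the quantity of
interest; the ±12 ambiguity resolves to +12). Production efficiency is
protein copies/cell per ribosome RPKM per timepoint,
replicate-averaged; translation efficiency is ribosome RPKM per RNA
RPKM and is skipped with a logged notice when no RNA table exists.
Zero denominators yield missing values, never infinities. 24-h summary
comparisons use arithmetic means over all sampled points (CT0 and CT24
both included as collected). uORF-dose stratification bins transcripts
by uORF count (k ≥ 5 pooled) and reports per-bin n/median/quartiles of
mean CDS RPKM plus a monotone-trend statistic: Kendall τ between k and
RPKM with its normal-approximation p.

## Synthetic data

The generator emulates the study design: 7 timepoints (CT0..CT24, 4-h
spacing) × 2 replicates. Defaults, chosen once as the study conditions:
2,000 transcripts; 5′UTRs 60–240 nt, CDS 80–400 codons, 3′UTRs
50–300 nt; uORF count Poisson(0.8), putting roughly half of transcripts
at k ≥ 1 (a balanced k ∈ {0..4} option serves dose-response designs);
repression factor r = 0.6 per planted uORF on CDS depth; 20% of
transcripts rhythmic with relative amplitude 0.3–0.6 and phases
von-Mises concentrated at CT0 (κ = 2; κ = 0 gives uniform phases for
null calibration); negative-binomial counts with dispersion 0.1
(Poisson as the dispersion→0 limit — profiling replicates are
overdispersed); frame bias (0.6, 0.25, 0.15); per-nt region weights
0.1/1.0/0.02 for UTR5/CDS/UTR3; uORF-interval reads with occupancy
0.5–2× CDS per-nt depth and a 2-h phase lead (uORF binding peaking
slightly before the CDS is a modelling knob, not a claim); 200,000
reads per sample — a deliberately desk-scale library that keeps the
full default pipeline under a minute while leaving the planted-effect
recoveries comfortably measurable. Protein series are cosines with the
planted phase shifted by a turnover delay (default +6 h), rescaled to
copies/cell, with 5% multiplicative Gaussian noise.

Planted uORFs are ATG + safe interior codons (no in-frame stop, no
nested ATG) + stop, placed without overlap; with background scrubbing
(default) every off-target ATG trigram in the 5′UTR is repaired, so a
canonical scan returns exactly the planted intervals; without
scrubbing it returns a superset. Reads are emitted in 5′-end mode by
inverting the +12 P-site offset (reads whose 5′ end would be negative
are dropped). Identical seed + config gives byte-identical files.

What the generator does *not* emulate: sequencing error, rRNA/tRNA
contamination, alignment ambiguity, isoform structure, nonuniform
codon-level pausing, or coupling between RNA abundance and translation.
Passing recovery tests therefore demonstrates correctness of the
analysis chain under the stated generative model, not robustness to
every artefact of real libraries.

## Numerical choices and degenerate inputs

Template cosines are rounded to 9 decimals before tie-grouping;
constant series return p = 1 with undefined τ; all-tied inputs to
Kendall's τ_b give (NaN, 0). Duplicate footprint keys are summed with a
warning; negative counts/positions and unknown transcripts are hard
errors. BH propagates NaN p-values outside the tested family. The
dose-response trend is undefined with fewer than two non-empty bins.
Seeds: every stochastic component takes a numpy Generator or an integer
seed; the CLI threads `--seed` through the generator and records it in
the run snapshot.

## Known limitations

- The exact Kendall null conditions on distinct data ranks; heavy count
  ties make p-values approximate (conservative in practice).
- Phase resolution equals the sampling interval (4 h); recovered phase
  delays land on the grid, so a planted +6 h delay reports as +4 or +8.
- One cosine harmonic only; asymmetric waveforms reduce power.
- BED12 support covers single records projected to transcript space,
  not general GTF exon arithmetic.
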