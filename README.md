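# riborhythm

Circadian analysis of ribosome-profiling data in transcript space:
footprint quantification, upstream open reading frame (uORF) discovery,
rank-based rhythm detection, and integration of ribosome binding with
protein abundance time courses.

## The problem

Around-the-clock ribosome profiling (e.g. mouse liver sampled at CT0,
CT4, ..., CT24 with replicates) measures *when* each mRNA is being
translated. Turning footprint alignments into biology needs a chain of
well-defined steps: shifting read 5′ ends to ribosomal P-sites,
restricting to transcripts with enough coverage to trust, detecting
24-h rhythms in occupancy, cataloguing uORFs in 5′UTRs (down to the
minimal ATG-stop pair, whose mutation derepresses the main CDS), and
relating translation to absolute protein levels. `riborhythm`
implements that chain as a tested library plus CLI, together with a
seeded synthetic-data generator so every stage can be validated against
planted ground truth.

## Core methods

- **P-site quantification.** Read 5′ ends are shifted by a
  length-dependent offset (default +12 nt for 26–32-nt footprints).
  Per-region counts are reported as RPKM = reads / (kb × mapped reads
  in millions); QC reports region fractions and the 3-nt reading-frame
  periodicity of CDS-mapped P-sites.
- **Well-translated filter.** Nonoverlapping five-codon windows are
  tiled across the CDS after excluding the first 15 and last 5 codons;
  a transcript passes if the median window read sum (pooled across all
  samples) is ≥ 2.
- **uORF scanner.** Every start codon in the 5′UTR (ATG, or the nine
  near-cognate single-mismatch variants) paired with its first in-frame
  stop codon inside the UTR. 5′UTR reads are allocated to uORF
  intervals for uORF-level rhythm analysis, and CDS occupancy is
  stratified by uORF count k (multiplicative repression per uORF).
- **Rhythm detection (JTK-style).** Each series y(t) is compared with
  cosine templates cos(2π(t − φ)/τ) over a period/phase grid via
  Kendall's τ_b. The null distribution of the Kendall S statistic is
  exact for the template's tie pattern (Gaussian-multinomial
  convolution), with a Bonferroni correction over sign-distinct
  templates; Benjamini–Hochberg controls FDR across features. Amplitude
  A, mesor M and acrophase φ come from a cosinor fit
  y = M + A·cos(2π(t − φ)/τ); Lomb–Scargle periodograms cover long
  irregular series.
- **Integration.** Circular phase delay (protein − ribosome, mapped to
  (−12, +12] h), protein production efficiency (copies/cell per
  ribosome RPKM), translation efficiency (ribosome RPKM per RNA RPKM)
  and ordinary regression summaries.

## Worked example

```python
import numpy as np
from riborhythm import TranscriptModel, scan_uorfs, TimeCourse, jtk_test

model = TranscriptModel(
    transcript_id="Per2-like",
    sequence="GGCC" + "ATGTAA" + "GCCA" + "ATG" + "GCT" * 8 + "TGA" + "C" * 12,
    utr5_len=14, cds_len=30, utr3_len=12,
)
for u in scan_uorfs(model, "canonical"):
    print(f"uORF {u.start}-{u.end}  start={u.start_codon}  "
          f"length={u.length_L} nt  distance_to_CDS={u.distance_d} nt")

t = np.repeat(np.arange(0.0, 25.0, 4.0), 2)      # CT0..CT24, 2 replicates
rng = np.random.default_rng(0)
y = 12.0 * (1 + 0.5 * np.cos(2 * np.pi * (t - 8.0) / 24.0))
y += 1.5 * rng.standard_normal(len(t))
res = jtk_test(TimeCourse("Per2-like", t, y))
print(f"period={res.period} h  phase=CT{res.phase:.0f}  tau={res.tau:.3f}  "
      f"amplitude={res.amplitude:.2f}  mesor={res.mesor:.2f}  p={res.p:.2e}")
```

prints

```
uORF 4-10  start=ATG  length=6 nt  distance_to_CDS=4 nt
period=24.0 h  phase=CT8  tau=0.839  amplitude=6.91  mesor=11.85  p=1.90e-05
```

The scanner finds the minimal 6-nt uORF (a bare ATG–TAA pair) 4 nt
upstream of the CDS, and the rhythm test recovers the planted CT8 peak
of the noisy series: τ_b = 0.84 against the best template, a fitted
amplitude of 6.9 RPKM around a mesor of 11.9 (planted: 6 and 12), and
an exact-null p of 2×10⁻⁵.

## Command line

```bash
riborhythm simulate --out ds --seed 1          # synthetic dataset + truth
riborhythm qc       --dataset ds --out out/qc
riborhythm filter   --dataset ds --out out/filter
riborhythm uorf     --dataset ds --out out/uorf
riborhythm rhythm   --dataset ds --out out/rhythm --features cds
riborhythm integrate --dataset ds --out out/integrate
```

All outputs are headered TSVs; each command writes a `run_config.json`
snapshot (parameters, seed, input checksums) and re-running with the
same inputs reproduces byte-identical files.

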