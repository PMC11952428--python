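# fibermod

Analysis toolkit for **antibody-directed DNA-methylation footprinting read
out by long-read sequencing**. In these assays a methyltransferase (e.g.
Hia5) is tethered by an antibody to a chromatin protein such as CTCF and
deposits N6-methyladenine (6mA) on accessible DNA near the binding site;
basecallers report each candidate base with an 8-bit confidence score in
the BAM MM/ML auxiliary tags, alongside endogenous CpG 5-methylcytosine.
The single-molecule readout carries rich structure: a methylation footprint
over the bound motif, nucleosome-phased oscillation of the flanking signal,
an exponential decay of peak methylation with distance from the site, and
allele-specific anticorrelation between binding (6mA) and CpG methylation
at imprinted loci.

The package is organised as an analysis project: every computation lives in
the library under `src/fibermod/`, the numbered scripts under `analysis/`
drive the study end to end, and `tests/` + `scripts/acceptance.py` validate
the whole chain against ground truth.

## What it does

- **`modbam_io`** — decode/encode MM/ML modified-base tags of aligned
  SAM/BAM records into reference-coordinate calls; bin-midpoint probability
  conversion `p = (score + 0.5)/256` (score 225 ↔ 0.88, 250 ↔ 0.98);
  single-cutoff binarization.
- **`fiber_sim`** — generative simulator of single chromatin fibers under
  the tethered-enzyme model: binding with probability `p_bound`, deposition
  probability `A·exp(−λ·|d|)` gated by a motif footprint and jittered
  phased nucleosomes, accessibility-driven IgG background, allele-specific
  CpG states, Beta-distributed basecaller scores; emits sorted indexed
  modBAM plus a ground-truth table.
- **`profile_agg`** — pileups and strand-aware, motif-centered aggregate
  profiles with box smoothing, non-targeting control subtraction, and fold
  enrichment.
- **`decay_fit`** — peak detection on the oscillating profile and bounded
  nonlinear least squares of `h = a·exp(−λ·d) + c` on flanking peak
  heights; condition comparison with propagated uncertainties.
- **`single_read`** — per-read binary methylation matrices in site-centered
  coordinates, split by strand and sorted by methylated fraction.
- **`haplotype`** — parental-allele splitting by contig suffix on a diploid
  assembly and the maternal/paternal imprinting contrast with two-proportion
  z statistics.
- **`regions`** — exact IUPAC consensus scanning on both strands and
  center-containment interval classification, feeding per-class profiles.
- **`image_quant`** — the 3D immunofluorescence arm: 7×7×3 median filter,
  Otsu segmentation with size filtering, a 2-voxel cytoplasm shell,
  chromosome/shell intensity ratios, Welch t-tests, and a confocal phantom
  generator with known ratios.
- **`pipeline` / CLI** — one `fibermod` entry point with subcommands
  (`simulate`, `pileup`, `profile`, `decayfit`, `comparefits`,
  `singleread`, `imprint`, `scan`, `classify`, `ifquant`, `run`).

## Worked example

Simulate a targeted and a non-targeting dataset on a shared reference and
measure enrichment, then fit the flanking decay:

```bash
python analysis/01_simulate_fibers.py
python analysis/02_enrichment_profiles.py
python analysis/03_decay_fit.py
```

which prints (seed 1):

```
 confidence  threshold_score  fold_enrichment
       0.75              192         5.036780
       0.88              225         4.940045
       0.98              251         5.002809

fold enrichment at score 225: 4.94 (>2-fold); variation across 0.75-0.98 band: 2.0%

default fit: a=0.0846 (truth 0.0741), lambda=0.00555/bp (truth 0.00500), 11 peaks
contrast: amplitude ratio 1.40 (generated 1.40), decay-constant ratio 1.24 (generated 1.25)
```

Reading this: targeted methylation near the motif is ~5-fold above the
accessibility-driven IgG background, and the fold is essentially flat
across confidence thresholds from 0.75 to 0.98 because the score model
rescales both conditions alike. The decay fit recovers the generative
spatial constraint λ = 1/200 bp⁻¹ within ~11% and, when two conditions are
generated with amplitude ratio 1.4 and decay-constant ratio 1.25, the
fitted ratios land on 1.40 and 1.24 — i.e. the "more efficient, tighter"
contrast is quantitatively recoverable from aggregate profiles.

The remaining scripts produce the single-read panels
(`04_single_read_matrix.py`), the haplotype imprinting contrast
(`05_imprinting.py`: maternal 6mA excess z ≈ 7, paternal CpG excess
z ≈ 14 at 25× coverage), motif/region-class profiles
(`06_motif_regions.py`), and the IF phantom cohort
(`07_if_quantification.py`: group means 3.00/2.00/1.20/1.00 against truth
3.0/2.0/1.2/1.0, Welch p < 10⁻¹⁰ for every stained group vs control).
Tables land in `results/`; BAM-scale intermediates go to `scratch/`.

## Layout

```
src/fibermod/      library (all computation)
analysis/          numbered study drivers
tests/             pytest suite incl. end-to-end scientific checks
scripts/           acceptance runner
docs/methods.md    model, estimator and design notes
```
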