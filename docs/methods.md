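# Methods

This note documents the models, estimators and design choices behind
fibermod: what the simulator generates and why, how each measurement is
defined, which numerical conventions are in force, and what the synthetic
validation does and does not establish about real data.

## Modified-base call model

A call is a (reference position, channel, integer score) triple decoded
from the MM/ML auxiliary tags of an aligned record. Scores `s ∈ 0..255`
encode the probability bin `[s/256, (s+1)/256)`; we label calls with the
bin midpoint `p = (s + 0.5)/256`, under which the conventional thresholds
225 and 250 correspond to 0.88 and 0.98 confidence at two decimals. Two
channels are supported: 6mA on adenines (`A+a`) and 5mC on CpG cytosines
(`C+m`), both expressed on the original read strand; other channels are
skipped with a warning. Thresholding is a single cutoff: a call with
`score ≥ t` is methylated, any other call is unmethylated and stays in the
denominator, so pileup depth does not depend on `t`. Implicit-skip and
explicitly listed MM flavors are treated identically. Coordinates are
0-based half-open throughout; decoding goes through the CIGAR, and calls on
inserted or clipped bases carry no reference position.

## Generative fiber model

`fiber_sim` draws aligned single-molecule reads from an explicit model of
tethered-enzyme footprinting. Per fiber and site, binding occurs with
probability `p_bound` (default 0.8). On a bound fiber, each adenine of the
molecule's strand at distance `d` from the motif center is truly methylated
with probability

```
P(6mA | d) = A_teth · exp(−lam_teth · |d|) · access(d)
```

with `A_teth = 0.6` and `lam_teth = 1/200 bp⁻¹` — an amplitude and spatial
constraint of the order seen in deep targeted datasets. `access(d)` is a
0/1 mask: zero inside the motif footprint (±60 bp) and inside each phased
nucleosome core. A linker of `NRL − core_len = 43 bp` abuts the footprint,
then 147-bp cores repeat every `NRL = 190 bp`; the k-th core center is
jittered by `Normal(0, 10·k)` bp independently per fiber and flank, so
phasing decays with distance, as aggregate profiles show. Placing the
linker against the footprint (rather than a core) is what produces the
observed geometry — tallest methylation peaks immediately flanking the
motif and >2-fold near-site enrichment over background; a core-first
arrangement would put the first accessible DNA ~200 bp out and invert the
near-site contrast.

Unbound fibers and the non-targeting (IgG) condition receive background
methylation `bg_rate · boost · access` with randomly phased nucleosomes,
`bg_rate = 0.03`, and `boost = 3` within ±200 bp of sites — free enzyme
preferentially marks accessible site-proximal DNA, which is why IgG
controls show site-centered signal at all. The IgG condition forces
`p_bound = 0`.

CpG methylation is anticorrelated with binding: near-site CpGs (±200 bp)
methylate at 0.1 on bound fibers and 0.9 on unbound ones (0.7 far from
sites). In diploid mode two identical contigs named `*_MATERNAL` /
`*_PATERNAL` emulate an imprinting control region: the maternal allele
binds (`p_bound` as configured) with hypomethylated near-site CpGs, the
paternal allele never binds and is CpG-hypermethylated; the near-site CpG
state is allele-wide, as imprinting is.

Scores are drawn from `255·Beta(9,1)` for truly modified bases and
`255·Beta(1,9)` otherwise, rounded to integers. This puts the true-positive
rate at 0.68 for threshold 225 and 0.17 at 250 with a negligible
false-positive rate (~10⁻⁸ at 225), so threshold choices rescale both
target and control signal by the same factor — the mechanism behind the
observed threshold-insensitivity of fold enrichment.

Reads are uniform random fragments (Normal length, mean 15 kb, sd 2 kb,
floor 2 kb) at 25× default coverage, emitted pre-aligned with perfect-match
CIGARs (alignment is out of scope; the analyses consume coordinates).
Bases are emitted as the reference — no sequencing errors — and fragment
lengths have no heavy tail. Every candidate base (all adenines of the
molecule's strand; all strand-appropriate CpG cytosines) receives a call,
and a ground-truth table records each read's bound state, haplotype and
true-methylated positions, so conservation (truth ⊆ emitted calls) is
testable.

## Profiles and enrichment

Pileups count, per reference position, calls of one channel (depth) and
calls above threshold (methylated), strands pooled. Site-centered
aggregation bins calls at offsets −W..+W from the motif center
(`floor((start+end)/2)`; the ≤1 bp asymmetry of even motifs is far below
the smoothing scale), reverses the axis for minus-strand sites, and pools
raw counts across sites (depth weighting keeps integer conservation exact
and matches pileup semantics; equal-per-site weighting is available).
Smoothing is a centered box filter over `window` bp (51 taps for the
default window 50), truncated at edges, with zero-depth offsets excluded;
window 0 is the identity. Control subtraction is a plain positionwise
difference of (smoothed) fractions, no renormalization, negatives retained.
Fold enrichment is the ratio of mean unsmoothed fractions over
|offset| ≤ 150 bp, target over control; a zero control mean reports
infinity with a flag.

## Decay fitting

Peaks are strict local maxima of a smoothed profile (window ≥ 20 bp),
outside a central exclusion zone (default ±60 bp, the footprint) and
within ±1000 bp, accepted greedily in descending height with ≥120 bp
mutual separation per flank; both flanks pool into distances `d =
|offset|`. Heights are fit with bounded (nonnegative) Levenberg–Marquardt
via trust-region least squares to `h = a·exp(−λ·d) + c`, initialized at
`a = range(h)`, `c = min(h)`, `λ = ln2/500`, with up to five perturbed
restarts; standard errors come from the local curvature. The baseline `c`
is included by default because aggregate profiles sit on a nonzero
background and omitting it biases λ; `baseline=False` gives the strict
two-parameter form. Constant heights collapse to a flagged degenerate
branch (`a→0, c=h`). Condition comparisons report `a₁/a₂` and `λ₁/λ₂` with
first-order error propagation; a larger λ ratio means a tighter spatial
distribution.

**Peak-height estimator for parameter recovery.** Point heights of far
peaks are depressed by nucleosome jitter (contrast falls roughly as
`exp(−(2πσₖ/NRL)²/2)` with σₖ = 10·k), which inflates a point-height λ by
~20% under the default generator. Jitter redistributes accessible mass
within each repeat but approximately conserves it, so
`period_averaged_heights` re-measures each detected peak as the mean raw
profile over one NRL centered on it; these heights decay with the true
envelope constant (residual bias ~+10%). Recovery analyses and the
acceptance runner use this estimator; its amplitude is on the
period-averaged scale, expected to equal

```
a_expected = p_bound · [A_teth·TPR(t) + (1−A_teth)·FPR(t)] · (linker/NRL)
```

with TPR/FPR from the Beta score model — the observable amplitude, since
`A_teth` alone is not identifiable after thresholding.

## Single-read matrices

Each read overlapping a site window is one row of {methylated,
unmethylated, no-call} cells at site-centered offsets (flipped for
minus-strand sites), at the stricter display threshold 250. Rows are
(read × site) pairs — a long read legitimately appears under several
windows. The per-row fraction is computed within the displayed window
(whole-read variant behind a flag), rows group by alignment strand and
sort by descending fraction with read-id tie-breaks, so ordering is a
deterministic, permutation-invariant function of the row set.
Column-summing the matrix reproduces the unsmoothed aggregate profile
exactly at the same threshold.

## Haplotype contrasts

Allele assignment is purely by `*_MATERNAL`/`*_PATERNAL` contig suffix of a
haplotype-resolved assembly; no SNP phasing. The imprinting contrast pools
calls over user-supplied homologous windows (maternal and paternal
coordinates generally differ; no liftover) and reports Δ6mA = maternal −
paternal and ΔCpG = paternal − maternal with pooled two-proportion z
statistics. The z treats calls as independent; calls on one fiber are
correlated, so z values are anticonservative in absolute terms and should
be read as strong/weak evidence rather than calibrated p-values. The
analyses use ±500 bp windows around a site center — about 2.5 tether decay
lengths, where targeted signal concentrates — chosen by a design-time
power scan and then frozen.

## Motif scanning and region classes

The scanner does exact IUPAC-consensus matching (regex with lookahead, so
overlapping hits are all reported) on the forward sequence and its reverse
complement, minus-strand hits in forward coordinates; a palindromic
pattern yields both strands at one interval. A log-odds PWM scanner is
deliberately out of scope: no matrix is shipped, and exact matching is
reproducible and sufficient for planted-motif validation. Site
classification assigns the annotation class containing the site center,
smallest containing interval first, then input order; sites in no
annotation are `"none"`. Per-class profiles delegate to the aggregator and
flag classes with fewer than 5 sites.

## Immunofluorescence quantification

Per manually cropped ROI: a 7×7×3 (y, x, z) median filter on the DAPI
channel — the smaller axial extent reflects coarser confocal z-sampling —
then a global threshold (Otsu by default, manual override available),
26-connected 3D component labeling, and removal of components below
`min_size` voxels. The cytoplasm estimate is a shell: dilation of the
chromosome mask by an isotropic radius-2 ball minus the mask ("2-voxel
rind"; the stated shell construction is ambiguous, so the radius is
configurable). The measurement is the ratio of mean antibody-channel
intensity over mask vs shell; groups are compared to the secondary-only
control with two-sided Welch t-tests, no multiple-testing correction
(per-line reporting).

**Phantoms.** `simulate_cells` builds two-channel stacks with a random
ellipsoid DAPI envelope and an antibody channel at `ratio × cytoplasm`
on the chromosome region, Gaussian noise on both channels. A digital
phantom cannot represent sub-voxel boundaries: with hard-edged ellipsoids
the segmented mask tracks the 50%-neighborhood-coverage isocontour, the
2-voxel shell clips the bright partial-volume rim, and the measured ratio
is biased low by ~10–20% regardless of noise. The phantom therefore
defines the signal-bright chromosome region as the median-stable interior
of the DAPI envelope (voxels whose 7×7×3 neighborhood is majority-inside),
making the generative ratio exactly recoverable. Phantom validation thus
establishes correctness of the filtering/segmentation/shell/statistics
chain under noise — not sub-voxel boundary accuracy, which on real images
remains a partial-volume limitation of the ratio definition itself.

## Reproducibility and problem sizes

All randomness flows from explicit seeds through `numpy.random.default_rng`;
identical seed and configuration give byte-identical datasets, and the
pipeline summary records the package version and a hash of every semantic
parameter. The validation suite runs at desk scale, chosen so each check
has clear statistical margin on one CPU: 50 sites × 25× coverage on a
600 kb genome for enrichment and parameter recovery (binomial error on λ
well under the 20% recovery band), a 150-site panel for the
condition-contrast ratios (the λ ratio is the noisiest statistic; at 150
sites its seed-to-seed spread is ~2–3 percentage points), 2×600 kb at 25×
for the diploid contrast, and 10 phantoms per group for the IF cohort.

## What passing tests do and do not show

The simulator reproduces the qualitative structure of targeted-methylation
data — footprint, phased oscillation, exponential flank decay, accessible
background, allele asymmetry, score noise — with independent fibers,
error-free bases, perfect alignments, a single motif, uniform coverage and
stationary nucleosome statistics. Real datasets add alignment error and
mappability structure, copy-number and repeat complexity, antibody
efficiency variation between sites, fragment-length heavy tails, and
basecaller score miscalibration; none of these are modeled, so green tests
certify the correctness of the measurement chain under the stated model,
not performance on any particular biological sample.
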