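"""Synthetic single-fiber modified-base datasets with known ground truth.

The generative model mirrors what antibody-tethered adenine-methyltransferase
footprinting measures on chromatin fibers:

* a protein bound at a planted motif deposits 6mA on accessible adenines with
  probability ``A_teth * exp(-lam_teth * |d|)`` at distance ``d`` from the
  motif center (the tethered enzyme's reach decays with distance);
* the bound protein footprints its own motif (no 6mA within
  ``footprint_halfwidth`` of the center);
* nucleosomes phased against the bound site block methylation inside their
  147-bp cores, with positional jitter growing with nucleosome index, which
  produces the characteristic oscillating aggregate profile;
* unbound fibers (and non-targeting IgG controls) receive accessibility-driven
  background methylation from free enzyme, elevated near open sites;
* CpG methylation is anticorrelated with binding (bound/maternal alleles
  hypomethylated, unbound/paternal alleles hypermethylated);
* integer confidence scores are drawn from separate Beta distributions for
  truly modified and unmodified bases, emulating basecaller uncertainty.

Reads are emitted as coordinate-sorted, indexed BAM with MM/ML tags plus a
ground-truth TSV, so every downstream analysis can be validated against
known parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from . import modbam_io
from .modbam_io import encode_read, revcomp, set_mod_tags

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class FiberSimConfig:
    """Full generative parameter set; defaults give realistic desk-scale data.

    Distances are bp, probabilities in [0, 1].  ``lam_teth`` is the per-bp
    decay constant of the tethered enzyme's reach (default 1/200 bp^-1, i.e.
    a ~200 bp e-folding radius).  Identical seed + config gives identical
    output.
    """

    seed: int = 0
    genome_length: int = 600_000
    n_sites: int = 50
    motif: str = "CCGCGAGGTGGCAG"
    site_spacing: int = 10_000
    p_bound: float = 0.8
    A_teth: float = 0.6
    lam_teth: float = 1.0 / 200.0
    footprint_halfwidth: int = 60
    nrl: int = 190  # nucleosome repeat length
    core_len: int = 147
    jitter_sd: float = 10.0  # sd of core-center jitter, scaled by index k
    n_phased_cores: int = 6  # phased cores per flank on bound fibers
    bg_rate: float = 0.03
    site_access_boost: float = 3.0
    boost_halfwidth: int = 200
    cpg_near_bound: float = 0.1
    cpg_near_unbound: float = 0.9
    cpg_far: float = 0.7
    cpg_near_halfwidth: int = 200
    score_meth: tuple[float, float] = (9.0, 1.0)  # Beta params, x255
    score_unmeth: tuple[float, float] = (1.0, 9.0)
    frag_len_mean: int = 15_000
    frag_len_sd: int = 2_000
    coverage: float = 25.0
    diploid: bool = False

    def validate(self) -> None:
        probs = [self.p_bound, self.A_teth, self.bg_rate,
                 self.cpg_near_bound, self.cpg_near_unbound, self.cpg_far]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.nrl <= self.core_len:
            raise ValueError("nucleosome repeat length must exceed core length")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.n_sites * self.site_spacing >= self.genome_length:
            raise ValueError("n_sites * site_spacing must be < genome_length")
        if any(b not in IUPAC for b in self.motif.upper()):
            raise ValueError(f"motif contains non-IUPAC codes: {self.motif}")

    def replace(self, **kw) -> "FiberSimConfig":
        return dataclasses.replace(self, **kw)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


# ---------------------------------------------------------------------------
# score model

def true_positive_rate(threshold_score: int, config: FiberSimConfig) -> float:
    """P(score >= threshold | base truly modified) under the Beta score model."""
    return _score_exceedance(threshold_score, config.score_meth)


def false_positive_rate(threshold_score: int, config: FiberSimConfig) -> float:
    """P(score >= threshold | base unmodified) under the Beta score model."""
    return _score_exceedance(threshold_score, config.score_unmeth)


def _score_exceedance(threshold_score: int, beta_params) -> float:
    t = int(threshold_score)
    if t <= 0:
        return 1.0
    a, b = beta_params
    # score = round(255 * x): score >= t  iff  x >= (t - 0.5) / 255
    return float(stats.beta.sf((t - 0.5) / 255.0, a, b))


def expected_amplitude(config: FiberSimConfig, threshold_score: int) -> float:
    """Expected observed methylated fraction at distance 0 on an accessible,
    bound fiber: the generative amplitude filtered through the score model."""
    tpr = true_positive_rate(threshold_score, config)
    fpr = false_positive_rate(threshold_score, config)
    return config.A_teth * tpr + (1.0 - config.A_teth) * fpr


def _draw_scores(rng, truth: np.ndarray, config: FiberSimConfig) -> np.ndarray:
    a1, b1 = config.score_meth
    a0, b0 = config.score_unmeth
    x = np.where(truth, rng.beta(a1, b1, truth.size), rng.beta(a0, b0, truth.size))
    return np.clip(np.rint(255.0 * x), 0, 255).astype(np.int64)


# ---------------------------------------------------------------------------
# reference construction

def _instantiate_motif(motif: str, rng) -> str:
    return "".join(IUPAC[b][rng.integers(len(IUPAC[b]))] for b in motif.upper())


def make_reference(config: FiberSimConfig, rng=None):
    """Random-base genome with the motif planted at regular spacing on
    alternating strands.  Returns ``(contigs, sites)``: a dict of contig name
    to sequence and a BED-like DataFrame (contig, start, end, name, strand).

    Diploid mode emits two contigs of identical sequence named with
    ``_MATERNAL`` / ``_PATERNAL`` suffixes, sites at identical offsets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    seq = rng.choice(list("ACGT"), size=config.genome_length)
    motif_len = len(config.motif)
    rows = []
    for i in range(config.n_sites):
        start = config.site_spacing // 2 + i * config.site_spacing
        strand = "+" if i % 2 == 0 else "-"
        inst = _instantiate_motif(config.motif, rng)
        planted = inst if strand == "+" else revcomp(inst)
        seq[start:start + motif_len] = list(planted)
        rows.append((start, start + motif_len, f"site_{i:03d}", strand))
    genome = "".join(seq)
    if config.diploid:
        contigs = {"chr_sim_MATERNAL": genome, "chr_sim_PATERNAL": genome}
    else:
        contigs = {"chr_sim": genome}
    sites = pd.DataFrame(
        [(c, s, e, n, st) for c in contigs for (s, e, n, st) in rows],
        columns=["contig", "start", "end", "name", "strand"],
    )
    return contigs, sites


def simulate_reference(config: FiberSimConfig, out_fasta, out_bed):
    """Write the synthetic reference FASTA (+ .fai index) and site BED."""
    contigs, sites = make_reference(config)
    out_fasta, out_bed = Path(out_fasta), Path(out_bed)
    with open(out_fasta, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    pysam.faidx(str(out_fasta))
    sites.to_csv(out_bed, sep="\t", header=False, index=False,
                 columns=["contig", "start", "end", "name", "strand"])
    return contigs, sites


# ---------------------------------------------------------------------------
# accessibility model

def accessibility(d, *, bound: bool, config: FiberSimConfig, rng=None,
                  phase_offset: float = 0.0):
    """Accessibility multiplier (0 or 1) at distance ``d`` from a site center.

    Bound fibers: 0 inside the motif footprint and inside each phased
    nucleosome core.  A linker of length ``nrl - core_len`` abuts the
    footprint (the tethered enzyme's tallest peak sits immediately outside
    the footprint), then cores repeat every NRL; the k-th core center is
    jittered by Normal(0, jitter_sd*k) when ``rng`` is given, deterministic
    otherwise.  Unbound fibers: cores tiled with the uniform phase
    ``phase_offset`` (no alignment across fibers).  Accepts scalars or
    arrays.
    """
    d = np.asarray(d, dtype=float)
    if bound:
        centers = phased_core_centers(config, rng)
        acc = np.abs(d) >= config.footprint_halfwidth
        half = config.core_len / 2.0
        for c in centers:
            acc &= ~((d >= c - half) & (d < c + half))
    else:
        # core occupies [phase + m*nrl, phase + m*nrl + core_len)
        rel = np.mod(d - phase_offset, config.nrl)
        acc = rel >= config.core_len
    return acc.astype(float)


def phased_core_centers(config: FiberSimConfig, rng=None) -> np.ndarray:
    """Jittered centers of the phased nucleosome cores on both flanks."""
    ks = np.arange(1, config.n_phased_cores + 1)
    linker = config.nrl - config.core_len
    base = (config.footprint_halfwidth + linker + config.core_len / 2.0
            + (ks - 1) * config.nrl)
    if rng is None:
        jr = jl = np.zeros_like(base)
    else:
        jr = rng.normal(0.0, config.jitter_sd * ks)
        jl = rng.normal(0.0, config.jitter_sd * ks)
    return np.concatenate([base + jr, -(base + jl)])


# ---------------------------------------------------------------------------
# fiber simulation

@dataclass
class SimulatedFiber:
    """One synthetic fiber: aligned coordinates plus per-base ground truth."""

    read_id: str
    contig: str
    start: int
    end: int
    strand: str  # aligned/molecule strand of the read
    site_id: int  # nearest overlapped site index, -1 if none
    bound: bool  # bound at the nearest site
    haplotype: str | None
    a_positions: np.ndarray  # ref positions of all adenine calls (read strand)
    a_truth: np.ndarray  # true modification state per adenine call
    a_scores: np.ndarray
    cpg_positions: np.ndarray
    cpg_truth: np.ndarray
    cpg_scores: np.ndarray
    sequence: str  # reference-forward sequence of the fragment


def _methylation_probability(positions, site_centers, bound_flags, tether_on,
                             config: FiberSimConfig, rng) -> np.ndarray:
    """Per-position probability that an accessible-channel adenine is truly
    methylated, combining tethered deposition at bound sites with
    accessibility-gated background elsewhere."""
    p = np.zeros(positions.size)
    reach = config.footprint_halfwidth + config.n_phased_cores * config.nrl
    phased = np.zeros(positions.size, dtype=bool)
    if tether_on:
        for center, bound in zip(site_centers, bound_flags):
            if not bound:
                continue
            d = positions - center
            local = np.abs(d) <= reach
            if not local.any():
                continue
            acc = accessibility(d[local], bound=True, config=config, rng=rng)
            teth = config.A_teth * np.exp(-config.lam_teth * np.abs(d[local])) * acc
            p[local] = np.maximum(p[local], teth)
            phased[local] = True
    # accessibility-driven background outside phased windows
    phase = rng.uniform(0.0, config.nrl)
    acc_bg = accessibility(positions - positions[0], bound=False, config=config,
                           phase_offset=phase)
    boost = np.ones(positions.size)
    for center in site_centers:
        boost = np.where(np.abs(positions - center) <= config.boost_halfwidth,
                         config.site_access_boost, boost)
    p_bg = np.minimum(config.bg_rate * boost, 1.0) * acc_bg
    return np.where(phased, p, p_bg)


def simulate_fiber(genome: str, seq_arr: np.ndarray, start: int, end: int,
                   strand: str, site_centers, bound_flags, haplotype,
                   config: FiberSimConfig, rng, read_id: str,
                   contig: str = "chr_sim", tether_on: bool = True,
                   cpg_near_override: float | None = None) -> SimulatedFiber:
    """Simulate true modification states and scores for one fiber.

    ``site_centers``/``bound_flags`` are the centers of sites whose influence
    can reach the fragment, and whether this fiber is bound at each.
    ``cpg_near_override`` fixes the near-site CpG probability (allele-wide
    imprinting); otherwise it follows the fiber's bound state per site.
    """
    positions = np.arange(start, end)
    frag = seq_arr[start:end]

    site_centers = np.asarray(site_centers, dtype=float)
    bound_flags = np.asarray(bound_flags, dtype=bool)
    p_meth = _methylation_probability(positions, site_centers, bound_flags,
                                      tether_on, config, rng)

    # adenines on the molecule's sequenced strand
    if strand == "+":
        a_mask = frag == b"A"
    else:
        a_mask = frag == b"T"
    a_positions = positions[a_mask]
    a_truth = rng.random(a_positions.size) < p_meth[a_mask]
    a_scores = _draw_scores(rng, a_truth, config)

    # CpG cytosines on the molecule's strand (C of CG on +, G of CG on -)
    is_c = frag == b"C"
    is_g = frag == b"G"
    if strand == "+":
        cpg_mask = is_c.copy()
        cpg_mask[:-1] &= is_g[1:]
        cpg_mask[-1] = False
    else:
        cpg_mask = is_g.copy()
        cpg_mask[1:] &= is_c[:-1]
        cpg_mask[0] = False
    cpg_positions = positions[cpg_mask]
    if site_centers.size:
        dmat = np.abs(cpg_positions[:, None] - site_centers[None, :])
        nearest = np.argmin(dmat, axis=1) if cpg_positions.size else np.array([], int)
        dist = dmat[np.arange(cpg_positions.size), nearest] if cpg_positions.size else np.array([])
        near = dist <= config.cpg_near_halfwidth
        if cpg_near_override is not None:
            p_near = np.full(cpg_positions.size, cpg_near_override)
        else:
            p_near = np.where(bound_flags[nearest], config.cpg_near_bound,
                              config.cpg_near_unbound)
        p_cpg = np.where(near, p_near, config.cpg_far)
    else:
        p_cpg = np.full(cpg_positions.size, config.cpg_far)
    cpg_truth = rng.random(cpg_positions.size) < p_cpg
    cpg_scores = _draw_scores(rng, cpg_truth, config)

    if site_centers.size:
        dists = np.abs(site_centers - (start + end) / 2.0)
        overlapped = (site_centers >= start) & (site_centers < end)
        if overlapped.any():
            cand = np.where(overlapped)[0]
            site_id = int(cand[np.argmin(dists[cand])])
            bound = bool(bound_flags[site_id])
        else:
            site_id, bound = -1, False
    else:
        site_id, bound = -1, False

    return SimulatedFiber(
        read_id=read_id, contig=contig, start=int(start), end=int(end),
        strand=strand, site_id=site_id, bound=bound, haplotype=haplotype,
        a_positions=a_positions, a_truth=a_truth, a_scores=a_scores,
        cpg_positions=cpg_positions, cpg_truth=cpg_truth, cpg_scores=cpg_scores,
        sequence=genome[start:end],
    )


def fiber_to_segment(fiber: SimulatedFiber, header: pysam.AlignmentHeader,
                     tid: int) -> pysam.AlignedSegment:
    """Emit a fiber as an aligned BAM record (perfect-match CIGAR) with MM/ML
    tags expressed on the original read strand."""
    length = fiber.end - fiber.start
    aln = pysam.AlignedSegment(header)
    aln.query_name = fiber.read_id
    aln.reference_id = tid
    aln.reference_start = fiber.start
    aln.mapping_quality = 60
    aln.cigarstring = f"{length}M"
    aln.flag = 0 if fiber.strand == "+" else 16
    aln.query_sequence = fiber.sequence  # stored in aligned orientation
    aln.query_qualities = pysam.qualitystring_to_array("I" * length)

    calls = []
    if fiber.strand == "+":
        read_seq = fiber.sequence
        for pos, score in zip(fiber.a_positions, fiber.a_scores):
            calls.append((pos - fiber.start, "A", "a", int(score)))
        for pos, score in zip(fiber.cpg_positions, fiber.cpg_scores):
            calls.append((pos - fiber.start, "C", "m", int(score)))
    else:
        read_seq = revcomp(fiber.sequence)
        for pos, score in zip(fiber.a_positions, fiber.a_scores):
            calls.append((fiber.end - 1 - pos, "A", "a", int(score)))
        for pos, score in zip(fiber.cpg_positions, fiber.cpg_scores):
            calls.append((fiber.end - 1 - pos, "C", "m", int(score)))
    mm, ml = encode_read(read_seq, calls)
    set_mod_tags(aln, mm, ml)
    return aln


# ---------------------------------------------------------------------------
# dataset simulation

def simulate_dataset(config: FiberSimConfig, condition: str, out_dir,
                     prefix: str | None = None):
    """Simulate a full aligned dataset for one assay condition.

    ``condition`` is ``"target"`` (antibody-directed: fibers bound with
    ``p_bound`` receive tethered methylation) or ``"igg"`` (non-targeting
    isotype control: binding forced to zero, background rates only).  Writes
    a coordinate-sorted indexed BAM, a ground-truth TSV, the reference FASTA
    and the site BED into ``out_dir``; returns a dict of paths.
    """
    if condition not in ("target", "igg"):
        raise ValueError(f"condition must be 'target' or 'igg', got {condition!r}")
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or condition

    rng = np.random.default_rng(config.seed)
    contigs, sites = make_reference(config, rng)
    fasta = out_dir / f"{prefix}_ref.fa"
    bed = out_dir / f"{prefix}_sites.bed"
    with open(fasta, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    pysam.faidx(str(fasta))
    sites.to_csv(bed, sep="\t", header=False, index=False)

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in contigs.items()],
    })
    tids = {n: i for i, n in enumerate(contigs)}

    tether_on = condition == "target"
    fibers: list[SimulatedFiber] = []
    for contig_name, genome in contigs.items():
        seq_arr = np.frombuffer(genome.encode(), dtype="S1")
        hap = modbam_io.haplotype_from_contig(contig_name)
        if config.diploid:
            p_bound = config.p_bound if hap == "maternal" else 0.0
            cpg_near = (config.cpg_near_bound if hap == "maternal"
                        else config.cpg_near_unbound)
        else:
            p_bound, cpg_near = config.p_bound, None
        if not tether_on:
            p_bound = 0.0

        csites = sites[sites.contig == contig_name]
        centers = ((csites.start + csites.end) // 2).to_numpy()
        L = len(genome)
        n_reads = int(round(config.coverage * L / config.frag_len_mean))
        reach = config.footprint_halfwidth + config.n_phased_cores * config.nrl

        starts = np.empty(n_reads, dtype=int)
        lengths = np.empty(n_reads, dtype=int)
        for i in range(n_reads):
            flen = int(np.clip(rng.normal(config.frag_len_mean, config.frag_len_sd),
                               2000, L))
            starts[i] = rng.integers(0, max(1, L - flen))
            lengths[i] = flen
        order = np.argsort(starts, kind="stable")
        for rank, i in enumerate(order):
            start, end = int(starts[i]), int(starts[i] + lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            influent = (centers >= start - reach) & (centers < end + reach)
            scenters = centers[influent]
            bflags = rng.random(scenters.size) < p_bound
            fiber = simulate_fiber(
                genome, seq_arr, start, end, strand, scenters, bflags, hap,
                config, rng, read_id=f"{contig_name}_read{rank:06d}",
                contig=contig_name, tether_on=tether_on,
                cpg_near_override=cpg_near,
            )
            fibers.append(fiber)

    bam_path = out_dir / f"{prefix}.bam"
    fibers.sort(key=lambda f: (tids[f.contig], f.start))
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for fiber in fibers:
            bam.write(fiber_to_segment(fiber, header, tids[fiber.contig]))
    pysam.index(str(bam_path))

    truth_path = out_dir / f"{prefix}_truth.tsv"
    rows = []
    for f in fibers:
        rows.append({
            "read_id": f.read_id, "contig": f.contig, "start": f.start,
            "end": f.end, "strand": f.strand, "site_id": f.site_id,
            "bound": int(f.bound), "haplotype": f.haplotype or "none",
            "n_a_calls": f.a_positions.size,
            "n_cpg_calls": f.cpg_positions.size,
            "a_meth_pos": ",".join(map(str, f.a_positions[f.a_truth])),
            "cpg_meth_pos": ",".join(map(str, f.cpg_positions[f.cpg_truth])),
        })
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)

    return {"bam": bam_path, "truth": truth_path, "fasta": fasta, "bed": bed,
            "sites": sites, "n_reads": len(fibers)}
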