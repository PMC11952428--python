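"""Allele-resolved methylation analysis on a diploid assembly.

Reads aligned to a haplotype-resolved genome assembly carry their parental
assignment in the contig name (``*_MATERNAL`` / ``*_PATERNAL`` suffixes);
no SNP-based phasing is performed.  The imprinting contrast quantifies the
hallmark of an imprinting control region: targeted 6mA enrichment on the
bound (maternal) allele together with CpG hypermethylation on the unbound
(paternal) allele, each tested with a two-proportion z statistic on pooled
call counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pysam

from .modbam_io import haplotype_from_contig
from .profile_agg import pileup


class HaplotypeError(ValueError):
    """Raised when no reads can be assigned to a parental haplotype."""


@dataclass
class AlleleCounts:
    """Pooled methylation-call counts for one allele over one window."""

    contig: str
    start: int
    end: int
    a_meth: int
    a_depth: int
    cpg_meth: int
    cpg_depth: int
    read_count: int

    @property
    def a_frac(self) -> float:
        return self.a_meth / self.a_depth if self.a_depth else math.nan

    @property
    def cpg_frac(self) -> float:
        return self.cpg_meth / self.cpg_depth if self.cpg_depth else math.nan


@dataclass
class AlleleSummary:
    """Maternal/paternal methylation summaries plus imprinting deltas.

    ``delta_6ma`` = maternal - paternal 6mA fraction; ``delta_cpg`` =
    paternal - maternal CpG fraction.  Both are positive at a canonically
    imprinted, maternally bound locus.  z statistics are two-proportion
    tests on pooled counts.
    """

    maternal: AlleleCounts
    paternal: AlleleCounts
    delta_6ma: float
    z_6ma: float
    delta_cpg: float
    z_cpg: float


def split_by_haplotype(bam_path):
    """Partition mapped reads by parental contig suffix.

    Returns ``{"maternal": [...], "paternal": [...], "unassigned": [...]}``
    of read names.  Raises :class:`HaplotypeError` when nothing is assigned
    (suffix convention mismatch is the likely cause).
    """
    streams = {"maternal": [], "paternal": [], "unassigned": []}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for aln in bam.fetch():
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            hap = haplotype_from_contig(aln.reference_name or "")
            streams[hap or "unassigned"].append(aln.query_name)
    if not streams["maternal"] and not streams["paternal"]:
        raise HaplotypeError(
            "no reads assigned to either haplotype; expected contig names "
            "ending in _MATERNAL or _PATERNAL")
    return streams


def _two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> float:
    """z statistic for H0: equal methylation proportions (pooled SE)."""
    if n1 == 0 or n2 == 0:
        return math.nan
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pool * (1.0 - pool) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        return 0.0 if p1 == p2 else math.inf if p1 > p2 else -math.inf
    return (p1 - p2) / se


def _count_region(bam_path, contig, start, end, threshold_score) -> AlleleCounts:
    _, a_meth, a_depth = pileup(bam_path, contig, start, end, "a",
                                threshold_score)
    _, m_meth, m_depth = pileup(bam_path, contig, start, end, "m",
                                threshold_score)
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        n_reads = sum(
            1 for aln in bam.fetch(contig, start, end)
            if not (aln.is_unmapped or aln.is_secondary or aln.is_supplementary)
        )
    return AlleleCounts(
        contig=contig, start=start, end=end,
        a_meth=int(a_meth.sum()), a_depth=int(a_depth.sum()),
        cpg_meth=int(m_meth.sum()), cpg_depth=int(m_depth.sum()),
        read_count=n_reads,
    )


def imprinting_contrast(bam_path, maternal_region, paternal_region,
                        threshold_score: int = 225) -> AlleleSummary:
    """Quantify allele-specific 6mA and CpG methylation over homologous
    windows ``(contig, start, end)`` on the two parental contigs.

    The windows are user-supplied because maternal and paternal coordinates
    differ on a diploid assembly; no liftover is attempted.
    """
    mat = _count_region(bam_path, *maternal_region, threshold_score)
    pat = _count_region(bam_path, *paternal_region, threshold_score)
    if mat.a_depth == 0 or pat.a_depth == 0:
        raise HaplotypeError("no 6mA call coverage on at least one allele")
    if mat.cpg_depth == 0 or pat.cpg_depth == 0:
        raise HaplotypeError("no CpG call coverage on at least one allele")
    return AlleleSummary(
        maternal=mat,
        paternal=pat,
        delta_6ma=mat.a_frac - pat.a_frac,
        z_6ma=_two_proportion_z(mat.a_meth, mat.a_depth, pat.a_meth,
                                pat.a_depth),
        delta_cpg=pat.cpg_frac - mat.cpg_frac,
        z_cpg=_two_proportion_z(pat.cpg_meth, pat.cpg_depth, mat.cpg_meth,
                                mat.cpg_depth),
    )
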