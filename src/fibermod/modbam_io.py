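"""Read, write, and threshold modified-base calls carried in SAM/BAM MM/ML tags.

Modified basecallers report, per candidate base, an 8-bit confidence score
``s`` in 0..255 encoding the probability bin ``[s/256, (s+1)/256)`` that the
base is modified (SAM optional-tag specification).  This module converts
between that representation and an explicit per-call record in reference
coordinates, supporting the two channels used throughout the package:
N6-methyladenine (``A+a``) and CpG 5-methylcytosine (``C+m``).

Coordinates are 0-based half-open everywhere.  Base identity and the MM/ML
tags themselves are expressed on the *original* (basecalled) read strand;
for reverse-aligned records the stored query sequence is the reverse
complement of the basecalled read, and position bookkeeping accounts for
that.
"""

from __future__ import annotations

import array
import logging
from dataclasses import dataclass, field

import pysam

logger = logging.getLogger(__name__)

#: Modification channels supported: (canonical base on read strand, mod code).
SUPPORTED_CHANNELS = (("A", "a"), ("C", "m"))

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ModBamFormatError(ValueError):
    """Raised for malformed MM/ML tags on a record."""


@dataclass(frozen=True)
class ModCall:
    """A single per-base modification call.

    ``ref_pos`` is the 0-based reference coordinate of the aligned base, or
    ``None`` for bases in insertions/soft-clips.  ``prob`` is the bin-midpoint
    probability ``(score + 0.5) / 256``.
    """

    read_id: str
    ref_pos: int | None
    read_strand: str  # '+' or '-'
    canonical_base: str  # 'A' or 'C' on the original read strand
    mod_code: str  # 'a' (6mA) or 'm' (5mCpG)
    score: int

    @property
    def prob(self) -> float:
        return ml_to_prob(self.score)


@dataclass
class ReadModRecord:
    """All modification calls of one aligned read, in reference coordinates."""

    read_id: str
    contig: str
    ref_start: int
    ref_end: int
    strand: str
    calls: list[ModCall] = field(default_factory=list)
    haplotype_label: str | None = None

    def calls_for(self, mod_code: str) -> list[ModCall]:
        return [c for c in self.calls if c.mod_code == mod_code]


def ml_to_prob(score: int) -> float:
    """Convert an 8-bit ML confidence score to its bin-midpoint probability.

    Score ``s`` denotes the probability bin ``[s/256, (s+1)/256)``; the
    midpoint ``(s + 0.5) / 256`` is returned, so 225 -> 0.881 ("0.88
    confidence") and 250 -> 0.978 ("0.98 confidence").
    """
    if isinstance(score, bool) or not isinstance(score, (int,)):
        # numpy integers pass through via __index__
        try:
            score = int(score.__index__())
        except AttributeError:
            raise TypeError(f"score must be an integer, got {score!r}")
    if not 0 <= score <= 255:
        raise ValueError(f"score must be in 0..255, got {score}")
    return (score + 0.5) / 256.0


def prob_to_min_score(prob: float) -> int:
    """Smallest integer score whose probability bin is entirely >= ``prob``."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"prob must be in [0, 1], got {prob}")
    return min(255, max(0, int(-(-prob * 256 // 1))))  # ceil(prob * 256)


def binarize(scores, threshold_score: int):
    """Label calls methylated (True) iff ``score >= threshold_score``.

    Sub-threshold calls stay in denominators as unmethylated; this keeps
    pileup depth independent of the threshold.
    """
    import numpy as np

    if not 0 <= int(threshold_score) <= 255:
        raise ValueError(f"threshold_score must be in 0..255, got {threshold_score}")
    return np.asarray(scores) >= int(threshold_score)


def haplotype_from_contig(contig: str) -> str | None:
    """Parse a parental-haplotype label from a contig-name suffix."""
    if contig.endswith("_MATERNAL"):
        return "maternal"
    if contig.endswith("_PATERNAL"):
        return "paternal"
    return None


def decode_read(aln: pysam.AlignedSegment) -> ReadModRecord:
    """Decode the MM/ML tags of one mapped record into reference coordinates.

    Every delta-encoded MM position is resolved to a query coordinate by
    pysam, then projected through the CIGAR to a reference coordinate; calls
    on inserted or soft-clipped bases keep ``ref_pos=None``.  Channels other
    than A+a and C+m are skipped with a logged warning.  The explicit-skip
    flavors (``.``/``?``) are treated identically to plain listing: a listed
    position is a call, an unlisted one is not.
    """
    if aln.is_unmapped:
        raise ValueError(f"record {aln.query_name} is unmapped")
    try:
        mods = aln.modified_bases  # stored (aligned) orientation positions
    except Exception as exc:  # pysam raises on inconsistent MM/ML lengths
        raise ModBamFormatError(
            f"read {aln.query_name}: malformed MM/ML tags ({exc})"
        ) from exc
    if mods is None:
        # htslib signals inconsistent MM/ML by returning nothing
        if aln.has_tag("MM") and str(aln.get_tag("MM")).strip(";"):
            raise ModBamFormatError(
                f"read {aln.query_name}: inconsistent MM/ML tag lengths")
        mods = {}

    strand = "-" if aln.is_reverse else "+"
    qry2ref = dict(aln.get_aligned_pairs(matches_only=True))
    calls: list[ModCall] = []
    for (base, _mm_strand, code), positions in mods.items():
        if (base, code) not in SUPPORTED_CHANNELS:
            logger.warning(
                "read %s: skipping unsupported modification channel %s+%s (%d calls)",
                aln.query_name, base, code, len(positions),
            )
            continue
        for qpos, score in positions:
            calls.append(
                ModCall(
                    read_id=aln.query_name,
                    ref_pos=qry2ref.get(qpos),
                    read_strand=strand,
                    canonical_base=base,
                    mod_code=code,
                    score=int(score),
                )
            )
    calls.sort(key=lambda c: (c.ref_pos is None, c.ref_pos or 0, c.mod_code))
    return ReadModRecord(
        read_id=aln.query_name,
        contig=aln.reference_name,
        ref_start=aln.reference_start,
        ref_end=aln.reference_end,
        strand=strand,
        calls=calls,
        haplotype_label=haplotype_from_contig(aln.reference_name or ""),
    )


def decode_read_arrays(aln: pysam.AlignedSegment) -> dict:
    """Vectorized variant of :func:`decode_read` for pileup-scale work.

    Returns ``{mod_code: (ref_pos, score)}`` as int64 numpy arrays with
    ``ref_pos = -1`` for unaligned (inserted/clipped) bases.  Same channel
    support and skip semantics as :func:`decode_read`.
    """
    import numpy as np

    try:
        mods = aln.modified_bases
    except Exception as exc:
        raise ModBamFormatError(
            f"read {aln.query_name}: malformed MM/ML tags ({exc})") from exc
    if mods is None and aln.has_tag("MM") and str(aln.get_tag("MM")).strip(";"):
        raise ModBamFormatError(
            f"read {aln.query_name}: inconsistent MM/ML tag lengths")
    out: dict = {}
    if not mods:
        return out
    cig = aln.cigartuples
    if cig is not None and len(cig) == 1 and cig[0][0] == 0:
        qry2ref = np.arange(aln.reference_start,
                            aln.reference_start + cig[0][1], dtype=np.int64)
    else:
        qry2ref = np.full(aln.query_length, -1, dtype=np.int64)
        pairs = aln.get_aligned_pairs(matches_only=True)
        if pairs:
            q, r = zip(*pairs)
            qry2ref[list(q)] = r
    for (base, _s, code), positions in mods.items():
        if (base, code) not in SUPPORTED_CHANNELS:
            logger.warning(
                "read %s: skipping unsupported modification channel %s+%s",
                aln.query_name, base, code)
            continue
        arr = np.asarray(positions, dtype=np.int64)
        if arr.size == 0:
            continue
        ref_pos = qry2ref[arr[:, 0]]
        prev_r, prev_s = out.get(code, (None, None))
        if prev_r is not None:
            ref_pos = np.concatenate([prev_r, ref_pos])
            scores = np.concatenate([prev_s, arr[:, 1]])
        else:
            scores = arr[:, 1]
        out[code] = (ref_pos, scores)
    return out


def encode_read(read_sequence: str, calls) -> tuple[str, list[int]]:
    """Build MM and ML tag values from per-read modification calls.

    ``calls`` is an iterable of ``(read_offset, canonical_base, mod_code,
    score)`` with offsets on the original read strand.  The inverse of
    :func:`decode_read` on a perfect-match alignment: decode(encode(x)) == x.
    """
    per_channel: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for read_off, base, code, score in calls:
        if (base, code) not in SUPPORTED_CHANNELS:
            raise ValueError(f"unsupported channel {base}+{code}")
        if read_sequence[read_off].upper() != base:
            raise ValueError(
                f"call at read offset {read_off} expects base {base}, "
                f"sequence has {read_sequence[read_off]}"
            )
        if not 0 <= int(score) <= 255:
            raise ValueError(f"score out of range: {score}")
        per_channel.setdefault((base, code), []).append((int(read_off), int(score)))

    mm_parts: list[str] = []
    ml: list[int] = []
    for (base, code) in sorted(per_channel):
        chan = sorted(per_channel[(base, code)])
        offs = [o for o, _ in chan]
        if len(set(offs)) != len(offs):
            raise ValueError(f"duplicate call offsets on channel {base}+{code}")
        # delta encoding: number of skipped canonical bases between calls
        base_positions = [i for i, b in enumerate(read_sequence.upper()) if b == base]
        rank = {p: i for i, p in enumerate(base_positions)}
        deltas = []
        prev_rank = -1
        for off in offs:
            if off not in rank:
                raise ValueError(f"offset {off} is not a {base} in the read")
            deltas.append(rank[off] - prev_rank - 1)
            prev_rank = rank[off]
        mm_parts.append(f"{base}+{code}," + ",".join(map(str, deltas)) + ";")
        ml.extend(s for _, s in chan)
    return "".join(mm_parts), ml


def set_mod_tags(aln: pysam.AlignedSegment, mm: str, ml: list[int]) -> None:
    """Attach MM/ML tag values to a record (typed as the SAM spec requires)."""
    if mm:
        aln.set_tag("MM", mm)
        aln.set_tag("ML", array.array("B", ml))


def iter_records(bam_path, contig=None, start=None, end=None):
    """Yield :class:`ReadModRecord` for each mapped read (optionally a region)."""
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        it = bam.fetch(contig, start, end) if contig is not None else bam.fetch()
        for aln in it:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            yield decode_read(aln)
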