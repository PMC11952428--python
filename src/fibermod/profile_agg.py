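"""Per-position pileups and site-centered aggregate methylation profiles.

A pileup counts, at every reference position, how many reads carry a call of
the requested modification channel there (depth) and what fraction of those
calls clear the confidence threshold (methylated fraction).  Site-centered
aggregation pools those counts at offsets relative to motif centers, with
minus-strand sites flipped so all profiles share the motif orientation, and
supports box-window smoothing, non-targeting (IgG) control subtraction, and
fold-enrichment summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

from .modbam_io import decode_read_arrays

logger = logging.getLogger(__name__)


@dataclass
class AggregateProfile:
    """Site-centered profile of methylated fraction and call depth.

    ``offsets`` run -W..+W in motif orientation; ``frac`` is NaN wherever
    ``depth`` is zero.  Before smoothing, ``frac * depth`` recovers the exact
    integer methylated-call counts.
    """

    offsets: np.ndarray
    frac: np.ndarray
    depth: np.ndarray
    n_sites: int
    mod_code: str
    threshold_score: int
    smoothing_window: int = 0
    meth: np.ndarray | None = None  # raw methylated counts (pre-smoothing)

    def __post_init__(self):
        if self.offsets.shape != self.frac.shape or self.offsets.shape != self.depth.shape:
            raise ValueError("offsets, frac and depth must have equal shapes")

    def same_axes(self, other: "AggregateProfile") -> bool:
        return (
            np.array_equal(self.offsets, other.offsets)
            and self.mod_code == other.mod_code
            and self.threshold_score == other.threshold_score
            and self.smoothing_window == other.smoothing_window
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "frac": self.frac, "depth": self.depth}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _accumulate(aln, mod_code, threshold_score, lo, hi, meth, depth,
                center=None, halfwidth=None, minus=False):
    """Add one read's calls of ``mod_code`` within [lo, hi) to count arrays.

    Without a ``center``, counts land at ``ref_pos - lo`` (plain pileup);
    with one, at site-relative offsets ``ref_pos - center`` (negated for
    minus-strand sites) shifted by ``halfwidth``.
    """
    chans = decode_read_arrays(aln)
    if mod_code not in chans:
        return
    ref_pos, scores = chans[mod_code]
    keep = (ref_pos >= lo) & (ref_pos < hi)
    if not keep.any():
        return
    ref_pos, scores = ref_pos[keep], scores[keep]
    if center is None:
        idx = ref_pos - lo
    else:
        off = ref_pos - center
        if minus:
            off = -off
        idx = off + halfwidth
    np.add.at(depth, idx, 1)
    hit = scores >= threshold_score
    if hit.any():
        np.add.at(meth, idx[hit], 1)


def pileup(bam_path, contig: str, start: int, end: int, mod_code: str = "a",
           threshold_score: int = 225):
    """Per-position (methylated count, depth) over a reference region.

    Strands are pooled.  Returns ``(positions, meth, depth)``; the methylated
    fraction is ``meth / depth`` where depth > 0.
    """
    if start >= end or start < 0:
        raise ValueError(f"bad region {contig}:{start}-{end}")
    n = end - start
    meth = np.zeros(n, dtype=np.int64)
    depth = np.zeros(n, dtype=np.int64)
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if contig not in bam.references:
            raise ValueError(f"contig {contig!r} not in BAM header")
        for aln in bam.fetch(contig, start, end):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            _accumulate(aln, mod_code, threshold_score, start, end, meth,
                        depth)
    return np.arange(start, end), meth, depth


def aggregate_at_sites(bam_path, sites, halfwidth: int, mod_code: str = "a",
                       threshold_score: int = 225,
                       weighting: str = "depth") -> AggregateProfile:
    """Pool methylation counts at offsets -W..+W around site centers.

    ``sites`` is a DataFrame with columns contig/start/end/strand (BED
    semantics, 0-based half-open).  Center = floor((start+end)/2); offsets of
    minus-strand sites are reversed before pooling so profiles are in motif
    orientation.  ``weighting="depth"`` pools base-level counts across sites;
    ``weighting="site"`` averages per-site fractions equally.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    if len(sites) == 0:
        raise ValueError("need at least one site")
    if weighting not in ("depth", "site"):
        raise ValueError("weighting must be 'depth' or 'site'")

    width = 2 * halfwidth + 1
    meth = np.zeros(width, dtype=np.float64)
    depth = np.zeros(width, dtype=np.float64)
    site_frac_sum = np.zeros(width)
    site_frac_n = np.zeros(width)
    clipped = 0

    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        lengths = dict(zip(bam.references, bam.lengths))
        for _, site in sites.iterrows():
            contig = site["contig"]
            if contig not in lengths:
                raise ValueError(f"site contig {contig!r} not in BAM header")
            center = (int(site["start"]) + int(site["end"])) // 2
            lo = center - halfwidth
            hi = center + halfwidth + 1
            if lo < 0 or hi > lengths[contig]:
                clipped += 1
            flo, fhi = max(lo, 0), min(hi, lengths[contig])
            smeth = np.zeros(width, dtype=np.int64)
            sdepth = np.zeros(width, dtype=np.int64)
            minus = str(site.get("strand", "+")) == "-"
            for aln in bam.fetch(contig, flo, fhi):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                _accumulate(aln, mod_code, threshold_score, flo, fhi, smeth,
                            sdepth, center=center, halfwidth=halfwidth,
                            minus=minus)
            meth += smeth
            depth += sdepth
            with np.errstate(invalid="ignore"):
                sf = smeth / sdepth
            ok = sdepth > 0
            site_frac_sum[ok] += sf[ok]
            site_frac_n[ok] += 1
    if clipped:
        logger.warning("%d site window(s) clipped at contig edges", clipped)

    offsets = np.arange(-halfwidth, halfwidth + 1)
    if weighting == "depth":
        with np.errstate(invalid="ignore"):
            frac = np.where(depth > 0, meth / np.maximum(depth, 1), np.nan)
    else:
        with np.errstate(invalid="ignore"):
            frac = np.where(site_frac_n > 0,
                            site_frac_sum / np.maximum(site_frac_n, 1), np.nan)
    return AggregateProfile(
        offsets=offsets, frac=frac, depth=depth.astype(np.int64),
        n_sites=len(sites), mod_code=mod_code, threshold_score=threshold_score,
        smoothing_window=0, meth=meth.astype(np.int64),
    )


def smooth(profile: AggregateProfile, window: int) -> AggregateProfile:
    """Centered moving average of the fraction track over ``window`` bp.

    Each in-window offset is weighted equally (a box filter of ``window + 1``
    taps for even windows, ``window`` for odd, so the kernel is symmetric);
    edges use the truncated window; undefined (zero-depth) offsets are
    excluded from the average.  ``window = 0`` is the identity.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if window == 0:
        return replace(profile, frac=profile.frac.copy())
    taps = window + 1 if window % 2 == 0 else window
    kernel = np.ones(taps)
    valid = np.isfinite(profile.frac)
    num = np.convolve(np.where(valid, profile.frac, 0.0), kernel, mode="same")
    den = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        sm = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return replace(profile, frac=sm, smoothing_window=window, meth=None)


def subtract_control(target: AggregateProfile,
                     control: AggregateProfile) -> AggregateProfile:
    """Positionwise target-minus-control fraction (no clamping; negative
    values record control excess).  Depth is the per-offset minimum."""
    if not target.same_axes(control):
        raise ValueError("profiles have mismatched axes or parameters")
    return AggregateProfile(
        offsets=target.offsets.copy(),
        frac=target.frac - control.frac,
        depth=np.minimum(target.depth, control.depth),
        n_sites=target.n_sites,
        mod_code=target.mod_code,
        threshold_score=target.threshold_score,
        smoothing_window=target.smoothing_window,
    )


def enrichment_ratio(target: AggregateProfile, control: AggregateProfile,
                     window: int = 150) -> tuple[float, bool]:
    """Fold enrichment of target over control near the site center.

    Mean target fraction over |offset| <= window divided by the control mean
    over the same span; both profiles must be unsmoothed with a shared
    threshold.  Returns ``(ratio, is_infinite)``: a zero control mean is
    reported as infinity with a flag rather than raised.
    """
    for p in (target, control):
        if p.smoothing_window != 0:
            raise ValueError("enrichment_ratio expects unsmoothed profiles")
    if target.threshold_score != control.threshold_score:
        raise ValueError("profiles use different thresholds")
    mask = np.abs(target.offsets) <= window
    t = np.nanmean(target.frac[mask])
    c = np.nanmean(control.frac[mask])
    if not np.isfinite(c) or c == 0.0:
        return float("inf"), True
    return float(t / c), False


def write_bedgraph(profile: AggregateProfile, contig: str, center: int, path):
    """Export a profile as bedGraph anchored at an absolute center position."""
    with open(path, "w") as fh:
        for off, frac in zip(profile.offsets, profile.frac):
            if np.isfinite(frac):
                pos = center + int(off)
                fh.write(f"{contig}\t{pos}\t{pos + 1}\t{frac:.6g}\n")
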