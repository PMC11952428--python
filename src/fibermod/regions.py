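"""Native motif scanning and interval classification.

``scan_motif`` matches an exact IUPAC consensus on both strands of a FASTA
(or in-memory) reference, reporting minus-strand hits in forward
coordinates.  ``classify_by_region`` labels each site with the annotation
class containing its center (smallest containing interval wins), which is
how motif hits are partitioned into, e.g., centromeric annotation classes
before per-class profile aggregation.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
import re

import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .fiber_sim import IUPAC
from .modbam_io import revcomp
from .profile_agg import aggregate_at_sites

logger = logging.getLogger(__name__)

BED_COLUMNS = ["contig", "start", "end", "name", "strand"]


def read_bed(path, names=None) -> pd.DataFrame:
    """Load a BED-like TSV into the interval frame used across the package."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = names or BED_COLUMNS[: df.shape[1]]
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def _iupac_regex(pattern: str) -> str:
    try:
        return "".join(
            b if len(IUPAC[b]) == 1 else f"[{IUPAC[b]}]"
            for b in pattern.upper()
        )
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in pattern: {exc}") from exc


def scan_motif(reference, pattern: str) -> pd.DataFrame:
    """All exact IUPAC-consensus matches on both strands.

    ``reference`` is a FASTA path or a dict of contig name to sequence.
    Overlapping matches are all reported; minus-strand matches carry strand
    '-' with coordinates on the forward reference, so a palindromic pattern
    yields a + and a - record at the same interval.
    """
    if len(pattern) < 4:
        raise ValueError("pattern must be at least 4 bp")
    fwd = re.compile(f"(?=({_iupac_regex(pattern)}))")
    rev = re.compile(f"(?=({_iupac_regex(revcomp(pattern))}))")

    if isinstance(reference, dict):
        contigs = reference.items()
    else:
        fa = Fasta(str(reference))
        contigs = ((name, str(fa[name][:])) for name in fa.keys())

    rows = []
    for contig, seq in contigs:
        seq = seq.upper()
        for m in fwd.finditer(seq):
            s = m.start()
            rows.append((contig, s, s + len(pattern), "+"))
        for m in rev.finditer(seq):
            s = m.start()
            rows.append((contig, s, s + len(pattern), "-"))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "strand"])
    df = df.sort_values(["contig", "start", "strand"]).reset_index(drop=True)
    df.insert(3, "name", [f"motif_{i:05d}" for i in range(len(df))])
    return df


def classify_by_region(sites: pd.DataFrame,
                       annotations: pd.DataFrame) -> pd.DataFrame:
    """Label each site with the class of the annotation containing its center.

    ``annotations`` needs contig/start/end plus a ``label`` (or ``name``)
    column.  Sites in no annotation get class ``"none"``; when several
    annotations contain the center, the smallest wins, then the earliest in
    (contig, start) sort order.
    """
    label_col = "label" if "label" in annotations.columns else "name"
    ann = annotations.sort_values(["contig", "start"]).reset_index(drop=True)
    trees: dict[str, IntervalTree] = {}
    for order, row in ann.iterrows():
        trees.setdefault(row["contig"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]), (order, str(row[label_col])))

    labels = []
    for _, site in sites.iterrows():
        center = (int(site["start"]) + int(site["end"])) // 2
        tree = trees.get(site["contig"])
        hits = tree[center] if tree is not None else set()
        if not hits:
            labels.append("none")
        else:
            best = min(hits, key=lambda iv: (iv.end - iv.begin, iv.data[0]))
            labels.append(best.data[1])
    out = sites.copy()
    out["region_class"] = labels
    return out


def class_profiles(bam_path, classified_sites: pd.DataFrame, halfwidth: int,
                   mod_code: str = "a", threshold_score: int = 225,
                   min_sites: int = 5) -> dict:
    """One aggregate profile per region class.

    Returns ``{class: (AggregateProfile | None, low_confidence_flag)}``;
    classes with fewer than ``min_sites`` sites are flagged, empty classes
    yield a warning and ``None``.
    """
    out = {}
    for cls, group in classified_sites.groupby("region_class"):
        if len(group) == 0:
            logger.warning("region class %r has no sites", cls)
            out[cls] = (None, True)
            continue
        prof = aggregate_at_sites(bam_path, group, halfwidth, mod_code,
                                  threshold_score)
        out[cls] = (prof, len(group) < min_sites)
    return out
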