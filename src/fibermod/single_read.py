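"""Per-read binary methylation vectors in site-centered coordinates.

Single-read panels display each molecule overlapping a site window as one
row of methylated / unmethylated / no-call cells at offsets from the motif
center, split by alignment strand and sorted within each strand block by
the fraction of called bases that are methylated.  The default confidence
threshold for single-read display is 250 (0.98), stricter than the 225 used
for aggregate pileups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .modbam_io import decode_read_arrays

logger = logging.getLogger(__name__)

METHYLATED = 1
UNMETHYLATED = 0
NO_CALL = -1  # no call at this offset, or offset outside the read's span


@dataclass
class ReadMatrix:
    """Rows are (read x site) pairs; columns are offsets -W..+W.

    ``cells`` holds int8 codes (1 methylated, 0 unmethylated called,
    -1 no call / outside span); ``rows`` carries read_id, site_id, strand and
    the within-window methylated fraction.
    """

    offsets: np.ndarray
    cells: np.ndarray  # (n_rows, 2W+1) int8
    rows: pd.DataFrame  # read_id, site_id, strand, methyl_fraction
    mod_code: str = "a"
    threshold_score: int = 250

    def __len__(self) -> int:
        return self.cells.shape[0]

    def column_counts(self):
        """Per-offset (methylated, called) counts across all rows."""
        meth = (self.cells == METHYLATED).sum(axis=0)
        called = (self.cells != NO_CALL).sum(axis=0)
        return meth, called

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cells, columns=[str(o) for o in self.offsets])
        return pd.concat([self.rows.reset_index(drop=True), df], axis=1)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _row_fraction(cells: np.ndarray) -> float:
    called = cells != NO_CALL
    if not called.any():
        return np.nan
    return float((cells == METHYLATED).sum() / called.sum())


def reads_at_sites(bam_path, sites, halfwidth: int, mod_code: str = "a",
                   threshold_score: int = 250,
                   whole_read_fraction: bool = False) -> ReadMatrix:
    """Extract one matrix row per read x overlapping site window.

    Offsets are flipped for minus-strand sites so all rows share motif
    orientation.  A long read spanning several site windows contributes one
    row per window.  By default the per-row methylated fraction is computed
    within the displayed window; ``whole_read_fraction=True`` uses every call
    on the read instead.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    width = 2 * halfwidth + 1
    offsets = np.arange(-halfwidth, halfwidth + 1)
    all_cells: list[np.ndarray] = []
    meta: list[dict] = []

    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        lengths = dict(zip(bam.references, bam.lengths))
        for _, site in sites.iterrows():
            contig = site["contig"]
            center = (int(site["start"]) + int(site["end"])) // 2
            minus = str(site.get("strand", "+")) == "-"
            lo = max(center - halfwidth, 0)
            hi = min(center + halfwidth + 1, lengths[contig])
            for aln in bam.fetch(contig, lo, hi):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                cells = np.full(width, NO_CALL, dtype=np.int8)
                chans = decode_read_arrays(aln)
                whole_meth = whole_called = 0
                if mod_code in chans:
                    ref_pos, scores = chans[mod_code]
                    aligned = ref_pos >= 0
                    ref_pos, scores = ref_pos[aligned], scores[aligned]
                    whole_called = ref_pos.size
                    hits = scores >= threshold_score
                    whole_meth = int(hits.sum())
                    off = ref_pos - center
                    if minus:
                        off = -off
                    inside = np.abs(off) <= halfwidth
                    cells[off[inside] + halfwidth] = np.where(
                        hits[inside], METHYLATED, UNMETHYLATED).astype(np.int8)
                if whole_read_fraction:
                    frac = (whole_meth / whole_called) if whole_called else np.nan
                else:
                    frac = _row_fraction(cells)
                all_cells.append(cells)
                meta.append({
                    "read_id": aln.query_name,
                    "site_id": str(site.get("name", f"{contig}:{center}")),
                    "strand": "-" if aln.is_reverse else "+",
                    "methyl_fraction": frac,
                })
    if not all_cells:
        logger.warning("no reads overlap any site window")
        cells = np.empty((0, width), dtype=np.int8)
        rows = pd.DataFrame(columns=["read_id", "site_id", "strand",
                                     "methyl_fraction"])
    else:
        cells = np.stack(all_cells)
        rows = pd.DataFrame(meta)
    return ReadMatrix(offsets=offsets, cells=cells, rows=rows,
                      mod_code=mod_code, threshold_score=threshold_score)


def order_matrix(matrix: ReadMatrix) -> ReadMatrix:
    """Group rows by read alignment strand, then sort each block by
    descending methylated fraction; ties break on read_id so the order is
    a deterministic function of the row set (permutation-invariant)."""
    if len(matrix) == 0:
        return matrix
    rows = matrix.rows.copy()
    rows["_order"] = np.arange(len(rows))
    key = rows.assign(_neg=-rows["methyl_fraction"].fillna(np.inf))
    idx = key.sort_values(["strand", "_neg", "read_id", "site_id"],
                          kind="mergesort").index.to_numpy()
    return ReadMatrix(
        offsets=matrix.offsets.copy(),
        cells=matrix.cells[idx],
        rows=matrix.rows.iloc[idx].reset_index(drop=True),
        mod_code=matrix.mod_code,
        threshold_score=matrix.threshold_score,
    )
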