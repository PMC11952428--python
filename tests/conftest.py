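"""Shared fixtures: in-memory BAM construction and a small shared simulation."""

import array

import numpy as np
import pysam
import pytest

from fibermod.fiber_sim import FiberSimConfig, simulate_dataset
from fibermod.modbam_io import encode_read, revcomp, set_mod_tags


def build_bam(path, reads, contigs=None):
    """Write an indexed BAM from read specs.

    Each spec is a dict with ``name``, ``start``, ``seq`` (aligned
    orientation) and optionally ``contig``, ``cigar``, ``strand`` and either
    ``calls`` (original-read-orientation tuples for :func:`encode_read`) or
    raw ``mm``/``ml`` tag values.
    """
    contigs = contigs or {"chr1": 100_000}
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in contigs.items()],
    })
    tid = {n: i for i, n in enumerate(contigs)}
    ordered = sorted(reads, key=lambda r: (tid[r.get("contig", "chr1")],
                                           r["start"]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for spec in ordered:
            a = pysam.AlignedSegment(header)
            a.query_name = spec["name"]
            a.reference_id = tid[spec.get("contig", "chr1")]
            a.reference_start = spec["start"]
            a.mapping_quality = 60
            a.query_sequence = spec["seq"]
            a.cigarstring = spec.get("cigar", f"{len(spec['seq'])}M")
            a.flag = 16 if spec.get("strand", "+") == "-" else 0
            if "calls" in spec:
                read_seq = (spec["seq"] if a.flag == 0
                            else revcomp(spec["seq"]))
                mm, ml = encode_read(read_seq, spec["calls"])
                set_mod_tags(a, mm, ml)
            elif "mm" in spec:
                a.set_tag("MM", spec["mm"])
                a.set_tag("ML", array.array("B", spec["ml"]))
            bam.write(a)
    pysam.index(str(path))
    return path


@pytest.fixture
def make_bam(tmp_path):
    def _make(reads, contigs=None, name="toy.bam"):
        return build_bam(tmp_path / name, reads, contigs)

    return _make


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A desk-scale targeted simulation shared across module tests."""
    cfg = FiberSimConfig(seed=3, genome_length=120_000, n_sites=10,
                         site_spacing=10_000, coverage=12,
                         frag_len_mean=8_000, frag_len_sd=1_000)
    out = simulate_dataset(cfg, "target", tmp_path_factory.mktemp("sim"))
    return cfg, out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
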