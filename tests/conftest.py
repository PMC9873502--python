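"""Shared fixtures: toy gene models, tagged BAMs, synthetic cohorts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam
import pytest

from skewc.fixtures import make_coverage_cohort, make_gene_model
from skewc.gene_model import GeneModel, TranscriptRecord, build_bin_index

TOY_HEADER = {
    "HD": {"VN": "1.6", "SO": "unsorted"},
    "SQ": [{"SN": "chrT1", "LN": 100_000}, {"SN": "chrT2", "LN": 100_000}],
}


def single_exon_model(strand: str = "+", start: int = 1000, length: int = 200) -> GeneModel:
    rec = TranscriptRecord(
        chrom="chrT1", start=start, end=start + length, name="tx1",
        strand=strand, block_count=1, block_sizes=(length,), block_starts=(0,),
    )
    return GeneModel(records=[rec])


def write_read(
    bamout: pysam.AlignmentFile,
    name: str,
    start: int,
    cigar: list[tuple[int, int]],
    barcode: str | None = None,
    refid: int = 0,
    flag: int = 0,
    mapq: int = 60,
) -> None:
    qlen = sum(length for op, length in cigar if op in (0, 1, 4, 7, 8))
    seg = pysam.AlignedSegment()
    seg.query_name = name
    seg.query_sequence = "A" * qlen
    seg.query_qualities = pysam.qualitystring_to_array("I" * qlen)
    seg.flag = flag
    seg.reference_id = refid
    seg.reference_start = start
    seg.mapping_quality = mapq
    seg.cigartuples = cigar
    if barcode is not None:
        seg.set_tag("CB", barcode)
    bamout.write(seg)


def make_tagged_bam(path: Path, reads: list[dict]) -> Path:
    """Write a BAM from simple read dicts (name, start, cigar, barcode...)."""
    with pysam.AlignmentFile(str(path), "wb", header=TOY_HEADER) as bamout:
        for spec in reads:
            write_read(bamout, **spec)
    return path


@pytest.fixture
def toy_model(tmp_path):
    bed = tmp_path / "toy.bed"
    model = make_gene_model(n_transcripts=5, seed=11, out_bed=bed)
    return model, bed


@pytest.fixture
def toy_index(toy_model):
    model, _ = toy_model
    return build_bin_index(model, min_mrna_length=100)


@pytest.fixture
def planted_cohort():
    """90 typical + 10 3'-skewed cells with truth labels (seed 7)."""
    return make_coverage_cohort(90, 10, seed=7)


def per_base_bin_map(rec: TranscriptRecord, n_bins: int = 100) -> dict[int, int]:
    """Independent per-base walk: genomic position -> 1-based bin id."""
    positions: list[int] = []
    exons = rec.exon_intervals()
    if rec.strand == "-":
        for gs, ge in reversed(exons):
            positions.extend(range(ge - 1, gs - 1, -1))
    else:
        for gs, ge in exons:
            positions.extend(range(gs, ge))
    L = len(positions)
    return {pos: (i * n_bins) // L + 1 for i, pos in enumerate(positions)}
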