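"""Synthetic inputs at toy scale: gene models, barcoded BAMs, coverage cohorts.

Everything the pipeline consumes can be generated here deterministically
from an integer seed, so the whole tool is exercised end-to-end without any
external download.  The coverage-cohort generator emulates the two cell
populations the QC targets: *typical* cells perturbing a mildly
mid-gene-peaked prototype profile, and *skewed* cells mixing that prototype
with a geometric end-loaded profile (3' loading is the canonical RNA
degradation signature; 5' loading is also available).  Per-cell noise is
Dirichlet: cell ~ Dirichlet(concentration * profile), which keeps vectors
non-negative and summing to one by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .coverage import CoverageVector, write_store_r, write_store_tsv
from .errors import ParameterError
from .gene_model import GeneModel, TranscriptRecord

N_BINS = 100

TOY_CONTIGS = (("chrT1", 100_000), ("chrT2", 100_000))


@dataclass
class SkewProfileSpec:
    """Parameters of one cell population's coverage-profile distribution.

    ``skew_strength`` is the mixing weight toward a geometric profile loaded
    on the ``skew_kind`` end; 0 means pure prototype.  Per-cell Dirichlet
    concentration ``noise_concentration`` scales profile*concentration:
    larger values mean less cell-to-cell noise.
    """

    skew_kind: str = "three_prime"  # or "five_prime"
    skew_strength: float = 0.0  # in [0, 1]
    noise_concentration: float = 2000.0
    prototype: np.ndarray | None = None  # default: mild mid-gene peak

    def mean_profile(self) -> np.ndarray:
        proto = self.prototype
        if proto is None:
            x = np.linspace(0, 1, N_BINS)
            proto = 1.0 + 0.5 * np.sin(np.pi * x)  # gentle mid-gene bump
            proto = proto / proto.sum()
        else:
            proto = np.asarray(proto, dtype=float)
            proto = proto / proto.sum()
        if self.skew_strength == 0:
            return proto
        if not 0 < self.skew_strength <= 1:
            raise ParameterError("skew_strength must be in (0, 1]")
        rate = 0.05  # geometric decay per bin: mass concentrated in ~20 bins
        g = (1 - rate) ** np.arange(N_BINS)
        g = g / g.sum()
        if self.skew_kind == "three_prime":
            g = g[::-1]
        elif self.skew_kind != "five_prime":
            raise ParameterError(f"unknown skew_kind {self.skew_kind!r}")
        return (1 - self.skew_strength) * proto + self.skew_strength * g

    def sample_cells(self, n: int, rng: np.random.Generator) -> np.ndarray:
        mean = self.mean_profile()
        conc = self.noise_concentration * mean
        if np.all(conc <= 0):
            raise ParameterError("degenerate spec: zero concentration everywhere")
        # Dirichlet with tiny concentrations underflows; floor keeps it proper
        return rng.dirichlet(np.maximum(conc, 1e-6), size=n)


# ---------------------------------------------------------------------------
# Gene models


def make_gene_model(
    n_transcripts: int = 5,
    length_range: tuple[int, int] = (600, 3000),
    strand_mix: float = 0.5,
    seed: int = 1,
    out_bed: str | Path | None = None,
    max_exons: int = 4,
) -> GeneModel:
    """Non-overlapping multi-exon transcripts packed onto the toy contigs.

    ``length_range`` bounds the genomic span; exon structure is random with
    1..``max_exons`` blocks.  Deterministic per seed.  Raises when the
    requested transcripts cannot be packed onto the toy contigs.
    """
    if n_transcripts < 1:
        raise ParameterError("n_transcripts must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[TranscriptRecord] = []
    cursor = {c: 100 for c, _ in TOY_CONTIGS}
    sizes = dict(TOY_CONTIGS)
    for t in range(n_transcripts):
        span = int(rng.integers(length_range[0], length_range[1] + 1))
        chrom = TOY_CONTIGS[t % len(TOY_CONTIGS)][0]
        start = cursor[chrom]
        end = start + span
        if end + 100 > sizes[chrom]:
            raise ParameterError(
                f"cannot pack {n_transcripts} transcripts of span "
                f"<= {length_range[1]} onto toy contigs"
            )
        cursor[chrom] = end + int(rng.integers(200, 500))
        n_exons = int(rng.integers(1, max_exons + 1))
        if n_exons == 1:
            block_starts, block_sizes = (0,), (span,)
        else:
            # pick exon boundaries: alternate exon/intron pieces covering span
            cuts = np.sort(rng.choice(np.arange(1, span), size=2 * n_exons - 2,
                                      replace=False))
            edges = np.concatenate([[0], cuts, [span]])
            block_starts = tuple(int(edges[2 * i]) for i in range(n_exons))
            block_sizes = tuple(int(edges[2 * i + 1] - edges[2 * i])
                                for i in range(n_exons))
            if sum(block_sizes) < 100:
                # too little exonic sequence to bin; collapse to one exon
                block_starts, block_sizes = (0,), (span,)
        strand = "+" if rng.random() < strand_mix else "-"
        records.append(
            TranscriptRecord(
                chrom=chrom, start=start, end=end, name=f"tx{t + 1}",
                strand=strand, block_count=len(block_sizes),
                block_sizes=block_sizes, block_starts=block_starts,
            )
        )
    model = GeneModel(records=records, source_path=str(out_bed or ""),
                      species_label="toy")
    if out_bed is not None:
        model.write_bed12(out_bed)
    return model


# ---------------------------------------------------------------------------
# BAM fixtures


def _transcript_base_to_genome(rec: TranscriptRecord, i: int) -> int:
    """Genomic position of transcript-oriented base i (0-based, 5'->3')."""
    exons = rec.exon_intervals()
    if rec.strand == "-":
        for gs, ge in reversed(exons):
            length = ge - gs
            if i < length:
                return ge - 1 - i
            i -= length
    else:
        for gs, ge in exons:
            length = ge - gs
            if i < length:
                return gs + i
            i -= length
    raise IndexError("transcript base out of range")


def _read_placement(
    rec: TranscriptRecord, t0: int, read_len: int
) -> tuple[int, list[tuple[int, int]]]:
    """Genomic start and CIGAR-ready genomic blocks covering transcript
    bases [t0, t0+read_len), merging across exon junctions (N gaps)."""
    positions = sorted(
        _transcript_base_to_genome(rec, i) for i in range(t0, t0 + read_len)
    )
    blocks: list[tuple[int, int]] = []
    for p in positions:
        if blocks and p == blocks[-1][1]:
            blocks[-1] = (blocks[-1][0], p + 1)
        else:
            blocks.append((p, p + 1))
    return blocks[0][0], blocks


def make_barcoded_bam(
    model: GeneModel,
    barcodes: list[str],
    reads_per_cell: int,
    out_bam: str | Path,
    placement: dict[str, SkewProfileSpec] | SkewProfileSpec | None = None,
    seed: int = 1,
    read_len: int = 60,
) -> "pd.DataFrame":
    """Write a CB-tagged BAM with known per-read placements; return the truth.

    Reads are placed along transcripts by sampling a gene-body bin from each
    cell's profile, then a start base within that bin (clamped so the read
    fits).  The returned truth table has one row per read: read name,
    barcode, transcript, and the exact genomic bases covered — enough to
    recompute any pileup from scratch.
    """
    import pandas as pd

    if reads_per_cell < 1:
        raise ParameterError("reads_per_cell must be >= 1")
    if len(set(barcodes)) != len(barcodes):
        raise ParameterError("barcodes must be unique")
    rng = np.random.default_rng(seed)
    if placement is None:
        placement = SkewProfileSpec()
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in TOY_CONTIGS],
    }
    refid = {c: i for i, (c, _) in enumerate(TOY_CONTIGS)}
    usable = [r for r in model.records if r.mrna_length >= read_len]
    if not usable:
        raise ParameterError("no transcript long enough for the read length")
    rows = []
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bamout:
        for bc in barcodes:
            spec = placement[bc] if isinstance(placement, dict) else placement
            profile = spec.mean_profile()
            for r in range(reads_per_cell):
                rec = usable[int(rng.integers(len(usable)))]
                L = rec.mrna_length
                b = int(rng.choice(N_BINS, p=profile))
                lo = b * L // N_BINS
                hi = max(lo + 1, (b + 1) * L // N_BINS)
                t0 = int(rng.integers(lo, hi))
                t0 = min(t0, L - read_len)
                gstart, blocks = _read_placement(rec, t0, read_len)
                seg = pysam.AlignedSegment()
                seg.query_name = f"{bc}:{r}"
                seg.query_sequence = "A" * read_len
                seg.query_qualities = pysam.qualitystring_to_array("I" * read_len)
                seg.flag = 0
                seg.reference_id = refid[rec.chrom]
                seg.reference_start = gstart
                seg.mapping_quality = 60
                cigar = []
                for j, (s, e) in enumerate(blocks):
                    if j > 0:
                        cigar.append((3, s - blocks[j - 1][1]))  # N gap
                    cigar.append((0, e - s))  # M
                seg.cigartuples = cigar
                seg.set_tag("CB", bc)
                bamout.write(seg)
                covered = ";".join(f"{s}-{e}" for s, e in blocks)
                rows.append({
                    "read_name": seg.query_name, "barcode": bc,
                    "transcript": rec.name, "chrom": rec.chrom,
                    "t0": t0, "blocks": covered,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Coverage cohorts


def make_coverage_cohort(
    n_typical: int = 90,
    n_skewed: int = 10,
    spec_typical: SkewProfileSpec | None = None,
    spec_skewed: SkewProfileSpec | None = None,
    seed: int = 1,
    outdir: str | Path | None = None,
) -> tuple[list[CoverageVector], dict[str, str]]:
    """Labeled synthetic cohort of coverage vectors, written in both dialects.

    Defaults: typical cells perturb the prototype profile; skewed cells mix
    it half-and-half with the 3'-loaded geometric profile.  Returns the
    vectors plus truth labels keyed by cell ID.
    """
    if n_typical + n_skewed < 12:
        raise ParameterError("cohort too small: need n_typical + n_skewed >= 12")
    spec_typical = spec_typical or SkewProfileSpec(skew_strength=0.0)
    spec_skewed = spec_skewed or SkewProfileSpec(skew_kind="three_prime",
                                                skew_strength=0.5)
    rng = np.random.default_rng(seed)
    vectors: list[CoverageVector] = []
    truth: dict[str, str] = {}
    for vals in spec_typical.sample_cells(n_typical, rng):
        cid = f"cell{len(vectors) + 1:04d}"
        vectors.append(CoverageVector(cid, vals, np.ones(N_BINS, dtype=np.int64)))
        truth[cid] = "typical"
    for vals in spec_skewed.sample_cells(n_skewed, rng):
        cid = f"cell{len(vectors) + 1:04d}"
        vectors.append(CoverageVector(cid, vals, np.ones(N_BINS, dtype=np.int64)))
        truth[cid] = "skewed"
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_store_tsv(vectors, outdir / "coverage.tsv")
        write_store_r(vectors, outdir / "coverage.r")
        with open(outdir / "truth.tsv", "w") as fh:
            for cid in sorted(truth):
                fh.write(f"{cid}\t{truth[cid]}\n")
    return vectors, truth
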