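"""Per-cell gene body coverage: 100-bin profiles from BAM alignments.

For every eligible alignment (primary, mapped, not flagged duplicate), each
aligned reference base (CIGAR M/=/X; N and D consume reference but cover
nothing) that falls on an indexed exonic base increments that base's
gene-body bin for every transcript indexing it.  Raw per-bin counts summed
over transcripts are normalized to sum to one, giving the relative coverage
profile the clustering stage consumes.  Cells whose reads hit no indexed
base get an all-zero vector and are flagged degenerate.

The per-cohort result is a CoverageStore, written in two dialects:

* TSV — one line per cell: ``cell_id`` then 100 tab-separated values;
* ``coverage.r`` — one R vector assignment per cell
  (```cell` <- c(v1,...,v100)``), drop-in compatible with downstream stages
  that historically consumed an R source file.
"""

from __future__ import annotations

import logging
import re
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .errors import FormatError, InputError
from .gene_model import BinIndex

log = logging.getLogger(__name__)

N_BINS = 100

# CIGAR op codes: M=0, I=1, D=2, N=3, S=4, H=5, P=6, ==7, X=8
_REF_COVERING = {0, 7, 8}
_REF_ADVANCING = {0, 2, 3, 7, 8}


@dataclass
class CoverageVector:
    """One cell's gene body coverage profile."""

    cell_id: str
    values: np.ndarray  # 100 floats, sum to 1 (or all zero when degenerate)
    raw_counts: np.ndarray  # 100 ints, covered exonic bases per bin
    n_reads_seen: int = 0
    n_reads_used: int = 0

    @property
    def degenerate(self) -> bool:
        return int(self.raw_counts.sum()) == 0


def aligned_reference_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference [start, end) intervals covered by M/=/X CIGAR ops.

    D and N advance the reference without covering it; I/S/H/P cover nothing.
    """
    blocks: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in _REF_COVERING:
            blocks.append((pos, pos + length))
        if op in _REF_ADVANCING:
            pos += length
    return blocks


def _eligible(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and not read.is_duplicate
        and read.mapping_quality >= min_mapq
    )


def compute_cell_coverage(
    bam: str | Path,
    index: BinIndex,
    cell_id: str | None = None,
    min_mapq: int = 0,
    log_path: str | Path | None = None,
) -> CoverageVector:
    """Compute one cell's 100-bin coverage vector from its BAM.

    Sorted and unsorted BAMs are both accepted (the scan is sequential).
    When the BAM's contigs share nothing with the index a loud warning is
    emitted and a degenerate all-zero vector returned — the classic cause of
    an empty gene-body-coverage plot.
    """
    bam = Path(bam)
    if cell_id is None:
        cell_id = bam.stem
    try:
        infile = pysam.AlignmentFile(str(bam), "rb", check_sq=False)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read BAM {bam}: {exc}") from exc

    raw = np.zeros(index.n_bins, dtype=np.int64)
    n_seen = 0
    n_used = 0
    with infile:
        bam_contigs = set(infile.references or ())
        if bam_contigs and not (bam_contigs & index.chromosomes):
            log.warning(
                "%s: no overlap between BAM contigs and indexed chromosomes "
                "(%s vs %s) — coverage will be empty",
                bam, sorted(bam_contigs)[:3], sorted(index.chromosomes)[:3],
            )
        for read in infile.fetch(until_eof=True):
            n_seen += 1
            if not _eligible(read, min_mapq):
                continue
            arrays = index.chrom_arrays.get(read.reference_name)
            if arrays is None:
                continue
            n_used += 1
            starts, ends, bins0 = arrays
            for bs, be in aligned_reference_blocks(read):
                overlap = np.minimum(ends, be) - np.maximum(starts, bs)
                mask = overlap > 0
                if mask.any():
                    np.add.at(raw, bins0[mask], overlap[mask])

    total = int(raw.sum())
    values = raw / total if total > 0 else np.zeros(index.n_bins, dtype=float)
    vec = CoverageVector(cell_id=cell_id, values=values, raw_counts=raw,
                         n_reads_seen=n_seen, n_reads_used=n_used)
    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write(f"cell_id\t{cell_id}\n")
            fh.write(f"reads_seen\t{n_seen}\n")
            fh.write(f"reads_used\t{n_used}\n")
            fh.write(f"covered_bases\t{total}\n")
            fh.write(f"degenerate\t{int(vec.degenerate)}\n")
    return vec


# ---------------------------------------------------------------------------
# CoverageStore serialization


def write_store_tsv(vectors: list[CoverageVector], path: str | Path) -> None:
    """TSV dialect: cell_id then 100 values per line, cells sorted by ID."""
    with open(path, "w") as fh:
        for vec in sorted(vectors, key=lambda v: v.cell_id):
            vals = "\t".join(format(v, ".10g") for v in vec.values)
            fh.write(f"{vec.cell_id}\t{vals}\n")


def write_store_r(vectors: list[CoverageVector], path: str | Path) -> None:
    """R-assignment dialect: one ```cell` <- c(...)`` line per cell."""
    with open(path, "w") as fh:
        for vec in sorted(vectors, key=lambda v: v.cell_id):
            vals = ",".join(format(v, ".10g") for v in vec.values)
            fh.write(f"`{vec.cell_id}` <- c({vals})\n")


_R_LINE = re.compile(r"^`?(?P<id>[^`]+?)`?\s*<-\s*c\((?P<vals>.*)\)\s*$")


def read_store(path: str | Path) -> list[CoverageVector]:
    """Read a CoverageStore in either dialect (TSV or R-assignment).

    Rows must carry exactly 100 values; a ragged row is a format error naming
    the cell.  An empty store is an error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"coverage store not found: {path}")
    vectors: list[CoverageVector] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            m = _R_LINE.match(line)
            if m:
                cell_id = m.group("id")
                vals = [float(t) for t in m.group("vals").split(",") if t.strip()]
            else:
                fields = line.split("\t")
                cell_id = fields[0]
                vals = [float(t) for t in fields[1:]]
            if len(vals) != N_BINS:
                raise FormatError(
                    f"{path} line {lineno}: cell {cell_id!r} has {len(vals)} "
                    f"values, expected {N_BINS}"
                )
            values = np.asarray(vals, dtype=float)
            total = values.sum()
            raw = np.zeros(N_BINS, dtype=np.int64)  # raw counts not serialized
            if total > 0:
                raw[:] = 1  # marker: non-degenerate
            vectors.append(CoverageVector(cell_id=cell_id, values=values, raw_counts=raw))
    if not vectors:
        raise FormatError(f"{path}: empty coverage store")
    return vectors


# ---------------------------------------------------------------------------
# Batch driver


@dataclass
class BatchResult:
    store_tsv: Path
    store_r: Path
    n_cells: int
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _worker(args: tuple[str, str, int, str]) -> tuple[str, np.ndarray, np.ndarray, int, int]:
    bam, index_path, min_mapq, log_path = args
    from .gene_model import load_bin_index

    index = load_bin_index(index_path)
    vec = compute_cell_coverage(bam, index, min_mapq=min_mapq, log_path=log_path)
    return vec.cell_id, vec.values, vec.raw_counts, vec.n_reads_seen, vec.n_reads_used


def batch_coverage(
    indir: str | Path,
    index: BinIndex,
    outdir: str | Path = "coverage",
    workers: int = 1,
    min_mapq: int = 0,
    index_path: str | Path | None = None,
) -> BatchResult:
    """Run coverage over every ``*.bam`` in ``indir``; write the stores.

    Output is deterministic regardless of worker count or BAM order: cells
    are keyed by filename stem and stores are written sorted by cell ID.  A
    corrupt BAM fails only its own cell; failures land in a manifest file and
    flip :attr:`BatchResult.ok`.  The bin index is always built/loaded before
    workers start, so index construction is never raced.
    """
    indir = Path(indir)
    outdir = Path(outdir)
    bams = sorted(indir.glob("*.bam"))
    if not bams:
        raise InputError(f"no BAM files in {indir}")
    outdir.mkdir(parents=True, exist_ok=True)

    vectors: list[CoverageVector] = []
    failures: dict[str, str] = {}
    if workers > 1 and index_path is None:
        # workers reload the index from disk; persist a scratch copy
        from .gene_model import save_bin_index

        index_path = outdir / "_index.idx"
        save_bin_index(index, index_path)

    jobs = [(str(b), str(index_path) if index_path else "", min_mapq,
             str(outdir / (b.stem + ".log"))) for b in bams]
    if workers <= 1:
        for bam in bams:
            try:
                vec = compute_cell_coverage(bam, index, min_mapq=min_mapq,
                                            log_path=outdir / (bam.stem + ".log"))
                vectors.append(vec)
            except Exception as exc:  # one corrupt BAM fails that cell only
                failures[bam.stem] = str(exc)
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            futures = {bam.stem: pool.submit(_worker, job)
                       for bam, job in zip(bams, jobs)}
            for stem, fut in futures.items():
                try:
                    cell_id, values, raw, n_seen, n_used = fut.result()
                    vectors.append(CoverageVector(cell_id, values, raw, n_seen, n_used))
                except Exception as exc:
                    failures[stem] = str(exc)

    store_tsv = outdir / "coverage.tsv"
    store_r = outdir / "coverage.r"
    write_store_tsv(vectors, store_tsv)
    write_store_r(vectors, store_r)
    manifest = outdir / "failures.tsv"
    with open(manifest, "w") as fh:
        for stem, msg in sorted(failures.items()):
            fh.write(f"{stem}\t{msg}\n")
    if failures:
        log.error("batch_coverage: %d of %d cells failed (see %s)",
                  len(failures), len(bams), manifest)
    return BatchResult(store_tsv=store_tsv, store_r=store_r,
                       n_cells=len(vectors), failures=failures)
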