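"""Split a barcoded BAM (Cell Ranger style) into one BAM per cell barcode.

The cell barcode is read from the ``CB`` auxiliary tag by default (the
corrected-barcode convention of Cell Ranger); ``CR`` can be requested
explicitly for uncorrected pipelines.  Splitting is lossless per barcode:
unmapped/secondary/supplementary records are passed through unchanged —
filtering is the coverage engine's concern.  The per-cell BAM filename stem
becomes the cell ID downstream.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pysam

from .errors import FormatError, InputError

log = logging.getLogger(__name__)

_SANITIZE_RE = re.compile(r"[^A-Za-z0-9._-]")


@dataclass
class BarcodeList:
    """Ordered, unique cell barcodes read from a barcodes.tsv(.gz) whitelist."""

    barcodes: list[str]
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.barcodes)


@dataclass
class SplitReport:
    """Census of a barcode split run."""

    per_cell: list[tuple[str, str, int]]  # (barcode, bam path, reads written)
    n_written: int
    n_skipped_unlisted: int
    n_skipped_untagged: int
    barcodes_seen_in_bam: int

    @property
    def n_total(self) -> int:
        return self.n_written + self.n_skipped_unlisted + self.n_skipped_untagged


def read_barcodes(path: str | Path) -> BarcodeList:
    """Read one barcode per line from a plain or gzipped text file.

    Trailing whitespace is stripped; order is preserved.  An empty file or a
    duplicated barcode is an error (the whitelist contract requires unique,
    non-empty entries).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"barcode file not found: {path}")
    opener = gzip.open if path.name.endswith(".gz") else open
    barcodes: list[str] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            bc = line.rstrip()
            if not bc:
                continue
            if any(ch.isspace() for ch in bc):
                raise FormatError(f"{path} line {lineno}: whitespace inside barcode {bc!r}")
            if bc in seen:
                raise FormatError(f"{path} line {lineno}: duplicate barcode {bc!r}")
            seen.add(bc)
            barcodes.append(bc)
    if not barcodes:
        raise FormatError(f"{path}: no barcodes")
    return BarcodeList(barcodes=barcodes, source_path=str(path))


def sanitize_barcode(barcode: str) -> str:
    """Filesystem-safe filename stem for a barcode."""
    return _SANITIZE_RE.sub("_", barcode)


def split_bam_by_barcode(
    bam: str | Path,
    barcodes: BarcodeList,
    outdir: str | Path = "input",
    tag: str = "CB",
) -> SplitReport:
    """Write one BAM per listed barcode under ``outdir``.

    Each output BAM carries the original header and exactly the input
    alignments whose ``tag`` value equals its barcode.  Reads with no tag or
    an unlisted tag are counted and skipped.  A barcode listed but absent
    from the BAM still yields an (empty) output BAM so the cell census is
    explicit.  Raises when the BAM is unreadable or when not a single listed
    barcode occurs in it (that run could only produce empty coverage plots).
    """
    bam = Path(bam)
    outdir = Path(outdir)
    try:
        infile = pysam.AlignmentFile(str(bam), "rb", check_sq=False)
        header = infile.header
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read BAM {bam}: {exc}") from exc
    outdir.mkdir(parents=True, exist_ok=True)

    listed = set(barcodes.barcodes)
    paths = {bc: outdir / f"{sanitize_barcode(bc)}.bam" for bc in barcodes.barcodes}
    writers = {bc: pysam.AlignmentFile(str(p), "wb", header=header)
               for bc, p in paths.items()}
    counts = {bc: 0 for bc in barcodes.barcodes}
    n_unlisted = 0
    n_untagged = 0
    seen_in_bam: set[str] = set()
    try:
        for read in infile.fetch(until_eof=True):
            try:
                bc = read.get_tag(tag)
            except KeyError:
                n_untagged += 1
                continue
            seen_in_bam.add(bc)
            if bc in listed:
                writers[bc].write(read)
                counts[bc] += 1
            else:
                n_unlisted += 1
    finally:
        infile.close()
        for w in writers.values():
            w.close()

    if not any(counts.values()):
        raise InputError(
            f"none of the {len(listed)} listed barcodes occur in {bam}; "
            "check that the barcode list matches the BAM"
        )
    n_listed_seen = len(seen_in_bam & listed)
    if len(seen_in_bam) != len(listed):
        log.warning(
            "barcode census mismatch: %d barcodes listed, %d distinct barcodes "
            "in BAM (%d in common)", len(listed), len(seen_in_bam), n_listed_seen,
        )
    for bc, c in counts.items():
        if c == 0:
            log.warning("listed barcode %s not present in BAM; wrote empty %s",
                        bc, paths[bc])
    return SplitReport(
        per_cell=[(bc, str(paths[bc]), counts[bc]) for bc in barcodes.barcodes],
        n_written=sum(counts.values()),
        n_skipped_unlisted=n_unlisted,
        n_skipped_untagged=n_untagged,
        barcodes_seen_in_bam=len(seen_in_bam),
    )
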