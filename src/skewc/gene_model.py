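"""BED12 gene models and the 100-bin gene-body index.

A gene model is an ordered list of BED12 transcript records.  For coverage
profiling, each transcript's exonic (mRNA) bases are partitioned into
``n_bins`` contiguous bins walked 5'->3' in transcript orientation, so bin 1
always sits at the transcript 5' end regardless of strand.  The per-base rule
is ``bin(i) = floor(i * n_bins / L) + 1`` for transcript-oriented base index
``i`` in ``[0, L)``; it is deterministic and keeps bin sizes within one base
of each other.

Models derived from repeat-contaminated annotations are cleaned with
:func:`exclude_overlapping`, which reproduces
``intersectBed -split -v -s -wa``: a record is dropped iff at least one of
its exon blocks shares >=1 base with an exon block of an exclusion record on
the same strand.
"""

from __future__ import annotations

import gzip
import hashlib
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateDataError, FormatError, InputError, StaleIndexError

log = logging.getLogger(__name__)

N_BINS_DEFAULT = 100
MIN_MRNA_LENGTH_DEFAULT = 100

_INDEX_FORMAT_VERSION = "1"


@dataclass(frozen=True)
class TranscriptRecord:
    """One BED12 line: a transcript with its exon block structure."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    name: str
    strand: str  # '+' or '-'
    block_count: int
    block_sizes: tuple[int, ...]
    block_starts: tuple[int, ...]  # offsets from `start`
    score: str = "0"
    thick_start: int | None = None
    thick_end: int | None = None
    item_rgb: str = "0"

    @property
    def mrna_length(self) -> int:
        return sum(self.block_sizes)

    def exon_intervals(self) -> list[tuple[int, int]]:
        """Genomic [start, end) intervals of the exon blocks, left to right."""
        return [
            (self.start + off, self.start + off + size)
            for off, size in zip(self.block_starts, self.block_sizes)
        ]

    def key(self) -> tuple[str, int, int, str, str]:
        return (self.chrom, self.start, self.end, self.name, self.strand)

    def to_bed12_line(self) -> str:
        thick_start = self.start if self.thick_start is None else self.thick_start
        thick_end = self.end if self.thick_end is None else self.thick_end
        return "\t".join(
            [
                self.chrom,
                str(self.start),
                str(self.end),
                self.name,
                self.score,
                self.strand,
                str(thick_start),
                str(thick_end),
                self.item_rgb,
                str(self.block_count),
                ",".join(str(s) for s in self.block_sizes) + ",",
                ",".join(str(s) for s in self.block_starts) + ",",
            ]
        )


@dataclass
class GeneModel:
    """Ordered collection of transcript records read from one BED12 file."""

    records: list[TranscriptRecord]
    source_path: str = ""
    species_label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def checksum(self) -> str:
        """Digest of the record content (not the file path)."""
        h = hashlib.sha256()
        for rec in self.records:
            h.update(rec.to_bed12_line().encode())
            h.update(b"\n")
        return h.hexdigest()

    def write_bed12(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(rec.to_bed12_line() + "\n")


def _open_text(path: str | Path) -> io.TextIOBase:
    """Open plain or gzip text transparently."""
    raw = open(path, "rb")
    if raw.read(2) == b"\x1f\x8b":
        raw.seek(0)
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    raw.seek(0)
    return io.TextIOWrapper(raw)


def _parse_int_list(text: str, lineno: int, what: str) -> tuple[int, ...]:
    try:
        return tuple(int(tok) for tok in text.rstrip(",").split(",") if tok != "")
    except ValueError as exc:
        raise FormatError(f"line {lineno}: cannot parse {what} list {text!r}") from exc


def read_bed12(path: str | Path, species_label: str = "") -> GeneModel:
    """Read a BED12 file (plain or gzipped) into a :class:`GeneModel`.

    Lines starting with ``track`` or ``browser`` and empty lines are skipped.
    Data lines must carry >=12 tab-separated fields; block arithmetic is
    validated against the record end.  Duplicate
    (chrom, start, end, name, strand) tuples are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"gene model file not found: {path}")
    records: list[TranscriptRecord] = []
    seen: set[tuple] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"line {lineno}: BED12 requires >=12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinates") from exc
            strand = fields[5]
            if strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: strand must be + or -, got {strand!r}")
            block_count = int(fields[9])
            sizes = _parse_int_list(fields[10], lineno, "blockSizes")
            starts = _parse_int_list(fields[11], lineno, "blockStarts")
            if not (len(sizes) == len(starts) == block_count):
                raise FormatError(
                    f"line {lineno}: blockCount={block_count} but "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            if block_count < 1 or any(s < 1 for s in sizes) or any(o < 0 for o in starts):
                raise FormatError(f"line {lineno}: invalid block geometry")
            if starts[0] != 0 or start + starts[-1] + sizes[-1] != end:
                raise FormatError(
                    f"line {lineno}: blocks inconsistent with record end "
                    f"(first blockStart must be 0, last block must end at chromEnd)"
                )
            for i in range(1, block_count):
                if starts[i] < starts[i - 1] + sizes[i - 1]:
                    raise FormatError(f"line {lineno}: exon blocks overlap or unsorted")
            rec = TranscriptRecord(
                chrom=fields[0],
                start=start,
                end=end,
                name=fields[3],
                score=fields[4],
                strand=strand,
                thick_start=int(fields[6]),
                thick_end=int(fields[7]),
                item_rgb=fields[8],
                block_count=block_count,
                block_sizes=sizes,
                block_starts=starts,
            )
            if rec.key() in seen:
                raise FormatError(f"line {lineno}: duplicate transcript {rec.key()}")
            seen.add(rec.key())
            records.append(rec)
    return GeneModel(records=records, source_path=str(path), species_label=species_label)


def exclude_overlapping(model: GeneModel, exclusion: GeneModel) -> GeneModel:
    """Drop records whose exon blocks overlap exclusion exon blocks, same strand.

    Mirrors ``intersectBed -split -v -s -wa -a model -b exclusion``: overlap
    is resolved at exon-block level (``-split``, so intron-only overlap does
    not count), restricted to the same strand (``-s``); surviving records are
    emitted unmodified (``-wa``) in input order (``-v`` keeps non-overlappers).
    """
    # bucket exclusion exon blocks by (chrom, strand)
    buckets: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for rec in exclusion.records:
        buckets.setdefault((rec.chrom, rec.strand), []).extend(rec.exon_intervals())
    for ivs in buckets.values():
        ivs.sort()

    def hits(rec: TranscriptRecord) -> bool:
        ivs = buckets.get((rec.chrom, rec.strand))
        if not ivs:
            return False
        for s, e in rec.exon_intervals():
            # linear scan is fine at gene-model scale; intervals are sorted
            for xs, xe in ivs:
                if xs >= e:
                    break
                if xe > s:
                    return True
        return False

    kept = [rec for rec in model.records if not hits(rec)]
    log.info("exclude_overlapping: kept %d of %d records", len(kept), len(model.records))
    return GeneModel(records=kept, source_path=model.source_path,
                     species_label=model.species_label)


@dataclass
class BinIndex:
    """Genomic-interval -> gene-body-bin mapping for every indexed transcript.

    ``entries`` maps transcript key -> array of rows
    ``(genomic_start, genomic_end, bin_id)`` with ``bin_id`` in 1..n_bins,
    5'->3' in transcript orientation.  ``chrom_arrays`` is the flattened
    per-chromosome view the coverage engine consumes: for each chromosome,
    three int64 arrays (starts, ends, bins-1) sorted by start.
    """

    entries: dict[tuple, np.ndarray]
    n_bins: int
    min_mrna_length: int
    checksum: str
    n_skipped_short: int = 0
    chrom_arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        if not self.chrom_arrays:
            self._build_chrom_arrays()

    def _build_chrom_arrays(self) -> None:
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for (chrom, *_rest), rows in self.entries.items():
            per_chrom.setdefault(chrom, []).extend(
                (int(s), int(e), int(b) - 1) for s, e, b in rows
            )
        self.chrom_arrays = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            arr = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
            self.chrom_arrays[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])

    @property
    def chromosomes(self) -> set[str]:
        return set(self.chrom_arrays)


def _transcript_bin_intervals(rec: TranscriptRecord, n_bins: int) -> np.ndarray:
    """Rows of (genomic_start, genomic_end, bin_id) for one transcript.

    Walks exonic bases 5'->3' in transcript orientation and assigns base i to
    bin floor(i*n_bins/L)+1, emitting maximal genomic runs of constant bin.
    """
    L = rec.mrna_length
    rows: list[tuple[int, int, int]] = []
    exons = rec.exon_intervals()
    if rec.strand == "-":
        exons = exons[::-1]
    i = 0  # transcript-oriented base index
    for gs, ge in exons:
        length = ge - gs
        j = 0
        while j < length:
            b = i * n_bins // L  # 0-based bin for this base
            # last transcript base of bin b is ceil((b+1)*L/n_bins) - 1
            bin_last = -(-(b + 1) * L // n_bins) - 1
            run = min(length - j, bin_last - i + 1)
            if rec.strand == "+":
                rows.append((gs + j, gs + j + run, b + 1))
            else:
                # transcript runs right-to-left on the genome
                rows.append((ge - j - run, ge - j, b + 1))
            i += run
            j += run
    return np.asarray(rows, dtype=np.int64).reshape(-1, 3)


def build_bin_index(
    model: GeneModel,
    n_bins: int = N_BINS_DEFAULT,
    min_mrna_length: int = MIN_MRNA_LENGTH_DEFAULT,
) -> BinIndex:
    """Partition each transcript's exonic bases into ``n_bins`` gene-body bins.

    Transcripts shorter than ``min_mrna_length`` mRNA bases are skipped (the
    count is logged).  Raises :class:`DegenerateDataError` when nothing
    survives the length filter.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    entries: dict[tuple, np.ndarray] = {}
    n_skipped = 0
    for rec in model.records:
        if rec.mrna_length < min_mrna_length:
            n_skipped += 1
            continue
        entries[rec.key()] = _transcript_bin_intervals(rec, n_bins)
    if n_skipped:
        log.info("build_bin_index: skipped %d transcripts shorter than %d mRNA bases",
                 n_skipped, min_mrna_length)
    if not entries:
        raise DegenerateDataError(
            f"no transcripts with mRNA length >= {min_mrna_length}; cannot build index"
        )
    return BinIndex(
        entries=entries,
        n_bins=n_bins,
        min_mrna_length=min_mrna_length,
        checksum=model.checksum(),
        n_skipped_short=n_skipped,
    )


def index_path_for(bed_path: str | Path, reference_dir: str | Path = "reference") -> Path:
    """Conventional persisted-index location: ``reference/<bedname>.idx``."""
    return Path(reference_dir) / (Path(bed_path).name + ".idx")


def save_bin_index(index: BinIndex, path: str | Path) -> None:
    """Persist a bin index as a versioned TSV with an embedded model checksum."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"#skewc-bin-index\tversion={_INDEX_FORMAT_VERSION}\n")
        fh.write(f"#checksum\t{index.checksum}\n")
        fh.write(f"#n_bins\t{index.n_bins}\n")
        fh.write(f"#min_mrna_length\t{index.min_mrna_length}\n")
        fh.write(f"#n_skipped_short\t{index.n_skipped_short}\n")
        for key, rows in index.entries.items():
            chrom, start, end, name, strand = key
            fh.write(f">{chrom}\t{start}\t{end}\t{name}\t{strand}\n")
            for s, e, b in rows:
                fh.write(f"{s}\t{e}\t{b}\n")


def load_bin_index(path: str | Path, model: GeneModel | None = None) -> BinIndex:
    """Load a persisted bin index, verifying it against ``model`` if given.

    Raises :class:`StaleIndexError` when the stored checksum does not match
    the model's — rebuild the index in that case.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"bin index not found: {path}")
    entries: dict[tuple, np.ndarray] = {}
    meta: dict[str, str] = {}
    current_key: tuple | None = None
    current_rows: list[tuple[int, int, int]] = []

    def flush() -> None:
        if current_key is not None:
            entries[current_key] = np.asarray(current_rows, dtype=np.int64).reshape(-1, 3)

    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#skewc-bin-index"):
            raise FormatError(f"{path}: not a skewc bin index file")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                k, v = line[1:].split("\t", 1)
                meta[k] = v
            elif line.startswith(">"):
                flush()
                chrom, start, end, name, strand = line[1:].split("\t")
                current_key = (chrom, int(start), int(end), name, strand)
                current_rows = []
            elif line:
                s, e, b = line.split("\t")
                current_rows.append((int(s), int(e), int(b)))
        flush()
    checksum = meta["checksum"]
    if model is not None and model.checksum() != checksum:
        raise StaleIndexError(
            f"{path} was built from a different gene model "
            f"(stored checksum {checksum[:12]}..., model {model.checksum()[:12]}...); "
            "rebuild the index"
        )
    return BinIndex(
        entries=entries,
        n_bins=int(meta["n_bins"]),
        min_mrna_length=int(meta["min_mrna_length"]),
        checksum=checksum,
        n_skipped_short=int(meta.get("n_skipped_short", 0)),
    )


def get_or_build_index(
    bed_path: str | Path,
    reference_dir: str | Path = "reference",
    n_bins: int = N_BINS_DEFAULT,
    min_mrna_length: int = MIN_MRNA_LENGTH_DEFAULT,
) -> BinIndex:
    """Load a cached index for ``bed_path`` if fresh, else build and persist it."""
    model = read_bed12(bed_path)
    idx_path = index_path_for(bed_path, reference_dir)
    if idx_path.exists():
        try:
            index = load_bin_index(idx_path, model)
            if index.n_bins == n_bins and index.min_mrna_length == min_mrna_length:
                return index
        except StaleIndexError:
            log.warning("stale index %s; rebuilding", idx_path)
    index = build_bin_index(model, n_bins=n_bins, min_mrna_length=min_mrna_length)
    save_bin_index(index, idx_path)
    return index
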