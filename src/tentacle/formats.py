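"""Readers and writers for the on-disk formats the pipeline touches.

Reads come in FASTA or FASTQ (optionally gzip-compressed), annotations in a
five-column tab-separated format (a minimal GFF-like subset), mapper output in
12-column BLAST tabular ("blast8"/"blast6out") or SAM text, and quantification
results leave as a nine-column TSV.

Coordinate conventions: every on-disk format here uses 1-based inclusive
coordinates (GFF, BLAST, SAM). Internally everything is 0-based half-open
[start, end); conversion happens only in this module, at file boundaries.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

GZIP_MAGIC = b"\x1f\x8b"

#: Reference-consuming CIGAR operations (advance the reference coordinate).
_CIGAR_REF_OPS = frozenset("MDN=X")
#: Operations that occupy alignment columns (for alignment length).
_CIGAR_ALN_OPS = frozenset("MID=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class FormatError(ValueError):
    """A record in an input file violates its format contract."""

    def __init__(self, message: str, path: Optional[str] = None,
                 line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class SequenceRecord:
    """One sequencing read (or reference sequence).

    ``id`` is the first whitespace-delimited token of the header line.
    ``qualities`` are Phred integer scores, ``None`` for FASTA input.
    """

    id: str
    sequence: str
    qualities: Optional[Sequence[int]] = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} quality values "
                f"for {len(self.sequence)} bases")


@dataclass(frozen=True, slots=True)
class Annotation:
    """One annotated region on a reference sequence.

    ``start``/``end`` are 0-based half-open; use :meth:`to_file_coords`
    for the on-disk 1-based inclusive convention.
    """

    ref_id: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"annotation {self.label!r}: invalid interval "
                f"[{self.start}, {self.end})")
        if not self.label:
            raise ValueError("annotation label must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_file_coords(self) -> tuple[int, int]:
        """Return (start, end) as 1-based inclusive."""
        return self.start + 1, self.end

    @classmethod
    def from_file_coords(cls, ref_id: str, start: int, end: int,
                         strand: str, label: str) -> "Annotation":
        """Build from 1-based inclusive file coordinates."""
        return cls(ref_id, start - 1, end, strand, label)


@dataclass(slots=True)
class Hit:
    """One normalized read-to-reference alignment record.

    ``ref_start``/``ref_end`` are the 0-based half-open reference interval
    covered by the alignment (reverse-strand hits already normalized).
    ``file_order`` is the ordinal position of the record in the source file,
    which defines the "best hit" (first listed) for ambiguous reads.
    """

    query_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    identity_pct: float
    aln_len: int
    file_order: int

    def __post_init__(self):
        if self.ref_start >= self.ref_end:
            raise ValueError(
                f"hit {self.query_id!r}->{self.ref_id!r}: empty interval "
                f"[{self.ref_start}, {self.ref_end})")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity {self.identity_pct} outside [0, 100]")


@dataclass(slots=True)
class RegionResult:
    """An annotation with its read count and coverage statistics.

    ``count`` and/or the coverage fields are ``None`` when the corresponding
    computation was disabled; they serialize as "NA".
    """

    annotation: Annotation
    count: Optional[int]
    median_cov: Optional[float]
    mean_cov: Optional[float]
    sd_cov: Optional[float]


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def open_maybe_gzip(path: PathLike, mode: str = "rt") -> IO:
    """Open *path* as text, transparently gunzipping (sniffed by magic bytes)."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, mode)
    return open(path, mode)


def sniff_read_format(handle: IO[str]) -> str:
    """Detect fasta/fastq from the first non-whitespace character."""
    pos = handle.tell()
    fmt = None
    while True:
        ch = handle.read(1)
        if not ch:
            break
        if not ch.isspace():
            fmt = {"@": "fastq", ">": "fasta"}.get(ch)
            break
    handle.seek(pos)
    if fmt is None:
        raise FormatError("cannot detect read format: file is empty or starts "
                          "with neither '>' nor '@'")
    return fmt


def stream_reads(path: PathLike, format_hint: str = "auto"
                 ) -> Iterator[SequenceRecord]:
    """Lazily yield :class:`SequenceRecord` from a FASTA/FASTQ file.

    gzip compression is detected from magic bytes and decompressed into a
    continuous in-memory stream; the whole file is never materialized.
    With ``format_hint='auto'`` the format is sniffed from the first
    non-empty character ('>' FASTA, '@' FASTQ).
    """
    if format_hint not in ("auto", "fasta", "fastq"):
        raise ValueError(f"unknown format hint {format_hint!r}")
    with open_maybe_gzip(path) as handle:
        fmt = format_hint
        if fmt == "auto":
            try:
                fmt = sniff_read_format(handle)
            except FormatError as exc:
                raise FormatError(str(exc), path=str(path)) from None
        n = 0
        parser = SeqIO.parse(handle, fmt)
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                # Bio.SeqIO does not expose line numbers; reconstruct the
                # position of the offending record from the record index.
                per_record = 4 if fmt == "fastq" else 2
                raise FormatError(
                    f"malformed {fmt} record #{n + 1}: {exc}",
                    path=str(path), line=n * per_record + 1) from None
            quals = rec.letter_annotations.get("phred_quality")
            yield SequenceRecord(rec.id, str(rec.seq),
                                 tuple(quals) if quals is not None else None)
            n += 1


def write_reads(records: Iterable[SequenceRecord], path: PathLike,
                fmt: str = "fasta") -> int:
    """Write records as FASTA or FASTQ (Phred+33). Returns records written."""
    n = 0
    with open(path, "w") as out:
        for rec in records:
            if fmt == "fastq":
                if rec.qualities is None:
                    raise FormatError(
                        f"record {rec.id!r} has no qualities; cannot write FASTQ")
                qual = "".join(chr(q + 33) for q in rec.qualities)
                out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            else:
                out.write(f">{rec.id}\n{rec.sequence}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(path: PathLike) -> list[Annotation]:
    """Parse the five-column annotation TSV.

    Columns: ref_id, start (1-based inclusive), end (inclusive), strand
    (+/-/.), label. Lines starting with '#' are ignored. File order is
    preserved; coordinates are normalized to 0-based half-open.
    """
    annotations: list[Annotation] = []
    with open_maybe_gzip(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(
                    f"expected 5 tab-separated columns, got {len(fields)}",
                    path=str(path), line=lineno)
            ref_id, start_s, end_s, strand, label = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"non-integer coordinates {start_s!r}, {end_s!r}",
                    path=str(path), line=lineno) from None
            if start < 1 or start > end:
                raise FormatError(
                    f"invalid coordinates start={start} end={end}",
                    path=str(path), line=lineno)
            if strand not in ("+", "-", "."):
                raise FormatError(f"invalid strand {strand!r}",
                                  path=str(path), line=lineno)
            try:
                annotations.append(
                    Annotation.from_file_coords(ref_id, start, end, strand, label))
            except ValueError as exc:
                raise FormatError(str(exc), path=str(path), line=lineno) from None
    return annotations


def write_annotations(annotations: Iterable[Annotation], path: PathLike) -> None:
    """Write annotations in the five-column TSV (1-based inclusive)."""
    with open(path, "w") as out:
        for ann in annotations:
            start, end = ann.to_file_coords()
            out.write(f"{ann.ref_id}\t{start}\t{end}\t{ann.strand}\t{ann.label}\n")


# ---------------------------------------------------------------------------
# Mapper output
# ---------------------------------------------------------------------------

def _as_line_stream(source: Union[PathLike, IO[str], Iterable[str]]
                    ) -> tuple[Iterable[str], Optional[str], bool]:
    """Normalize a path / file object / line iterable into lines to iterate."""
    if isinstance(source, (str, Path)):
        return open_maybe_gzip(source), str(source), True
    return source, getattr(source, "name", None), False


def parse_blast8(source: Union[PathLike, IO[str], Iterable[str]],
                 errors: str = "skip") -> Iterator[Hit]:
    """Stream hits from 12-column BLAST tabular output.

    Columns: query, subject, %identity, alignment length, mismatches, gap
    opens, qstart, qend, sstart, send, e-value, bitscore. Subject coordinates
    are 1-based inclusive and may have sstart > send for reverse-strand hits;
    the emitted interval is normalized to half-open [min-1, max).

    ``errors='skip'`` skips malformed lines with a logged summary;
    ``errors='strict'`` aborts with a :class:`FormatError`.
    """
    if errors not in ("skip", "strict"):
        raise ValueError(f"unknown error policy {errors!r}")
    lines, path, close = _as_line_stream(source)
    order = 0
    skipped = 0
    try:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) != 12:
                    raise ValueError(
                        f"expected 12 columns, got {len(fields)}")
                sstart = int(fields[8])
                send = int(fields[9])
                lo, hi = (sstart, send) if sstart <= send else (send, sstart)
                hit = Hit(
                    query_id=fields[0],
                    ref_id=fields[1],
                    ref_start=lo - 1,
                    ref_end=hi,
                    identity_pct=float(fields[2]),
                    aln_len=int(fields[3]),
                    file_order=order,
                )
            except ValueError as exc:
                if errors == "strict":
                    raise FormatError(f"malformed blast8 line: {exc}",
                                      path=path, line=lineno) from None
                skipped += 1
                logger.debug("skipping malformed blast8 line %s:%s: %s",
                             path, lineno, exc)
                continue
            yield hit
            order += 1
    finally:
        if close:
            lines.close()
        if skipped:
            logger.warning("parse_blast8: skipped %d malformed line(s) in %s",
                           skipped, path)


def cigar_reference_span(cigar: str) -> tuple[int, int]:
    """Return (reference span, alignment columns) of a CIGAR string.

    Reference span sums M/D/N/=/X lengths; alignment columns sum M/I/D/=/X.
    """
    span = 0
    columns = 0
    consumed = 0
    for m in _CIGAR_RE.finditer(cigar):
        length, op = int(m.group(1)), m.group(2)
        if op in _CIGAR_REF_OPS:
            span += length
        if op in _CIGAR_ALN_OPS:
            columns += length
        consumed += m.end() - m.start()
    if consumed != len(cigar):
        raise ValueError(f"invalid CIGAR string {cigar!r}")
    return span, columns


def parse_sam(source: Union[PathLike, IO[str], Iterable[str]],
              errors: str = "skip") -> Iterator[Hit]:
    """Stream hits from SAM text.

    Unmapped records (flag bit 0x4) are skipped. The reference interval is
    [POS-1, POS-1 + reference-consuming CIGAR length). Percent identity is
    derived from the NM tag when present ((columns - NM)/columns * 100),
    otherwise 100.0. A mapped record with CIGAR '*' is skipped and logged.
    Header lines are optional.
    """
    if errors not in ("skip", "strict"):
        raise ValueError(f"unknown error policy {errors!r}")
    lines, path, close = _as_line_stream(source)
    order = 0
    skipped = 0
    try:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 11:
                    raise ValueError(
                        f"expected >= 11 columns, got {len(fields)}")
                flag = int(fields[1])
                if flag & 0x4:
                    continue
                cigar = fields[5]
                if cigar == "*":
                    raise ValueError("mapped record without CIGAR")
                pos = int(fields[3])
                span, columns = cigar_reference_span(cigar)
                if span == 0:
                    raise ValueError(
                        f"CIGAR {cigar!r} consumes no reference bases")
                nm = None
                for tag in fields[11:]:
                    if tag.startswith("NM:i:"):
                        nm = int(tag[5:])
                        break
                if nm is not None and columns > 0:
                    identity = max(0.0, (columns - nm) / columns * 100.0)
                else:
                    identity = 100.0
                hit = Hit(
                    query_id=fields[0],
                    ref_id=fields[2],
                    ref_start=pos - 1,
                    ref_end=pos - 1 + span,
                    identity_pct=identity,
                    aln_len=columns,
                    file_order=order,
                )
            except ValueError as exc:
                if errors == "strict":
                    raise FormatError(f"malformed SAM record: {exc}",
                                      path=path, line=lineno) from None
                skipped += 1
                logger.debug("skipping SAM line %s:%s: %s", path, lineno, exc)
                continue
            yield hit
            order += 1
    finally:
        if close:
            lines.close()
        if skipped:
            logger.warning("parse_sam: skipped %d record(s) in %s",
                           skipped, path)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

RESULTS_HEADER = ("#ref_id\tstart\tend\tstrand\tlabel\tcount"
                  "\tmedian_cov\tmean_cov\tsd_cov")


def _fmt_count(v: Optional[int]) -> str:
    return "NA" if v is None else str(v)


def _fmt_float(v: Optional[float]) -> str:
    return "NA" if v is None else f"{v:.4f}"


def write_results(results: Iterable[RegionResult], path: PathLike) -> None:
    """Write quantification results as the nine-column TSV.

    One header comment line, then one row per annotation in annotation-file
    order: ref_id, start (1-based inclusive), end, strand, label, count,
    median_cov, mean_cov, sd_cov. Floats use fixed 4-decimal formatting;
    disabled fields are written as "NA".
    """
    with open(path, "w") as out:
        out.write(RESULTS_HEADER + "\n")
        for res in results:
            ann = res.annotation
            start, end = ann.to_file_coords()
            out.write("\t".join((
                ann.ref_id, str(start), str(end), ann.strand, ann.label,
                _fmt_count(res.count), _fmt_float(res.median_cov),
                _fmt_float(res.mean_cov), _fmt_float(res.sd_cov))) + "\n")


def read_results(path: PathLike) -> list[RegionResult]:
    """Parse a results TSV written by :func:`write_results`."""

    def _opt_int(s: str) -> Optional[int]:
        return None if s == "NA" else int(s)

    def _opt_float(s: str) -> Optional[float]:
        return None if s == "NA" else float(s)

    results = []
    with open_maybe_gzip(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"expected 9 columns, got {len(fields)}",
                    path=str(path), line=lineno)
            ann = Annotation.from_file_coords(
                fields[0], int(fields[1]), int(fields[2]), fields[3], fields[4])
            results.append(RegionResult(
                ann, _opt_int(fields[5]), _opt_float(fields[6]),
                _opt_float(fields[7]), _opt_float(fields[8])))
    return results
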