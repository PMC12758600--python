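"""Streaming FASTQ/FASTA plumbing shared by the indexer and the classifier.

Records are lossless ``(title, sequence, quality)`` string triplets (titles
without the leading ``@``).  Gzip compression is autodetected by magic bytes
on input and selected by a ``.gz`` suffix on output; gzip members are written
with a fixed zero mtime so identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import gzip
import io
import os
from contextlib import contextmanager
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FastqFormatError",
    "open_text",
    "open_text_write",
    "read_fastq",
    "write_fastq",
    "read_fasta",
]

_GZIP_MAGIC = b"\x1f\x8b"

FastqRecord = tuple[str, str, str]


class FastqFormatError(ValueError):
    """Malformed FASTQ input, reported with the offending record index."""


@contextmanager
def open_text(path: str | os.PathLike) -> Iterator[IO[str]]:
    """Open a possibly gzip-compressed text file, autodetected by magic."""
    with open(path, "rb") as raw:
        magic = raw.peek(2)[:2] if isinstance(raw, io.BufferedReader) else raw.read(2)
        raw.seek(0)
        if magic == _GZIP_MAGIC:
            with gzip.open(raw, "rt") as fh:
                yield fh
        else:
            with io.TextIOWrapper(raw) as fh:
                yield fh


@contextmanager
def open_text_write(path: str | os.PathLike) -> Iterator[IO[str]]:
    """Open a text sink; a ``.gz`` suffix selects deterministic gzip output."""
    if str(path).endswith(".gz"):
        with open(path, "wb") as raw:
            gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
            with io.TextIOWrapper(gz) as fh:
                yield fh
    else:
        with open(path, "w") as fh:
            yield fh


def _iter_fastq(handle: IO[str]) -> Iterator[FastqRecord]:
    it = FastqGeneralIterator(handle)
    i = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqFormatError(f"malformed FASTQ at record {i}: {exc}") from exc
        yield rec
        i += 1


def read_fastq(source: str | os.PathLike | IO[str]) -> Iterator[FastqRecord]:
    """Stream ``(title, seq, qual)`` triplets from a FASTQ file or handle."""
    if hasattr(source, "read"):
        yield from _iter_fastq(source)  # type: ignore[arg-type]
    else:
        with open_text(source) as fh:
            yield from _iter_fastq(fh)


def write_fastq(records: Iterable[FastqRecord], sink: str | os.PathLike | IO[str]) -> int:
    """Write 4-line FASTQ records; returns the number written."""
    if hasattr(sink, "write"):
        return _write_records(records, sink)  # type: ignore[arg-type]
    with open_text_write(sink) as fh:
        return _write_records(records, fh)


def _write_records(records: Iterable[FastqRecord], fh: IO[str]) -> int:
    n = 0
    for title, seq, qual in records:
        if len(seq) != len(qual):
            raise FastqFormatError(
                f"malformed FASTQ at record {n}: sequence and quality lengths differ"
            )
        fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
        n += 1
    return n


def read_fasta(source: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Stream ``(name, sequence)`` pairs from a (possibly gzipped) FASTA."""
    with open_text(source) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)
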