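"""Read classification by covered bases, and FASTQ stream filtering.

A read is queried against the seed index and classified as host if at least
``T * |read|`` of its base positions are covered by matching gapped k-mers
(threshold comparison is inclusive, default ``T = 0.5``).

Two modes are supported:

* *sensitive* — every window of the read is queried; a hit marks the
  significant (masked) positions of that window as covered.
* *sampling* — only every ``(floor(w/2) + 1)``-th window is queried,
  starting at offset 0, so that every base still overlaps up to two queried
  windows; a hit marks **all** ``w`` window positions as covered.

Reads shorter than the mask width carry no seed evidence and are always
retained.  Windows containing non-ACGT characters count as queried but can
never match (the index holds only defined bases).  For paired-end input the
two mates are classified independently and the pair is removed if either
mate is host.
"""

from __future__ import annotations

from contextlib import ExitStack
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .fastqio import FastqRecord, open_text_write, read_fastq
from .seedcodes import Mask, gapped_code_array

__all__ = [
    "ClassifyParams",
    "CoverageResult",
    "FilterSummary",
    "cover_sensitive",
    "cover_sampling",
    "classify_read",
    "classify_pair",
    "filter_stream",
]


@dataclass(frozen=True)
class ClassifyParams:
    """Classification parameters: coverage threshold and query mode."""

    threshold: float = 0.5
    mode: str = "sensitive"  # "sensitive" | "sampling"

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must be in [0, 1]")
        if self.mode not in ("sensitive", "sampling"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class CoverageResult:
    """Per-read outcome: query counts, covered bases, and the decision."""

    read_length: int
    windows_queried: int
    windows_hit: int
    covered_bases: int
    is_host: bool


def _decide(covered: int, L: int, w: int, threshold: float) -> bool:
    if L < w:
        return False  # no seed evidence: always retained
    return covered >= threshold * L


def cover_sensitive(read: str, store, mask: Mask, threshold: float = 0.5) -> CoverageResult:
    """Query every window; hits mark their significant positions."""
    L = len(read)
    w = mask.width_w
    codes, valid = gapped_code_array(read, mask)
    nwin = codes.shape[0]
    if nwin == 0:
        return CoverageResult(L, 0, 0, 0, _decide(0, L, w, threshold))
    hits = np.zeros(nwin, dtype=bool)
    vidx = np.flatnonzero(valid)
    if vidx.size:
        hits[vidx] = store.lookup_many(codes[vidx])
    covered = np.zeros(L, dtype=bool)
    hit_offsets = np.flatnonzero(hits)
    if hit_offsets.size:
        covered[(hit_offsets[:, None] + mask.kappa_array).ravel()] = True
    n_cov = int(covered.sum())
    return CoverageResult(L, nwin, int(hit_offsets.size), n_cov,
                          _decide(n_cov, L, w, threshold))


def cover_sampling(read: str, store, mask: Mask, threshold: float = 0.5) -> CoverageResult:
    """Query offsets 0, s, 2s, ... with step ``s = floor(w/2) + 1``; hits
    mark all ``w`` window positions."""
    L = len(read)
    w = mask.width_w
    codes, valid = gapped_code_array(read, mask)
    nwin = codes.shape[0]
    if nwin == 0:
        return CoverageResult(L, 0, 0, 0, _decide(0, L, w, threshold))
    step = w // 2 + 1
    offsets = np.arange(0, nwin, step)
    hits = np.zeros(offsets.shape[0], dtype=bool)
    q_valid = valid[offsets]
    if q_valid.any():
        hits[q_valid] = store.lookup_many(codes[offsets[q_valid]])
    covered = np.zeros(L, dtype=bool)
    for i in offsets[hits]:
        covered[i:i + w] = True
    n_cov = int(covered.sum())
    return CoverageResult(L, int(offsets.shape[0]), int(hits.sum()), n_cov,
                          _decide(n_cov, L, w, threshold))


def classify_read(read: str, store, mask: Mask, params: ClassifyParams) -> CoverageResult:
    if params.mode == "sensitive":
        return cover_sensitive(read, store, mask, params.threshold)
    return cover_sampling(read, store, mask, params.threshold)


def classify_pair(
    read1: str, read2: str, store, mask: Mask, params: ClassifyParams
) -> tuple[bool, CoverageResult, CoverageResult]:
    """Classify both mates independently; returns (remove_pair, r1, r2)."""
    r1 = classify_read(read1, store, mask, params)
    r2 = classify_read(read2, store, mask, params)
    return r1.is_host or r2.is_host, r1, r2


@dataclass
class FilterSummary:
    """Filtering outcome; paired input counts read *pairs* as units."""

    total: int = 0
    removed: int = 0
    retained: int = 0
    short_reads: int = 0  # reads (or pairs) shorter than the mask width

    def as_dict(self) -> dict:
        return {"total": self.total, "removed": self.removed,
                "retained": self.retained, "short_reads": self.short_reads}


class PairedLengthError(ValueError):
    """Paired FASTQ inputs with unequal record counts."""


def _record_stream(source) -> Iterable[FastqRecord]:
    if isinstance(source, (list, tuple)):
        return iter(source)
    return read_fastq(source)


class _Sink:
    """Write-through record sink: path, open handle, or None (discard)."""

    def __init__(self, target, stack: ExitStack):
        self._fh = None
        if target is None:
            return
        if hasattr(target, "write"):
            self._fh = target
        else:
            self._fh = stack.enter_context(open_text_write(target))

    def append(self, rec: FastqRecord) -> None:
        if self._fh is not None:
            title, seq, qual = rec
            self._fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


def filter_stream(
    store,
    mask: Mask,
    params: ClassifyParams,
    reads,
    out,
    reads2=None,
    out2=None,
    removed_out=None,
    removed_out2=None,
) -> FilterSummary:
    """Filter a FASTQ stream, writing retained (non-host) records in order.

    ``reads``/``reads2`` may be paths or lists of ``(title, seq, qual)``
    records; ``out``-type arguments may be paths, handles, or None (discard).
    Record identity (names, sequences, quality strings) is preserved; for
    paired input both mates of a pair are kept or removed together.
    """
    summary = FilterSummary()
    w = mask.width_w
    with ExitStack() as stack:
        keep1, keep2 = _Sink(out, stack), _Sink(out2, stack)
        drop1, drop2 = _Sink(removed_out, stack), _Sink(removed_out2, stack)

        if reads2 is None:
            for rec in _record_stream(reads):
                summary.total += 1
                res = classify_read(rec[1], store, mask, params)
                if len(rec[1]) < w:
                    summary.short_reads += 1
                if res.is_host:
                    summary.removed += 1
                    drop1.append(rec)
                else:
                    summary.retained += 1
                    keep1.append(rec)
        else:
            it1 = iter(_record_stream(reads))
            it2 = iter(_record_stream(reads2))
            while True:
                rec1 = next(it1, None)
                rec2 = next(it2, None)
                if rec1 is None and rec2 is None:
                    break
                if rec1 is None or rec2 is None:
                    raise PairedLengthError("paired inputs have unequal record counts")
                summary.total += 1
                remove, _, _ = classify_pair(rec1[1], rec2[1], store, mask, params)
                if len(rec1[1]) < w and len(rec2[1]) < w:
                    summary.short_reads += 1
                if remove:
                    summary.removed += 1
                    drop1.append(rec1)
                    drop2.append(rec2)
                else:
                    summary.retained += 1
                    keep1.append(rec1)
                    keep2.append(rec2)
    return summary
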