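"""Spaced-seed masks and 2-bit canonical k-mer codes.

A *(k, w)-mask* is a string over ``{#, _}`` of width ``w`` with exactly ``k``
significant positions (``#``), the first and last of which must be
significant.  Only *symmetric* masks (palindromic patterns) are accepted, so
that the canonical code of a window equals that of its reverse complement.

Encoding convention
-------------------
Nucleotides map to base-4 digits as **A=0, C=1, T=2, G=3** (so that the
complement of a digit is ``digit XOR 2``).  Note that this differs from the
more common A=0, C=1, G=2, T=3 order used by many other k-mer tools.  The
canonical code of a seed ``x`` is ``cc(x) = max(enc(x), enc(rc(x)))`` — the
**maximum** of the two encodings, not the minimum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterator

import numpy as np
from numba import njit

__all__ = [
    "Mask",
    "SeedHit",
    "DEFAULT_MASK",
    "parse_mask",
    "encode",
    "decode",
    "revcomp_code",
    "canonical_code",
    "extract_gapped",
    "min_coverage",
]

#: Default (29,33) symmetric mask used for host-genome indexing.
DEFAULT_MASK = "######_#######_###_#######_######"

_DIGIT = {"A": 0, "C": 1, "T": 2, "G": 3}
_BASE = "ACTG"  # index i -> nucleotide with digit i

# byte -> 2-bit digit, -1 for anything that is not an unambiguous base
_DIGIT_LUT = np.full(256, -1, dtype=np.int8)
for _b, _d in _DIGIT.items():
    _DIGIT_LUT[ord(_b)] = _d
    _DIGIT_LUT[ord(_b.lower())] = _d


class MaskError(ValueError):
    """Raised for syntactically or structurally invalid mask patterns."""


@dataclass(frozen=True)
class Mask:
    """A validated symmetric spaced-seed pattern.

    Attributes
    ----------
    pattern:
        The mask string over ``{#, _}``.
    weight_k:
        Number of significant positions.
    width_w:
        Window length (length of *pattern*).
    kappa:
        Sorted tuple of significant offsets in ``[0, width_w)``.
    """

    pattern: str
    weight_k: int = field(init=False)
    width_w: int = field(init=False)
    kappa: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        p = self.pattern
        if not p:
            raise MaskError("empty mask pattern")
        bad = set(p) - {"#", "_"}
        if bad:
            raise MaskError(f"illegal mask characters: {sorted(bad)}")
        if p[0] != "#" or p[-1] != "#":
            raise MaskError("first and last mask positions must be significant ('#')")
        if p != p[::-1]:
            raise MaskError("mask must be symmetric (palindromic)")
        kappa = tuple(i for i, c in enumerate(p) if c == "#")
        if len(kappa) < 2:
            raise MaskError("mask weight must be at least 2")
        object.__setattr__(self, "weight_k", len(kappa))
        object.__setattr__(self, "width_w", len(p))
        object.__setattr__(self, "kappa", kappa)

    @property
    def kappa_array(self) -> np.ndarray:
        return np.asarray(self.kappa, dtype=np.int64)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.pattern


@dataclass(frozen=True)
class SeedHit:
    """A gapped k-mer occurrence: 0-based window start and canonical code."""

    offset: int
    code: int


def parse_mask(pattern: str) -> Mask:
    """Parse and validate a mask string over ``{#, _}``.

    >>> m = parse_mask("##_#_##")
    >>> m.weight_k, m.width_w, m.kappa
    (5, 7, (0, 1, 3, 5, 6))
    """
    return Mask(pattern)


def encode(seq: str) -> int:
    """Encode a DNA string as a base-4 integer (A=0, C=1, T=2, G=3).

    Raises ``ValueError`` on any ambiguous base (N, IUPAC codes, ...).
    """
    value = 0
    for ch in seq.upper():
        try:
            value = (value << 2) | _DIGIT[ch]
        except KeyError:
            raise ValueError(f"ambiguous base {ch!r} in {seq!r}") from None
    return value


def decode(code: int, k: int) -> str:
    """Inverse of :func:`encode` for a k-mer of known length."""
    _check_code(code, k)
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_BASE[(code >> shift) & 3])
    return "".join(out)


def _check_code(code: int, k: int) -> None:
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")


def revcomp_code(code: int, k: int) -> int:
    """Reverse-complement a 2-bit encoded k-mer code.

    Digits are reversed and complemented; with this alphabet the complement
    of a digit is ``digit XOR 2``.
    """
    _check_code(code, k)
    out = 0
    for _ in range(k):
        out = (out << 2) | ((code & 3) ^ 2)
        code >>= 2
    return out


def canonical_code(code: int, k: int) -> int:
    """Canonical code: the **max** of a code and its reverse complement."""
    return max(code, revcomp_code(code, k))


@njit(cache=True)
def _gapped_codes(digits, kappa, w):  # pragma: no cover - numba kernel
    """Canonical gapped codes for every window of a digit sequence.

    digits: int8 array, 0..3 for A/C/T/G, negative for invalid bases.
    Returns (codes: uint64[nwin], valid: bool[nwin]); windows containing an
    invalid base are marked invalid with code 0.
    """
    L = digits.shape[0]
    k = kappa.shape[0]
    nwin = L - w + 1
    if nwin < 0:
        nwin = 0
    codes = np.zeros(nwin, dtype=np.uint64)
    valid = np.zeros(nwin, dtype=np.bool_)
    # prefix count of invalid bases for O(1) window validity
    bad = np.zeros(L + 1, dtype=np.int64)
    for i in range(L):
        bad[i + 1] = bad[i] + (1 if digits[i] < 0 else 0)
    for i in range(nwin):
        if bad[i + w] - bad[i] > 0:
            continue
        fwd = np.uint64(0)
        rev = np.uint64(0)
        for j in range(k):
            d = np.uint64(digits[i + kappa[j]])
            fwd = (fwd << np.uint64(2)) | d
            # masked reverse complement, exploiting mask symmetry:
            # digit j of rc contributes (d ^ 2) at weight 4**j
            rev |= (d ^ np.uint64(2)) << np.uint64(2 * j)
        codes[i] = fwd if fwd > rev else rev
        valid[i] = True
    return codes, valid


def seq_digits(seq: str) -> np.ndarray:
    """Map a sequence to int8 digits (A=0,C=1,T=2,G=3; -1 for other chars)."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _DIGIT_LUT[raw]


def gapped_code_array(seq: str, mask: Mask) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised window scan: (codes uint64[nwin], valid bool[nwin]).

    ``nwin = max(0, len(seq) - w + 1)``; invalid windows (containing a
    non-ACGT character) have ``valid == False``.
    """
    digits = seq_digits(seq)
    return _gapped_codes(digits, mask.kappa_array, mask.width_w)


def extract_gapped(seq: str, mask: Mask) -> list[SeedHit]:
    """Extract canonical gapped k-mer codes from every ACGT-only window.

    Windows overlapping any character outside ``{A,C,G,T}`` are skipped.
    Sequences shorter than the mask width yield an empty list.
    """
    codes, valid = gapped_code_array(seq, mask)
    return [SeedHit(int(i), int(codes[i])) for i in np.flatnonzero(valid)]


# ---------------------------------------------------------------------------
# Mask-coverage certification (exhaustive, worst case over substitution sets)
# ---------------------------------------------------------------------------


def _placement_bitmasks(offsets: np.ndarray, n_place: int, L: int) -> np.ndarray:
    """Per-placement covered-position bitsets as (n_place, n_words) uint64."""
    n_words = (L + 63) // 64
    masks = np.zeros((n_place, n_words), dtype=np.uint64)
    for i in range(n_place):
        pos = offsets + i
        np.bitwise_or.at(masks[i], pos // 64, np.uint64(1) << (pos % 64).astype(np.uint64))
    return masks


def _iter_chunks(it: Iterator, size: int):
    while True:
        chunk = list(itertools.islice(it, size))
        if not chunk:
            return
        yield chunk


def min_coverage(
    mask: Mask,
    L: int,
    s_max: int,
    *,
    semantics: str = "significant",
    budget: int = 10**7,
    chunk_size: int = 8192,
) -> int:
    """Worst-case covered positions of a length-``L`` window under at most
    ``s_max`` substitutions, by exhaustive enumeration.

    A seed placement at offset ``i`` survives a substitution set ``S`` iff no
    element of ``S`` falls on one of its significant positions
    ``{i + j : j in kappa}``.  Coverage of ``S`` is the size of the union of
    the marked positions of all surviving placements; the minimum over all
    ``S`` with ``|S| <= s_max`` is returned.

    Parameters
    ----------
    semantics:
        ``"significant"`` marks only significant positions of surviving
        placements (matching sensitive-mode read marking); ``"window"`` marks
        all ``w`` window positions instead.
    budget:
        Refuse enumeration when the number of substitution sets exceeds this.
    """
    w, kappa = mask.width_w, mask.kappa_array
    if L < w:
        raise ValueError(f"L={L} shorter than mask width {w}")
    if s_max < 0:
        raise ValueError("s_max must be >= 0")
    if semantics not in ("significant", "window"):
        raise ValueError(f"unknown semantics {semantics!r}")
    n_sets = sum(comb(L, s) for s in range(min(s_max, L) + 1))
    if n_sets > budget:
        raise ValueError(
            f"{n_sets} substitution sets exceed enumeration budget {budget}"
        )

    n_place = L - w + 1
    # kill[p, i]: substitution at position p kills placement i
    kill = np.zeros((L, n_place), dtype=bool)
    for i in range(n_place):
        kill[kappa + i, i] = True

    if semantics == "significant":
        cover = _placement_bitmasks(kappa, n_place, L)
    else:
        cover = _placement_bitmasks(np.arange(w), n_place, L)

    n_words = cover.shape[1]
    all_union = np.bitwise_or.reduce(cover, axis=0)
    best = int(np.bitwise_count(all_union).sum())  # empty substitution set

    for s in range(1, min(s_max, L) + 1):
        combos = itertools.combinations(range(L), s)
        for chunk in _iter_chunks(combos, chunk_size):
            idx = np.array(chunk, dtype=np.intp)  # (c, s)
            killed = kill[idx].any(axis=1)  # (c, n_place)
            surv = ~killed
            sel = np.where(surv[:, :, None], cover[None, :, :], np.uint64(0))
            union = np.bitwise_or.reduce(sel, axis=1)  # (c, n_words)
            counts = np.bitwise_count(union).sum(axis=1)
            m = int(counts.min())
            if m < best:
                best = m
    return best
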