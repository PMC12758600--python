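"""Cuckoo key-set stores for canonical gapped k-mer codes.

Two layouts are provided:

* :class:`BucketedCuckooTable` — an exact (d, l) bucketed Cuckoo hash table.
  The slot array is divided into disjoint buckets of ``l`` slots; a key may
  reside in any of the ``d*l`` slots of its ``d`` admissible buckets.  Full
  64-bit codes are stored, so membership answers are exact.
* :class:`WindowedCuckooFilter` — a probabilistic (d=2, l) windowed Cuckoo
  filter.  Slots form overlapping windows (a new window starts at every
  slot); only a ``p``-bit fingerprint is stored per key, so absent keys may
  be reported present with probability at most ``d*l*2**-p``, while inserted
  keys are always found.  The overlapping-window layout sustains higher load
  factors than disjoint buckets for the same (d, l).

Insertions use bounded random-walk eviction: when all admissible slots are
full, a random resident is displaced and re-inserted at one of its own
alternative locations, up to ``max_kicks`` relocation steps.  A failed
insertion leaves the store *dirty* (one displaced resident may be lost);
callers are expected to rebuild larger or reseed, which the indexer does.

Key 0 is reserved as the empty-slot sentinel of the exact table; canonical
codes are never 0 (the reverse complement of the all-A k-mer encodes to a
positive integer, and the canonical code is the larger of the two).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "CuckooParams",
    "BucketedCuckooTable",
    "WindowedCuckooFilter",
    "CuckooFullError",
    "SerializationError",
    "fingerprint",
    "fill_to_load",
    "measure_fpr",
    "serialize",
    "deserialize",
]

_M64 = (1 << 64) - 1
#: Default bound on random-walk relocation steps per insertion (exact table).
DEFAULT_MAX_KICKS = 500
#: Default walk bound for the windowed filter.  Near its operating load of
#: 95% the (2,2) windowed layout needs much longer (still constant-bounded)
#: eviction walks than the bucketed table; 500 steps stall around 92% load.
FILTER_MAX_KICKS = 10_000
#: Random keys used by the measurement harnesses are drawn below this bound;
#: absent-key queries are drawn from [2**57, 2**58), guaranteeing disjointness.
FILL_KEY_BITS = 57


class CuckooFullError(RuntimeError):
    """Insertion failed after the maximum number of relocation steps."""


class SerializationError(ValueError):
    """Malformed serialized store (bad magic, version, or truncation)."""


def _splitmix_py(state: int) -> tuple[int, int]:
    state = (state + 0x9E3779B97F4A7C15) & _M64
    z = state
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return state, z ^ (z >> 31)


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    """n distinct 64-bit hash seeds from one integer seed (splitmix64)."""
    state = seed & _M64
    out = np.empty(n, dtype=np.uint64)
    for i in range(n):
        state, z = _splitmix_py(state)
        out[i] = z
    return out


def _mix_py(x: int) -> int:
    x &= _M64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _M64
    return x ^ (x >> 31)


@njit(cache=True, inline="always")
def _mix(x):  # pragma: no cover - numba kernel
    x = x ^ (x >> np.uint64(30))
    x = x * np.uint64(0xBF58476D1CE4E5B9)
    x = x ^ (x >> np.uint64(27))
    x = x * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


@njit(cache=True, inline="always")
def _rng_next(state):  # pragma: no cover - xorshift64*
    state = state ^ (state >> np.uint64(12))
    state = state ^ (state << np.uint64(25))
    state = state ^ (state >> np.uint64(27))
    return state, state * np.uint64(0x2545F4914F6CDD1D)


def _rng_state(seed: int) -> np.uint64:
    s = _mix_py(seed ^ 0xDEADBEEFCAFEF00D)
    return np.uint64(s if s != 0 else 0x9E3779B97F4A7C15)


# ---------------------------------------------------------------------------
# bucketed table kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _bt_lookup(slots, ell, d, seeds, key):  # pragma: no cover
    b = np.uint64(slots.shape[0] // ell)
    for j in range(d):
        h = _mix(key ^ seeds[j]) % b
        base = np.int64(h) * ell
        for t in range(ell):
            v = slots[base + t]
            if v == key:
                return True
            if v == np.uint64(0):
                # free slot before the key: key cannot be stored further on
                break
    return False


@njit(cache=True)
def _bt_lookup_many(slots, ell, d, seeds, keys, out):  # pragma: no cover
    for i in range(keys.shape[0]):
        out[i] = _bt_lookup(slots, ell, d, seeds, keys[i])


@njit(cache=True)
def _bt_insert(slots, ell, d, seeds, max_kicks, key, state):  # pragma: no cover
    """Returns (status, kicks, state): status 1=inserted, 2=duplicate, 0=fail."""
    b = np.uint64(slots.shape[0] // ell)
    free = np.int64(-1)
    for j in range(d):
        h = _mix(key ^ seeds[j]) % b
        base = np.int64(h) * ell
        for t in range(ell):
            v = slots[base + t]
            if v == key:
                return np.int8(2), np.int64(0), state
            if v == np.uint64(0) and free < 0:
                free = base + t
    if free >= 0:
        slots[free] = key
        return np.int8(1), np.int64(0), state
    cur = key
    for kick in range(max_kicks):
        # displace a random resident from one of cur's d*l admissible slots
        state, r = _rng_next(state)
        j = np.int64(r % np.uint64(d))
        h = _mix(cur ^ seeds[j]) % b
        base = np.int64(h) * ell
        state, r = _rng_next(state)
        t = np.int64(r % np.uint64(ell))
        victim = slots[base + t]
        slots[base + t] = cur
        cur = victim
        # try the victim's alternative buckets for a free slot
        for j2 in range(d):
            h2 = _mix(cur ^ seeds[j2]) % b
            base2 = np.int64(h2) * ell
            for t2 in range(ell):
                if slots[base2 + t2] == np.uint64(0):
                    slots[base2 + t2] = cur
                    return np.int8(1), np.int64(kick + 1), state
    return np.int8(0), np.int64(max_kicks), state


@njit(cache=True)
def _bt_insert_many(slots, ell, d, seeds, max_kicks, keys, state):  # pragma: no cover
    """Insert keys until done or failure; returns (n_new, fail_index, state)."""
    n_new = np.int64(0)
    for i in range(keys.shape[0]):
        status, _, state = _bt_insert(slots, ell, d, seeds, max_kicks, keys[i], state)
        if status == 1:
            n_new += 1
        elif status == 0:
            return n_new, np.int64(i), state
    return n_new, np.int64(-1), state


@njit(cache=True)
def _bt_fill(slots, ell, d, seeds, max_kicks, target_occ, occupied, state):  # pragma: no cover
    """Insert random 57-bit keys until the target occupancy or failure."""
    span = np.uint64(1) << np.uint64(57)
    while occupied < target_occ:
        state, r = _rng_next(state)
        key = np.uint64(1) + (r % (span - np.uint64(1)))
        status, _, state = _bt_insert(slots, ell, d, seeds, max_kicks, key, state)
        if status == 1:
            occupied += 1
        elif status == 0:
            return occupied, np.int8(0), state
    return occupied, np.int8(1), state


# ---------------------------------------------------------------------------
# windowed filter kernels
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _wf_fp(key, seeds, pmask):  # pragma: no cover
    fp = _mix(key ^ seeds[1]) & pmask
    if fp == np.uint64(0):
        fp = np.uint64(1)  # 0 is the empty-slot sentinel
    return fp


@njit(cache=True, inline="always")
def _wf_delta(fp, seeds, wmask):  # pragma: no cover
    dlt = _mix(fp ^ seeds[2]) & wmask
    if dlt == np.uint64(0):
        dlt = np.uint64(1)  # partner must differ from the home window
    return dlt


@njit(cache=True)
def _wf_lookup(slots, ell, seeds, wmask, pmask, key):  # pragma: no cover
    a = _mix(key ^ seeds[0]) & wmask
    fp = _wf_fp(key, seeds, pmask)
    bwin = a ^ _wf_delta(fp, seeds, wmask)
    f16 = np.uint16(fp)
    ia = np.int64(a)
    ib = np.int64(bwin)
    for t in range(ell):
        if slots[ia + t] == f16 or slots[ib + t] == f16:
            return True
    return False


@njit(cache=True)
def _wf_lookup_many(slots, ell, seeds, wmask, pmask, keys, out):  # pragma: no cover
    for i in range(keys.shape[0]):
        out[i] = _wf_lookup(slots, ell, seeds, wmask, pmask, keys[i])


@njit(cache=True)
def _wf_insert(slots, tags, ell, seeds, wmask, pmask, max_kicks, key, state):  # pragma: no cover
    """Returns (status, kicks, state): 1=inserted, 2=already present, 0=fail."""
    a = _mix(key ^ seeds[0]) & wmask
    fp = _wf_fp(key, seeds, pmask)
    dlt = _wf_delta(fp, seeds, wmask)
    bwin = a ^ dlt
    f16 = np.uint16(fp)
    for win in (a, bwin):
        base = np.int64(win)
        for t in range(ell):
            if slots[base + t] == f16:
                return np.int8(2), np.int64(0), state
    for win in (a, bwin):
        base = np.int64(win)
        for t in range(ell):
            if slots[base + t] == np.uint16(0):
                slots[base + t] = f16
                tags[base + t] = np.uint8(t)
                return np.int8(1), np.int64(0), state
    state, r = _rng_next(state)
    cur_fp = fp
    cur_win = a if (r & np.uint64(1)) == np.uint64(0) else bwin
    for kick in range(max_kicks):
        partner = cur_win ^ _wf_delta(cur_fp, seeds, wmask)
        state, r = _rng_next(state)
        wv = cur_win if (r & np.uint64(1)) == np.uint64(0) else partner
        state, r = _rng_next(state)
        t = np.int64(r % np.uint64(ell))
        s = np.int64(wv) + t
        vfp = np.uint64(slots[s])
        vwin = np.uint64(s - np.int64(tags[s]))  # victim's home window
        slots[s] = np.uint16(cur_fp)
        tags[s] = np.uint8(t)
        # relocate the victim to its alternative window
        cur_fp = vfp
        cur_win = vwin ^ _wf_delta(cur_fp, seeds, wmask)
        alt = cur_win ^ _wf_delta(cur_fp, seeds, wmask)
        for win in (cur_win, alt):
            base = np.int64(win)
            for t2 in range(ell):
                if slots[base + t2] == np.uint16(0):
                    slots[base + t2] = np.uint16(cur_fp)
                    tags[base + t2] = np.uint8(t2)
                    return np.int8(1), np.int64(kick + 1), state
    return np.int8(0), np.int64(max_kicks), state


@njit(cache=True)
def _wf_insert_many(slots, tags, ell, seeds, wmask, pmask, max_kicks, keys, state):  # pragma: no cover
    n_new = np.int64(0)
    for i in range(keys.shape[0]):
        status, _, state = _wf_insert(
            slots, tags, ell, seeds, wmask, pmask, max_kicks, keys[i], state
        )
        if status == 1:
            n_new += 1
        elif status == 0:
            return n_new, np.int64(i), state
    return n_new, np.int64(-1), state


@njit(cache=True)
def _wf_fill(slots, tags, ell, seeds, wmask, pmask, max_kicks, target_occ, occupied, state):  # pragma: no cover
    span = np.uint64(1) << np.uint64(57)
    while occupied < target_occ:
        state, r = _rng_next(state)
        key = np.uint64(1) + (r % (span - np.uint64(1)))
        status, _, state = _wf_insert(
            slots, tags, ell, seeds, wmask, pmask, max_kicks, key, state
        )
        if status == 1:
            occupied += 1
        elif status == 0:
            return occupied, np.int8(0), state
    return occupied, np.int8(1), state


@njit(cache=True)
def _wf_count_fp(slots, ell, seeds, wmask, pmask, n_queries, state):  # pragma: no cover
    """Count positive answers for random keys from [2**57, 2**58)."""
    lo = np.uint64(1) << np.uint64(57)
    hits = np.int64(0)
    for _ in range(n_queries):
        state, r = _rng_next(state)
        key = lo + (r % lo)
        if _wf_lookup(slots, ell, seeds, wmask, pmask, key):
            hits += 1
    return hits, state


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CuckooParams:
    """Shared layout parameters of a Cuckoo store."""

    d: int
    ell: int
    n_slots: int
    max_kicks: int = DEFAULT_MAX_KICKS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("d must be >= 2")
        if self.ell < 1:
            raise ValueError("ell must be >= 1")
        if self.max_kicks < 1:
            raise ValueError("max_kicks must be >= 1")
        if self.n_slots < self.ell:
            raise ValueError("n_slots must be at least ell")


def fingerprint(code: int, p_bits: int, seed: int) -> int:
    """Deterministic p-bit fingerprint of a code; never 0 (0 marks empty)."""
    if p_bits < 2:
        raise ValueError("p_bits must be >= 2")
    seeds = _derive_seeds(seed, 3)
    fp = _mix_py((code & _M64) ^ int(seeds[1])) & ((1 << p_bits) - 1)
    return fp if fp != 0 else 1


class BucketedCuckooTable:
    """Exact (d, l) bucketed Cuckoo hash table over nonzero 64-bit codes."""

    kind = "exact"

    def __init__(
        self,
        n_slots: int,
        d: int = 3,
        ell: int = 4,
        max_kicks: int = DEFAULT_MAX_KICKS,
        seed: int = 0,
        mask: str = "",
    ) -> None:
        n_buckets = -(-n_slots // ell)  # ceil; round slots up to full buckets
        self.params = CuckooParams(d=d, ell=ell, n_slots=n_buckets * ell,
                                   max_kicks=max_kicks, seed=seed)
        self.n_buckets = n_buckets
        self.mask = mask
        self._seeds = _derive_seeds(seed, d)
        self.slots = np.zeros(self.params.n_slots, dtype=np.uint64)
        self.occupied = 0
        self.dirty = False  # a failed insertion may have dropped a resident
        self.last_kicks = 0
        self._state = _rng_state(seed)

    # -- properties ---------------------------------------------------------

    @property
    def n_slots(self) -> int:
        return self.params.n_slots

    @property
    def n_keys(self) -> int:
        return self.occupied

    @property
    def load(self) -> float:
        return self.occupied / self.params.n_slots

    @property
    def slot_bits(self) -> int:
        return 64

    # -- operations ---------------------------------------------------------

    def _check_key(self, code: int) -> np.uint64:
        code = int(code)
        if not 1 <= code <= _M64:
            raise ValueError("codes must be nonzero unsigned 64-bit integers")
        return np.uint64(code)

    def bucket_addresses(self, code: int) -> list[int]:
        """The d admissible bucket indices of a code (for inspection)."""
        key = int(self._check_key(code))
        return [
            _mix_py(key ^ int(s)) % self.n_buckets for s in self._seeds
        ]

    def lookup(self, code: int) -> bool:
        p = self.params
        return bool(_bt_lookup(self.slots, p.ell, p.d, self._seeds,
                               self._check_key(code)))

    def lookup_many(self, codes: np.ndarray) -> np.ndarray:
        codes = np.ascontiguousarray(codes, dtype=np.uint64)
        out = np.zeros(codes.shape[0], dtype=np.bool_)
        p = self.params
        _bt_lookup_many(self.slots, p.ell, p.d, self._seeds, codes, out)
        return out

    def insert(self, code: int) -> bool:
        """Insert one code; duplicate inserts are no-op successes."""
        p = self.params
        status, kicks, self._state = _bt_insert(
            self.slots, p.ell, p.d, self._seeds, p.max_kicks,
            self._check_key(code), self._state,
        )
        self.last_kicks = int(kicks)
        if status == 1:
            self.occupied += 1
            return True
        if status == 2:
            return True
        self.dirty = True
        return False

    def insert_many(self, codes: np.ndarray) -> int:
        """Insert codes in order; returns the number consumed before a
        failure (== len(codes) when all succeeded)."""
        codes = np.ascontiguousarray(codes, dtype=np.uint64)
        if codes.size and (codes == 0).any():
            raise ValueError("codes must be nonzero")
        p = self.params
        n_new, fail, self._state = _bt_insert_many(
            self.slots, p.ell, p.d, self._seeds, p.max_kicks, codes, self._state
        )
        self.occupied += int(n_new)
        if fail >= 0:
            self.dirty = True
            return int(fail)
        return codes.shape[0]


class WindowedCuckooFilter:
    """Probabilistic (2, l) windowed Cuckoo filter over p-bit fingerprints.

    The requested slot count is realised as ``W + l - 1`` slots where ``W``
    (the number of overlapping windows) is the next power of two at or above
    ``n_slots - l + 1``; a power-of-two window count lets the partner window
    be derived from (window, fingerprint) by an XOR involution, so eviction
    never needs the original key.  A per-slot home-offset tag records which
    of the ``l`` windows covering a slot owns the resident fingerprint.
    """

    kind = "filter"
    d = 2

    def __init__(
        self,
        n_slots: int,
        ell: int = 2,
        p_bits: int = 16,
        max_kicks: int = FILTER_MAX_KICKS,
        seed: int = 0,
        mask: str = "",
    ) -> None:
        if not 2 <= p_bits <= 16:
            raise ValueError("p_bits must be in [2, 16]")
        n_windows = 1 << max(0, (max(1, n_slots - ell + 1) - 1).bit_length())
        self.n_windows = n_windows
        self.params = CuckooParams(d=2, ell=ell, n_slots=n_windows + ell - 1,
                                   max_kicks=max_kicks, seed=seed)
        self.p_bits = p_bits
        self.mask = mask
        self._seeds = _derive_seeds(seed, 3)
        self._wmask = np.uint64(n_windows - 1)
        self._pmask = np.uint64((1 << p_bits) - 1)
        self.slots = np.zeros(self.params.n_slots, dtype=np.uint16)
        self.tags = np.zeros(self.params.n_slots, dtype=np.uint8)
        self.occupied = 0
        self.dirty = False
        self.last_kicks = 0
        self._state = _rng_state(seed)

    # -- properties ---------------------------------------------------------

    @property
    def n_slots(self) -> int:
        return self.params.n_slots

    @property
    def n_keys(self) -> int:
        return self.occupied

    @property
    def load(self) -> float:
        return self.occupied / self.params.n_slots

    @property
    def slot_bits(self) -> int:
        return self.p_bits

    @property
    def fpr_bound(self) -> float:
        """Upper bound on the false positive rate: d*l*2**-p."""
        return self.d * self.params.ell * 2.0 ** (-self.p_bits)

    # -- address helpers (inspection/testing) --------------------------------

    def fingerprint_of(self, code: int) -> int:
        fp = _mix_py(int(code) ^ int(self._seeds[1])) & int(self._pmask)
        return fp if fp != 0 else 1

    def partner_window(self, window: int, fp: int) -> int:
        dlt = _mix_py(int(fp) ^ int(self._seeds[2])) & int(self._wmask)
        return window ^ (dlt if dlt != 0 else 1)

    def admissible_windows(self, code: int) -> tuple[int, int]:
        a = _mix_py(int(code) ^ int(self._seeds[0])) & int(self._wmask)
        return a, self.partner_window(a, self.fingerprint_of(code))

    # -- operations ---------------------------------------------------------

    def lookup(self, code: int) -> bool:
        p = self.params
        return bool(_wf_lookup(self.slots, p.ell, self._seeds, self._wmask,
                               self._pmask, np.uint64(int(code))))

    def lookup_many(self, codes: np.ndarray) -> np.ndarray:
        codes = np.ascontiguousarray(codes, dtype=np.uint64)
        out = np.zeros(codes.shape[0], dtype=np.bool_)
        p = self.params
        _wf_lookup_many(self.slots, p.ell, self._seeds, self._wmask,
                        self._pmask, codes, out)
        return out

    def insert(self, code: int) -> bool:
        p = self.params
        status, kicks, self._state = _wf_insert(
            self.slots, self.tags, p.ell, self._seeds, self._wmask,
            self._pmask, p.max_kicks, np.uint64(int(code)), self._state,
        )
        self.last_kicks = int(kicks)
        if status == 1:
            self.occupied += 1
            return True
        if status == 2:
            return True
        self.dirty = True
        return False

    def insert_many(self, codes: np.ndarray) -> int:
        codes = np.ascontiguousarray(codes, dtype=np.uint64)
        p = self.params
        n_new, fail, self._state = _wf_insert_many(
            self.slots, self.tags, p.ell, self._seeds, self._wmask,
            self._pmask, p.max_kicks, codes, self._state,
        )
        self.occupied += int(n_new)
        if fail >= 0:
            self.dirty = True
            return int(fail)
        return codes.shape[0]


# ---------------------------------------------------------------------------
# measurement harnesses
# ---------------------------------------------------------------------------


def fill_to_load(store, target_load: float, rng_seed: int) -> float:
    """Insert distinct uniformly random keys (drawn from [1, 2**57)) until
    the target load is reached or an insertion fails; returns the achieved
    load ``occupied / n_slots``.
    """
    if not 0 < target_load <= 1:
        raise ValueError("target_load must be in (0, 1]")
    target_occ = int(np.ceil(target_load * store.n_slots))
    state = _rng_state(rng_seed)
    p = store.params
    if isinstance(store, BucketedCuckooTable):
        occ, ok, state = _bt_fill(
            store.slots, p.ell, p.d, store._seeds, p.max_kicks,
            np.int64(target_occ), np.int64(store.occupied), state,
        )
    elif isinstance(store, WindowedCuckooFilter):
        occ, ok, state = _wf_fill(
            store.slots, store.tags, p.ell, store._seeds, store._wmask,
            store._pmask, p.max_kicks, np.int64(target_occ),
            np.int64(store.occupied), state,
        )
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported store type {type(store)!r}")
    store.occupied = int(occ)
    if not ok:
        store.dirty = True
    return store.load


def measure_fpr(filt: WindowedCuckooFilter, n_queries: int, rng_seed: int) -> float:
    """Observed false positive rate over ``n_queries`` absent keys.

    Queries are drawn from [2**57, 2**58), disjoint from the [1, 2**57)
    range used by :func:`fill_to_load`, so every query key is truly absent.
    """
    if n_queries <= 0:
        raise ValueError("n_queries must be positive")
    p = filt.params
    hits, _ = _wf_count_fp(
        filt.slots, p.ell, filt._seeds, filt._wmask, filt._pmask,
        np.int64(n_queries), _rng_state(rng_seed),
    )
    return int(hits) / n_queries


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_MAGIC = b"RSIX"
_VERSION = 1
_KIND_EXACT = 1
_KIND_FILTER = 2
# magic, version, kind, d, ell, p_bits, n_slots, n_windows, occupied, seed,
# max_kicks, mask length
_HEADER = struct.Struct("<4sBBBBBQQQQIH")


def serialize(store) -> bytes:
    """Serialize a store to little-endian bytes (versioned, with header)."""
    p = store.params
    if isinstance(store, BucketedCuckooTable):
        kind, p_bits, n_windows = _KIND_EXACT, 0, 0
        payload = store.slots.tobytes()
    elif isinstance(store, WindowedCuckooFilter):
        kind, p_bits, n_windows = _KIND_FILTER, store.p_bits, store.n_windows
        payload = store.slots.tobytes() + store.tags.tobytes()
    else:
        raise TypeError(f"unsupported store type {type(store)!r}")
    mask = store.mask.encode("ascii")
    header = _HEADER.pack(
        _MAGIC, _VERSION, kind, p.d, p.ell, p_bits,
        p.n_slots, n_windows, store.occupied, p.seed, p.max_kicks, len(mask),
    )
    return header + mask + payload


def deserialize(data: bytes):
    """Reconstruct a store from :func:`serialize` output."""
    if len(data) < _HEADER.size:
        raise SerializationError("truncated header")
    (magic, version, kind, d, ell, p_bits, n_slots, n_windows,
     occupied, seed, max_kicks, mask_len) = _HEADER.unpack_from(data)
    if magic != _MAGIC:
        raise SerializationError(f"bad magic {magic!r}")
    if version != _VERSION:
        raise SerializationError(f"unsupported version {version}")
    off = _HEADER.size
    mask = data[off:off + mask_len].decode("ascii")
    off += mask_len
    if kind == _KIND_EXACT:
        store = BucketedCuckooTable(n_slots, d=d, ell=ell,
                                    max_kicks=max_kicks, seed=seed, mask=mask)
        end = off + 8 * n_slots
        if len(data) < end:
            raise SerializationError("truncated slot array")
        store.slots = np.frombuffer(data[off:end], dtype="<u8").copy()
    elif kind == _KIND_FILTER:
        store = WindowedCuckooFilter(n_slots, ell=ell, p_bits=p_bits,
                                     max_kicks=max_kicks, seed=seed, mask=mask)
        if store.n_slots != n_slots or store.n_windows != n_windows:
            raise SerializationError("inconsistent filter geometry")
        end = off + 2 * n_slots
        end2 = end + n_slots
        if len(data) < end2:
            raise SerializationError("truncated slot array")
        store.slots = np.frombuffer(data[off:end], dtype="<u2").copy()
        store.tags = np.frombuffer(data[end:end2], dtype="u1").copy()
    else:
        raise SerializationError(f"unknown store kind {kind}")
    store.occupied = int(occupied)
    return store
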