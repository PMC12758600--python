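"""Coverage computation in both modes, threshold semantics, paired-end
decision rule, and stream filtering."""

import io

import numpy as np
import pytest

from readsieve.classifier import (
    ClassifyParams,
    PairedLengthError,
    classify_pair,
    classify_read,
    cover_sampling,
    cover_sensitive,
    filter_stream,
)
from readsieve.cuckoo import BucketedCuckooTable
from readsieve.fixtures import sample_reads, synth_genome
from readsieve.seedcodes import gapped_code_array, parse_mask

from conftest import revcomp_str


class FakeStore:
    """Membership stub: hits exactly the configured window offsets."""

    def __init__(self, n_windows, hit_offsets):
        self.hits = np.zeros(n_windows, dtype=bool)
        self.hits[list(hit_offsets)] = True
        self._cursor = None

    def lookup_many(self, codes):
        # caller passes codes of valid windows in offset order; the stub is
        # only used with all-ACGT reads, so valid offsets are 0..n-1
        return self.hits[: len(codes)].copy()


@pytest.fixture(scope="module")
def indexed_genome(default_mask):
    genome = synth_genome(50_000, seed=33)
    codes, valid = gapped_code_array(genome, default_mask)
    store = BucketedCuckooTable(int(valid.sum() / 0.85), seed=3)
    assert store.insert_many(codes[valid]) == int(valid.sum())
    return genome, store


class TestSensitive:
    def test_exact_substring_fully_covered(self, indexed_genome, default_mask):
        genome, store = indexed_genome
        read = genome[10_000:10_150]
        res = cover_sensitive(read, store, default_mask)
        assert res.covered_bases == 150
        assert res.windows_queried == 150 - default_mask.width_w + 1
        assert res.windows_hit == res.windows_queried
        assert res.is_host

    def test_reverse_strand_read_fully_covered(self, indexed_genome, default_mask):
        genome, store = indexed_genome
        read = revcomp_str(genome[20_000:20_150])
        assert cover_sensitive(read, store, default_mask).covered_bases == 150

    def test_read_shorter_than_window(self, indexed_genome, default_mask):
        _, store = indexed_genome
        res = cover_sensitive("ACGT" * 8, store, default_mask)  # length 32 < 33
        assert (res.windows_queried, res.covered_bases) == (0, 0)
        assert not res.is_host

    def test_foreign_read_zero_coverage_on_exact_store(self, indexed_genome,
                                                       default_mask):
        _, store = indexed_genome
        foreign = synth_genome(150, seed=77)
        res = cover_sensitive(foreign, store, default_mask)
        assert res.covered_bases == 0
        assert not res.is_host

    def test_windows_with_N_count_as_queried_misses(self, indexed_genome,
                                                    default_mask):
        genome, store = indexed_genome
        read = genome[10_000:10_075] + "N" + genome[10_076:10_150]
        res = cover_sensitive(read, store, default_mask)
        assert res.windows_queried == 118
        assert res.windows_hit < res.windows_queried
        assert res.covered_bases < 150


class TestSampling:
    def test_query_count_and_step(self, indexed_genome, default_mask):
        genome, store = indexed_genome
        read = genome[15_000:15_150]
        res = cover_sampling(read, store, default_mask)
        # w=33 -> step 17, offsets 0,17,...,102
        assert res.windows_queried == 7

    def test_full_match_covers_queried_span(self, indexed_genome, default_mask):
        genome, store = indexed_genome
        read = genome[15_000:15_150]
        res = cover_sampling(read, store, default_mask)
        assert res.windows_hit == 7
        assert res.covered_bases == 135  # union of 7 width-33 windows, step 17
        assert res.is_host

    def test_every_base_in_span_has_one_or_two_chances(self, default_mask):
        """With step floor(w/2)+1, every base of the sampled span overlaps
        at least one and at most two queried windows."""
        w = default_mask.width_w
        L = 150
        step = w // 2 + 1
        offsets = list(range(0, L - w + 1, step))
        span = offsets[-1] + w
        counts = [sum(1 for i in offsets if i <= p < i + w) for p in range(span)]
        assert min(counts) == 1
        assert max(counts) == 2


class TestThresholds:
    def _fake(self, L, w, hit_offsets, mode="sensitive"):
        mask = parse_mask("#" * w)  # contiguous mask: hits mark w positions
        n = L - w + 1
        return FakeStore(n, hit_offsets), mask

    def test_boundary_is_inclusive(self):
        # 75 of 150 covered at T=0.5 -> host ("at least" semantics)
        store, mask = self._fake(150, 25, range(0, 51))  # covers [0,75)
        res = cover_sensitive("A" * 150, store, mask, threshold=0.5)
        assert res.covered_bases == 75
        assert res.is_host

    def test_one_below_boundary_is_not_host(self):
        store, mask = self._fake(150, 25, range(0, 50))  # covers [0,74)
        res = cover_sensitive("A" * 150, store, mask, threshold=0.5)
        assert res.covered_bases == 74
        assert not res.is_host

    def test_threshold_zero_marks_everything_host(self, indexed_genome,
                                                  default_mask):
        _, store = indexed_genome
        foreign = synth_genome(150, seed=78)
        params = ClassifyParams(threshold=0.0)
        assert classify_read(foreign, store, default_mask, params).is_host

    def test_threshold_one_requires_full_coverage(self, indexed_genome,
                                                  default_mask):
        genome, store = indexed_genome
        read = genome[12_000:12_150]
        mutated = read[:80] + ("A" if read[80] != "A" else "C") + read[81:]
        params = ClassifyParams(threshold=1.0)
        assert classify_read(read, store, default_mask, params).is_host
        assert not classify_read(mutated, store, default_mask, params).is_host

    def test_raising_threshold_never_creates_host_calls(self, indexed_genome,
                                                        default_mask, rng):
        genome, store = indexed_genome
        reads = sample_reads(genome, 30, 150, 0.03, seed=41).reads
        for _, seq, _ in reads:
            calls = [
                classify_read(seq, store, default_mask, ClassifyParams(t)).is_host
                for t in (0.0, 0.25, 0.5, 0.75, 1.0)
            ]
            assert calls == sorted(calls, reverse=True)  # monotone non-increasing


class TestPairs:
    def test_pair_removed_if_either_end_is_host(self, indexed_genome, default_mask):
        genome, store = indexed_genome
        host_read = genome[30_000:30_150]
        foreign = synth_genome(150, seed=79)
        params = ClassifyParams()
        remove, r1, r2 = classify_pair(host_read, foreign, store, default_mask, params)
        assert remove and r1.is_host and not r2.is_host
        remove_swapped, _, _ = classify_pair(foreign, host_read, store,
                                             default_mask, params)
        assert remove_swapped == remove

    def test_double_non_host_pair_retained(self, indexed_genome, default_mask):
        _, store = indexed_genome
        f1, f2 = synth_genome(150, seed=80), synth_genome(150, seed=81)
        remove, _, _ = classify_pair(f1, f2, store, default_mask, ClassifyParams())
        assert not remove


class TestFilterStream:
    def _records(self, seqs, prefix="r"):
        return [(f"{prefix}{i}", s, "I" * len(s)) for i, s in enumerate(seqs)]

    def test_partition_conserves_and_orders_records(self, indexed_genome,
                                                    default_mask):
        genome, store = indexed_genome
        host = [genome[i:i + 150] for i in range(0, 3000, 300)]
        foreign_genome = synth_genome(5_000, seed=90)
        foreign = [foreign_genome[i:i + 150] for i in range(0, 3000, 300)]
        records = self._records([x for pair in zip(host, foreign) for x in pair])
        keep, drop = io.StringIO(), io.StringIO()
        summary = filter_stream(store, default_mask, ClassifyParams(),
                                records, keep, removed_out=drop)
        assert summary.total == 20
        assert summary.removed + summary.retained == summary.total
        assert summary.removed == 10
        kept_names = [l[1:] for l in keep.getvalue().splitlines()[::4]]
        dropped_names = [l[1:] for l in drop.getvalue().splitlines()[::4]]
        # retained/removed partition the input, each preserving input order
        assert kept_names == [r[0] for r in records if r[0] in set(kept_names)]
        assert dropped_names == [r[0] for r in records if r[0] in set(dropped_names)]
        assert sorted(kept_names + dropped_names) == sorted(r[0] for r in records)

    def test_empty_input(self, indexed_genome, default_mask):
        _, store = indexed_genome
        out = io.StringIO()
        summary = filter_stream(store, default_mask, ClassifyParams(), [], out)
        assert summary.as_dict() == {"total": 0, "removed": 0, "retained": 0,
                                     "short_reads": 0}
        assert out.getvalue() == ""

    def test_paired_filtering_counts_pairs(self, indexed_genome, default_mask):
        genome, store = indexed_genome
        foreign_genome = synth_genome(5_000, seed=91)
        r1 = self._records([genome[0:150], foreign_genome[0:150]], prefix="a")
        r2 = self._records([foreign_genome[300:450], foreign_genome[600:750]],
                           prefix="b")
        o1, o2 = io.StringIO(), io.StringIO()
        summary = filter_stream(store, default_mask, ClassifyParams(), r1, o1,
                                reads2=r2, out2=o2)
        assert summary.total == 2
        assert summary.removed == 1  # first pair: host mate drags both out
        assert o1.getvalue().splitlines()[0] == "@a1"
        assert o2.getvalue().splitlines()[0] == "@b1"

    def test_unequal_paired_inputs_raise(self, indexed_genome, default_mask):
        _, store = indexed_genome
        r1 = self._records(["ACGT" * 40] * 2)
        r2 = self._records(["ACGT" * 40] * 3)
        with pytest.raises(PairedLengthError):
            filter_stream(store, default_mask, ClassifyParams(), r1,
                          io.StringIO(), reads2=r2, out2=io.StringIO())

    def test_short_reads_always_retained(self, indexed_genome, default_mask):
        _, store = indexed_genome
        records = self._records(["ACGTACGT"])  # shorter than the mask
        out = io.StringIO()
        summary = filter_stream(store, default_mask, ClassifyParams(), records, out)
        assert summary.retained == 1
        assert summary.short_reads == 1
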