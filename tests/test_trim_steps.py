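import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import oracle_maxinfo, oracle_sliding_window
from readtrim.core_model import Read
from readtrim.simdata import SimConfig, generate_read_pairs
from readtrim.trim_steps import (
    MaxInfoParams,
    avgqual,
    crop,
    headcrop,
    leading,
    maxinfo,
    min_length,
    sliding_window,
    tailcrop,
    trailing,
)


def mk(quals, bases=None) -> Read:
    quals = bytes(quals)
    if bases is None:
        bases = "A" * len(quals)
    return Read("r", bases, quals)


reads_strategy = st.lists(st.integers(0, 41), max_size=60).map(mk)


@given(
    reads_strategy,
    st.sampled_from(
        [
            lambda r: headcrop(r, 5),
            lambda r: tailcrop(r, 5),
            lambda r: crop(r, 10),
            lambda r: leading(r, 20),
            lambda r: trailing(r, 20),
            lambda r: sliding_window(r, 4, 20),
            lambda r: maxinfo(r, MaxInfoParams(30, 0.5)),
            lambda r: avgqual(r, 20),
            lambda r: min_length(r, 10),
        ]
    ),
)
def test_survivor_is_contiguous_subwindow(read, op):
    """Every operator returns a contiguous substring, trimmed in lockstep,
    with the cut bookkeeping summing to the original length."""
    out = op(read)
    if out.dropped:
        return
    n = len(read)
    start, end = out.cut_from_start, n - out.cut_from_end
    assert 0 <= start <= end <= n
    assert out.read.bases == read.bases[start:end]
    assert out.read.quals == read.quals[start:end]
    assert len(out.read) <= n


class TestFixedCrops:
    def test_headcrop_removes_leading_bases(self):
        r = mk(range(10))
        out = headcrop(r, 4)
        assert out.read.quals == r.quals[4:10]
        assert (out.cut_from_start, out.cut_from_end) == (4, 0)

    def test_headcrop_consuming_whole_read_drops(self):
        assert headcrop(mk([30] * 4), 4).dropped

    def test_tailcrop_removes_trailing_bases(self):
        out = tailcrop(mk(range(10)), 3)
        assert out.read.quals == bytes(range(7))

    def test_tailcrop_consuming_whole_read_drops(self):
        assert tailcrop(mk([30] * 3), 3).dropped

    def test_zero_crops_are_identity(self):
        r = mk([10, 20, 30])
        assert headcrop(r, 0).read.quals == r.quals
        assert tailcrop(r, 0).read.quals == r.quals

    @pytest.mark.parametrize("length,n,kept", [(100, 36, 36), (20, 36, 20), (5, 5, 5)])
    def test_crop_keeps_at_most_n_never_drops(self, length, n, kept):
        out = crop(mk([30] * length), n)
        assert not out.dropped and len(out.read) == kept

    @given(st.lists(st.integers(0, 41), min_size=11, max_size=40))
    def test_headcrop_tailcrop_commute(self, quals):
        r = mk(quals)
        a = tailcrop(headcrop(r, 3).read, 4)
        b = headcrop(tailcrop(r, 4).read, 3)
        assert a.read.quals == b.read.quals


class TestQualityEndTrims:
    def test_leading_strips_low_quality_start(self):
        out = leading(mk([2, 2, 30, 30]), 3)
        assert out.read.quals == bytes([30, 30]) and out.cut_from_start == 2

    def test_leading_all_below_drops(self):
        assert leading(mk([2, 2]), 3).dropped

    def test_trailing_strips_low_quality_end(self):
        out = trailing(mk([30, 30, 2, 2]), 3)
        assert out.read.quals == bytes([30, 30]) and out.cut_from_end == 2

    def test_trailing_all_below_drops(self):
        assert trailing(mk([1, 2]), 3).dropped

    def test_at_threshold_survives(self):
        r = mk([3, 3])
        assert leading(r, 3).read.quals == r.quals
        assert trailing(r, 3).read.quals == r.quals


class TestSlidingWindow:
    def test_truncates_at_first_failing_window(self):
        out = sliding_window(mk([30, 30, 30, 30, 10, 10, 10, 10]), 4, 20)
        assert out.read.quals == bytes([30, 30, 30])

    def test_mean_exactly_at_threshold_passes(self):
        r = mk([20] * 12)
        assert sliding_window(r, 4, 20).read.quals == r.quals

    def test_uniformly_bad_read_drops(self):
        assert sliding_window(mk([2] * 10), 4, 20).dropped

    def test_short_read_is_one_window(self):
        assert sliding_window(mk([10, 10]), 4, 20).dropped
        assert not sliding_window(mk([30, 30]), 4, 20).dropped

    def test_post_truncation_tail_cleanup(self):
        # first failing window starts at offset 3; quals[2] below q must go too
        out = sliding_window(mk([30, 30, 15, 35, 35, 2, 2, 2]), 4, 20)
        assert out.read.quals == bytes([30, 30])

    @given(st.lists(st.integers(0, 41), max_size=80),
           st.integers(1, 8), st.integers(0, 41))
    def test_matches_exhaustive_window_oracle(self, quals, w, q):
        out = sliding_window(mk(quals), w, q)
        kept = 0 if out.dropped else len(out.read)
        assert kept == oracle_sliding_window(quals, w, q)


class TestMaxInfo:
    def test_uniform_high_quality_keeps_full_read(self):
        r = mk([40] * 100)
        out = maxinfo(r, MaxInfoParams(40, 0.5))
        assert out.read.quals == r.quals

    def test_empty_read_drops(self):
        assert maxinfo(mk([]), MaxInfoParams(40, 0.5)).dropped

    def test_cuts_at_quality_cliff(self):
        out = maxinfo(mk([40] * 50 + [2] * 50), MaxInfoParams(40, 0.9))
        assert len(out.read) == 50

    def test_low_strictness_keeps_equal_quality_reads_whole(self):
        for n in (1, 5, 40, 120):
            r = mk([25] * n)
            assert len(maxinfo(r, MaxInfoParams(40, 0.001)).read) == n

    @given(st.lists(st.integers(0, 41), max_size=80),
           st.integers(1, 60),
           st.floats(0.01, 0.99))
    def test_matches_exhaustive_prefix_oracle(self, quals, target, strictness):
        out = maxinfo(mk(quals), MaxInfoParams(target, strictness))
        kept = 0 if out.dropped else len(out.read)
        assert kept == oracle_maxinfo(quals, target, strictness)


class TestWholeReadFilters:
    @pytest.mark.parametrize(
        "quals,q,kept",
        [([20, 20, 20, 20], 20, True), ([19, 19, 19, 19], 20, False),
         ([], 1, False)],
    )
    def test_avgqual_boundary(self, quals, q, kept):
        assert avgqual(mk(quals), q).dropped is not kept

    @pytest.mark.parametrize(
        "length,n,kept", [(36, 36, True), (35, 36, False), (0, 1, False)]
    )
    def test_min_length_boundary(self, length, n, kept):
        assert min_length(mk([30] * length), n).dropped is not kept

    @given(reads_strategy, st.integers(0, 50))
    def test_filters_are_idempotent(self, read, q):
        out = min_length(read, q)
        if not out.dropped:
            assert min_length(out.read, q).read.quals == out.read.quals
        out = avgqual(read, q)
        if not out.dropped:
            assert avgqual(out.read, q).read.quals == out.read.quals


def test_adaptive_trimmers_match_oracles_on_generator_reads():
    """Spot-check both adaptive trimmers against brute force on realistic
    simulated reads (the full 10k-read sweep runs in the acceptance suite)."""
    pairs, _ = generate_read_pairs(SimConfig(n_pairs=150, seed=9))
    reads = [p.fwd for p in pairs] + [p.rev for p in pairs]
    for read in reads:
        quals = list(read.quals)
        sw = sliding_window(read, 4, 20)
        assert (0 if sw.dropped else len(sw.read)) == \
            oracle_sliding_window(quals, 4, 20)
        mi = maxinfo(read, MaxInfoParams(40, 0.5))
        assert (0 if mi.dropped else len(mi.read)) == \
            oracle_maxinfo(quals, 40, 0.5)
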