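import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_coverage
from hetchrom.features import (
    FeatureInterval,
    GenomicWindow,
    classify_tandem_repeat,
    filter_segmental_duplication,
    make_windows,
    read_repeatmasker_out,
    read_trf_dat,
    read_unified_features,
    summarize_by_class,
    tabulate,
)
from hetchrom.regions import ChromatinRegion


class TestTandemRepeatClassification:
    @pytest.mark.parametrize(
        "period,copies,match,expected",
        [
            (4, 10, 85, "microsatellite"),
            (4, 5, 95, "rejected"),       # microsatellites need >= 8 copies
            (4, 8, 80, "microsatellite"),  # boundary values accepted
            (2, 8, 80, "microsatellite"),
            (6, 7.9, 99, "rejected"),
            (7, 2, 80, "minisatellite"),
            (7, 1.9, 99, "rejected"),
            (99, 2, 80, "minisatellite"),
            (100, 2, 80, "satellite"),
            (150, 2, 80, "satellite"),
            (50, 2, 79.9, "rejected"),     # below the match threshold
            (1, 100, 100, "rejected"),     # homopolymer runs excluded
        ],
    )
    def test_threshold_truth_table(self, period, copies, match, expected):
        assert classify_tandem_repeat(period, copies, match) == expected

    @given(
        period=st.integers(2, 1000),
        copies=st.floats(0.1, 1000),
        match=st.floats(0, 100),
    )
    @settings(max_examples=200, derandomize=True)
    def test_accepted_records_get_exactly_one_period_bin(self, period, copies, match):
        result = classify_tandem_repeat(period, copies, match)
        if result != "rejected":
            expected_bin = (
                "microsatellite" if period <= 6
                else "minisatellite" if period <= 99
                else "satellite"
            )
            assert result == expected_bin


class TestSegmentalDuplicationFilter:
    @pytest.mark.parametrize(
        "length,identity,expected",
        [
            (2500, 90.1, True),
            (2499, 99.0, False),
            (2500, 90.0, False),  # identity bound is strict
            (1_000_000, 95.0, True),
            (0, 99.0, False),
        ],
    )
    def test_thresholds(self, length, identity, expected):
        assert filter_segmental_duplication(length, identity) is expected


class TestMakeWindows:
    def test_x_pericentric_region_splits_into_five(self):
        region = ChromatinRegion("X", "PH", 20_009_764, 24_393_108)
        ws = make_windows([region], het_window=1_000_000)
        assert len(ws) == 5
        assert sum(w.length for w in ws) == 4_383_344
        assert max(w.length for w in ws) <= 876_669

    def test_exact_multiple_gives_single_window(self):
        region = ChromatinRegion("2R", "EU", 1, 5_000_001)
        ws = make_windows([region], eu_window=5_000_000)
        assert len(ws) == 1 and ws[0].length == 5_000_000

    def test_tiling_on_full_fixture(self, agamp3_regions):
        ws = make_windows(agamp3_regions)
        for w in ws:
            limit = 5_000_000 if w.chromatin_class in ("EU", "PEU") else 1_000_000
            assert w.length <= limit
        # windows tile each region exactly: contiguous cover, no class mixing
        for r in agamp3_regions:
            inside = [
                w for w in ws
                if w.arm == r.arm and r.start <= w.start and w.end <= r.end
            ]
            assert sum(w.length for w in inside) == r.size
            assert {w.chromatin_class for w in inside} == {r.chromatin_class}
        assert sum(w.length for w in ws) == sum(r.size for r in agamp3_regions)

    @given(size=st.integers(1, 2_000_000), window=st.integers(1_000, 5_000_000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_tiling_property(self, size, window):
        region = ChromatinRegion("X", "PH", 1, 1 + size)
        ws = make_windows([region], het_window=window)
        assert sum(w.length for w in ws) == size
        assert len(ws) == math.ceil(size / window)
        assert all(w.length <= window for w in ws)
        starts = [w.start for w in ws]
        assert starts[0] == 1 and all(
            a.end == b.start for a, b in zip(ws, ws[1:])
        )

    def test_nonpositive_window_rejected(self, agamp3_regions):
        with pytest.raises(ValueError):
            make_windows(agamp3_regions, eu_window=0)


def _win(start, end, cls="EU", arm="X"):
    return GenomicWindow(arm=arm, start=start, end=end, chromatin_class=cls)


def _iv(start, end, cls="gene", arm="X"):
    return FeatureInterval(arm=arm, start=start, end=end, feature_class=cls)


class TestTabulate:
    def test_worked_example_against_bp_oracle(self):
        # window [0,100) with intervals [10,20), [15,30), [90,120):
        # counts by start = 3, union coverage = [10,30) + [90,100) = 30 bp
        w = _win(0 + 1, 100 + 1)  # shift to 1-based internal coordinates
        spans = [(11, 21), (16, 31), (91, 121)]
        ivs = [_iv(s, e) for s, e in spans]
        recs = [r for r in tabulate([w], ivs, ["gene"])]
        assert recs[0].count == 3
        assert recs[0].coverage == 30
        assert recs[0].coverage == brute_force_coverage(w.start, w.end, spans)

    def test_no_intervals(self):
        recs = tabulate([_win(1, 100)], [], ["gene"])
        assert recs[0].count == 0 and recs[0].coverage == 0

    def test_full_window_coverage(self):
        w = _win(1, 101)
        recs = tabulate([w], [_iv(1, 101)], ["gene"])
        assert recs[0].coverage == w.length

    def test_interval_counted_once_across_windows(self):
        ws = [_win(1, 101), _win(101, 201)]
        ivs = [_iv(51, 151)]  # spans the boundary
        recs = tabulate(ws, ivs, ["gene"])
        assert [r.count for r in recs] == [1, 0]
        assert [r.coverage for r in recs] == [50, 50]

    def test_unknown_arm_skipped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            recs = tabulate([_win(1, 101)], [_iv(1, 50, arm="2R")], ["gene"])
        assert recs[0].count == 0
        assert any("skipped" in m for m in caplog.messages)

    def test_merging_idempotent(self):
        w = _win(1, 1001)
        ivs = [_iv(1, 500), _iv(100, 700), _iv(650, 900)]
        merged = [_iv(1, 900)]
        k1 = tabulate([w], ivs, ["gene"])[0].coverage
        k2 = tabulate([w], merged, ["gene"])[0].coverage
        assert k1 == k2 == 899

    @given(st.data())
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_equivalence_with_bp_oracle_on_small_windows(self, data):
        wlen = data.draw(st.integers(10, 2000))
        w = _win(1, 1 + wlen)
        n = data.draw(st.integers(0, 20))
        spans = []
        for _ in range(n):
            s = data.draw(st.integers(-50, wlen + 50))
            ln = data.draw(st.integers(1, 300))
            spans.append((s, s + ln))
        spans = [(max(s, 1), e) for s, e in spans if e > max(s, 1)]
        ivs = [_iv(s, e) for s, e in spans]
        rec = tabulate([w], ivs, ["gene"])[0]
        assert rec.coverage == brute_force_coverage(w.start, w.end, spans)
        assert 0 <= rec.coverage <= w.length


class TestSummaries:
    def test_identical_fractions_give_that_median(self):
        ws = [_win(1 + i * 100, 101 + i * 100) for i in range(4)]
        ivs = [_iv(w.start, w.start + 25) for w in ws]
        recs = tabulate(ws, ivs, ["gene"])
        out = summarize_by_class(recs)
        row = out[(out["class"] == "EU") & (out["feature"] == "gene")]
        assert row["median_coverage_pct"].iloc[0] == pytest.approx(25.0)

    def test_median_of_three(self):
        ws = [_win(1, 1001), _win(1001, 2001), _win(2001, 3001)]
        covs = [100, 200, 900]
        ivs = [_iv(w.start, w.start + c) for w, c in zip(ws, covs)]
        out = summarize_by_class(tabulate(ws, ivs, ["gene"]))
        assert out["median_coverage_pct"].iloc[0] == pytest.approx(20.0)


class TestParsers:
    def test_repeatmasker_out(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(
            "   SW  perc perc perc  query     position in query\n"
            "score  div. del. ins.  sequence  begin  end\n"
            "\n"
            "  463  1.3  0.6  1.7  2R  100  199  (0) + ELEMENT1  DNA/hAT  1 100 (0)  1\n"
            "  300  2.0  0.0  0.0  2R  500  999  (0) + ELEMENT2  LINE/L2  1 500 (0)  2\n"
            "  250  2.0  0.0  0.0  2R  1200 1299 (0) + ELEMENT3  Simple_repeat  1 100 (0) 3\n"
        )
        ivs = read_repeatmasker_out(p)
        assert [(iv.feature_class, iv.start, iv.end) for iv in ivs] == [
            ("dna_te", 100, 200),
            ("rna_te", 500, 1000),
        ]

    def test_trf_dat_applies_thresholds(self, tmp_path):
        p = tmp_path / "trf.dat"
        p.write_text(
            "Sequence: 3L\n"
            "\n"
            "100 199 4 25.0 4 90 0 200 25 25 25 25 1.9 ACGT ACGT\n"   # micro, ok
            "300 399 4 5.0 4 95 0 100 25 25 25 25 1.9 ACGT ACGT\n"    # too few copies
            "500 999 120 4.0 120 85 0 400 25 25 25 25 1.9 AC GT\n"    # satellite
        )
        ivs = read_trf_dat(p)
        assert [(iv.feature_class, iv.arm) for iv in ivs] == [
            ("microsatellite", "3L"),
            ("satellite", "3L"),
        ]

    def test_unified_tsv_filters(self, tmp_path):
        p = tmp_path / "features.tsv"
        p.write_text(
            "arm\tstart\tend\tfeature_class\tperiod\tcopies\tmatch\tidentity\tlength\n"
            "X\t1\t100\tgene\t.\t.\t.\t.\t.\n"
            "X\t200\t300\ttandem\t4\t10\t85\t.\t.\n"
            "X\t400\t500\ttandem\t4\t5\t85\t.\t.\n"
            "X\t600\t5000\tsd\t.\t.\t.\t95\t4400\n"
            "X\t700\t5000\tsd\t.\t.\t.\t90\t4300\n"
        )
        ivs = read_unified_features(p)
        assert [iv.feature_class for iv in ivs] == ["gene", "microsatellite", "sd"]
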