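"""Metagene profiles, segment rank-sum comparisons, RBP binning."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cosplice.annotation import ACCEPTOR, CassetteExonEvent, ExonRecord, splice_sites_of
from cosplice.features import extract_track_window
from cosplice.profiles import (
    DEFAULT_SEGMENTS,
    aggregate_profile,
    bin_rbp_peaks,
    compare_segments,
    correlate_expression_enrichment,
    ranksum_test,
    rbp_fold_profile,
    stars_for_p,
)
from cosplice.tracks import ArrayTrack, ConstantTrack

from _oracles import ranksum_oracle


def _event(exon_id, start, end, strand="+", label=None):
    rec = ExonRecord(exon_id, exon_id, exon_id, "chr1", start, end, strand, rank=2)
    acc, don = splice_sites_of(rec)
    return CassetteExonEvent(rec, acc, don, label)


def _psi_frame(mapping):
    return pd.DataFrame(
        {"exon_id": list(mapping), "psi": 50.0, "psi_class": list(mapping.values())}
    )


class TestAggregateProfile:
    def test_constant_track_gives_constant_profile(self):
        events = [_event(f"e{i}", 5000 + 800 * i, 5200 + 800 * i) for i in range(6)]
        classes = _psi_frame({e.event_id: c for e, c in zip(events, ["high", "low", "mid"] * 2)})
        profiles = aggregate_profile(events, ConstantTrack("c", 1.0), classes, flank=100)
        assert len(profiles) == 6  # 3 classes x 2 sites
        for p in profiles:
            assert np.allclose(p.mean_signal, 1.0)

    def test_single_event_profile_equals_its_window(self, rng):
        arr = rng.random(20_000).astype(np.float32)
        track = ArrayTrack("x", {"chr1": arr})
        ev = _event("e0", 9000, 9300)
        profiles = aggregate_profile([ev], track, _psi_frame({"e0": "high"}), flank=200)
        acc = next(p for p in profiles if p.site_kind == "acceptor_3p")
        assert np.allclose(acc.mean_signal, extract_track_window(track, ev.acceptor, 200))

    def test_profile_is_mean_of_event_windows(self, rng):
        arr = rng.random(40_000).astype(np.float32)
        track = ArrayTrack("x", {"chr1": arr})
        events = [
            _event(f"e{i}", 5000 + 1500 * i, 5400 + 1500 * i, strand="+" if i % 2 else "-")
            for i in range(8)
        ]
        classes = _psi_frame({e.event_id: "high" for e in events})
        profiles = aggregate_profile(events, track, classes, flank=150)
        don = next(p for p in profiles if p.site_kind == "donor_5p")
        oracle = np.mean([extract_track_window(track, e.donor, 150) for e in events], axis=0)
        assert np.allclose(don.mean_signal, oracle, atol=1e-6)
        assert don.n_events == 8

    def test_generator_bumps_recovered_at_argmax(self, profile_data):
        """High-PSI profiles peak at the generator's offsets (+100 bp into
        the exon at the acceptor, +50 bp at the donor); low-PSI profiles
        are flat around the splice site."""
        track = next(t for t in profile_data.tracks if t.name == "mark_act")
        classes = {r.exon_id: r.cls for r in profile_data.truth.itertuples(index=False)}
        psi = pd.DataFrame(
            {"exon_id": list(classes), "psi_class": ["high" if c == "included" else "low" if c == "skipped" else "mid" for c in classes.values()]}
        )
        profiles = aggregate_profile(profile_data.events, track, psi, flank=500)
        by = {(p.site_kind, p.psi_class): p for p in profiles}
        acc_high = by[("acceptor_3p", "high")]
        don_high = by[("donor_5p", "high")]
        assert abs(int(acc_high.positions[acc_high.mean_signal.argmax()]) - 100) <= 5
        assert abs(int(don_high.positions[don_high.mean_signal.argmax()]) - 50) <= 5
        low = by[("acceptor_3p", "low")]
        zone = np.abs(low.positions) < 150
        assert low.mean_signal[zone].max() < 0.5 * acc_high.mean_signal.max()


class TestRankSum:
    def test_separated_groups_exact_two_sided_p(self):
        u, p = ranksum_test([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_are_not_significant(self):
        _, p = ranksum_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.5

    def test_matches_exhaustive_permutation_oracle_with_ties(self, rng):
        for _ in range(12):
            n1, n2 = rng.integers(2, 5, size=2)
            x = rng.integers(0, 4, n1).astype(float)  # ties likely
            y = rng.integers(0, 4, n2).astype(float)
            u, p = ranksum_test(x, y)
            uo, po = ranksum_oracle(x, y)
            assert u == pytest.approx(uo)
            assert p == pytest.approx(po, abs=1e-12)

    def test_large_samples_use_normal_approximation(self, rng):
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.5, 1, 60)
        u, p = ranksum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    @pytest.mark.parametrize(
        "p,stars",
        [(0.2, "ns"), (0.05, "*"), (0.01, "**"), (0.001, "***"), (0.0001, "****"), (0.00005, "****")],
    )
    def test_star_bins(self, p, stars):
        assert stars_for_p(p) == stars


class TestCompareSegments:
    def _events_with_segment_shift(self, rng, n_per_class=8):
        """Class-dependent signal confined to the proximal intron (segment
        C, [-50, 0) upstream of the acceptor)."""
        arr = rng.normal(1.0, 0.05, 60_000).astype(np.float32)
        events, classes = [], {}
        pos = 2000
        for i in range(2 * n_per_class):
            cls = "high" if i < n_per_class else "low"
            ev = _event(f"e{i}", pos, pos + 200)
            if cls == "high":
                arr[pos - 50 : pos] += 2.0  # segment C only
            events.append(ev)
            classes[ev.event_id] = cls
            pos += 1200
        # a mid class so all pairs exist
        for i in range(2 * n_per_class, 2 * n_per_class + 3):
            ev = _event(f"e{i}", pos, pos + 200)
            events.append(ev)
            classes[ev.event_id] = "mid"
            pos += 1200
        return events, _psi_frame(classes), ArrayTrack("t", {"chr1": arr})

    def test_shifted_segment_attains_smaller_p_than_flat_segment(self, rng):
        events, psi, track = self._events_with_segment_shift(rng)
        comps = compare_segments(events, track, psi)
        by = {(c.segment_id, c.group_pair): c for c in comps}
        p_c = by[("C", ("high", "low"))].p_value
        p_a = by[("A", ("high", "low"))].p_value
        assert p_c < p_a
        assert by[("C", ("high", "low"))].stars in ("***", "****")

    def test_identical_groups_give_ns(self):
        arr = np.ones(30_000, dtype=np.float32)
        events = [_event(f"e{i}", 2000 + 1000 * i, 2200 + 1000 * i) for i in range(8)]
        classes = _psi_frame({e.event_id: ("high" if i % 2 else "low") for i, e in enumerate(events)})
        comps = compare_segments(events, ArrayTrack("t", {"chr1": arr}), classes)
        for c in comps:
            assert c.stars == "ns"

    def test_small_groups_skipped(self):
        arr = np.ones(10_000, dtype=np.float32)
        events = [_event(f"e{i}", 2000 + 1000 * i, 2200 + 1000 * i) for i in range(3)]
        classes = _psi_frame({"e0": "high", "e1": "high", "e2": "low"})
        comps = compare_segments(events, ArrayTrack("t", {"chr1": arr}), classes)
        assert comps == []


class TestExpressionCorrelation:
    def test_perfect_linear_coupling(self):
        x = np.linspace(1, 10, 30)
        out = correlate_expression_enrichment(x, 2 * x)
        assert out["pcc"] == pytest.approx(1.0)

    def test_independent_inputs_give_small_pcc(self, rng):
        n = 2000
        out = correlate_expression_enrichment(rng.random(n), rng.random(n))
        assert abs(out["pcc"]) < 3 / np.sqrt(n)

    def test_sign_of_coupling_recovered(self, rng):
        n = 300
        x = rng.random(n)
        noisy_pos = x + rng.normal(0, 0.3, n)
        noisy_neg = -x + rng.normal(0, 0.3, n)
        assert correlate_expression_enrichment(x, noisy_pos)["pcc"] > 0.5
        assert correlate_expression_enrichment(x, noisy_neg)["pcc"] < -0.5

    def test_zero_variance_flagged(self):
        out = correlate_expression_enrichment(np.ones(10), np.arange(10.0))
        assert out["pcc"] is None

    def test_group_comparisons_present(self, rng):
        x = np.sort(rng.random(60))
        y = x + rng.normal(0, 0.05, 60)
        out = correlate_expression_enrichment(x, y)
        assert len(out["group_comparisons"]) == 3  # tertile pairs


class TestRBPBinning:
    def _peak_frame(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])

    def test_no_peaks_gives_zero_profile(self):
        peaks = self._peak_frame([])
        events = [_event("e0", 5000, 5200)]
        table = bin_rbp_peaks(peaks, events)
        assert (table["count"] == 0).all()
        assert len(table) == 40  # 20 bins x 2 sites

    def test_single_intronic_peak_bins_at_minus_300_200(self):
        # peak midpoint 250 bp upstream of a + strand acceptor at 5000
        peaks = self._peak_frame([("chr1", 4740, 4760, "SRSF1", 1000, "+")])
        events = [_event("e0", 5000, 5200)]
        table = bin_rbp_peaks(peaks, events)
        acc = table[table.site_kind == "acceptor_3p"].set_index("bin_start")
        assert acc.loc[-300, "count"] == 1
        assert acc.loc[-300, "frequency"] == pytest.approx(0.01)
        assert acc.drop(index=-300)["count"].sum() <= 1  # donor side may also see it

    def test_score_filter_excludes_low_scores(self):
        peaks = self._peak_frame([("chr1", 4740, 4760, "SRSF1", 999, "+")])
        events = [_event("e0", 5000, 5200)]
        table = bin_rbp_peaks(peaks, events)
        assert (table["count"] == 0).all()

    def test_input_order_invariance(self, rng):
        rows = [
            ("chr1", int(p), int(p) + 20, "HNRNPA1", 1000, "+")
            for p in rng.integers(4000, 6000, 30)
        ]
        events = [_event("e0", 5000, 5200)]
        a = bin_rbp_peaks(self._peak_frame(rows), events)
        b = bin_rbp_peaks(self._peak_frame(rows[::-1]), events)
        pd.testing.assert_frame_equal(a, b)

    def test_strand_flip_mirrors_profile(self):
        peaks = self._peak_frame([("chr1", 4740, 4760, "SRSF1", 1000, "+")])
        plus = bin_rbp_peaks(peaks, [_event("e0", 5000, 5200, strand="+")])
        minus = bin_rbp_peaks(peaks, [_event("e0", 4800, 5000, strand="-")])
        # on the - strand event the acceptor sits at 5000 too; the same
        # peak is now 250 bp downstream in transcription direction
        acc_p = plus[plus.site_kind == "acceptor_3p"].set_index("bin_start")["count"]
        acc_m = minus[minus.site_kind == "acceptor_3p"].set_index("bin_start")["count"]
        assert acc_p.loc[-300] == 1
        assert acc_m.loc[200] == 1

    def test_fold_profile_contrasts_factor_sets(self):
        rows = [("chr1", 4740, 4760, "SRSF1", 1000, "+"), ("chr1", 4740, 4760, "DECOY", 1000, "+")]
        events = [_event("e0", 5000, 5200)]
        table = rbp_fold_profile(self._peak_frame(rows), events, splicing_factors=["SRSF1"])
        row = table[(table.site_kind == "acceptor_3p") & (table.bin_start == -300)].iloc[0]
        assert row["fold"] == pytest.approx(1.0)


def test_generated_rbp_peaks_bin_where_placed(rng):
    from cosplice.synth import RBPFactorSpec, SyntheticConfig, generate_rbp_peaks

    events = [_event(f"e{i}", 5000 + 3000 * i, 5200 + 3000 * i, strand="+" if i % 2 else "-") for i in range(10)]
    config = SyntheticConfig(n_genes=1, chrom="chr1")
    factors = [RBPFactorSpec(name="SRSF1", site="acceptor", offset=-250)]
    peaks = generate_rbp_peaks(events, factors, config, rng, genome_len=50_000)
    table = bin_rbp_peaks(peaks, events)
    acc = table[table.site_kind == "acceptor_3p"].set_index("bin_start")
    assert acc.loc[-300, "count"] == 10
    assert acc.drop(index=-300)["count"].sum() == 0
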