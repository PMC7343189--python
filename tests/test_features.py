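"""Feature-window construction: one-hot, enrichment, scaling, orientation."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from cosplice.annotation import ACCEPTOR, DONOR, SpliceSite
from cosplice.features import (
    FeatureWindow,
    build_dataset,
    extract_sequence_window,
    extract_track_window,
    one_hot,
    poisson_enrichment,
    reverse_time,
    scale01,
)
from cosplice.tracks import ArrayTrack, ConstantTrack


class TestOneHot:
    def test_acgt_convention(self):
        m = one_hot("ACGT")
        assert np.array_equal(m, np.eye(4))

    def test_n_gives_zero_row(self):
        assert np.array_equal(one_hot("N"), np.zeros((1, 4)))

    def test_random_sequence_matches_per_character_lookup(self, rng):
        lut = {"A": 0, "C": 1, "G": 2, "T": 3}
        seq = "".join(rng.choice(list("ACGTN"), size=50))
        m = one_hot(seq)
        for i, ch in enumerate(seq):
            row = np.zeros(4)
            if ch in lut:
                row[lut[ch]] = 1
            assert np.array_equal(m[i], row)
        assert np.array_equal(m.sum(axis=1), [1.0 if c in lut else 0.0 for c in seq])

    def test_lower_case_accepted(self):
        assert np.array_equal(one_hot("acgt"), np.eye(4))


class TestPoissonEnrichment:
    def test_zero_count_is_zero(self):
        assert poisson_enrichment(0, 1.0) == 0.0

    def test_closed_form_single_count(self):
        # P(X >= 1) = 1 - exp(-1)
        expected = -np.log10(1 - np.exp(-1))
        assert poisson_enrichment(1, 1.0) == pytest.approx(expected, abs=1e-10)
        assert poisson_enrichment(1, 1.0) == pytest.approx(0.19918, abs=1e-4)

    def test_cap_at_p_value_floor(self):
        # upper-tail sum oracle: P(X >= 5 | lam=1)
        import math

        p = sum(np.exp(-1) / math.factorial(k) for k in range(5))
        uncapped = -np.log10(1 - p)
        assert uncapped == pytest.approx(2.436, abs=1e-3)
        assert poisson_enrichment(5, 1.0) == 2.0

    def test_monotone_in_count(self, rng):
        lam = 2.5
        vals = [poisson_enrichment(k, lam) for k in range(15)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_bad_background_rejected(self):
        with pytest.raises(ValueError):
            poisson_enrichment(3, 0.0)


class TestScale01:
    def test_examples(self):
        assert np.allclose(scale01([0, 1, 2], cap=2), [0, 0.5, 1])
        assert np.allclose(scale01([5], cap=2), [1])

    def test_random_vector_matches_elementwise_oracle(self, rng):
        v = rng.normal(0, 3, size=200)
        cap = 1.7
        out = scale01(v, cap)
        oracle = np.array([min(max(x, 0.0), cap) / cap for x in v], dtype=np.float32)
        assert np.allclose(out, oracle, atol=1e-6)
        assert out.min() >= 0 and out.max() <= 1


class TestExtractWindow:
    def test_constant_track_gives_ones(self):
        site = SpliceSite("chr1", 500, ACCEPTOR, "+")
        track = ConstantTrack("c", 1.0)
        assert np.all(extract_track_window(track, site, 100) == 1.0)

    def test_plus_minus_strand_windows_are_mirror_images(self):
        arr = np.arange(1000, dtype=np.float32)
        track = ArrayTrack("ramp", {"chr1": arr})
        plus = extract_track_window(track, SpliceSite("chr1", 500, ACCEPTOR, "+"), 50)
        minus = extract_track_window(track, SpliceSite("chr1", 500, ACCEPTOR, "-"), 50)
        assert np.array_equal(plus, minus[::-1])

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_bump_downstream_lands_at_flank_plus_offset(self, strand):
        flank, off = 80, 50
        arr = np.zeros(2000, dtype=np.float32)
        pos = 1000
        center = pos + off if strand == "+" else pos - off - 1
        arr[center] = 7.0
        track = ArrayTrack("b", {"chr1": arr})
        vec = extract_track_window(track, SpliceSite("chr1", pos, ACCEPTOR, strand), flank)
        assert int(vec.argmax()) == flank + off

    def test_out_of_bounds_padded_with_fill(self):
        track = ArrayTrack("c", {"chr1": np.ones(100, dtype=np.float32)}, fill=0.0)
        vec = extract_track_window(track, SpliceSite("chr1", 10, ACCEPTOR, "+"), 50)
        assert len(vec) == 100
        assert np.all(vec[:40] == 0) and np.all(vec[40:60 + 50] == 1)

    def test_unknown_chromosome_raises(self):
        track = ArrayTrack("c", {"chr1": np.ones(10, dtype=np.float32)})
        with pytest.raises(KeyError):
            extract_track_window(track, SpliceSite("chr9", 5, ACCEPTOR, "+"), 2)


class TestReverseTime:
    def _window(self, rng):
        vals = rng.random((40, 3)).astype(np.float32)
        return FeatureWindow(
            site=SpliceSite("chr1", 100, ACCEPTOR, "+"),
            values=vals,
            channel_names=["A", "x", "y"],
        )

    def test_involution(self, rng):
        w = self._window(rng)
        back = reverse_time(reverse_time(w, ["x", "y"]), ["x", "y"])
        assert np.allclose(back.values, w.values)

    def test_constant_channel_unchanged(self, rng):
        w = self._window(rng)
        w.values[:, 1] = 0.3
        assert np.allclose(reverse_time(w, ["x"]).values, w.values)

    def test_ramp_slope_flips_and_others_untouched(self, rng):
        w = self._window(rng)
        w.values[:, 2] = np.linspace(0, 1, 40)
        out = reverse_time(w, ["y"])
        assert np.allclose(out.values[:, 2], np.linspace(1, 0, 40))
        assert np.allclose(out.values[:, :2], w.values[:, :2])

    def test_unknown_channel_rejected(self, rng):
        with pytest.raises(KeyError):
            reverse_time(self._window(rng), ["zzz"])


class TestBuildDataset:
    def test_shapes_and_channel_registry(self, strong_data):
        events = strong_data.events[:3]
        tracks = strong_data.tracks[:2]
        ds = build_dataset(events, strong_data.genome, tracks, flank_bp=100)
        assert ds.X_acc.shape == (3, 200, 6)
        assert ds.X_don.shape == (3, 200, 6)
        assert ds.channel_names[:4] == ["A", "C", "G", "T"]

    def test_dna_only_subset_has_four_channels(self, strong_dataset):
        dna = strong_dataset.dna_only()
        assert dna.n_channels == 4
        assert np.array_equal(dna.X_acc, strong_dataset.X_acc[:, :, :4])

    def test_epigenomic_values_unit_interval_dna_binary(self, strong_dataset):
        X = np.concatenate([strong_dataset.X_acc, strong_dataset.X_don])
        assert X[:, :, 4:].min() >= 0.0 and X[:, :, 4:].max() <= 1.0
        dna = X[:, :, :4]
        assert set(np.unique(dna)) <= {0.0, 1.0}
        # at most one hot base per position
        assert dna.sum(axis=2).max() <= 1.0

    def test_events_on_missing_contigs_dropped(self, strong_data):
        events = strong_data.events[:5]
        bad = events[0]
        import dataclasses

        bad_exon = dataclasses.replace(bad.exon, chrom="chrMissing")
        from cosplice.annotation import CassetteExonEvent, splice_sites_of

        acc, don = splice_sites_of(bad_exon)
        events = [CassetteExonEvent(bad_exon, acc, don, bad.label)] + events[1:]
        ds = build_dataset(events, strong_data.genome, strong_data.tracks[:1], flank_bp=50)
        assert len(ds) == 4

    def test_save_load_round_trip(self, strong_data, tmp_path):
        ds = build_dataset(strong_data.events[:4], strong_data.genome, strong_data.tracks[:2], flank_bp=60)
        ds.save(tmp_path / "d")
        from cosplice.features import SpliceDataset

        back = SpliceDataset.load(tmp_path / "d")
        assert back.event_ids == ds.event_ids
        assert back.channel_names == ds.channel_names
        assert np.array_equal(back.X_acc, ds.X_acc)
        assert np.array_equal(back.y, ds.y)


class TestOrientation:
    def test_acceptor_intronic_start_exonic_end_both_strands(self, strong_data):
        """With canonical splice sites, the acceptor window must show AG
        just before the splice site and the donor window GT just after,
        regardless of strand: index 0 is always the most 5' base in
        transcription direction."""
        flank = 30
        n_checked = {"+": 0, "-": 0}
        for ev in strong_data.events[:300]:
            acc_seq = extract_sequence_window(strong_data.genome, ev.acceptor, flank)
            don_seq = extract_sequence_window(strong_data.genome, ev.donor, flank)
            if acc_seq[flank - 2 : flank] == "AG" and don_seq[flank : flank + 2] == "GT":
                n_checked[ev.exon.strand] += 1
        # canonical fraction is 0.95, so the vast majority must match on both strands
        assert n_checked["+"] > 10 and n_checked["-"] > 10

    def test_mean_profile_of_informative_channel_matches_generator_bump(self, strong_data, strong_dataset):
        """Per-position mean of the included-class windows reproduces the
        generator's acceptor-side bump (center +100, sigma 20) within
        Monte-Carlo error."""
        ch = strong_dataset.channel_names.index("mark_act")
        inc = strong_dataset.X_acc[strong_dataset.y == 1, :, ch]
        spec = next(s for s in strong_data.config.channels if s.name == "mark_act")
        positions = np.arange(-100, 100)
        analytic = spec.amplitude_included * np.exp(-((positions - 100) ** 2) / (2 * spec.width**2))
        analytic = np.clip(analytic, 0, spec.cap) / spec.cap
        observed = inc.mean(axis=0)
        # noise mean after clipping at zero shifts the baseline slightly;
        # compare where the bump dominates
        bump_zone = positions > 40
        assert np.allclose(observed[bump_zone], analytic[bump_zone] + observed[positions < 0].mean(), atol=0.05)
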