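"""TIP characteristic profiles, regulatory scores and the average-signal baseline."""

import numpy as np
import pytest
from scipy import stats

from cyclescan.genomic_io import SignalTrack, TssRecord
from cyclescan.tip import (
    BindingProfile,
    DegenerateProfileError,
    average_signal,
    average_signals,
    characteristic_profile,
    regulatory_score,
    regulatory_scores,
    score_class_contrast,
    standardize_and_call,
)

from conftest import dense_expand, make_random_track, make_tss


def flat_track(value: float, length: int = 20000) -> SignalTrack:
    return SignalTrack({"chr1": length}, {"chr1": [(0, length, value)]})


class TestCharacteristicProfile:
    def test_constant_signal_gives_flat_profile_and_uniform_weights(self):
        t = flat_track(2.0)
        prof = characteristic_profile(t, [make_tss(pos=10000)], h=100)
        np.testing.assert_allclose(prof.profile, 2.0)
        np.testing.assert_allclose(prof.weights, 1.0 / 201)

    def test_point_signal_lands_at_strand_oriented_offset(self):
        t = SignalTrack({"chr1": 20000}, {"chr1": [(10100, 10101, 1.0)]})
        h = 200
        prof = characteristic_profile(t, [make_tss(pos=10000)], h=h)
        assert prof.profile[h + 100] == 1.0
        assert prof.profile.sum() == 1.0
        assert prof.weights[h + 100] == 1.0
        # on the '-' strand the same base sits at offset -100
        prof_m = characteristic_profile(t, [make_tss(pos=10000, strand="-")], h=h)
        assert prof_m.profile[h - 100] == 1.0

    def test_matches_brute_force_averaging_loop(self, rng):
        h = 50
        for _ in range(5):
            track = make_random_track(rng, {"chr1": 4000}, n_intervals=40)
            tss = [
                make_tss(pos=int(p), strand=s, gene_id=f"g{i}")
                for i, (p, s) in enumerate(
                    zip(rng.integers(100, 3900, 6), rng.choice(["+", "-"], 6))
                )
            ]
            prof = characteristic_profile(track, tss, h=h)
            # independent position-by-position averaging oracle
            expected = np.zeros(2 * h + 1)
            for k in range(-h, h + 1):
                vals = []
                for r in tss:
                    offset = k if r.strand == "+" else -k
                    pos = r.pos + offset
                    vals.append(track.query("chr1", pos) if 0 <= pos < 4000 else 0.0)
                expected[k + h] = np.mean(vals)
            np.testing.assert_allclose(prof.profile, expected, atol=1e-12)

    def test_all_zero_signal_raises_degenerate_error(self):
        t = SignalTrack({"chr1": 20000})
        with pytest.raises(DegenerateProfileError):
            characteristic_profile(t, [make_tss(pos=10000)], h=100)

    def test_smoothing_preserves_total_weight(self):
        t = SignalTrack({"chr1": 20000}, {"chr1": [(10000, 10010, 5.0)]})
        prof = characteristic_profile(t, [make_tss(pos=10000)], h=100, smooth=11)
        assert prof.weights.sum() == pytest.approx(1.0)


class TestRegulatoryScore:
    def test_flat_weights_equal_mean_signal(self, rng):
        track = make_random_track(rng, {"chr1": 30000}, n_intervals=80)
        h = 500
        prof = BindingProfile(h, np.ones(2 * h + 1))
        r = make_tss(pos=15000)
        expected = track.values("chr1", 15000 - h, 15000 + h + 1).mean()
        assert regulatory_score(prof, track, r) == pytest.approx(expected, abs=1e-12)

    def test_point_mass_weight_reads_tss_base(self):
        track = SignalTrack({"chr1": 30000}, {"chr1": [(15000, 15001, 7.0)]})
        h = 100
        c = np.zeros(2 * h + 1)
        c[h] = 1.0
        prof = BindingProfile(h, c)
        assert regulatory_score(prof, track, make_tss(pos=15000)) == 7.0

    def test_hand_computed_dot_product_h5(self):
        h = 5
        weights_raw = np.array([1, 0, 2, 0, 1, 4, 1, 0, 2, 0, 1], dtype=float)
        prof = BindingProfile(h, weights_raw)
        sig = np.arange(11, dtype=float)  # signal s[k] = k at offsets -5..5
        track = SignalTrack.from_dense({"chr1": np.concatenate([np.zeros(95), sig, np.zeros(100)])})
        expected = float(np.dot(weights_raw / weights_raw.sum(), sig))
        assert regulatory_score(prof, track, make_tss(pos=100)) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_window_extremes(self, rng):
        track = make_random_track(rng, {"chr1": 30000}, n_intervals=60)
        prof = characteristic_profile(track, [make_tss(pos=15000)], h=300)
        s = track.values("chr1", 15000 - 300, 15000 + 301)
        score = regulatory_score(prof, track, make_tss(pos=15000))
        assert s.min() - 1e-12 <= score <= s.max() + 1e-12

    def test_batch_scores_match_single_calls(self, rng):
        track = make_random_track(rng, {"chr1": 30000}, n_intervals=60)
        tss = [make_tss(pos=p, gene_id=f"g{p}", strand=s)
               for p, s in [(5000, "+"), (12000, "-"), (25000, "+")]]
        prof = characteristic_profile(track, tss, h=400)
        batch = regulatory_scores(prof, track, tss)
        for r in tss:
            assert batch[r.gene_id] == pytest.approx(regulatory_score(prof, track, r), abs=1e-12)

    def test_uniform_weights_equal_average_signal_at_same_half_width(self, rng):
        # flat-profile limit: TIP with uniform weights is the plain window mean
        track = make_random_track(rng, {"chr1": 30000}, n_intervals=60)
        h = 1000
        prof = BindingProfile(h, np.ones(2 * h + 1))
        r = make_tss(pos=15000)
        tip = regulatory_score(prof, track, r)
        # average_signal window is [pos-h, pos+h); TIP's is [pos-h, pos+h]
        manual = track.values("chr1", 15000 - h, 15000 + h + 1).mean()
        assert tip == pytest.approx(manual, abs=1e-12)

    def test_strand_symmetry_under_genome_reversal(self, rng):
        """Mirroring the genome and flipping strands leaves scores unchanged."""
        L = 30000
        track = make_random_track(rng, {"chr1": L}, n_intervals=50)
        tss = [make_tss(pos=p, strand=s, gene_id=f"g{i}")
               for i, (p, s) in enumerate([(6000, "+"), (14000, "-"), (22000, "+")])]
        mirrored = SignalTrack(
            {"chr1": L},
            {"chr1": [(L - end, L - start, v) for start, end, v in track.intervals("chr1")]},
        )
        flipped = [
            TssRecord("chr1", L - 1 - r.pos, "-" if r.strand == "+" else "+", r.gene_id)
            for r in tss
        ]
        h = 500
        orig = regulatory_scores(characteristic_profile(track, tss, h=h), track, tss)
        mirr = regulatory_scores(
            characteristic_profile(mirrored, flipped, h=h), mirrored, flipped
        )
        for g in orig:
            assert orig[g] == pytest.approx(mirr[g], abs=1e-10)


class TestAverageSignal:
    def test_constant_signal(self):
        assert average_signal(flat_track(3.5), make_tss(pos=10000)) == pytest.approx(3.5)

    def test_half_covered_window(self):
        t = SignalTrack({"chr1": 20000}, {"chr1": [(9000, 10000, 1.0)]})
        assert average_signal(t, make_tss(pos=10000)) == pytest.approx(0.5)

    def test_matches_per_base_loop(self, rng):
        track = make_random_track(rng, {"chr1": 5000}, n_intervals=50)
        r = make_tss(pos=2500)
        expected = np.mean([track.query("chr1", p) for p in range(1500, 3500)])
        assert average_signal(track, r) == pytest.approx(expected, abs=1e-12)

    def test_truncated_window_keeps_full_denominator(self):
        t = SignalTrack({"chr1": 5000}, {"chr1": [(0, 5000, 2.0)]})
        # window [-500, 1500): 500 off-chromosome bases count as zero
        assert average_signal(t, make_tss(pos=500)) == pytest.approx(2.0 * 1500 / 2000)

    def test_batch_matches_single(self, rng):
        track = make_random_track(rng, {"chr1": 20000}, n_intervals=40)
        tss = [make_tss(pos=p, gene_id=f"g{p}") for p in (3000, 9000, 17000)]
        batch = average_signals(track, tss)
        for r in tss:
            assert batch[r.gene_id] == pytest.approx(average_signal(track, r), abs=1e-12)


class TestStandardize:
    def test_three_scores_symmetric(self):
        res = standardize_and_call({"a": 1.0, "b": 2.0, "c": 3.0})
        assert res.z["a"] == pytest.approx(-1.0)
        assert res.z["b"] == pytest.approx(0.0)
        assert res.z["c"] == pytest.approx(1.0)
        assert res.p["b"] == pytest.approx(0.5)

    def test_all_equal_scores_error(self):
        with pytest.raises(ValueError, match="all scores equal"):
            standardize_and_call({"a": 1.0, "b": 1.0, "c": 1.0})

    def test_z_scores_standardised(self, rng):
        raw = {f"g{i}": float(v) for i, v in enumerate(rng.normal(5, 3, 200))}
        res = standardize_and_call(raw)
        z = np.array(list(res.z.values()))
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert all(0 < p < 1 for p in res.p.values())

    def test_null_scores_control_false_targets(self, rng):
        # 1000 null scores: expected BH false calls at q<0.01 is ~0
        raw = {f"g{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 1000))}
        res = standardize_and_call(raw, q_threshold=0.01)
        # binomial tolerance: P(>=5 calls) under the null is negligible
        assert len(res.targets) <= 5


class TestClassContrast:
    def test_identical_distributions_give_small_t(self, rng):
        x = rng.normal(0, 1, 400)
        scores = {f"g{i}": float(v) for i, v in enumerate(x)}
        labels = {f"g{i}": i % 2 for i in range(400)}
        t, p = score_class_contrast(scores, labels)
        assert abs(t) < 3.0 and p > 1e-3

    def test_hand_computed_welch_three_vs_three(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 9.0]
        scores = {f"p{i}": v for i, v in enumerate(a)} | {f"n{i}": v for i, v in enumerate(b)}
        labels = {f"p{i}": 1 for i in range(3)} | {f"n{i}": 0 for i in range(3)}
        t, p = score_class_contrast(scores, labels)
        expect = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(expect.statistic)
        assert p == pytest.approx(expect.pvalue)

    def test_separated_classes_highly_significant(self, rng):
        scores = {}
        labels = {}
        for i in range(500):
            scores[f"p{i}"], labels[f"p{i}"] = float(rng.normal(1, 1)), 1
            scores[f"n{i}"], labels[f"n{i}"] = float(rng.normal(0, 1)), 0
        _, p = score_class_contrast(scores, labels)
        assert p < 1e-10
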