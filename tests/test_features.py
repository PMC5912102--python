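"""The 207-feature bank: block contracts, hand-computed examples,
shift-invariance, finiteness."""

import numpy as np
import pytest

from conftest import make_recording
from gazetraits.events import Fixation, Saccade, detect_blinks, detect_fixations, \
    detect_saccades
from gazetraits.features import (
    FEATURE_FAMILIES,
    FEATURE_INDEX,
    FEATURE_NAMES,
    N_FEATURES,
    NGramConfig,
    event_features,
    extract_feature_vector,
    feature_subsets,
    feature_table,
    heatmap_features,
    ngram_features,
    ngram_histogram_features,
    raw_gaze_features,
)
from gazetraits.simulate import OculomotorParams, generate_recording
from gazetraits.windows import Window, slide_windows


def window_over(rec, start=0.0, size=None):
    size = size if size is not None else rec.duration
    i0 = int(np.searchsorted(rec.samples["t"].to_numpy(), start - 1e-12))
    i1 = int(np.searchsorted(rec.samples["t"].to_numpy(), start + size - 1e-12))
    return Window(start=start, end=start + size, i0=i0, i1=i1)


def make_saccade(direction=0.0, amplitude=0.2, t0=0.0, pv=4.0):
    return Saccade(start=t0, end=t0 + 0.05, amplitude=amplitude,
                   direction=direction, peak_velocity=pv, erroneous_share=0.0)


def make_fixation(duration=0.2, t0=0.0):
    return Fixation(start=t0, end=t0 + duration, centroid=(0.5, 0.5),
                    dispersion=0.01, pupil_mean=3.5, pupil_var=0.01,
                    erroneous_share=0.0, i0=0, i1=1)


class TestRawGaze:
    def test_constant_signal(self):
        rec = make_recording([0.3] * 120, [0.7] * 120)
        w = window_over(rec)
        v = raw_gaze_features(rec, w)
        get = lambda name: v[FEATURE_INDEX[name]]
        for st in ("min", "max", "mean", "median"):
            assert get(f"raw_x_{st}") == pytest.approx(0.3)
            assert get(f"raw_y_{st}") == pytest.approx(0.7)
        for name in ("raw_x_std", "raw_x_range", "raw_speed_mean",
                     "raw_speed_max", "raw_x_skew", "raw_xy_corr"):
            assert get(name) == 0.0
        assert get("raw_valid_fraction") == 1.0

    def test_alternating_x_speed(self):
        x = np.tile([0.0, 1.0], 60)
        rec = make_recording(x, np.full(120, 0.5))
        v = raw_gaze_features(rec, window_over(rec))
        assert v[FEATURE_INDEX["raw_x_range"]] == pytest.approx(1.0)
        assert v[FEATURE_INDEX["raw_speed_mean"]] == pytest.approx(60.0)

    def test_shape_and_finiteness(self):
        rng = np.random.default_rng(3)
        rec = make_recording(rng.uniform(0, 1, 300), rng.uniform(0, 1, 300),
                             np.where(rng.random(300) < 0.2, np.nan, 3.0))
        v = raw_gaze_features(rec, window_over(rec))
        assert v.shape == (34,)
        assert np.isfinite(v).all()


class TestHeatmap:
    def test_all_points_in_top_left(self):
        # one far outlier pushes the 95% interval; the mass sits top-left
        x = np.concatenate([np.full(199, 0.1), [0.9]])
        y = np.concatenate([np.full(199, 0.1), [0.9]])
        rec = make_recording(x, y)
        v = heatmap_features(rec, window_over(rec))
        assert v[0] == 1.0
        assert v[1:].sum() == 0.0

    def test_uniform_grid(self):
        centers = (np.arange(8) + 0.5) / 8
        xx, yy = np.meshgrid(centers, centers)
        rec = make_recording(xx.ravel(), yy.ravel())
        v = heatmap_features(rec, window_over(rec))
        assert np.allclose(v, 1.0 / 64.0)

    def test_row_major_enumeration_from_top_left(self):
        # points at top-right: row 0 (small y = top), col 7 -> cell 7
        x = np.concatenate([np.full(100, 0.9), np.full(100, 0.1)])
        y = np.concatenate([np.full(100, 0.1), np.full(100, 0.9)])
        rec = make_recording(x, y)
        v = heatmap_features(rec, window_over(rec))
        assert v[7] == pytest.approx(0.5)        # top-right
        assert v[56] == pytest.approx(0.5)       # bottom-left
        assert v.sum() == pytest.approx(1.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0.2, 0.5, 400)
        y = rng.uniform(0.2, 0.5, 400)
        v1 = heatmap_features(make_recording(x, y), window_over(make_recording(x, y)))
        v2 = heatmap_features(make_recording(x + 0.3, y + 0.2),
                              window_over(make_recording(x + 0.3, y + 0.2)))
        np.testing.assert_allclose(v1, v2)

    def test_degenerate_axis(self):
        rec = make_recording(np.full(100, 0.5), np.linspace(0.2, 0.8, 100))
        v = heatmap_features(rec, window_over(rec)).reshape(8, 8)
        assert v[:, 0].sum() == pytest.approx(1.0)  # all mass in column 0


class TestEventFeatures:
    def test_single_fixation(self):
        rec = make_recording([0.5] * 600, [0.5] * 600)
        w = window_over(rec, 0.0, 10.0)
        w.fixations = [make_fixation(duration=0.2)]
        v = event_features(rec, w)
        off = 98  # event block offset in the full vector
        get = lambda name: v[FEATURE_INDEX[name] - off]
        assert get("fix_count") == 1.0
        assert get("fix_dur_min") == get("fix_dur_max") == pytest.approx(0.2)
        assert get("fix_dur_mean") == pytest.approx(0.2)
        assert get("fix_dur_std") == 0.0

    def test_empty_blinks_are_zero(self):
        rec = make_recording([0.5] * 600, [0.5] * 600)
        w = window_over(rec, 0.0, 10.0)
        w.fixations = [make_fixation()]
        v = event_features(rec, w)
        off = 98
        for name in ("blink_count", "blink_rate_per_min", "blink_dur_min",
                     "blink_dur_max", "blink_dur_mean", "blink_dur_std"):
            assert v[FEATURE_INDEX[name] - off] == 0.0

    def test_statistics_match_direct_enumeration(self):
        rec = generate_recording(OculomotorParams(loss_fraction=0.05),
                                 duration=60, rate=60, seed=4)
        fix = detect_fixations(rec)
        sac = detect_saccades(rec, fix)
        blk = detect_blinks(rec)
        ws = slide_windows(rec, fix, sac, blk, 15.0)
        w = ws[0]
        v = event_features(rec, w)
        off = 98
        durs = [f.duration for f in w.fixations]
        assert v[FEATURE_INDEX["fix_count"] - off] == len(w.fixations)
        assert v[FEATURE_INDEX["fix_dur_mean"] - off] == pytest.approx(np.mean(durs))
        amps = [s.amplitude for s in w.saccades]
        assert v[FEATURE_INDEX["sacc_amp_max"] - off] == pytest.approx(np.max(amps))
        assert v[FEATURE_INDEX["sacc_count"] - off] == len(w.saccades)


class TestNGrams:
    def test_repeated_symbol_bigrams(self):
        w = Window(start=0, end=10, i0=0, i1=0)
        t0 = 0.0
        for _ in range(3):
            w.saccades.append(make_saccade(direction=np.pi / 2, amplitude=0.05,
                                           t0=t0))
            t0 += 1.0
        # encoding A, n=2: the same "small saccade up" bigram twice
        feats = ngram_features(w)
        base = FEATURE_INDEX["ngramA_n2_distinct"] - 151
        assert feats[base] == 1.0          # distinct
        assert feats[base + 1] == 2.0      # max
        assert feats[base + 2] == 2.0      # min
        assert feats[base + 3] == 2.0      # mean
        assert feats[base + 4] == 0.0      # variance

    def test_empty_sequence_conventions(self):
        w = Window(start=0, end=10, i0=0, i1=0)
        feats = ngram_features(w)
        for n in (1, 2, 3, 4):
            base = FEATURE_INDEX[f"ngramA_n{n}_distinct"] - 151
            assert list(feats[base : base + 5]) == [0.0] * 5
            assert list(feats[base + 5 : base + 7]) == [-1.0, -1.0]

    def test_interleaved_trigram(self):
        # "long saccade up, short fixation, short saccade up" -> one B 3-gram
        w = Window(start=0, end=10, i0=0, i1=0)
        w.saccades = [make_saccade(np.pi / 2, 0.3, t0=0.0),
                      make_saccade(np.pi / 2, 0.05, t0=1.0)]
        w.fixations = [make_fixation(duration=0.2, t0=0.4)]
        feats = ngram_features(w)
        base = FEATURE_INDEX["ngramB_n3_distinct"] - 151
        assert feats[base] == 1.0
        assert feats[base + 1] == 1.0
        # encoding A ignores the fixation: one bigram of the two saccades
        base_a = FEATURE_INDEX["ngramA_n2_distinct"] - 151
        assert feats[base_a] == 1.0

    def test_lexicographic_tie_breaks(self):
        # two distinct unigrams with equal counts: argmax = smaller index
        feats = ngram_histogram_features([5, 2, 5, 2], n=1, alphabet=16)
        assert feats[0] == 2.0       # distinct
        assert feats[5] == 2.0       # most frequent: smallest tied index
        assert feats[6] == 2.0       # least frequent: smallest tied index


class TestFullVector:
    def test_block_partition(self):
        sizes = {k: len(v) for k, v in FEATURE_FAMILIES.items()}
        assert sizes == {"raw": 34, "heatmap": 64, "event": 53, "ngram": 56}
        assert sum(sizes.values()) == N_FEATURES == 207
        concat = np.concatenate(list(FEATURE_FAMILIES.values()))
        assert sorted(concat.tolist()) == list(range(207))

    def test_index_map_is_stable_bijection(self):
        assert len(FEATURE_NAMES) == 207
        assert len(set(FEATURE_NAMES)) == 207
        assert [FEATURE_INDEX[n] for n in FEATURE_NAMES] == list(range(207))

    def test_subsets_cover_families(self):
        subs = feature_subsets()
        assert len(subs) == 9
        assert len(subs["all"]) == 207
        assert len(subs["no_ngram"]) == 207 - 56

    def test_vector_contract_and_determinism(self):
        rec = generate_recording(OculomotorParams(), duration=60, rate=60, seed=6)
        fix = detect_fixations(rec)
        sac = detect_saccades(rec, fix)
        blk = detect_blinks(rec)
        ws = slide_windows(rec, fix, sac, blk, 15.0)
        assert ws, "expected retained windows"
        v1 = extract_feature_vector(rec, ws[0])
        v2 = extract_feature_vector(rec, ws[0])
        assert v1.shape == (207,)
        np.testing.assert_array_equal(v1, v2)

    def test_all_features_finite_on_many_random_windows(self):
        total = 0
        for seed in range(3):
            rec = generate_recording(OculomotorParams(), duration=600,
                                     rate=60, seed=100 + seed)
            fix = detect_fixations(rec)
            sac = detect_saccades(rec, fix)
            blk = detect_blinks(rec)
            for size in (5.0, 15.0):
                tab = feature_table(rec, slide_windows(rec, fix, sac, blk, size))
                total += len(tab)
                assert np.isfinite(tab.iloc[:, 4:].to_numpy()).all()
        assert total >= 700
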