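import numpy as np
import pytest

from gazesal.events import FixationEvent, detect_events, heuristic_denoise
from gazesal.recording import TrialSegment, binocular_composite, write_gaze_csv
from gazesal.saliency import smooth_and_normalize
from gazesal.scoring import score_session
from gazesal.spectrum import cpd_per_cycle, high_freq_energy_fraction
from gazesal.synth import (
    ViewerProfile,
    expected_mean_value,
    make_feature_maps,
    simulate_cohort,
    simulate_recording,
)

from conftest import FIXTURE_GEOMETRY


def _blob_maps(image_ids, size=(200, 200), feature="color_red"):
    return {
        img: {feature: smooth_and_normalize(
            make_feature_maps("blob", size, {"n_blobs": 3}, seed=i + 1),
            sigma_px=0, feature_label=feature)}
        for i, img in enumerate(image_ids)
    }


def _profile(**kw):
    defaults = dict(
        label="t", attention_weights={"color_red": 1.0},
        fixation_duration_mean_ms=250.0, fixation_duration_sd_ms=50.0,
        min_fixation_ms=150.0, gaze_noise_deg=0.0, seed=0,
    )
    defaults.update(kw)
    return ViewerProfile(**defaults)


class TestMakeFeatureMaps:
    def test_field_half_left_indicator(self):
        m = make_feature_maps("field_half", (4, 6), {"side": "left"})
        assert np.all(m[:, :3] == 1.0)
        assert np.all(m[:, 3:] == 0.0)

    def test_blob_argmax_at_center(self):
        m = make_feature_maps("blob", (41, 41), {"centers": [(20, 20)], "sigma_px": 10})
        assert np.unravel_index(np.argmax(m), m.shape) == (20, 20)

    def test_background_complements_blob(self):
        params = {"centers": [(10, 10)], "sigma_px": 5}
        blob = make_feature_maps("blob", (21, 21), params)
        bg = make_feature_maps("background", (21, 21), params)
        assert np.allclose(blob + bg, 1.0)

    def test_grating_spectrum_cross_check(self, geometry):
        """A grating constructed at 5 cpd is classified entirely above 3 cpd."""
        rect = (560.0, 140.0, 800.0, 800.0)
        sx, _ = cpd_per_cycle(geometry, rect)
        cycles = 5.0 / sx  # cycles across the image for 5 cpd
        m = make_feature_maps("grating", (256, 256), {"cycles": round(cycles)})
        frac = high_freq_energy_fraction(m, geometry, rect, 3.0)
        assert frac == pytest.approx(1.0, abs=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            make_feature_maps("voronoi", (4, 4))

    def test_values_in_unit_interval(self):
        for kind in ("blob", "grating", "field_half", "background"):
            m = make_feature_maps(kind, (16, 16), seed=2)
            assert m.min() >= 0.0 and m.max() <= 1.0


class TestViewerProfile:
    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ViewerProfile(attention_weights={"a": -0.1})

    def test_weights_over_one_rejected(self):
        with pytest.raises(ValueError, match="at most 1"):
            ViewerProfile(attention_weights={"a": 0.7, "b": 0.5})


class TestSimulateRecording:
    def test_one_hot_map_pins_fixations(self, geometry):
        size = 50
        raw = np.zeros((size, size))
        raw[30, 20] = 1.0
        rect = (560.0, 140.0, 500.0, 500.0)
        trials = [TrialSegment("img0", 0.0, 3000.0, rect)]
        maps = {"img0": {"f": smooth_and_normalize(raw, sigma_px=0)}}
        v = _profile(attention_weights={"f": 1.0})
        rec, script = simulate_recording(v, maps, geometry, trials)
        expect_x = rect[0] + (20 + 0.5) * rect[2] / size - 0.5
        expect_y = rect[1] + (30 + 0.5) * rect[3] / size - 0.5
        for f in script.fixations:
            assert f.target_px == (expect_x, expect_y)

    def test_recording_satisfies_invariants(self, geometry):
        maps = _blob_maps(["img0"])
        trials = [TrialSegment("img0", 0.0, 3000.0, (560, 140, 800, 800))]
        rec, _ = simulate_recording(_profile(), maps, geometry, trials)
        t = rec.samples["t_ms"].to_numpy()
        assert np.all(np.diff(t) > 0)
        assert np.median(np.diff(t)) == pytest.approx(2.0)

    def test_renewal_fixation_count(self, geometry):
        """10 s trial, ~250 ms fixations + ~40 ms saccades -> about 34 fixations."""
        maps = _blob_maps(["img0"])
        trials = [TrialSegment("img0", 0.0, 10_000.0, (560, 140, 800, 800))]
        counts = [
            simulate_recording(
                _profile(seed=s, min_fixation_ms=80.0), maps, FIXTURE_GEOMETRY, trials
            )[1].n_fixations()
            for s in range(40)
        ]
        expected = 10_000 / (250 + 40)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se + 1.5

    def test_all_zero_mixture_rejected(self, geometry):
        raw = np.zeros((10, 10))
        maps = {"img0": {"f": smooth_and_normalize(raw, sigma_px=0)}}
        trials = [TrialSegment("img0", 0.0, 1000.0, (0, 0, 100, 100))]
        v = ViewerProfile(attention_weights={"f": 1.0})
        with pytest.raises(ValueError, match="mixture"):
            simulate_recording(v, maps, geometry, trials)

    def test_missing_trial_map_rejected(self, geometry):
        trials = [TrialSegment("imgX", 0.0, 1000.0, (0, 0, 100, 100))]
        with pytest.raises(ValueError, match="imgX"):
            simulate_recording(_profile(), {}, geometry, trials)


class TestGroundTruthRecovery:
    def _run(self, seed, noise=0.0, denoise=False):
        maps = _blob_maps(["img0", "img1"])
        trials = [
            TrialSegment("img0", 0.0, 5000.0, (560, 140, 800, 800)),
            TrialSegment("img1", 5000.0, 10000.0, (560, 140, 800, 800)),
        ]
        v = _profile(seed=seed, gaze_noise_deg=noise)
        rec, script = simulate_recording(v, maps, FIXTURE_GEOMETRY, trials)
        stream = binocular_composite(rec.samples)
        if denoise:
            stream = heuristic_denoise(stream, 3)
        events = detect_events(stream, FIXTURE_GEOMETRY)
        return rec, script, events

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noise_free_exact_recovery(self, seed):
        """Detection reproduces the scripted fixation count and centroids."""
        _, script, events = self._run(seed)
        fixations = [e for e in events if isinstance(e, FixationEvent)]
        assert len(fixations) == script.n_fixations()
        for s, d in zip(script.fixations, fixations):
            assert d.centroid_px[0] == pytest.approx(s.target_px[0], abs=0.5)
            assert d.centroid_px[1] == pytest.approx(s.target_px[1], abs=0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fixation_count_robust_to_noise(self, seed):
        """SD 0.02 deg of gaze jitter leaves the fixation count unchanged."""
        _, script, events = self._run(seed, noise=0.02, denoise=True)
        fixations = [e for e in events if isinstance(e, FixationEvent)]
        assert len(fixations) == script.n_fixations()

    def test_scored_values_match_script_lookup(self, seed=0):
        """Pipeline values equal direct map lookups at the scripted targets."""
        rec, script, events = self._run(seed)
        maps = _blob_maps(["img0", "img1"])
        flat = {(img, f): m for img, d in maps.items() for f, m in d.items()}
        records, _ = score_session(rec, events, flat)
        by_trial = {}
        for f in script.fixations:
            by_trial.setdefault(f.image_id, []).append(f)
        for r in records:
            smap = flat[(r.image_id, r.feature_label)]
            s = by_trial[r.image_id][r.fixation_index]
            # map coordinates via the same convention as the scorer
            mx = (s.target_px[0] - 560 + 0.5) * 200 / 800 - 0.5
            my = (s.target_px[1] - 140 + 0.5) * 200 / 800 - 0.5
            assert r.value == int(smap.intensities[round(my), round(mx)])


class TestAttentionWeightEffects:
    def _mean_value(self, w, seed, maps, trials, feature="color_red"):
        v = _profile(seed=seed, attention_weights={feature: w})
        _, script = simulate_recording(v, maps, FIXTURE_GEOMETRY, trials)
        smap = maps[trials[0].image_id][feature]
        rect = trials[0].image_rect
        vals = []
        for f in script.fixations:
            mx = (f.target_px[0] - rect[0] + 0.5) * smap.width_px / rect[2] - 0.5
            my = (f.target_px[1] - rect[1] + 0.5) * smap.height_px / rect[3] - 0.5
            vals.append(int(smap.intensities[round(my), round(mx)]))
        return float(np.mean(vals))

    def test_mean_value_increasing_in_weight(self):
        """Mean fixation saliency is strictly increasing over the weight grid."""
        maps = _blob_maps(["img0"])
        trials = [TrialSegment("img0", 0.0, 30_000.0, (560, 140, 800, 800))]
        means = [self._mean_value(w, seed=7, maps=maps, trials=trials)
                 for w in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_high_weight_viewer_scores_above_low_weight(self):
        maps = _blob_maps(["img0"])
        trials = [TrialSegment("img0", 0.0, 5000.0, (560, 140, 800, 800))]
        wins = 0
        n = 40
        for s in range(n):
            hi = self._mean_value(0.9, seed=s, maps=maps, trials=trials)
            lo = self._mean_value(0.1, seed=1000 + s, maps=maps, trials=trials)
            wins += hi > lo
        assert wins >= int(0.95 * n)

    def test_w1_mean_approaches_intensity_weighted_mean(self):
        """w=1 noise-free viewers converge on sum(I^2)/sum(I) of the map."""
        maps = _blob_maps(["img0"])
        smap = maps["img0"]["color_red"]
        trials = [TrialSegment("img0", 0.0, 60_000.0, (560, 140, 800, 800))]
        v = _profile(seed=3)
        _, script = simulate_recording(v, maps, FIXTURE_GEOMETRY, trials)
        rect = trials[0].image_rect
        vals = []
        for f in script.fixations:
            mx = (f.target_px[0] - rect[0] + 0.5) * 200 / rect[2] - 0.5
            my = (f.target_px[1] - rect[1] + 0.5) * 200 / rect[3] - 0.5
            vals.append(int(smap.intensities[round(my), round(mx)]))
        I = smap.intensities.astype(float)
        closed_form = (I**2).sum() / I.sum()
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - closed_form) < 3 * se

    def test_expected_mean_value_monotone(self):
        smap = _blob_maps(["img0"])["img0"]["color_red"]
        vals = [expected_mean_value(smap, w) for w in (0, 0.25, 0.5, 0.75, 1)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestSimulateCohort:
    def test_two_groups_distinct_ids(self):
        maps = _blob_maps(["img0"])
        trials = [TrialSegment("img0", 0.0, 2000.0, (560, 140, 800, 800))]
        profiles = {"cvi": _profile(), "control": _profile()}
        cohort = simulate_cohort(1, profiles, maps, FIXTURE_GEOMETRY, trials, seed=5)
        ids = [rec.participant_id for rec, _ in cohort]
        assert len(cohort) == 2
        assert len(set(ids)) == 2
        assert {rec.group_label for rec, _ in cohort} == {"cvi", "control"}

    def test_same_master_seed_bit_identical(self, tmp_path):
        maps = _blob_maps(["img0"])
        trials = [TrialSegment("img0", 0.0, 2000.0, (560, 140, 800, 800))]
        profiles = {"cvi": _profile(), "control": _profile()}
        paths = []
        for run in range(2):
            cohort = simulate_cohort(1, profiles, maps, FIXTURE_GEOMETRY, trials, seed=9)
            p = tmp_path / f"run{run}.csv"
            write_gaze_csv(cohort[0][0], p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_different_seeds_differ(self):
        maps = _blob_maps(["img0"])
        trials = [TrialSegment("img0", 0.0, 2000.0, (560, 140, 800, 800))]
        profiles = {"cvi": _profile()}
        c1 = simulate_cohort(1, profiles, maps, FIXTURE_GEOMETRY, trials, seed=1)
        c2 = simulate_cohort(1, profiles, maps, FIXTURE_GEOMETRY, trials, seed=2)
        assert not c1[0][0].samples.equals(c2[0][0].samples)

    def test_group_contrast_detectable(self):
        """Weight-separated groups produce a significant group difference."""
        maps = _blob_maps(["img0", "img1"])
        trials = [
            TrialSegment("img0", 0.0, 4000.0, (560, 140, 800, 800)),
            TrialSegment("img1", 4000.0, 8000.0, (560, 140, 800, 800)),
        ]
        profiles = {
            "cvi": _profile(attention_weights={"color_red": 0.8}),
            "control": _profile(attention_weights={"color_red": 0.1}),
        }
        cohort = simulate_cohort(6, profiles, maps, FIXTURE_GEOMETRY, trials, seed=17)
        flat = {(img, f): m for img, d in maps.items() for f, m in d.items()}
        import pandas as pd
        from gazesal.scoring import summaries_to_frame
        from gazesal.stats import compare_groups

        frames = []
        for rec, _ in cohort:
            stream = binocular_composite(rec.samples)
            events = detect_events(stream, FIXTURE_GEOMETRY)
            _, summaries = score_session(rec, events, flat)
            frames.append(summaries_to_frame(summaries))
        out = compare_groups(pd.concat(frames, ignore_index=True))
        assert out.iloc[0]["median_cvi"] > out.iloc[0]["median_control"]
        assert out.iloc[0]["p_value"] < 0.05
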