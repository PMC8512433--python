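"""Peak detection, retention warping, grouping, fill-in and replicate
averaging, checked against constructed chromatograms and planted truth."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import small_compound, small_design, small_recipe
from vinomix import features, synthio
from vinomix.features import (
    DetectionParams,
    GroupingParams,
    average_technical_replicates,
    correct_rt,
    detect_peaks,
    extract_eics,
    fill_missing,
    group_peaks,
)
from vinomix.synthio import Run, SampleMeta, simulate_study


def make_run(times, channel_data, meta=None):
    """Build a Run from {mz: intensity array} channel data."""
    mzs = np.array(sorted(channel_data), dtype=float)
    scans = []
    for i, t in enumerate(times):
        scans.append((float(t), mzs, np.array([channel_data[int(m)][i] for m in mzs], dtype=float)))
    return Run(meta=meta or SampleMeta("s1", "Own", "Full", 2018, 1, 1), scans=scans)


def gaussian_channel(times, rt0, sigma_s, height, floor=0.0):
    return floor + height * np.exp(-0.5 * ((times - rt0) * 60.0 / sigma_s) ** 2)


TIMES = np.arange(1.0, 9.0, 1.0 / 120.0)  # 2 scans/s over 8 min


class TestEics:
    def test_single_scan_channels(self):
        run = Run(
            meta=SampleMeta("s", "Own", "Full", 2018, 1, 1),
            scans=[
                (1.0, np.array([43.0, 71.0]), np.array([100.0, 50.0])),
                (1.01, np.array([43.0, 71.0]), np.array([0.0, 10.0])),
                (1.02, np.array([43.0, 71.0]), np.array([5.0, 0.0])),
            ],
        )
        times, ch = extract_eics(run)
        np.testing.assert_array_equal(ch[43], [100.0, 0.0, 5.0])
        np.testing.assert_array_equal(ch[71], [50.0, 10.0, 0.0])

    def test_tic_conservation(self, rng):
        n = 50
        scans = []
        for i in range(n):
            mz = rng.choice(np.arange(29, 120), size=5, replace=False).astype(float)
            scans.append((i * 0.01 + 1, np.sort(mz), rng.uniform(0, 100, 5)))
        run = Run(meta=SampleMeta("s", "Own", "Full", 2018, 1, 1), scans=scans)
        times, ch = extract_eics(run)
        total = np.zeros(n)
        for arr in ch.values():
            total += arr
        np.testing.assert_allclose(total, run.tic(), rtol=1e-12)

    def test_disjoint_scans_have_full_length_channels(self):
        run = Run(
            meta=SampleMeta("s", "Own", "Full", 2018, 1, 1),
            scans=[
                (1.0, np.array([43.0]), np.array([10.0])),
                (1.01, np.array([57.0]), np.array([20.0])),
            ],
        )
        _, ch = extract_eics(run)
        np.testing.assert_array_equal(ch[43], [10.0, 0.0])
        np.testing.assert_array_equal(ch[57], [0.0, 20.0])


class TestDetect:
    def test_clean_gaussian_detected_at_apex(self):
        run = make_run(TIMES, {55: gaussian_channel(TIMES, 5.0, 2.5, 1000.0, floor=1.0)})
        peaks = detect_peaks(run)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.mz == 55
        assert abs(p.rt - 5.0) <= 1.0 / 120.0 + 1e-9
        assert p.sn >= 6

    def test_too_narrow_peak_rejected(self):
        # half-height width 2 s < 5 s minimum
        sigma = 2.0 / 2.355
        run = make_run(TIMES, {55: gaussian_channel(TIMES, 5.0, sigma, 1000.0, floor=1.0)})
        assert detect_peaks(run) == []

    def test_too_wide_peak_rejected(self):
        sigma = 25.0 / 2.355
        run = make_run(TIMES, {55: gaussian_channel(TIMES, 5.0, sigma, 1000.0, floor=1.0)})
        assert detect_peaks(run) == []

    def test_pure_noise_rarely_yields_peaks(self):
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            run = make_run(TIMES, {55: g.poisson(5.0, TIMES.size).astype(float)})
            hits += bool(detect_peaks(run))
        assert hits <= 1  # >= 95 % of seeds clean

    def test_area_matches_gaussian_area(self):
        height, sigma_s = 1000.0, 2.5
        run = make_run(TIMES, {55: gaussian_channel(TIMES, 5.0, sigma_s, height)})
        p = detect_peaks(run)[0]
        true_area = height * sigma_s * np.sqrt(2 * np.pi)
        assert p.area == pytest.approx(true_area, rel=0.05)

    def test_short_run_returns_empty(self):
        t = np.array([1.0, 1.01])
        run = make_run(t, {55: np.array([10.0, 12.0])})
        assert detect_peaks(run) == []

    def test_prefilter_intensity_gate(self):
        run = make_run(TIMES, {55: gaussian_channel(TIMES, 5.0, 2.5, 90.0, floor=1.0)})
        assert detect_peaks(run) == []  # never reaches prefilter_I = 100
        assert detect_peaks(run, DetectionParams(prefilter_I=20.0)) != []

    def test_peak_count_monotone_in_sn_threshold(self):
        g = np.random.default_rng(3)
        ch = g.poisson(4.0, TIMES.size).astype(float)
        for rt0, h in [(3.0, 400.0), (5.0, 150.0), (7.0, 800.0)]:
            ch += gaussian_channel(TIMES, rt0, 2.5, h)
        run = make_run(TIMES, {55: ch})
        counts = [
            len(detect_peaks(run, DetectionParams(sn_threshold=s, prefilter_I=50.0)))
            for s in (2, 6, 50, 500)
        ]
        assert counts == sorted(counts, reverse=True)


def _study_peaks(recipe):
    runs, truth = simulate_study(recipe)
    peaks = []
    for run in runs:
        peaks.extend(detect_peaks(run))
    return runs, truth, peaks


class TestCorrectRt:
    def test_aligned_samples_identity_warp(self):
        design = small_design(n_vines=4)
        recipe = small_recipe(
            compounds=[small_compound("A", 800), small_compound("B", 950), small_compound("C", 1100)],
            design=design,
        )
        runs, _, peaks = _study_peaks(recipe)
        warps, corrected, _ = correct_rt(peaks, n_runs=len(runs))
        for w in warps.values():
            grid = np.linspace(1.5, 9.0, 50)
            assert np.max(np.abs(w(grid) - grid)) < 1.0 / 120.0

    def test_constant_shift_recovered(self):
        design = small_design(n_vines=4)
        recipe = small_recipe(
            compounds=[small_compound(f"c{i}", 760 + 60 * i) for i in range(7)],
            design=design,
        )
        runs, _, peaks = _study_peaks(recipe)
        shifted_id = runs[0].meta.run_id
        shifted = [
            features.Peak(p.run_id, p.mz, p.rt + 0.1, p.rt_lo + 0.1, p.rt_hi + 0.1, p.area, p.height, p.sn)
            if p.run_id == shifted_id
            else p
            for p in peaks
        ]
        warps, corrected, diag = correct_rt(shifted, n_runs=len(runs))
        errs = [
            abs(c.rt - p.rt)
            for c, p in zip(corrected, peaks)
            if p.run_id == shifted_id
        ]
        assert np.median(errs) < 0.01  # shift of 0.1 min recovered within 10 %

    def test_linear_drift_reduced(self):
        design = small_design(n_vines=4)
        recipe = small_recipe(
            compounds=[small_compound(f"c{i}", 760 + 60 * i) for i in range(7)],
            design=design,
        )
        runs, _, peaks = _study_peaks(recipe)
        drifted = []
        rates = {r.meta.run_id: 0.005 * k for k, r in enumerate(runs)}  # 0.5 %/min
        for p in peaks:
            f = rates[p.run_id]
            drifted.append(
                features.Peak(p.run_id, p.mz, p.rt * (1 + f), p.rt_lo * (1 + f), p.rt_hi * (1 + f), p.area, p.height, p.sn)
            )
        _, corrected, diag = correct_rt(drifted, n_runs=len(runs))
        assert (diag["mad_after_s"] <= diag["mad_before_s"] + 1e-9).all()
        # post-warp cross-sample spread shrinks
        def spread(ps):
            by = {}
            for p in ps:
                by.setdefault(p.mz, []).append(p.rt)
            return np.mean([np.std(v) for v in by.values() if len(v) > 2])
        assert spread(corrected) < spread(drifted)

    def test_warps_strictly_monotone(self):
        design = small_design(n_vines=3)
        recipe = small_recipe(
            compounds=[small_compound(f"c{i}", 760 + 80 * i) for i in range(5)],
            design=design,
            rt_drift_sd=0.02,
            noise_floor=2.0,
        )
        runs, _, peaks = _study_peaks(recipe)
        warps, _, _ = correct_rt(peaks, n_runs=len(runs))
        grid = np.linspace(0.5, 11.0, 500)
        for w in warps.values():
            assert np.all(np.diff(w(grid)) > 0)


class TestGrouping:
    def test_single_compound_single_feature(self):
        design = small_design(n_vines=4)
        recipe = small_recipe(compounds=[small_compound()], design=design, internal_standards=[])
        runs, _, peaks = _study_peaks(recipe)
        feats = group_peaks(peaks, design)
        assert len(feats) == 3  # one feature per spectrum ion
        assert all(len(f.intensity) == len(design) for f in feats)

    def test_minfrac_boundary_inclusive(self):
        # peak in 1 of 4 runs; its class has 2 runs -> fraction 1/2 >= 0.5 kept
        design = small_design(n_vines=2, rootstocks=("Own", "1103P"))
        peaks = [features.Peak(design[0].run_id, 55, 5.0, 4.9, 5.1, 100.0, 50.0, 10.0)]
        feats = group_peaks(peaks, design, GroupingParams(minfrac=0.5))
        assert len(feats) == 1
        assert group_peaks(peaks, design, GroupingParams(minfrac=0.51)) == []

    def test_two_compounds_same_mz_30s_apart(self):
        design = small_design(n_vines=2)
        peaks = []
        for m in design:
            peaks.append(features.Peak(m.run_id, 55, 5.0, 4.9, 5.1, 100.0, 50.0, 10.0))
            peaks.append(features.Peak(m.run_id, 55, 5.5, 5.4, 5.6, 80.0, 40.0, 10.0))
        feats = group_peaks(peaks, design)
        assert len(feats) == 2

    def test_tie_break_largest_area(self):
        design = small_design()
        rid = design[0].run_id
        peaks = [
            features.Peak(rid, 55, 5.00, 4.9, 5.1, 100.0, 50.0, 10.0),
            features.Peak(rid, 55, 5.01, 4.9, 5.1, 300.0, 60.0, 10.0),
            features.Peak(design[1].run_id, 55, 5.0, 4.9, 5.1, 90.0, 45.0, 10.0),
        ]
        feats = group_peaks(peaks, design)
        assert len(feats) == 1
        assert feats[0].intensity[rid] == 300.0

    def test_feature_count_monotone_in_minfrac(self):
        recipe = small_recipe(
            compounds=[small_compound(f"c{i}", 780 + 70 * i, cv=0.3) for i in range(5)],
            design=small_design(n_vines=3),
            noise_floor=3.0,
            seed=9,
        )
        runs, _, peaks = _study_peaks(recipe)
        counts = [
            len(group_peaks(peaks, recipe.design, GroupingParams(minfrac=f)))
            for f in (0.1, 0.5, 0.9, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestFillAndAverage:
    def test_complete_feature_unchanged(self):
        design = small_design(n_vines=2)
        recipe = small_recipe(compounds=[small_compound()], design=design, internal_standards=[])
        runs, _, peaks = _study_peaks(recipe)
        feats = group_peaks(peaks, design)
        filled = fill_missing(feats, runs)
        for f0, f1 in zip(feats, filled):
            assert f0.intensity == f1.intensity

    def test_missing_sample_filled_near_truth(self):
        design = small_design(n_vines=2)
        recipe = small_recipe(compounds=[small_compound()], design=design, internal_standards=[])
        runs, truth, peaks = _study_peaks(recipe)
        feats = group_peaks(peaks, design)
        target = [f for f in feats if f.mzmed == 43][0]
        victim = design[0].run_id
        removed = dict(target.intensity)
        true_area = removed.pop(victim)
        target.intensity = removed
        target.detected.discard(victim)
        filled = fill_missing([target], runs)[0]
        assert filled.intensity[victim] == pytest.approx(true_area, rel=0.30)

    def test_no_signal_filled_with_floor(self):
        design = small_design(n_vines=2)
        recipe = small_recipe(compounds=[small_compound()], design=design, internal_standards=[])
        runs, _, peaks = _study_peaks(recipe)
        f = features.Feature("M200T5.00", 200, 5.0, 4.9, 5.1, {}, set())
        filled = fill_missing([f], runs, noise_floor=1.0)[0]
        assert all(v > 0 for v in filled.intensity.values())

    def test_average_of_duplicate_injections(self):
        design = small_design(injections=2)
        f = features.Feature(
            "M55T5.00",
            55,
            5.0,
            4.9,
            5.1,
            {design[0].run_id: 100.0, design[1].run_id: 120.0, design[2].run_id: 80.0, design[3].run_id: 80.0},
            {design[0].run_id, design[1].run_id, design[2].run_id},
        )
        out = average_technical_replicates([f], design)[0]
        assert out.intensity[design[0].sample_id] == pytest.approx(110.0)
        assert out.intensity[design[2].sample_id] == pytest.approx(80.0)

    def test_single_injection_unchanged(self):
        design = small_design()
        f = features.Feature("M55T5.00", 55, 5.0, 4.9, 5.1, {design[0].run_id: 42.0, design[1].run_id: 7.0}, set())
        out = average_technical_replicates([f], design)[0]
        assert out.intensity == {design[0].sample_id: 42.0, design[1].sample_id: 7.0}

    def test_biological_column_count(self):
        design = small_design(n_vines=3, injections=2, rootstocks=("Own", "1103P"), irrigations=("Full", "RDI"))
        recipe = small_recipe(compounds=[small_compound()], design=design, internal_standards=[])
        runs, _, peaks = _study_peaks(recipe)
        feats = group_peaks(peaks, design)
        feats = fill_missing(feats, runs)
        out = average_technical_replicates(feats, design)
        n_bio = len({m.sample_id for m in design})
        assert all(len(f.intensity) == n_bio for f in out)


class TestEndToEndRecovery:
    def test_planted_compounds_recovered_noise_free(self):
        design = small_design(n_vines=3)
        compounds = [small_compound(f"c{i}", 770 + 75 * i, base=50.0 * (i + 1), cv=0.2) for i in range(6)]
        recipe = small_recipe(compounds=compounds, design=design, seed=4)
        runs, truth, peaks = _study_peaks(recipe)
        warps, corrected, _ = correct_rt(peaks, n_runs=len(runs))
        feats = group_peaks(corrected, design)
        feats = fill_missing(feats, runs, warps)
        out = average_technical_replicates(feats, design)
        for c in compounds:
            rt_true = synthio.ri_to_rt(c.true_ri, recipe.ladder)
            mine = [f for f in out if abs(f.rtmed - rt_true) * 60.0 <= 2.0 and f.mzmed == 43]
            assert mine, f"{c.name} lost"
            f = max(mine, key=lambda f: np.mean(list(f.intensity.values())))
            tr = truth.loc[c.name]
            vals = np.array([f.intensity[s] for s in tr.index])
            r = np.corrcoef(vals, tr.values.astype(float))[0, 1]
            assert r > 0.99
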