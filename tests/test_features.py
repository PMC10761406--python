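"""Feature detection, carbon estimation, MS2 alignment, blank correction."""

import numpy as np
import pytest

from conftest import make_gaussian_run, match_feature
from fluoroscreen import features as feat
from fluoroscreen import synthdata
from fluoroscreen.features import Feature, FeatureFinderParams


class TestDetectFeatures:
    def test_recovers_all_planted_peaks(self, full_noise_free,
                                        full_noise_free_features):
        truth = full_noise_free.truth
        det = full_noise_free_features
        for _, row in truth.iterrows():
            hits = match_feature(det, row.mz, row.rt)
            assert len(hits) == 1, f"{row.formula} at {row.mz:.4f}"
            f = hits[0]
            assert abs(f.mz - row.mz) / row.mz < 5e-6  # 5 ppm
            assert abs(f.rt - row.rt) < 0.05
        assert len(det) == len(truth)  # no duplicates, no spurious features

    def test_apex_intensity_ratio_matches_planted_carbon(
            self, full_noise_free, full_noise_free_features):
        truth = full_noise_free.truth
        for _, row in truth.iterrows():
            f = match_feature(full_noise_free_features, row.mz, row.rt)[0]
            ratio = f.intensity_M1 / f.intensity_M
            assert ratio == pytest.approx(row.carbon * 0.011145, rel=0.02)

    def test_peak_without_isotope_trace_rejected(self):
        run = make_gaussian_run([
            {"mz": 400.0, "rt": 1.5, "amp": 1e5, "m1_ratio": 0.1},
            {"mz": 500.0, "rt": 2.0, "amp": 1e5},  # no M+1 trace
        ])
        det = feat.detect_features(run)
        assert len(match_feature(det, 400.0, 1.5)) == 1
        assert len(match_feature(det, 500.0, 2.0)) == 0

    def test_narrow_spike_rejected_by_fwhm(self):
        # sigma 0.005 min -> FWHM ~ 0.7 s, below the 1 s floor
        run = make_gaussian_run([
            {"mz": 400.0, "rt": 1.5, "amp": 1e5, "m1_ratio": 0.1},
            {"mz": 500.0, "rt": 2.0, "amp": 1e5, "m1_ratio": 0.1,
             "sigma": 0.005},
        ])
        det = feat.detect_features(run)
        assert len(match_feature(det, 400.0, 1.5)) == 1
        assert len(match_feature(det, 500.0, 2.0)) == 0

    def test_below_threshold_not_seeded(self):
        run = make_gaussian_run([
            {"mz": 400.0, "rt": 1.5, "amp": 1500, "m1_ratio": 0.1},
        ])
        assert feat.detect_features(run) == []

    def test_features_sorted_by_area(self, full_noise_free_features):
        areas = [f.area for f in full_noise_free_features]
        assert areas == sorted(areas, reverse=True)

    def test_requires_three_ms1_scans(self):
        run = make_gaussian_run([{"mz": 400.0, "rt": 0.0, "amp": 1e5}],
                                rt_max=0.02)
        with pytest.raises(ValueError, match="MS1"):
            feat.detect_features(run)


class TestEstimateCarbon:
    @pytest.mark.parametrize("ratio,expected", [
        (0.08916, 8.0),
        (0.011145, 1.0),
    ])
    def test_exact_on_constructed_ratios(self, ratio, expected):
        f = Feature(mz=400.0, rt=1.0, area=1.0, intensity_M=1e5,
                    intensity_M1=1e5 * ratio)
        assert feat.estimate_carbon(f) == pytest.approx(expected, abs=1e-9)

    def test_no_m1_flags_feature(self):
        f = Feature(mz=400.0, rt=1.0, area=1.0, intensity_M=1e5,
                    intensity_M1=0.0)
        assert feat.estimate_carbon(f) is None
        assert "no_carbon_estimate" in f.flags

    def test_monte_carlo_c12_with_isotope_noise(self):
        """C12 species, 5% multiplicative noise on the isotope ratio:
        the estimator is unbiased and inherits the 5% relative spread
        (SD ~ 0.6 C), so ~95% of replicates land within 2 SD of 12."""
        rng = np.random.default_rng(42)
        reps = 400
        ests = []
        for _ in range(reps):
            ratio = 12 * 0.011145 * (1 + rng.normal(0, 0.05))
            f = Feature(mz=600.0, rt=1.0, area=1.0, intensity_M=1e6,
                        intensity_M1=1e6 * ratio)
            feat.estimate_carbon(f)
            ests.append(f.carbon_est)
        ests = np.array(ests)
        assert abs(ests.mean() - 12) < 0.1
        assert 0.45 < ests.std() < 0.75
        assert np.mean(np.abs(ests - 12) <= 1.2) >= 0.93


class TestAlignMs2:
    def test_highest_precursor_intensity_wins(self):
        run = make_gaussian_run(
            [{"mz": 400.0, "rt": 1.5, "amp": 1e5, "m1_ratio": 0.1}],
            ms2=[
                {"rt": 1.49, "precursor_mz": 400.001,
                 "precursor_intensity": 1e4, "peaks": [(119.0, 1e4)]},
                {"rt": 1.51, "precursor_mz": 400.002,
                 "precursor_intensity": 1e5, "peaks": [(169.0, 1e4)]},
            ])
        det = feat.detect_features(run)
        assignments = feat.align_ms2(det, run)
        spec = run.spectra[assignments[0]]
        assert spec.precursor_intensity == pytest.approx(1e5)

    def test_mz_tolerance_respected(self):
        run = make_gaussian_run(
            [{"mz": 400.0, "rt": 1.5, "amp": 1e5, "m1_ratio": 0.1}],
            ms2=[{"rt": 1.5, "precursor_mz": 400.006,
                  "precursor_intensity": 1e4, "peaks": [(119.0, 1e4)]}])
        det = feat.detect_features(run)
        assert feat.align_ms2(det, run) == {}
        assert det[0].ms2_index is None

    def test_ground_truth_assignment(self, full_noise_free,
                                     full_noise_free_features):
        run = full_noise_free.run
        det = list(full_noise_free_features)
        feat.align_ms2(det, run)
        truth = full_noise_free.truth
        for _, row in truth[truth.has_ms2].iterrows():
            f = match_feature(det, row.mz, row.rt)[0]
            assert f.ms2_index is not None
            spec = run.spectra[f.ms2_index]
            assert spec.precursor_mz == pytest.approx(row.mz, abs=1e-6)


class TestBlankCorrect:
    def _f(self, mz, rt, area):
        return Feature(mz=mz, rt=rt, area=area, intensity_M=area)

    def test_fold_change_rule(self):
        blank = [self._f(400.0, 2.0, 1e5)]
        kept = feat.blank_correct(
            [self._f(400.0005, 2.01, 1e6),   # 10-fold: kept
             self._f(400.0005, 2.02, 2e5)],  # 2-fold: removed
            blank)
        assert len(kept) == 1 and kept[0].area == 1e6

    def test_tolerances(self):
        blank = [self._f(400.0, 2.0, 1e5)]
        sample = [self._f(400.0030, 2.0, 1e5),  # 3 mDa off: kept
                  self._f(400.0, 2.15, 1e5)]    # 0.15 min off: kept
        assert len(feat.blank_correct(sample, blank)) == 2

    def test_empty_blank_warns_and_passes_through(self):
        sample = [self._f(400.0, 2.0, 1e5)]
        with pytest.warns(UserWarning, match="blank"):
            assert feat.blank_correct(sample, []) == sample

    def test_exact_contaminant_removal(self):
        """50 shared contaminants + 50 sample-only: exactly the 50
        sample-only features survive."""
        rng = np.random.default_rng(0)
        mzs = 200 + 600 * rng.random(100)
        rts = 1 + 8 * rng.random(100)
        sample = [self._f(m, t, 1e5) for m, t in zip(mzs, rts)]
        blank = [self._f(m, t, 0.9e5) for m, t in zip(mzs[:50], rts[:50])]
        kept = feat.blank_correct(sample, blank)
        assert kept == sample[50:]
        assert all("blank_removed" in f.flags for f in sample[:50])

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(1)
        blank = [self._f(300 + i, 2.0, 1e5) for i in range(20)]
        sample = [self._f(300 + i + rng.normal(0, 1e-4), 2.0, 2e5)
                  for i in range(40)]
        kept1 = feat.blank_correct(sample, blank)
        kept2 = feat.blank_correct(kept1, blank)
        assert kept1 == kept2
        kept3 = feat.blank_correct(sample, list(reversed(blank)))
        assert kept1 == kept3

    def test_pipeline_ground_truth(self, full_noise_free,
                                   full_noise_free_features):
        """Blank correction removes exactly the planted shared
        contaminants on the noise-free full preset."""
        truth = full_noise_free.truth
        blank_feats = feat.detect_features(full_noise_free.blank_run)
        det = list(full_noise_free_features)
        kept = feat.blank_correct(det, blank_feats)
        removed_mz = {round(f.mz, 3) for f in det if "blank_removed" in f.flags}
        expected = {round(m, 3) for m in truth[truth.in_blank].mz}
        assert removed_mz == expected
        assert len(kept) == len(truth) - truth.in_blank.sum()
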