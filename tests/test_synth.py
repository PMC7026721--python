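"""Synthetic generator: determinism, calibration, ground truth, reader model."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from angioquant.records import ImageRecord
from angioquant.stats import auc_mann_whitney
from angioquant.synth import (
    ReaderModelParams,
    SynthParams,
    generate_cohort,
    generate_image,
    make_centerline,
    sample_diameters,
    simulate_binormal_panel,
    simulate_reader_scores,
)
from angioquant.tortuosity import distance_metric, resample_centerline, sum_of_angles


class TestMakeCenterline:
    def test_zero_target_is_collinear(self):
        cl = make_centerline((0, 0, 0), (1, 0, 0), 1.0, 0.0, 0.05, seed=1)
        assert sum_of_angles(cl) == 0.0
        assert distance_metric(cl) == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        a = make_centerline((0, 0, 0), (0, 1, 0), 2.0, 3.0, 0.05, seed=9)
        b = make_centerline((0, 0, 0), (0, 1, 0), 2.0, 3.0, 0.05, seed=9)
        np.testing.assert_array_equal(a.points, b.points)

    def test_step_spacing(self):
        cl = make_centerline((0, 0, 0), (1, 0, 0), 2.0, 3.0, 0.05, seed=3)
        seg = np.linalg.norm(np.diff(cl.points, axis=0), axis=1)
        assert np.allclose(seg, 0.05, atol=1e-12)

    def test_realized_soam_matches_target(self):
        """Monte-Carlo calibration: 200 vessels at 3.6 rad/mm land within 10%."""
        vals = [
            sum_of_angles(resample_centerline(
                make_centerline((0, 0, 0), (1, 0, 0), 3.0, 3.6, 0.05, seed=s)
            ))
            for s in range(200)
        ]
        assert np.mean(vals) == pytest.approx(3.6, rel=0.10)

    def test_realized_soam_monotone_in_target(self):
        means = []
        for target in (1.0, 2.5, 4.0):
            vals = [
                sum_of_angles(make_centerline((0, 0, 0), (1, 0, 0), 3.0, target, 0.05, seed=s))
                for s in range(40)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            make_centerline((0, 0, 0), (1, 0, 0), 1.0, 3.0, step=0.0)
        with pytest.raises(ValueError):
            make_centerline((0, 0, 0), (1, 0, 0), -1.0, 3.0, step=0.05)
        with pytest.raises(ValueError):
            make_centerline((0, 0, 0), (1, 0, 0), 0.1, 3.0, step=0.05)


class TestDiameters:
    def test_truncation_bounds(self):
        d = sample_diameters(SynthParams(), 1000, 0)
        assert d.min() >= 0.8 and d.max() <= 8.2

    def test_median_near_target(self):
        d = sample_diameters(SynthParams(), 1000, 1)
        assert abs(np.median(d) - 2.3) < 0.4

    def test_skewed_toward_small(self):
        d = sample_diameters(SynthParams(), 1000, 2)
        assert np.mean(d < 3.0) > 0.5


class TestGenerateImage:
    def test_control_has_only_background(self, small_params):
        rec = generate_image(small_params, "control", seed=0)
        assert set(rec.truth_membership.values()) == {"background"}

    def test_tumor_cluster_contained_in_sphere(self, small_params):
        rec = generate_image(small_params, "tumor", 5.0, seed=1)
        member_ids = {k for k, v in rec.truth_membership.items() if v == "cluster"}
        assert member_ids
        for v in rec.vessels:
            if v.vessel_id in member_ids:
                dist = np.linalg.norm(v.centerline.points - rec.tumor_center, axis=1)
                assert dist.max() <= 2.5 + 1e-9

    def test_tumor_requires_diameter(self, small_params):
        with pytest.raises(ValueError):
            generate_image(small_params, "tumor", None, seed=0)

    def test_oversized_diameter_rejected(self, small_params):
        with pytest.raises(ValueError):
            generate_image(small_params, "tumor", 100.0, seed=0)

    def test_cluster_vessels_more_tortuous_than_background(self, small_params):
        """Across many tumor images the neovessel cluster dominates in SOAM."""
        diffs = []
        for s in range(40):
            rec = generate_image(small_params, "tumor", 4.0, seed=s)
            by = {"cluster": [], "background": []}
            for v in rec.vessels:
                if v.soam is not None:
                    by[rec.truth_membership[v.vessel_id]].append(v.soam)
            diffs.append(np.mean(by["cluster"]) - np.mean(by["background"]))
        from scipy.stats import ttest_1samp

        res = ttest_1samp(diffs, 0.0, alternative="greater")
        assert res.pvalue < 0.01


class TestGenerateCohort:
    def test_counts_and_labels(self, small_params):
        cohort = generate_cohort(small_params)
        assert len(cohort) == 7
        assert sum(r.is_tumor for r in cohort) == 4

    def test_all_diameters_within_bounds(self, small_params):
        cohort = generate_cohort(small_params)
        for rec in cohort:
            if rec.is_tumor:
                assert 0.8 <= rec.diameter_mm <= 8.2

    def test_reproducible_under_seed(self, small_params):
        a = generate_cohort(small_params)
        b = generate_cohort(small_params)
        for ra, rb in zip(a, b):
            assert ra.image_id == rb.image_id
            np.testing.assert_array_equal(
                ra.vessels[0].centerline.points, rb.vessels[0].centerline.points
            )

    def test_image_level_soam_calibration(self, default_cohort):
        """Group mean SOAM lands within 10% of the configured targets."""
        from angioquant.tortuosity import summarize_image

        means = {"tumor": [], "control": []}
        for rec in default_cohort:
            means[rec.label].append(summarize_image(rec.vessels, rec.image_id).mean_soam)
        assert np.mean(means["control"]) == pytest.approx(3.09, rel=0.10)
        assert np.mean(means["tumor"]) == pytest.approx(3.61, rel=0.10)
        assert np.mean(means["tumor"]) > np.mean(means["control"])


class TestReaderModel:
    def _cohort(self, n_tumor=31, n_control=17, seed=0):
        d = sample_diameters(SynthParams(), n_tumor, seed)
        recs = [
            ImageRecord(image_id=f"T{i}", label="tumor", diameter_mm=float(x))
            for i, x in enumerate(d)
        ]
        recs += [ImageRecord(image_id=f"C{j}", label="control") for j in range(n_control)]
        return recs

    def test_scores_in_range(self):
        panel = simulate_reader_scores(self._cohort(), ReaderModelParams(seed=0))
        assert panel.scores.min() >= 1 and panel.scores.max() <= 6

    def test_null_case_no_separation(self):
        """With zero class and diameter effects the group means agree to MC error."""
        rp = ReaderModelParams(class_separation=0.0, diameter_effect=0.0)
        diffs = []
        for s in range(100):
            panel = simulate_reader_scores(
                self._cohort(seed=s), dataclasses.replace(rp, seed=s)
            )
            diffs.append(
                panel.scores[:, panel.labels].mean() - panel.scores[:, ~panel.labels].mean()
            )
        # image effects (sd 0.8) dominate: per-cohort diff sd ~0.25, so the
        # mean over 100 cohorts has sd ~0.025; 4 sd bounds the null check
        assert abs(np.mean(diffs)) < 0.1
        t = np.mean(diffs) / (np.std(diffs, ddof=1) / np.sqrt(len(diffs)))
        assert abs(t) < 4.0

    def test_diameter_effect_correlates_with_scores(self):
        rhos = []
        for s in range(100):
            cohort = self._cohort(seed=s)
            panel = simulate_reader_scores(cohort, ReaderModelParams(seed=1000 + s))
            tum = panel.labels
            rhos.append(
                spearmanr(panel.diameters[tum], panel.scores[:, tum].mean(0)).statistic
            )
        assert np.mean(rhos) > 0.3
        assert np.mean(np.array(rhos) > 0) > 0.95

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            simulate_reader_scores([], ReaderModelParams())

    def test_cutpoints_validated(self):
        with pytest.raises(ValueError):
            ReaderModelParams(cutpoints=(1.0, 0.5, 2.0, 3.0, 4.0))

    def test_binormal_panel_auc_grows_with_beta(self):
        lo = simulate_binormal_panel(beta=0.05, seed=1)
        hi = simulate_binormal_panel(beta=0.9, seed=1)
        assert auc_mann_whitney(hi.scores.mean(0), hi.labels) > auc_mann_whitney(
            lo.scores.mean(0), lo.labels
        )
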