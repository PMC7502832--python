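"""CoV, bias and RMS reproducibility statistics plus protocol QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mpmtools.phantom import Study, StudyDesign, SiteEffect
from mpmtools.reprostats import (
    RoiSet,
    build_tissue_masks,
    compute_report,
    cov_inter,
    cov_intra,
    qc_check,
    rms_aggregate,
    site_bias,
    subgroup_summary,
)

positive_fields = hnp.arrays(
    float, (4, 4, 4), elements=st.floats(0.5, 100.0, allow_nan=False)
)


class TestCovIntra:
    def test_identical_scans_give_zero(self):
        x = np.random.default_rng(0).uniform(1, 5, (6, 6, 6))
        cov, sigma, mu = cov_intra(x, x.copy())
        assert np.allclose(cov, 0.0)
        np.testing.assert_allclose(mu, x)

    def test_90_110_pair_under_n_minus_1_convention(self):
        cov, sigma, mu = cov_intra(np.array([90.0]), np.array([110.0]))
        assert mu[0] == pytest.approx(100.0)
        assert sigma[0] == pytest.approx(14.142, abs=1e-3)
        assert cov[0] == pytest.approx(0.1414, abs=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(x1=positive_fields, x2=positive_fields, c=st.floats(0.1, 50))
    def test_scale_invariance(self, x1, x2, c):
        cov, _, _ = cov_intra(x1, x2)
        cov_scaled, _, _ = cov_intra(c * x1, c * x2)
        np.testing.assert_allclose(cov_scaled, cov, rtol=1e-9)

    def test_nonpositive_mean_masked(self):
        cov, _, _ = cov_intra(np.array([1.0, -3.0]), np.array([1.0, 1.0]))
        assert np.isfinite(cov[0]) and np.isnan(cov[1])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cov_intra(np.ones((3, 3, 3)), np.ones((4, 4, 4)))


class TestCovInter:
    def test_identical_maps_give_zero(self):
        x = np.random.default_rng(1).uniform(1, 5, (5, 5, 5))
        cov, _, _ = cov_inter([x] * 12)
        assert np.allclose(cov, 0.0)

    def test_two_map_case_equals_cov_intra(self):
        rng = np.random.default_rng(2)
        x1, x2 = rng.uniform(1, 5, (2, 5, 5, 5))
        np.testing.assert_allclose(cov_inter([x1, x2])[0], cov_intra(x1, x2)[0])

    def test_fewer_than_two_maps_rejected(self):
        with pytest.raises(ValueError):
            cov_inter([np.ones((3, 3, 3))])


class TestSiteBias:
    def test_equal_sites_give_zero(self):
        mu = np.full((4, 4, 4), 2.0)
        deltas = site_bias({"A": mu, "B": mu.copy(), "C": mu.copy()})
        for d in deltas.values():
            assert np.allclose(d, 0.0)

    def test_five_percent_offset(self):
        deltas = site_bias({"A": np.full((2, 2, 2), 1.05),
                            "B": np.full((2, 2, 2), 0.95)})
        assert np.allclose(deltas["A"], 0.05)
        assert np.allclose(deltas["B"], -0.05)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(mus=st.lists(positive_fields, min_size=2, max_size=5))
    def test_mean_over_sites_is_zero_voxelwise(self, mus):
        deltas = site_bias({str(i): m for i, m in enumerate(mus)})
        total = np.mean(np.stack(list(deltas.values())), axis=0)
        np.testing.assert_allclose(total, 0.0, atol=1e-9)

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            site_bias({"A": np.ones((2, 2, 2))})


class TestRmsAggregate:
    def test_constant_field(self):
        assert rms_aggregate(np.full((3, 3, 3), -2.5)) == pytest.approx(2.5)

    def test_three_four_example(self):
        assert rms_aggregate(np.array([3.0, 4.0])) == pytest.approx(3.5355, abs=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(x=hnp.arrays(float, (30,), elements=st.floats(-50, 50)))
    def test_rms_dominates_absolute_mean(self, x):
        assert rms_aggregate(x) >= abs(x.mean()) - 1e-12

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rms_aggregate(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool))


class TestTissueMasks:
    def test_identical_maps_equal_single_map_threshold(self, ground_truth):
        wm = ground_truth.probabilities["WM"]
        rois = build_tissue_masks({"WM": [wm, wm.copy(), wm.copy()]}, 0.95)
        np.testing.assert_array_equal(rois["WM"], wm > 0.95)

    def test_masks_erode_label_boundaries(self, ground_truth):
        rois = build_tissue_masks(
            {t: [ground_truth.probabilities[t]] for t in ("GM", "WM")}, 0.95)
        for tissue in ("GM", "WM"):
            mask = rois[tissue]
            labels = ground_truth.tissue_mask(tissue)
            assert mask.any()
            assert np.all(labels[mask])          # strictly inside the tissue
            assert mask.sum() < labels.sum()     # boundary voxels dropped

    def test_impossible_threshold_names_it(self, ground_truth):
        with pytest.raises(ValueError, match="1.0"):
            build_tissue_masks({"WM": [ground_truth.probabilities["WM"]]}, 1.0)

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            build_tissue_masks({"WM": [np.full((4, 4, 4), 1.2)]}, 0.5)


def _toy_report(noise=0.0, sites=("A", "B", "C"), seed=0, biased_site=None):
    rng = np.random.default_rng(seed)
    base = rng.uniform(1, 3, (8, 8, 8))
    maps = {}
    for subject in (1, 2):
        for site in sites:
            factor = 1.1 if site == biased_site else 1.0
            for scan in (1, 2):
                maps[("MT", subject, site, scan)] = (
                    base * factor + noise * rng.standard_normal(base.shape)
                )
    return compute_report(maps, ["MT"], [1, 2], list(sites)), maps


class TestReportAndSubgroups:
    def test_noiseless_no_site_effect_study_is_all_zero(self):
        report, _ = _toy_report(noise=0.0)
        for f in report.cov_intra_fields.values():
            assert np.allclose(f, 0.0, atol=1e-12)
        for f in report.cov_inter_fields.values():
            assert np.allclose(f, 0.0, atol=1e-12)
        for f in report.bias_fields.values():
            assert np.allclose(f, 0.0, atol=1e-12)

    def test_noise_monotonically_raises_intra_cov(self):
        medians = []
        for noise in (0.01, 0.05, 0.2):
            report, _ = _toy_report(noise=noise, seed=3)
            medians.append(np.nanmedian(np.stack(
                list(report.cov_intra_fields.values()))))
        assert medians[0] < medians[1] < medians[2]

    def test_biased_site_shows_in_bias_fields(self):
        report, _ = _toy_report(biased_site="C")
        delta_c = report.bias_fields[("MT", 1, "C")]
        assert np.nanmedian(delta_c) > 0.05

    def test_subgroup_rms_composition(self):
        # full-study RMS^2 equals the count-weighted mean of subgroup RMS^2
        report, _ = _toy_report(noise=0.05, seed=4)
        rois = RoiSet({"all": np.ones((8, 8, 8), bool)})
        table = subgroup_summary(
            report, {"ab": ["A", "B"], "c": ["C"], "all": ["A", "B", "C"]}, rois)
        intra = table[table.statistic == "cov_intra"].set_index("group")
        lhs = intra.loc["all", "rms"] ** 2 * intra.loc["all", "n"]
        rhs = (intra.loc["ab", "rms"] ** 2 * intra.loc["ab", "n"]
               + intra.loc["c", "rms"] ** 2 * intra.loc["c", "n"])
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_noisier_vendor_subgroup_has_larger_cov(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(1, 3, (8, 8, 8))
        maps = {}
        for subject in (1,):
            for site, noise in (("A", 0.01), ("B", 0.01), ("P", 0.2)):
                for scan in (1, 2):
                    maps[("MT", subject, site, scan)] = (
                        base + noise * rng.standard_normal(base.shape))
        report = compute_report(maps, ["MT"], [1], ["A", "B", "P"])
        rois = RoiSet({"all": np.ones((8, 8, 8), bool)})
        table = subgroup_summary(report, {"quiet": ["A", "B"], "loud": ["P"]},
                                 rois)
        intra = table[table.statistic == "cov_intra"].set_index("group")["rms"]
        assert intra["loud"] > 3 * intra["quiet"]

    def test_unknown_site_in_grouping_rejected(self):
        report, _ = _toy_report()
        rois = RoiSet({"all": np.ones((8, 8, 8), bool)})
        with pytest.raises(KeyError, match="XX"):
            subgroup_summary(report, {"bad": ["XX"]}, rois)


class TestQC:
    def _reference(self):
        from mpmtools.pipeline import _reference_protocol_doc

        return _reference_protocol_doc("siemens")

    def test_identical_metadata_is_clean(self, tiny_design):
        meta = Study(tiny_design).session(1, "ZH", 1).meta
        assert qc_check(meta, self._reference()) == []

    def test_te_scaling_detected_with_correct_magnitude(self, tiny_design):
        from mpmtools.phantom import inject_protocol_deviation

        meta = Study(tiny_design).session(1, "ZH", 1).meta
        mutated = inject_protocol_deviation(
            meta, {"protocols.PDw.te_ms": ("scale", 1.04)})
        deviations = qc_check(mutated, self._reference())
        assert len(deviations) == 1
        d = deviations[0]
        assert d.field == "protocols.PDw.te_ms"
        assert d.relative == pytest.approx(0.04, abs=1e-9)

    def test_below_tolerance_deviation_passes(self, tiny_design):
        from mpmtools.phantom import inject_protocol_deviation

        meta = Study(tiny_design).session(1, "ZH", 1).meta
        mutated = inject_protocol_deviation(
            meta, {"protocols.PDw.te_ms": ("scale", 1.004)})
        assert qc_check(mutated, self._reference(), tolerance=0.01) == []

    def test_all_injected_deviations_detected_no_false_positives(self):
        design = StudyDesign(
            n_subjects=1,
            sites=[SiteEffect("ZH"), SiteEffect("HD")],
            shape=(32, 32, 32), seed=5,
            deviations=[
                {"site": "ZH", "scan": 1,
                 "field": "protocols.PDw.te_ms", "op": "scale", "value": 1.04},
                {"site": "HD", "scan": 2,
                 "field": "calibration.flip_deg", "op": "set", "value": 23.0},
            ],
        )
        study = Study(design)
        flagged = {}
        for subject, site, scan in study.iter_index():
            meta = study.session(subject, site, scan).meta
            devs = qc_check(meta, self._reference())
            if devs:
                flagged[(site, scan)] = [d.field for d in devs]
        assert flagged == {
            ("ZH", 1): ["protocols.PDw.te_ms"],
            ("HD", 2): ["calibration.flip_deg"],
        }
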