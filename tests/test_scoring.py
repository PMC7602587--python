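"""Seven-criterion scoring: boundaries, detectors, truth agreement."""

import numpy as np
import pytest

from mucoct.geometry import ScanGeometry
from mucoct.phantom import (Attenuation, SurfaceFeatureSpec, build_profile,
                            render_bscan)
from mucoct.scoring import (CriteriaScore, ScoringConfig, detect_components,
                            score_basement_membrane, score_bscan,
                            score_from_truth, score_homogeneity,
                            score_surface_integrity, score_surface_profile)
from mucoct.segmentation import segment_bscan


def _lesion_profile(n_lesions_rate, seed_hint=0):
    return build_profile("buccal", overrides={
        "surface_features": (
            SurfaceFeatureSpec("lesion", (80.0, 140.0), (25.0, 35.0),
                               rate_per_mm=n_lesions_rate),),
        "vessel_density_target": 0.0})


class TestSurfaceIntegrity:
    def test_lesion_count_boundary_exact(self, geometry):
        """'intact' holds up to exactly one lesion, flips at two."""
        base = np.full(480, 40)

        def with_notches(centers):
            t = base.copy()
            for c in centers:
                t[c - 10:c + 10] += 6       # 100 um wide, 6 rows deep
            return t

        for centers, label, count in [((), "intact", 0),
                                      ((100,), "intact", 1),
                                      ((100, 250), "with_alterations", 2),
                                      ((100, 250, 400), "with_alterations", 3)]:
            got_label, got_count = score_surface_integrity(with_notches(centers),
                                                           geometry)
            assert (got_label, got_count) == (label, count)

    def test_detector_matches_truth_counts(self, geometry):
        """Detected lesion count equals the generated one on >=90% of seeds."""
        agree = 0
        n = 20
        for seed in range(n):
            bscan, truth = render_bscan(_lesion_profile(0.8), seed=1300 + seed)
            seg = segment_bscan(bscan)
            _, count = score_surface_integrity(seg.surface_trace, geometry)
            agree += count == truth.lesion_count()
        assert agree >= 0.9 * n


class TestSurfaceProfile:
    def _trace_with_bump(self, geometry, diameter_um, amplitude_um, sign):
        from mucoct.phantom import _feature_delta_rows
        base = np.full(geometry.n_columns, 60.0)
        delta = _feature_delta_rows(geometry.n_columns, 240, diameter_um,
                                    amplitude_um / geometry.axial_pixel,
                                    geometry.lateral_pixel_fast)
        return np.round(base + sign * delta).astype(np.int64)

    def test_flat_is_even(self, geometry):
        label, feats = score_surface_profile(np.full(480, 40), geometry)
        assert label == "even" and feats == []

    def test_diameter_boundary_at_200_um(self, geometry):
        """150 um ridge stays 'even'; 400 um ridge is 'uneven' with its
        extent recovered within 2 lateral pixels."""
        label_150, feats = score_surface_profile(
            self._trace_with_bump(geometry, 150, 50, -1), geometry)
        assert label_150 == "even"
        assert feats and feats[0].kind == "ridge"

        label_400, feats = score_surface_profile(
            self._trace_with_bump(geometry, 400, 50, -1), geometry)
        assert label_400 == "uneven"
        ridge = [f for f in feats if f.kind == "ridge"][0]
        assert ridge.diameter_um == pytest.approx(400, abs=2 * 5)

    def test_crypt_detected_concave(self, geometry):
        label, feats = score_surface_profile(
            self._trace_with_bump(geometry, 300, 50, +1), geometry)
        assert label == "uneven"
        assert feats[0].kind == "crypt"


class TestHomogeneity:
    def test_uniform_band_is_homogeneous(self, sublingual_scan,
                                         sublingual_segmentation, geometry):
        bscan, _ = sublingual_scan
        label, regions = score_homogeneity(
            bscan.image, sublingual_segmentation.epithelial_mask, geometry)
        assert label == "homogeneous" and regions == []

    def test_keratin_cap_detected_on_90pct_of_seeds(self, geometry):
        profile = build_profile("hard_palate", overrides={"surface_features": ()})
        hits = 0
        n = 20
        for seed in range(n):
            bscan, truth = render_bscan(profile, seed=1400 + seed)
            seg = segment_bscan(bscan)
            label, regions = score_homogeneity(bscan.image,
                                               seg.epithelial_mask, geometry)
            # anomaly must overlap the truth keratin cap
            if label == "inhomogeneous":
                overlap = any(truth.masks["keratin"]
                              [r["bbox"][0]:r["bbox"][2],
                               r["bbox"][1]:r["bbox"][3]].any()
                              for r in regions)
                hits += overlap
        assert hits >= 0.9 * n

    def test_empty_mask_raises(self, geometry):
        with pytest.raises(ValueError):
            score_homogeneity(np.ones((10, 10)), np.zeros((10, 10), bool),
                              geometry)


class TestBasementMembraneLabel:
    def test_all_found_is_intact(self):
        assert score_basement_membrane(np.array(["found"] * 10, object)) == "intact"

    def test_mostly_absent_is_not_assessable(self):
        status = np.array(["absent"] * 6 + ["found"] * 4, object)
        assert score_basement_membrane(status) == "not_assessable"

    def test_unsharp_majority_is_unsharp(self):
        status = np.array(["unsharp"] * 7 + ["found"] * 3, object)
        assert score_basement_membrane(status) == "unsharp"

    def test_unsharp_columns_count_as_assessable(self):
        """An image whose BM is located everywhere but weakly demarcated is
        'unsharp', not 'not assessable'."""
        status = np.array(["unsharp"] * 10, object)
        assert score_basement_membrane(status) == "unsharp"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            score_basement_membrane(np.array([], object))


class TestComponents:
    def test_truth_mode_passthrough(self, geometry):
        bscan, truth = render_bscan(build_profile("soft_palate_oropharynx"),
                                    seed=1500)
        seg = segment_bscan(bscan)
        kinds, _ = detect_components(bscan.image, seg, geometry, truth=truth)
        expected = set()
        if truth.masks["gland"].any():
            expected.add("salivary_gland")
        assert kinds == expected

    def test_follicle_detected_on_80pct_of_seeds(self, geometry):
        hits = tot = 0
        for seed in range(20):
            bscan, truth = render_bscan(build_profile("tonsil"), seed=600 + seed)
            if not truth.masks["follicle"].any():
                continue
            tot += 1
            kinds, _ = detect_components(bscan.image, segment_bscan(bscan),
                                         geometry)
            hits += "lymphoid_follicle" in kinds
        assert tot >= 10
        assert hits >= 0.8 * tot

    def test_vessel_only_phantom_yields_no_components(self, geometry):
        """Vessels are quantified by the vessel-density criterion, never
        reported as glands/follicles."""
        for seed in range(10):
            bscan, truth = render_bscan(build_profile("sublingual"),
                                        seed=800 + seed)
            assert not truth.masks["gland"].any()
            kinds, _ = detect_components(bscan.image, segment_bscan(bscan),
                                         geometry)
            assert kinds == set()


class TestScoreBscan:
    def test_sublingual_modal_labels(self, sublingual_scan,
                                     sublingual_segmentation):
        bscan, truth = sublingual_scan
        score = score_bscan(bscan, sublingual_segmentation)
        assert score.surface_integrity == "intact"
        assert score.surface_profile == "even"
        assert score.epithelial_homogeneity == "homogeneous"
        assert score.bm_assessment == "intact"

    def test_hard_palate_uneven_and_inhomogeneous_co_occur(self):
        for seed in range(10):
            bscan, truth = render_bscan(build_profile("hard_palate"),
                                        seed=1600 + seed)
            if not any(f.kind == "ridge" and f.diameter_um > 200
                       for f in truth.features):
                continue
            score = score_bscan(bscan, segment_bscan(bscan))
            assert score.surface_profile == "uneven"
            assert score.epithelial_homogeneity == "inhomogeneous"
            return
        pytest.fail("no seed produced a >200 um ridge")

    def test_not_assessable_clears_quantities(self):
        p = build_profile("buccal", overrides={
            "thickness_mean_geom": 500.0, "thickness_sd_geom": 0.0,
            "attenuation": Attenuation(ep=0.006, lp=0.0015),
            "surface_features": ()})
        bscan, _ = render_bscan(p, seed=9)
        score = score_bscan(bscan, segment_bscan(bscan))
        assert score.bm_assessment == "not_assessable"
        assert score.thickness is None
        assert score.vascularization is None

    def test_invariant_enforced(self):
        from mucoct.quantify import VascularizationResult
        with pytest.raises(ValueError):
            CriteriaScore("intact", 0, "even", [], "homogeneous",
                          "not_assessable",
                          vascularization=VascularizationResult(1, 10, 0.1,
                                                                "moderate"))


def test_truth_label_agreement_all_presets(geometry):
    """Detector labels match the truth-implied labels for >=90% of seeds
    per preset and per categorical criterion."""
    from mucoct.phantom import REGION_PRESETS
    n = 10
    for region in sorted(REGION_PRESETS):
        agree = {"surface_integrity": 0, "surface_profile": 0,
                 "epithelial_homogeneity": 0, "bm_assessment": 0}
        for seed in range(n):
            bscan, truth = render_bscan(build_profile(region), seed=1700 + seed)
            det = score_bscan(bscan, segment_bscan(bscan))
            ref = score_from_truth(truth, geometry)
            for k in agree:
                agree[k] += getattr(det, k) == getattr(ref, k)
        for k, v in agree.items():
            assert v >= 0.9 * n, f"{region}/{k}: {v}/{n}"
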