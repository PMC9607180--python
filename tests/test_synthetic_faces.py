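"""Synthetic face generator, pair derivation, and cohort simulation."""

import numpy as np
import pytest

from facedev.deviation_map import absolute_deviation
from facedev.mesh_core import write_stl
from facedev.regional_analysis import summarize_regions
from facedev.synthetic_faces import (
    FACIAL_REGIONS,
    LATERAL_SITES,
    DeviationProfile,
    FaceParams,
    PerturbationSpec,
    cohort_manifest,
    derive_pair,
    generate_face,
    simulate_cohort,
    write_case_bundle,
)

from conftest import TEST_MIN_REGION_VERTICES, TEST_RESOLUTION


class TestGenerateFace:
    def test_deterministic_bytes(self, tmp_path):
        p = FaceParams(resolution=TEST_RESOLUTION)
        for name in ("a", "b"):
            face = generate_face(p, min_region_vertices=TEST_MIN_REGION_VERTICES)
            write_stl(face.mesh, tmp_path / f"{name}.stl")
        assert (tmp_path / "a.stl").read_bytes() == (tmp_path / "b.stl").read_bytes()

    def test_default_resolution_hosts_all_regions(self):
        # full-size check: 23 named regions, each with >= 20 vertices
        face = generate_face(FaceParams())  # resolution 128
        assert len(FACIAL_REGIONS) == 23
        assert set(face.atlas.region_names) == set(FACIAL_REGIONS)
        for region in FACIAL_REGIONS:
            assert len(face.atlas.vertices_in(region)) >= 20

    def test_too_low_resolution_errors(self):
        with pytest.raises(ValueError, match="vertices"):
            generate_face(FaceParams(resolution=30), min_region_vertices=20)

    def test_resolution_floor(self):
        with pytest.raises(ValueError):
            FaceParams(resolution=29)

    def test_left_right_centroids_mirror(self, small_face):
        verts = small_face.mesh.vertices
        for region in ("ala nasi", "orbital region", "oral/labial commisure"):
            cl = verts[small_face.atlas.vertices_in(f"{region} L")].mean(axis=0)
            cr = verts[small_face.atlas.vertices_in(f"{region} R")].mean(axis=0)
            np.testing.assert_allclose(cl * [-1, 1, 1], cr, atol=1e-6)

    def test_landmarks_present_and_finite(self, small_face):
        for name in ("glabella", "temple L", "temple R", "pronasale", "zygion L", "zygion R"):
            assert name in small_face.landmarks
            assert np.isfinite(small_face.landmarks[name]).all()

    def test_lateral_sites_subset_of_regions(self):
        assert set(LATERAL_SITES) <= set(FACIAL_REGIONS)
        assert len(LATERAL_SITES) == 7


class TestDerivePair:
    def test_null_spec_decimation_only(self, null_pair):
        # scan vertices are a strict subset of shell vertices
        field = absolute_deviation(null_pair.scan, null_pair.shell)
        summaries = summarize_regions(
            field, null_pair.scan_atlas, min_vertices=TEST_MIN_REGION_VERTICES
        )
        for s in summaries:
            if s.assessable:
                assert s.p95_mm < 0.3

    def test_resolution_ratio(self, small_face, null_pair):
        ratio = small_face.mesh.n_faces / null_pair.scan.n_faces
        assert 3.0 < ratio < 5.0

    def test_ground_truth_bookkeeping(self, small_face):
        pair = derive_pair(
            small_face,
            PerturbationSpec(region_offsets={"orbital region L": (4.0, 0.1)}),
        )
        assert pair.truth.region_deviation_mm["orbital region L"] == 4.0
        assert set(pair.truth.region_deviation_mm) == set(FACIAL_REGIONS)

    def test_offset_recovered_without_registration(self, small_face):
        # measuring against the unmoved shell recovers the injected mean
        delta = 5.0
        pair = derive_pair(
            small_face,
            PerturbationSpec(region_offsets={"frontal region": (delta, 0.0)}),
        )
        field = absolute_deviation(pair.scan, pair.shell)
        m = pair.scan_atlas.labels == "frontal region"
        measured = field.raw[m & field.valid].mean()
        assert measured == pytest.approx(delta, abs=0.2)

    def test_forehead_crop_removes_top_band(self, small_face):
        crop = 0.3
        pair = derive_pair(small_face, PerturbationSpec(forehead_crop=crop))
        frontal_full = small_face.atlas.vertices_in("frontal region")
        yf = small_face.mesh.vertices[frontal_full, 1]
        cut = yf.max() - crop * (yf.max() - yf.min())
        assert (pair.shell.vertices[:, 1] <= cut + 1e-9).all()

    def test_oversized_offset_errors(self, small_face):
        with pytest.raises(ValueError, match="self-intersect"):
            derive_pair(
                small_face,
                PerturbationSpec(region_offsets={"philtrum": (30.0, 0.0)}),
            )

    def test_unknown_region_errors(self, small_face):
        with pytest.raises(ValueError, match="unknown region"):
            derive_pair(
                small_face, PerturbationSpec(region_offsets={"nowhere": (1.0, 0.0)})
            )

    def test_misalignment_recorded(self, misaligned_pair):
        T = misaligned_pair.truth.transform
        assert not np.allclose(T.rotation, np.eye(3))
        # scan landmarks moved with the scan
        np.testing.assert_allclose(
            misaligned_pair.scan_landmarks["pronasale"],
            T.apply(misaligned_pair.shell_landmarks["pronasale"]),
            atol=1e-9,
        )

    def test_concave_regions_noisier_than_nose_tip(self, small_face):
        # concavity-scaled noise must hit hollows harder than the nose tip
        pair = derive_pair(
            small_face,
            PerturbationSpec(base_noise_sd=0.0, concavity_gain=1.0, seed=3),
        )
        field = absolute_deviation(pair.scan, pair.shell)
        labels = pair.scan_atlas.labels

        def mae(region):
            m = (labels == region) & field.valid
            return field.raw[m].mean()

        # at test resolution the mentolabial groove holds no scan vertex,
        # so compare via the orbital hollows (same convexity class)
        concave = np.mean([mae("orbital region L"), mae("orbital region R")])
        assert concave > mae("apex of nose")

    def test_eyelid_mismatch_hits_orbital(self, small_face):
        pair = derive_pair(small_face, PerturbationSpec(eyelid_mismatch=True))
        field = absolute_deviation(pair.scan, pair.shell)
        labels = pair.scan_atlas.labels
        orbital = (np.isin(labels, ["orbital region L", "orbital region R"])) & field.valid
        cheek = (labels == "buccal region") & field.valid
        assert field.raw[orbital].mean() > field.raw[cheek].mean()
        assert field.raw[orbital].max() > 1.0


class TestSimulateCohort:
    def test_default_composition(self):
        cases = simulate_cohort(seed=0)
        assert len(cases) == 60
        assert sum(c.sex == "M" for c in cases) == 19
        assert sum(c.sex == "F" for c in cases) == 41

    def test_seed_reproducibility(self):
        a = simulate_cohort(seed=5)
        b = simulate_cohort(seed=5)
        for x, y in zip(a, b):
            assert x.spec == y.spec
            assert x.params == y.params
            assert x.interval_days == y.interval_days

    def test_subject_substreams_stable_under_cohort_growth(self):
        small = simulate_cohort(n_men=5, n_women=0, seed=9)
        large = simulate_cohort(n_men=12, n_women=0, seed=9)
        for x, y in zip(small, large):
            assert x.spec == y.spec

    def test_defect_probability_recovered(self):
        # 600 subjects, orbital probability 0.65: injected rate within the
        # 99% binomial CI
        profile = DeviationProfile(region_probs={"orbital region L": 0.65})
        cases = simulate_cohort(n_men=300, n_women=300, profile=profile, seed=2)
        hits = sum("orbital region L" in c.spec.region_offsets for c in cases)
        p_hat = hits / 600
        half = 2.576 * np.sqrt(0.65 * 0.35 / 600)
        assert 0.65 - half <= p_hat <= 0.65 + half

    def test_sex_specific_probabilities(self):
        profile = DeviationProfile(region_probs={"frontal region": (1.0, 0.0)})
        cases = simulate_cohort(n_men=10, n_women=10, profile=profile, seed=3)
        for c in cases:
            has = "frontal region" in c.spec.region_offsets
            assert has == (c.sex == "M")

    def test_interval_metadata_range(self):
        cases = simulate_cohort(seed=1)
        days = [c.interval_days for c in cases]
        assert min(days) >= 0 and max(days) <= 10

    def test_manifest_shape(self):
        cases = simulate_cohort(n_men=3, n_women=4, seed=0)
        m = cohort_manifest(cases)
        assert list(m.columns) == [
            "subject_id", "sex", "interval_days", "expression_ok", "artifact_ok",
        ]
        assert len(m) == 7

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            simulate_cohort(n_men=0, n_women=0)

    def test_case_bundle_write(self, tmp_path):
        profile = DeviationProfile(resolution=TEST_RESOLUTION)
        case = simulate_cohort(n_men=1, n_women=0, profile=profile, seed=4)[0]
        out = write_case_bundle(
            case, tmp_path / case.subject_id, TEST_MIN_REGION_VERTICES
        )
        for name in ("shell.stl", "scan.stl", "landmarks.json", "atlas.csv", "truth.csv"):
            assert (out / name).exists()
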