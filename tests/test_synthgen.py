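"""Synthetic-data generator: point processes, cap meshes, case assembly."""

import numpy as np
import pytest

from synquant.geometry import Window3D, pairwise_min_distance
from synquant import morphometry, synthgen


class TestCSR:
    def test_mean_count_matches_poisson_intensity(self, cube_window):
        # λV = 0.5 × 1000 μm³ = 500
        counts = [synthgen.simulate_csr_pattern(0.5, cube_window, seed=s).n
                  for s in range(200)]
        mean = np.mean(counts)
        se = np.sqrt(500 / 200)
        assert abs(mean - 500) < 4 * se

    def test_seed_determinism(self, cube_window):
        a = synthgen.simulate_csr_pattern(0.5, cube_window, seed=11)
        b = synthgen.simulate_csr_pattern(0.5, cube_window, seed=11)
        np.testing.assert_array_equal(a.points, b.points)

    def test_points_inside_window(self, csr_pattern):
        assert csr_pattern.window.contains(csr_pattern.points).all()

    def test_rejects_bad_inputs(self, cube_window):
        with pytest.raises(ValueError):
            synthgen.simulate_csr_pattern(0.0, cube_window, seed=1)
        with pytest.raises(ValueError):
            Window3D(extents=(0.0, 10.0, 10.0))


class TestHardcore:
    def test_min_pairwise_distance_exhaustive(self, cube_window):
        for s in range(5):
            p = synthgen.simulate_hardcore_pattern(0.5, 250.0, cube_window, seed=s)
            assert pairwise_min_distance(p.points) >= 500.0

    def test_achieves_target_count(self, cube_window):
        p = synthgen.simulate_hardcore_pattern(0.5, 250.0, cube_window, seed=3)
        assert p.n == round(0.5 * cube_window.volume_um3)

    def test_zero_radius_is_binomial(self, cube_window):
        p = synthgen.simulate_hardcore_pattern(0.5, 0.0, cube_window, seed=3)
        assert p.n == 500
        assert cube_window.contains(p.points).all()

    def test_saturation_raises_with_achieved_count(self):
        w = Window3D(extents=(1_000.0, 1_000.0, 1_000.0))
        with pytest.raises(synthgen.RSASaturationError) as err:
            synthgen.simulate_hardcore_pattern(
                50.0, 400.0, w, seed=1, max_attempts=5_000)
        assert err.value.achieved < err.value.target

    def test_determinism(self, cube_window):
        a = synthgen.simulate_hardcore_pattern(0.3, 200.0, cube_window, seed=9)
        b = synthgen.simulate_hardcore_pattern(0.3, 200.0, cube_window, seed=9)
        np.testing.assert_array_equal(a.points, b.points)


class TestCapMesh:
    def test_flat_limit_is_planar_disc(self, flat_mesh):
        assert morphometry.mesh_area(flat_mesh) == pytest.approx(50_000.0, rel=1e-9)
        assert morphometry.sas_curvature(flat_mesh) == pytest.approx(0.0, abs=1e-6)

    def test_hemisphere_projects_to_half_area(self):
        m = synthgen.synthesize_sas_mesh(10_000.0, 0.5, resolution=2_000, seed=2)
        assert morphometry.projected_area(m) == pytest.approx(5_000.0, rel=0.01)

    def test_control_as_working_point(self, cap_mesh):
        # cap with curvature 0.049 has half-angle ≈ 25.7°
        cos_theta = 1 - 2 * 0.049
        assert np.degrees(np.arccos(cos_theta)) == pytest.approx(25.7, abs=0.2)
        assert morphometry.mesh_area(cap_mesh) == pytest.approx(117_800.0, rel=1e-9)
        assert morphometry.sas_curvature(cap_mesh) == pytest.approx(0.049, rel=0.01)

    def test_area_and_curvature_error_decrease_with_resolution(self):
        errs = []
        for res in (100, 400, 1_600):
            m = synthgen.synthesize_sas_mesh(20_000.0, 0.15, resolution=res, seed=4)
            errs.append(abs(morphometry.sas_curvature(m) - 0.15))
        assert errs[0] > errs[1] > errs[2]

    def test_orientation_random_but_reproducible(self):
        a = synthgen.synthesize_sas_mesh(1_000.0, 0.2, seed=1)
        b = synthgen.synthesize_sas_mesh(1_000.0, 0.2, seed=1)
        c = synthgen.synthesize_sas_mesh(1_000.0, 0.2, seed=2)
        np.testing.assert_array_equal(a.vertices, b.vertices)
        assert not np.allclose(a.vertices, c.vertices)

    def test_invalid_curvature_rejected(self):
        with pytest.raises(ValueError):
            synthgen.synthesize_sas_mesh(1_000.0, 1.0, seed=1)
        with pytest.raises(ValueError):
            synthgen.synthesize_sas_mesh(-5.0, 0.1, seed=1)


@pytest.fixture(scope="module")
def case():
    params = synthgen.CaseParams(seed=21, n_stacks=2, artifact_fraction=0.2)
    return synthgen.generate_case(params, case_id="c1", group="control")


class TestGenerateCase:

    def test_structure(self, case):
        assert len(case.stacks) == 2
        for st in case.stacks:
            assert st.pattern.n == len(st.types) == len(st.meshes)

    def test_all_as_when_fraction_one(self):
        p = synthgen.CaseParams(seed=2, n_stacks=1, as_fraction=1.0)
        case = synthgen.generate_case(p)
        assert (case.stacks[0].types == "AS").all()

    def test_artifact_fraction_is_analytic(self, case):
        for st in case.stacks:
            assert st.artifact_fraction == pytest.approx(0.2, rel=1e-9)

    def test_artifacts_do_not_overlap_and_stay_inside(self, case):
        for st in case.stacks:
            arts = st.artifacts
            for i, e in enumerate(arts):
                c = np.asarray(e.center)
                a = np.asarray(e.semiaxes)
                assert np.all(c - a >= st.window.lo - 1e-9)
                assert np.all(c + a <= st.window.hi + 1e-9)
                for f in arts[i + 1:]:
                    cf = np.asarray(f.center)
                    af = np.asarray(f.semiaxes)
                    # disjoint axis-aligned bounding boxes on some axis
                    gap = np.abs(c - cf) - (a + af)
                    assert np.any(gap >= -1e-9)

    def test_synapses_avoid_artifacts(self, case):
        for st in case.stacks:
            for e in st.artifacts:
                assert not e.contains(st.pattern.points).any()

    def test_hardcore_holds_inside_case(self, case):
        for st in case.stacks:
            assert pairwise_min_distance(st.pattern.points) >= 500.0

    def test_determinism(self):
        p = synthgen.CaseParams(seed=33, n_stacks=1)
        a = synthgen.generate_case(p)
        b = synthgen.generate_case(p)
        np.testing.assert_array_equal(a.stacks[0].pattern.points,
                                      b.stacks[0].pattern.points)
        np.testing.assert_array_equal(a.stacks[0].meshes[0].vertices,
                                      b.stacks[0].meshes[0].vertices)

    def test_as_fraction_within_binomial_ci(self):
        p = synthgen.CaseParams(seed=5, n_stacks=4, as_fraction=0.9564,
                                artifact_fraction=0.0)
        case = synthgen.generate_case(p)
        types = np.concatenate([st.types for st in case.stacks])
        frac = (types == "AS").mean()
        se = np.sqrt(0.9564 * (1 - 0.9564) / len(types))
        assert abs(frac - 0.9564) < 4 * se


class TestStudy:
    def test_layout_and_determinism(self):
        params = synthgen.StudyParams(
            n_cases_per_group=2, seed=4,
            control=synthgen.CaseParams(n_stacks=1, seed=0),
            disease=synthgen.CaseParams.alzheimer_defaults(n_stacks=1, seed=0))
        a = synthgen.generate_study(params)
        b = synthgen.generate_study(params)
        assert len(a.cases) == 4
        assert {c.group for c in a.cases} == {"control", "disease"}
        for ca, cb in zip(a.cases, b.cases):
            np.testing.assert_array_equal(ca.thickness_mm, cb.thickness_mm)
        assert all(3 <= c.thickness_mm.shape[0] <= 5 and c.thickness_mm.shape[1] == 3
                   for c in a.cases)


class TestSemithin:
    def test_exact_pixel_tally_matches_request(self):
        img = synthgen.render_semithin((7.17, 0.50, 3.28), image_size=400, seed=1)
        for name, pct in img.exact_fractions.items():
            assert pct == pytest.approx(img.ground_truth[name], abs=1e-9)
        assert img.ground_truth["neuropil"] == pytest.approx(89.05, abs=0.01)

    def test_uniform_neuropil(self):
        img = synthgen.render_semithin((0.0, 0.0, 0.0), image_size=100, seed=1)
        assert (img.labels == 0).all()

    def test_rejects_fractions_summing_to_100(self):
        with pytest.raises(ValueError):
            synthgen.render_semithin((60.0, 30.0, 10.0), image_size=50, seed=1)
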