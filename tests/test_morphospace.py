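"""PCA morphospace, hull occupation, overlaps, ontogenetic vectors."""
import numpy as np
import pandas as pd
import pytest

from hookmorph import (
    Appendage,
    DesignSpec,
    GroupSummary,
    HookShapeParams,
    NormalizedEFD,
    Site,
    SpecimenRecord,
    Stage,
    assemble_matrix,
    eigen_shape,
    estimate_curvature_thickness,
    generate_dataset,
    group_hulls,
    hull_overlap,
    normalize_efd,
    ontogenetic_vectors,
    run_pca,
)
from hookmorph.morphospace import MorphospaceResult, coefficient_columns
from hookmorph.pipeline import analyze_records, records_to_nefs

from ._oracles import brute_force_hull_area


def _dummy_record(i, coeffs, **labels):
    defaults = dict(species=f"sp{i}", stage=Stage.ADULT, site=Site.GILL, appendage=Appendage.P1)
    defaults.update(labels)
    return SpecimenRecord(specimen_id=f"s{i}", shape=NormalizedEFD(coeffs), **defaults)


def _coeffs(n_harmonics, rng=None, jitter=0.0):
    c = np.zeros((n_harmonics, 4))
    c[0, 0] = 1.0
    c[0, 3] = 0.3
    c[1:, :] = 0.01
    if jitter and rng is not None:
        c[1:, :] += jitter * rng.standard_normal((n_harmonics - 1, 4))
    return c


class TestAssembleMatrix:
    def test_sixty_records_at_n20_give_77_columns(self):
        records = [_dummy_record(i, _coeffs(20)) for i in range(60)]
        m = assemble_matrix(records, 20)
        assert m.data.shape == (60, 77)

    def test_low_harmonic_record_named_in_error(self):
        records = [_dummy_record(0, _coeffs(20)), _dummy_record(1, _coeffs(10))]
        with pytest.raises(ValueError, match="s1"):
            assemble_matrix(records, 20)

    def test_truncates_extra_harmonics(self):
        records = [_dummy_record(i, _coeffs(30)) for i in range(3)]
        assert assemble_matrix(records, 10).data.shape == (3, 37)

    def test_constant_first_harmonic_columns_excluded(self):
        cols = coefficient_columns(20)
        assert "a1" not in cols and "b1" not in cols and "c1" not in cols
        assert "d1" in cols and len(cols) == 77


class TestRunPCA:
    def test_identical_shapes_give_zero_eigenvalues(self):
        records = [_dummy_record(i, _coeffs(10)) for i in range(10)]
        res = run_pca(assemble_matrix(records, 10))
        assert np.all(res.eigenvalues == 0.0)

    def test_two_clusters_separate_on_pc1(self, rng):
        records = []
        for i in range(30):
            c = _coeffs(10, rng, jitter=1e-4)
            if i >= 15:
                c[2, 0] += 0.5  # cluster offset along one coefficient
            records.append(_dummy_record(i, c))
        res = run_pca(assemble_matrix(records, 10))
        assert res.variance_fraction[0] > 0.9
        pc1 = res.scores["PC1"].to_numpy()
        lo, hi = sorted([pc1[:15], pc1[15:]], key=lambda v: v.mean())
        assert lo.max() < hi.min()

    def test_reconstruction_property(self, rng):
        records = [_dummy_record(i, _coeffs(8, rng, jitter=0.02)) for i in range(12)]
        m = assemble_matrix(records, 8)
        res = run_pca(m)
        X = m.data.to_numpy()
        approx = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.mean_vector.to_numpy()
        np.testing.assert_allclose(approx, X, atol=1e-8)

    def test_variance_fractions_sum_to_one_sorted(self, rng):
        records = [_dummy_record(i, _coeffs(8, rng, jitter=0.02)) for i in range(12)]
        res = run_pca(assemble_matrix(records, 8))
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(res.eigenvalues >= 0)
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-9

    def test_eigenvalues_invariant_under_column_rotation(self, rng):
        records = [_dummy_record(i, _coeffs(6, rng, jitter=0.02)) for i in range(15)]
        m = assemble_matrix(records, 6)
        res1 = run_pca(m)
        from scipy.stats import ortho_group

        Q = ortho_group.rvs(m.data.shape[1], random_state=1)
        m2 = assemble_matrix(records, 6)
        m2.data = pd.DataFrame(
            m.data.to_numpy() @ Q, index=m.data.index, columns=m.data.columns
        )
        res2 = run_pca(m2)
        np.testing.assert_allclose(res2.eigenvalues, res1.eigenvalues, atol=1e-9)


@pytest.fixture(scope="module")
def curvature_result():
    from hookmorph import generate_hook

    hooks = [
        SpecimenRecord(
            specimen_id=f"k{i}",
            species=f"k{i}",
            stage=Stage.ADULT,
            site=Site.GILL,
            appendage=Appendage.P1,
            shape=generate_hook(HookShapeParams(kappa=k)),
        )
        for i, k in enumerate(np.linspace(0.8, 2.2, 12))
    ]
    return analyze_records(hooks, n_harmonics=15)


class TestEigenShape:
    def test_k0_gives_mean_shape_for_all_components(self, curvature_result):
        s1 = eigen_shape(curvature_result, 1, 0.0)
        s2 = eigen_shape(curvature_result, 2, 0.0)
        np.testing.assert_allclose(s1.points, s2.points, atol=1e-12)

    def test_pc1_extremes_differ_monotonically_in_curvature(self, curvature_result):
        kappas = []
        for k_sd in (-2.0, 0.0, 2.0):
            shape = eigen_shape(curvature_result, 1, k_sd, n_points=256)
            kappa_hat, _ = estimate_curvature_thickness(shape)
            kappas.append(kappa_hat)
        assert kappas[0] < kappas[1] < kappas[2] or kappas[0] > kappas[1] > kappas[2]

    def test_eigen_shapes_closed_and_simple(self, curvature_result):
        from ._oracles import is_simple_polygon

        for comp in (1, 2):
            for k_sd in (-2.0, -1.0, 1.0, 2.0):
                shape = eigen_shape(curvature_result, comp, k_sd, n_points=128)
                assert is_simple_polygon(shape.points)

    def test_component_out_of_range_errors(self, curvature_result):
        with pytest.raises(ValueError, match="component"):
            eigen_shape(curvature_result, 99, 1.0)


def _result_from_scores(scores, labels):
    idx = pd.Index([f"s{i}" for i in range(len(scores))], name="specimen_id")
    k = scores.shape[1]
    return MorphospaceResult(
        eigenvalues=np.ones(k),
        variance_fraction=np.ones(k) / k,
        scores=pd.DataFrame(scores, index=idx, columns=[f"PC{j+1}" for j in range(k)]),
        loadings=pd.DataFrame(np.eye(k), index=[f"v{j}" for j in range(k)], columns=[f"PC{j+1}" for j in range(k)]),
        mean_vector=pd.Series(np.zeros(k), index=[f"v{j}" for j in range(k)]),
        labels=pd.DataFrame(labels, index=idx),
        n_harmonics=2,
    )


class TestHulls:
    def test_collinear_points_zero_area(self):
        scores = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        res = _result_from_scores(scores, {"site": ["gill"] * 3, "stage": ["adult"] * 3,
                                           "species": list("abc"), "appendage": ["P1"] * 3})
        [h] = group_hulls(res, group_by=("site",))
        assert h.hull_area == 0.0

    def test_unit_square_corners(self):
        scores = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        res = _result_from_scores(scores, {"site": ["gill"] * 4, "stage": ["adult"] * 4,
                                           "species": list("abcd"), "appendage": ["P1"] * 4})
        [h] = group_hulls(res, group_by=("site",))
        assert h.hull_area == pytest.approx(1.0)
        assert h.n == 4

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            pts = rng.standard_normal((50, 2))
            res = _result_from_scores(
                pts,
                {"site": ["gill"] * 50, "stage": ["adult"] * 50,
                 "species": [f"s{i}" for i in range(50)], "appendage": ["P1"] * 50},
            )
            [h] = group_hulls(res, group_by=("site",))
            assert h.hull_area == pytest.approx(brute_force_hull_area(pts), rel=1e-9)

    def test_adding_point_never_shrinks_hull(self, rng):
        pts = rng.standard_normal((20, 2))
        areas = []
        for n in range(3, 21):
            areas.append(brute_force_hull_area(pts[:n]))
        assert np.all(np.diff(areas) >= -1e-12)


class TestHullOverlap:
    def _square(self, x0, y0, side=1.0):
        v = np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]])
        return GroupSummary(key=("g",), n=4, hull_area=side**2, hull_vertices=v)

    def test_identical_hulls(self):
        a = self._square(0, 0)
        assert hull_overlap(a, a) == pytest.approx(a.hull_area)

    def test_disjoint_hulls(self):
        assert hull_overlap(self._square(0, 0), self._square(5, 5)) == 0.0

    def test_offset_squares_analytic(self):
        assert hull_overlap(self._square(0, 0), self._square(0.5, 0)) == pytest.approx(0.5)

    def test_symmetry_and_bound(self):
        a, b = self._square(0, 0), self._square(0.3, 0.4)
        ab, ba = hull_overlap(a, b), hull_overlap(b, a)
        assert ab == pytest.approx(ba)
        assert 0 <= ab <= min(a.hull_area, b.hull_area)


class TestOntogeneticVectors:
    def _paired_result(self, displacements):
        scores, labels = [], {"species": [], "stage": [], "site": [], "appendage": []}
        for i, d in enumerate(displacements):
            scores.append([0.0, 0.0])
            scores.append(list(d))
            for stage in ("immature", "adult"):
                labels["species"].append(f"sp{i}")
                labels["stage"].append(stage)
                labels["site"].append("gill")
                labels["appendage"].append("P1")
        return _result_from_scores(np.array(scores, dtype=float), labels)

    def test_identical_displacements_rbar_one(self):
        res = self._paired_result([(1.0, 0.5)] * 6)
        vecs, summary = ontogenetic_vectors(res)
        assert summary["rbar"] == pytest.approx(1.0)
        assert all(v.magnitude == pytest.approx(np.hypot(1.0, 0.5)) for v in vecs)

    def test_three_symmetric_directions_rbar_zero(self):
        disp = [
            (np.cos(a), np.sin(a)) for a in np.radians([0.0, 120.0, 240.0])
        ]
        _, summary = ontogenetic_vectors(self._paired_result(disp))
        assert summary["rbar"] == pytest.approx(0.0, abs=1e-12)

    def test_unpaired_species_skipped_with_warning(self, caplog):
        import logging

        res = self._paired_result([(1.0, 0.0)] * 3)
        res.labels.iloc[0, res.labels.columns.get_loc("stage")] = "adult"  # s0 now unpaired
        with caplog.at_level(logging.WARNING):
            vecs, summary = ontogenetic_vectors(res)
        assert summary["n"] == 2
        assert any("missing a stage" in r.message for r in caplog.records)

    def test_thickness_only_stage_effect_aligns_with_tau_direction(self):
        design = DesignSpec(
            seed=11,
            site_effects={Site.MOUTH: (0.0, 0.0), Site.GILL: (0.0, 0.0), Site.EXTERNAL: (0.0, 0.0)},
            stage_effects={Stage.IMMATURE: (0.0, -0.04), Stage.ADULT: (0.0, 0.04)},
            species_sd=(0.1, 0.01),
        )
        res = analyze_records(generate_dataset(design).records, n_harmonics=15)
        vecs, summary = ontogenetic_vectors(res)
        assert summary["rbar"] > 0.8
        # direction of the tau response in the PC plane, from two mean hooks
        from hookmorph.pipeline import outline_to_nef
        from hookmorph import generate_hook

        lo = outline_to_nef(generate_hook(HookShapeParams(tau=0.24)), n_harmonics=15)
        hi = outline_to_nef(generate_hook(HookShapeParams(tau=0.32)), n_harmonics=15)

        def row(nef):
            c = nef.coeffs
            return np.concatenate([c[1:, 0], c[1:, 1], c[1:, 2], c[:, 3]])

        delta = row(hi) - row(lo)
        tau_dir = delta @ res.loadings.to_numpy()[:, :2]
        tau_dir /= np.hypot(*tau_dir)
        mean_disp = np.mean([v.displacement for v in vecs], axis=0)
        mean_disp /= np.hypot(*mean_disp)
        assert abs(float(np.dot(tau_dir, mean_disp))) > 0.9
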