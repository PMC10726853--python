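import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mosaicmap import (
    ParcellationScheme,
    VertexMap,
    exhaustive_null,
    fit_reference,
    patch_pvalues,
    run_map_subject,
    thin_patch_fraction,
    threshold_map,
    zscore_patches,
)
from mosaicmap.errors import ConsistencyError, ValidationError
from mosaicmap.map_core import residualize_profiles
from mosaicmap.parcellate import PatchProfile

from _oracles import brute_force_loo_z, brute_force_pvalues


def _profiles(mat):
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    return [
        PatchProfile(f"c{i}", row, np.ones(row.size, dtype=int))
        for i, row in enumerate(mat)
    ]


class TestReference:
    def test_mean_and_sample_sd(self):
        ref = fit_reference(_profiles([[2.0], [2.2], [2.4]]))
        assert np.isclose(ref.patch_mean_ref[0], 2.2)
        assert np.isclose(ref.patch_sd_ref[0], 0.2)

    def test_identical_controls_flagged_degenerate(self):
        ref = fit_reference(_profiles([[2.0, 1.0], [2.0, 2.0]]))
        assert ref.degenerate.tolist() == [True, False]

    def test_single_control_is_error(self):
        with pytest.raises(ValidationError):
            fit_reference(_profiles([[2.0]]))

    def test_mixed_schemes_rejected(self):
        profs = _profiles([[2.0, 2.1]]) + _profiles([[2.0]])
        with pytest.raises(ConsistencyError):
            fit_reference(profs)


class TestZScores:
    def test_patient_at_reference_mean_is_zero(self):
        ref = fit_reference(_profiles([[2.0], [2.2], [2.4]]))
        z = zscore_patches(_profiles([[2.2]])[0], ref)
        assert np.isclose(z[0], 0.0)

    def test_hand_example(self):
        ref = fit_reference(_profiles([[2.0], [2.2], [2.4]]))
        z = zscore_patches(_profiles([[1.8]])[0], ref)
        assert np.isclose(z[0], -2.0)

    def test_affine_invariance(self, rng):
        mat = rng.normal(2.3, 0.1, size=(6, 4))
        pat = rng.normal(2.3, 0.1, size=4)
        z1 = zscore_patches(_profiles([pat])[0], fit_reference(_profiles(mat)))
        c, d = 3.7, 1.2
        z2 = zscore_patches(_profiles([c * pat + d])[0],
                            fit_reference(_profiles(c * mat + d)))
        assert np.allclose(z1, z2)

    def test_degenerate_patch_is_nan_not_inf(self):
        ref = fit_reference(_profiles([[2.0], [2.0]]))
        z = zscore_patches(_profiles([[1.5]])[0], ref)
        assert np.isnan(z[0])

    def test_crawford_howell_scaling(self):
        ref = fit_reference(_profiles([[2.0], [2.2], [2.4]]))
        z = zscore_patches(_profiles([[1.8]])[0], ref)
        z_ch = zscore_patches(_profiles([[1.8]])[0], ref, crawford_howell=True)
        assert np.isclose(z_ch[0], z[0] / np.sqrt(1 + 1 / 3))


class TestExhaustiveNull:
    def test_row_count_is_pooled_size(self):
        ref = fit_reference(_profiles([[2.0], [2.1], [2.3]]))
        null = exhaustive_null(_profiles([[1.5]])[0], ref)
        assert null.shape == (4, 1)

    def test_row0_equals_observed_zscores(self, rng):
        mat = rng.normal(2.3, 0.1, size=(8, 5))
        pat = _profiles([rng.normal(2.3, 0.1, size=5)])[0]
        ref = fit_reference(_profiles(mat))
        null = exhaustive_null(pat, ref)
        assert np.array_equal(null[0], zscore_patches(pat, ref))

    def test_matches_enumeration_oracle(self):
        pooled = np.array([[1.5], [2.0], [2.1], [2.2]])
        ref = fit_reference(_profiles(pooled[1:]))
        null = exhaustive_null(_profiles(pooled[:1])[0], ref)
        assert np.allclose(null, brute_force_loo_z(pooled), atol=1e-10)

    def test_all_equal_pooled_values_not_evaluable(self):
        ref = fit_reference(_profiles([[2.0], [2.0], [2.0]]))
        pat = _profiles([[2.0]])[0]
        p = patch_pvalues(zscore_patches(pat, ref), exhaustive_null(pat, ref))
        assert np.isnan(p[0])


class TestPValues:
    def test_strict_minimum_of_four_rows(self):
        null = np.array([[-3.0], [0.1], [0.5], [1.0]])
        assert patch_pvalues(np.array([-3.0]), null)[0] == pytest.approx(0.25)

    def test_observed_maximum_gives_one(self):
        null = np.array([[2.0], [0.1], [0.5], [1.0]])
        assert patch_pvalues(np.array([2.0]), null)[0] == 1.0

    def test_all_ties_give_one(self):
        null = np.zeros((5, 1))
        assert patch_pvalues(np.array([0.0]), null)[0] == 1.0

    def test_nan_null_cells_count_as_not_smaller(self):
        null = np.array([[-1.0], [np.nan], [0.5], [1.0]])
        assert patch_pvalues(np.array([-1.0]), null)[0] == pytest.approx(0.25)


class TestThreshold:
    def test_per_patch_calls(self):
        thin = threshold_map(np.array([0.011, 0.5, 1.0]), alpha=0.05)
        assert thin.tolist() == [True, False, False]

    def test_alpha_below_grid_warns_and_calls_nothing(self):
        null = np.zeros((10, 2))
        p = np.array([0.1, 0.1])
        with pytest.warns(UserWarning, match="attainable"):
            thin = threshold_map(p, alpha=0.01, null_z=null)
        assert not thin.any()

    def test_invalid_alpha(self):
        with pytest.raises(ValidationError):
            threshold_map(np.array([0.5]), alpha=1.5)

    def test_maxstat_equals_per_patch_on_single_patch(self, rng):
        pooled = rng.normal(size=(10, 1))
        ref = fit_reference(_profiles(pooled[1:]))
        pat = _profiles(pooled[:1])[0]
        z = zscore_patches(pat, ref)
        null = exhaustive_null(pat, ref)
        p = patch_pvalues(z, null)
        for alpha in (0.05, 0.11, 0.35):
            a = threshold_map(p, alpha, "per-patch")
            b = threshold_map(p, alpha, "max-stat", observed_z=z, null_z=null)
            assert a.tolist() == b.tolist()

    def test_maxstat_is_never_more_liberal(self, rng):
        pooled = rng.normal(size=(30, 8))
        ref = fit_reference(_profiles(pooled[1:]))
        pat = _profiles(pooled[:1])[0]
        z = zscore_patches(pat, ref)
        null = exhaustive_null(pat, ref)
        p = patch_pvalues(z, null)
        per = threshold_map(p, 0.1, "per-patch")
        mx = threshold_map(p, 0.1, "max-stat", observed_z=z, null_z=null)
        assert not (mx & ~per).any()


class TestThinPatchFraction:
    @pytest.mark.parametrize("n_thin,n_eval,n_total,expected", [
        (0, 100, 100, 0.0),
        (5, 100, 100, 0.05),
        (3, 50, 60, 0.06),
    ])
    def test_denominator_is_evaluable_patches(self, n_thin, n_eval, n_total, expected):
        thin = np.zeros(n_total, bool)
        thin[:n_thin] = True
        evaluable = np.zeros(n_total, bool)
        evaluable[:n_eval] = True
        assert thin_patch_fraction(thin, evaluable) == pytest.approx(expected)

    def test_zero_evaluable_is_error(self):
        with pytest.raises(ValidationError):
            thin_patch_fraction(np.zeros(3, bool), np.zeros(3, bool))


class TestRunMapSubject:
    def test_patient_at_cohort_mean_has_zero_fraction(self, rng):
        V, N = 60, 6
        scheme = ParcellationScheme(np.repeat(np.arange(1, N + 1), V // N))
        controls = [VertexMap(f"c{i}", rng.uniform(2.0, 2.8, V)) for i in range(12)]
        mean_map = VertexMap("pat", np.mean([c.values for c in controls], axis=0))
        res = run_map_subject(mean_map, controls, scheme)
        assert np.allclose(res.z, 0.0, atol=1e-10)
        assert res.thin_patch_fraction == 0.0

    def test_shifted_patch_reaches_floor_p_with_89_controls(self, rng):
        V, N = 100, 10
        scheme = ParcellationScheme(np.repeat(np.arange(1, N + 1), V // N))
        controls = [VertexMap(f"c{i}", rng.normal(2.4, 0.1, V)) for i in range(89)]
        ref_sd = np.std([c.values[:10].mean() for c in controls], ddof=1)
        vals = rng.normal(2.4, 0.1, V)
        vals[:10] -= 6 * ref_sd
        res = run_map_subject(VertexMap("pat", vals), controls, scheme)
        assert res.p[0] == pytest.approx(1 / 90)
        assert res.thin[0]
        assert res.n_permutations == 90

    def test_p_values_on_discrete_grid(self, small_cohort):
        coh = small_cohort
        pat = coh.maps_for(coh.patient_ids)[0]
        res = run_map_subject(pat, coh.maps_for(coh.control_ids), coh.scheme,
                              coh.mask)
        n_rows = coh.config.n_controls + 1
        k = res.p[np.isfinite(res.p)] * n_rows
        assert np.allclose(k, np.round(k), atol=1e-9)
        assert res.p[np.isfinite(res.p)].min() >= 1 / n_rows

    def test_monotone_in_patient_thickness(self, rng):
        V, N = 40, 4
        scheme = ParcellationScheme(np.repeat(np.arange(1, N + 1), V // N))
        controls = [VertexMap(f"c{i}", rng.uniform(2.0, 2.8, V)) for i in range(9)]
        vals = rng.uniform(2.0, 2.8, V)
        res1 = run_map_subject(VertexMap("p", vals), controls, scheme)
        lowered = vals.copy()
        lowered[3] -= 0.5  # vertex 3 lies in patch 1
        res2 = run_map_subject(VertexMap("p", lowered), controls, scheme)
        assert res2.z[0] <= res1.z[0] + 1e-12
        assert res2.p[0] <= res1.p[0] + 1e-12
        assert np.allclose(res2.z[1:], res1.z[1:])

    def test_affine_invariance_end_to_end(self, rng):
        V, N = 30, 3
        scheme = ParcellationScheme(np.repeat(np.arange(1, N + 1), V // N))
        controls = [VertexMap(f"c{i}", rng.uniform(2.0, 2.8, V)) for i in range(7)]
        vals = rng.uniform(2.0, 2.8, V)
        res1 = run_map_subject(VertexMap("p", vals), controls, scheme)
        c, d = 2.0, 0.3
        controls2 = [VertexMap(m.subject_id, c * m.values + d) for m in controls]
        res2 = run_map_subject(VertexMap("p", c * vals + d), controls2, scheme)
        assert np.allclose(res1.z, res2.z)
        assert np.array_equal(res1.p, res2.p)
        assert res1.thin_patch_fraction == res2.thin_patch_fraction


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(3, 8), st.integers(1, 5), st.integers(0, 10_000))
def test_pvalues_agree_with_brute_force(n_ref, n_patches, seed):
    """The vectorized exhaustive null matches independent enumeration of
    every relabeling, z to 1e-10 and p exactly."""
    rng = np.random.default_rng(seed)
    pooled = rng.normal(2.3, 0.1, size=(n_ref + 1, n_patches))
    ref = fit_reference(_profiles(pooled[1:]))
    pat = _profiles(pooled[:1])[0]
    null = exhaustive_null(pat, ref)
    assert np.allclose(null, brute_force_loo_z(pooled), atol=1e-10)
    p = patch_pvalues(zscore_patches(pat, ref), null)
    assert np.array_equal(p, brute_force_pvalues(pooled))


def test_residualization_removes_linear_age_effect(rng):
    n, N = 30, 5
    age = rng.uniform(20, 70, n)
    base = rng.normal(2.4, 0.05, size=(n, N))
    slope = -0.004
    mat = base + slope * (age[:, None] - age.mean())
    profs = [PatchProfile(f"s{i}", mat[i], np.ones(N, int)) for i in range(n)]
    cov = np.column_stack([age, rng.integers(0, 2, n)])
    out = residualize_profiles(profs, cov)
    resid = np.vstack([p.patch_means for p in out])
    # age effect gone: regression of residuals on age is ~0
    for k in range(N):
        r = np.corrcoef(age, resid[:, k])[0, 1]
        beta = np.polyfit(age, resid[:, k], 1)[0]
        assert abs(beta) < 1e-10 or abs(r) < 1e-6
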