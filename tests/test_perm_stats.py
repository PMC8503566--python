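import numpy as np
import pytest

from mvba import (
    BinaryMask,
    TfceParams,
    build_permutation_scheme,
    fwer_pmap,
    max_statistic_distribution,
    perm_t_tensor,
    run_univariate,
    single_case_t,
    tfce_transform,
)
from mvba.synthetic_cohort import LesionSpec, SyntheticConfig, generate_cohort

# ---------------------------------------------------------------------------
# independent brute-force TFCE oracle (flood fill per threshold)
# ---------------------------------------------------------------------------

_FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                 (0, 0, 1), (0, 0, -1)]


def tfce_oracle(stat, h_exp, e_exp, n_steps):
    stat = np.clip(np.asarray(stat, dtype=float), 0.0, None)
    out = np.zeros_like(stat)
    vmax = stat.max()
    if vmax <= 0:
        return out
    dh = vmax / n_steps
    shape = stat.shape
    for i in range(1, n_steps + 1):
        h = i * dh
        sup = stat >= h
        seen = np.zeros(shape, dtype=bool)
        for idx in np.argwhere(sup):
            idx = tuple(idx)
            if seen[idx]:
                continue
            # BFS flood fill of the component containing idx
            comp = [idx]
            seen[idx] = True
            queue = [idx]
            while queue:
                cur = queue.pop()
                for off in _FACE_OFFSETS:
                    nb = tuple(c + o for c, o in zip(cur, off))
                    if all(0 <= c < s for c, s in zip(nb, shape)) \
                            and sup[nb] and not seen[nb]:
                        seen[nb] = True
                        comp.append(nb)
                        queue.append(nb)
            incr = len(comp) ** e_exp * h ** h_exp * dh
            for v in comp:
                out[v] += incr
    return out


class TestSingleCaseT:
    def test_centered_patient_gives_zero(self):
        controls = np.array([[1.0], [2.0], [3.0]])
        assert single_case_t(np.array([2.0]), controls)[0] == 0.0

    def test_known_value_sqrt3(self):
        controls = np.array([1.0, 2.0, 3.0, 4.0, 5.0])[:, None]
        t = single_case_t(np.array([6.0]), controls)[0]
        assert t == pytest.approx(np.sqrt(3.0), rel=1e-12)

    def test_odd_symmetry(self, rng):
        controls = rng.standard_normal((6, 50))
        patient = rng.standard_normal(50)
        np.testing.assert_allclose(single_case_t(-patient, -controls),
                                   -single_case_t(patient, controls))

    def test_zero_variance_voxels_get_zero(self):
        controls = np.full((4, 3), 2.0)
        t = single_case_t(np.array([5.0, 2.0, -1.0]), controls)
        np.testing.assert_array_equal(t, 0.0)

    def test_fewer_than_two_controls_rejected(self):
        with pytest.raises(ValueError):
            single_case_t(np.array([1.0]), np.array([[1.0]]))


class TestPermutationScheme:
    def test_one_vs_62_is_exhaustive_63(self):
        scheme = build_permutation_scheme(62, requested=10000)
        assert scheme.exhaustive
        assert scheme.n_perms == 63
        assert sorted(scheme.assignments.tolist()) == list(range(63))

    def test_identity_always_first(self):
        for n, req in [(4, 3), (10, 5), (5, 100)]:
            scheme = build_permutation_scheme(n, requested=req, seed=1)
            assert scheme.assignments[0] == n

    def test_sampled_scheme_reproducible(self):
        a = build_permutation_scheme(50, requested=10, seed=7)
        b = build_permutation_scheme(50, requested=10, seed=7)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        assert not a.exhaustive and a.n_perms == 10
        assert len(set(a.assignments.tolist())) == 10  # without replacement

    def test_tensor_row0_reproduces_observed_map(self, rng):
        subjects = rng.standard_normal((8, 30))
        scheme = build_permutation_scheme(7)
        tensor = perm_t_tensor(subjects, scheme)
        direct = single_case_t(subjects[-1], subjects[:-1])
        np.testing.assert_allclose(tensor.values[0], direct, atol=1e-10)

    def test_tensor_rows_match_explicit_relabeling(self, rng):
        subjects = rng.standard_normal((6, 20))
        scheme = build_permutation_scheme(5)
        tensor = perm_t_tensor(subjects, scheme)
        for row, j in enumerate(scheme.assignments):
            rest = np.delete(subjects, j, axis=0)
            np.testing.assert_allclose(tensor.values[row],
                                       single_case_t(subjects[j], rest),
                                       atol=1e-10)


class TestTfce:
    def test_zero_map_maps_to_zero(self, full_mask):
        out = tfce_transform(np.zeros((6, 6, 6)), full_mask((6, 6, 6)))
        np.testing.assert_array_equal(out, 0.0)

    def test_isolated_voxel_closed_form(self, full_mask):
        # single suprathreshold voxel of height v: e == 1 so the integral is
        # int_0^v h^2 dh = v^3 / 3 in the fine-step limit
        v = 2.5
        stat = np.zeros((7, 7, 7))
        stat[3, 3, 3] = v
        out = tfce_transform(stat, full_mask((7, 7, 7)),
                             TfceParams(n_steps=200))
        assert out[3, 3, 3] == pytest.approx(v ** 3 / 3, rel=0.02)
        assert np.count_nonzero(out) == 1

    def test_positive_scaling_by_c_cubed(self, rng, full_mask):
        stat = np.clip(rng.standard_normal((8, 8, 8)), 0, None)
        mask = full_mask((8, 8, 8))
        params = TfceParams(n_steps=64)
        base = tfce_transform(stat, mask, params)
        scaled = tfce_transform(3.0 * stat, mask, params)
        np.testing.assert_allclose(scaled, 27.0 * base, rtol=1e-9)

    def test_matches_brute_force_oracle(self, rng, full_mask):
        stat = np.clip(rng.standard_normal((6, 6, 6)), 0, None)
        out = tfce_transform(stat, full_mask((6, 6, 6)),
                             TfceParams(n_steps=17))
        expected = tfce_oracle(stat, 2.0, 0.5, 17)
        np.testing.assert_allclose(out, expected, rtol=1e-9)

    def test_pointwise_monotone_for_dominated_maps(self, rng, full_mask):
        # reduce some voxels but keep the global max, so both maps share the
        # same step grid and domination carries through exactly
        a = np.clip(rng.standard_normal((8, 8, 8)) + 1, 0, None)
        b = a.copy()
        peak = np.unravel_index(np.argmax(a), a.shape)
        shrink = rng.random(a.shape) < 0.5
        shrink[peak] = False
        b[shrink] *= rng.random(a.shape)[shrink]
        mask = full_mask((8, 8, 8))
        params = TfceParams(n_steps=40)
        ta = tfce_transform(a, mask, params)
        tb = tfce_transform(b, mask, params)
        assert np.all(ta >= tb - 1e-12)

    def test_negative_values_clamped(self, full_mask):
        stat = np.full((5, 5, 5), -3.0)
        stat[2, 2, 2] = 1.0
        out = tfce_transform(stat, full_mask((5, 5, 5)), TfceParams(n_steps=50))
        assert out[2, 2, 2] > 0
        assert np.count_nonzero(out) == 1

    def test_non_finite_rejected(self, full_mask):
        stat = np.zeros((4, 4, 4))
        stat[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            tfce_transform(stat, full_mask((4, 4, 4)))


class TestMaxDistributionAndPmap:
    def test_single_voxel_mask_gives_that_voxel(self, rng):
        rows = rng.random((5, 1))
        np.testing.assert_array_equal(max_statistic_distribution(rows),
                                      rows[:, 0])

    def test_voxel_order_irrelevant(self, rng):
        rows = rng.random((7, 40))
        perm = rng.permutation(40)
        np.testing.assert_array_equal(max_statistic_distribution(rows),
                                      max_statistic_distribution(rows[:, perm]))

    def test_counting_rule_with_ties_and_self(self):
        # 63 exhaustive perms; observed max exceeded by exactly 2 others
        null_max = np.concatenate([[5.0, 6.0, 7.0], np.linspace(0, 4, 60)])
        p = fwer_pmap(np.array([5.0]), null_max)
        assert p[0] == pytest.approx(3 / 63)

    def test_extremes(self):
        null_max = np.concatenate([[10.0], np.linspace(0, 5, 62)])
        assert fwer_pmap(np.array([10.0]), null_max)[0] == pytest.approx(1 / 63)
        assert fwer_pmap(np.array([0.0]), null_max)[0] == 1.0

    def test_antitone_in_observed_statistic(self, rng):
        null_max = rng.random(30)
        obs = np.sort(rng.random(10))
        p = fwer_pmap(obs, null_max)
        assert np.all(np.diff(p) <= 0)

    def test_p_bounded_below_by_one_over_nperms(self, rng):
        # the identity permutation is part of the null distribution, so any
        # observed value (which is <= null_max[0] by construction) has p >= 1/n
        obs = rng.random(50)
        null_max = np.concatenate([[obs.max()], rng.random(20)])
        p = fwer_pmap(obs, null_max)
        assert np.all(p >= 1 / 21 - 1e-15)


class TestRunUnivariate:
    def test_strong_decrease_detected_and_localized(self, full_mask):
        config = SyntheticConfig(n_controls=20, seed=42, modalities=("NDI",))
        lesion = LesionSpec((31.0, 31.0, 31.0), 8.0, {"NDI": -5.0})
        ds = generate_cohort(config, lesion)
        result = run_univariate(ds.patient["NDI"], ds.controls["NDI"],
                                full_mask(ds.shape), direction="decrease",
                                tfce_params=TfceParams(n_steps=32))
        assert result.findings.n_voxels > 0
        overlap = result.findings.data & ds.truth_mask.data
        assert overlap.sum() > 0.5 * ds.truth_mask.n_voxels

    def test_wrong_direction_misses_planted_decrease(self, full_mask):
        config = SyntheticConfig(n_controls=20, seed=42, modalities=("NDI",))
        lesion = LesionSpec((31.0, 31.0, 31.0), 8.0, {"NDI": -5.0})
        ds = generate_cohort(config, lesion)
        result = run_univariate(ds.patient["NDI"], ds.controls["NDI"],
                                full_mask(ds.shape), direction="increase",
                                tfce_params=TfceParams(n_steps=32))
        assert not (result.findings.data & ds.truth_mask.data).any()

    def test_findings_within_mask_and_p_range(self, full_mask):
        config = SyntheticConfig(shape=(16, 16, 16), n_controls=20, seed=9,
                                 modalities=("FA",),
                                 cerebellar_region=((4, 10), (4, 10), (2, 8)))
        ds = generate_cohort(config)
        mask = BinaryMask(np.zeros(ds.shape, dtype=bool))
        mask.data[4:12, 4:12, 4:12] = True
        result = run_univariate(ds.patient["FA"], ds.controls["FA"], mask,
                                tfce_params=TfceParams(n_steps=16))
        assert not (result.findings.data & ~mask.data).any()
        inside = result.p_map[mask.data]
        assert inside.min() >= 1 / 21 - 1e-15 and inside.max() <= 1.0
        assert np.all(result.p_map[~mask.data] == 1.0)
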