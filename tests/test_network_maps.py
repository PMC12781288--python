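import math

import numpy as np
import pytest
import scipy.integrate

from anm.network_maps import (
    AnmConfig,
    ExperimentZStack,
    binarize,
    build_group_maps,
    contrast_maps,
    critical_t,
    experiment_mean_z,
    group_t_map,
    map_similarity,
    min_retaining_count,
    one_sample_t,
    overlap_map,
)
from anm.volumes import volume_from_vector


def brute_force_t(stack: np.ndarray) -> np.ndarray:
    """Per-voxel loop oracle: t = mean / (sd / sqrt(n)), sd with n-1."""
    n, V = stack.shape
    out = np.zeros(V)
    for v in range(V):
        vals = stack[:, v]
        m = sum(vals) / n
        sd = math.sqrt(sum((x - m) ** 2 for x in vals) / (n - 1))
        out[v] = 0.0 if sd == 0 else m / (sd / math.sqrt(n))
    return out


class TestOneSampleT:
    def test_hand_computed_example(self, small_mask):
        # values (1, 2, 3): mean 2, sd 1, t = 2 / (1/sqrt(3)) = 3.4641...
        stack = np.zeros((3, small_mask.n_voxels))
        stack[:, 0] = [1.0, 2.0, 3.0]
        t = one_sample_t(stack, small_mask)
        assert t.values_in(small_mask)[0] == pytest.approx(2 * math.sqrt(3), abs=1e-12)

    def test_all_zero_stack_gives_zero_t(self, small_mask):
        t = one_sample_t(np.zeros((5, small_mask.n_voxels)), small_mask)
        assert np.all(t.data == 0.0)

    def test_matches_loop_oracle_on_random_voxels(self, small_mask):
        rng = np.random.default_rng(0)
        stack = rng.normal(size=(10, small_mask.n_voxels))
        t = one_sample_t(stack, small_mask).values_in(small_mask)
        cols = rng.choice(small_mask.n_voxels, 50, replace=False)
        assert np.allclose(t[cols], brute_force_t(stack[:, cols]), atol=1e-10)

    def test_fewer_than_three_maps_rejected(self, small_mask):
        with pytest.raises(ValueError, match=">= 3"):
            one_sample_t(np.zeros((2, small_mask.n_voxels)), small_mask)


class TestBinarize:
    def test_boundary_is_strict(self, small_mask):
        t = volume_from_vector(np.full(small_mask.n_voxels, 5.66), small_mask, "t")
        assert binarize(t, 5.66, small_mask).data.sum() == 0

    def test_mask_restriction(self, small_mask):
        t = volume_from_vector(np.full(small_mask.n_voxels, 100.0), small_mask, "t")
        t.data[~small_mask.data] = 100.0  # values outside the mask must be ignored
        b = binarize(t, 5.66, small_mask)
        assert np.array_equal(b.data.astype(bool), small_mask.data)

    def test_elementwise_comparison_oracle(self, small_mask):
        rng = np.random.default_rng(1)
        vals = rng.normal(scale=4.0, size=small_mask.n_voxels)
        b = binarize(volume_from_vector(vals, small_mask, "t"), 2.0, small_mask)
        assert np.array_equal(b.data[small_mask.data], (vals > 2.0).astype(float))


class TestOverlapMap:
    def test_minimal_retaining_count_for_18_experiments(self, small_mask):
        # computed through the actual retention rule, not the helper
        for count, expect_retained in [(10, False), (11, True)]:
            maps = [
                volume_from_vector(
                    (np.arange(small_mask.n_voxels) == 0).astype(float) if e < count
                    else np.zeros(small_mask.n_voxels),
                    small_mask, "binary",
                )
                for e in range(18)
            ]
            ov = overlap_map(maps, 0.60, small_mask)
            assert bool(ov.retained.values_in(small_mask)[0]) is expect_retained
        assert min_retaining_count(18, 0.60) == 11

    def test_single_experiment_is_retained_verbatim(self, small_mask):
        rng = np.random.default_rng(2)
        m = volume_from_vector(
            (rng.random(small_mask.n_voxels) < 0.3).astype(float), small_mask, "binary"
        )
        ov = overlap_map([m], 0.60, small_mask)
        assert np.array_equal(ov.retained.data, m.data)

    def test_counting_oracle_for_seven_experiments(self, small_mask):
        rng = np.random.default_rng(3)
        stack = (rng.random((7, small_mask.n_voxels)) < 0.5).astype(float)
        ov = overlap_map(
            [volume_from_vector(row, small_mask, "binary") for row in stack],
            0.60, small_mask,
        )
        # per-voxel recount: 7 * 0.6 = 4.2, so >= 5 retains
        counts = np.array([sum(stack[:, v]) for v in range(small_mask.n_voxels)])
        assert np.array_equal(ov.count.values_in(small_mask), counts)
        assert np.array_equal(ov.retained.values_in(small_mask), (counts >= 5).astype(float))

    def test_count_conservation(self, small_mask):
        rng = np.random.default_rng(4)
        stack = (rng.random((6, small_mask.n_voxels)) < 0.4).astype(float)
        ov = overlap_map([volume_from_vector(r, small_mask, "binary") for r in stack],
                         0.60, small_mask)
        assert ov.count.data.sum() == sum(r.sum() for r in stack)

    def test_non_binary_input_rejected(self, small_mask):
        with pytest.raises(ValueError, match="binary"):
            overlap_map([np.full(small_mask.n_voxels, 0.5)], 0.6, small_mask)


def make_stack(small_mask, n_participants=5, seed=0, study="s1", shift=0.0):
    rng = np.random.default_rng(seed)
    zmat = rng.normal(loc=shift, size=(n_participants, small_mask.n_voxels))
    return ExperimentZStack(
        study_id=study, group="NT", mask=small_mask, zmat=zmat,
        participant_ids=tuple(f"p{i}" for i in range(n_participants)),
    )


class TestExperimentMeanAndGroupT:
    def test_mean_of_one_is_identity(self, small_mask):
        s = make_stack(small_mask, n_participants=3, seed=5)
        s.zmat = s.zmat[:1].repeat(3, axis=0)
        assert np.allclose(experiment_mean_z(s).values_in(small_mask), s.zmat[0])

    def test_map_and_negation_cancel(self, small_mask):
        s = make_stack(small_mask, n_participants=4, seed=6)
        s.zmat[2] = -s.zmat[0]
        s.zmat[3] = -s.zmat[1]
        assert np.allclose(experiment_mean_z(s).values_in(small_mask), 0.0, atol=1e-12)

    def test_mean_matches_accumulation_oracle(self, small_mask):
        rng = np.random.default_rng(7)
        zmat = rng.normal(size=(9, small_mask.n_voxels))
        s = ExperimentZStack(study_id="s", group="NT", mask=small_mask, zmat=zmat)
        acc = np.zeros(small_mask.n_voxels)
        for row in zmat:
            acc += row
        assert np.allclose(experiment_mean_z(s).values_in(small_mask), acc / 9, atol=1e-12)

    def test_identical_constant_maps_hit_zero_variance_rule(self, small_mask):
        maps = [volume_from_vector(np.full(small_mask.n_voxels, 2.5), small_mask, "mean_z")
                for _ in range(5)]
        tm = group_t_map(maps, AnmConfig(), small_mask)
        assert np.all(tm.t.data == 0.0)
        assert tm.thresholded.data.sum() == 0
        assert tm.df == 4

    def test_hand_oracle_at_one_voxel(self, small_mask):
        maps = []
        for v in (1.0, 2.0, 3.0):
            vec = np.zeros(small_mask.n_voxels)
            vec[0] = v
            maps.append(volume_from_vector(vec, small_mask, "mean_z"))
        tm = group_t_map(maps, AnmConfig(), small_mask)
        assert tm.t.values_in(small_mask)[0] == pytest.approx(2 * math.sqrt(3), abs=1e-12)

    def test_experiment_order_invariance(self, small_mask):
        rng = np.random.default_rng(8)
        maps = [volume_from_vector(rng.normal(size=small_mask.n_voxels), small_mask, "mean_z")
                for _ in range(6)]
        a = group_t_map(maps, AnmConfig(), small_mask)
        b = group_t_map(maps[::-1], AnmConfig(), small_mask)
        assert np.allclose(a.t.data, b.t.data, atol=1e-12)


class TestBuildGroupMaps:
    def test_duplicated_experiment_collapses_to_its_binarized_map(self, small_mask):
        base = make_stack(small_mask, n_participants=8, seed=9, shift=0.5)
        stacks = [
            ExperimentZStack(study_id=f"s{i}", group="NT", mask=small_mask,
                             zmat=base.zmat.copy(),
                             participant_ids=base.participant_ids)
            for i in range(5)
        ]
        config = AnmConfig(t_threshold=2.0)
        ov, _ = build_group_maps(stacks, config, small_mask, group="NT")
        expected = binarize(one_sample_t(base.zmat, small_mask), 2.0, small_mask)
        assert np.array_equal(ov.retained.data, expected.data)

    def test_invariant_to_experiment_and_participant_order(self, small_mask):
        stacks = [make_stack(small_mask, 6, seed=10 + i, study=f"s{i}", shift=0.3)
                  for i in range(4)]
        config = AnmConfig(t_threshold=2.0)
        ov_a, tm_a = build_group_maps(stacks, config, small_mask, group="NT")
        perm = np.random.default_rng(0).permutation(6)
        shuffled = [
            ExperimentZStack(study_id=s.study_id, group=s.group, mask=small_mask,
                             zmat=s.zmat[perm],
                             participant_ids=tuple(s.participant_ids[i] for i in perm))
            for s in reversed(stacks)
        ]
        ov_b, tm_b = build_group_maps(shuffled, config, small_mask, group="NT")
        assert np.array_equal(ov_a.retained.data, ov_b.retained.data)
        assert np.allclose(tm_a.t.data, tm_b.t.data, atol=1e-12)

    def test_mismatched_rosters_rejected(self, small_mask):
        a = make_stack(small_mask, 5, seed=1, study="s1")
        b = make_stack(small_mask, 5, seed=2, study="s2")
        c = ExperimentZStack(study_id="s3", group="NT", mask=small_mask,
                             zmat=b.zmat, participant_ids=tuple(f"q{i}" for i in range(5)))
        with pytest.raises(ValueError, match="roster"):
            build_group_maps([a, b, c], AnmConfig(), small_mask, group="NT")

    def test_too_few_experiments_rejected(self, small_mask):
        stacks = [make_stack(small_mask, 5, seed=i, study=f"s{i}") for i in range(2)]
        with pytest.raises(ValueError, match=">= 3"):
            build_group_maps(stacks, AnmConfig(), small_mask, group="NT")


def group_inputs(small_mask, seed, shift=0.4, n_exp=4):
    stacks = [make_stack(small_mask, 6, seed=seed + i, study=f"s{i}", shift=shift)
              for i in range(n_exp)]
    config = AnmConfig(t_threshold=2.0)
    ov, tm = build_group_maps(stacks, config, small_mask, group="g")
    return ov, tm, stacks


class TestContrasts:
    @pytest.mark.parametrize("mode", ["set_difference", "proportion_test", "two_sample_t"])
    def test_identical_groups_give_empty_contrast(self, small_mask, mode):
        ov, tm, stacks = group_inputs(small_mask, seed=20)
        config = AnmConfig(t_threshold=2.0, contrast_mode=mode)
        res = contrast_maps((ov, tm, stacks), (ov, tm, stacks), config, small_mask)
        for vol in (res.overlap_nt_minus_asd, res.overlap_asd_minus_nt,
                    res.t_nt_minus_asd, res.t_asd_minus_nt):
            assert np.count_nonzero(vol.data) == 0

    def test_set_difference_is_exact_boolean_algebra(self, small_mask):
        nt = group_inputs(small_mask, seed=30, shift=0.6)
        asd = group_inputs(small_mask, seed=40, shift=0.2)
        config = AnmConfig(t_threshold=2.0)
        res = contrast_maps(nt, asd, config, small_mask)
        nt_ret = nt[0].retained.data.astype(bool)
        asd_ret = asd[0].retained.data.astype(bool)
        assert np.array_equal(res.overlap_nt_minus_asd.data.astype(bool), nt_ret & ~asd_ret)
        assert np.array_equal(res.overlap_asd_minus_nt.data.astype(bool), asd_ret & ~nt_ret)
        # the two directions are disjoint
        assert not np.any(res.overlap_nt_minus_asd.data * res.overlap_asd_minus_nt.data)

    def test_superset_recovers_difference_exactly(self, small_mask):
        ov, tm, stacks = group_inputs(small_mask, seed=50, shift=0.6)
        # ASD retained: a strict subset of NT retained
        sub = ov.retained.data.copy()
        nz = np.argwhere(sub > 0)
        sub[tuple(nz[0])] = 0.0
        asd_ov = overlap_map(
            [volume_from_vector(sub[small_mask.data], small_mask, "binary")],
            0.60, small_mask,
        )
        config = AnmConfig(t_threshold=2.0)
        res = contrast_maps((ov, tm, stacks), (asd_ov, tm, stacks), config, small_mask)
        expected = ov.retained.data.astype(bool) & ~sub.astype(bool)
        assert np.array_equal(res.overlap_nt_minus_asd.data.astype(bool), expected)


class TestMapSimilarity:
    def test_self_correlation_is_one(self, small_mask):
        vec = np.random.default_rng(60).normal(size=small_mask.n_voxels)
        vol = volume_from_vector(vec, small_mask, "t")
        assert map_similarity(vol, vol, small_mask) == pytest.approx(1.0, abs=1e-12)

    def test_negation_gives_minus_one(self, small_mask):
        vec = np.random.default_rng(61).normal(size=small_mask.n_voxels)
        a = volume_from_vector(vec, small_mask, "t")
        b = volume_from_vector(-vec, small_mask, "t")
        assert map_similarity(a, b, small_mask) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_formula_oracle(self, small_mask):
        rng = np.random.default_rng(62)
        x = rng.normal(size=small_mask.n_voxels)
        y = 0.3 * x + rng.normal(size=small_mask.n_voxels)
        got = map_similarity(
            volume_from_vector(x, small_mask, "t"),
            volume_from_vector(y, small_mask, "t"),
            small_mask,
        )
        expected = np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_operand_rejected(self, small_mask):
        flat = volume_from_vector(np.ones(small_mask.n_voxels), small_mask, "t")
        other = volume_from_vector(
            np.random.default_rng(63).normal(size=small_mask.n_voxels), small_mask, "t"
        )
        with pytest.raises(ValueError, match="variance"):
            map_similarity(flat, other, small_mask)


class TestCriticalT:
    def test_normal_limit(self):
        assert critical_t(0.05, 10**7) == pytest.approx(1.95996, abs=1e-4)

    def test_cauchy_quartile(self):
        assert critical_t(0.5, 1) == pytest.approx(1.0, abs=1e-12)

    def test_matches_numeric_tail_integration_oracle(self):
        # independent oracle: bisection on the numerically integrated t density
        alpha = 0.05 / 285903
        df = 999

        def t_pdf(x):
            log_pdf = (
                math.lgamma((df + 1) / 2)
                - math.lgamma(df / 2)
                - 0.5 * math.log(df * math.pi)
                - (df + 1) / 2 * math.log1p(x * x / df)
            )
            return math.exp(log_pdf)

        def upper_tail(t0):
            val, _ = scipy.integrate.quad(t_pdf, t0, np.inf)
            return val

        lo, hi = 1.0, 10.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if upper_tail(mid) > alpha / 2:
                lo = mid
            else:
                hi = mid
        assert critical_t(alpha, df) == pytest.approx(0.5 * (lo + hi), abs=1e-6)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            critical_t(0.0, 10)
        with pytest.raises(ValueError):
            critical_t(0.05, 0)


class TestMonotonicity:
    def test_raising_threshold_never_grows_any_mask(self, small_mask):
        rng = np.random.default_rng(70)
        stacks = [make_stack(small_mask, 6, seed=70 + i, study=f"s{i}", shift=0.4)
                  for i in range(5)]
        prev_ov = prev_tm = None
        for thr in (1.0, 2.0, 3.0):
            ov, tm = build_group_maps(
                stacks, AnmConfig(t_threshold=thr), small_mask, group="NT"
            )
            if prev_ov is not None:
                assert np.all(ov.count.data <= prev_ov.count.data)
                assert np.all(ov.retained.data <= prev_ov.retained.data)
                assert np.all(tm.thresholded.data <= prev_tm.thresholded.data)
            prev_ov, prev_tm = ov, tm

    def test_raising_overlap_fraction_never_grows_retained(self, small_mask):
        rng = np.random.default_rng(71)
        maps = [volume_from_vector((rng.random(small_mask.n_voxels) < 0.5).astype(float),
                                   small_mask, "binary") for _ in range(9)]
        prev = None
        for frac in (0.2, 0.4, 0.6, 0.8):
            ov = overlap_map(maps, frac, small_mask)
            if prev is not None:
                assert np.all(ov.retained.data <= prev)
            prev = ov.retained.data
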