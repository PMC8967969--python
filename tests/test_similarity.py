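import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from emgsi.errors import DataError, DegenerateReferenceError, ExclusionError
from emgsi.montage import CANONICAL_CHANNELS, ChannelLabel, TaskId
from emgsi.preprocess import BaselineProfile
from emgsi.similarity import (
    ResponseVector,
    aggregate,
    decompose,
    ipsilateral_first,
    magnitude,
    prototype_response_vector,
    response_vector,
    similarity_index,
)

from conftest import make_events, make_recording

nonneg_vectors = hnp.arrays(
    float, 10, elements=st.floats(0.0, 1e3, allow_nan=False, allow_infinity=False)
)


def rv_for(values, joint="ankle", leg="less", side="r", **kw):
    return ResponseVector(np.asarray(values, float), TaskId(joint, leg), side=side, **kw)


class TestResponseVector:
    def _recording(self, rms_per_rep):
        """Piecewise-constant channel 0 with the given amplitude per 1-s rep."""
        fs = 100.0
        x = np.zeros((800, 10))
        for i, amp in enumerate(rms_per_rep):
            x[int((1 + 2 * i) * fs) : int((2 + 2 * i) * fs), 0] = amp
        return make_recording(x, fs=fs), make_events([(1.0, 2.0), (3.0, 4.0), (5.0, 6.0)])

    def _baseline(self, value):
        b = np.zeros(10)
        b[0] = value
        return BaselineProfile(b, np.zeros(10))

    def test_baseline_subtracted_then_averaged(self):
        rec, events = self._recording([4.0, 6.0, 8.0])
        rv = response_vector(rec, events, TaskId("ankle", "less"), self._baseline(1.0))
        assert rv.values[0] == pytest.approx(5.0)

    def test_floor_at_zero_when_baseline_dominates(self):
        rec, events = self._recording([4.0, 6.0, 8.0])
        rv = response_vector(rec, events, TaskId("ankle", "less"), self._baseline(10.0))
        assert rv.values[0] == 0.0

    def test_excluded_repetition_dropped_from_mean(self):
        rec, events = self._recording([4.0, 6.0, 8.0])
        excl = frozenset({(TaskId("ankle", "less"), 2, ChannelLabel("TA", "r"))})
        rv = response_vector(rec, events, TaskId("ankle", "less"), exclusions=excl)
        assert rv.values[0] == pytest.approx(6.0)  # mean of 4 and 8

    def test_all_reps_excluded_raises(self):
        rec, events = self._recording([4.0, 6.0, 8.0])
        task = TaskId("ankle", "less")
        ch = ChannelLabel("TA", "r")
        excl = frozenset({(task, r, ch) for r in (1, 2, 3)})
        with pytest.raises(ExclusionError, match="TA_r"):
            response_vector(rec, events, task, exclusions=excl)

    def test_side_comes_from_recording_side_map(self):
        rec, events = self._recording([1.0, 1.0, 1.0])
        rv = response_vector(rec, events, TaskId("ankle", "less"))
        assert rv.side == "r"  # default side_map maps "less" -> right


class TestMagnitude:
    def test_zero(self):
        assert magnitude(rv_for(np.zeros(10))) == 0.0

    def test_three_four_five(self):
        v = np.zeros(10)
        v[0], v[5] = 3.0, 4.0
        assert magnitude(rv_for(v)) == pytest.approx(5.0)

    @settings(derandomize=True, max_examples=50)
    @given(nonneg_vectors)
    def test_matches_brute_force(self, v):
        assert magnitude(v) == pytest.approx(np.sqrt(np.sum(v * v)), rel=1e-12, abs=1e-12)


class TestPrototype:
    def test_identical_rvs_reproduced(self):
        rvs = [rv_for(np.arange(1.0, 11.0)) for _ in range(5)]
        prv = prototype_response_vector(rvs)
        np.testing.assert_allclose(prv.values, np.arange(1.0, 11.0))
        assert prv.n_reference == 5

    def test_elementwise_mean(self):
        a = np.zeros(10); a[0] = 2.0
        b = np.zeros(10); b[1] = 2.0
        prv = prototype_response_vector([rv_for(a), rv_for(b)])
        expected = np.zeros(10); expected[0] = expected[1] = 1.0
        np.testing.assert_allclose(prv.values, expected)

    def test_mean_matches_brute_force(self, rng):
        rvs = [rv_for(rng.uniform(0, 50, 10)) for _ in range(31)]
        prv = prototype_response_vector(rvs)
        stacked = np.stack([rv.values for rv in rvs])
        np.testing.assert_allclose(prv.values, stacked.mean(axis=0), rtol=1e-12)

    def test_side_pooling_mirrors_left_tasks(self):
        v = np.zeros(10); v[0] = 4.0  # TA_r active, right-leg task
        w = np.zeros(10); w[5] = 2.0  # TA_l active, left-leg task
        rvs = [rv_for(v, side="r"), rv_for(w, leg="more", side="l")]
        prv = prototype_response_vector(rvs, pool_sides=True)
        # both map onto the ipsilateral TA slot
        expected = np.zeros(10); expected[0] = 3.0
        np.testing.assert_allclose(prv.values, expected)

    def test_empty_list_rejected(self):
        with pytest.raises(DataError):
            prototype_response_vector([])

    def test_zero_reference_rejected(self):
        with pytest.raises(DegenerateReferenceError):
            prototype_response_vector([rv_for(np.zeros(10))])

    def test_mixed_sides_without_pooling_rejected(self):
        rvs = [rv_for(np.ones(10), side="r"), rv_for(np.ones(10), leg="more", side="l")]
        with pytest.raises(DataError):
            prototype_response_vector(rvs, pool_sides=False)


class TestSimilarityIndex:
    def test_self_similarity_is_exactly_one(self, rng):
        v = rng.uniform(0, 10, 10)
        prv = prototype_response_vector([rv_for(v)])
        assert similarity_index(rv_for(v), prv) == 1.0

    def test_orthogonal_supports_give_zero(self):
        a = np.zeros(10); a[:5] = 1.0
        b = np.zeros(10); b[5:] = 1.0
        assert similarity_index(a, b) == 0.0

    def test_scale_invariance(self, rng):
        v = rng.uniform(0.1, 10, 10)
        p = rng.uniform(0.1, 10, 10)
        for c in (1e-6, 0.5, 3.0, 1e6):
            assert similarity_index(c * v, p) == pytest.approx(
                similarity_index(v, p), abs=1e-12
            )

    def test_degenerate_rv_is_missing_not_zero(self, rng):
        prv = prototype_response_vector([rv_for(rng.uniform(1, 2, 10))])
        assert np.isnan(similarity_index(rv_for(np.zeros(10)), prv))

    def test_zero_prototype_rejected(self):
        with pytest.raises(DegenerateReferenceError):
            similarity_index(np.ones(10), np.zeros(10))

    @settings(derandomize=True, max_examples=200)
    @given(nonneg_vectors, nonneg_vectors)
    def test_bounded_in_unit_interval(self, v, p):
        if np.linalg.norm(v) == 0 or np.linalg.norm(p) == 0:
            return
        si = similarity_index(v, p)
        assert 0.0 <= si <= 1.0

    def test_adding_off_support_mass_strictly_decreases_si(self, rng):
        p = np.zeros(10)
        p[:5] = rng.uniform(1, 5, 5)  # prototype silent on channels 5..9
        base = similarity_index(p, p)
        for ch in range(5, 10):
            v = p.copy()
            v[ch] += 1.0
            assert similarity_index(v, p) < base

    def test_mirrored_left_task_scores_like_right_task(self):
        # same physiological pattern on opposite legs -> same SI vs pooled PRV
        v = np.zeros(10); v[0], v[3] = 5.0, 3.0
        prv = prototype_response_vector([rv_for(v, side="r")])
        mirrored = ipsilateral_first(v, "l")  # express as a left-leg pattern
        rv_left = rv_for(mirrored, leg="more", side="l")
        assert similarity_index(rv_left, prv) == pytest.approx(1.0)


class TestAggregate:
    def _tasks(self, values):
        return {
            TaskId(j, leg): values.get((j, leg), np.nan)
            for leg in ("less", "more")
            for j in ("hip", "knee", "ankle", "STJ")
        }

    def test_all_ones(self):
        scores = aggregate(self._tasks({(j, l): 1.0 for j in ("hip", "knee", "ankle", "STJ") for l in ("less", "more")}))
        assert scores.leg_means["less"] == 1.0
        assert scores.total_mean == 1.0

    def test_leg_mean_arithmetic(self):
        vals = {("hip", "less"): 0.77, ("knee", "less"): 0.79,
                ("ankle", "less"): 0.91, ("STJ", "less"): 0.85}
        vals.update({(j, "more"): 0.5 for j in ("hip", "knee", "ankle", "STJ")})
        scores = aggregate(self._tasks(vals))
        assert scores.leg_means["less"] == pytest.approx(0.83)

    def test_strict_missing_propagation(self):
        vals = {(j, l): 0.8 for j in ("hip", "knee", "ankle", "STJ") for l in ("less", "more")}
        del vals[("knee", "less")]
        scores = aggregate(self._tasks(vals))
        assert np.isnan(scores.leg_means["less"])
        assert not np.isnan(scores.leg_means["more"])
        assert np.isnan(scores.total_mean)

    def test_min_tasks_coverage_rule(self):
        vals = {(j, l): 0.8 for j in ("hip", "knee", "ankle", "STJ") for l in ("less", "more")}
        del vals[("knee", "less")]
        scores = aggregate(self._tasks(vals), min_tasks=3)
        assert scores.leg_means["less"] == pytest.approx(0.8)
        assert scores.total_mean == pytest.approx(0.8)

    def test_permutation_invariance_within_leg(self, rng):
        vals = rng.uniform(0, 1, 4)
        joints = ("hip", "knee", "ankle", "STJ")
        base = {("hip", "more"): 0.5, ("knee", "more"): 0.5,
                ("ankle", "more"): 0.5, ("STJ", "more"): 0.5}
        first = aggregate(self._tasks({**base, **dict(zip([(j, "less") for j in joints], vals))}))
        second = aggregate(self._tasks({**base, **dict(zip([(j, "less") for j in joints], vals[::-1]))}))
        assert first.leg_means["less"] == pytest.approx(second.leg_means["less"], abs=1e-15)


class TestDecompose:
    def test_pure_target_activity(self):
        v = np.zeros(10)
        v[0], v[3] = 3.0, 2.0  # TA_r and GM_r: the ankle pair, right leg
        d = decompose(rv_for(v, joint="ankle"))
        assert d.target_share == pytest.approx(1.0)
        assert d.ipsilateral_offtarget_share == 0.0
        assert d.contralateral_share == 0.0

    def test_uniform_activity_splits_half_contralateral(self):
        d = decompose(rv_for(np.ones(10), joint="knee"))
        assert d.contralateral_share == pytest.approx(0.5)
        assert d.target_share == pytest.approx(0.2)
        assert d.ipsilateral_offtarget_share == pytest.approx(0.3)

    @settings(derandomize=True, max_examples=100)
    @given(nonneg_vectors)
    def test_shares_sum_to_one(self, v):
        if np.linalg.norm(v) == 0:
            return
        d = decompose(rv_for(v, joint="STJ"))
        total = d.target_share + d.ipsilateral_offtarget_share + d.contralateral_share
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_shares_match_brute_force_group_sums(self, rng):
        v = rng.uniform(0, 5, 10)
        d = decompose(rv_for(v, joint="ankle", leg="more", side="l"))
        vi = ipsilateral_first(v, "l")
        tot = np.sum(vi**2)
        # ankle pair = TA, GM -> ipsi-first positions 0 and 3
        assert d.target_share == pytest.approx((vi[0] ** 2 + vi[3] ** 2) / tot, rel=1e-12)
        assert d.contralateral_share == pytest.approx(np.sum(vi[5:] ** 2) / tot, rel=1e-12)

    def test_degenerate_rv_flagged(self):
        d = decompose(rv_for(np.zeros(10)))
        assert d.degenerate
        assert np.isnan(d.target_share)
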