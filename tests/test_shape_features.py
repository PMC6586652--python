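"""Shape variables, grouping, segment rules and drift-rate arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import driftdive as dd
from driftdive.rbsa import InflectionOrder
from driftdive.shape_features import (
    DEFAULT_WHITELIST,
    UnassignableSegmentError,
    load_segment_rules,
)


def make_summary(T, D, E, start=(0.0, 0.0), dive_id="s"):
    pts = np.zeros((6, 2))
    pts[0] = start
    pts[1:5, 0] = T
    pts[1:5, 1] = D
    pts[5] = (E, 0.0)
    return dd.SummarizedDive(dive_id, pts)


def order_for(summary):
    return dd.recover_order(summary)


class TestShapeVariables:
    def test_mdepthbias_from_definition(self):
        """E = 1000 s, max depth at T = 400 s -> mdepthbias = -100 s."""
        s = make_summary([200, 400, 600, 800], [300, 400, 250, 100], 1000.0)
        v = dd.compute_shape_variables(s, order_for(s))
        assert v.mdepthbias == pytest.approx(-100.0)

    def test_depth_ratios_and_meand(self):
        s = make_summary([200, 400, 600, 800], [200, 250, 300, 400], 1000.0)
        v = dd.compute_shape_variables(s, order_for(s))
        assert (v.d1, v.d2, v.d3, v.d4) == pytest.approx((0.5, 0.625, 0.75, 1.0))
        assert v.meand == pytest.approx(0.71875)

    def test_collinear_points_zero_regression_residuals(self):
        T = np.array([200.0, 400, 600, 800])
        D = 100.0 + 0.3 * T  # collinear
        s = make_summary(T, D, 1000.0)
        v = dd.compute_shape_variables(s, order_for(s))
        assert (v.r1, v.r2, v.r3, v.r4) == pytest.approx((0, 0, 0, 0), abs=1e-9)
        d = D / D.max()
        assert v.sdd == pytest.approx(np.std(d, ddof=1))

    def test_proportions_sum_to_one_and_residuals_sum_to_zero(self, small_trip):
        profiles, _, _ = small_trip
        kept, _ = dd.preprocess_filter(profiles)
        for p in kept[:80]:
            s = dd.bsa_summarize(p).summarized
            v = dd.compute_shape_variables(s, order_for(s))
            assert v.ps0 + v.ps1 + v.ps2 + v.ps3 + v.ps4 == pytest.approx(1.0, abs=1e-9)
            assert v.r1 + v.r2 + v.r3 + v.r4 == pytest.approx(0.0, abs=1e-6)
            assert 0 < v.t1 < v.t2 < v.t3 < v.t4 < 1
            assert max(v.d1, v.d2, v.d3, v.d4) == pytest.approx(1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        c=st.floats(0.1, 20.0),
        k=st.floats(0.1, 20.0),
    )
    def test_scale_invariance(self, c, k):
        """Scaling depths by c and times by k leaves proportional variables
        unchanged and scales the drift rate by c/k."""
        T = np.array([150.0, 850, 1000, 1150])
        D = np.array([260.0, 380, 250, 120])
        s1 = make_summary(T, D, 1300.0)
        s2 = make_summary(T * k, D * c, 1300.0 * k)
        o1, o2 = order_for(s1), order_for(s2)
        assert o1.label == o2.label
        v1 = dd.compute_shape_variables(s1, o1)
        v2 = dd.compute_shape_variables(s2, o2)
        for name in ("d1", "d2", "d3", "d4", "t1", "t4", "ps0", "ps1", "ps2",
                     "ps3", "ps4", "meand", "sdd", "mdepthr", "mrratio"):
            assert getattr(v1, name) == pytest.approx(getattr(v2, name), rel=1e-9), name
        r1 = dd.compute_drift_rate(s1, 1)
        r2 = dd.compute_drift_rate(s2, 1)
        assert r2 == pytest.approx(r1 * c / k, rel=1e-9)


class TestGrouping:
    def test_whitelist_membership(self):
        assert dd.assign_group("3.2.1.4") == "3.2.1.4"
        assert dd.assign_group("4.2.1.3") == "4.2.1.3"
        assert dd.assign_group("1.2.3.4") is None

    def test_exactly_eight_of_24_accepted(self):
        from driftdive.rbsa import ALL_ORDERS

        accepted = [o for o in ALL_ORDERS if dd.assign_group(o) is not None]
        assert len(accepted) == 8
        assert set(accepted) == set(DEFAULT_WHITELIST)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            dd.assign_group("1.1.2.3")


def vars_with(**overrides):
    """A neutral variable set, overridable per test."""
    base = dict(
        d1=0.5, d2=0.6, d3=0.7, d4=0.4,
        t1=0.1, t2=0.4, t3=0.7, t4=0.9,
        ps0=0.1, ps1=0.3, ps2=0.3, ps3=0.2, ps4=0.1,
        f=0.1, s=-0.1, t=0.2,
        sratio=5.0, meand=0.55, sdd=0.1,
        r1=1.0, r2=-1.0, r3=1.0, r4=-1.0,
        mrratio=0.05, mdepthbias=10.0, mdepthr=0.55,
        avratio=-1.0, hp2=0.6, hp3=0.7,
    )
    base.update(overrides)
    return dd.DiveShapeVariables(**base)


class TestSegmentRules:
    def test_group_3214_always_segment_2(self, rng):
        """Any variable values map group 3.2.1.4 to segment 2."""
        for _ in range(25):
            v = vars_with(
                mdepthbias=float(rng.normal(0, 100)),
                ps1=float(rng.uniform(0, 0.6)),
                avratio=float(rng.normal(0, 2)),
            )
            assert dd.assign_drift_segment("3.2.1.4", v) == 2

    def test_group_2143_ps1_rule(self, rng):
        """ps1 above 0.25 makes segment 1 the drift segment."""
        for _ in range(25):
            v = vars_with(ps1=float(rng.uniform(0.26, 0.8)),
                          ps2=float(rng.uniform(0, 0.3)),
                          ps3=float(rng.uniform(0, 0.3)))
            assert dd.assign_drift_segment("2.1.4.3", v) == 1
        assert dd.assign_drift_segment("2.1.4.3", vars_with(ps1=0.30)) == 1

    def test_group_2134_mdepthbias_branches(self):
        assert dd.assign_drift_segment("2.1.3.4", vars_with(mdepthbias=50.0)) == 1
        assert dd.assign_drift_segment("2.1.3.4", vars_with(mdepthbias=-50.0)) == 2

    def test_group_4213_inclusive_zero(self):
        assert dd.assign_drift_segment("4.2.1.3", vars_with(mdepthbias=0.0)) == 2

    def test_fallback_when_nothing_fires(self):
        # 2.1.3.4 with mdepthbias exactly zero falls back
        rules = load_segment_rules()
        seg = dd.assign_drift_segment("2.1.3.4", vars_with(mdepthbias=0.0), rules)
        assert seg == rules.groups["2.1.3.4"][1]

    def test_degenerate_variables_rejected(self):
        v = vars_with()
        v.degenerate = True
        with pytest.raises(UnassignableSegmentError):
            dd.assign_drift_segment("2.1.3.4", v)

    def test_unknown_group_raises(self):
        with pytest.raises(KeyError):
            dd.assign_drift_segment("1.2.3.4", vars_with())


class TestDriftRate:
    @pytest.fixture()
    def summary(self):
        return make_summary([300, 900, 1000, 1100], [200, 320, 250, 120], 1300.0)

    def test_sinking_is_negative(self, summary):
        assert dd.compute_drift_rate(summary, 1) == pytest.approx(-0.2)
        assert dd.drift_sign(-0.2) == "negative"

    def test_rising_is_positive(self):
        s = make_summary([300, 900, 1000, 1100], [320, 200, 150, 100], 1300.0)
        assert dd.compute_drift_rate(s, 1) == pytest.approx(0.2)
        assert dd.drift_sign(0.2) == "positive"

    def test_zero_rate_no_sign(self):
        s = make_summary([300, 900, 1000, 1100], [200, 200, 150, 100], 1300.0)
        assert dd.compute_drift_rate(s, 1) == 0.0
        assert dd.drift_sign(0.0) is None

    def test_bad_segment_index(self, summary):
        with pytest.raises(ValueError, match="segment"):
            dd.compute_drift_rate(summary, 0)
        with pytest.raises(ValueError, match="segment"):
            dd.compute_drift_rate(summary, 4)


class TestSegmentAssignmentOnSyntheticDives:
    def test_assigned_segment_overlaps_true_drift_phase(self, small_trip, label_map):
        """For accepted synthetic drift dives the assigned drift segment
        overlaps the true passive phase in at least 90% of cases."""
        profiles, _, _ = small_trip
        from driftdive.pipeline import detect_candidates

        kept, _ = dd.preprocess_filter(profiles)
        summaries = [dd.bsa_summarize(p).summarized for p in kept]
        cands, _ = detect_candidates(summaries)
        accepted, _ = dd.apply_threshold_rules(cands)
        prof = {p.dive_id: p for p in profiles}
        hits = total = 0
        for c in accepted:
            lab = label_map[c.dive_id]
            if lab.kind != "drift":
                continue
            total += 1
            p = prof[c.dive_id]
            lo, hi = lab.true_drift_segment
            seg_t0 = c.summary.T[c.drift_segment - 1]
            seg_t1 = c.summary.T[c.drift_segment]
            if max(seg_t0, p.times[lo]) < min(seg_t1, p.times[hi]):
                hits += 1
        assert total >= 20
        assert hits / total >= 0.90
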