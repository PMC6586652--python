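"""Sequential threshold engine and the accepting-rejecting tuner."""

import itertools

import numpy as np
import pytest

import driftdive as dd
from driftdive.threshold_filter import (
    FilterTrace,
    RulesetError,
    ThresholdRule,
    apply_threshold_rules,
    tune_threshold,
)
from test_shape_features import vars_with


def make_candidate(group="2.1.3.4", sign="negative", **var_overrides):
    import driftdive.shape_features as sf

    pts = np.array(
        [[0, 0], [150, 260], [1000, 380], [1100, 250], [1200, 120], [1300, 0]],
        dtype=float,
    )
    s = dd.SummarizedDive(f"c-{group}-{sign}", pts)
    order = dd.recover_order(s)
    return sf.CandidateDrift(
        summary=s,
        order=order,
        group=group,
        variables=vars_with(**var_overrides),
        drift_segment=1,
        drift_rate=-0.2 if sign == "negative" else 0.2,
        sign=sign,
    )


class TestApplyRules:
    def test_d1_rule_rejects_and_trace_names_criterion(self):
        cand = make_candidate(d1=0.9)
        rule = ThresholdRule("2.1.3.4", "negative", "d1", 1, op="<", value=0.8)
        accepted, traces = apply_threshold_rules([cand], [rule])
        assert accepted == []
        assert traces[0].outcome == "rejected"
        assert traces[0].failed_rule[1] == "d1"

    def test_group_3214_uses_d2_not_d1(self):
        """In the always-segment-2 group the 0.8 depth-ratio bound applies
        to d2; d1 is unconstrained."""
        cand = make_candidate(group="3.2.1.4", d1=0.95, d2=0.85)
        rules = dd.load_threshold_rules()
        accepted, traces = apply_threshold_rules([cand], rules)
        assert accepted == []
        assert traces[0].failed_rule[1] == "d2"

    def test_empty_ruleset_accepts_all(self):
        cands = [make_candidate(d1=v) for v in (0.1, 0.9, 0.99)]
        accepted, traces = apply_threshold_rules(cands, [])
        assert len(accepted) == 3
        assert all(t.outcome == "accepted" for t in traces)

    def test_first_failing_rule_recorded(self):
        cand = make_candidate(d1=0.9, d4=0.9)
        rules = [
            ThresholdRule("2.1.3.4", "both", "d1", 1, op="<", value=0.8),
            ThresholdRule("2.1.3.4", "both", "d4", 2, op="<", value=0.8),
        ]
        _, traces = apply_threshold_rules([cand], rules)
        assert traces[0].failed_rule == ("2.1.3.4", "d1", 1)

    def test_sign_specific_rules_skip_other_sign(self):
        cand = make_candidate(sign="positive", ps1=0.05)
        rule = ThresholdRule("2.1.3.4", "negative", "ps1", 1, op=">", value=0.4)
        accepted, _ = apply_threshold_rules([cand], [rule])
        assert len(accepted) == 1

    def test_interval_rule_is_open(self):
        rule = ThresholdRule("2.1.3.4", "both", "sdd", 1, lo=0.13, hi=0.4)
        at_edge = make_candidate(sdd=0.13)
        inside = make_candidate(sdd=0.2)
        accepted, _ = apply_threshold_rules([at_edge, inside], [rule])
        assert [c.variables.sdd for c in accepted] == [0.2]

    def test_unknown_variable_is_config_error(self):
        with pytest.raises(RulesetError, match="nope"):
            rule = ThresholdRule("2.1.3.4", "both", "nope", 1, op="<", value=0.5)
            apply_threshold_rules([make_candidate()], [rule])

    def test_order_invariance_of_accepted_set(self):
        """Conjunctive rules: sequential order changes traces only."""
        rules = [
            ThresholdRule("2.1.3.4", "both", "d1", 1, op="<", value=0.8),
            ThresholdRule("2.1.3.4", "both", "mrratio", 2, op="<", value=0.3),
            ThresholdRule("2.1.3.4", "both", "t4", 3, op=">", value=0.8),
        ]
        cands = [
            make_candidate(d1=d1, mrratio=mr, t4=t4)
            for d1 in (0.5, 0.9)
            for mr in (0.1, 0.5)
            for t4 in (0.7, 0.9)
        ]
        reference = None
        for perm in itertools.permutations(range(3)):
            shuffled = [
                ThresholdRule(r.group, r.sign, r.criterion, i + 1, op=r.op, value=r.value)
                for i, r in enumerate(rules[j] for j in perm)
            ]
            accepted, _ = apply_threshold_rules(cands, shuffled)
            ids = {id(c) for c in accepted}
            reference = ids if reference is None else reference
            assert ids == reference

    def test_tightening_bound_shrinks_accepted_set(self):
        cands = [make_candidate(d1=v) for v in np.linspace(0.1, 0.99, 20)]
        prev = None
        for bound in (0.9, 0.7, 0.5, 0.3):
            rule = ThresholdRule("2.1.3.4", "both", "d1", 1, op="<", value=bound)
            accepted, _ = apply_threshold_rules(cands, [rule])
            ids = {c.variables.d1 for c in accepted}
            if prev is not None:
                assert ids <= prev
            prev = ids

    def test_trace_invariant(self):
        with pytest.raises(ValueError, match="iff"):
            FilterTrace("x", "rejected", None)


class TestDefaultsReduceCandidates:
    def test_threshold_stage_outcome_on_synthetic_trip(self, small_trip, label_map):
        """Default rules cut the candidate pool hard while retaining at
        least 85% of the true drift dives that survived grouping.  (The
        <10%-of-all-dives property at the generator's default trip size is
        asserted in the end-to-end acceptance test.)"""
        from driftdive.pipeline import detect_candidates

        profiles, _, _ = small_trip
        kept, _ = dd.preprocess_filter(profiles)
        summaries = [dd.bsa_summarize(p).summarized for p in kept]
        cands, _ = detect_candidates(summaries)
        accepted, _ = apply_threshold_rules(cands)
        assert len(accepted) < len(cands) / 3
        drift_grouped = [c for c in cands if label_map[c.dive_id].kind == "drift"]
        drift_kept = [c for c in accepted if label_map[c.dive_id].kind == "drift"]
        assert len(drift_kept) / len(drift_grouped) >= 0.85


class TestTuneThreshold:
    def _labelled(self, drift_vals, non_vals, criterion="d1"):
        out = []
        for v in drift_vals:
            out.append((vars_with(**{criterion: float(v)}), "drift_certain"))
        for v in non_vals:
            out.append((vars_with(**{criterion: float(v)}), "non_drift"))
        return out

    def test_perfectly_separable(self):
        rule, curve = tune_threshold(
            self._labelled(np.linspace(0.1, 0.4, 50), np.linspace(0.6, 0.9, 50)),
            "d1",
        )
        assert rule is not None
        values = np.array([0.1 + i * 0.3 / 49 for i in range(50)])
        keep = values < rule.value if rule.op == "<" else values > rule.value
        assert keep.all()  # no drift dive lost
        non = np.linspace(0.6, 0.9, 50)
        rej = ~(non < rule.value if rule.op == "<" else non > rule.value)
        assert rej.all()  # all non-drift rejected

    def test_identical_distributions_return_none(self):
        vals = np.linspace(0, 1, 40)
        rule, _ = tune_threshold(self._labelled(vals, vals), "d1")
        assert rule is None

    def test_quantile_mixture_brute_force(self, rng):
        """Drift below 0.5, non-drift uniform on (0, 1): the optimum is a
        cutoff near 0.5 rejecting about half the non-drift dives.  Verified
        against a brute-force scan over all cutoffs."""
        drift = rng.uniform(0.0, 0.5, 400)
        non = rng.uniform(0.0, 1.0, 400)
        labelled = self._labelled(drift, non)
        rule, curve = tune_threshold(labelled, "d1", target_rejection=0.4, max_loss=0.0)
        assert rule is not None and rule.op == "<"
        assert rule.value == pytest.approx(0.5, abs=0.05)
        sel = curve[(curve.loss <= 0.0) & (curve.op == "<")]
        assert rule.value == sel.loc[sel.rejection.idxmax(), "cutoff"]
        best = sel.rejection.max()
        assert best == pytest.approx(0.5, abs=0.08)

    def test_constant_criterion_returns_none(self):
        rule, curve = tune_threshold(self._labelled([0.5] * 10, [0.5] * 10), "d1")
        assert rule is None
        assert curve.empty

    def test_needs_both_labels(self):
        with pytest.raises(ValueError, match="both"):
            tune_threshold(self._labelled([0.2], []), "d1")
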