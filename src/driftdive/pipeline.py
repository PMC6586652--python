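"""End-to-end drift-dive detection pipeline.

Chains the stages for one seal: pre-detection filters, broken-stick
summarization (when starting from high-resolution profiles), selection-
order recovery, candidate grouping, drift-segment assignment and drift
rate, sequential threshold criteria, and the trajectory filter.  Each
stage is also usable on its own; this module only wires them together and
keeps the bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bsa import bsa_summarize
from .dive_model import HighResProfile, LabelledDive, SummarizedDive, preprocess_filter
from .rbsa import recover_order
from .shape_features import (
    CandidateDrift,
    SegmentRules,
    UnassignableSegmentError,
    assign_drift_segment,
    assign_group,
    compute_drift_rate,
    compute_shape_variables,
    drift_sign,
    load_segment_rules,
)
from .threshold_filter import ThresholdRule, apply_threshold_rules, load_threshold_rules
from .trajectory_filter import (
    BuoyancyModel,
    FilteredTrajectory,
    FitConfig,
    fit_trajectory_filter,
)

__all__ = ["PipelineResult", "summarize_profiles", "detect_candidates", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced for one seal."""

    n_input_dives: int
    summaries: list[SummarizedDive]
    candidates: list[CandidateDrift]  # after grouping + segment + sign
    thresholded: list[CandidateDrift]  # after threshold criteria
    trajectory: FilteredTrajectory | None
    final: pd.DataFrame  # accepted dives: dive_id, date, rate, p_inside
    pre_filter_table: pd.DataFrame  # candidates sent to the trajectory filter
    rejections: dict[str, int] = field(default_factory=dict)

    @property
    def retained_fraction(self) -> float:
        return len(self.final) / self.n_input_dives if self.n_input_dives else np.nan


def summarize_profiles(
    profiles: list[HighResProfile],
    min_depth: float = 100.0,
    min_duration: float = 300.0,
) -> tuple[list[SummarizedDive], list[tuple[str, str]]]:
    """Pre-filter high-resolution dives and summarize the keepers."""
    kept, log = preprocess_filter(profiles, min_depth=min_depth, min_duration=min_duration)
    return [bsa_summarize(p).summarized for p in kept], log


def detect_candidates(
    summaries: list[SummarizedDive],
    segment_rules: SegmentRules | None = None,
) -> tuple[list[CandidateDrift], dict[str, int]]:
    """Grouping, drift-segment assignment and signed drift rate.

    Returns the candidate drift dives and a tally of rejection reasons
    (non-candidate order, degenerate geometry, zero drift rate).
    """
    rules = segment_rules or load_segment_rules()
    candidates: list[CandidateDrift] = []
    tally = {"order_not_candidate": 0, "degenerate": 0, "zero_rate": 0}
    for s in summaries:
        order = recover_order(s)
        group = assign_group(order, rules.whitelist)
        if group is None:
            tally["order_not_candidate"] += 1
            continue
        variables = compute_shape_variables(s, order)
        try:
            segment = assign_drift_segment(group, variables, rules)
        except UnassignableSegmentError:
            tally["degenerate"] += 1
            continue
        rate = compute_drift_rate(s, segment)
        sign = drift_sign(rate)
        if sign is None:
            tally["zero_rate"] += 1
            continue
        candidates.append(
            CandidateDrift(
                summary=s,
                order=order,
                group=group,
                variables=variables,
                drift_segment=segment,
                drift_rate=rate,
                sign=sign,
            )
        )
    return candidates, tally


def _candidate_table(cands: list[CandidateDrift]) -> pd.DataFrame:
    rows = []
    for c in cands:
        rows.append(
            {
                "dive_id": c.dive_id,
                "date": c.summary.start_datetime,
                "rate": c.drift_rate,
                "group": c.group,
                "segment": c.drift_segment,
            }
        )
    return pd.DataFrame(rows, columns=["dive_id", "date", "rate", "group", "segment"])


def run_pipeline(
    profiles: list[HighResProfile] | None = None,
    summaries: list[SummarizedDive] | None = None,
    segment_rules: SegmentRules | None = None,
    threshold_rules: list[ThresholdRule] | None = None,
    model: BuoyancyModel | None = None,
    fit_config: FitConfig | None = None,
    seed: int | None = None,
    min_depth: float = 100.0,
    min_duration: float = 300.0,
) -> PipelineResult:
    """Run the full hierarchical detection for one seal.

    Give either high-resolution ``profiles`` (summarized in-package) or
    transmitted ``summaries``.  Dive start datetimes are required for the
    trajectory filter's time axis (days since the first candidate).
    """
    if (profiles is None) == (summaries is None):
        raise ValueError("give exactly one of profiles or summaries")
    if profiles is not None:
        n_input = len(profiles)
        summaries, _ = summarize_profiles(profiles, min_depth, min_duration)
    else:
        n_input = len(summaries)
        summaries, _ = preprocess_filter(summaries, min_depth, min_duration)

    candidates, tally = detect_candidates(summaries, segment_rules)
    thresholded, traces = apply_threshold_rules(
        candidates, threshold_rules if threshold_rules is not None else load_threshold_rules()
    )
    tally["threshold_rejected"] = sum(t.outcome == "rejected" for t in traces)

    pre_table = _candidate_table(thresholded)
    if pre_table.empty:
        return PipelineResult(
            n_input_dives=n_input,
            summaries=summaries,
            candidates=candidates,
            thresholded=thresholded,
            trajectory=None,
            final=pre_table.assign(p_inside=pd.Series(dtype=float)),
            pre_filter_table=pre_table,
            rejections=tally,
        )
    if pre_table["date"].isna().any():
        raise ValueError("candidates need start datetimes for the trajectory filter")

    pre_table = pre_table.sort_values("date", kind="stable").reset_index(drop=True)
    dates = pd.to_datetime(pre_table["date"], utc=True)
    t_days = (dates - dates.iloc[0]).dt.total_seconds().to_numpy() / 86400.0
    # strictly increasing times: nudge exact duplicates by a second
    eps = 1.0 / 86400.0
    for i in range(1, t_days.size):
        if t_days[i] <= t_days[i - 1]:
            t_days[i] = t_days[i - 1] + eps

    traj = fit_trajectory_filter(
        t_days, pre_table["rate"].to_numpy(), model=model, config=fit_config, seed=seed
    )
    final = pre_table.copy()
    final["p_inside"] = traj.table["p_inside"].to_numpy()
    final = final.loc[final["p_inside"] > traj.threshold].reset_index(drop=True)
    tally["trajectory_rejected"] = len(pre_table) - len(final)

    return PipelineResult(
        n_input_dives=n_input,
        summaries=summaries,
        candidates=candidates,
        thresholded=thresholded,
        trajectory=traj,
        final=final,
        pre_filter_table=pre_table,
        rejections=tally,
    )
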