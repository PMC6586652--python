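"""Dive-shape variables, candidate grouping and drift-rate computation.

Every variable is proportional (unit-free) wherever possible so that the
same thresholds apply to short/long and shallow/deep dives alike.  Notation
follows the summarized-dive geometry: the four subsurface inflection points
IFP1..IFP4 at {T_i, D_i}, dive duration E, segments S1..S3 joining
consecutive inflection points (the descent start->IFP1 and final ascent
IFP4->end are never drift segments).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from ._predicates import Predicate, PredicateError
from .dive_model import SummarizedDive
from .rbsa import ALL_ORDERS, InflectionOrder

__all__ = [
    "DiveShapeVariables",
    "CandidateDrift",
    "SegmentRules",
    "UnassignableSegmentError",
    "DEFAULT_WHITELIST",
    "compute_shape_variables",
    "assign_group",
    "assign_drift_segment",
    "compute_drift_rate",
    "drift_sign",
    "load_segment_rules",
]

#: The eight inflection-order groups retained as candidate drift dives.
DEFAULT_WHITELIST = frozenset(
    {"2.1.3.4", "2.1.4.3", "2.4.1.3", "3.1.2.4", "3.1.4.2", "3.2.1.4",
     "3.4.1.2", "4.2.1.3"}
)


class UnassignableSegmentError(ValueError):
    """No segment rule fired and the group declares no fallback."""


@dataclass
class DiveShapeVariables:
    """Numeric shape descriptors of one summarized dive.

    d1..d4
        Depth ratios D_i / max_depth (unitless, in [0, 1]).
    t1..t4
        Time ratios T_i / E.
    ps0..ps4
        Duration proportions of the descent, segments 1-3, and the final
        ascent; they sum to 1.
    f, s, t
        Vertical rates (m/s, positive = deepening) of segments 1-3.
    sratio
        Descent rate divided by the first post-descent segment rate.
    meand, sdd
        Mean and sample standard deviation of {d1..d4}.
    r1..r4
        Residuals (m) of the least-squares line through {(T_i, D_i)}; they
        sum to zero.
    mrratio
        Smallest recovered BSA residual over the maximum depth.
    mdepthbias
        Time at maximum depth minus half the dive duration (seconds;
        positive = deepest point in the second half of the dive).
    mdepthr
        Mean of D1..D4 over the maximum depth.
    avratio
        Mean signed vertical rate over the segments after the deepest
        inflection point divided by the mean over those before it.
    hp2, hp3
        Proportional depths of inflection points 2 and 3 (aliases of
        d2, d3 used by some group rules).
    """

    d1: float; d2: float; d3: float; d4: float
    t1: float; t2: float; t3: float; t4: float
    ps0: float; ps1: float; ps2: float; ps3: float; ps4: float
    f: float; s: float; t: float
    sratio: float
    meand: float; sdd: float
    r1: float; r2: float; r3: float; r4: float
    mrratio: float
    mdepthbias: float
    mdepthr: float
    avratio: float
    hp2: float; hp3: float
    degenerate: bool = False

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "degenerate"}


@dataclass
class CandidateDrift:
    """A summarized dive that survived grouping, with its drift segment."""

    summary: SummarizedDive
    order: InflectionOrder
    group: str
    variables: DiveShapeVariables
    drift_segment: int  # 1-3
    drift_rate: float  # m/s, negative = sinking
    sign: str  # positive | negative

    @property
    def dive_id(self) -> str:
        return self.summary.dive_id


def compute_shape_variables(
    summary: SummarizedDive, order: InflectionOrder
) -> DiveShapeVariables:
    """Compute all shape variables for one summarized dive."""
    T, D = summary.T, summary.D
    E = summary.E
    max_depth = float(D.max())
    start_t, end_t = summary.points[0, 0], summary.points[5, 0]

    seg_dt = np.diff(np.concatenate(([start_t], T, [end_t])))
    degenerate = bool(np.any(seg_dt <= 0) or E <= 0 or max_depth <= 0)

    d = D / max_depth
    t_ratio = (T - start_t) / E
    ps = seg_dt / E  # ps0..ps4

    seg_dz = np.diff(np.concatenate(([summary.points[0, 1]], D, [summary.points[5, 1]])))
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = seg_dz / seg_dt  # descent, S1, S2, S3, ascent
        sratio = rates[0] / rates[1] if rates[1] != 0 else np.inf

    # least-squares line through the four inflection points, residuals in m
    X = np.column_stack([np.ones(4), T])
    coef, *_ = np.linalg.lstsq(X, D, rcond=None)
    r = D - X @ coef

    residuals = order.residuals
    mrratio = float(np.min(residuals) / max_depth) if max_depth > 0 else np.inf

    i_deep = int(np.argmax(D))  # 0-based index of deepest inflection point
    mdepthbias = float((T[i_deep] - start_t) - E / 2.0)

    before = rates[: i_deep + 1]  # segments ending at or before the deepest point
    after = rates[i_deep + 1 :]
    mb, ma = float(np.mean(before)), float(np.mean(after))
    avratio = ma / mb if mb != 0 else np.inf

    return DiveShapeVariables(
        d1=float(d[0]), d2=float(d[1]), d3=float(d[2]), d4=float(d[3]),
        t1=float(t_ratio[0]), t2=float(t_ratio[1]),
        t3=float(t_ratio[2]), t4=float(t_ratio[3]),
        ps0=float(ps[0]), ps1=float(ps[1]), ps2=float(ps[2]),
        ps3=float(ps[3]), ps4=float(ps[4]),
        f=float(rates[1]), s=float(rates[2]), t=float(rates[3]),
        sratio=float(sratio),
        meand=float(np.mean(d)), sdd=float(np.std(d, ddof=1)),
        r1=float(r[0]), r2=float(r[1]), r3=float(r[2]), r4=float(r[3]),
        mrratio=mrratio,
        mdepthbias=mdepthbias,
        mdepthr=float(np.mean(d)) if max_depth > 0 else np.nan,
        avratio=float(avratio),
        hp2=float(d[1]), hp3=float(d[2]),
        degenerate=degenerate,
    )


def assign_group(
    order: InflectionOrder | str,
    whitelist: frozenset[str] | set[str] = DEFAULT_WHITELIST,
) -> str | None:
    """Return the candidate group label, or None when the order is not a
    candidate drift-dive group."""
    label = order if isinstance(order, str) else order.label
    if label not in ALL_ORDERS:
        raise ValueError(f"{label!r} is not a permutation of 1..4")
    return label if label in whitelist else None


# ---------------------------------------------------------------------------
# Segment-rule engine
# ---------------------------------------------------------------------------


@dataclass
class SegmentRules:
    """Declarative drift-segment rules: per group an ordered list of
    (predicate, segment) plus an optional fallback segment."""

    whitelist: frozenset[str]
    groups: dict[str, tuple[list[tuple[Predicate, int]], int | None]]

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "SegmentRules":
        groups = {}
        for label, entry in raw["groups"].items():
            rules = [
                (Predicate(r["when"]), int(r["segment"]))
                for r in entry.get("rules", [])
            ]
            for _, seg in rules:
                if seg not in (1, 2, 3):
                    raise PredicateError(f"group {label}: segment {seg} not in 1..3")
            fb = entry.get("fallback")
            groups[label] = (rules, int(fb) if fb is not None else None)
        return cls(whitelist=frozenset(raw["whitelist"]), groups=groups)


_default_segment_rules: SegmentRules | None = None


def load_segment_rules(path=None) -> SegmentRules:
    """Load segment rules from YAML (the packaged defaults when ``path`` is
    None)."""
    global _default_segment_rules
    if path is None:
        if _default_segment_rules is None:
            text = resources.files("driftdive.data").joinpath("segment_rules.yml").read_text()
            _default_segment_rules = SegmentRules.from_mapping(yaml.safe_load(text))
        return _default_segment_rules
    with open(path) as fh:
        return SegmentRules.from_mapping(yaml.safe_load(fh))


def assign_drift_segment(
    group: str,
    variables: DiveShapeVariables,
    rules: SegmentRules | None = None,
) -> int:
    """Assign the drifting segment (1-3) for a grouped candidate dive."""
    rules = rules or load_segment_rules()
    if group not in rules.groups:
        raise KeyError(f"no segment rules for group {group!r}")
    if variables.degenerate:
        raise UnassignableSegmentError(f"group {group}: degenerate variables")
    row, fallback = rules.groups[group]
    vars_dict = variables.to_dict()
    for predicate, segment in row:
        if predicate(vars_dict):
            return segment
    if fallback is None:
        raise UnassignableSegmentError(
            f"group {group}: no predicate fired and no fallback declared"
        )
    return fallback


def compute_drift_rate(summary: SummarizedDive, segment: int) -> float:
    """Signed drift rate (m/s) over a segment's endpoints.

    Dr = -(D_end - D_start) / (T_end - T_start) under the positive-down
    depth convention: a sinking seal (depth increasing) has negative Dr.
    """
    if segment not in (1, 2, 3):
        raise ValueError(f"segment must be 1, 2 or 3, got {segment}")
    T, D = summary.T, summary.D
    dt = T[segment] - T[segment - 1]
    if dt <= 0:
        raise ValueError(f"dive {summary.dive_id!r}: zero-duration segment {segment}")
    return float(-(D[segment] - D[segment - 1]) / dt)


def drift_sign(drift_rate: float) -> str | None:
    """Sign subgroup of a drift rate; exactly-zero rates belong to neither
    subgroup and return None."""
    if drift_rate > 0:
        return "positive"
    if drift_rate < 0:
        return "negative"
    return None
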