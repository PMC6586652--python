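"""Sequential per-group, per-sign threshold criteria for candidate dives.

Each rule bounds one shape variable; rules matching a candidate's
(group, sign) are applied in order and the first failure rejects the dive.
All bounds are strict inequalities and bracketed pairs in the published
criteria are open intervals, so an interval is expressed as two sequential
one-sided rules.  The engine is deliberately data-driven: the default
ruleset ships as an editable YAML file.

`tune_threshold` is the accepting-rejecting utility used to derive such
criteria from labelled data: it scans every observed cutoff for one
variable and proposes the one-sided rule that rejects the most non-drift
dives while losing at most a small budgeted fraction of true drift dives.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .shape_features import CandidateDrift, DiveShapeVariables

__all__ = [
    "ThresholdRule",
    "FilterTrace",
    "RulesetError",
    "load_threshold_rules",
    "apply_threshold_rules",
    "tune_threshold",
]


class RulesetError(ValueError):
    """A threshold rule is malformed or names an unknown variable."""


_OPS = {
    "<": lambda x, v: x < v,
    ">": lambda x, v: x > v,
    "<=": lambda x, v: x <= v,
    ">=": lambda x, v: x >= v,
}


@dataclass(frozen=True)
class ThresholdRule:
    """One bound on one shape variable for one (group, sign) cell.

    Either ``op``/``value`` (one-sided bound) or ``lo``/``hi`` (open
    interval) must be given.  ``sign`` is "negative", "positive" or "both".
    """

    group: str
    sign: str
    criterion: str
    order_index: int
    op: str | None = None
    value: float | None = None
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self):
        if self.sign not in ("negative", "positive", "both"):
            raise RulesetError(f"rule {self}: bad sign {self.sign!r}")
        if self.op is not None:
            if self.op not in _OPS or self.value is None:
                raise RulesetError(f"rule {self}: bad one-sided bound")
        elif self.lo is not None and self.hi is not None:
            if not self.lo < self.hi:
                raise RulesetError(f"rule {self}: interval needs lo < hi")
        else:
            raise RulesetError(f"rule {self}: neither bound nor interval given")

    def matches(self, group: str, sign: str) -> bool:
        return self.group == group and self.sign in ("both", sign)

    def passes(self, variables: DiveShapeVariables) -> bool:
        if self.criterion not in variables.to_dict():
            raise RulesetError(
                f"rule on {self.criterion!r} (group {self.group}): unknown variable"
            )
        x = getattr(variables, self.criterion)
        if not np.isfinite(x):
            return False
        if self.op is not None:
            return bool(_OPS[self.op](x, self.value))
        return bool(self.lo < x < self.hi)

    def describe(self) -> str:
        if self.op is not None:
            return f"{self.criterion} {self.op} {self.value:g}"
        return f"{self.criterion} in ({self.lo:g}, {self.hi:g})"


@dataclass
class FilterTrace:
    """Per-dive outcome of the threshold stage."""

    dive_id: str
    outcome: str  # accepted | rejected
    failed_rule: tuple[str, str, int] | None = None  # (group, criterion, order)

    def __post_init__(self):
        if (self.outcome == "rejected") != (self.failed_rule is not None):
            raise ValueError("failed_rule present iff rejected")


_default_rules: list[ThresholdRule] | None = None


def load_threshold_rules(path=None) -> list[ThresholdRule]:
    """Load threshold rules from YAML (packaged defaults when ``path`` is
    None)."""
    global _default_rules
    if path is None and _default_rules is not None:
        return list(_default_rules)
    if path is None:
        raw = yaml.safe_load(
            resources.files("driftdive.data").joinpath("threshold_rules.yml").read_text()
        )
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    rules = []
    for r in raw["rules"]:
        rules.append(
            ThresholdRule(
                group=str(r["group"]),
                sign=str(r.get("sign", "both")),
                criterion=str(r["criterion"]),
                order_index=int(r["order"]),
                op=r.get("op"),
                value=r.get("value"),
                lo=r.get("lo"),
                hi=r.get("hi"),
            )
        )
    if path is None:
        _default_rules = list(rules)
    return rules


def apply_threshold_rules(
    candidates: Sequence[CandidateDrift],
    ruleset: Iterable[ThresholdRule] | None = None,
) -> tuple[list[CandidateDrift], list[FilterTrace]]:
    """Apply the sequential threshold criteria to candidate drift dives.

    Returns the accepted candidates (input order preserved) and one trace
    per candidate.  An empty ruleset accepts everything.
    """
    ruleset = load_threshold_rules() if ruleset is None else list(ruleset)
    accepted, traces = [], []
    for cand in candidates:
        rules = sorted(
            (r for r in ruleset if r.matches(cand.group, cand.sign)),
            key=lambda r: r.order_index,
        )
        failed = None
        for rule in rules:
            if not rule.passes(cand.variables):
                failed = (rule.group, rule.criterion, rule.order_index)
                break
        if failed is None:
            accepted.append(cand)
            traces.append(FilterTrace(cand.dive_id, "accepted"))
        else:
            traces.append(FilterTrace(cand.dive_id, "rejected", failed))
    return accepted, traces


def tune_threshold(
    labelled: Sequence[tuple[DiveShapeVariables, str]],
    criterion: str,
    target_rejection: float = 0.5,
    max_loss: float = 0.10,
    group: str = "*",
    sign: str = "both",
) -> tuple[ThresholdRule | None, pd.DataFrame]:
    """Propose a one-sided threshold for one criterion from labelled dives.

    ``labelled`` pairs shape variables with a label, where any label
    starting with ``"drift"`` counts as a drift dive.  Every observed value
    of the criterion is scanned as a cutoff in both directions; among
    cutoffs losing at most ``max_loss`` of the drift dives, the one
    rejecting the most non-drift dives is proposed, provided it reaches
    ``target_rejection``.  Returns (rule or None, accept/reject curve).

    The curve has one row per (cutoff, direction) with the non-drift
    rejection fraction and drift-dive loss fraction, for plotting.
    """
    values = np.array([getattr(v, criterion) for v, _ in labelled], dtype=float)
    is_drift = np.array([lbl.startswith("drift") for _, lbl in labelled])
    if not (is_drift.any() and (~is_drift).any()):
        raise ValueError("need both drift and non-drift dives")
    n_drift = int(is_drift.sum())
    n_non = int((~is_drift).sum())

    cutoffs = np.unique(values[np.isfinite(values)])
    if cutoffs.size < 2:
        return None, pd.DataFrame(columns=["cutoff", "op", "rejection", "loss"])

    rows = []
    # op "<" keeps x < c (rejects x >= c); op ">" keeps x > c.
    for op in ("<", ">"):
        for c in cutoffs:
            keep = values < c if op == "<" else values > c
            loss = 1.0 - keep[is_drift].sum() / n_drift
            rejection = 1.0 - keep[~is_drift].sum() / n_non
            rows.append((float(c), op, float(rejection), float(loss)))
    curve = pd.DataFrame(rows, columns=["cutoff", "op", "rejection", "loss"])

    ok = curve[(curve["loss"] <= max_loss) & (curve["rejection"] >= target_rejection)]
    if ok.empty:
        return None, curve
    best = ok.sort_values(["rejection", "loss"], ascending=[False, True]).iloc[0]
    rule = ThresholdRule(
        group=group,
        sign=sign,
        criterion=criterion,
        order_index=1,
        op=str(best["op"]),
        value=float(best["cutoff"]),
    )
    return rule, curve
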