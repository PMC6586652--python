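"""Evaluation of detected drift rates against high-resolution truth.

Two levels of comparison:

* per dive — the "true" drift rate of a dive is the median of the
  per-time-step vertical rates inside its (known) drifting segment of the
  high-resolution record; bias is the summarized-profile rate minus that
  median.
* per day — the observed daily averaged drift rate (ODDR, from
  high-resolution drift dives) against the daily averaged drift rate from
  summarized profiles (SDDR), before and after the trajectory filter; the
  squared error per shared day and its mean (msr) quantify the filter's
  improvement.

Daily bins are UTC calendar days of the dive start; daily averages are
arithmetic means over the day's dives; days present in only one series are
dropped from the msr (pairwise-complete) and logged in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dive_model import HighResProfile

__all__ = ["ValidationReport", "true_drift_rate", "daily_mean", "compute_validation_metrics"]


def true_drift_rate(profile: HighResProfile, segment: tuple[int, int]) -> float:
    """Median per-time-step vertical rate (m/s) inside a sample range.

    ``segment`` is an inclusive (start, stop) pair of sample indices.  The
    sign convention matches the summarized drift rate: negative = sinking.
    The median makes the estimate robust to an isolated spike in a way the
    mean is not.
    """
    lo, hi = segment
    if hi - lo + 1 < 2:
        raise ValueError("segment must contain at least 2 samples")
    t = profile.times[lo : hi + 1]
    z = profile.depths[lo : hi + 1]
    rates = -np.diff(z) / np.diff(t)
    return float(np.median(rates))


def daily_mean(table: pd.DataFrame, value: str = "rate") -> pd.DataFrame:
    """Mean of ``value`` per UTC calendar day of ``date`` with dive counts."""
    df = table.copy()
    df["day"] = pd.to_datetime(df["date"], utc=True).dt.date
    out = df.groupby("day", as_index=False).agg(
        mean=(value, "mean"), n_dives=(value, "size")
    )
    return out


@dataclass
class ValidationReport:
    """Bias table, daily series and mean-squared-error summary."""

    bias: pd.DataFrame  # per matched dive: dive_id, rate, true_rate, bias
    daily: pd.DataFrame  # day, ODDR, SDDR_pre, SDDR_post, n columns
    msr_pre: float
    msr_post: float
    se_upper95_pre: float
    se_upper95_post: float
    dropped_days: list

    @property
    def median_bias(self) -> float:
        return float(self.bias["bias"].median()) if len(self.bias) else np.nan


def compute_validation_metrics(
    truth: pd.DataFrame,
    detected: pd.DataFrame,
    pre_filter: pd.DataFrame,
) -> ValidationReport:
    """Compare detected drift rates with high-resolution ground truth.

    Parameters
    ----------
    truth : frame with columns dive_id, date, rate
        Per-dive median "true" rates of the known drift dives.
    detected : frame with columns dive_id, date, rate
        Rates accepted by the full method (post trajectory filter).
    pre_filter : frame with columns dive_id, date, rate
        Candidate rates before the trajectory filter.

    Notes
    -----
    Per-dive bias is computed over dives present in both ``truth`` and
    ``detected``.  The daily ODDR comes from ``truth``; SDDR_pre/SDDR_post
    from the two detection tables; msr is the mean squared error between
    each SDDR and the ODDR over shared days.
    """
    merged = detected.merge(
        truth.rename(columns={"rate": "true_rate"})[["dive_id", "true_rate"]],
        on="dive_id",
        how="inner",
    )
    merged["bias"] = merged["rate"] - merged["true_rate"]

    oddr = daily_mean(truth).rename(columns={"mean": "ODDR", "n_dives": "n_true"})
    pre = daily_mean(pre_filter).rename(columns={"mean": "SDDR_pre", "n_dives": "n_pre"})
    post = daily_mean(detected).rename(columns={"mean": "SDDR_post", "n_dives": "n_post"})
    daily = oddr.merge(pre, on="day", how="outer").merge(post, on="day", how="outer")

    def _msr(col):
        both = daily.dropna(subset=["ODDR", col])
        if both.empty:
            return np.nan, np.nan, []
        se = (both[col] - both["ODDR"]) ** 2
        dropped = sorted(set(daily["day"]) - set(both["day"]))
        return float(se.mean()), float(se.quantile(0.95)), dropped

    msr_pre, up_pre, dropped_pre = _msr("SDDR_pre")
    msr_post, up_post, dropped_post = _msr("SDDR_post")
    if np.isnan(msr_pre) and np.isnan(msr_post):
        import warnings

        warnings.warn("no overlapping days between truth and detections", stacklevel=2)

    return ValidationReport(
        bias=merged,
        daily=daily,
        msr_pre=msr_pre,
        msr_post=msr_post,
        se_upper95_pre=up_pre,
        se_upper95_post=up_post,
        dropped_days=sorted(set(dropped_pre) | set(dropped_post)),
    )
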