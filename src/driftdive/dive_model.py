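"""Core dive containers, tabular I/O and the pre-detection dive filters.

Depth convention throughout the package: metres, positive downward.  Times
within a dive are seconds since the dive start (float); the absolute start
timestamp is kept separately and is only used for daily (UTC) binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HighResProfile",
    "SummarizedDive",
    "LabelledDive",
    "DiveValidationError",
    "DiveFormatError",
    "load_profiles",
    "write_profiles",
    "load_summaries",
    "write_summaries",
    "preprocess_filter",
    "split_dives",
    "SURFACE_THRESHOLD_M",
]

#: Depth (m) at or above which a sample counts as "at the surface" when
#: splitting continuous records into dives.
SURFACE_THRESHOLD_M = 2.0


class DiveValidationError(ValueError):
    """A dive violates a structural invariant (named in the message)."""


class DiveFormatError(ValueError):
    """An input table cannot be interpreted as dive data."""


@dataclass
class HighResProfile:
    """One dive's raw time-depth(-velocity) series.

    Parameters
    ----------
    dive_id : str
        Identifier unique within a data set.
    times : array of float
        Seconds since dive start, strictly increasing.
    depths : array of float
        Depth in metres, positive downward, all >= 0.
    velocity : array of float, optional
        Swim speed (m/s) per sample, if the tag recorded it.
    start_datetime : pandas.Timestamp, optional
        Absolute start of the dive, used for daily binning.
    """

    dive_id: str
    times: np.ndarray
    depths: np.ndarray
    velocity: np.ndarray | None = None
    start_datetime: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.velocity is not None:
            self.velocity = np.asarray(self.velocity, dtype=float)
        if self.times.size < 3:
            raise DiveValidationError(
                f"dive {self.dive_id!r}: needs >= 3 samples, got {self.times.size}"
            )
        if self.times.size != self.depths.size:
            raise DiveValidationError(
                f"dive {self.dive_id!r}: times and depths differ in length"
            )
        if not np.all(np.diff(self.times) > 0):
            raise DiveValidationError(
                f"dive {self.dive_id!r}: times are not strictly increasing"
            )
        if np.any(self.depths < 0):
            raise DiveValidationError(f"dive {self.dive_id!r}: negative depth")

    @property
    def max_depth(self) -> float:
        return float(self.depths.max())

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def n_samples(self) -> int:
        return int(self.times.size)


@dataclass
class SummarizedDive:
    """Six-point broken-stick abstraction of a dive.

    ``points`` holds the (time s, depth m) pairs sorted by time:
    start {0, ~0}, the four subsurface inflection points
    IFP1 {T1, D1} .. IFP4 {T4, D4}, and end {E, ~0}.

    ``bsa_residuals`` are the four residual magnitudes (m) in *selection*
    order; the last one is the largest discrepancy still unexplained by the
    summary and indexes vertical activity the summary missed.
    """

    dive_id: str
    points: np.ndarray  # shape (6, 2): columns (time, depth)
    bsa_residuals: np.ndarray | None = None
    selection_order: tuple[int, int, int, int] | None = None
    start_datetime: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (6, 2):
            raise DiveValidationError(
                f"dive {self.dive_id!r}: summary needs 6 (time, depth) points"
            )
        t = self.points[:, 0]
        if not np.all(np.diff(t) > 0):
            raise DiveValidationError(
                f"dive {self.dive_id!r}: summary times not strictly increasing"
            )
        if self.bsa_residuals is not None:
            self.bsa_residuals = np.asarray(self.bsa_residuals, dtype=float)
            if self.bsa_residuals.shape != (4,):
                raise DiveValidationError(
                    f"dive {self.dive_id!r}: expected 4 residuals"
                )
            if np.any(self.bsa_residuals < 0):
                raise DiveValidationError(
                    f"dive {self.dive_id!r}: negative residual"
                )

    # -- convenience accessors (T1..T4, D1..D4, E in field notation) ------
    @property
    def T(self) -> np.ndarray:
        """Times of the four subsurface inflection points."""
        return self.points[1:5, 0]

    @property
    def D(self) -> np.ndarray:
        """Depths of the four subsurface inflection points."""
        return self.points[1:5, 1]

    @property
    def E(self) -> float:
        """Total dive duration (time of the end point)."""
        return float(self.points[5, 0] - self.points[0, 0])

    @property
    def duration(self) -> float:
        return self.E

    @property
    def max_depth(self) -> float:
        return float(self.D.max())


@dataclass
class LabelledDive:
    """Ground-truth label attached to a dive (synthetic or visual)."""

    dive_id: str
    label: str  # drift_certain | drift_uncertain | non_drift
    sign: str = "none"  # positive | negative | none
    true_drift_segment: tuple[int, int] | None = None  # sample index range
    kind: str | None = None  # generator dive kind, if synthetic

    def __post_init__(self) -> None:
        if self.label not in {"drift_certain", "drift_uncertain", "non_drift"}:
            raise DiveValidationError(f"unknown label {self.label!r}")
        if self.sign not in {"positive", "negative", "none"}:
            raise DiveValidationError(f"unknown sign {self.sign!r}")
        if (self.sign == "none") != (self.label == "non_drift"):
            raise DiveValidationError(
                f"dive {self.dive_id!r}: sign 'none' iff label 'non_drift'"
            )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "dive_id": "dive_id",
    "time": "time",
    "depth": "depth",
    "velocity": "velocity",
    "start_datetime": "start_datetime",
}

SUMMARY_COLUMNS = (
    ["dive_id", "start_time", "E"]
    + [f"T{i}" for i in range(1, 5)]
    + [f"D{i}" for i in range(1, 5)]
    + ["max_depth"]
    + [f"res{i}" for i in range(1, 5)]
)


def load_profiles(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    depth_positive_up: bool = False,
    sep: str = ",",
) -> list[HighResProfile]:
    """Read high-resolution profiles from a delimited text file.

    The file has one row per sample.  ``column_map`` maps the logical names
    ``dive_id``, ``time``, ``depth`` (and optionally ``velocity``,
    ``start_datetime``) to the file's column names.  Set
    ``depth_positive_up=True`` when the file stores depth as negative-down;
    depths are always stored positive-down in memory.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.empty:
        raise DiveFormatError(f"{path}: no rows")
    missing = [v for k, v in cols.items() if k in ("dive_id", "time", "depth") and v not in df.columns]
    if missing:
        raise DiveFormatError(f"{path}: missing columns {missing}")
    vel_col = cols.get("velocity")
    dt_col = cols.get("start_datetime")
    profiles = []
    for dive_id, grp in df.groupby(cols["dive_id"], sort=False):
        times = grp[cols["time"]].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise DiveValidationError(
                f"dive {dive_id!r}: non-monotone or duplicated timestamps"
            )
        depths = grp[cols["depth"]].to_numpy(dtype=float)
        if depth_positive_up:
            depths = -depths
        velocity = None
        if vel_col and vel_col in grp.columns:
            velocity = grp[vel_col].to_numpy(dtype=float)
        start_dt = None
        if dt_col and dt_col in grp.columns:
            start_dt = pd.Timestamp(grp[dt_col].iloc[0])
        profiles.append(
            HighResProfile(
                dive_id=str(dive_id),
                times=times - times[0],
                depths=depths,
                velocity=velocity,
                start_datetime=start_dt,
            )
        )
    return profiles


def write_profiles(profiles: Iterable[HighResProfile], path, sep: str = ",") -> None:
    """Write profiles to the same one-row-per-sample schema read by
    :func:`load_profiles`."""
    frames = []
    for p in profiles:
        df = pd.DataFrame({"dive_id": p.dive_id, "time": p.times, "depth": p.depths})
        if p.velocity is not None:
            df["velocity"] = p.velocity
        if p.start_datetime is not None:
            df["start_datetime"] = p.start_datetime
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def write_summaries(summaries: Iterable[SummarizedDive], path, sep: str = ",") -> None:
    """Write summarized dives, one row per dive, in the stable wide schema
    (dive_id, start_time, E, T1..T4, D1..D4, max_depth, res1..res4)."""
    rows = []
    for s in summaries:
        row = {"dive_id": s.dive_id, "start_time": s.start_datetime, "E": s.E}
        for i in range(4):
            row[f"T{i + 1}"] = s.T[i]
            row[f"D{i + 1}"] = s.D[i]
        row["max_depth"] = s.max_depth
        res = s.bsa_residuals if s.bsa_residuals is not None else [np.nan] * 4
        for i in range(4):
            row[f"res{i + 1}"] = res[i]
        if s.selection_order is not None:
            row["ifp_order"] = ".".join(str(i) for i in s.selection_order)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def load_summaries(path, sep: str = ",") -> list[SummarizedDive]:
    """Read summarized dives from the wide schema written by
    :func:`write_summaries`."""
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.empty:
        raise DiveFormatError(f"{path}: no rows")
    needed = [c for c in SUMMARY_COLUMNS if c not in ("start_time", "max_depth") and not c.startswith("res")]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DiveFormatError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        E = float(row["E"])
        pts = np.zeros((6, 2))
        pts[5, 0] = E
        for i in range(4):
            pts[i + 1, 0] = row[f"T{i + 1}"]
            pts[i + 1, 1] = row[f"D{i + 1}"]
        res = None
        if all(f"res{i}" in df.columns and np.isfinite(row[f"res{i}"]) for i in range(1, 5)):
            res = np.array([row[f"res{i}"] for i in range(1, 5)], dtype=float)
        start_dt = None
        if "start_time" in df.columns and not pd.isna(row["start_time"]):
            start_dt = pd.Timestamp(row["start_time"])
        order = None
        if "ifp_order" in df.columns and isinstance(row.get("ifp_order"), str):
            order = tuple(int(x) for x in row["ifp_order"].split("."))
        out.append(
            SummarizedDive(
                dive_id=str(row["dive_id"]),
                points=pts,
                bsa_residuals=res,
                selection_order=order,
                start_datetime=start_dt,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Pre-detection filters
# ---------------------------------------------------------------------------


def preprocess_filter(
    dives: Sequence,
    min_depth: float = 100.0,
    min_duration: float = 300.0,
) -> tuple[list, list[tuple[str, str]]]:
    """Drop shallow and short exploratory dives before detection.

    Retains dives with maximum depth >= ``min_depth`` (inclusive: a dive
    reaching exactly 100 m is kept, avoiding residual-lung-air bias only
    above that depth) AND duration >= ``min_duration`` (a dive of exactly
    300 s is kept; only strictly shorter dives are "short").

    Works on either :class:`HighResProfile` or :class:`SummarizedDive`
    collections (both expose ``max_depth`` and ``duration``).

    Returns
    -------
    (kept, log) : kept dives in input order, and a list of
        (dive_id, reason) tuples for the rejected ones.
    """
    kept, log = [], []
    for d in dives:
        if d.max_depth < min_depth:
            log.append((d.dive_id, f"max depth {d.max_depth:.1f} m < {min_depth:g} m"))
        elif d.duration < min_duration:
            log.append((d.dive_id, f"duration {d.duration:.0f} s < {min_duration:g} s"))
        else:
            kept.append(d)
    return kept, log


def split_dives(
    times: np.ndarray,
    depths: np.ndarray,
    surface_threshold: float = SURFACE_THRESHOLD_M,
    min_samples: int = 3,
    id_prefix: str = "dive",
) -> list[HighResProfile]:
    """Cut a continuous depth record into individual dives.

    A dive is a maximal run of samples deeper than ``surface_threshold``,
    extended by one surface sample on each side where available so the
    profile starts and ends at the surface.
    """
    times = np.asarray(times, dtype=float)
    depths = np.asarray(depths, dtype=float)
    under = depths > surface_threshold
    dives: list[HighResProfile] = []
    i, n = 0, len(depths)
    k = 0
    while i < n:
        if not under[i]:
            i += 1
            continue
        j = i
        while j < n and under[j]:
            j += 1
        lo = max(i - 1, 0)
        hi = min(j + 1, n)
        if hi - lo >= min_samples:
            k += 1
            dives.append(
                HighResProfile(
                    dive_id=f"{id_prefix}{k:05d}",
                    times=times[lo:hi] - times[lo],
                    depths=depths[lo:hi],
                )
            )
        i = j
    return dives
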