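"""Synthetic seal trips with known labels and a known buoyancy trajectory.

The generator emulates the dive repertoire a time-depth recorder sees on a
southern-elephant-seal foraging trip, at 30-s sampling:

* drift dives (~6% of dives): an active descent, a long passive phase whose
  linear vertical rate equals the day's true buoyancy (plus per-dive
  jitter and depth noise), and an active ascent.  Negative-buoyancy dives
  drift downward, positive upward.
* drift mimics (~5%): the same three-phase geometry but with a passive-
  phase slope unrelated to the buoyancy trajectory (and optionally small
  wiggles) — the false positives the threshold and trajectory filters must
  reject.
* V-shaped dives: a clean descent/ascent with a single depth extremum.
* U-shaped dives: descent, a wiggly bottom phase, ascent.
* exploratory dives: shallow (< 100 m) or short (< 300 s), removed by the
  pre-detection filters.

Active phases carry mild rate changes (a mid-ascent gear shift and
curvature) because real swimming is not metronomic; the passive phase is
the straightest part of a drift dive.  That contrast is what makes the
broken-stick summary place its inflection points around the drift segment
and is why drift dives concentrate in a handful of inflection-order
groups.

Everything is reproducible from the seed; the per-day true buoyancy series
is returned alongside the dives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dive_model import HighResProfile, LabelledDive

__all__ = ["TripConfig", "simulate_trip", "simulate_dive"]


@dataclass
class TripConfig:
    """Generator settings; the defaults are the package's reference
    conditions for end-to-end tests."""

    n_days: int = 60
    dives_per_day: int = 50
    drift_fraction: float = 0.06
    mimic_fraction: float = 0.05
    exploratory_fraction: float = 0.025
    sampling_interval: float = 30.0  # s
    # buoyancy trajectory: initial daily drift rate (m/s) and per-day
    # increment; a fattening seal becomes less negatively buoyant.
    initial_buoyancy: float = -0.3
    daily_increment: float = 0.004
    buoyancy_schedule: np.ndarray | None = None  # overrides the linear ramp
    # drift-dive geometry
    drift_start_depth: tuple[float, float] = (180.0, 320.0)
    drift_duration: tuple[float, float] = (720.0, 1680.0)  # s
    drift_rate_jitter: float = 0.02  # m/s per-dive SD around the daily value
    depth_noise: float = 1.0  # m, additive on passive-phase samples
    # non-drift dives
    vshape_depth: tuple[float, float] = (120.0, 600.0)
    wiggle_amplitude: tuple[float, float] = (8.0, 25.0)  # m
    wiggle_period: tuple[float, float] = (120.0, 360.0)  # s
    emit_velocity: bool = False
    seed: int | None = None

    def __post_init__(self):
        for name in ("drift_fraction", "mimic_fraction", "exploratory_fraction"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.drift_fraction + self.mimic_fraction + self.exploratory_fraction > 1:
            raise ValueError("kind fractions exceed 1")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.drift_duration[0] < 2 * self.sampling_interval:
            raise ValueError("drift phase must span at least 2 samples")

    def daily_buoyancy(self) -> np.ndarray:
        if self.buoyancy_schedule is not None:
            sched = np.asarray(self.buoyancy_schedule, dtype=float)
            if sched.size != self.n_days:
                raise ValueError("buoyancy_schedule length must equal n_days")
            return sched
        return self.initial_buoyancy + self.daily_increment * np.arange(self.n_days)


def _resample(times: np.ndarray, depths: np.ndarray, dt: float):
    """Resample a breakpoint path onto the regular sampling grid."""
    grid = np.arange(0.0, times[-1] + dt / 2, dt)
    if grid[-1] < times[-1]:
        grid = np.append(grid, times[-1])
    return grid, np.interp(grid, times, depths)


def _active_limb(z0: float, z1: float, rate: float, rng, pieces: int = 2):
    """Breakpoints of an active (swimming) limb from depth z0 to z1.

    The limb is split into ``pieces`` sub-segments with rates varying
    around ``rate``, giving the mild curvature of real swimming.
    """
    span = z1 - z0
    fracs = rng.dirichlet(np.full(pieces, 5.0))
    rates = rate * rng.uniform(0.7, 1.4, pieces)
    zs = z0 + np.concatenate(([0.0], np.cumsum(fracs * span)))
    zs[-1] = z1
    ts = [0.0]
    for i in range(pieces):
        ts.append(ts[-1] + abs(zs[i + 1] - zs[i]) / rates[i])
    return np.array(ts), zs


def simulate_dive(
    kind: str,
    params: dict | None = None,
    seed: int | None = None,
    config: TripConfig | None = None,
) -> tuple[HighResProfile, LabelledDive]:
    """Simulate a single dive of a given kind.

    ``kind`` is one of ``drift``, ``mimic``, ``vshape``, ``ushape`` or
    ``exploratory``.  For drift (and mimic) dives ``params['drift_rate']``
    sets the passive-phase vertical rate (m/s, negative = sinking).
    """
    cfg = config or TripConfig()
    rng = np.random.default_rng(seed)
    params = dict(params or {})
    dive_id = params.get("dive_id", f"{kind}-{seed}")
    dt = cfg.sampling_interval

    if kind in ("drift", "mimic"):
        rate = float(params.get("drift_rate", -0.3))
        if "start_depth" in params:
            z_start = params["start_depth"]
        elif rate > 0:
            # upward drifters start deep so the passive phase fits above
            # the 130 m ceiling
            z_start = rng.uniform(cfg.drift_start_depth[0] + 120.0,
                                  cfg.drift_start_depth[1] + 180.0)
        else:
            z_start = rng.uniform(*cfg.drift_start_depth)
        dur = params.get("drift_duration", rng.uniform(*cfg.drift_duration))
        # keep the passive phase in open water: never shallower than 130 m,
        # never deeper than 650 m
        if rate > 0:
            dur = min(dur, max((z_start - 130.0) / max(rate, 1e-6), 2 * dt))
        else:
            dur = min(dur, max((650.0 - z_start) / max(-rate, 1e-6), 2 * dt))
        dur = max(round(dur / dt), 2) * dt  # phase boundaries on the grid
        z_end = z_start + (-rate) * dur  # positive-down: sinking deepens

        desc_rate = rng.uniform(1.5, 2.0)
        asc_rate = rng.uniform(1.2, 1.8)
        if rate <= 0:
            # negative drift: straight descent, ascent with two features so
            # the summary spends points there (real ascents are not linear)
            t_desc, z_desc = _active_limb(0.0, z_start, desc_rate, rng, pieces=1)
            t_asc, z_asc = _active_limb(z_end, 0.0, asc_rate, rng, pieces=3)
        else:
            # positive drift: featured descent, straighter ascent
            t_desc, z_desc = _active_limb(0.0, z_start, desc_rate, rng, pieces=3)
            t_asc, z_asc = _active_limb(z_end, 0.0, asc_rate, rng, pieces=1)
        # snap the descent so the drift phase starts exactly on a sample
        t_knee = max(round(t_desc[-1] / dt), 1) * dt
        t_desc = t_desc * (t_knee / t_desc[-1])

        bp_t = np.concatenate([t_desc, [t_knee + dur], t_knee + dur + t_asc[1:]])
        bp_z = np.concatenate([z_desc, [z_end], z_asc[1:]])
        times, depths = _resample(bp_t, bp_z, dt)

        drift_mask = (times >= t_knee - dt / 4) & (times <= t_knee + dur + dt / 4)
        idx = np.flatnonzero(drift_mask)
        noise = rng.normal(0.0, cfg.depth_noise, idx.size)
        noise[0] = noise[-1] = 0.0  # keep the knees crisp
        depths[idx] += noise
        if kind == "mimic" and rng.random() < 0.5:
            amp = rng.uniform(1.0, 6.0)
            period = rng.uniform(*cfg.wiggle_period)
            depths[idx] += amp * np.sin(2 * np.pi * (times[idx] - times[idx[0]]) / period)
        depths = np.clip(depths, 0.0, None)
        depths[0] = depths[-1] = 0.0

        label = LabelledDive(
            dive_id=dive_id,
            label="drift_certain" if kind == "drift" else "non_drift",
            sign=("positive" if rate > 0 else "negative") if kind == "drift" else "none",
            true_drift_segment=(int(idx[0]), int(idx[-1])),
            kind=kind,
        )

    elif kind == "vshape":
        # clean V: exactly one depth extremum, asymmetric limb rates
        z_max = params.get("max_depth", rng.uniform(*cfg.vshape_depth))
        down = rng.uniform(1.2, 2.0)
        up = rng.uniform(1.2, 2.0)
        bp_t = np.array([0.0, z_max / down, z_max / down + z_max / up])
        bp_z = np.array([0.0, z_max, 0.0])
        times, depths = _resample(bp_t, bp_z, dt)
        label = LabelledDive(dive_id=dive_id, label="non_drift", sign="none", kind=kind)

    elif kind == "ushape":
        z_max = params.get("max_depth", rng.uniform(*cfg.vshape_depth))
        bottom = rng.uniform(300.0, 900.0)
        down = rng.uniform(1.2, 2.0)
        up = rng.uniform(1.2, 2.0)
        t1 = z_max / down
        bp_t = np.array([0.0, t1, t1 + bottom, t1 + bottom + z_max / up])
        bp_z = np.array([0.0, z_max, z_max, 0.0])
        times, depths = _resample(bp_t, bp_z, dt)
        amp = rng.uniform(*cfg.wiggle_amplitude)
        period = rng.uniform(*cfg.wiggle_period)
        phase = rng.uniform(0, 2 * np.pi)
        bottom_mask = (times > t1) & (times < t1 + bottom)
        depths[bottom_mask] -= amp * (
            0.5 + 0.5 * np.sin(2 * np.pi * times[bottom_mask] / period + phase)
        )
        depths += rng.normal(0.0, 0.5, depths.size)
        depths = np.clip(depths, 0.0, None)
        depths[0] = depths[-1] = 0.0
        label = LabelledDive(dive_id=dive_id, label="non_drift", sign="none", kind=kind)

    elif kind == "exploratory":
        # filter bait: shallow and/or short
        z_max = rng.uniform(30.0, 90.0)
        down = rng.uniform(0.8, 1.5)
        bp_t = np.array([0.0, z_max / down, 2.2 * z_max / down])
        bp_z = np.array([0.0, z_max, 0.0])
        times, depths = _resample(bp_t, bp_z, dt)
        label = LabelledDive(dive_id=dive_id, label="non_drift", sign="none", kind=kind)

    else:
        raise ValueError(f"unknown dive kind {kind!r}")

    velocity = None
    if cfg.emit_velocity:
        grad = np.abs(np.gradient(depths, times))
        velocity = np.where(grad > 0.5, grad * rng.uniform(1.0, 1.2), 0.1)

    profile = HighResProfile(
        dive_id=dive_id,
        times=times,
        depths=depths,
        velocity=velocity,
        start_datetime=params.get("start_datetime"),
    )
    return profile, label


def simulate_trip(
    config: TripConfig | None = None,
) -> tuple[list[HighResProfile], list[LabelledDive], pd.DataFrame]:
    """Simulate a whole trip.

    Returns the high-resolution profiles, their ground-truth labels, and a
    per-day frame with columns ``date`` and ``buoyancy`` (the true daily
    drift rate in m/s).
    """
    cfg = config or TripConfig()
    rng = np.random.default_rng(cfg.seed)
    daily = cfg.daily_buoyancy()
    t0 = pd.Timestamp("2004-01-01", tz="UTC")

    kinds = np.array(["drift", "mimic", "exploratory", "vshape", "ushape"])
    other = 1.0 - cfg.drift_fraction - cfg.mimic_fraction - cfg.exploratory_fraction
    probs = np.array(
        [cfg.drift_fraction, cfg.mimic_fraction, cfg.exploratory_fraction,
         other / 2, other / 2]
    )

    profiles: list[HighResProfile] = []
    labels: list[LabelledDive] = []
    counter = 0
    slot = 86400.0 / cfg.dives_per_day
    for day in range(cfg.n_days):
        for j in range(cfg.dives_per_day):
            counter += 1
            kind = str(rng.choice(kinds, p=probs))
            params: dict = {
                "dive_id": f"d{counter:06d}",
                "start_datetime": t0 + pd.Timedelta(seconds=day * 86400.0 + j * slot),
            }
            if kind == "drift":
                params["drift_rate"] = daily[day] + rng.normal(0.0, cfg.drift_rate_jitter)
            elif kind == "mimic":
                params["drift_rate"] = rng.uniform(-0.6, 0.6)
            profile, label = simulate_dive(
                kind, params, seed=int(rng.integers(2**31 - 1)), config=cfg
            )
            profiles.append(profile)
            labels.append(label)

    truth = pd.DataFrame(
        {
            "date": (t0 + pd.to_timedelta(np.arange(cfg.n_days), unit="D")).date,
            "buoyancy": daily,
        }
    )
    return profiles, labels, truth
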