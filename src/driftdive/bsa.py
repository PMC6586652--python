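"""Broken-Stick summarization of high-resolution dives.

The broken-stick algorithm (BSA) is the on-board abstraction used by
satellite-relay tags: starting from the line joining the dive's start and
end, it greedily keeps the sample with the largest vertical discrepancy
from the current piecewise-linear reconstruction, four times, yielding a
six-point summary (start, four subsurface inflection points, end) plus the
sequence of residual magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dive_model import HighResProfile, SummarizedDive

__all__ = ["BsaResult", "bsa_summarize", "reconstruct_depth"]


@dataclass
class BsaResult:
    """Outcome of summarizing one dive.

    ``selection_order`` gives, for each selection step, the time-sorted
    index (1-4) of the chosen subsurface point; ``residuals`` the maximal
    discrepancy (m) at each step, in selection order.  ``tied`` records
    whether any step's argmax was shared by several samples (broken by
    earliest time).
    """

    summarized: SummarizedDive
    selection_order: tuple[int, int, int, int]
    residuals: np.ndarray
    tied: bool = False


def _interp(xs: np.ndarray, ys: np.ndarray, x: np.ndarray) -> np.ndarray:
    # xs strictly increasing; np.interp is the shared linear primitive
    return np.interp(x, xs, ys)


#: Discrepancies below this (metres) are treated as exact zeros so the
#: earliest-time tie rule engages on flat/linear stretches instead of
#: floating-point noise.
TIE_TOL = 1e-9


def bsa_summarize(profile: HighResProfile, n_subsurface: int = 4) -> BsaResult:
    """Summarize a dive with the greedy broken-stick point selection.

    The first selected point is the dive's deepest sample (earliest such
    sample on ties); each following point maximizes the absolute depth
    discrepancy between the profile and the piecewise-linear reconstruction
    through the already-selected points.  The first and last samples are
    endpoints, never selectable.  If fewer than ``n_subsurface`` samples
    carry positive discrepancy, the remaining slots are filled with the
    earliest-time unselected interior samples (zero residual), keeping the
    output schema fixed.
    """
    t, z = profile.times, profile.depths
    n = t.size
    if n < n_subsurface + 2:
        raise ValueError(
            f"dive {profile.dive_id!r}: {n} samples < {n_subsurface + 2} needed"
        )
    interior = np.arange(1, n - 1)

    selected: list[int] = []  # sample indices, selection order
    residuals: list[float] = []
    tied = False

    # step 1: deepest sample; its residual is the discrepancy from the
    # start-end line (the "surface" reconstruction).
    base = _interp(t[[0, n - 1]], z[[0, n - 1]], t)
    deepest = int(interior[np.argmax(z[interior])])
    if np.sum(z[interior] == z[deepest]) > 1:
        tied = True
    selected.append(deepest)
    residuals.append(float(abs(z[deepest] - base[deepest])))

    for _ in range(n_subsurface - 1):
        knots = np.unique(np.array([0, n - 1] + selected))
        recon = _interp(t[knots], z[knots], t)
        disc = np.abs(z - recon)
        disc[disc < TIE_TOL] = 0.0
        disc[knots] = -np.inf  # already selected / endpoints
        disc[0] = disc[-1] = -np.inf
        best = int(np.argmax(disc))  # argmax returns the earliest on ties
        if np.sum(np.abs(disc - disc[best]) <= TIE_TOL) > 1:
            tied = True
        selected.append(best)
        residuals.append(float(max(disc[best], 0.0)))

    order_time = np.argsort(selected, kind="stable")
    # selection_order[k] = time-sorted label (1-4) of the k-th selected point
    rank = np.empty(n_subsurface, dtype=int)
    rank[order_time] = np.arange(1, n_subsurface + 1)
    sel_order = tuple(int(r) for r in rank)

    idx_sorted = sorted(selected)
    pts = np.zeros((n_subsurface + 2, 2))
    pts[0] = (t[0], z[0])
    pts[-1] = (t[-1], z[-1])
    for i, s in enumerate(idx_sorted):
        pts[i + 1] = (t[s], z[s])

    summary = SummarizedDive(
        dive_id=profile.dive_id,
        points=pts,
        bsa_residuals=np.array(residuals),
        selection_order=sel_order,
        start_datetime=profile.start_datetime,
    )
    return BsaResult(
        summarized=summary,
        selection_order=sel_order,
        residuals=np.array(residuals),
        tied=tied,
    )


def reconstruct_depth(summary: SummarizedDive, t) -> np.ndarray | float:
    """Depth (m) of the summarized profile at time ``t`` (s since start).

    Linear interpolation between the bracketing summary points; exact at
    the points themselves.  ``t`` outside [0, E] raises ValueError.
    """
    t_arr = np.asarray(t, dtype=float)
    t0, t1 = summary.points[0, 0], summary.points[5, 0]
    if np.any(t_arr < t0) or np.any(t_arr > t1):
        raise ValueError(f"t outside [{t0:g}, {t1:g}]")
    out = np.interp(t_arr, summary.points[:, 0], summary.points[:, 1])
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
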