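"""Reverse Broken-Stick Algorithm (RBSA).

From a transmitted six-point summary alone, recover the order in which the
on-board BSA selected the four subsurface inflection points, and regenerate
the BSA residuals.  The only point whose selection position is known a
priori is the deepest one — it was selected first, since it has the largest
discrepancy from the surface line.  The remaining order is recovered by
recursively reconstructing the piecewise-linear profile through the
already-placed points and taking, among the remaining transmitted points,
the one with the largest vertical discrepancy.

Discrepancies are measured only at the four transmitted points: the
high-resolution series is, by construction, unavailable.  Ties are broken
by earliest time, mirroring the forward BSA, so the round trip
``recover_order(bsa_summarize(p).summarized) == bsa_summarize(p).selection_order``
holds whenever the per-step argmaxes are unique (and on zero-residual fill
ties as well).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .dive_model import SummarizedDive

__all__ = ["InflectionOrder", "recover_order", "ALL_ORDERS"]

#: All 24 attainable order labels (permutations of the four point indices).
ALL_ORDERS = frozenset(
    ".".join(str(x) for x in perm) for perm in itertools.permutations((1, 2, 3, 4))
)


@dataclass
class InflectionOrder:
    """Recovered selection order and residuals for one summarized dive.

    ``label`` is the dotted order over time-sorted point indices
    (e.g. ``"2.1.3.4"``: the first point the BSA selected was the second
    timestamp).  ``residuals`` are the recovered residual magnitudes (m) in
    selection order; the last one indexes vertical activity the summary did
    not capture.  ``ambiguous`` flags that some step's argmax was tied (the
    earliest-time rule was applied).
    """

    label: str
    residuals: np.ndarray
    ambiguous: bool = False

    @property
    def order(self) -> tuple[int, ...]:
        return tuple(int(x) for x in self.label.split("."))

    @property
    def last_residual(self) -> float:
        return float(self.residuals[-1])

    @property
    def deepest_index(self) -> int:
        """Time-sorted index (1-4) of the first-selected (deepest) point."""
        return self.order[0]


def recover_order(summary: SummarizedDive, tol: float = 1e-9) -> InflectionOrder:
    """Recover the BSA selection order from a six-point summary.

    Step 1 selects the deepest of the four subsurface points (earliest on a
    duplicate maximum, with a warning); each later step reconstructs the
    profile through start, end and the already-selected points and selects
    the remaining point with the largest absolute depth discrepancy.
    """
    pts = summary.points
    T, D = pts[1:5, 0], pts[1:5, 1]
    ambiguous = False

    deepest = int(np.argmax(D))
    if np.sum(np.abs(D - D[deepest]) <= tol) > 1:
        ambiguous = True
        warnings.warn(
            f"dive {summary.dive_id!r}: duplicate maximum depth among "
            "transmitted points; earliest selected",
            stacklevel=2,
        )

    base = np.interp(T, pts[[0, 5], 0], pts[[0, 5], 1])
    selected = [deepest]
    residuals = [float(abs(D[deepest] - base[deepest]))]

    for _ in range(3):
        knot_t = np.concatenate(([pts[0, 0]], T[sorted(selected)], [pts[5, 0]]))
        knot_d = np.concatenate(([pts[0, 1]], D[sorted(selected)], [pts[5, 1]]))
        recon = np.interp(T, knot_t, knot_d)
        disc = np.abs(D - recon)
        disc[disc < tol] = 0.0
        disc[selected] = -np.inf
        best = int(np.argmax(disc))  # earliest index on exact ties
        if np.sum(np.abs(disc - disc[best]) <= tol) > 1:
            ambiguous = True
        selected.append(best)
        residuals.append(float(max(disc[best], 0.0)))

    label = ".".join(str(i + 1) for i in selected)
    return InflectionOrder(
        label=label, residuals=np.array(residuals), ambiguous=ambiguous
    )
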