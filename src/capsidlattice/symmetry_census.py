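"""Classification of capsomer sites against the global icosahedral axes.

A hexamer with only 2-fold internal symmetry (a split or skew hexamer)
cannot sit on a global 3-fold axis without a symmetry mismatch, so a
capsid can be built entirely from split/skew hexamers exactly when no
hexamer center coincides with a 3-fold axis.  This module decides that
question by brute-force 3-D geometry — point-to-axis distances of every
site against all 31 axes — and cross-checks the result against the
exact lattice predicates assigned at build time.  The geometric route
never consults the T-number, which is what makes it an independent
oracle for the divisibility-by-three criterion implemented in
:mod:`capsidlattice.hexlattice`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capsid_builder import CapsidLattice, CapsomerSite, build_capsid, symmetry_axes
from .errors import ClassificationMismatchError, InvalidStepError
from .hexlattice import AxialStep, enumerate_t_numbers, predict_centered_hexamer

__all__ = [
    "SiteClassification",
    "SurveyRow",
    "SurveyReport",
    "classify_sites",
    "has_centered_hexamer",
    "all_skew_compatible",
    "survey",
]

DEFAULT_TOL = 1e-6


@dataclass(frozen=True)
class SiteClassification:
    """Geometric verdict for one site: the highest-order global axis
    passing within ``tol * radius`` of it (0 = general position)."""

    site: CapsomerSite
    on_axis_order: int  # 0 | 2 | 3 | 5
    distance_to_nearest_axis: float


def _geometric_orders(capsid: CapsidLattice, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """On-axis order and nearest-axis distance per site, by pure
    point-to-line geometry."""
    if tol <= 0:
        raise InvalidStepError(f"tolerance must be positive, got {tol!r}")
    axes = symmetry_axes(capsid.icosahedron)
    P = capsid.positions
    orders = np.zeros(len(P), dtype=int)
    nearest = np.full(len(P), np.inf)
    cutoff = tol * capsid.radius
    for axis in axes:
        n = axis.direction
        proj = P - np.outer(P @ n, n)
        d = np.linalg.norm(proj, axis=1)
        nearest = np.minimum(nearest, d)
        hit = d < cutoff
        orders[hit] = np.maximum(orders[hit], axis.order)
    return orders, nearest


def classify_sites(capsid: CapsidLattice, tol: float = DEFAULT_TOL) -> list[SiteClassification]:
    """Classify every capsomer site against the 31 global axes.

    Each site is assigned the highest-order axis whose line passes
    within ``tol * radius`` of its position.  The exact lattice
    predicates recorded on each site (vertex, face centroid, edge
    midpoint) must agree with the geometric assignment; a disagreement
    raises :class:`ClassificationMismatchError` — it would mean the
    construction and the oracle contradict each other.
    """
    orders, nearest = _geometric_orders(capsid, tol)
    out = []
    for site, order, dist in zip(capsid.sites, orders, nearest):
        if order != site.expected_axis_order:
            raise ClassificationMismatchError(
                f"T={capsid.T} site at {site.position}: lattice predicate says "
                f"axis order {site.expected_axis_order}, geometry says {order}"
            )
        out.append(SiteClassification(site=site, on_axis_order=int(order),
                                      distance_to_nearest_axis=float(dist)))
    return out


def has_centered_hexamer(capsid: CapsidLattice, tol: float = DEFAULT_TOL) -> bool:
    """True iff at least one hexamer center lies on a global 3-fold
    axis, decided purely geometrically (no divisibility test)."""
    orders, _ = _geometric_orders(capsid, tol)
    return any(o == 3 and s.kind == "hexamer"
               for o, s in zip(orders, capsid.sites))


def all_skew_compatible(capsid: CapsidLattice, tol: float = DEFAULT_TOL) -> bool:
    """True iff the capsid has at least one hexamer and none is centered
    on a global 3-fold axis.

    Split/skew hexamers retain 2-fold symmetry, so hexamers sitting on
    global 2-fold axes are compatible and do not block the tiling; only
    a 3-fold-centered hexamer forces a 6-fold (or 3-fold) symmetric
    capsomer.  T=1 is vacuously incompatible (it has no hexamers at
    all).
    """
    if capsid.T == 1:
        return False
    return not has_centered_hexamer(capsid, tol)


@dataclass(frozen=True)
class SurveyRow:
    T: int
    representations: tuple[AxialStep, ...]
    has_hexamers: bool
    centered_hexamer_geometric: bool
    centered_hexamer_predicted: bool
    n_pentamers: int
    n_hexamers: int
    n_hexamers_on_3fold: int
    n_hexamers_on_2fold: int
    all_skew_compatible: bool


@dataclass(frozen=True)
class SurveyReport:
    """Per-T classification of every capsid architecture up to a bound.

    ``centered_t`` / ``all_skew_t`` partition the hexamer-bearing
    T-numbers (T=1 is listed as a row but excluded from both counts).
    """

    t_max: int
    rows: tuple[SurveyRow, ...]

    @property
    def centered_t(self) -> list[int]:
        return [r.T for r in self.rows if r.has_hexamers and r.centered_hexamer_geometric]

    @property
    def all_skew_t(self) -> list[int]:
        return [r.T for r in self.rows if r.all_skew_compatible]

    @property
    def n_centered(self) -> int:
        return len(self.centered_t)

    @property
    def n_all_skew(self) -> int:
        return len(self.all_skew_t)

    @property
    def all_consistent(self) -> bool:
        return all(r.centered_hexamer_geometric == r.centered_hexamer_predicted
                   for r in self.rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([
            {
                "T": r.T,
                "h": r.representations[0].h,
                "k": r.representations[0].k,
                "centered_hexamer": r.centered_hexamer_geometric,
                "n_pentamers": r.n_pentamers,
                "n_hexamers": r.n_hexamers,
                "n_hex_on_3fold": r.n_hexamers_on_3fold,
                "n_hex_on_2fold": r.n_hexamers_on_2fold,
                "all_skew_compatible": r.all_skew_compatible,
            }
            for r in self.rows
        ])


def survey_row(step, tol: float = DEFAULT_TOL, radius: float = 300.0) -> SurveyRow:
    """Build one capsid and classify all its sites (both routes)."""
    capsid = build_capsid(step, radius=radius)
    classes = classify_sites(capsid, tol=tol)
    n_pent = sum(1 for c in classes if c.site.kind == "pentamer")
    n_hex3 = sum(1 for c in classes
                 if c.site.kind == "hexamer" and c.on_axis_order == 3)
    n_hex2 = sum(1 for c in classes
                 if c.site.kind == "hexamer" and c.on_axis_order == 2)
    from .hexlattice import enumerate_t_numbers as _enum  # reps for this T

    reps = next(r.representations for r in _enum(capsid.T) if r.T == capsid.T)
    return SurveyRow(
        T=capsid.T,
        representations=reps,
        has_hexamers=capsid.T > 1,
        centered_hexamer_geometric=has_centered_hexamer(capsid, tol),
        centered_hexamer_predicted=predict_centered_hexamer(capsid.T),
        n_pentamers=n_pent,
        n_hexamers=len(capsid.sites) - n_pent,
        n_hexamers_on_3fold=n_hex3,
        n_hexamers_on_2fold=n_hex2,
        all_skew_compatible=all_skew_compatible(capsid, tol),
    )


def survey(t_max: int, tol: float = DEFAULT_TOL, radius: float = 300.0) -> SurveyReport:
    """Classify every distinct capsid architecture with ``T <= t_max``.

    Each row is produced by actually building the capsid in 3-D and
    running both the geometric and the exact-lattice classification;
    the two routes must agree or the survey raises.
    """
    records = enumerate_t_numbers(t_max)  # validates t_max
    rows = []
    for rec in records:
        row = survey_row(rec.representations[0], tol=tol, radius=radius)
        rows.append(row)
    return SurveyReport(t_max=t_max, rows=tuple(rows))
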