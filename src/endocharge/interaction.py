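"""Charge-product interaction statistic alpha(pH).

Treating the ApoE R112C domain and each LDL-A repeat as point charges,
the Coulomb interaction energy between them is proportional to the
product of their net charges,

    alpha(pH) = Z_ligand(pH) * Z_repeat(pH)      [charge^2 units].

alpha > 0 means electrostatic repulsion, alpha < 0 attraction.  The
combined effect over the receptor's ligand-binding stalk is summarized
by the arithmetic mean of alpha over the seven repeats, which, because
the ligand factor is shared, equals Z_ligand times the mean repeat
charge at every pH.

This module also provides the curve geometry needed to turn sampled
alpha curves into statements about pH ranges: sign-crossing detection
with bisection refinement on the continuous titration product,
extraction of the interval where a curve is negative, tiling of the pH
range into repulsive / neutral / attractive segments given a neutrality
threshold eps, and ranking of the repeats by charge at a given pH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .protonation import BISECTION_TOL, ChargeCurve, TitrationError, _bisect

logger = logging.getLogger(__name__)

ATOL = 1e-12


class AlignmentError(ValueError):
    """Curves sampled on different pH grids cannot be combined."""


def _check_grids(a: ChargeCurve, b: ChargeCurve) -> None:
    if len(a.ph_grid) != len(b.ph_grid) or not np.allclose(
        a.ph_grid, b.ph_grid, rtol=0, atol=ATOL
    ):
        raise AlignmentError(
            f"pH grids of {a.sequence_id!r} and {b.sequence_id!r} differ"
        )


def alpha_curve(ligand: ChargeCurve, repeat: ChargeCurve) -> np.ndarray:
    """Pointwise charge product Z_ligand * Z_repeat on the shared grid."""
    _check_grids(ligand, repeat)
    return ligand.values * repeat.values


@dataclass(frozen=True)
class InteractionProfile:
    """Per-repeat alpha curves and their repeat average for one isoform."""

    isoform_id: str
    ph_grid: np.ndarray
    per_repeat_alpha: dict[str, np.ndarray]
    mean_alpha: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ph_grid)
        for rid, vals in self.per_repeat_alpha.items():
            if len(vals) != n:
                raise AlignmentError(f"alpha curve of {rid!r} has wrong length")
        if len(self.mean_alpha) != n:
            raise AlignmentError("mean_alpha has wrong length")


def build_profile(
    isoform: ChargeCurve, repeats: Sequence[ChargeCurve]
) -> InteractionProfile:
    """Assemble the interaction profile of one isoform against all repeats.

    ``mean_alpha`` is the arithmetic mean of the per-repeat products; by
    distributivity it factorizes as Z_isoform times the mean repeat
    charge, which downstream code and tests rely on.
    """
    if not repeats:
        raise AlignmentError("build_profile needs at least one repeat curve")
    per = {r.sequence_id: alpha_curve(isoform, r) for r in repeats}
    mean = np.mean(list(per.values()), axis=0)
    return InteractionProfile(isoform.sequence_id, isoform.ph_grid, per, mean)


def sign_crossings(
    ph_grid: Sequence[float],
    values: Sequence[float],
    f: Callable[[float], float] | None = None,
    tol: float = BISECTION_TOL,
) -> list[float]:
    """pH values where the curve changes sign.

    Candidate brackets come from sign changes of the sampled values
    (piecewise-linear interpolant); each bracket is refined either by
    bisection of the continuous function ``f`` (e.g. the underlying
    titration product) when given, or by linear interpolation.  A value
    exactly zero at a grid point is reported once, at that grid point.
    """
    grid = np.asarray(ph_grid, dtype=float)
    vals = np.asarray(values, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise TitrationError("pH grid must be strictly increasing")
    out: list[float] = []
    for i, v in enumerate(vals):
        if v == 0.0:
            out.append(float(grid[i]))
    for i in range(len(grid) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if v0 == 0.0 or v1 == 0.0 or v0 * v1 > 0:
            continue
        lo, hi = float(grid[i]), float(grid[i + 1])
        if f is None:
            out.append(lo - v0 * (hi - lo) / (v1 - v0))
        else:
            g = f if f(lo) > 0 else (lambda x: -f(x))
            out.append(_bisect(g, lo, hi, tol))
    return sorted(out)


def negativity_interval(
    ph_grid: Sequence[float],
    values: Sequence[float],
    f: Callable[[float], float] | None = None,
) -> tuple[float, float] | None:
    """The contiguous pH interval where the curve is negative.

    Returns None when the curve is nonnegative everywhere.  Endpoints
    are refined sign crossings, clipped to the grid range; an endpoint
    at the grid boundary means the true crossing may lie outside the
    sampled range.  When several disjoint negative intervals exist the
    widest is returned and the multiplicity is logged (the analysis
    assumes a single attraction window).
    """
    grid = np.asarray(ph_grid, dtype=float)
    vals = np.asarray(values, dtype=float)
    if not np.any(vals < 0):
        return None
    crossings = sign_crossings(grid, vals, f)
    edges = [float(grid[0])] + crossings + [float(grid[-1])]
    intervals = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi - lo <= 0:
            continue
        mid = 0.5 * (lo + hi)
        probe = f(mid) if f is not None else np.interp(mid, grid, vals)
        if probe < 0:
            intervals.append((lo, hi))
    if not intervals:
        return None
    # merge adjacent negative spans separated by a refined touch point
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        if abs(lo - merged[-1][1]) < 10 * BISECTION_TOL:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    if len(merged) > 1:
        logger.warning(
            "multiple negative intervals %s; returning the widest", merged
        )
    return max(merged, key=lambda iv: iv[1] - iv[0])


@dataclass(frozen=True)
class SignSegment:
    """A pH segment classified by the sign and size of alpha."""

    lo: float
    hi: float
    label: str  # repulsive | neutral | attractive


def classify_value(value: float, eps: float) -> str:
    """Classify one alpha value: repulsive (>= eps), attractive (<= -eps), else neutral."""
    if value >= eps:
        return "repulsive"
    if value <= -eps:
        return "attractive"
    return "neutral"


def classify_segments(
    ph_grid: Sequence[float],
    values: Sequence[float],
    eps: float,
    f: Callable[[float], float] | None = None,
) -> list[SignSegment]:
    """Tile the sampled pH range into repulsive/neutral/attractive segments.

    Segment boundaries are the (refined) crossings of alpha with +eps
    and -eps; each segment's label is the classification of the curve
    at its midpoint.
    """
    if eps <= 0:
        raise TitrationError("eps must be positive")
    grid = np.asarray(ph_grid, dtype=float)
    vals = np.asarray(values, dtype=float)
    edges = set()
    for shift in (eps, -eps):
        fs = (lambda x, s=shift: f(x) - s) if f is not None else None
        edges.update(sign_crossings(grid, vals - shift, fs))
    bounds = [float(grid[0])] + sorted(
        e for e in edges if grid[0] < e < grid[-1]
    ) + [float(grid[-1])]
    segments: list[SignSegment] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo <= 0:
            continue
        mid = 0.5 * (lo + hi)
        probe = f(mid) if f is not None else float(np.interp(mid, grid, vals))
        label = classify_value(probe, eps)
        if segments and segments[-1].label == label:
            segments[-1] = SignSegment(segments[-1].lo, hi, label)
        else:
            segments.append(SignSegment(lo, hi, label))
    return segments


@dataclass(frozen=True)
class RepeatRanking:
    """Repeat ids ordered by net charge at one pH, most positive first."""

    ph: float
    order: tuple[str, ...]
    charges: dict[str, float]

    @property
    def most_positive(self) -> str:
        return self.order[0]

    @property
    def most_negative(self) -> str:
        return self.order[-1]


def rank_repeats(
    repeat_curves: Sequence[ChargeCurve], ph: float
) -> RepeatRanking:
    """Order repeats by interpolated charge at ``ph``, descending.

    Ties break by position in the input list (ascending repeat index).
    """
    if not repeat_curves:
        raise TitrationError("rank_repeats needs at least one curve")
    charges = {c.sequence_id: c.at(ph) for c in repeat_curves}
    ids = [c.sequence_id for c in repeat_curves]
    order = tuple(sorted(ids, key=lambda rid: (-charges[rid], ids.index(rid))))
    return RepeatRanking(ph, order, charges)
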