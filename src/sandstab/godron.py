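"""The improved M. Godron community-stability measurement.

The classical Godron procedure ranks a community's species by dominance,
plots the cumulative percentage of species (x) against the cumulative
relative frequency (y), draws a smooth curve through the scatter, and
intersects it with the anti-diagonal joining (0, 100) and (100, 0). A
community whose curve crosses that line near the ideal 20/80 configuration
— 20 % of species accounting for 80 % of the community — is considered
stable; the Euclidean distance from the intersection to the reference
point (20, 80) quantifies the departure, with sqrt(10^2 + 10^2) = 14.142
as the inclusive stability threshold. The "improved" variant implemented
here cumulates species *coverage* instead of frequency, which is better
suited to sparse sandy-land vegetation where frequencies saturate.

The module exposes the primitive operations (curve construction, ordinary
least-squares polynomial fitting, closed-form intersection, distance,
classification) plus a model/results pair: :class:`GodronStability` is
built from a stratum's observations or a coverage mapping, and its
:meth:`~GodronStability.fit` returns a :class:`GodronStabilityResults`
carrying the fitted coefficients, R^2, the intersection, the distance and
the verdict, with ``summary()`` and ``plot()``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from numpy.polynomial import polynomial as npoly

from .errors import DegenerateInputError, FitError, NoIntersectionError
from .io import SpeciesObservation

logger = logging.getLogger(__name__)

__all__ = [
    "STABILITY_POINT",
    "STABILITY_THRESHOLD",
    "CumulativeCurve",
    "FittedCurve",
    "StabilityAssessment",
    "GodronStability",
    "GodronStabilityResults",
    "build_cumulative_curve",
    "fit_smooth_curve",
    "intersect_with_antidiagonal",
    "distance_to_stability_point",
    "classify_stability",
    "assess_stability",
]

#: The ideal stable configuration: 20 % of species carry 80 % of coverage.
STABILITY_POINT: tuple[float, float] = (20.0, 80.0)

#: Inclusive stability threshold sqrt(10^2 + 10^2) ~= 14.142.
STABILITY_THRESHOLD: float = math.sqrt(10.0 ** 2 + 10.0 ** 2)

_TOL = 1e-9


@dataclass(frozen=True)
class CumulativeCurve:
    """Ordered cumulative scatter (x = % of species, y = % of measure).

    Point i (1-based) sits at x = 100 i / S; y is the running total of the
    ranked per-species measure as a percentage of the grand total, so the
    final point is (100, 100).
    """

    points: tuple[tuple[float, float], ...]
    S: int
    measure: str = "coverage"

    def __post_init__(self):
        if self.S != len(self.points) or self.S < 1:
            raise DegenerateInputError("curve must have S >= 1 points")
        xs = [p[0] for p in self.points]
        ys = [p[1] for p in self.points]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise DegenerateInputError("x must be strictly increasing")
        if any(b < a - _TOL for a, b in zip(ys, ys[1:])):
            raise DegenerateInputError("y must be non-decreasing")
        if abs(xs[-1] - 100.0) > _TOL or abs(ys[-1] - 100.0) > _TOL:
            raise DegenerateInputError("curve must end at (100, 100)")

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class FittedCurve:
    """A degree-1 or degree-2 polynomial y = c0 + c1 x + c2 x^2."""

    degree: int
    coefficients: tuple[float, float, float]  # ascending powers
    r_squared: float

    def __post_init__(self):
        if self.degree not in (1, 2):
            raise FitError(f"degree must be 1 or 2, got {self.degree}")
        if self.degree == 1 and self.coefficients[2] != 0.0:
            raise FitError("degree-1 curve must have c2 = 0")

    def __call__(self, x):
        c0, c1, c2 = self.coefficients
        return c0 + c1 * np.asarray(x) + c2 * np.asarray(x) ** 2


@dataclass(frozen=True)
class StabilityAssessment:
    """Outcome of the Godron procedure for one stratum."""

    intersection: tuple[float, float]
    distance: float
    stable: bool
    threshold: float = STABILITY_THRESHOLD
    reference_point: tuple[float, float] = STABILITY_POINT


def build_cumulative_curve(per_species_measure: Mapping[str, float],
                           measure: str = "coverage") -> CumulativeCurve:
    """Rank species by ``measure`` descending and cumulate.

    Ties are broken lexicographically by species name so the curve is
    deterministic. The curve is invariant to rescaling all species by a
    common positive factor, since only relative cumulated shares enter.
    """
    if not per_species_measure:
        raise DegenerateInputError("no species")
    if any(v < 0 for v in per_species_measure.values()):
        raise DegenerateInputError(f"negative {measure} value")
    total = sum(per_species_measure.values())
    if total <= 0:
        raise DegenerateInputError(f"total {measure} is zero")
    ranked = sorted(per_species_measure.items(), key=lambda kv: (-kv[1], kv[0]))
    S = len(ranked)
    points = []
    running = 0.0
    for i, (_, value) in enumerate(ranked, start=1):
        running += value
        points.append((100.0 * i / S, 100.0 * running / total))
    # guard against accumulated floating error at the endpoint
    points[-1] = (100.0, 100.0)
    return CumulativeCurve(points=tuple(points), S=S, measure=measure)


def fit_smooth_curve(curve: CumulativeCurve, degree: int = 2) -> FittedCurve:
    """Unconstrained ordinary least-squares polynomial fit of the scatter.

    The intercept is free (the empirical curves of interest do not pass
    through the origin). Coefficients are in ascending powers.
    """
    if degree not in (1, 2):
        raise FitError(f"degree must be 1 or 2, got {degree}")
    if curve.S < degree + 1:
        raise FitError(
            f"need at least {degree + 1} points for a degree-{degree} fit, "
            f"have {curve.S}")
    x, y = curve.x, curve.y
    if np.ptp(x) == 0:
        raise FitError("singular design: all x equal")
    coeffs = npoly.polyfit(x, y, degree)
    fitted = npoly.polyval(x, coeffs)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    c = tuple(float(v) for v in coeffs) + (0.0,) * (3 - len(coeffs))
    return FittedCurve(degree=degree, coefficients=c[:3], r_squared=r2)


def intersect_with_antidiagonal(f: FittedCurve) -> tuple[float, float]:
    """Closed-form intersection of the fitted curve with y = 100 - x.

    Solves c2 x^2 + (c1 + 1) x + (c0 - 100) = 0 and returns the smallest
    real root in [0, 100] with y* = 100 - x*. When both roots are in range
    the smaller is taken (with a logged note); for the empirical curves of
    interest the second root lies far beyond 100.
    """
    c0, c1, c2 = f.coefficients
    if c2 == 0.0:
        slope = c1 + 1.0
        if slope == 0.0:
            raise NoIntersectionError("curve is parallel to the anti-diagonal")
        roots = [(100.0 - c0) / slope]
    else:
        a, b, c = c2, c1 + 1.0, c0 - 100.0
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise NoIntersectionError(
                "fitted curve does not reach the anti-diagonal")
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
    in_range = sorted(r for r in roots if -_TOL <= r <= 100.0 + _TOL)
    if not in_range:
        raise NoIntersectionError(
            f"no intersection with the anti-diagonal in [0, 100]; "
            f"roots {roots}")
    if len(in_range) > 1:
        logger.info("both roots %s lie in [0, 100]; taking the smaller",
                    in_range)
    x_star = min(max(in_range[0], 0.0), 100.0)
    return (x_star, 100.0 - x_star)


def distance_to_stability_point(p: tuple[float, float],
                                reference: tuple[float, float] = STABILITY_POINT
                                ) -> float:
    """Euclidean distance from a point to the 20/80 stability point.

    For points on the anti-diagonal this equals sqrt(2) * |x - 20|.
    """
    return math.hypot(p[0] - reference[0], p[1] - reference[1])


def classify_stability(distance: float,
                       threshold: float = STABILITY_THRESHOLD) -> bool:
    """Stable iff distance <= threshold (inclusive at the boundary)."""
    if distance < 0:
        raise DegenerateInputError(f"distance must be >= 0, got {distance}")
    return distance <= threshold


class GodronStability:
    """Godron stability model for one stratum.

    Parameters
    ----------
    per_species_measure : mapping of species name to its cumulated measure
        (total coverage by default) over the stratum.
    measure : which measure is cumulated; ``"coverage"`` is the improved
        method, ``"frequency"`` the classical one (the caller supplies
        frequencies in that case — the pipeline itself computes coverage).
    degree : requested polynomial degree (default 2). When the stratum has
        fewer than 3 species the fit falls back to degree 1 automatically.

    Use :meth:`from_observations` to build the model straight from a
    stratum's :class:`~sandstab.io.SpeciesObservation` records.
    """

    def __init__(self, per_species_measure: Mapping[str, float],
                 measure: str = "coverage", degree: int = 2):
        self.measure = measure
        self.requested_degree = degree
        self.curve = build_cumulative_curve(per_species_measure, measure)
        self.degree = degree if self.curve.S >= degree + 1 else 1
        if self.degree != degree:
            logger.info("only %d species: falling back to a degree-%d fit",
                        self.curve.S, self.degree)
        if self.curve.S < self.degree + 1:
            raise FitError(
                f"stratum has {self.curve.S} species; need at least 2")

    @classmethod
    def from_observations(cls, obs: Iterable[SpeciesObservation],
                          measure: str = "coverage",
                          degree: int = 2) -> "GodronStability":
        totals: dict[str, float] = {}
        for o in obs:
            value = o.coverage if measure == "coverage" else 1.0
            totals[o.species] = totals.get(o.species, 0.0) + value
        if not totals:
            raise DegenerateInputError("empty stratum: no observations")
        return cls(totals, measure=measure, degree=degree)

    @classmethod
    def from_curve(cls, curve: CumulativeCurve,
                   degree: int = 2) -> "GodronStability":
        model = cls.__new__(cls)
        model.measure = curve.measure
        model.requested_degree = degree
        model.curve = curve
        model.degree = degree if curve.S >= degree + 1 else 1
        return model

    def fit(self, paper_compat: bool = False) -> "GodronStabilityResults":
        """Fit the smooth curve and derive the stability assessment.

        ``paper_compat=True`` rounds the intersection coordinates to two
        decimals before the distance, and the distance itself to two
        decimals — the precision at which such tables are published.
        """
        fitted = fit_smooth_curve(self.curve, self.degree)
        x_star, y_star = intersect_with_antidiagonal(fitted)
        if paper_compat:
            x_star, y_star = round(x_star, 2), round(y_star, 2)
        distance = distance_to_stability_point((x_star, y_star))
        if paper_compat:
            distance = round(distance, 2)
        return GodronStabilityResults(
            model=self,
            fitted_curve=fitted,
            assessment=StabilityAssessment(
                intersection=(x_star, y_star),
                distance=distance,
                stable=classify_stability(distance),
            ),
            paper_compat=paper_compat,
        )


@dataclass(frozen=True)
class GodronStabilityResults:
    """Fitted Godron stability curve and the derived verdict."""

    model: GodronStability
    fitted_curve: FittedCurve
    assessment: StabilityAssessment
    paper_compat: bool = False

    @property
    def params(self) -> np.ndarray:
        """Polynomial coefficients (c0, c1, c2), ascending powers."""
        return np.array(self.fitted_curve.coefficients)

    @property
    def rsquared(self) -> float:
        return self.fitted_curve.r_squared

    @property
    def intersection(self) -> tuple[float, float]:
        return self.assessment.intersection

    @property
    def distance(self) -> float:
        return self.assessment.distance

    @property
    def stable(self) -> bool:
        return self.assessment.stable

    def summary(self) -> str:
        c0, c1, c2 = self.fitted_curve.coefficients
        eq = (f"y = {c2:+.4g}x^2 {c1:+.4g}x {c0:+.4g}"
              if self.fitted_curve.degree == 2
              else f"y = {c1:.4g}x {c0:+.4g}")
        x_star, y_star = self.intersection
        lines = [
            "Godron community stability (coverage-based)",
            "-" * 47,
            f"species (S):          {self.model.curve.S}",
            f"measure:              {self.model.measure}",
            f"fitted curve:         {eq}",
            f"R^2:                  {self.rsquared:.4f}",
            f"intersection:         ({x_star:.2f}, {y_star:.2f})",
            f"reference point:      {self.assessment.reference_point}",
            f"Euclidean distance:   {self.distance:.2f}",
            f"threshold:            {self.assessment.threshold:.3f}",
            f"verdict:              {'stable' if self.stable else 'unstable'}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter, fitted curve, anti-diagonal and the 20/80 point."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        curve = self.model.curve
        ax.scatter(curve.x, curve.y, s=18, zorder=3,
                   label="cumulative scatter")
        grid = np.linspace(0, 100, 200)
        ax.plot(grid, self.fitted_curve(grid), lw=1.5, label="fitted curve")
        ax.plot([0, 100], [100, 0], "k--", lw=1, label="anti-diagonal")
        ax.plot(*self.assessment.reference_point, "r*", ms=12,
                label="stability point (20, 80)")
        ax.plot(*self.intersection, "o", ms=7, mfc="none",
                label=f"intersection (d = {self.distance:.2f})")
        ax.set_xlim(0, 100)
        ax.set_ylim(0, 105)
        ax.set_xlabel("cumulative % of species")
        ax.set_ylabel(f"cumulative relative {self.model.measure} (%)")
        ax.legend(fontsize=8)
        return ax


def assess_stability(obs: Iterable[SpeciesObservation],
                     measure: str = "coverage",
                     degree: int = 2,
                     paper_compat: bool = False) -> StabilityAssessment:
    """One-call pipeline: observations -> curve -> fit -> verdict."""
    results = GodronStability.from_observations(
        obs, measure=measure, degree=degree).fit(paper_compat=paper_compat)
    return results.assessment
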