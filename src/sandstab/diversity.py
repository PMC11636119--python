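"""Importance values and alpha-diversity indices for a stratum.

The importance value Iv of a species is the mean of its relative height,
relative coverage and relative density within the stratum, so Iv sums to 1
over species and measures dominance. The four classical indices are
computed from proportional weights P_i:

* Margalef richness      R = (S - 1) / ln N
* Simpson dominance      D = 1 - sum P_i^2
* Shannon-Wiener         H = -sum P_i ln P_i
* Pielou evenness        E = H / ln S

Weights default to importance values (the convention in Chinese vegetation
surveys, where N_i in the index formulas is glossed as the species
importance value); abundance counts are available as an alternative mode.
N in Margalef's index is always an individual count, never the importance
total (whose logarithm would be ln 1 = 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import DegenerateInputError, InconsistencyError
from .io import SpeciesObservation

logger = logging.getLogger(__name__)

__all__ = [
    "ImportanceRecord",
    "DiversityProfile",
    "importance_values",
    "proportions",
    "margalef_richness",
    "simpson",
    "shannon",
    "pielou",
    "diversity_profile",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ImportanceRecord:
    species: str
    relative_height: float
    relative_coverage: float
    relative_density: float
    Iv: float


@dataclass(frozen=True)
class DiversityProfile:
    """Alpha-diversity summary of one stratum.

    ``E`` is NaN for a monoculture (S = 1), where evenness H/ln S is the
    indeterminate form 0/0; result tables print it as NA.
    """

    S: int
    N: float
    R: float
    D: float
    H: float
    E: float
    weight_mode: str


def importance_values(obs: Iterable[SpeciesObservation]
                      ) -> list[ImportanceRecord]:
    """Per-species importance values over a stratum's observations.

    Species are first aggregated across the stratum's quadrats — mean
    height, summed coverage, summed density — then each aggregate is divided
    by the stratum total. Output is sorted by Iv descending, ties broken
    lexicographically by species name.
    """
    obs = list(obs)
    if not obs:
        raise DegenerateInputError("empty stratum: no observations")
    heights: dict[str, list[float]] = {}
    coverage: dict[str, float] = {}
    density: dict[str, float] = {}
    for o in obs:
        heights.setdefault(o.species, []).append(o.height)
        coverage[o.species] = coverage.get(o.species, 0.0) + o.coverage
        density[o.species] = density.get(o.species, 0.0) + o.density
    mean_height = {sp: sum(v) / len(v) for sp, v in heights.items()}
    totals = {
        "height": sum(mean_height.values()),
        "coverage": sum(coverage.values()),
        "density": sum(density.values()),
    }
    for component, total in totals.items():
        if total <= 0:
            raise DegenerateInputError(
                f"stratum total {component} is zero; importance values "
                "are undefined")
    records = []
    for sp in mean_height:
        rh = mean_height[sp] / totals["height"]
        rc = coverage[sp] / totals["coverage"]
        rd = density[sp] / totals["density"]
        records.append(ImportanceRecord(sp, rh, rc, rd, (rh + rc + rd) / 3.0))
    records.sort(key=lambda r: (-r.Iv, r.species))
    total_iv = sum(r.Iv for r in records)
    if abs(total_iv - 1.0) > _SUM_TOL:
        raise InconsistencyError(
            f"importance values sum to {total_iv!r}, expected 1")
    return records


def proportions(weights: Mapping[str, float]) -> dict[str, float]:
    """Normalize non-negative per-species weights to proportions P_i.

    Zero-weight species carry no information for the indices and are
    dropped with a logged note.
    """
    if any(w < 0 for w in weights.values()):
        raise DegenerateInputError("negative weight")
    total = sum(weights.values())
    if total <= 0:
        raise DegenerateInputError("all weights are zero")
    dropped = [sp for sp, w in weights.items() if w == 0]
    if dropped:
        logger.info("dropping %d zero-weight species: %s",
                    len(dropped), sorted(dropped))
    return {sp: w / total for sp, w in weights.items() if w > 0}


def margalef_richness(S: int, N: float) -> float:
    """Margalef's richness index R = (S - 1) / ln N.

    A monoculture has R = 0 regardless of N. For S >= 2 the index needs
    ln N > 0, i.e. more than one individual.
    """
    if S < 1:
        raise DegenerateInputError(f"S must be >= 1, got {S}")
    if S == 1:
        return 0.0
    if N <= 1:
        raise DegenerateInputError(
            f"Margalef's index needs N > 1 when S >= 2; got N={N}")
    return (S - 1) / math.log(N)


def _check_proportions(P: Sequence[float]) -> None:
    if abs(sum(P) - 1.0) > 1e-6:
        raise DegenerateInputError(
            f"proportions must sum to 1, got {sum(P)!r}")


def simpson(P: Sequence[float] | Mapping[str, float]) -> float:
    """Simpson's dominance diversity D = 1 - sum P_i^2."""
    values = list(P.values()) if isinstance(P, Mapping) else list(P)
    _check_proportions(values)
    return 1.0 - sum(p * p for p in values)


def shannon(P: Sequence[float] | Mapping[str, float]) -> float:
    """Shannon-Wiener diversity H = -sum P_i ln P_i (0 ln 0 := 0)."""
    values = list(P.values()) if isinstance(P, Mapping) else list(P)
    _check_proportions(values)
    return -sum(p * math.log(p) for p in values if p > 0)


def pielou(H: float, S: int) -> float:
    """Pielou's evenness E = H / ln S; NaN for S = 1 (0/0 indeterminate)."""
    if S < 1:
        raise DegenerateInputError(f"S must be >= 1, got {S}")
    if S == 1:
        logger.warning("Pielou evenness is undefined for a monoculture; "
                       "returning NaN")
        return math.nan
    if H > math.log(S) + 1e-9:
        raise InconsistencyError(
            f"H={H} exceeds ln S={math.log(S)}: inconsistent inputs")
    return min(H / math.log(S), 1.0)


def diversity_profile(obs: Iterable[SpeciesObservation],
                      weight_mode: str = "importance_value"
                      ) -> DiversityProfile:
    """Full alpha-diversity profile of one stratum.

    ``weight_mode`` selects the P_i weights: ``"importance_value"``
    (default) or ``"abundance"``. N for Margalef's index is the total
    abundance when counts were recorded, otherwise the total density
    rounded to the nearest integer (floored at 2 so ln N > 0).
    """
    obs = list(obs)
    if weight_mode not in ("importance_value", "abundance"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    records = importance_values(obs)
    S = len(records)

    counts: dict[str, float] = {}
    have_abundance = all(o.abundance is not None for o in obs)
    for o in obs:
        n = o.abundance if have_abundance else o.density
        counts[o.species] = counts.get(o.species, 0.0) + n
    if have_abundance:
        N = float(sum(counts.values()))
    else:
        N = float(max(2, round(sum(counts.values()))))

    if weight_mode == "importance_value":
        P = proportions({r.species: r.Iv for r in records})
    else:
        P = proportions(counts)

    H = shannon(P)
    return DiversityProfile(
        S=S,
        N=N,
        R=margalef_richness(S, N),
        D=simpson(P),
        H=H,
        E=pielou(H, S),
        weight_mode=weight_mode,
    )
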