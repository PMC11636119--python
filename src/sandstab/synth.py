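"""Seeded generator of chronosequence community and soil tables.

Real quadrat data for the study system (shrub-stabilised alpine sandy
land surveyed at restoration ages 0/13/25/45) are not public, so this
module emulates their statistical structure: species richness rising from
3 to 21 across the chronosequence, a geometric (niche-preemption)
rank-abundance profile whose dominance parameter k relaxes with age,
an under-crown vs outside-crown dominance contrast that shrinks with age,
and soil trends — pH declining, SOM and AN rising to 3.5008x and 5.4243x
their unrestored-control means by year 45, TP flat in time but enriched in
the 0-20 cm surface layer.

Everything is a deterministic function of (config, seed): the same config
regenerates byte-identical tables, and the manifest records the ground
truth (true shares, true soil means) so recovery tests can compare
pipeline output against what was configured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import ConfigError
from .io import (Dataset, DepthLayer, LifeForm, Position, Quadrat,
                 SoilSample, SpeciesObservation, write_community_table,
                 write_soil_table)

__all__ = ["SynthConfig", "geometric_shares", "generate_community",
           "generate_soil", "generate_dataset", "shares_matching_curve"]


def _default_richness() -> dict[int, int]:
    # endpoints (3 and 21 species) follow the study system; interior ages
    # interpolate monotonically
    return {0: 3, 13: 15, 25: 17, 45: 21}


def _default_k() -> dict[int, float]:
    # geometric dominance parameter; k = 0.38 at S = 3 puts the control's
    # dominant share at 0.50, relaxing slightly as restoration evens the
    # community (the stability trend is driven mostly by rising richness)
    return {0: 0.38, 13: 0.32, 25: 0.31, 45: 0.30}


def _default_contrast() -> dict[int, float]:
    # under-crown richness deficit (fraction of the stratum's species
    # missing under the crown), decaying with age: under-crown strata are
    # less diverse and farther from the 20/80 configuration, and the gap
    # closes as restoration proceeds
    return {0: 0.0, 13: 0.20, 25: 0.10, 45: 0.05}


def _default_soil_controls() -> dict[str, float]:
    # unrestored mobile-sand control means: pH (unitless), SOM g/kg,
    # AN mg/kg, TP g/kg
    return {"pH": 8.4, "SOM": 4.0, "AN": 12.0, "TP": 0.30}


def _default_noise() -> dict[str, float]:
    # lognormal sigma for positive variables; additive normal sd for pH
    return {"community": 0.15, "soil": 0.2, "pH": 0.1}


@dataclass
class SynthConfig:
    """Configuration of the synthetic chronosequence.

    ``k_by_year`` is the geometric-series dominance parameter per age.
    ``under_vs_outside_contrast`` is the fraction of the stratum's species
    absent under the crown, so a positive contrast makes the under-crown
    community poorer and farther from the 20/80 configuration (less
    diverse and less Godron-stable), shrinking with age as the canopy
    effect fades.
    """

    seed: int = 0
    years: tuple[int, ...] = (0, 13, 25, 45)
    positions: tuple[Position, ...] = (Position.under_crown,
                                       Position.outside_crown)
    soil_positions: tuple[Position, ...] = (Position.under_crown,
                                            Position.crown_edge,
                                            Position.outside_crown)
    quadrats_per_stratum: int = 3
    soil_reps: int = 3
    richness_by_year: dict[int, int] = field(default_factory=_default_richness)
    k_by_year: dict[int, float] = field(default_factory=_default_k)
    under_vs_outside_contrast: dict[int, float] = field(
        default_factory=_default_contrast)
    total_coverage: float = 80.0   # % of quadrat area, all species combined
    total_density: float = 60.0    # individuals per quadrat
    base_height: float = 18.0      # cm, community mean
    soil_controls: dict[str, float] = field(
        default_factory=_default_soil_controls)
    som_ratio: float = 3.5008      # SOM(45 yr) / SOM(control), expectation
    an_ratio: float = 5.4243       # AN(45 yr) / AN(control), expectation
    ph_drop: float = 0.8           # pH decline from control to 45 yr
    tp_surface_factor: float = 1.4  # TP enrichment of the 0-20 cm layer
    noise: dict[str, float] = field(default_factory=_default_noise)

    def validate(self) -> None:
        missing = [y for y in self.years if y not in self.richness_by_year]
        if missing:
            raise ConfigError(f"richness_by_year lacks year(s) {missing}")
        rich = [self.richness_by_year[y] for y in sorted(self.years)]
        if any(b < a for a, b in zip(rich, rich[1:])):
            raise ConfigError("richness_by_year must be non-decreasing")
        if any(r < 1 for r in rich):
            raise ConfigError("richness must be >= 1")
        for y in self.years:
            k = self.k_by_year.get(y)
            if k is None or not 0.0 < k < 1.0:
                raise ConfigError(f"k_by_year[{y}] must lie in (0, 1)")
            c = self.under_vs_outside_contrast.get(y, 0.0)
            if not 0.0 <= c < 1.0:
                raise ConfigError(
                    "under_vs_outside_contrast must lie in [0, 1)")
        if self.quadrats_per_stratum < 1 or self.soil_reps < 1:
            raise ConfigError("replication must be >= 1")
        for name in ("som_ratio", "an_ratio", "tp_surface_factor"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if any(s < 0 for s in self.noise.values()):
            raise ConfigError("noise sigmas must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["positions"] = [p.value for p in self.positions]
        d["soil_positions"] = [p.value for p in self.soil_positions]
        d["years"] = list(self.years)
        return d


def geometric_shares(k: float, S: int) -> np.ndarray:
    """Renormalized geometric (niche-preemption) shares k(1-k)^(i-1).

    The first species takes fraction ~k of the resource, the next k of the
    remainder, and so on; renormalisation makes the S shares sum to 1.
    """
    if not 0.0 < k < 1.0:
        raise ConfigError(f"k must lie in (0, 1), got {k}")
    if S < 1:
        raise ConfigError(f"S must be >= 1, got {S}")
    raw = k * (1.0 - k) ** np.arange(S)
    return raw / raw.sum()


def _species_pool(n: int) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(n)]


def _life_form(pool_index: int) -> LifeForm:
    # roughly 4 annuals among 21 species, the rest perennial herbs
    return (LifeForm.annual_herb if pool_index % 5 == 4
            else LifeForm.perennial_herb)


def _stratum_richness(config: SynthConfig, year: int,
                      position: Position) -> int:
    """Species count of a stratum: the year's richness, thinned under the
    crown by the configured contrast fraction."""
    S = config.richness_by_year[year]
    if position == Position.under_crown:
        c = config.under_vs_outside_contrast.get(year, 0.0)
        S = max(1, round(S * (1.0 - c)))
    return S


def generate_community(config: SynthConfig
                       ) -> tuple[Dataset, dict]:
    """Generate the community table and its ground-truth manifest.

    Per stratum (year x position): S species with geometric coverage
    shares; heights and densities proportional to the shares (dominants
    are taller and denser) with multiplicative lognormal noise, so at
    sigma = 0 every relative component — and hence every importance value —
    equals the configured share exactly.
    """
    config.validate()
    sigma = config.noise.get("community", 0.0)
    pool = _species_pool(max(config.richness_by_year[y]
                             for y in config.years))
    quadrats: list[Quadrat] = []
    observations: list[SpeciesObservation] = []
    manifest: dict = {"config": config.to_dict(), "community": {}}
    for year in config.years:
        for pos_idx, pos in enumerate(config.positions):
            S = _stratum_richness(config, year, pos)
            k = config.k_by_year[year]
            shares = geometric_shares(k, S)
            species = pool[:S]
            rng = np.random.default_rng([config.seed, year, pos_idx])
            manifest["community"][f"y{year}_{pos.value}"] = {
                "richness": S,
                "k": float(k),
                "species": species,
                "shares": [float(s) for s in shares],
            }
            for q in range(config.quadrats_per_stratum):
                qid = f"y{year}_{pos.value}_q{q + 1}"
                quadrats.append(Quadrat(qid, year, pos))
                noise = (np.exp(sigma * rng.standard_normal((3, S)))
                         if sigma > 0 else np.ones((3, S)))
                for i, sp in enumerate(species):
                    coverage = config.total_coverage * shares[i] * noise[0, i]
                    height = config.base_height * S * shares[i] * noise[1, i]
                    density = config.total_density * shares[i] * noise[2, i]
                    observations.append(SpeciesObservation(
                        quadrat_id=qid,
                        species=sp,
                        life_form=_life_form(i),
                        height=float(height),
                        coverage=float(min(coverage, 100.0)),
                        density=float(density),
                        abundance=int(max(1, round(density))),
                    ))
    return Dataset(quadrats=quadrats, observations=observations), manifest


def _soil_mean(config: SynthConfig, variable: str, year: int,
               layer: DepthLayer, position: Position) -> float:
    """Deterministic trend surface the noisy draws are centred on."""
    control = config.soil_controls[variable]
    max_year = max(config.years)
    t = year / max_year if max_year else 0.0
    if variable == "pH":
        mean = control - config.ph_drop * t
        mean += {Position.under_crown: -0.05, Position.crown_edge: 0.0,
                 Position.outside_crown: 0.02}[position]
        return mean
    if variable == "SOM":
        ratio = config.som_ratio ** t
        layer_f = {DepthLayer.d0_20: 1.15, DepthLayer.d20_40: 0.95,
                   DepthLayer.d40_60: 0.90}[layer]
    elif variable == "AN":
        ratio = config.an_ratio ** t
        layer_f = 1.0
    elif variable == "TP":
        ratio = 1.0
        layer_f = {DepthLayer.d0_20: config.tp_surface_factor,
                   DepthLayer.d20_40: 0.90,
                   DepthLayer.d40_60: 0.85}[layer]
    else:
        raise ConfigError(f"unknown soil variable {variable!r}")
    pos_f = {Position.under_crown: 1.08, Position.crown_edge: 1.0,
             Position.outside_crown: 0.94}[position]
    return control * ratio * layer_f * pos_f


def generate_soil(config: SynthConfig) -> tuple[list[SoilSample], dict]:
    """Generate the soil table and manifest entries of true means.

    Nutrients get mean-preserving lognormal noise
    (value = mean * exp(sigma z - sigma^2 / 2)), pH additive normal noise,
    so expectations sit exactly on the trend surface at any sigma and the
    configured 45-yr/control SOM and AN ratios hold in expectation.
    """
    config.validate()
    sigma = config.noise.get("soil", 0.0)
    sigma_ph = config.noise.get("pH", 0.0)
    samples: list[SoilSample] = []
    true_means: dict[str, dict[str, float]] = {}
    for y_idx, year in enumerate(config.years):
        for l_idx, layer in enumerate(DepthLayer):
            for p_idx, pos in enumerate(config.soil_positions):
                rng = np.random.default_rng(
                    [config.seed, 1000 + y_idx, l_idx, p_idx])
                means = {v: _soil_mean(config, v, year, layer, pos)
                         for v in ("pH", "SOM", "AN", "TP")}
                true_means[f"y{year}_{layer.value}_{pos.value}"] = means
                for _ in range(config.soil_reps):
                    values = {}
                    for v in ("SOM", "AN", "TP"):
                        if sigma > 0:
                            z = rng.standard_normal()
                            values[v] = means[v] * math.exp(
                                sigma * z - 0.5 * sigma * sigma)
                        else:
                            values[v] = means[v]
                    ph = means["pH"] + (sigma_ph * rng.standard_normal()
                                        if sigma_ph > 0 else 0.0)
                    samples.append(SoilSample(
                        restoration_years=year, depth_layer=layer,
                        position=pos, pH=float(ph), SOM=float(values["SOM"]),
                        AN=float(values["AN"]), TP=float(values["TP"])))
    return samples, {"soil_true_means": true_means}


def generate_dataset(config: SynthConfig, out_dir: str | Path
                     ) -> dict[str, Path]:
    """Write community.csv, soil.csv and manifest.yaml under ``out_dir``.

    The files are consumable unchanged by the readers in
    :mod:`sandstab.io`; returns the paths, keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset, manifest = generate_community(config)
    soil, soil_manifest = generate_soil(config)
    manifest.update(soil_manifest)
    paths = {
        "community": write_community_table(dataset,
                                           out_dir / "community.csv"),
        "soil": write_soil_table(soil, out_dir / "soil.csv"),
        "manifest": out_dir / "manifest.yaml",
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths


def shares_matching_curve(coefficients: tuple[float, float, float],
                          S: int = 21,
                          intersection_x: float | None = None
                          ) -> dict[str, float]:
    """Coverage shares whose quadratic OLS fit hits a target intersection.

    A published cumulative-curve fit cannot in general be reproduced
    exactly by any valid cumulative profile: an empirical quadratic may
    exceed y = 100 or turn over before x = 100, while a cumulative curve
    is non-decreasing and ends at (100, 100). This helper constructs the
    closest feasible stand-in: the monotone share profile nearest to the
    target curve, constrained (via an equality-constrained least-squares
    projection) so that the degree-2 OLS fit of its cumulative points
    passes exactly through the target curve's anti-diagonal intersection.
    Downstream stability output (intersection, distance, verdict) then
    matches the target curve's.

    Parameters
    ----------
    coefficients : (c0, c1, c2) of the target quadratic, ascending powers.
    S : number of species to synthesise.
    intersection_x : x of the anti-diagonal crossing to reproduce; by
        default the target curve's own closed-form crossing.
    """
    c0, c1, c2 = coefficients
    if intersection_x is None:
        a, b, c = c2, c1 + 1.0, c0 - 100.0
        if a == 0:
            intersection_x = -c / b
        else:
            disc = b * b - 4 * a * c
            if disc < 0:
                raise ConfigError("target curve misses the anti-diagonal")
            roots = sorted(x for x in
                           ((-b - math.sqrt(disc)) / (2 * a),
                            (-b + math.sqrt(disc)) / (2 * a))
                           if 0 <= x <= 100)
            if not roots:
                raise ConfigError("no in-range intersection to match")
            intersection_x = roots[0]
    x = 100.0 * np.arange(1, S + 1) / S
    X = np.vander(x, 3, increasing=True)
    f = X @ np.array([c0, c1, c2])
    # starting guess: the target curve capped at 100, made monotone,
    # pinned to end at 100
    g = np.maximum.accumulate(np.minimum(f, 100.0))
    g[-1] = 100.0
    p_g = np.diff(np.concatenate([[0.0], g]))
    H = np.linalg.solve(X.T @ X, X.T @ np.tril(np.ones((S, S))))
    v = np.array([1.0, intersection_x, intersection_x ** 2])
    A = np.vstack([np.ones(S), v @ H])
    b_eq = np.array([100.0, 100.0 - intersection_x])
    lam = np.linalg.solve(A @ A.T, b_eq - A @ p_g)
    p = p_g + A.T @ lam
    if np.any(p <= 0):
        raise ConfigError(
            "no positive share profile matches this curve; try another S")
    return {name: float(share)
            for name, share in zip(_species_pool(S), p)}
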