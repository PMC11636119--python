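"""Data model and delimited-table I/O for quadrat community surveys and soil
samples.

The analysis unit throughout the package is the *stratum*: one restoration
age crossed with one canopy position (under the shrub crown, at the crown
edge, or on open ground outside it). Community tables hold one row per
species observation within a quadrat; soil tables hold one row per
depth-layer composite sample. Coverage is stored as a percentage of quadrat
area in [0, 100] — per-unit values are rejected rather than rescaled, so a
100x unit error cannot pass silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ReferentialError, RowError, SchemaError, NotFoundError

logger = logging.getLogger(__name__)

__all__ = [
    "LifeForm",
    "Position",
    "DepthLayer",
    "SpeciesObservation",
    "Quadrat",
    "StratumKey",
    "SoilSample",
    "Dataset",
    "read_community_table",
    "read_soil_table",
    "write_community_table",
    "write_soil_table",
    "write_results",
    "stratify",
]


class LifeForm(str, Enum):
    annual_herb = "annual_herb"
    perennial_herb = "perennial_herb"
    shrub = "shrub"


class Position(str, Enum):
    """Sampling position relative to the shrub canopy."""

    under_crown = "under_crown"
    crown_edge = "crown_edge"
    outside_crown = "outside_crown"


class DepthLayer(str, Enum):
    """Soil depth layer of a composite sample (cm)."""

    d0_20 = "d0_20"
    d20_40 = "d20_40"
    d40_60 = "d40_60"


@dataclass(frozen=True)
class SpeciesObservation:
    """One species' measurements within one quadrat.

    Parameters
    ----------
    height : float
        Mean plant height in cm; must be positive.
    coverage : float
        Percent of quadrat area covered, in [0, 100].
    density : float
        Individuals per quadrat (may be fractional after averaging).
    abundance : int, optional
        Raw individual count when recorded.
    """

    quadrat_id: str
    species: str
    life_form: LifeForm
    height: float
    coverage: float
    density: float
    abundance: int | None = None

    def __post_init__(self):
        if not self.height > 0:
            raise RowError(f"height must be > 0, got {self.height!r} "
                           f"({self.quadrat_id}/{self.species})")
        if not 0.0 <= self.coverage <= 100.0:
            raise RowError(
                f"coverage must lie in [0, 100] percent, got {self.coverage!r} "
                f"({self.quadrat_id}/{self.species})")
        if self.density < 0:
            raise RowError(f"density must be >= 0, got {self.density!r} "
                           f"({self.quadrat_id}/{self.species})")
        if self.abundance is not None and self.abundance < 0:
            raise RowError(f"abundance must be >= 0, got {self.abundance!r}")


@dataclass(frozen=True)
class Quadrat:
    quadrat_id: str
    restoration_years: int
    position: Position
    area: float = 0.25  # m^2; the field survey used 0.5 m x 0.5 m frames

    def __post_init__(self):
        if self.restoration_years < 0:
            raise RowError("restoration_years must be >= 0")
        if not self.area > 0:
            raise RowError("quadrat area must be > 0")


@dataclass(frozen=True)
class StratumKey:
    """Grouping key: restoration age crossed with canopy position.

    ``position="all"`` is a wildcard that matches every position.
    """

    restoration_years: int
    position: Position | str = "all"

    def matches(self, quadrat: Quadrat) -> bool:
        if quadrat.restoration_years != self.restoration_years:
            return False
        return self.position == "all" or quadrat.position == self.position


@dataclass(frozen=True)
class SoilSample:
    """One depth-layer composite sample.

    pH is unitless in (0, 14); SOM (soil organic matter) and TP (total
    phosphorus) are g/kg; AN (alkali-hydrolyzable nitrogen) is mg/kg.
    """

    restoration_years: int
    depth_layer: DepthLayer
    position: Position
    pH: float
    SOM: float
    AN: float
    TP: float

    def __post_init__(self):
        if not 0.0 < self.pH < 14.0:
            raise RowError(f"pH must lie in (0, 14), got {self.pH!r}")
        for name in ("SOM", "AN", "TP"):
            if getattr(self, name) < 0:
                raise RowError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if self.restoration_years < 0:
            raise RowError("restoration_years must be >= 0")


@dataclass
class Dataset:
    """A validated survey: quadrats, their species observations, and soil."""

    quadrats: list[Quadrat] = field(default_factory=list)
    observations: list[SpeciesObservation] = field(default_factory=list)
    soil: list[SoilSample] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [q.quadrat_id for q in self.quadrats]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ReferentialError(f"duplicate quadrat_id(s): {dup}")
        known = set(ids)
        for obs in self.observations:
            if obs.quadrat_id not in known:
                raise ReferentialError(
                    f"observation of {obs.species!r} references unknown "
                    f"quadrat {obs.quadrat_id!r}")
        pairs = [(o.quadrat_id, o.species) for o in self.observations]
        if len(pairs) != len(set(pairs)):
            dup = sorted({p for p in pairs if pairs.count(p) > 1})
            raise ReferentialError(
                f"duplicate (quadrat_id, species) pair(s): {dup}")

    @property
    def quadrat_index(self) -> dict[str, Quadrat]:
        return {q.quadrat_id: q for q in self.quadrats}

    def years(self) -> list[int]:
        return sorted({q.restoration_years for q in self.quadrats})

    def strata(self) -> list[StratumKey]:
        """All (year, position) pairs present, in sorted order."""
        seen = sorted({(q.restoration_years, q.position) for q in self.quadrats},
                      key=lambda t: (t[0], t[1].value))
        return [StratumKey(y, p) for y, p in seen]


# Default column names for community tables; callers may remap any of them.
COMMUNITY_COLUMNS: dict[str, str] = {
    "quadrat_id": "quadrat_id",
    "restoration_years": "restoration_years",
    "position": "position",
    "area": "area",
    "species": "species",
    "life_form": "life_form",
    "height": "height",
    "coverage": "coverage",
    "density": "density",
    "abundance": "abundance",  # optional
}

SOIL_COLUMNS: dict[str, str] = {
    "restoration_years": "restoration_years",
    "depth_layer": "depth_layer",
    "position": "position",
    "pH": "pH",
    "SOM": "SOM",
    "AN": "AN",
    "TP": "TP",
}

_OPTIONAL_COMMUNITY = {"abundance", "area"}


def _check_columns(df: pd.DataFrame, colmap: Mapping[str, str],
                   optional: set[str], what: str) -> None:
    required = {v for k, v in colmap.items() if k not in optional}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"{what} table is missing required column(s): {sorted(missing)}")
    unknown = set(df.columns) - set(colmap.values())
    if unknown:
        logger.warning("%s table: ignoring unknown column(s) %s",
                       what, sorted(unknown))


def _num(value, field_name: str, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowError(f"cannot parse {field_name}={value!r} as a number",
                       line=line) from None


def read_community_table(path: str | Path,
                         column_map: Mapping[str, str] | None = None,
                         delimiter: str = ",") -> Dataset:
    """Read a community survey CSV into a validated :class:`Dataset`.

    One row per species observation; quadrat attributes (restoration age,
    position, area) are carried on each row and must be consistent across
    the rows of a quadrat. Unknown columns are ignored with a warning.
    """
    colmap = dict(COMMUNITY_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, delimiter=delimiter, dtype=str,
                     keep_default_na=False, encoding="utf-8")
    _check_columns(df, colmap, _OPTIONAL_COMMUNITY, "community")

    quadrats: dict[str, Quadrat] = {}
    observations: list[SpeciesObservation] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        rec = {k: getattr(row, colmap[k]) if colmap[k] in df.columns else ""
               for k in colmap}
        qid = str(rec["quadrat_id"])
        try:
            position = Position(rec["position"])
        except ValueError:
            raise RowError(f"unknown position {rec['position']!r}", line=line)
        years = int(_num(rec["restoration_years"], "restoration_years", line))
        area = _num(rec["area"], "area", line) if rec.get("area") else 0.25
        quad = Quadrat(qid, years, position, area)
        if qid in quadrats:
            if quadrats[qid] != quad:
                raise RowError(
                    f"quadrat {qid!r} redefined with conflicting attributes",
                    line=line)
        else:
            quadrats[qid] = quad
        try:
            life_form = LifeForm(rec["life_form"])
        except ValueError:
            raise RowError(f"unknown life_form {rec['life_form']!r}", line=line)
        abundance = rec.get("abundance", "")
        try:
            observations.append(SpeciesObservation(
                quadrat_id=qid,
                species=str(rec["species"]),
                life_form=life_form,
                height=_num(rec["height"], "height", line),
                coverage=_num(rec["coverage"], "coverage", line),
                density=_num(rec["density"], "density", line),
                abundance=int(_num(abundance, "abundance", line))
                if abundance != "" else None,
            ))
        except RowError as err:
            if err.line is None:
                raise RowError(str(err), line=line) from None
            raise
    return Dataset(quadrats=list(quadrats.values()), observations=observations)


def read_soil_table(path: str | Path,
                    column_map: Mapping[str, str] | None = None,
                    delimiter: str = ",") -> list[SoilSample]:
    """Read a soil sample CSV (one row per depth-layer composite)."""
    colmap = dict(SOIL_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, delimiter=delimiter, dtype=str,
                     keep_default_na=False, encoding="utf-8")
    _check_columns(df, colmap, set(), "soil")
    samples = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2
        rec = {k: getattr(row, colmap[k]) for k in colmap}
        try:
            layer = DepthLayer(rec["depth_layer"])
            position = Position(rec["position"])
        except ValueError as err:
            raise RowError(str(err), line=line) from None
        try:
            samples.append(SoilSample(
                restoration_years=int(_num(rec["restoration_years"],
                                           "restoration_years", line)),
                depth_layer=layer,
                position=position,
                pH=_num(rec["pH"], "pH", line),
                SOM=_num(rec["SOM"], "SOM", line),
                AN=_num(rec["AN"], "AN", line),
                TP=_num(rec["TP"], "TP", line),
            ))
        except RowError as err:
            if err.line is None:
                raise RowError(str(err), line=line) from None
            raise
    return samples


def community_to_frame(dataset: Dataset) -> pd.DataFrame:
    """Flatten a Dataset's community part to one row per observation."""
    qindex = dataset.quadrat_index
    rows = []
    for obs in dataset.observations:
        q = qindex[obs.quadrat_id]
        rows.append({
            "quadrat_id": obs.quadrat_id,
            "restoration_years": q.restoration_years,
            "position": q.position.value,
            "area": q.area,
            "species": obs.species,
            "life_form": obs.life_form.value,
            "height": obs.height,
            "coverage": obs.coverage,
            "density": obs.density,
            "abundance": "" if obs.abundance is None else obs.abundance,
        })
    return pd.DataFrame(rows, columns=list(COMMUNITY_COLUMNS.values()))


def soil_to_frame(samples: Iterable[SoilSample]) -> pd.DataFrame:
    rows = [{
        "restoration_years": s.restoration_years,
        "depth_layer": s.depth_layer.value,
        "position": s.position.value,
        "pH": s.pH, "SOM": s.SOM, "AN": s.AN, "TP": s.TP,
    } for s in samples]
    return pd.DataFrame(rows, columns=list(SOIL_COLUMNS.values()))


def write_community_table(dataset: Dataset, path: str | Path) -> Path:
    path = Path(path)
    community_to_frame(dataset).to_csv(path, index=False, encoding="utf-8")
    return path


def write_soil_table(samples: Iterable[SoilSample], path: str | Path) -> Path:
    path = Path(path)
    soil_to_frame(samples).to_csv(path, index=False, encoding="utf-8")
    return path


# Fixed, documented column orders for the result tables written by the
# pipeline. Tables not listed here are written with their own column order.
RESULT_COLUMNS: dict[str, list[str]] = {
    "diversity": ["restoration_years", "position", "S", "N", "R", "D", "H",
                  "E", "weight_mode"],
    "importance": ["restoration_years", "position", "species",
                   "relative_height", "relative_coverage", "relative_density",
                   "Iv"],
    "stability": ["restoration_years", "position", "degree", "c0", "c1", "c2",
                  "r_squared", "x_star", "y_star", "distance", "threshold",
                  "stable"],
    "soil_summary": ["restoration_years", "depth_layer", "position",
                     "variable", "mean", "sd", "n", "pct_change_vs_control"],
}


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  mode: str = "full") -> dict[str, Path]:
    """Write one CSV per result table into ``out_dir``.

    ``mode="paper_compat"`` rounds numeric columns to 2 decimals, mirroring
    the precision of published community-ecology tables; the default keeps
    full precision so written values round-trip bit-identically.
    """
    if mode not in ("full", "paper_compat"):
        raise ValueError(f"unknown formatting mode {mode!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        df = df.copy()
        order = RESULT_COLUMNS.get(name)
        if order is not None:
            cols = [c for c in order if c in df.columns]
            cols += [c for c in df.columns if c not in cols]
            df = df[cols] if len(df.columns) else pd.DataFrame(columns=order)
            if df.empty and not len(df.columns):
                df = pd.DataFrame(columns=order)
        if mode == "paper_compat":
            for col in df.columns:
                if pd.api.types.is_float_dtype(df[col]):
                    df[col] = df[col].round(2)
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, encoding="utf-8", na_rep="NA")
        written[name] = path
    return written


def stratify(dataset: Dataset, key: StratumKey) -> list[SpeciesObservation]:
    """Observations whose quadrat matches ``key``.

    ``key.position == "all"`` matches every canopy position. An empty
    selection is legal (a position with no quadrats that year); a
    restoration age absent from the dataset entirely is an error.
    """
    if key.restoration_years not in dataset.years():
        raise NotFoundError(
            f"restoration_years={key.restoration_years} not present; "
            f"dataset has {dataset.years()}")
    qindex = dataset.quadrat_index
    return [obs for obs in dataset.observations
            if key.matches(qindex[obs.quadrat_id])]
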