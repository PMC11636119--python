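"""End-to-end analysis: dataset -> importance, diversity, stability, soil
tables, one row (or block) per stratum."""

from __future__ import annotations

import logging
import math

import pandas as pd

from .diversity import diversity_profile, importance_values
from .errors import FitError, NoIntersectionError
from .godron import GodronStability
from .io import Dataset, stratify
from .soil import soil_summary_table

logger = logging.getLogger(__name__)

__all__ = ["analyze"]


def analyze(dataset: Dataset, weight_mode: str = "importance_value",
            degree: int = 2, paper_compat: bool = False
            ) -> dict[str, pd.DataFrame]:
    """Run every analysis stage over all strata of a dataset.

    Returns the four result tables keyed ``importance``, ``diversity``,
    ``stability`` and (when soil samples are present) ``soil_summary``,
    ready for :func:`sandstab.io.write_results`. Strata too small to fit
    a curve are skipped from the stability table with a logged note.
    """
    imp_rows, div_rows, stab_rows = [], [], []
    for key in dataset.strata():
        obs = stratify(dataset, key)
        if not obs:
            continue
        label = {"restoration_years": key.restoration_years,
                 "position": key.position.value}
        for rec in importance_values(obs):
            imp_rows.append({**label, "species": rec.species,
                             "relative_height": rec.relative_height,
                             "relative_coverage": rec.relative_coverage,
                             "relative_density": rec.relative_density,
                             "Iv": rec.Iv})
        prof = diversity_profile(obs, weight_mode=weight_mode)
        div_rows.append({**label, "S": prof.S, "N": prof.N, "R": prof.R,
                         "D": prof.D, "H": prof.H,
                         "E": prof.E if not math.isnan(prof.E) else None,
                         "weight_mode": prof.weight_mode})
        try:
            res = GodronStability.from_observations(
                obs, degree=degree).fit(paper_compat=paper_compat)
        except (FitError, NoIntersectionError) as err:
            logger.warning("stability skipped for %s: %s", label, err)
            continue
        c0, c1, c2 = res.fitted_curve.coefficients
        stab_rows.append({**label, "degree": res.fitted_curve.degree,
                          "c0": c0, "c1": c1, "c2": c2,
                          "r_squared": res.rsquared,
                          "x_star": res.intersection[0],
                          "y_star": res.intersection[1],
                          "distance": res.distance,
                          "threshold": res.assessment.threshold,
                          "stable": res.stable})
    tables = {
        "importance": pd.DataFrame(imp_rows),
        "diversity": pd.DataFrame(div_rows),
        "stability": pd.DataFrame(stab_rows),
    }
    if dataset.soil:
        tables["soil_summary"] = soil_summary_table(dataset.soil)
    return tables
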