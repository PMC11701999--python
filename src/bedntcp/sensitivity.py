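"""Sensitivity analysis over alpha/beta assumptions and dose parameters.

For each (alpha/beta, dose metric) cell the full modeling procedure is
rerun — metric extraction on the BED axis, AIC backward elimination, and
(optionally) bootstrap shrinkage — and the cell records whether the
fractionation-schedule indicator (HYPOTREAT) survived elimination.  Survival
means the metric did not describe the dose-response independently of
schedule, disqualifying it under that alpha/beta assumption.

Volume-threshold metrics are specified in *physical* dose (e.g. V70, V75 of
the conventional 39-fraction schedule) and converted to a BED threshold per
alpha/beta cell, so V75 becomes V147.1 at alpha/beta = 2 Gy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .dosimetry import (
    CF_SCHEME,
    DoseMetricSpec,
    FractionationScheme,
    RadiobiologyParams,
    physical_to_bed,
)
from .ntcp import (
    CLINICAL_CANDIDATES,
    DegenerateModelError,
    FittedNTCPModel,
    ModelSpec,
    develop_model,
    extract_features,
    hypotreat_retained,
)

__all__ = [
    "GridCell",
    "SensitivityGrid",
    "default_metric_axis",
    "resolve_metric_spec",
    "run_grid",
]

#: Default dose-parameter axis: hottest-volume doses, EUD volume exponents,
#: and physical V-thresholds of the conventional schedule (converted to a
#: BED threshold per alpha/beta cell).
DEFAULT_METRIC_AXIS: tuple[tuple[str, float], ...] = (
    ("D_xcm3", 0.1),
    ("D_xcm3", 2.0),
    ("EUD", 0.05),
    ("EUD", 0.10),
    ("EUD", 0.15),
    ("EUD", 0.20),
    ("V_physical", 70.0),
    ("V_physical", 75.0),
)


def default_metric_axis() -> tuple[tuple[str, float], ...]:
    return DEFAULT_METRIC_AXIS


def resolve_metric_spec(
    kind: str,
    parameter: float,
    alpha_beta: float,
    reference_scheme: FractionationScheme = CF_SCHEME,
) -> DoseMetricSpec:
    """Turn a metric-axis entry into a concrete BED-axis metric.

    ``V_physical`` thresholds are physical doses under the reference
    (conventional) schedule and are converted with the cell's alpha/beta;
    all other kinds pass through unchanged.
    """
    if kind == "V_physical":
        threshold = physical_to_bed(parameter, reference_scheme, RadiobiologyParams(alpha_beta))
        return DoseMetricSpec("V_D", round(threshold, 1))
    return DoseMetricSpec(kind, parameter)


@dataclass
class GridCell:
    alpha_beta: float
    metric: DoseMetricSpec
    hypotreat_retained: Optional[bool] = None
    model: Optional[FittedNTCPModel] = None
    error: Optional[str] = None


@dataclass
class SensitivityGrid:
    cells: list[GridCell]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            odds = c.model.odds_ratios() if c.model is not None else {}
            rows.append(
                {
                    "alpha_beta": c.alpha_beta,
                    "metric": c.metric.label,
                    "hypotreat_retained": c.hypotreat_retained,
                    "retained": "+".join(c.model.retained) if c.model else None,
                    "or_dose": odds.get(c.metric.label),
                    "shrinkage": c.model.shrinkage_factor if c.model else None,
                    "error": c.error,
                }
            )
        return pd.DataFrame(rows)


def _cell_rng(seed: int, alpha_beta: float, metric: DoseMetricSpec) -> np.random.Generator:
    # keyed on (seed, cell spec) so each cell is reproducible in isolation
    # and the grid is permutation-invariant in cell order
    kind_code = ("EUD", "V_D", "D_xcm3").index(metric.kind)
    return np.random.default_rng(
        [int(seed), int(round(alpha_beta * 1000)), kind_code, int(round(metric.parameter * 1000))]
    )


def run_grid(
    cohort: Cohort,
    seed: int,
    alpha_beta_values: Sequence[float] = (2.0, 3.0),
    metric_axis: Optional[Sequence[tuple[str, float]]] = None,
    clinical_candidates: tuple[str, ...] = CLINICAL_CANDIDATES,
    shrinkage_bootstraps: int = 0,
    reference_scheme: FractionationScheme = CF_SCHEME,
) -> SensitivityGrid:
    """Run the modeling procedure on every (alpha/beta, metric) cell.

    ``shrinkage_bootstraps=0`` (default) records the model before shrinkage,
    which is all the HYPOTREAT-retention criterion needs (shrinkage rescales
    coefficients but never changes the retained set); pass a positive count
    to record shrunk models as well.  Cell-level fit failures are recorded
    in the cell and the grid continues.
    """
    metric_axis = DEFAULT_METRIC_AXIS if metric_axis is None else tuple(metric_axis)
    cells: list[GridCell] = []
    for ab in alpha_beta_values:
        for kind, parameter in metric_axis:
            metric = resolve_metric_spec(kind, parameter, ab, reference_scheme)
            cell = GridCell(alpha_beta=float(ab), metric=metric)
            spec = ModelSpec(metric, clinical_candidates, alpha_beta=float(ab), label=metric.label)
            try:
                X, y = extract_features(cohort, spec)
                model = develop_model(
                    X, y, spec,
                    rng=_cell_rng(seed, float(ab), metric),
                    shrinkage_bootstraps=shrinkage_bootstraps,
                )
                cell.model = model
                cell.hypotreat_retained = hypotreat_retained(model)
            except (DegenerateModelError, ValueError) as exc:
                cell.error = str(exc)
            cells.append(cell)
    return SensitivityGrid(cells=cells, seed=int(seed))
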