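"""Logistic NTCP model development.

A model predicts the probability of grade >=2 late rectal bleeding from one
BED-based dose metric plus clinical candidates (prior abdominal surgery
ABD_SURG; hypofractionation-arm indicator HYPOTREAT) through a binary
logistic regression:

    logit p = b0 + b_dose * metric + b_abd * ABD_SURG + b_hf * HYPOTREAT

Development follows internal-validation best practice: maximum-likelihood
fit, AIC backward elimination, a bootstrap-based uniform shrinkage factor on
the slopes, and intercept re-estimation with the shrunk linear predictor as
a fixed offset.  If HYPOTREAT survives elimination the dose metric failed to
describe the dose-response independently of fractionation schedule, which
disqualifies that metric.

The shrinkage factor is estimated by replaying the full modeling procedure
(selection + fit) on bootstrap resamples and averaging the calibration slope
of each bootstrap model evaluated on the original data; degenerate resamples
(single outcome class, non-convergence, intercept-only models) are excluded
and counted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort import Cohort, score_g2_lrb
from .dosimetry import DoseMetricSpec, RadiobiologyParams, compute_metric

__all__ = [
    "CLINICAL_CANDIDATES",
    "ModelSpec",
    "standard_model_specs",
    "LogisticFit",
    "FittedNTCPModel",
    "DegenerateModelError",
    "extract_features",
    "fit_logistic",
    "backward_eliminate",
    "hypotreat_retained",
    "estimate_shrinkage",
    "apply_shrinkage",
    "develop_model",
    "predict_ntcp",
    "serialize_model",
    "deserialize_model",
    "save_model",
    "load_model",
]

CLINICAL_CANDIDATES = ("ABD_SURG", "HYPOTREAT")

#: Coefficients this large on the standardized scale flag (quasi-)separation.
_SEPARATION_BOUND = 20.0

MODEL_SCHEMA_VERSION = "1"


class DegenerateModelError(RuntimeError):
    """Raised when a modeling run yields no usable model (separation,
    single-class outcome, or an intercept-only model where slopes are needed)."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: exactly one dose metric plus clinical candidates."""

    dose_metric: DoseMetricSpec
    clinical_candidates: tuple[str, ...] = CLINICAL_CANDIDATES
    alpha_beta: float = 3.0
    label: str = ""

    def __post_init__(self) -> None:
        bad = set(self.clinical_candidates) - set(CLINICAL_CANDIDATES)
        if bad:
            raise ValueError(f"unknown clinical candidates: {sorted(bad)}")
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be > 0")

    @property
    def candidate_order(self) -> tuple[str, ...]:
        """Dose metric first, then clinical candidates (elimination tie-break order)."""
        return (self.dose_metric.label,) + tuple(self.clinical_candidates)


def standard_model_specs(alpha_beta: float = 3.0) -> dict[str, ModelSpec]:
    """The five candidate models A-E (one dose parameter each).

    V-threshold 111.9 Gy is the BED of 70 Gy physical in 39 x 2 Gy at
    alpha/beta = 3; under another alpha/beta the caller should recompute the
    threshold (see the sensitivity module).
    """
    metrics = {
        "A": DoseMetricSpec("V_D", 111.9),
        "B": DoseMetricSpec("EUD", 0.1),
        "C": DoseMetricSpec("EUD", 0.2),
        "D": DoseMetricSpec("D_xcm3", 0.1),
        "E": DoseMetricSpec("D_xcm3", 2.0),
    }
    return {
        lab: ModelSpec(m, CLINICAL_CANDIDATES, alpha_beta=alpha_beta, label=lab)
        for lab, m in metrics.items()
    }


def extract_features(
    cohort: Cohort, spec: ModelSpec, horizon_months: int = 60
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (dose metric + clinical candidates) and scored outcomes."""
    rb = RadiobiologyParams(spec.alpha_beta)
    rows, y = [], []
    for p in cohort:
        if p.dvh is None:
            raise ValueError(f"patient {p.patient_id} has no DVH; run eligibility_filter first")
        row = {spec.dose_metric.label: compute_metric(p.dvh, spec.dose_metric, p.scheme, rb)}
        if "ABD_SURG" in spec.clinical_candidates:
            row["ABD_SURG"] = float(p.abd_surg)
        if "HYPOTREAT" in spec.clinical_candidates:
            row["HYPOTREAT"] = float(p.hypotreat)
        rows.append(row)
        y.append(float(score_g2_lrb(p, horizon_months)))
    index = [p.patient_id for p in cohort]
    return pd.DataFrame(rows, index=index), pd.Series(y, index=index, name="g2_lrb")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit; params indexed 'const' + columns."""

    params: pd.Series
    loglik: float
    aic: float
    converged: bool
    n_obs: int

    @property
    def k(self) -> int:
        return len(self.params)


def fit_logistic(X: pd.DataFrame, y) -> LogisticFit:
    """ML logistic regression of y on X plus intercept (Newton/IRLS).

    Non-convergence and (quasi-)separation are reported through the
    ``converged`` flag rather than an exception, so bootstrap loops can
    count degenerate resamples; a single-class outcome raises.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcomes contain a single class; logistic fit undefined")
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValueError(f"column {col!r} is constant; drop it before fitting")
    Xc = sm.add_constant(X, has_constant="add")
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100, tol=1e-10, warn_convergence=False)
        converged = bool(res.mle_retvals.get("converged", False))
        params = res.params
        loglik = float(res.llf)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticFit(
            params=pd.Series(np.nan, index=["const", *X.columns]),
            loglik=-np.inf,
            aic=np.inf,
            converged=False,
            n_obs=len(y),
        )
    # separation check on the standardized scale
    scale = X.std(ddof=0).replace(0.0, 1.0)
    if np.any(np.abs(params[X.columns] * scale) > _SEPARATION_BOUND):
        converged = False
    aic = 2 * len(params) - 2 * loglik
    return LogisticFit(params=params, loglik=loglik, aic=aic, converged=converged, n_obs=len(y))


@dataclass
class FittedNTCPModel:
    """A (possibly shrunk) logistic NTCP model.

    ``coefficients`` maps 'intercept' and each retained predictor to its
    log-odds coefficient (per Gy BED for dose metrics on the Gy scale, per
    percentage point for V_D, per unit for binary covariates).
    """

    spec: ModelSpec
    retained: tuple[str, ...]
    coefficients: dict[str, float]
    loglik: float
    aic: float
    converged: bool
    shrinkage_factor: Optional[float] = None
    elimination_trace: list = field(default_factory=list)

    @property
    def intercept_only(self) -> bool:
        return len(self.retained) == 0

    def odds_ratios(self) -> dict[str, float]:
        return {k: float(np.exp(v)) for k, v in self.coefficients.items() if k != "intercept"}

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.coefficients["intercept"], dtype=float)
        for name in self.retained:
            if name not in X.columns:
                raise KeyError(f"feature {name!r} required by the model is missing")
            eta += self.coefficients[name] * X[name].to_numpy(dtype=float)
        return eta

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(X))


def _model_from_fit(spec: ModelSpec, retained: Sequence[str], fit: LogisticFit, trace) -> FittedNTCPModel:
    coeffs = {"intercept": float(fit.params["const"])}
    for name in retained:
        coeffs[name] = float(fit.params[name])
    return FittedNTCPModel(
        spec=spec,
        retained=tuple(retained),
        coefficients=coeffs,
        loglik=fit.loglik,
        aic=fit.aic,
        converged=fit.converged,
        elimination_trace=list(trace),
    )


def backward_eliminate(X: pd.DataFrame, y, spec: ModelSpec) -> FittedNTCPModel:
    """AIC backward elimination starting from the full candidate set.

    At each step the predictor whose removal lowers AIC the most is dropped;
    elimination stops when no removal lowers AIC.  The intercept is never
    removed.  Ties remove the predictor listed later in the candidate order
    (dose metric first), so the dose metric is maximally protected.
    Non-converged fits score AIC = +inf, steering elimination away from
    separated submodels; if every model is non-converged a
    :class:`DegenerateModelError` is raised.
    """
    order = [c for c in spec.candidate_order if c in X.columns]
    if set(X.columns) - set(order):
        raise ValueError(f"design matrix has columns outside the spec: {set(X.columns) - set(order)}")

    def _aic(cols: list[str]) -> tuple[float, LogisticFit]:
        if cols:
            f = fit_logistic(X[cols], y)
        else:
            f = _intercept_only_fit(y)
        return (f.aic if f.converged else np.inf), f

    current = list(order)
    current_aic, current_fit = _aic(current)
    trace = [(tuple(current), current_aic)]
    while current:
        best_col, best_aic, best_fit = None, np.inf, None
        for col in current:  # later-listed candidates win ties via <=
            reduced = [c for c in current if c != col]
            a, f = _aic(reduced)
            if a <= best_aic:
                best_col, best_aic, best_fit = col, a, f
        if best_aic < current_aic:
            current = [c for c in current if c != best_col]
            current_aic, current_fit = best_aic, best_fit
            trace.append((tuple(current), current_aic))
        else:
            break
    if not np.isfinite(current_aic):
        raise DegenerateModelError("no converged model found during backward elimination")
    return _model_from_fit(spec, current, current_fit, trace)


def _intercept_only_fit(y) -> LogisticFit:
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcomes contain a single class")
    p = y.mean()
    n = len(y)
    ll = n * (p * np.log(p) + (1 - p) * np.log(1 - p))
    return LogisticFit(
        params=pd.Series({"const": float(np.log(p / (1 - p)))}),
        loglik=float(ll),
        aic=float(2 - 2 * ll),
        converged=True,
        n_obs=n,
    )


def fit_full_model(X: pd.DataFrame, y, spec: ModelSpec) -> FittedNTCPModel:
    """ML fit of the full candidate set without any selection.

    Useful as the overfitting-prone reference procedure in validation
    experiments; raises :class:`DegenerateModelError` on non-convergence.
    """
    order = [c for c in spec.candidate_order if c in X.columns]
    fit = fit_logistic(X[order], y)
    if not fit.converged:
        raise DegenerateModelError("full-model fit did not converge")
    return _model_from_fit(spec, order, fit, [(tuple(order), fit.aic)])


def hypotreat_retained(model: FittedNTCPModel) -> bool:
    """True iff the fractionation-schedule indicator survived elimination.

    Retention means the dose metric (with ABD_SURG) failed to describe the
    dose-response independently of fractionation schedule; such a model is
    disqualified in the sensitivity analysis.
    """
    return "HYPOTREAT" in model.retained


@dataclass
class ShrinkageEstimate:
    factor: float
    slopes: np.ndarray
    n_bootstraps: int
    n_degenerate: int


def estimate_shrinkage(
    X: pd.DataFrame,
    y,
    spec: ModelSpec,
    B: int = 300,
    rng: Optional[np.random.Generator] = None,
    reselect: bool = True,
) -> ShrinkageEstimate:
    """Bootstrap uniform shrinkage factor.

    For each of B resamples (with replacement, same n): rerun the modeling
    procedure (backward elimination by default, plain refit of the original
    retained set when ``reselect=False``), evaluate that model's linear
    predictor on the ORIGINAL data, and fit a logistic calibration of the
    original outcomes on it.  The factor is the mean calibration slope over
    usable bootstraps; resamples with one outcome class, non-converged or
    intercept-only models are excluded and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    y_arr = np.asarray(y, dtype=float)
    n = len(y_arr)
    if not reselect:
        base = backward_eliminate(X, y, spec)
        base_cols = list(base.retained)
    slopes: list[float] = []
    n_degenerate = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        yb = y_arr[idx]
        if yb.min() == yb.max():
            n_degenerate += 1
            continue
        Xb = X.iloc[idx]
        try:
            if reselect:
                model_b = backward_eliminate(Xb.reset_index(drop=True), yb, spec)
            else:
                fb = fit_logistic(Xb[base_cols].reset_index(drop=True), yb)
                if not fb.converged:
                    raise DegenerateModelError("bootstrap refit did not converge")
                model_b = _model_from_fit(spec, base_cols, fb, [])
        except (DegenerateModelError, ValueError):
            n_degenerate += 1
            continue
        if model_b.intercept_only or not model_b.converged:
            n_degenerate += 1
            continue
        lp = model_b.linear_predictor(X)
        if np.ptp(lp) < 1e-12:
            n_degenerate += 1
            continue
        cal = fit_logistic(pd.DataFrame({"lp": lp}, index=X.index), y_arr)
        if not cal.converged:
            n_degenerate += 1
            continue
        slopes.append(float(cal.params["lp"]))
    if not slopes:
        raise DegenerateModelError("all shrinkage bootstraps were degenerate")
    slopes_arr = np.asarray(slopes)
    return ShrinkageEstimate(
        factor=float(slopes_arr.mean()),
        slopes=slopes_arr,
        n_bootstraps=B,
        n_degenerate=n_degenerate,
    )


def apply_shrinkage(
    model: FittedNTCPModel, s: float, X: pd.DataFrame, y
) -> FittedNTCPModel:
    """Multiply slope coefficients by s and re-estimate the intercept.

    The intercept is re-fit by maximum likelihood with the shrunk linear
    predictor held as a fixed offset, so mean predicted probability equals
    observed prevalence (the intercept score equation).  On the odds-ratio
    scale the shrunk coefficients satisfy OR_final = OR^s.
    """
    if s <= 0:
        raise ValueError(f"shrinkage factor must be > 0, got {s}")
    if model.intercept_only:
        raise DegenerateModelError("cannot shrink an intercept-only model")
    y_arr = np.asarray(y, dtype=float)
    offset = np.zeros(len(X))
    new_coeffs = {}
    for name in model.retained:
        new_coeffs[name] = s * model.coefficients[name]
        offset += new_coeffs[name] * X[name].to_numpy(dtype=float)
    glm = sm.GLM(y_arr, np.ones((len(X), 1)), family=sm.families.Binomial(), offset=offset)
    res = glm.fit(tol=1e-10)
    new_coeffs["intercept"] = float(res.params[0])
    eta = new_coeffs["intercept"] + offset
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y_arr * np.log(p) + (1 - y_arr) * np.log(1 - p)))
    k = len(model.retained) + 1
    return replace(
        model,
        coefficients=new_coeffs,
        shrinkage_factor=float(s),
        loglik=ll,
        aic=2 * k - 2 * ll,
    )


def develop_model(
    X: pd.DataFrame,
    y,
    spec: ModelSpec,
    rng: Optional[np.random.Generator] = None,
    shrinkage_bootstraps: int = 300,
    reselect_in_bootstrap: bool = True,
    allow_intercept_only: bool = True,
) -> FittedNTCPModel:
    """The full modeling procedure: elimination + shrinkage + intercept refit.

    ``shrinkage_bootstraps=0`` skips shrinkage (the model before shrinkage is
    returned).  Intercept-only outcomes either pass through (flagged by
    ``intercept_only``) or raise, controlled by ``allow_intercept_only`` —
    optimism bootstraps treat them as degenerate.
    """
    model = backward_eliminate(X, y, spec)
    if model.intercept_only:
        if allow_intercept_only:
            return model
        raise DegenerateModelError("backward elimination removed every predictor")
    if shrinkage_bootstraps > 0:
        est = estimate_shrinkage(
            X, y, spec, B=shrinkage_bootstraps, rng=rng, reselect=reselect_in_bootstrap
        )
        model = apply_shrinkage(model, est.factor, X, y)
    return model


def predict_ntcp(
    model: FittedNTCPModel, dose_metric_value: float, covariates: Optional[dict] = None
) -> float:
    """NTCP for one patient: p = 1 / (1 + exp(-eta)).

    ``covariates`` must cover every retained clinical predictor
    (e.g. ``{"ABD_SURG": 1, "HYPOTREAT": 0}``); extras are ignored.
    """
    covariates = covariates or {}
    row = {model.spec.dose_metric.label: float(dose_metric_value)}
    for name in model.retained:
        if name == model.spec.dose_metric.label:
            continue
        if name not in covariates:
            raise KeyError(f"missing covariate {name!r} required by the model")
        row[name] = float(covariates[name])
    return float(model.predict(pd.DataFrame([row]))[0])


# ---------------------------------------------------------------------------
# JSON (de)serialization

def serialize_model(model: FittedNTCPModel) -> dict:
    return {
        "schema_version": MODEL_SCHEMA_VERSION,
        "spec": {
            "dose_metric": {"kind": model.spec.dose_metric.kind, "parameter": model.spec.dose_metric.parameter},
            "clinical_candidates": list(model.spec.clinical_candidates),
            "alpha_beta": model.spec.alpha_beta,
            "label": model.spec.label,
        },
        "retained": list(model.retained),
        "coefficients": dict(model.coefficients),
        "loglik": model.loglik,
        "aic": model.aic,
        "converged": model.converged,
        "shrinkage_factor": model.shrinkage_factor,
    }


def deserialize_model(doc: dict) -> FittedNTCPModel:
    def _require(d: dict, key: str, path: str):
        if key not in d:
            raise ValueError(f"model document missing field {path}.{key}")
        return d[key]

    if _require(doc, "schema_version", "$") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {doc['schema_version']!r}")
    spec_doc = _require(doc, "spec", "$")
    dm = _require(spec_doc, "dose_metric", "$.spec")
    spec = ModelSpec(
        dose_metric=DoseMetricSpec(_require(dm, "kind", "$.spec.dose_metric"), _require(dm, "parameter", "$.spec.dose_metric")),
        clinical_candidates=tuple(_require(spec_doc, "clinical_candidates", "$.spec")),
        alpha_beta=_require(spec_doc, "alpha_beta", "$.spec"),
        label=spec_doc.get("label", ""),
    )
    coefficients = dict(_require(doc, "coefficients", "$"))
    retained = tuple(_require(doc, "retained", "$"))
    if "intercept" not in coefficients:
        raise ValueError("model document missing field $.coefficients.intercept")
    for name in retained:
        if name not in coefficients:
            raise ValueError(f"model document missing field $.coefficients.{name}")
    return FittedNTCPModel(
        spec=spec,
        retained=retained,
        coefficients=coefficients,
        loglik=_require(doc, "loglik", "$"),
        aic=_require(doc, "aic", "$"),
        converged=_require(doc, "converged", "$"),
        shrinkage_factor=doc.get("shrinkage_factor"),
    )


def save_model(model: FittedNTCPModel, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(serialize_model(model), indent=1, sort_keys=True))


def load_model(path: Union[str, Path]) -> FittedNTCPModel:
    return deserialize_model(json.loads(Path(path).read_text()))
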