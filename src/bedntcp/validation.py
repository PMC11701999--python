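"""Model performance: discrimination, calibration, and optimism correction.

Measures
--------
* AUC — Mann–Whitney formulation (ties count one half), equal to the
  trapezoidal area under the ROC curve.
* Brier score — mean squared distance between predicted probability and the
  0/1 outcome.
* Calibration slope / intercept — logistic recalibration of outcomes on the
  logit of the predictions; slope from a free fit, intercept from a fit with
  the prediction logit as fixed offset (calibration-in-the-large).  A
  maximum-likelihood model evaluated on its own training data has slope 1
  and intercept 0 by the score equations.
* ICI — integrated calibration index: the mean absolute gap between a
  loess-smoothed calibration curve and the identity line, evaluated at each
  patient's predicted probability.  Lower is better-calibrated.

Internal validation uses Harrell's optimism bootstrap: the full modeling
procedure is replayed on each resample, its performance measured on the
resample (apparent) and on the original data (test); the mean of
apparent − test is the optimism, subtracted from the apparent performance of
the original model.  Resamples yielding intercept-only or non-converged
models are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .ntcp import DegenerateModelError, FittedNTCPModel, fit_logistic

__all__ = [
    "auc",
    "brier",
    "calibration_slope_intercept",
    "loess_calibration_curve",
    "ici",
    "MeasurePerformance",
    "PerformanceReport",
    "optimism_correct",
    "quintile_calibration",
    "plot_calibration",
]

MEASURES = ("AUC", "ICI", "calibration_intercept", "calibration_slope", "Brier")

_CLIP = 1e-12


def auc(predictions, outcomes) -> float:
    """Area under the ROC curve via the Mann–Whitney U statistic."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = rankdata(p)  # average ranks: ties count 1/2
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def brier(predictions, outcomes) -> float:
    """Mean squared difference between prediction and 0/1 outcome."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("predictions must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def calibration_slope_intercept(predictions, outcomes) -> tuple[float, float]:
    """(slope, intercept) of the logistic recalibration of outcomes.

    slope: coefficient of logit(p) in a free logistic fit;
    intercept: intercept of a logistic fit with logit(p) as fixed offset.
    Predictions are clipped away from {0, 1} before the logit.
    """
    import statsmodels.api as sm

    p = np.clip(np.asarray(predictions, dtype=float), _CLIP, 1 - _CLIP)
    y = np.asarray(outcomes, dtype=float)
    lp = logit(p)
    if np.ptp(lp) < 1e-12:
        raise ValueError("zero-variance prediction logits; calibration slope undefined")
    free = fit_logistic(pd.DataFrame({"lp": lp}), y)
    slope = float(free.params["lp"])
    offset_fit = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp).fit(
        tol=1e-10
    )
    intercept = float(offset_fit.params[0])
    return slope, intercept


def loess_calibration_curve(predictions, outcomes, span: float = 0.75) -> np.ndarray:
    """Loess smooth of the 0/1 outcomes on the predictions.

    Local-linear (degree 1) regression with tricube weights over the nearest
    ``span`` fraction of neighbors; returns the smoothed observed proportion
    at each patient's predicted value, clipped to [0, 1].
    """
    if not (0 < span <= 1):
        raise ValueError(f"span must lie in (0, 1], got {span}")
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(p) < 10:
        raise ValueError("loess calibration requires at least 10 observations")
    if np.ptp(p) < 1e-12:
        # constant predictions: the local smooth degenerates to the global mean
        return np.full_like(p, np.clip(y.mean(), 0.0, 1.0))
    smoothed = lowess(y, p, frac=span, it=0, return_sorted=False)
    return np.clip(smoothed, 0.0, 1.0)


def ici(predictions, outcomes, span: float = 0.75) -> float:
    """Integrated calibration index: mean |loess curve − prediction|."""
    p = np.asarray(predictions, dtype=float)
    curve = loess_calibration_curve(p, outcomes, span=span)
    return float(np.mean(np.abs(curve - p)))


def _compute_measures(predictions, outcomes, measures: Sequence[str], span: float) -> dict[str, float]:
    out: dict[str, float] = {}
    for m in measures:
        if m == "AUC":
            out[m] = auc(predictions, outcomes)
        elif m == "Brier":
            out[m] = brier(predictions, outcomes)
        elif m == "ICI":
            out[m] = ici(predictions, outcomes, span=span)
        elif m in ("calibration_slope", "calibration_intercept"):
            if "calibration_slope" not in out and "calibration_intercept" not in out:
                slope, intercept = calibration_slope_intercept(predictions, outcomes)
                if "calibration_slope" in measures:
                    out["calibration_slope"] = slope
                if "calibration_intercept" in measures:
                    out["calibration_intercept"] = intercept
        else:
            raise ValueError(f"unknown performance measure {m!r}")
    return out


@dataclass
class MeasurePerformance:
    apparent: float
    optimism: Optional[float] = None
    corrected: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass
class PerformanceReport:
    """Apparent and optimism-corrected performance for one model."""

    measures: dict[str, MeasurePerformance]
    n_bootstraps: int
    n_degenerate: int
    span: float
    model: Optional[FittedNTCPModel] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.measures.items():
            rows.append(
                {
                    "measure": name,
                    "apparent": m.apparent,
                    "optimism": m.optimism,
                    "corrected": m.corrected,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                }
            )
        return pd.DataFrame(rows).set_index("measure")

    def to_dict(self) -> dict:
        return {
            "measures": {
                k: {
                    "apparent": v.apparent,
                    "optimism": v.optimism,
                    "corrected": v.corrected,
                    "ci": [v.ci_low, v.ci_high],
                }
                for k, v in self.measures.items()
            },
            "n_bootstraps": self.n_bootstraps,
            "n_degenerate": self.n_degenerate,
            "span": self.span,
        }


def optimism_correct(
    X: pd.DataFrame,
    y,
    modeling_procedure: Callable[[pd.DataFrame, np.ndarray, np.random.Generator], "FittedNTCPModel"],
    B: int = 1000,
    rng: Optional[np.random.Generator] = None,
    measures: Sequence[str] = MEASURES,
    span: float = 0.75,
) -> PerformanceReport:
    """Harrell's optimism bootstrap around an arbitrary modeling procedure.

    ``modeling_procedure(X, y, rng)`` must return an object with a
    ``predict(X) -> probabilities`` method (a :class:`FittedNTCPModel` from
    :func:`bedntcp.ntcp.develop_model`, typically) and raise
    :class:`DegenerateModelError` for unusable fits.  Per resample:
    apparent_b (on the resample) minus test_b (on the original data) is the
    optimism; corrected = apparent − mean optimism, with a percentile 95% CI
    of the per-resample corrected values.  ICI is clipped at 0.  ``B=0``
    reports apparent values only.  More than 50% degenerate resamples is an
    error.
    """
    rng = np.random.default_rng() if rng is None else rng
    y_arr = np.asarray(y, dtype=float)
    n = len(y_arr)

    model = modeling_procedure(X, y_arr, rng)
    apparent = _compute_measures(model.predict(X), y_arr, measures, span)
    report = {m: MeasurePerformance(apparent=v) for m, v in apparent.items()}
    if B == 0:
        return PerformanceReport(report, n_bootstraps=0, n_degenerate=0, span=span, model=model)

    optimisms: dict[str, list[float]] = {m: [] for m in apparent}
    n_degenerate = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        yb = y_arr[idx]
        if yb.min() == yb.max():
            n_degenerate += 1
            continue
        Xb = X.iloc[idx].reset_index(drop=True)
        try:
            model_b = modeling_procedure(Xb, yb, rng)
            if getattr(model_b, "intercept_only", False) or not getattr(model_b, "converged", True):
                raise DegenerateModelError("degenerate bootstrap model")
            app_b = _compute_measures(model_b.predict(Xb), yb, measures, span)
            test_b = _compute_measures(model_b.predict(X), y_arr, measures, span)
        except (DegenerateModelError, ValueError):
            n_degenerate += 1
            continue
        for m in optimisms:
            optimisms[m].append(app_b[m] - test_b[m])

    if n_degenerate > B / 2:
        raise DegenerateModelError(
            f"{n_degenerate}/{B} optimism bootstraps degenerate; data too sparse to validate"
        )
    for m, perf in report.items():
        opt = np.asarray(optimisms[m])
        perf.optimism = float(opt.mean())
        corrected_draws = perf.apparent - opt
        if m == "ICI":
            corrected_draws = np.clip(corrected_draws, 0.0, None)
        perf.corrected = float(perf.apparent - perf.optimism)
        if m == "ICI":
            perf.corrected = max(perf.corrected, 0.0)
        perf.ci_low = float(np.percentile(corrected_draws, 2.5))
        perf.ci_high = float(np.percentile(corrected_draws, 97.5))
    return PerformanceReport(
        report, n_bootstraps=B, n_degenerate=n_degenerate, span=span, model=model
    )


def quintile_calibration(predictions, outcomes) -> pd.DataFrame:
    """Mean predicted vs observed proportion per quintile of predictions."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    q = pd.qcut(p, 5, labels=False, duplicates="drop")
    rows = []
    for g in np.unique(q):
        mask = q == g
        rows.append(
            {
                "quintile": int(g) + 1,
                "mean_predicted": float(p[mask].mean()),
                "observed_rate": float(y[mask].mean()),
                "sd_observed": float(y[mask].std(ddof=0)),
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def plot_calibration(predictions, outcomes, span: float = 0.75, path=None):
    """Calibration plot: quintile points with SD bars plus the loess curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    qdf = quintile_calibration(p, y)
    ax.errorbar(
        qdf["mean_predicted"], qdf["observed_rate"], yerr=qdf["sd_observed"],
        fmt="o", capsize=3, label="quintiles (±SD)",
    )
    order = np.argsort(p)
    curve = loess_calibration_curve(p, y, span=span)
    ax.plot(p[order], curve[order], "-", label=f"loess (span={span:g})")
    lim = max(p.max(), qdf["observed_rate"].max()) * 1.1
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="perfect calibration")
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed proportion")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
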