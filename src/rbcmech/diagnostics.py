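"""Biomarker classification performance: logistic models, stepwise selection
under a sample-size-penalised information criterion, and ROC/AUC with DeLong
confidence intervals.

The selection criterion is ``IC = -2 log L + penalty * p`` with ``p`` the
number of coefficients (intercept included) and ``penalty`` defaulting to
``ln(n)`` — a strong, sample-size-dependent per-parameter penalty suited to
small cohorts.  Backward elimination removes, at each step, the feature whose
removal most decreases the criterion, stopping when no removal helps.

AUC is computed by the Mann–Whitney pair-counting identity (ties count 1/2),
which equals the trapezoidal area under the empirical ROC curve; its variance
comes from DeLong's structural components, and the confidence interval is
formed on the logit scale and truncated to [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import ValidationError

__all__ = [
    "LogisticModel",
    "StepwiseTrace",
    "RocResult",
    "fit_logistic",
    "stepwise_backward",
    "auc_pair_counting",
    "roc_curve",
    "auc_confidence_interval",
]

#: Cap applied to standardized coefficients when separation is detected.
_SEPARATION_CAP = 25.0


@dataclass
class LogisticModel:
    """Maximum-likelihood logistic fit on standardized features."""

    features: list[str]
    coefficients: np.ndarray   # intercept first, then one per feature
    log_likelihood: float      # nats
    n: int
    converged: bool
    separation: bool = False
    scaler: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd)

    def information_criterion(self, penalty_per_param: float) -> float:
        return -2.0 * self.log_likelihood + penalty_per_param * self.coefficients.size

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            X = (X - self.scaler[0]) / self.scaler[1]
        eta = self.coefficients[0] + X @ self.coefficients[1:]
        return 1.0 / (1.0 + np.exp(-eta))


def _binary_labels(table: pd.DataFrame, label_col: str, positive: str) -> np.ndarray:
    labels = table[label_col].to_numpy()
    return (labels == positive).astype(float)


def fit_logistic(
    table: pd.DataFrame,
    features: Sequence[str],
    label_col: str = "group",
    positive: str = "AD",
) -> LogisticModel:
    """Fit a logistic regression of group membership on ``features``.

    Features are standardized (zero mean, unit SD) before the fit so the
    criterion and coefficient magnitudes are comparable across biomarkers
    with different units.  Perfect separation is detected (all fitted
    probabilities within 1e-6 of the labels) and reported via the
    ``separation`` flag with coefficients capped rather than diverging.
    """
    features = list(features)
    cols = features + [label_col]
    data = table[cols].dropna()
    y = _binary_labels(data, label_col, positive)
    n = len(data)
    if n < len(features) + 2:
        raise ValidationError(
            f"{n} complete cases cannot support {len(features)} features"
        )
    if features:
        X = data[features].to_numpy(dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xs = (X - mean) / sd
        design = sm.add_constant(Xs, has_constant="add")
        scaler = (mean, sd)
    else:
        design = np.ones((n, 1))
        scaler = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            params = np.asarray(res.params, dtype=float)
            llf = float(res.llf)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            # Fall back to a capped ridge-stabilised fit (separation etc.)
            params, llf, converged = _capped_irls(design, y)
    prob = 1.0 / (1.0 + np.exp(-(design @ params)))
    separation = bool(np.all(np.abs(prob - y) < 1e-6)) and len(features) > 0
    if separation or np.any(np.abs(params) > _SEPARATION_CAP):
        params = np.clip(params, -_SEPARATION_CAP, _SEPARATION_CAP)
        prob = 1.0 / (1.0 + np.exp(-(design @ params)))
        eps = 1e-12
        llf = float(np.sum(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))
        separation = True
        warnings.warn(
            f"perfect separation detected for features {features}; "
            f"coefficients capped at ±{_SEPARATION_CAP}",
            stacklevel=2,
        )
    return LogisticModel(
        features=features,
        coefficients=params,
        log_likelihood=llf,
        n=n,
        converged=converged,
        separation=separation,
        scaler=scaler,
    )


def _capped_irls(design: np.ndarray, y: np.ndarray, n_iter: int = 50):
    """Ridge-stabilised IRLS used when the unpenalised fit diverges."""
    beta = np.zeros(design.shape[1])
    for _ in range(n_iter):
        eta = np.clip(design @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = design * w[:, None]
        H = design.T @ WX + 1e-8 * np.eye(design.shape[1])
        beta = np.linalg.solve(H, WX.T @ z)
        beta = np.clip(beta, -_SEPARATION_CAP, _SEPARATION_CAP)
    eta = np.clip(design @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    llf = float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))
    return beta, llf, False


@dataclass
class StepwiseTrace:
    """Record of a backward stepwise elimination run."""

    steps: list[dict] = field(default_factory=list)  # {features, ic, action}
    selected: list[str] = field(default_factory=list)
    penalty_per_param: float = float("nan")

    @property
    def removal_order(self) -> list[str]:
        return [s["action"].split(":", 1)[1] for s in self.steps
                if s["action"].startswith("removed:")]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"action": s["action"], "ic": s["ic"],
              "features": "+".join(s["features"])} for s in self.steps]
        )


def stepwise_backward(
    table: pd.DataFrame,
    features: Sequence[str],
    penalty_per_param: float | None = None,
    label_col: str = "group",
    positive: str = "AD",
) -> StepwiseTrace:
    """Backward elimination minimising ``-2 log L + penalty * n_coefficients``.

    ``penalty_per_param`` defaults to ``ln(n)`` with ``n`` the number of
    complete cases of the full model.  At every step the feature whose
    removal most decreases the criterion is dropped; the trace records each
    criterion value so the elimination path can be plotted.
    """
    features = list(features)
    full = fit_logistic(table, features, label_col, positive)
    if penalty_per_param is None:
        penalty_per_param = math.log(full.n)
    trace = StepwiseTrace(penalty_per_param=penalty_per_param)
    current = features
    ic = full.information_criterion(penalty_per_param)
    trace.steps.append({"features": list(current), "ic": ic, "action": "start"})
    while current:
        best_ic, best_drop = ic, None
        for feat in current:
            reduced = [f for f in current if f != feat]
            model = fit_logistic(table, reduced, label_col, positive)
            cand = model.information_criterion(penalty_per_param)
            if cand < best_ic - 1e-12:
                best_ic, best_drop = cand, feat
        if best_drop is None:
            break
        current = [f for f in current if f != best_drop]
        ic = best_ic
        trace.steps.append(
            {"features": list(current), "ic": ic, "action": f"removed:{best_drop}"}
        )
    trace.selected = list(current)
    return trace


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    """Empirical ROC curve with pair-counting AUC and DeLong interval."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    flipped: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        })


def auc_pair_counting(cases: np.ndarray, controls: np.ndarray) -> float:
    """AUC as the fraction of correctly ordered case–control pairs (ties 1/2)."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    diff = cases[:, None] - controls[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def _delong_variance(cases: np.ndarray, controls: np.ndarray, auc: float) -> float:
    """DeLong variance of the empirical AUC via structural components."""
    m, n = cases.size, controls.size
    # V10[i]: P(case_i > control) with ties 1/2; V01[j] analogous.
    diff = cases[:, None] - controls[None, :]
    ind = (diff > 0) + 0.5 * (diff == 0)
    v10 = ind.mean(axis=1)
    v01 = ind.mean(axis=0)
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_curve(
    scores: Sequence[float],
    labels: Sequence,
    positive=1,
    level: float = 0.95,
    auto_flip: bool = True,
) -> RocResult:
    """Empirical ROC over all distinct thresholds with pair-counting AUC.

    Scores where lower values indicate disease are auto-flipped (reported via
    ``flipped``) so AUC >= 0.5, matching common ROC tooling; pass
    ``auto_flip=False`` to keep the raw orientation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    cases, controls = scores[pos], scores[~pos]
    if cases.size == 0 or controls.size == 0:
        raise ValidationError("both classes must be present")
    auc_raw = auc_pair_counting(cases, controls)
    flipped = bool(auto_flip and auc_raw < 0.5)
    if flipped:
        scores, cases, controls = -scores, -cases, -controls
    auc = auc_pair_counting(cases, controls)

    thr = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.array([(cases >= t).mean() for t in thr])
    spec = np.array([(controls < t).mean() for t in thr])
    lo, hi = auc_confidence_interval(cases, controls, auc, level)
    return RocResult(
        thresholds=thr, sensitivity=sens, specificity=spec,
        auc=auc, ci_low=lo, ci_high=hi,
        n_cases=cases.size, n_controls=controls.size, flipped=flipped,
    )


def auc_confidence_interval(
    cases: np.ndarray,
    controls: np.ndarray,
    auc: float | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """DeLong confidence interval for the AUC, on the logit scale.

    The logit transform keeps the interval inside (0, 1) and is the standard
    small-sample stabilisation; degenerate AUCs of exactly 0 or 1 have zero
    DeLong variance and return a collapsed interval at the limit.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size < 2 or controls.size < 2:
        raise ValidationError("need >= 2 observations per class for a CI")
    if auc is None:
        auc = auc_pair_counting(cases, controls)
    var = _delong_variance(cases, controls, auc)
    z = sps.norm.ppf(0.5 + level / 2.0)
    if auc <= 0.0 or auc >= 1.0 or var == 0.0:
        # Degenerate: logit limit collapses the interval at the estimate.
        return float(np.clip(auc - z * math.sqrt(var), 0, 1)), float(
            np.clip(auc + z * math.sqrt(var), 0, 1)
        )
    logit = math.log(auc / (1 - auc))
    se_logit = math.sqrt(var) / (auc * (1 - auc))
    lo = 1.0 / (1.0 + math.exp(-(logit - z * se_logit)))
    hi = 1.0 / (1.0 + math.exp(-(logit + z * se_logit)))
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def marker_auc_table(
    table: pd.DataFrame,
    markers: Sequence[str],
    combined: Sequence[str] | None = None,
    label_col: str = "group",
    positive: str = "AD",
) -> pd.DataFrame:
    """AUC (with CI) per marker plus an optional combined logistic model."""
    rows = []
    for m in markers:
        sub = table[[m, label_col]].dropna()
        roc = roc_curve(sub[m].to_numpy(), sub[label_col].to_numpy(), positive)
        rows.append({"marker": m, "auc": roc.auc, "ci_low": roc.ci_low,
                     "ci_high": roc.ci_high, "flipped": roc.flipped})
    if combined:
        model = fit_logistic(table, list(combined), label_col, positive)
        sub = table[list(combined) + [label_col]].dropna()
        prob = model.predict_proba(sub[list(combined)].to_numpy(dtype=float))
        roc = roc_curve(prob, sub[label_col].to_numpy(), positive)
        rows.append({"marker": "+".join(combined), "auc": roc.auc,
                     "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                     "flipped": roc.flipped})
    return pd.DataFrame(rows)
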