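"""Regression harness: seven standard estimators behind one fit/predict
surface, the three accuracy metrics, qualitative grading bands, and a
benchmark grid over feature regimes.

The estimators themselves are the stock scikit-learn / xgboost
implementations — the harness only pins reproducible defaults (no
hyperparameter search is run by default) and reports
R², RMSE and MAE on calibration and validation sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import BayesianRidge, Ridge
from sklearn.svm import SVR
from xgboost import XGBRegressor

MODEL_NAMES = ("PLSR", "BRR", "RR", "KRR", "SVMR", "XGBoost", "RFR")


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------- metrics

def r2(y, yhat) -> float:
    """Coefficient of determination 1 − Σ(ŷ−y)² / Σ(y−ȳ)²."""
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ModelError("r2 undefined for a constant y")
    return 1.0 - float(np.sum((yhat - y) ** 2)) / ss_tot


def rmse(y, yhat) -> float:
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise ModelError("y and yhat must be nonempty and the same length")
    return y, yhat


GRADE_LABELS = (
    "excellent",
    "good",
    "approximate-quantitative",
    "feasible-needs-improvement",
    "not-quantifiable",
)


def grade(r2_value: float) -> str:
    """Qualitative prediction grade from validation R².

    > 0.9 excellent; 0.82–0.9 good (usable for actual detection);
    0.66–0.82 approximate quantitative prediction; 0.5–0.66 feasible but
    needing improvement; < 0.5 not quantifiable. The boundary at exactly
    0.9 grades as good.
    """
    if r2_value > 1:
        raise ModelError("R² cannot exceed 1")
    if r2_value > 0.9:
        return "excellent"
    if r2_value >= 0.82:
        return "good"
    if r2_value >= 0.66:
        return "approximate-quantitative"
    if r2_value >= 0.5:
        return "feasible-needs-improvement"
    return "not-quantifiable"


# ------------------------------------------------------------- estimators

@dataclass(frozen=True)
class ModelSpec:
    """A named regressor plus hyperparameter overrides.

    Unknown hyperparameter keys are rejected against the estimator's
    signature at construction time. ``seed`` feeds the stochastic models
    (XGBoost, RFR); the others are deterministic.
    """

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ModelError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        valid = set(self._build(10, 20, {}).get_params())
        bad = set(self.hyperparameters) - valid
        if bad:
            raise ModelError(f"unknown hyperparameter(s) for {self.name}: {sorted(bad)}")

    def build(self, n_features: int, n_train: int):
        """Construct the underlying estimator with documented defaults."""
        return self._build(n_features, n_train, dict(self.hyperparameters))

    def _build(self, n_features: int, n_train: int, hp: dict):
        if self.name == "PLSR":
            ncomp = hp.pop("n_components", min(10, n_features, n_train - 1))
            return PLSRegression(n_components=ncomp, scale=False, **hp)
        if self.name == "BRR":
            return BayesianRidge(**hp)
        if self.name == "RR":
            return Ridge(**{"alpha": 1.0, **hp})
        if self.name == "KRR":
            return KernelRidge(**{"kernel": "rbf", "alpha": 0.1, **hp})
        if self.name == "SVMR":
            return SVR(**{"kernel": "rbf", "C": 100.0, "epsilon": 0.05,
                          "gamma": "scale", **hp})
        if self.name == "XGBoost":
            return XGBRegressor(**{
                "n_estimators": 300, "max_depth": 3, "learning_rate": 0.1,
                "subsample": 1.0, "n_jobs": 1, "random_state": self.seed,
                "verbosity": 0, **hp})
        if self.name == "RFR":
            return RandomForestRegressor(**{
                "n_estimators": 300, "n_jobs": 1, "random_state": self.seed, **hp})
        raise ModelError(self.name)  # unreachable


def fit_predict(spec: ModelSpec, X_cal, y_cal, X_val):
    """Fit a model on the (already standardized) calibration block and
    predict the validation block. Returns (cal_pred, val_pred)."""
    X_cal = np.asarray(X_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    est = spec.build(n_features=X_cal.shape[1], n_train=X_cal.shape[0])
    try:
        est.fit(X_cal, y_cal)
        cal = np.asarray(est.predict(X_cal), dtype=float).ravel()
        val = np.asarray(est.predict(X_val), dtype=float).ravel()
    except Exception as exc:  # surface with the model name attached
        raise ModelError(f"{spec.name} failed to fit/predict: {exc}") from exc
    if not (np.all(np.isfinite(cal)) and np.all(np.isfinite(val))):
        raise ModelError(f"{spec.name} produced non-finite predictions")
    return cal, val


# -------------------------------------------------------------- benchmark

REPORT_COLUMNS = ("regime", "model", "Rc2", "RMSEc", "MAEc",
                  "Rp2", "RMSEp", "MAEp", "grade", "best", "error")


def default_model_specs(seed: int = 0, names=MODEL_NAMES):
    return [ModelSpec(name=n, seed=seed) for n in names]


def benchmark(regimes: dict, y, split, specs=None, seed: int = 0) -> pd.DataFrame:
    """Fill the (regime × model) accuracy grid.

    ``regimes`` maps a regime name (e.g. ``"IRIV"``, ``"IRIV-SCA"``) to an
    (n_samples, k) feature matrix on the full sample set. Each regime is
    standardized on the calibration rows of ``split`` (the same transform is
    applied to validation rows), every model is fit, and calibration /
    validation R², RMSE and MAE are reported. A failing model is recorded in
    its row's ``error`` column, not fatal to the grid. Per regime, the row
    with maximum Rp² (ties → minimum RMSEp) is flagged best.
    """
    from .preprocess import standardize

    if specs is None:
        specs = default_model_specs(seed=seed)
    y = np.asarray(y, dtype=float).ravel()
    cal, val = split.calibration, split.validation
    rows = []
    for regime, X in regimes.items():
        X = np.asarray(X, dtype=float)
        if X.shape[0] != y.size:
            raise ModelError(f"regime {regime!r}: feature rows != target length")
        Xc_s, Xv_s, _ = standardize(X[cal], X[val])
        for spec in specs:
            row = {"regime": regime, "model": spec.name, "error": ""}
            try:
                pc, pv = fit_predict(spec, Xc_s, y[cal], Xv_s)
                row.update(
                    Rc2=r2(y[cal], pc), RMSEc=rmse(y[cal], pc), MAEc=mae(y[cal], pc),
                    Rp2=r2(y[val], pv), RMSEp=rmse(y[val], pv), MAEp=mae(y[val], pv),
                )
                row["grade"] = grade(row["Rp2"])
            except ModelError as exc:
                row.update(Rc2=np.nan, RMSEc=np.nan, MAEc=np.nan,
                           Rp2=np.nan, RMSEp=np.nan, MAEp=np.nan,
                           grade="", error=str(exc))
            rows.append(row)
    report = pd.DataFrame(rows)
    report["best"] = False
    for regime in regimes:
        sub = report[(report.regime == regime) & report.Rp2.notna()]
        if len(sub):
            ranked = sub.sort_values(["Rp2", "RMSEp"], ascending=[False, True])
            report.loc[ranked.index[0], "best"] = True
    return report[list(REPORT_COLUMNS)]
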