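"""Fusion of the CNN probability with liver-metastasis status.

A two-variable binary logistic model

    log(p_i / (1 - p_i)) = beta0 + beta1 * X1 + beta2 * X2

where ``p_i`` is the probability the nodule is a metastasis (Y = 1),
``X1`` is the CNN-derived malignancy probability on its natural [0,1]
scale and ``X2`` indicates presence of a synchronous >= 1 cm hepatic
metastasis on the same scan.  Because X1 lives on [0,1], the clinically
quoted effect size is the odds ratio per 10% (0.1) increase in CNN
probability, exp(0.1 * beta1), with a Wald CI.

``screen_predictors`` implements the predictor-screening step: fit the
full multivariable model over candidate covariates (e.g. adding
extrahepatic metastatic disease), drop non-significant predictors one at
a time (least significant first) at alpha = 0.05, refit, and report every
intermediate model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class CombinedLogisticModel:
    """Fitted two-predictor logistic model (intercept, X1, X2)."""

    beta0: float
    beta1: float
    beta2: float
    se: np.ndarray  # (3,) standard errors, order (beta0, beta1, beta2)
    cov: np.ndarray
    pvalues: np.ndarray
    n: int
    converged: bool
    fitted: bool = True
    penalized: bool = False

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "se": self.se.tolist(),
            "cov": self.cov.tolist(),
            "pvalues": self.pvalues.tolist(),
            "n": self.n,
            "converged": self.converged,
            "penalized": self.penalized,
        }


def _validate_xy(x1, x2, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=int)
    if not (x1.shape == x2.shape == y.shape) or x1.ndim != 1:
        raise ValueError("x1, x2 and y must be 1-d arrays of equal length")
    if np.any((x1 < 0) | (x1 > 1)):
        raise ValueError("x1 (CNN probability) must lie in [0,1]")
    if not set(np.unique(x2)) <= {0.0, 1.0}:
        raise ValueError("x2 must be a binary indicator")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes")
    return x1, x2, y


def fit_combined(x1, x2, y) -> CombinedLogisticModel:
    """Maximum-likelihood fit of the two-variable fusion model.

    Degenerate (constant) predictors and perfect separation are reported
    as explicit errors rather than silently diverging.
    """
    x1, x2, y = _validate_xy(x1, x2, y)
    if y.size < 10:
        raise ValueError(f"need at least 10 observations, got {y.size}")
    for name, col in (("x1", x1), ("x2", x2)):
        if np.ptp(col) == 0:
            raise ValueError(f"predictor {name} is constant ({col[0]}): cannot fit")
    X = sm.add_constant(np.column_stack([x1, x2]))
    try:
        with np.errstate(over="ignore", divide="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise ValueError(f"logistic fit failed (possible perfect separation): {exc}") from exc
    if not res.mle_retvals.get("converged", False) or np.any(res.bse > 1e3):
        raise ValueError(
            "logistic fit did not converge to finite estimates — the data "
            "are likely perfectly or quasi-perfectly separated"
        )
    return CombinedLogisticModel(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        beta2=float(res.params[2]),
        se=np.asarray(res.bse),
        cov=np.asarray(res.cov_params()),
        pvalues=np.asarray(res.pvalues),
        n=int(y.size),
        converged=bool(res.mle_retvals.get("converged", False)),
    )


def fit_combined_penalized(x1, x2, y, l2: float = 1.0) -> CombinedLogisticModel:
    """Ridge-penalized fusion fit for (quasi-)separated data.

    When the maximum-likelihood fit is degenerate — e.g. the CNN
    probability already separates the classes perfectly — a small L2
    penalty keeps the coefficients finite.  Standard errors and Wald
    p-values are not defined for this estimator and are reported as NaN;
    the model is flagged ``penalized``.
    """
    x1, x2, y = _validate_xy(x1, x2, y)
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(penalty="l2", C=1.0 / l2, solver="lbfgs", max_iter=1000)
    clf.fit(np.column_stack([x1, x2]), y)
    nan3 = np.full(3, np.nan)
    return CombinedLogisticModel(
        beta0=float(clf.intercept_[0]),
        beta1=float(clf.coef_[0, 0]),
        beta2=float(clf.coef_[0, 1]),
        se=nan3,
        cov=np.full((3, 3), np.nan),
        pvalues=nan3,
        n=int(y.size),
        converged=True,
        penalized=True,
    )


def odds_ratio_per_decile(model: CombinedLogisticModel, alpha: float = 0.05) -> dict:
    """Odds ratio per 0.1 (10%) increase in CNN probability, with Wald CI."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    z = stats.norm.ppf(1 - alpha / 2)
    se1 = model.se[1]
    return {
        "odds_ratio": float(np.exp(0.1 * model.beta1)),
        "ci_low": float(np.exp(0.1 * (model.beta1 - z * se1))),
        "ci_high": float(np.exp(0.1 * (model.beta1 + z * se1))),
        "p_value": float(model.pvalues[1]),
    }


def liver_met_odds_ratio(model: CombinedLogisticModel, alpha: float = 0.05) -> dict:
    """Odds ratio for presence of a synchronous >= 1 cm hepatic metastasis."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    z = stats.norm.ppf(1 - alpha / 2)
    se2 = model.se[2]
    return {
        "odds_ratio": float(np.exp(model.beta2)),
        "ci_low": float(np.exp(model.beta2 - z * se2)),
        "ci_high": float(np.exp(model.beta2 + z * se2)),
        "p_value": float(model.pvalues[2]),
    }


def predict_combined(model: CombinedLogisticModel, x1, x2) -> np.ndarray:
    """Fused probability of malignancy, logistic(beta0 + beta1 x1 + beta2 x2)."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any((x1 < 0) | (x1 > 1)):
        raise ValueError("x1 must lie in [0,1]")
    if not set(np.unique(x2)) <= {0.0, 1.0}:
        raise ValueError("x2 must be binary")
    eta = model.beta0 + model.beta1 * x1 + model.beta2 * x2
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class ScreeningResult:
    """Backward-elimination trace over candidate predictors."""

    candidates: list[str]
    retained: list[str]
    steps: list[pd.DataFrame] = field(default_factory=list)

    @property
    def final_table(self) -> pd.DataFrame:
        return self.steps[-1]


def screen_predictors(
    candidates: dict[str, np.ndarray],
    y,
    alpha: float = 0.05,
) -> ScreeningResult:
    """Backward elimination of non-significant predictors.

    Fits a multivariable logistic model over all candidates, then
    repeatedly drops the least-significant predictor with Wald p >= alpha
    and refits, reporting each intermediate model as a DataFrame with
    odds ratios, 95% CIs and p-values.
    """
    if not candidates:
        raise ValueError("need at least one candidate predictor")
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes")
    names = list(candidates)
    cols = {k: np.asarray(v, dtype=float) for k, v in candidates.items()}
    for k, v in cols.items():
        if v.shape != y.shape:
            raise ValueError(f"candidate {k!r} length mismatch")
        if np.ptp(v) == 0:
            raise ValueError(f"candidate {k!r} is constant: cannot fit")

    steps: list[pd.DataFrame] = []
    z = stats.norm.ppf(1 - alpha / 2)
    while names:
        X = sm.add_constant(np.column_stack([cols[k] for k in names]))
        with np.errstate(over="ignore", divide="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        table = pd.DataFrame(
            {
                "predictor": names,
                "odds_ratio": np.exp(res.params[1:]),
                "ci_low": np.exp(res.params[1:] - z * res.bse[1:]),
                "ci_high": np.exp(res.params[1:] + z * res.bse[1:]),
                "p_value": res.pvalues[1:],
            }
        )
        steps.append(table)
        worst = table.sort_values("p_value", ascending=False).iloc[0]
        if worst.p_value >= alpha:
            names = [k for k in names if k != worst.predictor]
        else:
            break
    return ScreeningResult(candidates=list(candidates), retained=names, steps=steps)
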