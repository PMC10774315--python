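"""Evaluation statistics: AUROC, logistic scoring, Kaplan-Meier, log-rank,
and Gleason-adjusted Cox proportional hazards.

These are the standard instruments the signature is judged with. AUROC uses
the Mann-Whitney formulation with midrank ties; the Kaplan-Meier estimator,
log-rank test and Cox model (Efron tie correction, Wald inference) are
provided through lifelines behind this module's interface.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_auc_score
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .datatypes import GLEASON_LEVELS


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE diverges; use the ridge option."""


def auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2).

    Mann-Whitney formulation with midrank tie handling; equals the
    proportion of positive-negative pairs correctly ordered.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


def fit_logistic(
    X, y, ridge: float | None = None, add_intercept: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic regression (Newton/IRLS).

    Returns ``(coefficients, fitted probabilities)``; the intercept is the
    first coefficient when ``add_intercept``. Perfect separation raises
    :class:`SeparationError` recommending the ridge penalty (``ridge`` > 0
    adds an L2 penalty of strength ``ridge`` on the slopes).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more samples than covariates")
    if np.any(X.std(axis=0) == 0.0) and X.shape[1] > 0:
        raise ValueError("constant (zero-variance) covariate column")
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    if ridge is not None and ridge > 0:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(
            C=1.0 / ridge, fit_intercept=add_intercept, solver="lbfgs",
            max_iter=1000,
        )
        lr.fit(X, y)
        coef = np.concatenate([lr.intercept_, lr.coef_.ravel()]) if add_intercept \
            else lr.coef_.ravel()
        probs = lr.predict_proba(X)[:, 1]
        return coef, probs
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, design).fit(disp=0, method="newton")
    except (PerfectSeparationError, PerfectSeparationWarning) as err:
        raise SeparationError(
            "perfect separation detected; refit with the ridge penalty "
            "(ridge > 0)"
        ) from err
    params = np.asarray(fit.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e3:
        raise SeparationError(
            "diverging coefficients indicate separation; refit with ridge > 0"
        )
    return params, np.asarray(fit.predict(design), dtype=float)


def kaplan_meier(times, events, group) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves per group.

    Returns ``{group: DataFrame(time, survival)}``; censored subjects leave
    the risk set after their time. An empty group is an error.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    if len(times) == 0:
        raise ValueError("no subjects")
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(group):
        mask = group == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def logrank(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError("log-rank test needs exactly 2 groups")
    if events.sum() == 0:
        raise ValueError("zero events: log-rank test undefined")
    m = group == levels[0]
    res = logrank_test(times[m], times[~m], events[m], events[~m])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalFit:
    """Cox proportional-hazards fit: per-covariate Wald inference.

    ``table`` columns: coef (log-hazard), hr, ci_lower, ci_upper (95%,
    log-scale Wald), p.
    """

    table: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    n_dropped: int = 0

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def summary(self) -> str:
        head = (
            f"Cox proportional hazards  n={self.n}  events={self.n_events}"
            + (f"  dropped={self.n_dropped}" if self.n_dropped else "")
        )
        return head + "\n" + self.table.to_string()

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_events": self.n_events,
            "n_dropped": self.n_dropped,
            "log_likelihood": self.log_likelihood,
            "covariates": self.table.reset_index()
            .rename(columns={"index": "covariate"})
            .to_dict(orient="records"),
        }


def gleason_dummies(gleason: pd.Series) -> pd.DataFrame:
    """Indicator columns for Gleason 7/8/9/10 with <=6 as reference."""
    cat = pd.Categorical(gleason, categories=list(GLEASON_LEVELS))
    dummies = pd.get_dummies(cat, prefix="gleason", dtype=float)
    dummies.index = gleason.index
    return dummies.drop(columns=["gleason_<=6"])


def cox_ph(design: pd.DataFrame, times, events) -> SurvivalFit:
    """Multivariate Cox PH via Newton-Raphson with Efron tie correction.

    ``design`` holds the covariates (e.g. predicted class plus Gleason
    dummies from :func:`gleason_dummies`). Rows with missing values are
    dropped (complete-case; count reported). No events, or a monotone
    partial likelihood (all events stacked on one covariate level), raise.
    """
    df = design.copy().astype(float)
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=float)
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if df["_event"].sum() < 1:
        raise ValueError("no events: Cox model undefined")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as err:
        raise ConvergenceError(
            f"Cox fit did not converge (likely monotone likelihood / "
            f"complete separation): {err}"
        ) from err
    s = cph.summary
    if (s["coef"].abs() > 10).any() or (s["se(coef)"] > 100).any():
        worst = s["coef"].abs().idxmax()
        raise ConvergenceError(
            f"diverging coefficient for {worst!r}: monotone partial "
            "likelihood (e.g. all events in one covariate level)"
        )
    table = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    return SurvivalFit(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(df["_event"].sum()),
        n_dropped=n_dropped,
    )


@dataclass
class EvaluationReport:
    """End-to-end evaluation of a fitted signature."""

    auroc_train: float
    auroc_test: float
    signature: pd.DataFrame
    logrank_stat: float | None = None
    logrank_p: float | None = None
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    survival_fit: SurvivalFit | None = None
    extra: dict = field(default_factory=dict)

    schema_version = 1

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "auroc_train": self.auroc_train,
            "auroc_test": self.auroc_test,
            "signature": self.signature.to_dict(orient="records"),
            "logrank_stat": self.logrank_stat,
            "logrank_p": self.logrank_p,
            "km_curves": {
                g: df.to_dict(orient="list") for g, df in self.km_curves.items()
            },
            "survival_fit": self.survival_fit.to_dict() if self.survival_fit else None,
            "extra": self.extra,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def plot_roc(self, scores, labels, ax=None):
        """Minimal ROC figure for the given scores/labels."""
        from sklearn.metrics import roc_curve
        import matplotlib.pyplot as plt

        fpr, tpr, _ = roc_curve(labels, scores)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr)
        ax.plot([0, 1], [0, 1], ls="--", c="gray")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        return ax

    def plot_km(self, ax=None):
        """Minimal Kaplan-Meier step plot of the stored per-group curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g, df in self.km_curves.items():
            ax.step(df["time"], df["survival"], where="post", label=str(g))
        ax.set_xlabel("months")
        ax.set_ylabel("progression-free survival")
        ax.legend()
        return ax
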