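"""Cox proportional-hazards analysis of disease-free and overall survival.

The same category-wise selection scheme used for pathway association is
applied to survival: every feature is screened with a univariate Cox model
(Efron tie handling, z-standardized continuous features, hazard ratio per
1 SD), the smallest-p feature per category is selected subject to the p < 0.2
gate, and the selected features enter one joint Cox model. The fitted linear
predictor (prognostic index) is scored by AUC against the event-ever-observed
indicator; censoring-aware time-dependent AUC is a noted alternative, not
implemented.

Entry point: :class:`SurvivalAssociationModel` → ``fit()`` →
:class:`SurvivalAssociationResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .association import FitResult, SelectionResult, _flagged, roc_auc, select_per_category
from .cohort import feature_categories, zscore

__all__ = [
    "univariate_cox",
    "multivariate_cox",
    "survival_auc",
    "SurvivalAssociationModel",
    "SurvivalAssociationResults",
]

_SEPARATION_BETA = 15.0


def _cox_fit(df: pd.DataFrame, covariates: list[str]) -> tuple[dict[str, FitResult], np.ndarray | None]:
    """Shared Cox fit: df must hold time, event and z-scored covariates."""
    if df["event"].sum() < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[["time", "event", *covariates]], duration_col="time", event_col="event")
    except Exception:
        return {c: _flagged("nonconvergence") for c in covariates}, None
    out: dict[str, FitResult] = {}
    for c in covariates:
        beta = float(cph.params_[c])
        se = float(cph.standard_errors_[c])
        if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > _SEPARATION_BETA:
            out[c] = _flagged("separation")
        else:
            out[c] = FitResult(
                p=float(cph.summary.loc[c, "p"]),
                odds_ratio=math.exp(beta),  # hazard ratio, same OR-scale container
                ci_low=float(cph.summary.loc[c, "exp(coef) lower 95%"]),
                ci_high=float(cph.summary.loc[c, "exp(coef) upper 95%"]),
                beta=beta,
            )
    lp = cph.predict_partial_hazard(df).to_numpy()
    return out, np.log(lp)


def univariate_cox(
    feature: np.ndarray, time: np.ndarray, event: np.ndarray, standardize: bool = True
) -> FitResult:
    """Single-feature Cox partial-likelihood fit; HR per 1 SD with Wald CI.

    Zero/one-event data and constant features return flagged results;
    monotone-likelihood blowups are flagged as separation.
    """
    x = np.asarray(feature, dtype=np.float64)
    t = np.asarray(time, dtype=np.float64)
    e = np.asarray(event, dtype=np.float64)
    keep = np.isfinite(x) & np.isfinite(t) & np.isfinite(e)
    x, t, e = x[keep], t[keep], e[keep]
    if e.sum() < 2:
        return _flagged("single_class")
    if x.size == 0 or x.std(ddof=1) == 0:
        return _flagged("constant")
    if standardize:
        x = zscore(x)
    df = pd.DataFrame({"time": t, "event": e, "x": x})
    try:
        res, _ = _cox_fit(df, ["x"])
    except ValueError:
        return _flagged("single_class")
    return res["x"]


def multivariate_cox(
    cohort: pd.DataFrame,
    features: list[str],
    time: np.ndarray,
    event: np.ndarray,
    standardize: bool = True,
) -> tuple[dict[str, FitResult], np.ndarray | None]:
    """Joint Cox fit on the selected features; returns results + linear predictor."""
    if not features:
        return {}, None
    t = np.asarray(time, dtype=np.float64)
    e = np.asarray(event, dtype=np.float64)
    X = cohort[features].to_numpy(dtype=np.float64)
    keep = np.isfinite(X).all(axis=1) & np.isfinite(t) & np.isfinite(e)
    df = pd.DataFrame(
        {"time": t[keep], "event": e[keep]},
    )
    for k, feat in enumerate(features):
        col = X[keep, k]
        df[feat] = zscore(col) if standardize else col
    try:
        res, lp_kept = _cox_fit(df, features)
    except ValueError:
        return {f: _flagged("single_class") for f in features}, None
    lp = np.full(len(t), np.nan)
    if lp_kept is not None:
        lp[keep] = lp_kept
    return res, lp


def survival_auc(linear_predictor: np.ndarray, event: np.ndarray) -> float:
    """AUC of the prognostic index against the event-ever-observed indicator."""
    return roc_auc(linear_predictor, event)


class SurvivalAssociationModel:
    """Category-wise Cox biomarker model for one endpoint (``dfs`` or ``os``).

    Expects the cohort table to hold ``time_<endpoint>`` (months) and
    ``event_<endpoint>`` (1 = recurrence for DFS, death for OS; 0 = censored).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        endpoint: str = "dfs",
        categories: dict[str, str] | None = None,
        selection_threshold: float = 0.2,
    ) -> None:
        if endpoint not in ("dfs", "os"):
            raise ValueError("endpoint must be 'dfs' or 'os'")
        for col in (f"time_{endpoint}", f"event_{endpoint}"):
            if col not in cohort.columns:
                raise ValueError(f"cohort lacks column {col!r}")
        self.cohort = cohort
        self.endpoint = endpoint
        self.categories = categories or feature_categories(cohort)
        self.selection_threshold = selection_threshold

    def fit(self) -> "SurvivalAssociationResults":
        t = self.cohort[f"time_{self.endpoint}"].to_numpy(dtype=np.float64)
        e = self.cohort[f"event_{self.endpoint}"].to_numpy(dtype=np.float64)
        if np.nansum(e) < 2:
            raise ValueError(f"endpoint {self.endpoint}: fewer than 2 events")
        uni = {
            feat: univariate_cox(self.cohort[feat].to_numpy(dtype=np.float64), t, e)
            for feat in self.categories
        }
        selection = select_per_category(uni, self.categories, self.selection_threshold)
        multi, lp = multivariate_cox(self.cohort, selection.features, t, e)
        auc = None
        if lp is not None and np.isfinite(lp).any():
            keep = np.isfinite(lp)
            if len(np.unique(e[keep])) == 2:
                auc = survival_auc(lp[keep], e[keep])
        return SurvivalAssociationResults(
            model=self, selection=selection, multivariate=multi,
            linear_predictor=lp, auc=auc, n_tests=len(uni),
        )


@dataclass
class SurvivalAssociationResults:
    """Fitted survival-biomarker results; hazard ratios per 1 SD."""

    model: SurvivalAssociationModel
    selection: SelectionResult
    multivariate: dict[str, FitResult]
    linear_predictor: np.ndarray | None
    auc: float | None
    n_tests: int

    @property
    def selected_features(self) -> list[str]:
        return self.selection.features

    def to_dict(self) -> dict:
        def fr(r: FitResult) -> dict:
            return {"p": r.p, "hazard_ratio": r.odds_ratio,
                    "ci95": [r.ci_low, r.ci_high], "flag": r.flag}

        return {
            "endpoint": self.model.endpoint,
            "selected_by_category": dict(self.selection.selected),
            "multivariate": {f: fr(r) for f, r in self.multivariate.items()},
            "auc": self.auc,
            "n_univariate_tests": self.n_tests,
        }

    def summary(self) -> str:
        lines = [f"Survival model ({self.model.endpoint.upper()}): "
                 f"{self.n_tests} screens, gate p < {self.selection.threshold}"]
        if not self.selected_features:
            lines.append("  no feature cleared the screening gate — no model")
            return "\n".join(lines)
        lines.append(f"  {'category':<22}{'feature':<28}{'HR (95% CI)':<28}{'p':>8}")
        for cat, feat in self.selection.selected.items():
            if feat is None:
                continue
            r = self.multivariate.get(feat)
            if r is None or not r.ok:
                lines.append(f"  {cat:<22}{feat:<28}(flagged: {r.flag if r else 'n/a'})")
            else:
                ci = f"{r.odds_ratio:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
                lines.append(f"  {cat:<22}{feat:<28}{ci:<28}{r.p:>8.3f}")
        if self.auc is not None:
            lines.append(f"  AUC vs event indicator: {self.auc:.3f}")
        return "\n".join(lines)
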