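"""Pathway-association statistics: screening, selection, logistic models, AUC.

The analysis follows a category-wise biomarker selection scheme. For a given
pathway label, every clinicoradiological feature is screened by univariate
logistic regression (label on the z-standardized feature plus intercept).
Within each of the 8 feature categories the smallest-p feature is selected,
but only if its p-value is below the 0.2 screening threshold; otherwise the
category contributes nothing. The selected features enter one joint
(multivariate) logistic model whose per-feature odds ratios, Wald confidence
intervals and p-values are reported, together with the in-sample AUC of the
fitted linear predictor.

Odds ratios for continuous features are per 1 SD of the feature. No
multiple-testing correction is applied; the report carries the number of
tests performed as context.

The statsmodels-style entry point is :class:`PathwayAssociationModel`, whose
``fit()`` returns a :class:`PathwayAssociationResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import feature_categories, zscore

__all__ = [
    "FitResult",
    "SelectionResult",
    "univariate_logistic",
    "select_per_category",
    "multivariate_logistic",
    "roc_auc",
    "fisher_exact_rx2",
    "smoking_association",
    "PathwayAssociationModel",
    "PathwayAssociationResults",
]

SELECTION_THRESHOLD = 0.2

# |beta| above this on the z-scale is treated as (quasi-)complete separation
_SEPARATION_BETA = 15.0


@dataclass
class FitResult:
    """One coefficient's estimate on the odds-ratio scale.

    ``flag`` is None for a clean fit, else one of ``"separation"``,
    ``"constant"``, ``"single_class"`` or ``"nonconvergence"``; flagged fits
    carry NaN p and an infinite/NaN OR marker rather than crashing.
    """

    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    beta: float = math.nan
    flag: str | None = None

    @property
    def ok(self) -> bool:
        return self.flag is None


@dataclass
class SelectionResult:
    """Per-category screening outcome: at most one feature per category."""

    selected: dict[str, str | None]            # category -> feature name or None
    univariate: dict[str, FitResult]           # feature -> screening fit
    threshold: float = SELECTION_THRESHOLD

    @property
    def features(self) -> list[str]:
        return [f for f in self.selected.values() if f is not None]


def _clean_xy(feature: np.ndarray, label: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(feature, dtype=np.float64)
    y = np.asarray(label, dtype=np.float64)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def _wald(beta: float, se: float) -> FitResult:
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    with np.errstate(over="ignore"):  # wide CIs near separation overflow to inf
        return FitResult(
            p=float(p),
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.959963984540054 * se)),
            ci_high=float(np.exp(beta + 1.959963984540054 * se)),
            beta=float(beta),
        )


def _flagged(flag: str) -> FitResult:
    orr = math.inf if flag == "separation" else math.nan
    return FitResult(p=math.nan, odds_ratio=orr, ci_low=math.nan, ci_high=math.nan, flag=flag)


def univariate_logistic(feature: np.ndarray, label: np.ndarray, standardize: bool = True) -> FitResult:
    """Logistic fit of a binary label on one feature (+ intercept).

    Continuous features are z-standardized so the OR is per 1 SD. Complete
    separation, constant features and single-class labels return flagged
    results rather than raising.
    """
    x, y = _clean_xy(feature, label)
    if x.size == 0 or min((y == 0).sum(), (y == 1).sum()) < 2:
        return _flagged("single_class")
    if x.std(ddof=1) == 0:
        return _flagged("constant")
    if standardize:
        x = zscore(x)
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception:
        return _flagged("separation")
    beta, se = res.params[1], res.bse[1]
    if not np.isfinite(beta) or not np.isfinite(se):
        return _flagged("separation")
    if abs(beta) > _SEPARATION_BETA:
        return _flagged("separation")
    if not res.mle_retvals.get("converged", True):
        return _flagged("nonconvergence")
    return _wald(beta, se)


def select_per_category(
    univariate: dict[str, FitResult],
    categories: dict[str, str],
    threshold: float = SELECTION_THRESHOLD,
) -> SelectionResult:
    """Smallest-p feature per category, gated at ``p < threshold``.

    Flagged (p = NaN) fits never win; ties break lexicographically on the
    feature name. Categories where no feature clears the gate select None.
    """
    selected: dict[str, str | None] = {}
    for cat in dict.fromkeys(categories.values()):
        candidates = [
            (res.p, feat)
            for feat, res in univariate.items()
            if categories.get(feat) == cat and res.ok and res.p < threshold
        ]
        selected[cat] = min(candidates)[1] if candidates else None
    return SelectionResult(selected=selected, univariate=dict(univariate), threshold=threshold)


def multivariate_logistic(
    cohort: pd.DataFrame,
    features: list[str],
    label: np.ndarray,
    standardize: bool = True,
) -> tuple[dict[str, FitResult], np.ndarray | None]:
    """Joint logistic fit on the selected features.

    Returns per-feature results and the linear predictor on the rows used
    (NaN where a row was dropped for missing values). With a single feature
    this reduces exactly to the univariate fit.
    """
    if not features:
        return {}, None
    y = np.asarray(label, dtype=np.float64)
    Xdf = cohort[features].astype(np.float64)
    keep = np.isfinite(Xdf.to_numpy()).all(axis=1) & np.isfinite(y)
    if keep.sum() < 5 * len(features):
        warnings.warn(
            f"only {int(keep.sum())} complete rows for {len(features)} predictors",
            stacklevel=2,
        )
    X = Xdf.to_numpy()[keep]
    yk = y[keep]
    if standardize:
        X = np.column_stack([zscore(X[:, k]) for k in range(X.shape[1])])
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(yk, Xc).fit(disp=0, maxiter=200)
        params, bses = res.params, res.bse
        converged = res.mle_retvals.get("converged", True)
    except Exception:
        params = np.full(len(features) + 1, np.nan)
        bses = params
        converged = False
    out: dict[str, FitResult] = {}
    for k, feat in enumerate(features, start=1):
        beta, se = params[k], bses[k]
        if not converged or not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > _SEPARATION_BETA:
            out[feat] = _flagged("separation" if converged else "nonconvergence")
        else:
            out[feat] = _wald(beta, se)
    lp = np.full(len(y), np.nan)
    if np.all(np.isfinite(params)):
        lp[keep] = Xc @ params
    return out, lp


def roc_auc(score: np.ndarray, label: np.ndarray) -> float:
    """AUC = P(score_case > score_control) + 0.5*P(tie) (Mann–Whitney form)."""
    s, y = _clean_xy(score, label)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both label classes")
    return float(roc_auc_score(y, s))


def fisher_exact_rx2(table: np.ndarray) -> float:
    """Exact conditional test for an r×2 contingency table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed table
    (two-sided, probability ordering — the classical r×c generalization).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2 or (t < 0).any():
        raise ValueError("expected a nonnegative r×2 table")
    rows = t.sum(axis=1)
    if (rows == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: empty row or column")
    c0 = int(t[:, 0].sum())
    n = int(t.sum())
    lgam = math.lgamma

    def log_comb(a: int, b: int) -> float:
        return lgam(a + 1) - lgam(b + 1) - lgam(a - b + 1)

    denom = log_comb(n, c0)

    def logp(cells: tuple[int, ...]) -> float:
        return sum(log_comb(int(r), a) for r, a in zip(rows, cells)) - denom

    obs = logp(tuple(int(v) for v in t[:, 0]))
    total = 0.0

    def rec(i: int, remaining: int, prefix: tuple[int, ...]) -> None:
        nonlocal total
        if i == len(rows) - 1:
            if remaining <= rows[i]:
                lp = logp(prefix + (remaining,))
                if lp <= obs + 1e-9:
                    total += math.exp(lp)
            return
        tail = int(rows[i + 1:].sum())
        lo = max(0, remaining - tail)
        hi = min(int(rows[i]), remaining)
        for a in range(lo, hi + 1):
            rec(i + 1, remaining - a, prefix + (a,))

    rec(0, c0, ())
    return min(total, 1.0)


def smoking_association(
    smoking_status: np.ndarray, pack_years: np.ndarray, altered: np.ndarray
) -> dict[str, float]:
    """Smoking vs pathway alteration: Fisher exact + Wilcoxon rank-sum.

    Fisher's exact test is run on the smoking-status × alteration table
    (status levels 0/1/2 = never/former/current); the Wilcoxon rank-sum test
    compares pack-years between altered and unaltered patients.
    """
    status = np.asarray(smoking_status)
    py = np.asarray(pack_years, dtype=np.float64)
    y = np.asarray(altered).astype(int)
    levels = np.unique(status)
    table = np.array([[(status[y == 0] == lv).sum(), (status[y == 1] == lv).sum()] for lv in levels])
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or (table.sum(axis=0) == 0).any():
        return {"fisher_p": math.nan, "wilcoxon_p": math.nan, "flag": "degenerate"}
    fisher_p = fisher_exact_rx2(table)
    g0, g1 = py[y == 0], py[y == 1]
    if g0.size == 0 or g1.size == 0:
        wil_p = math.nan
    else:
        wil_p = float(stats.mannwhitneyu(g1, g0, alternative="two-sided").pvalue)
    return {"fisher_p": float(fisher_p), "wilcoxon_p": wil_p}


# --------------------------------------------------------------------------
# Model / Results objects


class PathwayAssociationModel:
    """Category-wise selection + multivariate logistic model for one pathway.

    Parameters
    ----------
    cohort : DataFrame
        One row per patient with feature columns and a binary label column
        ``pathway_<pathway>`` (or exactly ``pathway``).
    pathway : str
        Pathway name, e.g. ``"apoptosis"``.
    categories : mapping, optional
        feature → category; defaults to the built-in 73-feature map
        restricted to the cohort's columns.
    selection_threshold : float
        Univariate screening gate (default 0.2).
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        pathway: str,
        categories: dict[str, str] | None = None,
        selection_threshold: float = SELECTION_THRESHOLD,
    ) -> None:
        self.cohort = cohort
        self.pathway = pathway
        label_col = f"pathway_{pathway}" if f"pathway_{pathway}" in cohort.columns else pathway
        if label_col not in cohort.columns:
            raise ValueError(f"cohort lacks a label column for pathway {pathway!r}")
        self.label_col = label_col
        self.categories = categories or feature_categories(cohort)
        self.selection_threshold = selection_threshold

    def fit(self) -> "PathwayAssociationResults":
        y = self.cohort[self.label_col].to_numpy(dtype=np.float64)
        uni = {
            feat: univariate_logistic(self.cohort[feat].to_numpy(dtype=np.float64), y)
            for feat in self.categories
        }
        selection = select_per_category(uni, self.categories, self.selection_threshold)
        multi, lp = multivariate_logistic(self.cohort, selection.features, y)
        auc = None
        if lp is not None and np.isfinite(lp).any():
            keep = np.isfinite(lp)
            if len(np.unique(y[keep])) == 2:
                auc = roc_auc(lp[keep], y[keep])
        return PathwayAssociationResults(
            model=self, selection=selection, multivariate=multi,
            linear_predictor=lp, auc=auc, n_tests=len(uni),
        )


@dataclass
class PathwayAssociationResults:
    """Fitted pathway-association results with a Table-2-style summary."""

    model: PathwayAssociationModel
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
            return {
                "p": r.p, "odds_ratio": r.odds_ratio,
                "ci95": [r.ci_low, r.ci_high], "flag": r.flag,
            }

        return {
            "pathway": self.model.pathway,
            "selected_by_category": dict(self.selection.selected),
            "univariate": {f: fr(r) for f, r in self.selection.univariate.items()
                           if f in self.selected_features},
            "multivariate": {f: fr(r) for f, r in self.multivariate.items()},
            "auc": self.auc,
            "n_univariate_tests": self.n_tests,
        }

    def summary(self) -> str:
        lines = [
            f"Pathway association model: {self.model.pathway}",
            f"  univariate screens: {self.n_tests} features, "
            f"gate p < {self.selection.threshold}",
        ]
        if not self.selected_features:
            lines.append("  no feature cleared the screening gate — no model")
            return "\n".join(lines)
        lines.append(f"  {'category':<22}{'feature':<28}{'OR (95% CI)':<26}{'p':>8}")
        for cat, feat in self.selection.selected.items():
            if feat is None:
                lines.append(f"  {cat:<22}{'—':<28}")
                continue
            r = self.multivariate.get(feat)
            if r is None or not r.ok:
                lines.append(f"  {cat:<22}{feat:<28}{'(flagged: ' + str(r.flag if r else 'n/a') + ')'}")
            else:
                ci = f"{r.odds_ratio:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
                lines.append(f"  {cat:<22}{feat:<28}{ci:<26}{r.p:>8.3f}")
        if self.auc is not None:
            lines.append(f"  in-sample AUC: {self.auc:.3f}")
        return "\n".join(lines)
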