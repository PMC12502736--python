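"""LASSO variable selection with cross-validation, multivariable logistic
refinement, and AUC with DeLong confidence intervals.

The screening stage proposes candidate drugs; an L1-penalized logistic path
with stratified 10-fold cross-validation picks the regularization strength
(λ_min maximizing mean CV AUC, or the parsimonious λ_1se within one standard
error), and the retained variables are refit by unpenalized maximum
likelihood to obtain odds ratios, Wald CIs, FDR-adjusted p-values, and
in-sample AUC.  A drug is significant when its adjusted p < 0.05 and the OR
CI lower bound is ≥ 1.

The penalty λ follows the glmnet convention (average log-likelihood plus
λ‖β‖₁ with standardized predictors), so liblinear's C maps to
1/(n·λ).  Modeling rows are complete cases on age and sex; the dropped-row
count is reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .cohort import (AnalyticalDataset, CaseDefinition, DrugNormalizer,
                     IndicationClassifier, build_dataset)
from .errors import DegenerateDatasetError
from .faers import ReportStore
from .signals import fdr_adjust, screen

logger = logging.getLogger(__name__)

__all__ = ["LassoResult", "LogisticResult", "lasso_select", "logistic_fit",
           "auc_ci", "run_all_schemes", "SchemeResult"]


# ---------------------------------------------------------------------------
# design matrix helpers

def _design(frame: pd.DataFrame, variables: list[str]
            ) -> tuple[pd.DataFrame, pd.Series, int]:
    """Complete-case design matrix; sex is encoded as ``sex_male`` 0/1."""
    df = frame.copy()
    if "sex" in variables or "sex_male" in variables:
        df["sex_male"] = df["sex"].map({"M": 1, "F": 0})
    variables = ["sex_male" if v == "sex" else v for v in variables]
    cols = [v for v in variables if v in df.columns]
    X = df[cols].apply(pd.to_numeric, errors="coerce")
    ok = X.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    return X[ok], df.loc[ok, "case"].astype(int), n_dropped


# ---------------------------------------------------------------------------
# AUC with DeLong CI

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Mann–Whitney AUC (tie-corrected) and its DeLong variance."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v10, ddof=1) / n if n > 1 else 0.0)
    return float(auc), float(var)


def auc_ci(scores, labels, alpha: float = 0.05, method: str = "delong",
           n_boot: int = 2000, seed: int = 0) -> tuple[float, float, float]:
    """AUC with a confidence interval (DeLong by default).

    Falls back to a seeded bootstrap when the DeLong variance degenerates
    (e.g. constant scores within a class).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc, var = _delong(labels, scores)
    z = stats.norm.ppf(1 - alpha / 2)
    if method == "delong" and var > 0 and np.isfinite(var):
        half = z * np.sqrt(var)
        return auc, max(0.0, auc - half), min(1.0, auc + half)
    rng = np.random.default_rng(seed)
    idx_pos = np.where(labels == 1)[0]
    idx_neg = np.where(labels == 0)[0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate([rng.choice(idx_pos, len(idx_pos)),
                               rng.choice(idx_neg, len(idx_neg))])
        aucs[b] = _delong(labels[take], scores[take])[0]
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return auc, float(lo), float(hi)


# ---------------------------------------------------------------------------
# LASSO path + cross-validation

@dataclass
class LassoResult:
    lambdas: np.ndarray
    cv_mean: np.ndarray           # per-λ mean CV score
    cv_se: np.ndarray             # per-λ SE over folds
    criterion: str                # 'auc' (maximized) or 'deviance' (minimized)
    lambda_min: float
    lambda_1se: float
    selected_min: list[str]
    selected_1se: list[str]
    n_nonzero: np.ndarray
    variables: list[str]
    seed: int
    n_used: int
    dropped_allzero: list[str] = field(default_factory=list)

    def cv_table(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambdas, "cv_mean": self.cv_mean,
                             "cv_se": self.cv_se, "n_nonzero": self.n_nonzero})


def _l1_path_fit(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    n = len(y)
    clf = LogisticRegression(penalty="l1", solver="liblinear",
                             C=1.0 / (n * lam), max_iter=2000, tol=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf


def lasso_select(dataset: AnalyticalDataset | pd.DataFrame,
                 variables: list[str] | None = None, folds: int = 10,
                 seed: int = 0, n_lambdas: int = 100, decades: float = 4.0,
                 criterion: str = "auc") -> LassoResult:
    """L1-penalized logistic path with stratified K-fold cross-validation.

    Predictors default to age, sex, and every candidate drug indicator of
    the dataset.  All predictors are standardized for the penalty (the
    reported selection is on the original variables).  λ_min maximizes mean
    CV AUC (or minimizes deviance); λ_1se is the largest λ within one
    standard error of the optimum.  Deterministic given ``seed``.
    """
    if criterion not in ("auc", "deviance"):
        raise ValueError("criterion must be 'auc' or 'deviance'")
    frame = dataset.frame if isinstance(dataset, AnalyticalDataset) else dataset
    if variables is None:
        drugs = (dataset.candidate_drugs
                 if isinstance(dataset, AnalyticalDataset)
                 else [c for c in frame.columns
                       if c not in ("primaryid", "case", "age", "sex")])
        variables = ["age", "sex", *drugs]
    X_df, y, n_dropped = _design(frame, variables)
    if n_dropped:
        logger.info("lasso: dropped %d rows with missing age/sex", n_dropped)

    allzero = [c for c in X_df.columns if X_df[c].nunique() <= 1]
    if allzero:
        logger.info("lasso: dropped constant predictors %s", allzero)
        X_df = X_df.drop(columns=allzero)
    names = list(X_df.columns)
    X = X_df.to_numpy(dtype=float)
    yv = y.to_numpy()
    if yv.sum() < folds or (len(yv) - yv.sum()) < folds:
        raise DegenerateDatasetError(
            "need at least one case and one control per fold")

    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mu) / sd
    n = len(yv)
    lam_max = np.abs(Xs.T @ (yv - yv.mean())).max() / n
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max) - decades,
                          n_lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros((folds, n_lambdas))
    for k, (tr, va) in enumerate(skf.split(Xs, yv)):
        for j, lam in enumerate(lambdas):
            clf = _l1_path_fit(Xs[tr], yv[tr], lam)
            p = np.clip(clf.predict_proba(Xs[va])[:, 1], 1e-12, 1 - 1e-12)
            if criterion == "auc":
                scores[k, j] = _delong(yv[va], p)[0]
            else:
                scores[k, j] = -2 * np.mean(
                    yv[va] * np.log(p) + (1 - yv[va]) * np.log(1 - p))
    cv_mean = scores.mean(axis=0)
    cv_se = scores.std(axis=0, ddof=1) / np.sqrt(folds)

    if criterion == "auc":
        j_min = int(np.argmax(cv_mean))
        within = cv_mean >= cv_mean[j_min] - cv_se[j_min]
    else:
        j_min = int(np.argmin(cv_mean))
        within = cv_mean <= cv_mean[j_min] + cv_se[j_min]
    j_1se = int(np.flatnonzero(within)[0])  # lambdas are decreasing

    def _selected(lam: float) -> tuple[list[str], np.ndarray]:
        clf = _l1_path_fit(Xs, yv, lam)
        coefs = clf.coef_.ravel()
        return [names[i] for i in np.flatnonzero(np.abs(coefs) > 1e-8)], coefs

    n_nonzero = np.array([
        len(np.flatnonzero(np.abs(_l1_path_fit(Xs, yv, lam).coef_.ravel())
                           > 1e-8)) for lam in lambdas])
    sel_min, _ = _selected(lambdas[j_min])
    sel_1se, _ = _selected(lambdas[j_1se])

    return LassoResult(lambdas=lambdas, cv_mean=cv_mean, cv_se=cv_se,
                       criterion=criterion,
                       lambda_min=float(lambdas[j_min]),
                       lambda_1se=float(lambdas[j_1se]),
                       selected_min=sel_min, selected_1se=sel_1se,
                       n_nonzero=n_nonzero, variables=names, seed=seed,
                       n_used=n, dropped_allzero=allzero)


# ---------------------------------------------------------------------------
# unpenalized logistic refit

@dataclass
class LogisticResult:
    table: pd.DataFrame           # variable, or, ci_low, ci_high, p, p_adj, significant
    auc: float
    auc_ci: tuple[float, float]
    n_cases: int
    n_controls: int
    n_dropped_missing: int
    converged: bool

    @property
    def significant(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "variable"])


def logistic_fit(dataset: AnalyticalDataset | pd.DataFrame,
                 variables: list[str], alpha: float = 0.05) -> LogisticResult:
    """Unpenalized ML logistic regression of case status on ``variables``.

    Wald CIs on the log-odds scale are exponentiated to odds ratios;
    per-variable p-values are FDR-adjusted across the model's variables.
    Non-convergence (e.g. separation) is flagged, not raised; a singular
    design raises with the offending columns named.
    """
    frame = dataset.frame if isinstance(dataset, AnalyticalDataset) else dataset
    if len(set(variables)) != len(variables):
        raise ValueError("duplicate variables in model specification")
    X_df, y, n_dropped = _design(frame, variables)
    Xc = sm.add_constant(X_df.astype(float), has_constant="add")

    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        r = np.linalg.qr(Xc.to_numpy(), mode="r")
        bad = [Xc.columns[i] for i in range(Xc.shape[1])
               if abs(r[i, i]) < 1e-8]
        raise ValueError(f"singular design matrix; collinear columns: {bad}")

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception as exc:  # separation and friends
            logger.warning("logistic fit failed: %s", exc)
            res = sm.Logit(y, Xc).fit_regularized(alpha=1e-8, disp=0)
            converged = False
    params = res.params.drop("const")
    ci = res.conf_int(alpha=alpha).drop(index="const")
    pvals = res.pvalues.drop("const")
    # absurd Wald SEs are another separation symptom
    if np.any(res.bse > 1e3):
        converged = False
    with np.errstate(over="ignore"):
        table = pd.DataFrame({
            "variable": params.index,
            "or": np.exp(params.values),
            "ci_low": np.exp(ci[0].values),
            "ci_high": np.exp(ci[1].values),
            "p": pvals.values,
        })
    table["p_adj"] = fdr_adjust(np.nan_to_num(table["p"].values, nan=1.0))
    table["significant"] = (table["p_adj"] < 0.05) & (table["ci_low"] >= 1.0)

    p_hat = np.asarray(res.predict(Xc))
    auc, lo, hi = auc_ci(p_hat, y.to_numpy())
    return LogisticResult(table=table.reset_index(drop=True), auc=auc,
                          auc_ci=(lo, hi), n_cases=int(y.sum()),
                          n_controls=int((1 - y).sum()),
                          n_dropped_missing=n_dropped, converged=converged)


# ---------------------------------------------------------------------------
# orchestration across exclusion schemes

@dataclass
class SchemeResult:
    scheme: str
    candidates: list[str]
    lasso: LassoResult | None
    logistic: LogisticResult | None
    skipped: str | None = None


def run_all_schemes(store: ReportStore, seed: int = 0,
                    schemes=("main", "sensitivity_A", "sensitivity_B"),
                    definition: CaseDefinition | None = None,
                    normalizer: DrugNormalizer | None = None,
                    classifier: IndicationClassifier | None = None,
                    min_cases: int = 3, folds: int = 10,
                    n_lambdas: int = 100, criterion: str = "auc",
                    control_ratio: int | None = None,
                    ) -> tuple[dict[str, SchemeResult], pd.DataFrame, set[str]]:
    """Candidate screen → LASSO(λ_min) → logistic, per exclusion scheme.

    Returns per-scheme results, a long forest-plot table (drug, scheme, OR,
    CI, adjusted p, significance) and the cross-scheme intersection of
    significant drugs.  ``control_ratio`` optionally subsamples controls to
    k per case (seeded) for tractability on very large corpora.
    """
    from .cohort import retained_primaryids

    definition = definition or CaseDefinition()
    normalizer = normalizer or DrugNormalizer()
    classifier = classifier or IndicationClassifier()

    results: dict[str, SchemeResult] = {}
    forest_rows = []
    sig_sets = []
    for scheme in schemes:
        retained = retained_primaryids(store, scheme, classifier)
        sub = store.subset(retained)
        sig = screen(sub, definition=definition, normalizer=normalizer,
                     min_cases=min_cases)
        candidates = sorted(sig.loc[sig["signal"], "drug"])
        if not candidates:
            logger.info("scheme %s: no candidate signals, skipped", scheme)
            results[scheme] = SchemeResult(scheme, [], None, None,
                                           skipped="no candidate signals")
            continue
        ds = build_dataset(store, scheme, candidates, definition=definition,
                           normalizer=normalizer, classifier=classifier)
        frame = ds.frame
        if control_ratio:
            rng = np.random.default_rng(seed)
            ctrl = frame[frame["case"] == 0]
            n_keep = min(len(ctrl), control_ratio * int(frame["case"].sum()))
            keep = rng.choice(ctrl.index.to_numpy(), n_keep, replace=False)
            frame = pd.concat([frame[frame["case"] == 1],
                               frame.loc[np.sort(keep)]], ignore_index=True)
            ds = AnalyticalDataset(scheme=ds.scheme, frame=frame,
                                   candidate_drugs=ds.candidate_drugs,
                                   provenance=ds.provenance)
        lasso = lasso_select(ds, folds=folds, seed=seed, n_lambdas=n_lambdas,
                             criterion=criterion)
        if not lasso.selected_min:
            results[scheme] = SchemeResult(scheme, candidates, lasso, None,
                                           skipped="lasso selected nothing")
            continue
        logit = logistic_fit(ds, lasso.selected_min)
        results[scheme] = SchemeResult(scheme, candidates, lasso, logit)
        drug_vars = set(candidates)
        for _, row in logit.table.iterrows():
            forest_rows.append((scheme, row["variable"], row["or"],
                                row["ci_low"], row["ci_high"], row["p_adj"],
                                bool(row["significant"])))
        sig_sets.append({v for v in logit.significant if v in drug_vars})

    forest = pd.DataFrame(forest_rows, columns=[
        "scheme", "variable", "or", "ci_low", "ci_high", "p_adj", "significant"])
    overlap = set.intersection(*sig_sets) if sig_sets else set()
    return results, forest, overlap
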