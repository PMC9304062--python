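"""Multivariable diagnosis models and ROC comparison.

Three logistic models predict nigrostriatal degeneration (the PS/PD/DLB
class) from different inputs:

* Model 1 — the conventional ROI indices (mean SBR and asymmetry index);
* Model 2 — the machine-learned probability of overall abnormality from the
  best-performing classifier, used directly without refitting;
* Model 3 — the machine-learned probabilities of the low-uptake, asymmetry
  and dot features plus patient age, with the variable set chosen by forward
  stepwise selection on AUC.

All fitted models implement ``p = 1 / (1 + exp(-(b0 + sum_i b_i x_i)))``.
Operating thresholds maximize the Youden index (sensitivity + specificity
- 1); paired AUCs on the same subjects are compared with the DeLong
covariance-aware test.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .feature_ml import auc_mann_whitney

__all__ = [
    "DiagnosisModel",
    "RocResult",
    "fit_logistic",
    "predict_probability",
    "build_model1",
    "build_model2",
    "forward_stepwise",
    "roc_with_youden",
    "compare_auc",
]


@dataclass
class DiagnosisModel:
    """Named logistic model: intercept b0 and one coefficient per variable."""

    name: str
    variables: list[str]
    intercept: float
    coefficients: np.ndarray
    standard_errors: np.ndarray | None = None
    converged: bool = True
    separation: bool = False

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.variables):
            raise ValueError("one coefficient per variable required")

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "variables": list(self.variables),
            "intercept": float(self.intercept),
            "coefficients": [float(b) for b in self.coefficients],
            "converged": bool(self.converged),
            "separation": bool(self.separation),
        }


def _design_matrix(design, variables=None):
    if isinstance(design, pd.DataFrame):
        cols = list(design.columns) if variables is None else list(variables)
        X = design[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        cols = [f"x{i}" for i in range(X.shape[1])] if variables is None else list(variables)
    return X, cols


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # columns whose removal restores full rank, identified via QR pivoting
    _, r = np.linalg.qr(np.column_stack([np.ones(len(X)), X]))
    diag = np.abs(np.diag(r))
    tol = diag.max() * len(X) * np.finfo(float).eps * 100
    bad = [names[i - 1] for i in range(1, len(diag)) if diag[i] < tol]
    return bad or names


def fit_logistic(design, outcome, variables: Sequence[str] | None = None,
                 name: str = "custom") -> DiagnosisModel:
    """Maximum-likelihood logistic fit of a binary outcome.

    On (quasi-)perfect separation the unpenalized likelihood has no finite
    maximizer; the fit is then ridge-stabilized (small L2 penalty) and
    flagged via ``separation``.
    """
    X, cols = _design_matrix(design, variables)
    y = np.asarray(outcome, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome contains a single class")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more observations than predictors plus one")
    full = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        bad = _collinear_columns(X, cols)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, full).fit(disp=0, maxiter=200)
            params = res.params
            bse = res.bse
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            params, bse, converged = None, None, False
    separation = params is None or not converged or np.abs(params).max() > 50
    if separation:
        ridge = LogisticRegression(C=100.0, solver="lbfgs", max_iter=5000)
        ridge.fit(X, y)
        params = np.concatenate([ridge.intercept_, ridge.coef_.ravel()])
        bse = None
        converged = True
    return DiagnosisModel(name=name, variables=cols, intercept=float(params[0]),
                          coefficients=params[1:],
                          standard_errors=None if bse is None else np.asarray(bse[1:]),
                          converged=converged, separation=bool(separation))


def predict_probability(model: DiagnosisModel, x) -> float | np.ndarray:
    """Evaluate 1 / (1 + exp(-(b0 + sum b_i x_i))) for one subject or a table."""
    if isinstance(x, Mapping):
        missing = [v for v in model.variables if v not in x]
        if missing:
            raise ValueError(f"missing predictors: {missing}")
        vec = np.asarray([x[v] for v in model.variables], dtype=float)
        lin = model.intercept + vec @ model.coefficients
        return float(1.0 / (1.0 + np.exp(-lin)))
    if isinstance(x, pd.DataFrame):
        missing = [v for v in model.variables if v not in x.columns]
        if missing:
            raise ValueError(f"missing predictors: {missing}")
        X = x[model.variables].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(x, dtype=float))
        if X.shape[1] != len(model.variables):
            raise ValueError("predictor count mismatch")
    lin = model.intercept + X @ model.coefficients
    return 1.0 / (1.0 + np.exp(-lin))


def build_model1(roi: pd.DataFrame, outcome,
                 variables: Sequence[str] = ("sbr_mean", "asymmetry_index")) -> DiagnosisModel:
    """Model 1: logistic fit on the ROI-based indices."""
    model = fit_logistic(roi, outcome, variables=list(variables), name="model1")
    return model


@dataclass
class RocResult:
    """Full ROC read-out with the Youden operating point."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_se: float
    youden_threshold: float
    sens_at_youden: float
    spec_at_youden: float
    youden_defined: bool = True
    p_value_vs_chance: float = float("nan")


def roc_with_youden(scores, outcome) -> RocResult:
    """ROC over all distinct score cuts, with the Youden-optimal threshold.

    Candidate cuts are midpoints between consecutive distinct scores plus
    open ends; a subject is called positive when its score is >= the cut.
    Ties on the Youden index resolve toward higher specificity (higher cut).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if len(s) != len(y):
        raise ValueError("scores and outcome must align")
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(s)
    if len(uniq) == 1:
        return RocResult(np.array([uniq[0]]), np.array([1.0]), np.array([0.0]),
                         auc=0.5, auc_se=float("nan"), youden_threshold=float("nan"),
                         sens_at_youden=float("nan"), spec_at_youden=float("nan"),
                         youden_defined=False, p_value_vs_chance=1.0)
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0,
                           [uniq[-1] + 1.0]])
    pos_sorted = np.sort(s[y == 1])
    neg_sorted = np.sort(s[y == 0])
    tp = n1 - np.searchsorted(pos_sorted, cuts, side="left")
    fp = n0 - np.searchsorted(neg_sorted, cuts, side="left")
    sens = tp / n1
    spec = (n0 - fp) / n0
    # exact integer Youden criterion (J = TP/n1 - FP/n0, scaled by n1*n0)
    # avoids float ties; ties resolve toward higher specificity
    j_int = tp * n0 - fp * n1
    best = max(range(len(cuts)), key=lambda i: (j_int[i], n0 - fp[i]))
    auc = auc_mann_whitney(s, y)
    se = _delong_se(s, y)
    pos, neg = s[y == 1], s[y == 0]
    pval = float(stats.mannwhitneyu(pos, neg, alternative="two-sided",
                                    method="asymptotic").pvalue)
    return RocResult(cuts, sens, spec, auc=auc, auc_se=se,
                     youden_threshold=float(cuts[best]),
                     sens_at_youden=float(sens[best]),
                     spec_at_youden=float(spec[best]),
                     p_value_vs_chance=pval)


def build_model2(p_abnormal, outcome) -> RocResult:
    """Model 2: ROC of the abnormality probability itself (no refitting)."""
    p = np.asarray(p_abnormal, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return roc_with_youden(p, outcome)


def _feature_family(name: str) -> str:
    # "p_low_gbt" -> "low"; plain predictors (age, sbr_mean ...) are their own family
    if name.startswith("p_") and name.count("_") >= 2:
        return name.split("_")[1]
    return name


def _cv_auc(X: np.ndarray, y: np.ndarray, seed: int, n_folds: int = 4) -> float:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    for tr, va in skf.split(X, y):
        clf = LogisticRegression(C=1000.0, solver="lbfgs", max_iter=5000)
        clf.fit(X[tr], y[tr])
        oof[va] = clf.predict_proba(X[va])[:, list(clf.classes_).index(1)]
    return auc_mann_whitney(oof, y)


def forward_stepwise(candidates: pd.DataFrame, outcome,
                     criterion: str = "cv", epsilon: float = 0.005,
                     seed: int = 0, max_variables: int | None = None,
                     name: str = "model3") -> tuple[DiagnosisModel, list[dict]]:
    """Greedy forward selection of predictors by AUC.

    At each step the candidate giving the largest AUC (cross-validated by
    default, in-sample with ``criterion="insample"``) joins the model;
    selection stops when no candidate improves the AUC by more than
    ``epsilon``.  Columns named ``p_<family>_<method>`` are mutually
    exclusive within a family, so each visual feature contributes through at
    most one classifier, mirroring a per-feature choice of method.

    Returns the refitted final model and the selection trace.
    """
    if candidates.shape[1] == 0:
        raise ValueError("no candidate predictors supplied")
    y = np.asarray(outcome, dtype=int)
    selected: list[str] = []
    used_families: set[str] = set()
    trace: list[dict] = []
    best_auc = 0.5
    while True:
        pool = [c for c in candidates.columns
                if c not in selected and _feature_family(c) not in used_families]
        if not pool or (max_variables and len(selected) >= max_variables):
            break
        scores = {}
        for c in pool:
            X = candidates[selected + [c]].to_numpy(dtype=float)
            if criterion == "cv":
                scores[c] = _cv_auc(X, y, seed)
            else:
                clf = LogisticRegression(C=1000.0, solver="lbfgs", max_iter=5000)
                clf.fit(X, y)
                p = clf.predict_proba(X)[:, list(clf.classes_).index(1)]
                scores[c] = auc_mann_whitney(p, y)
        best_c = max(scores, key=lambda c: scores[c])
        gain = scores[best_c] - best_auc
        if selected and gain <= epsilon:
            break
        selected.append(best_c)
        used_families.add(_feature_family(best_c))
        best_auc = scores[best_c]
        trace.append({"added": best_c, "auc": best_auc, "gain": gain})
        if not selected:
            break
    model = fit_logistic(candidates, y, variables=selected, name=name)
    return model, trace


def _placements(scores: np.ndarray, y: np.ndarray):
    pos, neg = scores[y == 1], scores[y == 0]
    n1, n0 = len(pos), len(neg)
    # placement values via midranks (DeLong structural components)
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n0 for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / n1 for x in neg])
    return v10, v01


def _delong_se(scores, y) -> float:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    v10, v01 = _placements(scores, y)
    var = (np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0) + \
          (np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0)
    return float(np.sqrt(max(var, 0.0)))


def compare_auc(scores_a, scores_b, outcome) -> dict:
    """Paired DeLong comparison of two scores on the same subjects.

    Returns ``auc_a``, ``auc_b``, ``difference`` (a - b) and the two-sided
    ``p_value`` accounting for the correlation between the two ROC curves.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scores and outcome must cover the same subjects")
    auc_a = auc_mann_whitney(a, y)
    auc_b = auc_mann_whitney(b, y)
    va10, va01 = _placements(a, y)
    vb10, vb01 = _placements(b, y)
    n1, n0 = len(va10), len(va01)
    diff = auc_a - auc_b
    if n1 > 1 and n0 > 1:
        s10 = np.cov(np.vstack([va10, vb10]))
        s01 = np.cov(np.vstack([va01, vb01]))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 + \
              (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    else:
        var = 0.0
    if var <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
        z = float("inf") if p == 0.0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "difference": diff,
            "z": float(z), "p_value": p}
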