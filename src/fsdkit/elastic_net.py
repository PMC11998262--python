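"""Penalized logistic regression for predictors of FSD caseness.

The model is binary logistic regression with the elastic-net penalty

    min_{b0, b}  (1/n) * sum_i log(1 + exp(-z_i (b0 + x_i' b)))
                 + lambda * [ (1-alpha)/2 * ||b||_2^2 + alpha * ||b||_1 ]

(intercept unpenalized; z_i = +/-1). alpha blends ridge (0) and lasso
(1); lambda is the penalty strength. Data are split 80/20 into training
and test; (alpha, lambda) are chosen by 10-fold cross-validation on the
training set, either at the loss minimum (lambda_min) or by the
one-standard-error rule (lambda_1se: the largest lambda whose mean CV
loss is within one SE of the minimum, at the chosen alpha). Continuous
predictors are standardized with training-set statistics only. Accuracy
is summarized by the AUC on the held-out test set.

The solver is iteratively reweighted coordinate descent (outer
quadratic approximation of the log-likelihood, inner cyclic coordinate
descent with soft thresholding), warm-started along the lambda path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DiseaseCatalog
from .errors import ContractViolation

#: Table-5-style predictor set for the caseness model.
DESIGN_FEATURES = (
    "musculoskeletal_condition", "gastrointestinal_condition",
    "cardiorespiratory_condition", "neurological_condition",
    "concurrent_anxiety", "concurrent_depression",
    "providers_visited", "ldi", "lte", "loneliness", "neuroticism", "ctq",
    "work_hours", "eq5d", "male", "age", "ethnicity_other",
    "education_medium", "education_high",
    "household_size", "relationship_duration",
)

CONTINUOUS_FEATURES = ("providers_visited", "ldi", "lte", "loneliness",
                       "neuroticism", "ctq", "work_hours", "eq5d", "age",
                       "household_size", "relationship_duration")


# ---------------------------------------------------------------------------
# Design matrix

def build_design_matrix(records, classifications,
                        disease_catalog: Optional[DiseaseCatalog] = None,
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the complete-case design matrix and caseness outcome.

    Chronic-disease predictors are plain per-system indicators (a disease
    from that system is present), not the same-system specifier — the
    specifier is false for every non-case by construction and would be a
    perfect separator.
    """
    disease_catalog = disease_catalog or DiseaseCatalog.default()
    by_id = {c.respondent_id: c for c in classifications}
    rows, outcomes = [], []
    for rec in records:
        cls = by_id.get(rec.respondent_id)
        if cls is None:
            continue
        systems = {disease_catalog.system_of(code) for code in rec.chronic_diseases}
        row = {
            "musculoskeletal_condition": float("musculoskeletal" in systems),
            "gastrointestinal_condition": float("gastrointestinal" in systems),
            "cardiorespiratory_condition": float("cardiorespiratory" in systems),
            "neurological_condition": float("neurological_other" in systems),
            "concurrent_anxiety": None if rec.mini_anxiety is None else float(rec.mini_anxiety),
            "concurrent_depression": None if rec.mini_depression is None else float(rec.mini_depression),
            "providers_visited": rec.providers_visited,
            "ldi": rec.ldi, "lte": rec.lte, "loneliness": rec.loneliness,
            "neuroticism": rec.neuroticism, "ctq": rec.ctq,
            "work_hours": rec.work_hours, "eq5d": rec.eq5d,
            "male": None if rec.sex is None else float(rec.sex == "male"),
            "age": rec.age,
            "ethnicity_other": None if rec.ethnicity is None else float(rec.ethnicity == "other"),
            "education_medium": None if rec.education is None else float(rec.education == "medium"),
            "education_high": None if rec.education is None else float(rec.education == "high"),
            "household_size": rec.household_size,
            "relationship_duration": rec.relationship_duration,
        }
        rows.append(row)
        outcomes.append(float(cls.is_case))
    X = pd.DataFrame(rows, columns=list(DESIGN_FEATURES), dtype=float)
    y = pd.Series(outcomes, name="is_case", dtype=float)
    keep = ~X.isna().any(axis=1)
    return X.loc[keep].reset_index(drop=True), y.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Split / standardize

def split_train_test(n: int, fraction_test: float = 0.2,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Reproducible disjoint, exhaustive 80/20 index partition."""
    if n < 10:
        raise ContractViolation("split_train_test needs n >= 10")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * fraction_test))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


@dataclass
class Standardizer:
    """Mean/SD scaling of selected columns, fitted on training data only."""

    columns: tuple
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)

    @classmethod
    def fit(cls, X: pd.DataFrame,
            columns: Optional[Sequence[str]] = None) -> "Standardizer":
        if columns is None:
            columns = [c for c in X.columns if X[c].nunique() > 2]
        self = cls(tuple(columns))
        for c in self.columns:
            self.means[c] = float(X[c].mean())
            sd = float(X[c].std(ddof=0))
            self.sds[c] = sd if sd > 0 else 1.0
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for c in self.columns:
            out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out


# ---------------------------------------------------------------------------
# Solver

def _soft_threshold(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def fit_penalized_logistic(X, y, alpha: float, lam: float,
                           tol: float = 1e-8, max_iter: int = 200,
                           warm_start: Optional[tuple] = None,
                           ) -> tuple[float, np.ndarray]:
    """Fit the elastic-net logistic objective; returns (intercept, coef).

    Outer loop: quadratic (IRLS) approximation of the mean negative
    log-likelihood at the current estimate; inner loop: cyclic coordinate
    descent with soft thresholding on the penalized weighted least
    squares, intercept unpenalized. Converges when no parameter moves by
    more than ``tol`` in an outer iteration. lam = 0 gives the
    unpenalized MLE; with separable data the iteration cap bounds the
    divergence.

    ``warm_start=(intercept, coef)`` seeds the solver (used along the
    lambda path).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))) or classes.size > 2:
        raise ContractViolation("y must be binary 0/1")
    if lam < 0 or not (0.0 <= alpha <= 1.0):
        raise ContractViolation("need lambda >= 0 and alpha in [0, 1]")
    n, p = X.shape

    if warm_start is not None:
        b0, beta = float(warm_start[0]), np.asarray(warm_start[1], float).copy()
    else:
        pbar = min(max(y.mean(), 1e-9), 1 - 1e-9)
        b0, beta = float(np.log(pbar / (1 - pbar))), np.zeros(p)

    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)
    for _ in range(max_iter):
        eta = b0 + X @ beta
        prob = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-9, 1 - 1e-9)
        w = np.maximum(prob * (1.0 - prob), 1e-5)
        z = eta + (y - prob) / w
        r = z - eta                      # working residual
        wsum = w.sum()
        wx = w[:, None] * X
        wx2 = np.einsum("ij,ij->j", wx, X)

        b0_old, beta_old = b0, beta.copy()
        for _sweep in range(1000):
            max_delta = 0.0
            for j in range(p):
                rho = (wx[:, j] @ r) / n + (wx2[j] / n) * beta[j]
                new = _soft_threshold(rho, l1) / (wx2[j] / n + l2)
                delta = new - beta[j]
                if delta != 0.0:
                    r -= X[:, j] * delta
                    beta[j] = new
                    max_delta = max(max_delta, abs(delta))
            delta0 = (w @ r) / wsum
            if delta0 != 0.0:
                b0 += delta0
                r -= delta0
                max_delta = max(max_delta, abs(delta0))
            if max_delta < tol * 0.1:
                break
        if max(abs(b0 - b0_old), float(np.max(np.abs(beta - beta_old)))
               if p else 0.0) < tol:
            break
    return b0, beta


def predict_proba(X, intercept: float, coef: np.ndarray) -> np.ndarray:
    eta = intercept + np.asarray(X, dtype=float) @ coef
    return 1.0 / (1.0 + np.exp(-eta))


def binomial_deviance(y, p) -> float:
    """Mean binomial deviance, -2/n * log-likelihood (clipped)."""
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def brier_score(y, p) -> float:
    return float(np.mean((np.asarray(p) - np.asarray(y)) ** 2))


_LOSSES = {"deviance": binomial_deviance, "brier": brier_score}


# ---------------------------------------------------------------------------
# Cross-validation

DEFAULT_ALPHA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


def make_lambda_grid(X, y, n_lambda: int = 20, ratio: float = 1e-3) -> np.ndarray:
    """Descending log-spaced lambda grid from the smallest all-zero
    lambda (lasso convention: max |x_j'(y - ybar)| / n) downwards."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / X.shape[0]
    lam_max = max(lam_max, 1e-4)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


@dataclass
class CVResult:
    path: pd.DataFrame            # alpha, lambda, mean_loss, se_loss
    alpha: float
    lambda_min: float
    lambda_1se: float
    loss: str
    k: int
    seed: int


def cross_validate(X, y, alpha_grid=DEFAULT_ALPHA_GRID,
                   lambda_grid=None, k: int = 10, seed: int = 0,
                   loss: str = "deviance", tol: float = 1e-6) -> CVResult:
    """k-fold CV over the (alpha, lambda) grid.

    Per grid point the mean and standard error of the held-fold loss are
    recorded; the selected alpha is the one whose minimum mean loss is
    lowest; lambda_min is that minimizer and lambda_1se the largest
    lambda (at that alpha) with mean loss <= min + 1 SE.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ContractViolation(f"k={k} folds exceed n={n} training rows")
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(X, y)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    alpha_grid = list(alpha_grid)
    if not alpha_grid or lambda_grid.size == 0:
        raise ContractViolation("alpha and lambda grids must be nonempty")

    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(fold_of)
    loss_fn = _LOSSES[loss]

    losses = {(alpha, lam): [] for alpha in alpha_grid for lam in lambda_grid}
    for alpha in alpha_grid:
        for fold in range(k):
            test = fold_of == fold
            warm = None
            for lam in lambda_grid:        # descending: warm-started path
                b0, b = fit_penalized_logistic(X[~test], y[~test], alpha, lam,
                                               tol=tol, warm_start=warm)
                warm = (b0, b)
                losses[(alpha, lam)].append(
                    loss_fn(y[test], predict_proba(X[test], b0, b)))
    rows = []
    for alpha in alpha_grid:
        for lam in lambda_grid:
            fold_losses = np.asarray(losses[(alpha, lam)])
            rows.append({"alpha": alpha, "lambda": lam,
                         "mean_loss": float(fold_losses.mean()),
                         "se_loss": float(fold_losses.std(ddof=1) / np.sqrt(k))})
    path = pd.DataFrame(rows)

    best = path.loc[path["mean_loss"].idxmin()]
    alpha_star = float(best["alpha"])
    sub = path[path["alpha"] == alpha_star]
    lambda_min = float(best["lambda"])
    cutoff = float(best["mean_loss"] + best["se_loss"])
    eligible = sub[sub["mean_loss"] <= cutoff]
    lambda_1se = float(eligible["lambda"].max())
    return CVResult(path=path, alpha=alpha_star, lambda_min=lambda_min,
                    lambda_1se=lambda_1se, loss=loss, k=k, seed=seed)


# ---------------------------------------------------------------------------
# AUC

def evaluate_auc(scores, labels) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), via the midrank
    (Mann–Whitney) formula."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractViolation("evaluate_auc needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# End-to-end fit and reporting

@dataclass
class PenalizedFit:
    feature_names: tuple
    intercept: float
    coefficients: np.ndarray      # standardized scale
    odds_ratios: np.ndarray
    alpha: float
    lambda_: float
    selection_rule: str           # "lambda_min" | "lambda_1se"
    cv: CVResult
    auc_test: float
    train_index: np.ndarray
    test_index: np.ndarray
    seed: int


def fit_caseness_model(X: pd.DataFrame, y: pd.Series,
                       alpha_grid=DEFAULT_ALPHA_GRID, lambda_grid=None,
                       k: int = 10, seed: int = 0, loss: str = "deviance",
                       selection_rule: str = "lambda_1se") -> PenalizedFit:
    """The full procedure: 80/20 split, training-set standardization,
    10-fold CV over (alpha, lambda), final fit at the selected point,
    AUC on the held-out test set."""
    if selection_rule not in ("lambda_min", "lambda_1se"):
        raise ContractViolation(f"unknown selection rule {selection_rule!r}")
    train_idx, test_idx = split_train_test(len(X), seed=seed)
    scaler = Standardizer.fit(X.iloc[train_idx])
    X_train = scaler.transform(X.iloc[train_idx]).to_numpy(dtype=float)
    X_test = scaler.transform(X.iloc[test_idx]).to_numpy(dtype=float)
    y_train = y.iloc[train_idx].to_numpy(dtype=float)
    y_test = y.iloc[test_idx].to_numpy(dtype=float)

    cv = cross_validate(X_train, y_train, alpha_grid=alpha_grid,
                        lambda_grid=lambda_grid, k=k, seed=seed, loss=loss)
    lam = cv.lambda_1se if selection_rule == "lambda_1se" else cv.lambda_min
    b0, b = fit_penalized_logistic(X_train, y_train, cv.alpha, lam)
    auc = evaluate_auc(predict_proba(X_test, b0, b), y_test)
    return PenalizedFit(tuple(X.columns), b0, b, np.exp(b), cv.alpha, lam,
                        selection_rule, cv, auc, train_idx, test_idx, seed)


def report_model(fit: PenalizedFit) -> pd.DataFrame:
    """Listing of features sorted by |coefficient|; zeroed features print
    '.' (they do not contribute to the model), odds ratios to 2 d.p."""
    order = np.argsort(-np.abs(fit.coefficients), kind="stable")
    rows = []
    for i in order:
        coef = fit.coefficients[i]
        rows.append({
            "feature": fit.feature_names[i],
            "coefficient": "." if coef == 0 else f"{coef:.4f}",
            "odds_ratio": "." if coef == 0 else f"{fit.odds_ratios[i]:.2f}",
        })
    return pd.DataFrame(rows, columns=["feature", "coefficient", "odds_ratio"])
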