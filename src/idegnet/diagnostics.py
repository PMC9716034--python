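"""Diagnostic-signature evaluation with four classifier families.

The key-gene signature is evaluated on a stratified 7:3 train/test split
shared by all families so AUCs are comparable: L1-penalized logistic
regression (lambda by minimum cross-validated deviance), random forest
(Gini and permutation-accuracy importances), gradient-boosted trees
(gain importance) and an RBF support-vector machine on standardized
inputs.  AUC is the Mann-Whitney pair-counting probability that a random
case outscores a random control, ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .study import GROUP_CASE, ExpressionStudy


# ---------------------------------------------------------------------------
# Split
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    train: list[str]
    test: list[str]
    ratio: float
    stratified: bool
    seed: int


def split_7_3(study: ExpressionStudy, seed: int = 0, ratio: float = 0.7,
              stratified: bool = True) -> SplitSpec:
    """Stratified random split; train size = round(ratio * n) per class."""
    groups = study.groups
    if stratified:
        classes = sorted(set(groups))
    else:
        classes = [None]
    rng = np.random.default_rng(seed)
    # total train size is round(ratio * n); class quotas by largest remainder
    n_total = len(groups)
    n_train_total = int(round(ratio * n_total))
    sizes = {c: (n_total if c is None else int((groups == c).sum()))
             for c in classes}
    quota = {c: int(np.floor(ratio * sizes[c])) for c in classes}
    leftover = n_train_total - sum(quota.values())
    frac_order = sorted(classes, key=lambda c: (-(ratio * sizes[c]
                                                 - quota[c]), str(c)))
    for c in frac_order[:leftover]:
        quota[c] += 1
    train: list[str] = []
    test: list[str] = []
    for cls in classes:
        members = list(groups.index if cls is None else groups.index[groups == cls])
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        perm = rng.permutation(len(members))
        n_train = min(max(quota[cls], 1), len(members) - 1)
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return SplitSpec(train=sorted(train), test=sorted(test), ratio=ratio,
                     stratified=stratified, seed=seed)


def _design(study: ExpressionStudy, genes, samples) -> tuple[np.ndarray, np.ndarray]:
    x = study.expr.loc[list(genes), list(samples)].to_numpy(dtype=float).T
    y = (study.groups.loc[list(samples)] == GROUP_CASE).to_numpy(dtype=int)
    return x, y


# ---------------------------------------------------------------------------
# LASSO logistic regression with CV-chosen lambda
# ---------------------------------------------------------------------------

@dataclass
class LassoModel:
    features: list[str]
    coef: np.ndarray             # on the original expression scale
    intercept: float
    lam: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray      # mean held-out binomial deviance per lambda
    rule: str = "lambda.min"

    def score(self, expression: pd.Series | dict,
              include_intercept: bool = False) -> float:
        """Linear signature score sum(coef_i * expr_i); intercept optional.

        The printed form of such signatures omits the intercept, so the
        default mirrors that; pass ``include_intercept=True`` for the
        full linear predictor.
        """
        vals = []
        for f in self.features:
            try:
                vals.append(float(expression[f]))
            except (KeyError, IndexError):
                raise KeyError(f"expression vector lacks feature {f!r}")
        s = float(np.dot(self.coef, vals))
        return s + self.intercept if include_intercept else s


def _fit_l1_at(x_std: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """L1 logistic fit at one lambda on standardized features.

    glmnet-style objective (1/n) * deviance/2 ... the sklearn C mapping is
    C = 1 / (n * lam).  lam == 0 falls back to an unpenalized fit.
    """
    n = x_std.shape[0]
    if lam <= 0:
        clf = LogisticRegression(C=np.inf, max_iter=5000, tol=1e-10)
    else:
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
            max_iter=5000, tol=1e-10,
        )
    clf.fit(x_std, y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_lasso(study: ExpressionStudy, genes, samples, folds: int = 10,
              seed: int = 0, n_lambda: int = 100) -> LassoModel:
    """L1 logistic regression; lambda at minimum mean CV deviance.

    The lambda grid is log-spaced over four decades below lambda_max (the
    smallest penalty zeroing every coefficient).  Coefficients are mapped
    back to the original expression scale.
    """
    x, y = _design(study, genes, samples)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if len(set(y)) < 2:
        raise ValueError("training labels contain a single class")

    scaler = StandardScaler().fit(x)
    x_std = scaler.transform(x)
    n = x.shape[0]
    ybar = y.mean()
    lam_max = np.abs(x_std.T @ (y - ybar)).max() / n
    grid = np.geomspace(lam_max, lam_max * 1e-4, n_lambda)

    folds = min(folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(seed) % (2**32))
    dev = np.zeros((folds, n_lambda))
    for k, (tr, te) in enumerate(skf.split(x_std, y)):
        if len(set(y[tr])) < 2:
            raise ValueError("a CV fold lost one class")
        for j, lam in enumerate(grid):
            coef, icpt = _fit_l1_at(x_std[tr], y[tr], lam)
            eta = x_std[te] @ coef + icpt
            dev[k, j] = _binomial_deviance(y[te], eta)
    mean_dev = dev.mean(axis=0)
    j_best = int(np.argmin(mean_dev))
    lam = float(grid[j_best])

    coef_std, icpt_std = _fit_l1_at(x_std, y, lam)
    coef = coef_std / scaler.scale_
    intercept = icpt_std - float(np.dot(coef, scaler.mean_))
    return LassoModel(features=list(genes), coef=coef, intercept=intercept,
                      lam=lam, lambda_grid=grid, cv_deviance=mean_dev)


# ---------------------------------------------------------------------------
# Tree and kernel families
# ---------------------------------------------------------------------------

@dataclass
class ModelEval:
    family: str
    auc: float
    importance: dict[str, float] = field(default_factory=dict)
    importance_alt: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    extras: dict = field(default_factory=dict)


def fit_rf(study: ExpressionStudy, genes, train, test, trees: int = 500,
           seed: int = 0) -> ModelEval:
    """Random forest; Gini (impurity-decrease) and permutation-accuracy
    importances are both reported."""
    x_tr, y_tr = _design(study, genes, train)
    x_te, y_te = _design(study, genes, test)
    if len(set(y_tr)) < 2:
        raise ValueError("training labels contain a single class")
    rf = RandomForestClassifier(n_estimators=trees, random_state=int(seed) % (2**32),
                                n_jobs=1)
    rf.fit(x_tr, y_tr)
    gini = dict(zip(genes, rf.feature_importances_))
    perm = permutation_importance(rf, x_tr, y_tr, n_repeats=10,
                                  random_state=int(seed) % (2**32), n_jobs=1)
    acc = dict(zip(genes, perm.importances_mean))
    scores = rf.predict_proba(x_te)[:, 1]
    return ModelEval("RF", roc_auc(scores, y_te), importance=gini,
                     importance_alt=acc, seed=seed)


def fit_boost(study: ExpressionStudy, genes, train, test, rounds: int = 100,
              depth: int = 3, seed: int = 0) -> ModelEval:
    """Gradient-boosted trees (logistic loss) with gain importance."""
    x_tr, y_tr = _design(study, genes, train)
    x_te, y_te = _design(study, genes, test)
    if len(set(y_tr)) < 2:
        raise ValueError("training labels contain a single class")
    booster = XGBClassifier(
        n_estimators=rounds, max_depth=depth, learning_rate=0.3,
        objective="binary:logistic", random_state=int(seed) % (2**32),
        n_jobs=1, verbosity=0, eval_metric="logloss",
    )
    booster.fit(x_tr, y_tr)
    raw = booster.get_booster().get_score(importance_type="gain")
    gain = {g: float(raw.get(f"f{i}", 0.0)) for i, g in enumerate(genes)}
    scores = booster.predict_proba(x_te)[:, 1]
    return ModelEval("XGBoost", roc_auc(scores, y_te), importance=gain,
                     seed=seed)


def fit_svm(study: ExpressionStudy, genes, train, test, kernel: str = "rbf",
            seed: int = 0) -> ModelEval:
    """SVM on train-standardized inputs; decision scores feed the ROC."""
    x_tr, y_tr = _design(study, genes, train)
    x_te, y_te = _design(study, genes, test)
    if len(set(y_tr)) < 2:
        raise ValueError("training labels contain a single class")
    scaler = StandardScaler().fit(x_tr)
    svm = SVC(kernel=kernel, random_state=int(seed) % (2**32))
    svm.fit(scaler.transform(x_tr), y_tr)
    scores = svm.decision_function(scaler.transform(x_te))
    return ModelEval("SVM", roc_auc(scores, y_te), seed=seed)


def eval_lasso(model: LassoModel, study: ExpressionStudy, test,
               seed: int = 0) -> ModelEval:
    x_te, y_te = _design(study, model.features, test)
    scores = x_te @ model.coef + model.intercept
    imp = {f: float(abs(c)) for f, c in zip(model.features, model.coef)}
    return ModelEval("LASSO", roc_auc(scores, y_te), importance=imp, seed=seed,
                     extras={"lambda": model.lam})


# ---------------------------------------------------------------------------
# AUC (Mann-Whitney pair counting)
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """P(case score > control score) + 0.5 P(tie), via midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def evaluate_models(study: ExpressionStudy, signature_genes, seed: int = 0,
                    split: SplitSpec | None = None) -> dict[str, ModelEval]:
    """Run all four families from one shared split; returns family -> eval."""
    genes = [g for g in signature_genes if g in study.genes]
    if len(genes) < 2:
        raise ValueError("signature needs at least 2 genes present")
    sp = split or split_7_3(study, seed=seed)
    lasso = fit_lasso(study, genes, sp.train, seed=seed)
    out = {
        "LASSO": eval_lasso(lasso, study, sp.test, seed=seed),
        "RF": fit_rf(study, genes, sp.train, sp.test, seed=seed),
        "XGBoost": fit_boost(study, genes, sp.train, sp.test, seed=seed),
        "SVM": fit_svm(study, genes, sp.train, sp.test, seed=seed),
    }
    out["LASSO"].extras["model"] = lasso
    return out
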