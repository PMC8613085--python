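"""Machine-learning stage: scaling, design assembly, fixed model
specifications, five-fold cross-validation and label-permutation tests.

Six model specifications are evaluated per task and prediction target:
three algorithms (L2 logistic regression / RBF support-vector machine /
50-tree random forest, plus their regression counterparts with ordinary
least squares in place of logistic regression) crossed with two design
modes — application-stage features only, or application − baseline
difference scores that absorb stable individual differences.

Significance of a cross-validated score is assessed against 500 refits
on permuted labels: the true model must beat the permuted score strictly
(ties count against it) at least 475 of 500 times for p < .05 and at
least 496 of 500 for the Bonferroni-corrected .0083 level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import RobustScaler
from sklearn.svm import SVC, SVR

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "CVResult",
    "PermutationResult",
    "CLASSIFIER_FAMILIES",
    "REGRESSOR_FAMILIES",
    "robust_scale",
    "make_design",
    "fit_predict_cv",
    "permutation_test",
    "evaluate_regression",
    "run_model_grid",
    "win_threshold",
]

CLASSIFIER_FAMILIES = (
    "linear_logistic",
    "rbf_svm_classifier",
    "random_forest_classifier",
)
REGRESSOR_FAMILIES = (
    "linear_least_squares",
    "rbf_svm_regressor",
    "random_forest_regressor",
)


@dataclass(frozen=True)
class ModelSpec:
    """One of the six fixed model specifications (no tuning).

    Hyperparameters are pinned: C = 1.0 and L2 penalty for the logistic
    model; RBF kernel with gamma = 1/(n_features × variance of the
    flattened feature matrix) and C = 1.0 for the SVMs; 50 trees and no
    depth limit for the random forests; OLS with intercept.
    """

    family: str

    def __post_init__(self):
        if self.family not in CLASSIFIER_FAMILIES + REGRESSOR_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    @property
    def is_classifier(self) -> bool:
        return self.family in CLASSIFIER_FAMILIES

    def build(self, seed: int | None = None):
        if self.family == "linear_logistic":
            # liblinear's default penalty is the L2 norm
            return LogisticRegression(solver="liblinear", C=1.0)
        if self.family == "rbf_svm_classifier":
            # gamma="scale" is exactly 1 / (n_features * X.var())
            return SVC(kernel="rbf", gamma="scale", C=1.0)
        if self.family == "random_forest_classifier":
            return RandomForestClassifier(
                n_estimators=50, max_depth=None, random_state=seed
            )
        if self.family == "linear_least_squares":
            return LinearRegression(fit_intercept=True)
        if self.family == "rbf_svm_regressor":
            return SVR(kernel="rbf", gamma="scale", C=1.0)
        return RandomForestRegressor(n_estimators=50, max_depth=None, random_state=seed)


@dataclass
class CVResult:
    """Per-fold and mean cross-validation scores."""

    fold_scores: list[float]
    design_mode: str = "application_only"

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.fold_scores))


@dataclass
class PermutationResult:
    """Label-permutation significance of a cross-validated score.

    ``wins`` counts permutations the true score strictly exceeds; ties
    count against the true model.  ``significant_at`` maps each alpha to
    whether wins reaches the corresponding threshold (475 and 496 for
    500 permutations at .05 and .0083).
    """

    true_score: float
    perm_scores: np.ndarray
    design_mode: str = "application_only"

    @property
    def n_perm(self) -> int:
        return len(self.perm_scores)

    @property
    def wins(self) -> int:
        return int(np.sum(self.perm_scores < self.true_score))

    @property
    def p_emp(self) -> float:
        return (self.n_perm - self.wins) / self.n_perm

    @property
    def significant_at(self) -> dict[float, bool]:
        return {
            alpha: self.wins >= win_threshold(alpha, self.n_perm)
            for alpha in (0.05, 0.0083)
        }


def win_threshold(alpha: float, n_perm: int = 500) -> int:
    """Minimum number of permutation wins for significance at ``alpha``.

    The true model must outperform at least ceil((1−alpha)·n_perm)
    permuted refits: 475 of 500 at alpha = .05, 496 of 500 at .0083.
    """
    return math.ceil((1.0 - alpha) * n_perm)


def robust_scale(X) -> np.ndarray:
    """Median/IQR column scaling; zero-IQR columns are centered only.

    Quantiles use linear interpolation (25th–75th percentile).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    med = np.median(X, axis=0)
    q25, q75 = np.percentile(X, [25, 75], axis=0)
    iqr = q75 - q25
    iqr = np.where(iqr == 0, 1.0, iqr)
    return (X - med) / iqr


def make_design(
    features: pd.DataFrame,
    mode: str,
    target: str = "condition",
    feature_cols: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, y, pids) from a tidy per-session feature table.

    ``features`` must hold one row per (pid, stage) with feature columns
    plus ``pid``, ``stage``, ``condition`` and any rating columns.  In
    ``application_only`` mode X is the application-stage feature block;
    in ``difference_score`` mode X (and a rating target) is application
    minus baseline, participants lacking a baseline are dropped with a
    warning.  ``target`` is ``condition`` (labels) or a rating column.
    """
    if mode not in ("application_only", "difference_score"):
        raise ValueError(f"unknown design mode {mode!r}")
    if feature_cols is None:
        reserved = {"pid", "task", "stage", "condition"}
        feature_cols = [
            c
            for c in features.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(features[c])
            and not c.startswith(("valence", "arousal"))
        ]
    app = features[features["stage"] == "application"].set_index("pid")
    if mode == "application_only":
        X = app[feature_cols].to_numpy(dtype=float)
        y = (
            app["condition"].to_numpy()
            if target == "condition"
            else app[target].to_numpy(dtype=float)
        )
        return X, y, app.index.tolist()

    base = features[features["stage"] == "baseline"].set_index("pid")
    shared = app.index.intersection(base.index)
    dropped = app.index.difference(base.index)
    if len(dropped):
        logger.warning(
            "difference_score design: dropping %d participants without a "
            "baseline: %s", len(dropped), ", ".join(map(str, dropped[:5])),
        )
    X = (
        app.loc[shared, feature_cols].to_numpy(dtype=float)
        - base.loc[shared, feature_cols].to_numpy(dtype=float)
    )
    if target == "condition":
        y = app.loc[shared, "condition"].to_numpy()
    else:
        y = (
            app.loc[shared, target].to_numpy(dtype=float)
            - base.loc[shared, target].to_numpy(dtype=float)
        )
    return X, y, shared.tolist()


def _cv_scores(X, y, spec: ModelSpec, k: int, seed: int, scale_in_cv: bool) -> list[float]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) < k:
        raise ValueError(f"need at least {k} rows for {k}-fold CV")
    if spec.is_classifier:
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("classification needs both classes present")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        if np.all(y == y.flat[0]):
            raise ValueError("constant target: R^2 undefined")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    if not scale_in_cv:
        X = robust_scale(X)
    scores = []
    for fold, (tr, te) in enumerate(splitter.split(X, y if spec.is_classifier else None)):
        if spec.is_classifier and len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold} is missing a class in training data")
        est = spec.build(seed=seed + fold if seed is not None else None)
        model = (
            Pipeline([("scale", RobustScaler()), ("model", est)])
            if scale_in_cv
            else est
        )
        model.fit(X[tr], y[tr])
        scores.append(float(model.score(X[te], y[te])))
    return scores


def fit_predict_cv(
    X,
    y,
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    design_mode: str = "application_only",
    scale_in_cv: bool = True,
) -> CVResult:
    """Seeded (stratified) k-fold CV; score is accuracy or R² per fold.

    The robust scaler is fit on each training fold only and applied to
    its test fold — no leakage.  ``scale_in_cv=False`` scales the whole
    matrix up front instead (the replication-oriented variant).
    """
    return CVResult(
        fold_scores=_cv_scores(X, y, spec, k, seed, scale_in_cv),
        design_mode=design_mode,
    )


def evaluate_regression(
    X, y, spec: ModelSpec, k: int = 5, seed: int = 0,
    design_mode: str = "application_only", scale_in_cv: bool = True,
) -> CVResult:
    """Cross-validated R² against each test fold's observations.

    The mean-of-training predictor scores exactly 0 on its own training
    data and at most 0 in expectation out of sample, so R² > 0 marks a
    model that beats the null.
    """
    if spec.is_classifier:
        raise ValueError("evaluate_regression expects a regressor spec")
    return fit_predict_cv(
        X, y, spec, k=k, seed=seed, design_mode=design_mode, scale_in_cv=scale_in_cv
    )


def permutation_test(
    X,
    y,
    spec: ModelSpec,
    n_perm: int = 500,
    seed: int = 0,
    k: int = 5,
    design_mode: str = "application_only",
    scale_in_cv: bool = True,
) -> PermutationResult:
    """Label-permutation significance of the cross-validated score.

    Each permutation shuffles y and reruns the identical CV procedure
    with a freshly derived fold seed (re-partitioning per permutation);
    wins counts permutations whose score falls strictly below the true
    score.
    """
    rng = np.random.default_rng(seed)
    true = fit_predict_cv(
        X, y, spec, k=k, seed=seed, design_mode=design_mode, scale_in_cv=scale_in_cv
    )
    perm_scores = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        perm_seed = int(rng.integers(0, 2**31 - 1))
        perm_scores[i] = fit_predict_cv(
            X, y_perm, spec, k=k, seed=perm_seed, design_mode=design_mode,
            scale_in_cv=scale_in_cv,
        ).mean_score
    return PermutationResult(
        true_score=true.mean_score, perm_scores=perm_scores, design_mode=design_mode
    )


def run_model_grid(
    features: pd.DataFrame,
    task: str,
    target: str = "condition",
    n_perm: int = 500,
    k: int = 5,
    seed: int = 0,
    scale_in_cv: bool = True,
) -> pd.DataFrame:
    """Evaluate 3 algorithms × 2 design modes for one task and target.

    Classification rows (target ``condition``) carry the mean CV accuracy
    and permutation-test columns; regression rows (rating targets) carry
    the mean CV R², with permutation columns only where R² exceeds 0 —
    a model no better than the mean-predictor null needs no test.
    """
    families = CLASSIFIER_FAMILIES if target == "condition" else REGRESSOR_FAMILIES
    rows = []
    for mode in ("application_only", "difference_score"):
        X, y, _ = make_design(features, mode, target=target)
        for fam in families:
            spec = ModelSpec(fam)
            row = {
                "task": task,
                "target": target,
                "algorithm": fam,
                "design_mode": mode,
            }
            if target == "condition":
                res = permutation_test(
                    X, y, spec, n_perm=n_perm, seed=seed, k=k, scale_in_cv=scale_in_cv
                )
                row.update(
                    score=res.true_score,
                    wins=res.wins,
                    p_emp=res.p_emp,
                    sig_05=res.significant_at[0.05],
                    sig_0083=res.significant_at[0.0083],
                )
            else:
                cv = evaluate_regression(
                    X, y, spec, k=k, seed=seed, design_mode=mode,
                    scale_in_cv=scale_in_cv,
                )
                row["score"] = cv.mean_score
                if cv.mean_score > 0:
                    res = permutation_test(
                        X, y, spec, n_perm=n_perm, seed=seed, k=k,
                        design_mode=mode, scale_in_cv=scale_in_cv,
                    )
                    row.update(
                        wins=res.wins,
                        p_emp=res.p_emp,
                        sig_05=res.significant_at[0.05],
                        sig_0083=res.significant_at[0.0083],
                    )
            rows.append(row)
    return pd.DataFrame(rows)
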