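"""Classifier models and results for DSB site prediction.

Organised in the statsmodels style: a model object is built from a labeled
feature matrix, its ``fit()`` returns a results object carrying the learned
parameters (permutation variable importances for the forest, coefficients
for the logistic families), prediction, evaluation and a ``summary()``
table.

Three families are provided:

``RandomForestDSB``
    Bagged randomized decision trees (500 trees, mtry = floor(sqrt(p)) by
    default). Scores are vote fractions; variable importance is the mean
    decrease in out-of-bag accuracy under per-feature permutation.
``LassoLogisticDSB``
    L1-penalized logistic regression, penalty selected by cross-validated
    deviance; coefficients are reported on the original feature scale.
``LogisticDSB``
    Unpenalized maximum-likelihood logistic regression with Wald p-values,
    for significance assessment; refuses separable data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import auc as _auc
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from .intervals import IntervalSet

__all__ = [
    "LabeledDataset",
    "assemble_dataset",
    "DSBModel",
    "RandomForestDSB",
    "LassoLogisticDSB",
    "LogisticDSB",
    "DSBResults",
    "ForestResults",
    "LassoResults",
    "LogisticResults",
    "EvalResult",
    "evaluate",
    "evaluate_scores",
    "train_forest",
    "train_lasso",
    "train_logistic_unpenalized",
    "VennSummary",
    "venn_summary",
    "percentage",
    "SeparationError",
]


# ---------------------------------------------------------------------------
# Dataset assembly


@dataclass
class LabeledDataset:
    """Feature matrix + binary labels with a train/test row split."""

    features: pd.DataFrame
    labels: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(int)
        if len(self.labels) != len(self.features):
            raise ValueError("labels not aligned with feature rows")
        for name, idx in (("train", self.train_idx), ("test", self.test_idx)):
            classes = set(self.labels[idx])
            if classes != {0, 1}:
                raise ValueError(f"{name} split must contain both classes")

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def X_train(self) -> np.ndarray:
        return self.features.to_numpy()[self.train_idx]

    @property
    def y_train(self) -> np.ndarray:
        return self.labels[self.train_idx]

    @property
    def X_test(self) -> np.ndarray:
        return self.features.to_numpy()[self.test_idx]

    @property
    def y_test(self) -> np.ndarray:
        return self.labels[self.test_idx]


def assemble_dataset(
    pos: pd.DataFrame,
    neg: pd.DataFrame,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> LabeledDataset:
    """Stack positive and negative feature matrices and split stratified.

    Both matrices must carry identical feature columns (a mismatch raises,
    listing the symmetric difference). Labels are 1 for ``pos`` rows, 0 for
    ``neg``; the train/test split is stratified and reproducible by seed.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    if list(pos.columns) != list(neg.columns):
        diff = sorted(set(pos.columns) ^ set(neg.columns))
        raise ValueError(f"feature mismatch between classes: {diff or 'column order differs'}")
    features = pd.concat([pos, neg], axis=0, ignore_index=True)
    labels = np.r_[np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)]
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed
    )
    return LabeledDataset(features, labels, np.sort(train_idx), np.sort(test_idx), seed)


# ---------------------------------------------------------------------------
# Results


class DSBResults:
    """Base results object: learned parameters plus prediction and summary."""

    family = "base"

    def __init__(self, model: "DSBModel", feature_names: list[str], seed: int, hyperparams: dict):
        self.model = model
        self.feature_names = list(feature_names)
        self.seed = seed
        self.hyperparams = dict(hyperparams)

    # subclasses implement scoring on a raw array in training column order
    def _score(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def predict_proba(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Score sites in [0, 1]; DataFrames are aligned to training columns.

        Missing training features in a DataFrame raise — scores are never
        computed from silently zero-filled inputs.
        """
        if isinstance(features, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in features.columns]
            if missing:
                raise ValueError(f"features missing for scoring: {missing}")
            X = features[self.feature_names].to_numpy(dtype=float)
        else:
            X = np.asarray(features, dtype=float)
            if X.shape[1] != len(self.feature_names):
                raise ValueError("feature count mismatch")
        return self._score(X)

    def evaluate(
        self, data: LabeledDataset, n_boot: int = 2000, seed: int = 0
    ) -> "EvalResult":
        """ROC/PR evaluation on the dataset's test split."""
        scores = self.predict_proba(self.model._test_frame(data))
        return evaluate_scores(data.y_test, scores, n_boot=n_boot, seed=seed)

    def params_table(self) -> pd.DataFrame:  # pragma: no cover - abstract
        raise NotImplementedError

    def summary(self) -> str:
        """Human-readable parameter table, statsmodels style."""
        head = (
            f"{type(self).__name__} [{self.family}] "
            f"p={len(self.feature_names)} seed={self.seed}\n"
            + " ".join(f"{k}={v}" for k, v in self.hyperparams.items())
        )
        return head + "\n" + self.params_table().to_string(float_format=lambda v: f"{v: .4f}")


class ForestResults(DSBResults):
    family = "forest"

    def __init__(self, model, feature_names, seed, hyperparams, ensemble, importance):
        super().__init__(model, feature_names, seed, hyperparams)
        self.ensemble = ensemble
        self.importance = importance  # pd.Series, OOB permutation VI

    def _score(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros(len(X))
        for tree in self.ensemble.estimators_:
            votes += tree.predict(X)
        return votes / len(self.ensemble.estimators_)

    def importance_rank(self, feature: str) -> int:
        """1-based rank of a feature by variable importance (1 = most important)."""
        order = self.importance.sort_values(ascending=False).index
        return int(np.where(order == feature)[0][0]) + 1

    def params_table(self) -> pd.DataFrame:
        return (
            self.importance.rename("importance")
            .sort_values(ascending=False)
            .to_frame()
        )


class LassoResults(DSBResults):
    family = "lasso_logistic"

    def __init__(self, model, feature_names, seed, hyperparams, clf, coef, intercept, dropped):
        super().__init__(model, feature_names, seed, hyperparams)
        self.clf = clf
        self.coef = coef  # pd.Series on the original feature scale
        self.intercept = float(intercept)
        self.dropped_features = list(dropped)

    def _score(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + X @ self.coef.reindex(self.feature_names).to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.coef).rename("odds_ratio")

    def params_table(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.coef, "odds_ratio": np.exp(self.coef)})


class LogisticResults(DSBResults):
    family = "logistic"

    def __init__(self, model, feature_names, seed, hyperparams, sm_results):
        super().__init__(model, feature_names, seed, hyperparams)
        self.sm_results = sm_results
        params = sm_results.params
        self.intercept = float(params[0])
        self.coef = pd.Series(np.asarray(params[1:]), index=feature_names, name="beta")
        self.pvalues = pd.Series(
            np.asarray(sm_results.pvalues[1:]), index=feature_names, name="p"
        )

    def _score(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + X @ self.coef.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def params_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.coef, "odds_ratio": np.exp(self.coef), "p": self.pvalues}
        )


# ---------------------------------------------------------------------------
# Models


class SeparationError(RuntimeError):
    """Raised when unpenalized logistic regression meets separable data."""


class DSBModel:
    """Base model: holds a :class:`LabeledDataset`; ``fit`` returns results."""

    min_class_train = 20

    def __init__(self, data: LabeledDataset):
        self.data = data

    @classmethod
    def from_features(
        cls,
        pos: pd.DataFrame,
        neg: pd.DataFrame,
        test_fraction: float = 0.3,
        seed: int = 0,
    ) -> "DSBModel":
        return cls(assemble_dataset(pos, neg, test_fraction, seed))

    def _check_train(self) -> None:
        y = self.data.y_train
        if len(set(y)) < 2:
            raise ValueError("training split contains a single class")
        n1 = int(y.sum())
        if min(n1, len(y) - n1) < self.min_class_train:
            raise ValueError(
                f"need >= {self.min_class_train} training rows per class "
                f"(got {n1} / {len(y) - n1})"
            )

    def _test_frame(self, data: LabeledDataset) -> pd.DataFrame:
        return data.features.iloc[data.test_idx]

    def fit(self, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class RandomForestDSB(DSBModel):
    """Random forest: bagged trees with random feature subsetting at splits."""

    def fit(
        self,
        n_trees: int = 500,
        mtry: int | None = None,
        seed: int = 0,
        compute_importance: bool = True,
    ) -> ForestResults:
        self._check_train()
        p = len(self.data.feature_names)
        mtry = mtry or max(1, int(np.sqrt(p)))
        base = DecisionTreeClassifier(max_features=mtry, criterion="gini")
        ensemble = BaggingClassifier(
            estimator=base,
            n_estimators=n_trees,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
        X, y = self.data.X_train, self.data.y_train
        ensemble.fit(X, y)
        importance = (
            self._oob_permutation_importance(ensemble, X, y, seed)
            if compute_importance
            else pd.Series(np.nan, index=self.data.feature_names)
        )
        return ForestResults(
            self,
            self.data.feature_names,
            seed,
            {"n_trees": n_trees, "mtry": mtry},
            ensemble,
            importance,
        )

    def _oob_permutation_importance(
        self, ensemble: BaggingClassifier, X: np.ndarray, y: np.ndarray, seed: int
    ) -> pd.Series:
        """Mean decrease in out-of-bag accuracy under per-feature permutation.

        For each tree, accuracy on its out-of-bag rows is compared with the
        accuracy after permuting one feature column among those rows; the
        importance of the feature is the decrease averaged over trees.
        """
        rng = np.random.default_rng(seed)
        n, p = X.shape
        drops = np.zeros((len(ensemble.estimators_), p))
        used = np.zeros(len(ensemble.estimators_), dtype=bool)
        for t, (tree, samples) in enumerate(
            zip(ensemble.estimators_, ensemble.estimators_samples_)
        ):
            oob = np.setdiff1d(np.arange(n), samples)
            if oob.size == 0:
                continue
            used[t] = True
            Xo, yo = X[oob], y[oob]
            base_acc = float((tree.predict(Xo) == yo).mean())
            perm = rng.permutation(oob.size)
            for f in range(p):
                Xp = Xo.copy()
                Xp[:, f] = Xo[perm, f]
                drops[t, f] = base_acc - float((tree.predict(Xp) == yo).mean())
        vi = drops[used].mean(axis=0)
        return pd.Series(vi, index=self.data.feature_names, name="importance")


class LassoLogisticDSB(DSBModel):
    """L1-penalized logistic regression with cross-validated penalty."""

    def fit(self, n_folds: int = 10, seed: int = 0, n_penalties: int = 30) -> LassoResults:
        self._check_train()
        if len(self.data.train_idx) < 2 * n_folds:
            raise ValueError("too few training rows for the requested fold count")
        X, y = self.data.X_train.astype(float), self.data.y_train
        names = self.data.feature_names
        sd = X.std(axis=0)
        dropped = [names[i] for i in np.where(sd == 0)[0]]
        if dropped:
            import warnings

            warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
        keep = np.where(sd > 0)[0]
        kept_names = [names[i] for i in keep]
        Xk = X[:, keep]
        mu, sigma = Xk.mean(axis=0), Xk.std(axis=0)
        Z = (Xk - mu) / sigma
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        clf = LogisticRegressionCV(
            l1_ratios=(1.0,),
            solver="liblinear",
            Cs=n_penalties,
            cv=cv,
            scoring="neg_log_loss",
            random_state=seed,
            max_iter=2000,
        )
        clf.fit(Z, y)
        beta_std = clf.coef_.ravel()
        beta = pd.Series(0.0, index=names, name="beta")
        beta[kept_names] = beta_std / sigma
        intercept = float(clf.intercept_[0]) - float((beta_std * mu / sigma).sum())
        return LassoResults(
            self,
            names,
            seed,
            {"n_folds": n_folds, "C": float(clf.C_[0])},
            clf,
            beta,
            intercept,
            dropped,
        )


class LogisticDSB(DSBModel):
    """Unpenalized ML logistic regression with Wald p-values."""

    min_class_train = 5

    def fit(self, seed: int = 0) -> LogisticResults:
        import statsmodels.api as sm

        self._check_train()
        X = sm.add_constant(self.data.X_train.astype(float), has_constant="add")
        y = self.data.y_train
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels PerfectSeparationError et al.
            raise SeparationError(
                f"logistic fit failed ({exc}); data may be separable — "
                "use the penalized model instead"
            ) from exc
        fitted = res.predict(X)
        eps = 1e-8
        if np.all((fitted > 1 - eps) == (y == 1)) and np.all((fitted < eps) == (y == 0)):
            raise SeparationError(
                "perfect separation detected; coefficients diverge — "
                "use the penalized model instead"
            )
        if not np.isfinite(np.asarray(res.bse)).all():
            raise SeparationError(
                "non-finite standard errors (quasi-separation); "
                "use the penalized model instead"
            )
        return LogisticResults(self, self.data.feature_names, seed, {}, res)


# spec-facing functional wrappers --------------------------------------------


def train_forest(data: LabeledDataset, seed: int = 0, **kwargs) -> ForestResults:
    return RandomForestDSB(data).fit(seed=seed, **kwargs)


def train_lasso(data: LabeledDataset, n_folds: int = 10, seed: int = 0) -> LassoResults:
    return LassoLogisticDSB(data).fit(n_folds=n_folds, seed=seed)


def train_logistic_unpenalized(data: LabeledDataset, seed: int = 0) -> LogisticResults:
    return LogisticDSB(data).fit(seed=seed)


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvalResult:
    """ROC/PR curves, their areas, and a bootstrap CI for the AUROC."""

    roc_points: pd.DataFrame  # columns fpr, tpr
    pr_points: pd.DataFrame  # columns recall, precision
    auroc: float
    aupr: float
    auroc_ci: tuple[float, float]
    n_boot: int

    def summary(self) -> str:
        lo, hi = self.auroc_ci
        return (
            f"AUROC = {self.auroc:.3f} (95% CI [{lo:.3f}, {hi:.3f}], "
            f"{self.n_boot} bootstrap replicates); AUPR = {self.aupr:.3f}"
        )


def evaluate_scores(
    labels: np.ndarray,
    scores: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvalResult:
    """Threshold-sweep ROC and PR evaluation of continuous scores.

    AUROC is the trapezoid area under the ROC curve; AUPR is the step-wise
    (non-interpolated) integral of the PR curve. The CI is the 2.5/97.5
    percentile of the AUROC over ``n_boot`` plain bootstrap resamples of the
    evaluated rows (resamples that lose a class are redrawn).
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels)) < 2:
        raise ValueError("evaluation requires both classes")
    fpr, tpr, _ = roc_curve(labels, scores)
    auroc = float(_auc(fpr, tpr))
    precision, recall, _ = precision_recall_curve(labels, scores)
    aupr = float(average_precision_score(labels, scores))
    ci = (float("nan"), float("nan"))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(labels)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            while True:
                idx = rng.integers(0, n, n)
                yb = labels[idx]
                if yb.min() != yb.max():
                    break
            fb, tb, _ = roc_curve(yb, scores[idx])
            boots[b] = _auc(fb, tb)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return EvalResult(
        pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pd.DataFrame({"recall": recall, "precision": precision}),
        auroc,
        aupr,
        ci,
        n_boot,
    )


def evaluate(
    results: DSBResults,
    data: LabeledDataset,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvalResult:
    """Evaluate fitted results on the dataset's test split."""
    return results.evaluate(data, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Venn summaries


def percentage(part: int, whole: int) -> float:
    """100 * part / whole rounded half-up to 2 decimal places."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    frac = Decimal(100) * Decimal(part) / Decimal(whole)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class VennSummary:
    """Three-set overlap summary between predictions and two reference sets.

    For each of the three interval sets, its intervals are classified by
    >= 1-base overlap with the other two; ``counts`` maps a set name to the
    counts of its four membership cells, e.g. ``counts['refA']['pred']`` is
    the number of refA intervals overlapping a prediction (regardless of
    refB). Percentages are derived with :func:`percentage` (half-up, 2 d.p.).
    """

    counts: dict[str, dict[str, int]]

    def pct(self, set_name: str, cell: str) -> float:
        total = self.counts[set_name]["total"]
        return percentage(self.counts[set_name][cell], total)


def venn_summary(
    pred: IntervalSet, refA: IntervalSet, refB: IntervalSet
) -> VennSummary:
    """Classify each set's intervals by overlap with the other two sets."""

    def classify(base: IntervalSet, o1: IntervalSet, o2: IntervalSet, k1: str, k2: str):
        cells = {"total": len(base), k1: 0, k2: 0, "both": 0, "neither": 0}
        for iv in base:
            in1 = o1.overlaps_any(iv.chrom, iv.start, iv.end)
            in2 = o2.overlaps_any(iv.chrom, iv.start, iv.end)
            if in1:
                cells[k1] += 1
            if in2:
                cells[k2] += 1
            if in1 and in2:
                cells["both"] += 1
            if not in1 and not in2:
                cells["neither"] += 1
        return cells

    return VennSummary(
        {
            "pred": classify(pred, refA, refB, "refA", "refB"),
            "refA": classify(refA, pred, refB, "pred", "refB"),
            "refB": classify(refB, pred, refA, "pred", "refA"),
        }
    )
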