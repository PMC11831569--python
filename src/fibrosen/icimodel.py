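"""Immune-checkpoint-inhibitor response modeling harness.

Cohorts are merged after per-cohort gene-wise standardization (a declared,
rank-preserving surrogate for empirical-Bayes batch correction), split
80:20 with stratified largest-remainder allocation, and a cross-validated
classifier (gradient boosting, or a logistic baseline) is trained on
signature-gene features. Evaluation uses the Mann-Whitney formulation of
ROC AUC and Kaplan-Meier / log-rank comparison of predicted risk groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold

DEFAULT_GBM_GRID = {"n_estimators": [100], "learning_rate": [0.05, 0.1], "max_depth": [2, 3]}
DEFAULT_LOGISTIC_GRID = {"C": [0.1, 1.0, 10.0]}


def batch_standardize(expr: pd.DataFrame, cohort: pd.Series) -> pd.DataFrame:
    """Center and scale each gene to unit variance within each cohort.

    Genes with zero within-cohort variance are set to 0 there. Rank order
    within a cohort is preserved per gene. Singleton cohorts are rejected.
    """
    cohort = cohort.loc[expr.index]
    sizes = cohort.value_counts()
    singletons = sizes.index[sizes < 2].tolist()
    if singletons:
        raise ValueError(f"cohort(s) with a single sample cannot be standardized: {singletons}")

    def _z(block: pd.DataFrame) -> pd.DataFrame:
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        out = (block - mu).div(sd.replace(0.0, np.nan), axis=1)
        return out.fillna(0.0)

    return expr.groupby(cohort, group_keys=False).apply(_z).loc[expr.index]


def partition_cohort(
    sample_ids: pd.Index | list,
    labels: pd.Series | np.ndarray | None = None,
    train_frac: float = 0.8,
    seed: int = 0,
) -> tuple[pd.Index, pd.Index]:
    """Seeded train/validation partition with stratified allocation.

    The training size is round-half-up of ``train_frac * n`` (821 samples at
    8:2 give 657 training and 164 validation). When labels are given, the
    per-class training allocation follows the largest-remainder rule so the
    class proportions match the global split within one sample; a class too
    small to appear in both splits triggers an unstratified fallback.
    """
    ids = pd.Index(sample_ids)
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 samples to partition")
    n_train = int(np.floor(train_frac * n + 0.5))
    rng = np.random.default_rng(seed)

    if labels is not None:
        labels = pd.Series(np.asarray(labels), index=ids)
        classes = labels.value_counts().sort_index()
        quota = train_frac * classes.to_numpy(dtype=float)
        base = np.floor(quota).astype(int)
        remainder = quota - base
        short = n_train - base.sum()
        order = np.argsort(-remainder, kind="stable")
        alloc = base.copy()
        alloc[order[: max(short, 0)]] += 1
        if np.any(alloc == 0) or np.any(alloc == classes.to_numpy()):
            import warnings

            warnings.warn("a class would be absent from one split; falling back to unstratified")
        else:
            train_parts = []
            for cls, k in zip(classes.index, alloc):
                members = ids[labels == cls]
                train_parts.append(pd.Index(rng.permutation(members)[:k]))
            train = train_parts[0].append(train_parts[1:]) if len(train_parts) > 1 else train_parts[0]
            train = pd.Index([i for i in ids if i in set(train)])
            val = pd.Index([i for i in ids if i not in set(train)])
            return train, val

    shuffled = rng.permutation(ids)
    train_set = set(shuffled[:n_train])
    train = pd.Index([i for i in ids if i in train_set])
    val = pd.Index([i for i in ids if i not in train_set])
    return train, val


@dataclass
class ResponseModel:
    """A fitted response classifier with its CV record."""

    features: list[str]
    estimator: object
    model_kind: str
    cv_folds: int
    cv_repeats: int
    seed: int
    cv_auc: float
    best_params: dict
    cv_results: pd.DataFrame = field(repr=False, default=None)

    def predict_score(self, expr: pd.DataFrame) -> pd.Series:
        missing = [g for g in self.features if g not in expr.columns]
        if missing:
            raise ValueError(f"expression table missing model features: {missing[:5]}")
        probs = self.estimator.predict_proba(expr[self.features].to_numpy())[:, 1]
        return pd.Series(probs, index=expr.index, name="response_score")


def train_response_classifier(
    expr: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    model: str = "gbm",
    cv: tuple[int, int] = (10, 5),
    seed: int = 0,
    param_grid: dict | None = None,
) -> ResponseModel:
    """Grid-searched, repeated-CV classifier of responder status.

    ``labels`` uses 'R'/'NR' (or 1/0). The grid is selected by mean CV ROC
    AUC and the winner refit on the full training table.
    """
    y = pd.Series(np.asarray(labels), index=expr.index)
    y01 = y.map({"R": 1, "NR": 0}).fillna(y).astype(float).to_numpy()
    if len(np.unique(y01)) < 2:
        raise ValueError("both response classes must be present for training")
    k, r = cv
    if model == "gbm":
        base = GradientBoostingClassifier(random_state=seed)
        grid = param_grid or DEFAULT_GBM_GRID
    elif model == "logistic":
        base = LogisticRegression(max_iter=2000)
        grid = param_grid or DEFAULT_LOGISTIC_GRID
    else:
        raise ValueError(f"unknown model {model!r} (expected 'gbm' or 'logistic')")
    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=r, random_state=seed)
    search = GridSearchCV(base, grid, scoring="roc_auc", cv=splitter, refit=True, n_jobs=None)
    search.fit(expr.to_numpy(), y01)
    return ResponseModel(
        features=list(expr.columns),
        estimator=search.best_estimator_,
        model_kind=model,
        cv_folds=k,
        cv_repeats=r,
        seed=seed,
        cv_auc=float(search.best_score_),
        best_params=dict(search.best_params_),
        cv_results=pd.DataFrame(search.cv_results_),
    )


def roc_auc(scores: np.ndarray | pd.Series, labels: np.ndarray | pd.Series) -> float:
    """ROC AUC via the Mann-Whitney formulation (ties count one half)."""
    y = pd.Series(np.asarray(labels))
    y01 = y.map({"R": 1, "NR": 0}).fillna(y).astype(float).to_numpy()
    if len(np.unique(y01)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(y01, np.asarray(scores, dtype=float)))


@dataclass
class SurvivalComparison:
    """Two-group Kaplan-Meier curves plus the log-rank test."""

    km_curves: dict[str, pd.DataFrame]  # group -> columns (time, survival)
    logrank_stat: float
    p_value: float
    group_sizes: dict[str, int]


def kaplan_meier_logrank(
    times: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
) -> SurvivalComparison:
    """Product-limit curves per group and the two-group log-rank test."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups))
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    if events.sum() == 0:
        raise ValueError("no events observed in either group")
    curves, sizes = {}, {}
    for name in names:
        mask = groups == name
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[str(name)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        sizes[str(name)] = int(mask.sum())
    a = groups == names[0]
    res = logrank_test(times[a], times[~a], events[a], events[~a])
    return SurvivalComparison(
        km_curves=curves,
        logrank_stat=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes=sizes,
    )
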