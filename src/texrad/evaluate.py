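"""Repeated stratified cross-validated classification.

Linear-SVM and random-forest tuning grids are evaluated with a
k-fold cross-validation repeated R times (50 train/test fits per
hyperparameter at the defaults).  Standardization and, when requested,
filter feature selection (Mann-Whitney p-value or MIC ranking) are fit
inside each training fold so test folds never leak into model building.
Performance is the per-iteration AUC averaged over the k*R iterations
(mean +/- SD), alongside sensitivity/specificity/accuracy at the
classifiers' native decision thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from texrad.mic import DEFAULT_GRID_EXPONENT, mic_score
from texrad.pipeline import FeatureTable, standardize
from texrad.screen import mann_whitney_u


@dataclass(frozen=True)
class ModelGrid:
    """Hyperparameter grids of the two classifiers."""

    svm_C: tuple[float, ...] = (2**-3, 2**-2, 2**-1, 1.0, 2.0, 2**2, 2**3)
    rf_mtry: tuple[int, ...] = (2, 4, 6, 8, 10, 12)
    rf_ntree: int = 250

    def __post_init__(self) -> None:
        if not self.svm_C or not self.rf_mtry:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.rf_ntree < 1:
            raise ValueError("rf_ntree must be >= 1")

    def configs(self) -> list[tuple[str, float]]:
        return [("svm", c) for c in self.svm_C] + [("rf", m) for m in self.rf_mtry]


@dataclass(frozen=True)
class CVPlan:
    """Stratified k-fold plan repeated R times (always stratified)."""

    k: int = 5
    repeats: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def n_iterations(self) -> int:
        return self.k * self.repeats


@dataclass(frozen=True)
class RankingConfig:
    """Filter feature-ranking method used inside training folds."""

    method: str = "pvalue"
    mic_grid_exponent: float = DEFAULT_GRID_EXPONENT

    def __post_init__(self) -> None:
        if self.method not in ("pvalue", "mic"):
            raise ValueError("method must be 'pvalue' or 'mic'")
        if not (0 < self.mic_grid_exponent < 1):
            raise ValueError("mic_grid_exponent must be in (0, 1)")


def make_folds(labels, plan: CVPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train, test) positional index pairs for all k*R iterations.

    Repetition ``r`` shuffles with seed ``base_seed + r``; within a
    repetition the test folds partition the sample set with class
    proportions within one sample of the global proportions.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < plan.k:
        raise ValueError(f"smallest class has {counts.min()} samples; needs >= k={plan.k}")
    splits = []
    for r in range(plan.repeats):
        skf = StratifiedKFold(n_splits=plan.k, shuffle=True,
                              random_state=plan.base_seed + r)
        for train, test in skf.split(np.zeros(len(labels)), labels):
            splits.append((train, test))
    return splits


def roc_auc(scores, labels) -> float:
    """Probability that a random positive outranks a random negative.

    Ties count one half (equivalently the trapezoidal ROC area).  NaN when
    only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def rank_features(train: FeatureTable, cfg: RankingConfig) -> list[str]:
    """Feature names ordered by decreasing univariate discriminative power.

    ``pvalue``: ascending two-sided Mann-Whitney p.  ``mic``: descending
    MIC against the label.  Ties are broken by feature name so the ranking
    is stable and deterministic.
    """
    labels = train.labels.to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("ranking requires both classes in the training rows")
    keys = []
    for col in train.data.columns:
        values = train.data[col].to_numpy(dtype=float)
        if cfg.method == "pvalue":
            _, p = mann_whitney_u(values[labels == 1], values[labels == 0])
            keys.append((p, col))
        else:
            m = mic_score(values, labels.astype(float), cfg.mic_grid_exponent)
            keys.append((-m, col))
    return [col for _, col in sorted(keys)]


def _iteration_seed(base_seed: int, rep: int, fold: int, config_idx: int) -> int:
    ss = np.random.SeedSequence([base_seed, rep, fold, config_idx])
    return int(ss.generate_state(1)[0])


def _fit_score(kind: str, param: float, grid: ModelGrid, seed: int,
               x_train, y_train, x_test) -> np.ndarray:
    """Continuous test-fold scores of one fitted model.

    SVM scores are signed distances to the hyperplane (threshold 0); RF
    scores are the fraction of trees voting positive (threshold 0.5).
    """
    if kind == "svm":
        model = SVC(kernel="linear", C=param)
        model.fit(x_train, y_train)
        return model.decision_function(x_test)
    model = RandomForestClassifier(
        n_estimators=grid.rf_ntree,
        max_features=min(int(param), x_train.shape[1]),
        random_state=seed,
    )
    model.fit(x_train, y_train)
    return model.predict_proba(x_test)[:, 1]


_THRESHOLD = {"svm": 0.0, "rf": 0.5}


@dataclass
class ConfigResult:
    """Per-iteration metrics of one (model, hyperparameter[, top_k]) config."""

    model: str
    param: float
    top_k: int | None
    aucs: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    accuracies: np.ndarray
    n_failed: int = 0

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.nanstd(self.aucs, ddof=1))


@dataclass
class CVResult:
    """Full cross-validation traces for a hyperparameter grid."""

    configs: dict[tuple, ConfigResult]
    tested: dict[tuple, np.ndarray]    # per config: times each sample was in a test fold
    correct: dict[tuple, np.ndarray]   # per config: times each sample was classified right
    subject_ids: list[str]
    selection_trace: list[list[str]] = field(default_factory=list)
    n_iterations: int = 0

    def best(self, model: str) -> ConfigResult:
        """Config of one model family with the highest mean AUC."""
        candidates = [c for c in self.configs.values() if c.model == model]
        if not candidates:
            raise KeyError(f"no configs for model {model!r}")
        return max(candidates, key=lambda c: c.mean_auc)

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.configs.values():
            rows.append({
                "model": c.model, "param": c.param, "top_k": c.top_k,
                "mean_auc": c.mean_auc, "sd_auc": c.sd_auc,
                "mean_sensitivity": float(np.nanmean(c.sensitivities)),
                "mean_specificity": float(np.nanmean(c.specificities)),
                "mean_accuracy": float(np.nanmean(c.accuracies)),
                "n_failed": c.n_failed,
            })
        return pd.DataFrame(rows)


def evaluate(
    table: FeatureTable,
    grid: ModelGrid | None = None,
    plan: CVPlan | None = None,
    selection: RankingConfig | None = None,
    top_k: int | list[int] | None = None,
    standardize_mode: str = "fold",
) -> CVResult:
    """Repeated stratified k-fold evaluation of the whole tuning grid.

    When ``selection`` is given, features are ranked inside each training
    fold and the ``top_k`` best are used (a list sweeps several subset
    sizes on identical folds).  ``standardize_mode="fold"`` (default,
    leakage-safe) fits the scaler on training folds; ``"global"``
    standardizes the full table up front.

    Iterations whose training fold degenerates are flagged and excluded
    from the averages, never imputed.
    """
    grid = grid or ModelGrid()
    plan = plan or CVPlan()
    if standardize_mode not in ("fold", "global"):
        raise ValueError("standardize_mode must be 'fold' or 'global'")
    if selection is None:
        top_ks: list[int | None] = [None]
    else:
        if top_k is None:
            top_ks = list(range(1, table.n_features + 1))
        else:
            top_ks = [top_k] if isinstance(top_k, int) else list(top_k)

    if standardize_mode == "global":
        table = standardize(table)[0]

    labels = table.labels.to_numpy()
    folds = make_folds(labels, plan)
    model_configs = grid.configs()

    n = table.n_subjects
    keys = [(kind, param, k) for kind, param in model_configs for k in top_ks]
    metrics = {key: {m: np.full(len(folds), np.nan) for m in
                     ("auc", "sens", "spec", "acc")} for key in keys}
    failed = {key: 0 for key in keys}
    tested = {key: np.zeros(n, dtype=int) for key in keys}
    correct = {key: np.zeros(n, dtype=int) for key in keys}
    selection_trace: list[list[str]] = []

    for it, (train_idx, test_idx) in enumerate(folds):
        rep, fold = divmod(it, plan.k)
        train = table.subset_rows(table.data.index[train_idx])
        test = table.subset_rows(table.data.index[test_idx])
        y_train = train.labels.to_numpy()
        y_test = test.labels.to_numpy()
        if len(np.unique(y_train)) < 2:
            for key in keys:
                failed[key] += 1
            continue

        if standardize_mode == "fold":
            train, test, _ = standardize(train, test, on_zero_sd="unit")

        ranking = None
        if selection is not None:
            ranking = rank_features(train, selection)
            selection_trace.append(ranking)

        for cfg_idx, (kind, param) in enumerate(model_configs):
            seed = _iteration_seed(plan.base_seed, rep, fold, cfg_idx)
            for k in top_ks:
                if k is None:
                    cols = list(train.data.columns)
                else:
                    # keep table column order so a model sees the same design
                    # matrix regardless of rank permutations within the subset
                    chosen = set(ranking[:k])
                    cols = [c for c in train.data.columns if c in chosen]
                scores = _fit_score(kind, param, grid, seed,
                                    train.data[cols].to_numpy(), y_train,
                                    test.data[cols].to_numpy())
                key = (kind, param, k)
                pred = (scores > _THRESHOLD[kind]).astype(int)
                tp = int(((pred == 1) & (y_test == 1)).sum())
                tn = int(((pred == 0) & (y_test == 0)).sum())
                n_pos = int((y_test == 1).sum())
                n_neg = int((y_test == 0).sum())
                metrics[key]["auc"][it] = roc_auc(scores, y_test)
                metrics[key]["sens"][it] = tp / n_pos if n_pos else np.nan
                metrics[key]["spec"][it] = tn / n_neg if n_neg else np.nan
                metrics[key]["acc"][it] = (tp + tn) / len(y_test)
                tested[key][test_idx] += 1
                correct[key][test_idx] += (pred == y_test).astype(int)

    configs = {}
    for key in keys:
        kind, param, k = key
        m = metrics[key]
        configs[key] = ConfigResult(
            model=kind, param=param, top_k=k,
            aucs=m["auc"], sensitivities=m["sens"],
            specificities=m["spec"], accuracies=m["acc"],
            n_failed=failed[key],
        )
    return CVResult(
        configs=configs, tested=tested, correct=correct,
        subject_ids=list(table.data.index),
        selection_trace=selection_trace, n_iterations=len(folds),
    )


def selection_sweep(
    table: FeatureTable,
    grid: ModelGrid | None = None,
    plan: CVPlan | None = None,
    ranking: RankingConfig | None = None,
    top_ks: list[int] | None = None,
) -> tuple[pd.DataFrame, CVResult]:
    """Mean-AUC profile over feature-subset sizes under one ranking method.

    Returns a tidy profile (model, param, top_k, mean_auc, sd_auc) plus the
    underlying result.  The profile at ``top_k = m`` (all features) matches
    :func:`evaluate` without selection on the same plan.
    """
    ranking = ranking or RankingConfig(method="mic")
    result = evaluate(table, grid, plan, selection=ranking, top_k=top_ks)
    profile = result.summary().rename(columns={"top_k": "top_k"})
    return profile[["model", "param", "top_k", "mean_auc", "sd_auc"]], result


def argmax_k(profile: pd.DataFrame, model: str) -> tuple[int, float]:
    """Best subset size for one model family: (top_k, mean AUC over its grid best)."""
    sub = profile[profile["model"] == model]
    by_k = sub.groupby("top_k")["mean_auc"].max()
    best_k = int(by_k.idxmax())
    return best_k, float(by_k.max())


def sample_consistency(result: CVResult, key: tuple) -> pd.DataFrame:
    """Per-sample proportion of correct classifications for one config.

    Samples never tested get NaN and are flagged.
    """
    tested = result.tested[key].astype(float)
    correct = result.correct[key].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(tested > 0, correct / np.maximum(tested, 1), np.nan)
    return pd.DataFrame({
        "subject_id": result.subject_ids,
        "times_tested": result.tested[key],
        "times_correct": result.correct[key],
        "proportion_correct": prop,
        "never_tested": tested == 0,
    }).set_index("subject_id")


def consistency_intersection(
    a: pd.DataFrame, b: pd.DataFrame, threshold: float = 0.8
) -> pd.Series:
    """Samples classified correctly >= threshold of the time by BOTH configs."""
    return (a["proportion_correct"] >= threshold) & (b["proportion_correct"] >= threshold)


def bootstrap_pearson(
    x, y, n_boot: int = 1000, seed: int = 0, ci: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Sample Pearson r with a percentile bootstrap confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1D samples of size >= 3")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance sample")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(x)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if xb.std() == 0 or yb.std() == 0:
            reps[b] = np.nan
            continue
        reps[b] = np.corrcoef(xb, yb)[0, 1]
    reps = reps[np.isfinite(reps)]
    lo, hi = np.quantile(reps, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return r, (float(lo), float(hi))
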