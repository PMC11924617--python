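"""Two-stage fall-risk model with adaptive RWF routing.

Stage one fits the adaptive DDI threshold and, per candidate ``alpha``,
partitions the training subjects into RWF/DWF branches, selects features
per branch and scores the overall training accuracy with a fixed
default-hyperparameter surrogate classifier; the best ``alpha`` (ties to
the smallest) freezes the partition and feature sets.  Stage two selects
and tunes a classifier per branch from a seven-candidate roster, each with
exactly two tuned hyperparameters, under subject-grouped stratified CV.
Evaluation is leave-one-subject-out: every scaler, threshold, feature set
and classifier is refit without the held-out subject, whose windows are
routed through its own (unlabelled) DDI and aggregated by majority vote.

Feature selection is three-phase: a Student's t-test pre-selection, an
eleven-selector nomination stage (five filters, four wrappers, two
embedded), and a final cut by nomination frequency with the cardinality
chosen by subject-grouped cross-validated accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import sklearn
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .ddi import (
    DDIRecord,
    DWF,
    RWF,
    ThresholdModel,
    classify_type,
    compute_ddi,
    fit_threshold,
)
from .features import FeatureExtractor, Standardizer, table_vectors
from .io import (
    InsufficientDataError,
    Recording,
    RunConfig,
    ShortRecordingWarning,
    UndefinedFeatureError,
    UndefinedMetricsError,
    UndefinedMetricWarning,
    ValidationError,
    vectors_to_table,
    warn,
)
from .windows import cut_windows, discard_startup, plan_windows, segment_steps

logger = logging.getLogger("weakfoot")

POSITIVE = "HR"  # high fall risk is the positive class throughout


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalReport:
    """Confusion counts (HR positive) and the derived proportions."""

    tp: int
    tn: int
    fp: int
    fn: int
    sub_reports: dict[str, "EvalReport"] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        if denom == 0:
            warn(UndefinedMetricWarning, "F1 undefined (no positives anywhere); reporting 0")
            return 0.0
        return 2 * self.tp / denom

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        if denom == 0:
            warn(UndefinedMetricWarning, "sensitivity undefined (no positives); reporting 0")
            return 0.0
        return self.tp / denom

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        if denom == 0:
            warn(UndefinedMetricWarning, "specificity undefined (no negatives); reporting 0")
            return 0.0
        return self.tn / denom


def metrics(tp: int, tn: int, fp: int, fn: int) -> EvalReport:
    """Closed-form evaluation metrics from confusion counts."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValidationError("confusion counts must be non-negative")
    if sum(counts) == 0:
        raise UndefinedMetricsError("all confusion counts are zero")
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# Subject preparation (recordings -> per-window feature tables)
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """Per-subject window feature tables at the configured lengths."""

    subject_id: str
    label: str
    low: pd.DataFrame    # weak-foot vector features at the short length
    high: pd.DataFrame   # full registry at the long / stage-two length
    n_steps: int
    high_length: int     # the length actually used (may be shorter on short walks)


def recording_table(rec: Recording, config: RunConfig, length: int,
                    registry: Sequence[str] | None = None) -> pd.DataFrame:
    """Segment one recording and extract window features at one length."""
    registry = tuple(registry if registry is not None else config.registry)
    idx = segment_steps(rec, min_dur_ms=config.min_dur_ms, eps_frac=config.eps_frac)
    idx = discard_startup(idx, config.startup_discard)
    plan = plan_windows(len(idx), length, config.stride)
    extractor = FeatureExtractor(rec, idx, eps_frac=config.eps_frac)
    vectors = [extractor.extract(w, registry) for w in cut_windows(rec, idx, plan)]
    return vectors_to_table(vectors)


def prepare_subjects(recs: Sequence[Recording], config: RunConfig) -> list[SubjectData]:
    """Extract the low- and high-length window tables for every subject.

    A walk too short for the configured long length falls back to the
    longest length that still yields two windows, with a warning; a walk
    too short even for that is rejected.
    """
    out = []
    for rec in recs:
        idx = segment_steps(rec, min_dur_ms=config.min_dur_ms, eps_frac=config.eps_frac)
        idx = discard_startup(idx, config.startup_discard)
        S = len(idx)
        if S < config.low_length + config.stride:
            raise InsufficientDataError(
                f"{rec.subject_id}: only {S} steps; need >= "
                f"{config.low_length + config.stride} for the short windows"
            )
        high_len = config.high_length
        if S < high_len + config.stride:
            high_len = S - config.stride
            warn(ShortRecordingWarning,
                 f"{rec.subject_id}: {S} steps too short for L={config.high_length}; "
                 f"falling back to L={high_len}")
        extractor = FeatureExtractor(rec, idx, eps_frac=config.eps_frac)
        tables = {}
        for L, registry in ((config.low_length, config.weak_features),
                            (high_len, config.registry)):
            plan = plan_windows(S, L, config.stride)
            vecs = [extractor.extract(w, registry) for w in cut_windows(rec, idx, plan)]
            tables[L] = vectors_to_table(vecs)
        out.append(SubjectData(subject_id=rec.subject_id, label=rec.label,
                               low=tables[config.low_length], high=tables[high_len],
                               n_steps=S, high_length=high_len))
    return out


def _stack(subjects: Iterable[SubjectData], which: str = "high") -> pd.DataFrame:
    return pd.concat([getattr(s, which) for s in subjects], ignore_index=True)


def _xy(table: pd.DataFrame, names: Sequence[str]):
    X = table[list(names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        bad = [n for j, n in enumerate(names) if not np.all(np.isfinite(X[:, j]))]
        raise UndefinedFeatureError(bad)
    y = (table["label"].to_numpy() == POSITIVE).astype(int)
    groups = table["subject"].to_numpy()
    return X, y, groups


# ---------------------------------------------------------------------------
# Classifier roster
# ---------------------------------------------------------------------------

#: The two tuned hyperparameters per candidate (misclassification cost and
#: iteration budget for LR, neighbours/leaf size for KNN, cost/gamma for
#: SVM, depth/leaf size for the trees, estimators/learning rate for the
#: boosters).  Ensemble sizes are kept small; windows are few and heavily
#: overlapping, so larger ensembles only add runtime.
HYPER_GRIDS: dict[str, dict[str, list]] = {
    "LR": {"C": [1.0, 10.0], "max_iter": [50, 200]},
    "SVM": {"C": [1.0, 10.0], "gamma": ["scale", 0.1]},
    "KNN": {"n_neighbors": [3, 5], "leaf_size": [15, 30]},
    "DT": {"max_depth": [3, 8], "min_samples_leaf": [1, 5]},
    "RF": {"max_depth": [3, 8], "min_samples_leaf": [1, 5]},
    "GBDT": {"n_estimators": [8, 16], "learning_rate": [0.1, 0.5]},
    "AdaBoost": {"n_estimators": [8, 16], "learning_rate": [0.5, 1.0]},
}


def make_classifier(name: str, params: dict | None = None, seed: int = 0) -> Pipeline:
    """A (scaler, classifier) pipeline; no params -> library defaults."""
    params = dict(params or {})
    # cost-sensitive candidates weight classes inversely to frequency, so a
    # branch that lost most of one class after routing is not simply
    # overwhelmed by the majority label
    if name == "LR":
        clf = LogisticRegression(solver="liblinear", random_state=seed,
                                 class_weight="balanced", **params)
    elif name == "SVM":
        clf = SVC(random_state=seed, class_weight="balanced", **params)
    elif name == "KNN":
        clf = KNeighborsClassifier(**params)
    elif name == "DT":
        clf = DecisionTreeClassifier(random_state=seed,
                                     class_weight="balanced", **params)
    elif name == "RF":
        params.setdefault("n_estimators", 10)
        clf = RandomForestClassifier(random_state=seed,
                                     class_weight="balanced", **params)
    elif name == "GBDT":
        clf = GradientBoostingClassifier(random_state=seed, **params)
    elif name == "AdaBoost":
        clf = AdaBoostClassifier(random_state=seed, **params)
    else:
        raise ValidationError(f"unknown classifier {name!r}")
    return Pipeline([("scaler", StandardScaler()), ("clf", clf)])


class BranchFallback(Exception):
    """Signal: a branch cannot train its own model; use the pooled one."""


def grouped_cv(y: np.ndarray, groups: np.ndarray, n_splits: int, seed: int):
    """Subject-grouped stratified folds; folds missing a class are dropped."""
    uniq = np.unique(groups)
    n_splits = min(n_splits, len(uniq))
    if n_splits < 2:
        raise BranchFallback("not enough subjects for grouped CV")
    splitter = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    dummy = np.zeros((len(y), 1))
    folds = []
    for tr, te in splitter.split(dummy, y, groups):
        if len(np.unique(y[tr])) == 2 and len(te):
            folds.append((tr, te))
    if not folds:
        raise BranchFallback("no usable CV fold (a class is confined to one subject)")
    return folds


# ---------------------------------------------------------------------------
# Three-phase feature selection
# ---------------------------------------------------------------------------

def _lsq_accuracy(X: np.ndarray, y: np.ndarray) -> float:
    """In-sample accuracy of a least-squares linear discriminant."""
    yy = 2.0 * y - 1.0
    A = np.column_stack([np.ones(len(X)), X])
    w, *_ = np.linalg.lstsq(A, yy, rcond=None)
    return float(np.mean(np.where(A @ w >= 0, 1.0, -1.0) == yy))


def _centroid_accuracy(X: np.ndarray, y: np.ndarray) -> float:
    """In-sample accuracy of a nearest-centroid rule."""
    c0 = X[y == 0].mean(axis=0)
    c1 = X[y == 1].mean(axis=0)
    d0 = ((X - c0) ** 2).sum(axis=1)
    d1 = ((X - c1) ** 2).sum(axis=1)
    return float(np.mean((d1 < d0).astype(int) == y))


def _greedy_search(X: np.ndarray, y: np.ndarray, k: int, score, forward: bool) -> list[int]:
    p = X.shape[1]
    if forward:
        sel: list[int] = []
        while len(sel) < k:
            best_j, best_s = -1, -np.inf
            for j in range(p):
                if j in sel:
                    continue
                s = score(X[:, sel + [j]], y)
                if s > best_s:
                    best_j, best_s = j, s
            sel.append(best_j)
        return sel
    sel = list(range(p))
    while len(sel) > k:
        best_j, best_s = -1, -np.inf
        for j in sel:
            rest = [i for i in sel if i != j]
            s = score(X[:, rest], y)
            if s > best_s:
                best_j, best_s = j, s
        sel.remove(best_j)
    return sel


def _relief_weights(Xz: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Relief-style margin: |x - nearest miss| - |x - nearest hit|, summed."""
    D = squareform(pdist(Xz))
    np.fill_diagonal(D, np.inf)
    same = y[:, None] == y[None, :]
    d_hit = np.where(same, D, np.inf)
    d_miss = np.where(~same, D, np.inf)
    hit = np.argmin(d_hit, axis=1)
    miss = np.argmin(d_miss, axis=1)
    return np.abs(Xz - Xz[miss]).sum(axis=0) - np.abs(Xz - Xz[hit]).sum(axis=0)


def _binned_mutual_info(Xz: np.ndarray, y: np.ndarray, bins: int = 8) -> np.ndarray:
    """Mutual information of each (quantile-binned) feature with the class."""
    n, p = Xz.shape
    mi = np.zeros(p)
    py = np.bincount(y, minlength=2) / n
    qs = np.linspace(0, 1, bins + 1)[1:-1]
    for j in range(p):
        edges = np.quantile(Xz[:, j], qs)
        b = np.searchsorted(edges, Xz[:, j])
        joint = np.zeros((bins, 2))
        np.add.at(joint, (b, y), 1.0)
        joint /= n
        px = joint.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = joint * np.log(joint / (px[:, None] * py[None, :]))
        mi[j] = np.nansum(term)
    return mi


def _point_biserial(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = X.std(axis=0)
    sy = y.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).mean(axis=0) / (sx * sy)
    return np.abs(np.nan_to_num(r))


def _top_k(scores: np.ndarray, k: int) -> tuple[int, ...]:
    order = np.argsort(-scores, kind="stable")
    return tuple(int(i) for i in order[:k])


def select_features(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                    names: Sequence[str], config: RunConfig, seed: int,
                    ) -> tuple[list[str], dict]:
    """Three-phase feature selection; returns chosen names and a trace.

    Phase 1 keeps features whose class means differ (two-sample t-test,
    p < ``config.p_threshold``); if none survives, the cut relaxes to the
    ``n_nominate`` smallest p-values.  Phase 2 runs eleven selectors, each
    nominating ``n_nominate`` features.  Phase 3 ranks by nomination count
    and picks the cardinality with the best subject-grouped CV accuracy
    under the surrogate classifier.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    names = list(names)
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise ValidationError("feature selection needs both classes")
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        return _select_features_inner(X, y, groups, names, config, seed)


def _select_features_inner(X, y, groups, names, config, seed):
    n, p = X.shape

    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(X[y == 1], X[y == 0], axis=0)
    pvals = np.nan_to_num(pvals, nan=1.0)
    surv = np.flatnonzero(pvals < config.p_threshold)
    relaxed = False
    if surv.size == 0:
        relaxed = True
        surv = np.array(_top_k(-pvals, min(config.n_nominate, p)))
        logger.warning("no feature passed the t-test cut; relaxing to top %d by p-value",
                       surv.size)
    Xs = X[:, surv]
    k = min(config.n_nominate, surv.size)
    mu = Xs.mean(axis=0)
    sd = Xs.std(axis=0)
    Xz = (Xs - mu) / np.where(sd > 0, sd, 1.0)
    rng_seed = int(np.random.SeedSequence([seed, 17]).generate_state(1)[0] % (2**31))

    nominations: dict[str, tuple[int, ...]] = {}
    # -- five filters
    with np.errstate(invalid="ignore", divide="ignore"):
        f_scores, _ = f_classif(Xs, y)
    nominations["anova_f"] = _top_k(np.nan_to_num(f_scores), k)
    nominations["mutual_info"] = _top_k(_binned_mutual_info(Xz, y), k)
    nominations["point_biserial"] = _top_k(_point_biserial(Xs, y), k)
    rng_col = Xs.max(axis=0) - Xs.min(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mm = np.where(rng_col > 0, (Xs - Xs.min(axis=0)) / rng_col, 0.0)
    nominations["variance"] = _top_k(mm.var(axis=0), k)
    nominations["relief"] = _top_k(_relief_weights(Xz, y), k)
    # -- four wrappers (forward/backward greedy around two light base learners)
    for tag, score in (("lsq", _lsq_accuracy), ("centroid", _centroid_accuracy)):
        nominations[f"forward_{tag}"] = tuple(_greedy_search(Xz, y, k, score, True))
        nominations[f"backward_{tag}"] = tuple(_greedy_search(Xz, y, k, score, False))
    # -- two embedded
    l1 = LogisticRegression(l1_ratio=1.0, C=1.0, solver="liblinear",
                            max_iter=200, random_state=rng_seed).fit(Xz, y)
    nominations["l1_logistic"] = _top_k(np.abs(l1.coef_[0]), k)
    forest = RandomForestClassifier(n_estimators=10, random_state=rng_seed).fit(Xz, y)
    nominations["tree_ensemble"] = _top_k(forest.feature_importances_, k)

    counts = np.zeros(surv.size, dtype=int)
    for chosen in nominations.values():
        counts[list(chosen)] += 1
    # rank: nomination count desc, then smaller t-test p, then input order
    order = sorted(range(surv.size), key=lambda j: (-counts[j], pvals[surv[j]], j))

    # -- phase 3: cardinality by subject-grouped CV under the surrogate
    best_c, best_score = 1, -np.inf
    cv_scores = []
    try:
        folds = grouped_cv(y, groups, config.selection_cv, rng_seed)
    except BranchFallback:
        folds = None
    # cardinalities beyond a handful never win on windows this correlated
    for c in range(1, min(surv.size, config.n_nominate + 3) + 1):
        cols = surv[order[:c]]
        if folds is None:
            score = _lsq_accuracy((X[:, cols] - X[:, cols].mean(0)) /
                                  np.where(X[:, cols].std(0) > 0, X[:, cols].std(0), 1), y)
        else:
            accs = []
            for tr, te in folds:
                clf = make_classifier(config.surrogate, seed=rng_seed)
                clf.fit(X[np.ix_(tr, cols)], y[tr])
                accs.append(float(np.mean(clf.predict(X[np.ix_(te, cols)]) == y[te])))
            score = float(np.mean(accs))
        cv_scores.append(score)
        if score > best_score + 1e-12:
            best_c, best_score = c, score

    selected = [names[surv[j]] for j in order[:best_c]]
    trace = {
        "p_values": dict(zip(names, (float(v) for v in pvals))),
        "relaxed": relaxed,
        "nominations": {sel: tuple(names[surv[j]] for j in chosen)
                        for sel, chosen in nominations.items()},
        "counts": {names[surv[j]]: int(counts[j]) for j in range(surv.size)},
        "cardinality_scores": cv_scores,
        "selected": selected,
    }
    return selected, trace


# ---------------------------------------------------------------------------
# Per-branch classifier selection and tuning
# ---------------------------------------------------------------------------

def _grid_points(grid: dict[str, list]) -> list[dict]:
    (k1, v1), (k2, v2) = grid.items()
    return [{k1: a, k2: b} for a in v1 for b in v2]


def tune_branch(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                config: RunConfig, seed: int) -> tuple[str, dict, float]:
    """Grid-search the roster's two hyperparameters per candidate.

    Subject-grouped stratified CV; returns (classifier name, params, mean
    CV accuracy).  Raises :class:`BranchFallback` when the branch cannot
    support its own model (single class or too few subjects).
    """
    uniq = np.unique(groups)
    if len(uniq) < config.branch_min_subjects:
        raise BranchFallback(f"branch has only {len(uniq)} subjects")
    if len(np.unique(y)) < 2:
        raise BranchFallback("branch contains a single class")
    rng_seed = int(np.random.SeedSequence([seed, 29]).generate_state(1)[0] % (2**31))
    folds = grouped_cv(y, groups, config.inner_cv, rng_seed)
    best: tuple[str, dict, float] | None = None
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        for name in config.roster:
            for params in _grid_points(HYPER_GRIDS[name]):
                accs = []
                for tr, te in folds:
                    clf = make_classifier(name, params, seed=rng_seed)
                    try:
                        clf.fit(X[tr], y[tr])
                        accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
                    except ValueError:  # e.g. KNN with more neighbours than samples
                        accs.append(0.0)
                score = float(np.mean(accs))
                if best is None or score > best[2] + 1e-12:
                    best = (name, params, score)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# The two-stage model
# ---------------------------------------------------------------------------

@dataclass
class BranchModel:
    features: tuple[str, ...]
    clf_name: str
    params: dict
    pipeline: Pipeline
    cv_score: float
    training_subjects: frozenset[str]
    is_fallback: bool


@dataclass
class SelectionTrace:
    alpha_scores: list[tuple[float, int, float]]  # (alpha, n_rwf, train accuracy)
    chosen_alpha: float
    branch_features: dict[str, tuple[str, ...]]
    selection_traces: dict[str, dict]
    tuning: dict[str, tuple[str, dict, float]]

    @property
    def best_recorded_accuracy(self) -> float:
        return max(acc for _, _, acc in self.alpha_scores)


@dataclass
class TwoStageModel:
    threshold: ThresholdModel
    scaler_low: Standardizer
    scaler_high: Standardizer
    weak_features: tuple[str, ...]
    branches: dict[str, BranchModel]   # keys RWF / DWF
    training_subjects: frozenset[str]
    config: RunConfig
    reference: dict[str, float] | None = None  # non-None when DDI is replaced


def _subject_ddi(subject: SubjectData, scaler_low: Standardizer,
                 scaler_high: Standardizer, config: RunConfig) -> DDIRecord:
    v_low = table_vectors(subject.low, config.weak_features, scaler_low)
    v_high = table_vectors(subject.high, config.weak_features, scaler_high)
    return compute_ddi(subject.subject_id, v_low, v_high)


def _selectable(subjects: Sequence[SubjectData]) -> bool:
    labels = pd.Series([s.label for s in subjects])
    counts = labels.value_counts()
    return counts.get("HR", 0) >= 2 and counts.get("LR", 0) >= 2


class _FitCache:
    """Memoises selection/tuning keyed by the exact training-subject set.

    Results depend only on the branch's subjects (their windows and labels),
    so sharing across folds and alpha values cannot leak the held-out
    subject: its id never appears in a key used for its own fold.
    """

    def __init__(self):
        self.store: dict = {}

    def get(self, key, fn):
        if key not in self.store:
            self.store[key] = fn()
        return self.store[key]


def _pooled_branch(subjects: list[SubjectData], config: RunConfig, seed: int,
                   cache: _FitCache) -> BranchModel:
    ids = frozenset(s.subject_id for s in subjects)

    def build():
        table = _stack(subjects)
        X, y, groups = _xy(table, config.registry)
        feats, _ = cache.get(("sel", ids),
                             lambda: select_features(X, y, groups, config.registry,
                                                     config, seed))
        Xf = table[list(feats)].to_numpy(dtype=float)
        try:
            name, params, score = tune_branch(Xf, y, groups, config, seed)
        except BranchFallback:
            name, params, score = config.surrogate, {}, float("nan")
        pipe = make_classifier(name, params, seed=seed).fit(Xf, y)
        return BranchModel(tuple(feats), name, params, pipe, score, ids, True)

    return cache.get(("pooled", ids), build)


def _model_cv_map(fit_subjects: list[SubjectData], model: BranchModel,
                  cache: _FitCache, config: RunConfig, seed: int,
                  ) -> dict[str, tuple[int, int]]:
    """Per-subject grouped-CV correctness of one tuned (classifier, features)."""
    ids = frozenset(s.subject_id for s in fit_subjects)
    key = ("cvmap", ids, model.features, model.clf_name,
           tuple(sorted(model.params.items())))

    def run():
        table = _stack(fit_subjects)
        X = table[list(model.features)].to_numpy(dtype=float)
        y = (table["label"].to_numpy() == POSITIVE).astype(int)
        groups = table["subject"].to_numpy()
        rng_seed = int(np.random.SeedSequence([seed, 61]).generate_state(1)[0]
                       % (2**31))
        hits: dict[str, list[int]] = {}
        try:
            folds = grouped_cv(y, groups, config.inner_cv, rng_seed)
        except BranchFallback:
            return {}
        with sklearn.config_context(assume_finite=True,
                                    skip_parameter_validation=True):
            for tr, te in folds:
                clf = make_classifier(model.clf_name, model.params, seed=seed)
                try:
                    clf.fit(X[tr], y[tr])
                    ok = clf.predict(X[te]) == y[te]
                except ValueError:
                    ok = np.zeros(len(te), dtype=bool)
                for g, o in zip(groups[te], ok):
                    hits.setdefault(g, []).append(int(o))
        return {g: (sum(v), len(v)) for g, v in hits.items()}

    return cache.get(key, run)


def fit_two_stage(subjects: Sequence[SubjectData], config: RunConfig, seed: int,
                  cache: _FitCache | None = None,
                  reference: dict[str, float] | None = None,
                  ) -> tuple[TwoStageModel, SelectionTrace]:
    """Fit threshold, per-branch feature sets and tuned branch classifiers.

    ``reference`` optionally replaces each training subject's DDI with an
    externally supplied reference value (used by the random-reference
    ablation); routing at test time then also uses that reference.
    """
    subjects = list(subjects)
    if not _selectable(subjects):
        raise InsufficientDataError("training needs >= 2 subjects per class")
    cache = cache or _FitCache()
    ids = frozenset(s.subject_id for s in subjects)

    low_all = _stack(subjects, "low")
    high_all = _stack(subjects, "high")
    scaler_low = Standardizer.fit(low_all, config.weak_features)
    scaler_high = Standardizer.fit(high_all, config.weak_features)
    if reference is None:
        values = {s.subject_id: _subject_ddi(s, scaler_low, scaler_high, config).ddi
                  for s in subjects}
    else:
        values = {s.subject_id: reference[s.subject_id] for s in subjects}

    by_id = {s.subject_id: s for s in subjects}

    # -- step 1: alpha + per-branch feature sets by overall training accuracy
    def pooled_features() -> tuple[str, ...]:
        def run():
            table = _stack(subjects)
            X, y, groups = _xy(table, config.registry)
            return select_features(X, y, groups, config.registry, config, seed)
        return tuple(cache.get(("sel", ids), run)[0])

    def branch_selection(branch_subjects: list[SubjectData]):
        bids = frozenset(s.subject_id for s in branch_subjects)
        if _selectable(branch_subjects):
            def run():
                table = _stack(branch_subjects)
                X, y, groups = _xy(table, config.registry)
                return select_features(X, y, groups, config.registry, config, seed)
            return cache.get(("sel", bids), run), bids, False
        # under-populated or single-class branch: pooled feature set
        def run_pooled():
            table = _stack(subjects)
            X, y, groups = _xy(table, config.registry)
            return select_features(X, y, groups, config.registry, config, seed)
        return cache.get(("sel", ids), run_pooled), ids, True

    def surrogate_cv_correct(fit_subjects, feats) -> dict[str, tuple[int, int]]:
        """Per-subject (correct, total) window counts of the default-setting
        surrogate under subject-grouped CV over ``fit_subjects``.

        Grouped CV keeps the branch score an out-of-subject estimate;
        scoring in-sample would always reward flagging more subjects, since
        smaller branches are easier to fit.
        """
        fit_ids = frozenset(s.subject_id for s in fit_subjects)
        key = ("surrcv", fit_ids, tuple(feats))

        def run():
            table = _stack(fit_subjects)
            X = table[list(feats)].to_numpy(dtype=float)
            y = (table["label"].to_numpy() == POSITIVE).astype(int)
            groups = table["subject"].to_numpy()
            hits: dict[str, list[int]] = {}
            # repeated grouped CV: a single split is noisy enough for small
            # branches to win the alpha search by luck
            for rep in (53, 54):
                rng_seed = int(np.random.SeedSequence([seed, rep])
                               .generate_state(1)[0] % (2**31))
                try:
                    folds = grouped_cv(y, groups, config.selection_cv, rng_seed)
                except BranchFallback:
                    continue
                with sklearn.config_context(assume_finite=True,
                                            skip_parameter_validation=True):
                    for tr, te in folds:
                        clf = make_classifier(config.surrogate, seed=seed)
                        clf.fit(X[tr], y[tr])
                        ok = clf.predict(X[te]) == y[te]
                        for g, o in zip(groups[te], ok):
                            hits.setdefault(g, []).append(int(o))
            return {g: (sum(v), len(v)) for g, v in hits.items()}

        return cache.get(key, run)

    alpha_scores: list[tuple[float, int, float]] = []
    partitions: dict[frozenset, float] = {}
    best = None  # (accuracy, alpha, threshold, partition, feats per branch, traces)
    for alpha in config.alphas:
        thr = fit_threshold(list(values.values()), float(alpha),
                            robust=config.robust_bounds)
        rwf_ids = frozenset(sid for sid, v in values.items()
                            if classify_type(v, thr) == RWF)
        if rwf_ids in partitions:
            acc = partitions[rwf_ids]
            alpha_scores.append((float(alpha), len(rwf_ids), acc))
            continue
        correct = total = 0
        feats_by_branch: dict[str, tuple[str, ...]] = {}
        traces_by_branch: dict[str, dict] = {}
        for branch, members in ((RWF, sorted(rwf_ids)),
                                (DWF, sorted(ids - rwf_ids))):
            if not members:
                feats_by_branch[branch] = ()
                continue
            branch_subjects = [by_id[sid] for sid in members]
            (feats, trace), fit_ids, pooled = branch_selection(branch_subjects)
            feats_by_branch[branch] = tuple(feats)
            traces_by_branch[branch] = trace
            # out-of-subject windows score for this branch's members, under
            # whichever view (branch-specific or pooled) serves them better:
            # a branch that does not beat the pooled model on its own CV
            # will fall back to the pooled model in step 2
            pooled_map = surrogate_cv_correct(subjects, pooled_features())
            candidates = [pooled_map]
            if not pooled:
                own = surrogate_cv_correct(branch_subjects, tuple(feats))
                if own:
                    candidates.append(own)
            scored = []
            for cand in candidates:
                c = sum(cand.get(sid, (0, 0))[0] for sid in members)
                t = sum(cand.get(sid, (0, 0))[1] for sid in members)
                scored.append((c / max(t, 1), c, t))
            _, c, t = max(scored, key=lambda s: s[0])
            correct += c
            total += t
        acc = correct / max(total, 1)
        partitions[rwf_ids] = acc
        alpha_scores.append((float(alpha), len(rwf_ids), acc))
        if best is None or acc > best[0] + 1e-12:
            best = (acc, float(alpha), thr, rwf_ids, feats_by_branch, traces_by_branch)

    assert best is not None
    _, chosen_alpha, threshold, rwf_ids, feats_by_branch, traces_by_branch = best

    # -- step 2: classifier selection and tuning per branch
    branches: dict[str, BranchModel] = {}
    tuning: dict[str, tuple[str, dict, float]] = {}
    def _branch_beats_pooled(branch_subjects, feats) -> bool:
        """Overfitting guard: adapt only when the branch view wins its own CV.

        Both sides are scored on the full registry: branch-selected features
        were chosen on these very members, so scoring them would bias the
        comparison toward the branch.
        """
        members = [s.subject_id for s in branch_subjects]
        own = surrogate_cv_correct(branch_subjects, tuple(config.registry))
        pooled_map = surrogate_cv_correct(subjects, tuple(config.registry))
        if not own:
            return False
        c_o = sum(own.get(sid, (0, 0))[0] for sid in members)
        t_o = sum(own.get(sid, (0, 0))[1] for sid in members)
        c_p = sum(pooled_map.get(sid, (0, 0))[0] for sid in members)
        t_p = sum(pooled_map.get(sid, (0, 0))[1] for sid in members)
        return c_o / max(t_o, 1) > c_p / max(t_p, 1) + config.gate_margin

    for branch, members in ((RWF, sorted(rwf_ids)), (DWF, sorted(ids - rwf_ids))):
        branch_subjects = [by_id[sid] for sid in members]
        bids = frozenset(members)
        feats = feats_by_branch.get(branch) or ()
        built = None
        may_specialize = config.specialize == "both" or branch == RWF
        plain = config.gate_margin < 0
        if members and may_specialize and _selectable(branch_subjects) and \
                len(members) >= config.branch_min_subjects and feats and \
                bids != ids and (plain or _branch_beats_pooled(branch_subjects, feats)):
            def build(branch_subjects=branch_subjects, feats=feats, bids=bids):
                table = _stack(branch_subjects)
                X = table[list(feats)].to_numpy(dtype=float)
                y = (table["label"].to_numpy() == POSITIVE).astype(int)
                groups = table["subject"].to_numpy()
                name, params, score = tune_branch(X, y, groups, config, seed)
                pipe = make_classifier(name, params, seed=seed).fit(X, y)
                return BranchModel(feats, name, params, pipe, score, bids, False)
            try:
                built = cache.get(("branch", bids, feats), build)
            except BranchFallback as exc:
                logger.info("branch %s falls back to pooled model: %s", branch, exc)
            else:
                # second guard at the final-model level: the tuned branch
                # classifier must beat the tuned pooled classifier on the
                # branch members' own grouped CV
                if plain:
                    branches[branch] = built
                    tuning[branch] = (built.clf_name, built.params, built.cv_score)
                    continue
                pooled_now = _pooled_branch(subjects, config, seed, cache)
                own_map = _model_cv_map(branch_subjects, built, cache, config, seed)
                pool_map = _model_cv_map(subjects, pooled_now, cache, config, seed)
                c_o = sum(own_map.get(sid, (0, 0))[0] for sid in members)
                t_o = sum(own_map.get(sid, (0, 0))[1] for sid in members)
                c_p = sum(pool_map.get(sid, (0, 0))[0] for sid in members)
                t_p = sum(pool_map.get(sid, (0, 0))[1] for sid in members)
                if not t_o or c_o / t_o <= c_p / max(t_p, 1):
                    logger.info("branch %s tuned model below pooled CV; fallback",
                                branch)
                    built = None
        if built is None:
            built = _pooled_branch(subjects, config, seed, cache)
        branches[branch] = built
        tuning[branch] = (built.clf_name, built.params, built.cv_score)

    model = TwoStageModel(
        threshold=threshold, scaler_low=scaler_low, scaler_high=scaler_high,
        weak_features=tuple(config.weak_features), branches=branches,
        training_subjects=ids, config=config, reference=reference,
    )
    trace = SelectionTrace(
        alpha_scores=alpha_scores, chosen_alpha=chosen_alpha,
        branch_features={b: feats_by_branch.get(b, ()) for b in (RWF, DWF)},
        selection_traces=traces_by_branch, tuning=tuning,
    )
    return model, trace


# ---------------------------------------------------------------------------
# Prediction and LOSO evaluation
# ---------------------------------------------------------------------------

def predict_subject(model: TwoStageModel, subject: SubjectData,
                    reference_value: float | None = None) -> dict:
    """Route one unlabelled subject and aggregate window votes.

    The subject's own windows plus the *training* scalers give its DDI; no
    label enters.  Window predictions aggregate by majority vote, ties to
    the positive (HR) call, since screening favours sensitivity.
    """
    config = model.config
    if reference_value is not None:
        value = reference_value
    else:
        scl, sch = model.scaler_low, model.scaler_high
        value = compute_ddi(
            subject.subject_id,
            table_vectors(subject.low, model.weak_features, scl),
            table_vectors(subject.high, model.weak_features, sch),
        ).ddi
    subject_type = classify_type(value, model.threshold)
    branch = model.branches[subject_type]
    X = subject.high[list(branch.features)].to_numpy(dtype=float)
    votes = branch.pipeline.predict(X)
    call = POSITIVE if votes.mean() >= 0.5 else "LR"
    return {
        "subject": subject.subject_id,
        "ddi": value if reference_value is None else float("nan"),
        "reference": value,
        "type": subject_type,
        "call": call,
        "window_votes": votes,
    }


def evaluate_loso(subjects: Sequence[SubjectData], config: RunConfig, seed: int,
                  stage: str = "two", cache: _FitCache | None = None,
                  ) -> tuple[EvalReport, pd.DataFrame, list[dict]]:
    """Leave-one-subject-out evaluation of the two-stage model.

    ``stage``: ``"two"`` (full model), ``"one"`` (pooled single-stage
    baseline: same feature selection and tuning, no routing) or
    ``"random"`` (the ablation that replaces every DDI with a uniform
    random reference value).  Returns the confusion report, a per-subject
    prediction table and per-fold fingerprints of the training-subject
    sets (for leakage auditing).
    """
    subjects = sorted(subjects, key=lambda s: s.subject_id)
    if len(subjects) < 3 or not _selectable(subjects):
        raise InsufficientDataError("LOSO needs >= 3 subjects and both classes")
    if stage not in ("two", "one", "random"):
        raise ValidationError(f"unknown stage {stage!r}")
    cache = cache or _FitCache()
    refs = None
    if stage == "random":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
        refs = {s.subject_id: float(rng.uniform()) for s in subjects}

    rows = []
    fingerprints = []
    tp = tn = fp = fn = 0
    sub_counts = {RWF: [0, 0, 0, 0], DWF: [0, 0, 0, 0]}  # tp, tn, fp, fn
    for held in subjects:
        train = [s for s in subjects if s.subject_id != held.subject_id]
        if stage == "one":
            pooled = _pooled_branch(train, config, seed, cache)
            X = held.high[list(pooled.features)].to_numpy(dtype=float)
            votes = pooled.pipeline.predict(X)
            call = POSITIVE if votes.mean() >= 0.5 else "LR"
            pred = {"subject": held.subject_id, "ddi": float("nan"),
                    "reference": float("nan"), "type": DWF, "call": call,
                    "window_votes": votes}
            train_ids = pooled.training_subjects
        else:
            model, _ = fit_two_stage(train, config, seed, cache=cache,
                                     reference=refs)
            pred = predict_subject(
                model, held,
                reference_value=None if refs is None else refs[held.subject_id])
            train_ids = model.training_subjects
        fingerprints.append({"held_out": held.subject_id,
                             "training_ids": frozenset(train_ids)})
        is_pos = held.label == POSITIVE
        called_pos = pred["call"] == POSITIVE
        slot = 0 if (is_pos and called_pos) else 1 if (not is_pos and not called_pos) \
            else 2 if called_pos else 3
        tp += slot == 0
        tn += slot == 1
        fp += slot == 2
        fn += slot == 3
        sub_counts[pred["type"]][slot] += 1
        rows.append({"subject": held.subject_id, "label": held.label,
                     "call": pred["call"], "type": pred["type"],
                     "ddi": pred["ddi"], "correct": (pred["call"] == held.label)})

    report = EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sub_reports={b: EvalReport(*c) for b, c in sub_counts.items() if sum(c)},
    )
    return report, pd.DataFrame(rows), fingerprints


# ---------------------------------------------------------------------------
# Pilot length sweep
# ---------------------------------------------------------------------------

def count_sweep_runs(n_subjects: int, lengths: Sequence[int]) -> int:
    """Number of per-fold feature-selection runs in the pilot sweep."""
    return n_subjects * len(lengths)


def length_sweep(recs: Sequence[Recording], config: RunConfig, seed: int,
                 lengths: Sequence[int] | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pilot study: window-level LOSO accuracy and selection counts per length.

    For each length the recordings are re-windowed and, per LOSO fold,
    features are re-selected on the training windows and a surrogate
    classifier scores the held-out subject's windows.  Returns the
    per-(length, subject) accuracy table and the per-(length, feature)
    selection-count table.
    """
    lengths = list(lengths if lengths is not None else config.sweep_lengths)
    acc_rows = []
    count_rows: dict[tuple[int, str], int] = {}
    for L in lengths:
        tables = []
        for rec in recs:
            try:
                tables.append(recording_table(rec, config, L))
            except InsufficientDataError:
                logger.warning("%s skipped at L=%d (too few steps)", rec.subject_id, L)
        if len(tables) < 3:
            continue
        all_windows = pd.concat(tables, ignore_index=True)
        for held in sorted(all_windows["subject"].unique()):
            train = all_windows[all_windows["subject"] != held]
            test = all_windows[all_windows["subject"] == held]
            X, y, groups = _xy(train, config.registry)
            if len(np.unique(y)) < 2:
                continue
            feats, _ = select_features(X, y, groups, config.registry, config, seed)
            for f in feats:
                count_rows[(L, f)] = count_rows.get((L, f), 0) + 1
            clf = make_classifier(config.surrogate, seed=seed)
            clf.fit(train[feats].to_numpy(dtype=float),
                    (train["label"] == POSITIVE).astype(int))
            pred = clf.predict(test[feats].to_numpy(dtype=float))
            truth = (test["label"] == POSITIVE).astype(int).to_numpy()
            acc_rows.append({"length": L, "subject": held,
                             "n_windows": len(test),
                             "window_accuracy": float(np.mean(pred == truth))})
    counts = pd.DataFrame(
        [{"length": L, "feature": f, "count": c} for (L, f), c in sorted(count_rows.items())]
    )
    return pd.DataFrame(acc_rows), counts
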