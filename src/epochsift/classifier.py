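"""Consensus-weighted random forest with grouped cross-validation.

Observations are weighted by the certainty of the rater consensus (from
7/7 agreement down to a 4/3 split), folds are grouped by infant so no
subject straddles train/validation, and hyperparameters are chosen by
exhaustive grid search on the class-support-weighted F1 score.  The
forest's posterior probability — the mean over trees of the predicted
artefact probability — estimates the probability that the rater group
would reject the epoch.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path

import joblib
import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score

from .consensus import ConsensusLabel
from .features import FEATURE_NAMES, MANIFEST_VERSION

logger = logging.getLogger(__name__)

SERIAL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters plus the training seed."""

    n_trees: int = 300
    max_depth: int | None = None
    min_samples_leaf: int = 5
    max_features: str | None = "sqrt"  # "sqrt" or None (all features)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_samples_leaf < 1:
            raise ValueError("counts must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")


#: Default search grid.  min_samples_leaf gets the widest range: it is
#: the hyperparameter whose tuning most visibly moves performance here.
DEFAULT_GRID: dict[str, list] = {
    "n_trees": [100, 300],
    "max_depth": [None, 5, 10],
    "min_samples_leaf": [1, 5, 10, 20],
    "max_features": ["sqrt", None],
}


@dataclass
class TrainedForest:
    """A fitted ensemble plus everything needed to apply it safely."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    config: ForestConfig
    threshold: float = 0.5
    fingerprint: str = ""
    manifest_version: str = MANIFEST_VERSION

    def _check_manifest(self, feature_names) -> None:
        if feature_names is None:
            return
        got = tuple(feature_names)
        if got != self.feature_names:
            bad = [g for g, w in zip(got, self.feature_names) if g != w]
            extra = set(got) ^ set(self.feature_names)
            raise ValueError(
                f"feature manifest mismatch: offending feature(s) "
                f"{bad or sorted(extra)}"
            )


def _artefact_column(forest: RandomForestClassifier) -> int:
    return int(np.where(forest.classes_ == 1)[0][0])


def _fingerprint(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> str:
    h = hashlib.sha256()
    for arr in (X, y, w):
        h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# splits

def loso_folds(infant_ids: list[str]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-subject-out folds grouped by infant.

    One fold per infant; all of an infant's epochs sit in the same
    validation fold and never in its training side.
    """
    ids = np.asarray(infant_ids)
    unique = list(dict.fromkeys(ids))  # first-appearance order
    if len(unique) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 infants")
    folds = []
    for infant in unique:
        val = np.where(ids == infant)[0]
        train = np.where(ids != infant)[0]
        folds.append((train, val))
    return folds


def grouped_stratified_split(
    infant_ids: list[str],
    age_groups: list[str],
    stimuli: list[str],
    test_fraction: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Grouped train/test split stratified by (age group, stimulus).

    No infant straddles the split.  Infants are assigned to the test
    side by a seeded greedy pass that minimises the total absolute
    deviation of per-stratum test counts from ``test_fraction`` of each
    stratum; deviations forced by group structure are logged.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    ids = np.asarray(infant_ids)
    strata = list(zip(age_groups, stimuli))
    stratum_names = sorted(set(strata))
    targets = {
        s: test_fraction * sum(1 for x in strata if x == s) for s in stratum_names
    }
    per_infant: dict[str, dict] = {}
    for i, infant in enumerate(ids):
        per_infant.setdefault(infant, {s: 0 for s in stratum_names})
        per_infant[infant][strata[i]] += 1

    rng = np.random.default_rng(seed)
    infants = list(dict.fromkeys(ids))
    order = rng.permutation(len(infants))
    counts = {s: 0.0 for s in stratum_names}

    def deviation(c: dict) -> float:
        return sum(abs(c[s] - targets[s]) for s in stratum_names)

    test_set: set[str] = set()
    improved = True
    while improved:
        improved = False
        best_gain, best_infant = 0.0, None
        for k in order:
            infant = infants[k]
            if infant in test_set:
                continue
            trial = {s: counts[s] + per_infant[infant][s] for s in stratum_names}
            gain = deviation(counts) - deviation(trial)
            if gain > best_gain + 1e-12:
                best_gain, best_infant = gain, infant
        if best_infant is not None:
            test_set.add(best_infant)
            for s in stratum_names:
                counts[s] += per_infant[best_infant][s]
            improved = True

    resid = deviation(counts)
    if resid > len(stratum_names):
        logger.warning(
            "stratified split best-effort: total deviation %.1f epochs", resid
        )
    test_mask = np.array([i in test_set for i in ids])
    return np.where(~test_mask)[0], np.where(test_mask)[0]


# ---------------------------------------------------------------------------
# training and prediction

def train(
    X: np.ndarray,
    consensus: list[ConsensusLabel],
    config: ForestConfig = ForestConfig(),
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> TrainedForest:
    """Fit the forest with per-observation consensus-certainty weights."""
    X = np.asarray(X, dtype=float)
    y = np.array([c.label for c in consensus], dtype=int)
    w = np.array([c.weight for c in consensus], dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("features and labels must align")
    if X.shape[1] != len(feature_names):
        raise ValueError(
            f"{X.shape[1]} feature columns but {len(feature_names)} names"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        max_features=config.max_features,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y, sample_weight=w)
    return TrainedForest(
        forest=forest,
        feature_names=tuple(feature_names),
        config=config,
        fingerprint=_fingerprint(X, y, w),
    )


def predict_proba(
    model: TrainedForest, X: np.ndarray, feature_names=None
) -> np.ndarray:
    """Posterior artefact probability: mean of per-tree class probabilities."""
    model._check_manifest(feature_names)
    X = np.asarray(X, dtype=float)
    return model.forest.predict_proba(X)[:, _artefact_column(model.forest)]


def classify(
    model: TrainedForest,
    X: np.ndarray,
    threshold: float | None = None,
    feature_names=None,
) -> np.ndarray:
    """Label = artefact iff posterior >= threshold (default the model's)."""
    if threshold is None:
        threshold = model.threshold
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return (predict_proba(model, X, feature_names) >= threshold).astype(int)


# ---------------------------------------------------------------------------
# model selection

def _config_sort_key(cfg: ForestConfig):
    depth = cfg.max_depth if cfg.max_depth is not None else np.inf
    return (
        cfg.n_trees,
        depth,
        -cfg.min_samples_leaf,
        str(cfg.max_features),
    )


def grid_search(
    X: np.ndarray,
    consensus: list[ConsensusLabel],
    folds: list[tuple[np.ndarray, np.ndarray]],
    grid: dict[str, list] | None = None,
    seed: int = 0,
) -> tuple[ForestConfig, list[tuple[ForestConfig, float]]]:
    """Exhaustive grid search scored by weighted F1 averaged over folds.

    Ties are broken towards the simpler model — fewer trees, shallower
    depth, larger leaf — then lexicographically, so the winner is
    deterministic and independent of grid enumeration order.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    X = np.asarray(X, dtype=float)
    y = np.array([c.label for c in consensus], dtype=int)
    keys = sorted(grid)
    results: list[tuple[ForestConfig, float]] = []
    for combo in product(*(grid[k] for k in keys)):
        cfg = ForestConfig(**dict(zip(keys, combo)), seed=seed)
        fold_scores = []
        for train_idx, val_idx in folds:
            sub = [consensus[i] for i in train_idx]
            if len({c.label for c in sub}) < 2:
                continue  # degenerate fold: cannot fit
            model = train(X[train_idx], sub, cfg)
            pred = classify(model, X[val_idx])
            fold_scores.append(
                f1_score(y[val_idx], pred, average="weighted", zero_division=0)
            )
        if not fold_scores:
            raise ValueError("no usable folds for grid search")
        results.append((cfg, float(np.mean(fold_scores))))
    # deterministic tie-break: best score, then simplest config
    top = max(r[1] for r in results)
    tied = [cfg for cfg, s in results if abs(s - top) < 1e-12]
    best_cfg = sorted(tied, key=_config_sort_key)[0]
    return best_cfg, results


def cross_val_posteriors(
    X: np.ndarray,
    consensus: list[ConsensusLabel],
    folds: list[tuple[np.ndarray, np.ndarray]],
    config: ForestConfig = ForestConfig(),
) -> np.ndarray:
    """Out-of-fold posterior for every epoch (grouped cross-validation)."""
    X = np.asarray(X, dtype=float)
    post = np.full(X.shape[0], np.nan)
    for train_idx, val_idx in folds:
        sub = [consensus[i] for i in train_idx]
        if len({c.label for c in sub}) < 2:
            logger.warning("fold skipped: single-class training side")
            continue
        model = train(X[train_idx], sub, config)
        post[val_idx] = predict_proba(model, X[val_idx])
    return post


# ---------------------------------------------------------------------------
# model comparison

def mcnemar(pred_a: np.ndarray, pred_b: np.ndarray, truth: np.ndarray) -> float:
    """McNemar's test p-value for two paired classifiers.

    Exact two-sided binomial on the discordant pairs; with >= 25
    discordant pairs the continuity-corrected chi-square approximation
    is used.  No discordant pairs gives p = 1.
    """
    a = np.asarray(pred_a).astype(int)
    b = np.asarray(pred_b).astype(int)
    t = np.asarray(truth).astype(int)
    if not (a.shape == b.shape == t.shape):
        raise ValueError("prediction and truth vectors must align")
    a_ok, b_ok = a == t, b == t
    n01 = int(np.sum(a_ok & ~b_ok))
    n10 = int(np.sum(~a_ok & b_ok))
    m = n01 + n10
    if m == 0:
        return 1.0
    if m >= 25:
        chi2 = (abs(n01 - n10) - 1) ** 2 / m
        return float(stats.chi2.sf(chi2, df=1))
    p = 2.0 * stats.binom.cdf(min(n01, n10), m, 0.5)
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# serialization

def save_model(model: TrainedForest, path: str | Path) -> None:
    """Serialize to a versioned container embedding the manifest."""
    payload = {
        "format_version": SERIAL_FORMAT_VERSION,
        "manifest_version": model.manifest_version,
        "feature_names": model.feature_names,
        "config": asdict(model.config),
        "threshold": model.threshold,
        "fingerprint": model.fingerprint,
        "forest": model.forest,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedForest:
    payload = joblib.load(path)
    if payload.get("format_version") != SERIAL_FORMAT_VERSION:
        raise ValueError("unsupported model container version")
    return TrainedForest(
        forest=payload["forest"],
        feature_names=tuple(payload["feature_names"]),
        config=ForestConfig(**payload["config"]),
        threshold=payload["threshold"],
        fingerprint=payload["fingerprint"],
        manifest_version=payload["manifest_version"],
    )
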