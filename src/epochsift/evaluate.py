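"""Evaluation battery: confusion metrics, ROC, importance, screening, SNR.

Balanced accuracy — the mean of sensitivity and specificity — is the
headline metric throughout, because artefact prevalence is well below
half and raw accuracy would reward the majority class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn import metrics as sk_metrics
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.inspection import permutation_importance as _sk_perm

from .consensus import cohens_kappa
from .epoch_io import Epoch
from .classifier import TrainedForest, classify

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Confusion counts and derived metrics for one scored set."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    kappa_vs_consensus: float | None = None
    roc_points: list[tuple[float, float, float]] = field(default_factory=list)
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_markdown(self) -> str:
        lines = [
            "| metric | value |",
            "| --- | --- |",
            f"| n epochs | {self.n} |",
            f"| TP / FP / TN / FN | {self.tp} / {self.fp} / {self.tn} / {self.fn} |",
            f"| sensitivity | {self.sensitivity:.3f} |",
            f"| specificity | {self.specificity:.3f} |",
            f"| balanced accuracy | {self.balanced_accuracy:.3f} |",
        ]
        if self.kappa_vs_consensus is not None:
            lines.append(f"| Cohen's kappa vs consensus | {self.kappa_vs_consensus:.3f} |")
        if self.auc is not None:
            lines.append(f"| ROC AUC | {self.auc:.3f} |")
        return "\n".join(lines)


def confusion_metrics(pred: np.ndarray, truth: np.ndarray) -> EvalReport:
    """Sensitivity, specificity and balanced accuracy, artefact-positive."""
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must align")
    if len(np.unique(truth)) < 2:
        raise ValueError("truth contains a single class; metrics undefined")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        kappa_vs_consensus=cohens_kappa(pred, truth),
    )


def roc(
    posteriors: np.ndarray, truth: np.ndarray
) -> tuple[list[tuple[float, float, float]], float]:
    """ROC curve (fpr, tpr, threshold) and trapezoidal AUC.

    The AUC equals the probability that a random artefact epoch scores
    a higher posterior than a random clean one (ties counted half).
    """
    truth = np.asarray(truth).astype(int)
    if len(np.unique(truth)) < 2:
        raise ValueError("truth contains a single class; ROC undefined")
    fpr, tpr, thr = sk_metrics.roc_curve(truth, posteriors)
    auc = float(sk_metrics.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist(), thr.tolist())), auc


def full_report(
    pred: np.ndarray, truth: np.ndarray, posteriors: np.ndarray | None = None
) -> EvalReport:
    """Confusion metrics plus ROC/AUC when posteriors are supplied."""
    rep = confusion_metrics(pred, truth)
    if posteriors is not None:
        rep.roc_points, rep.auc = roc(posteriors, truth)
    return rep


# ---------------------------------------------------------------------------
# feature importance and screening

class _ThresholdedForest(BaseEstimator, ClassifierMixin):
    """sklearn-compatible shim applying a TrainedForest at its threshold."""

    def __init__(self, model: TrainedForest):
        self.model = model
        self.classes_ = np.array([0, 1])

    def fit(self, X, y=None):  # already fitted
        return self

    def predict(self, X):
        return classify(self.model, X)


def permutation_importance(
    model: TrainedForest,
    X: np.ndarray,
    truth: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
) -> dict[str, tuple[float, float, float]]:
    """Per-feature balanced-accuracy drop under random permutation.

    Each feature column is shuffled ``n_perm`` times; the mean drop and
    a 95 % normal interval of the mean are reported per feature name.
    """
    res = _sk_perm(
        _ThresholdedForest(model),
        np.asarray(X, dtype=float),
        np.asarray(truth).astype(int),
        scoring="balanced_accuracy",
        n_repeats=n_perm,
        random_state=seed,
    )
    out: dict[str, tuple[float, float, float]] = {}
    for i, name in enumerate(model.feature_names):
        mean = float(res.importances_mean[i])
        half = 1.96 * float(res.importances_std[i]) / np.sqrt(n_perm)
        out[name] = (mean, mean - half, mean + half)
    return out


def feature_univariate_p(values: np.ndarray, labels: np.ndarray) -> float:
    """Wald p-value of a single-feature binomial logit for artefact.

    Fits label ~ intercept + feature and returns the two-sided p for
    the slope.  Perfect separation is reported as p = 0 with a logged
    separation flag.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least 2 observations per class")
    # complete separation: a threshold on x splits the classes exactly
    if np.max(x[y == 0], initial=-np.inf) < np.min(x[y == 1], initial=np.inf) or (
        np.max(x[y == 1], initial=-np.inf) < np.min(x[y == 0], initial=np.inf)
    ):
        logger.warning("perfect separation in univariate logit; p = 0")
        return 0.0
    design = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        logger.warning("perfect separation in univariate logit; p = 0")
        return 0.0
    p = float(fit.pvalues[1])
    if not np.isfinite(p) or abs(fit.params[1]) > 1e3:
        logger.warning("(quasi-)separation in univariate logit; p = 0")
        return 0.0
    return p


# ---------------------------------------------------------------------------
# signal-to-noise ratio

def snr(epoch: Epoch, erp_magnitude: str = "max_abs") -> float:
    """SNR = mag(ERP) / std(baseline).

    The ERP magnitude is the maximum absolute post-stimulus amplitude
    (or post-stimulus peak-to-peak with ``erp_magnitude='peak_to_peak'``);
    the noise term is the standard deviation of the pre-stimulus window.
    """
    split = int(round(epoch.event_offset * epoch.fs))
    if split < 2:
        raise ValueError("epoch has no pre-stimulus baseline")
    baseline, post = epoch.samples[:split], epoch.samples[split:]
    sd = float(np.std(baseline))
    if sd == 0.0:
        raise ValueError("zero-variance baseline; SNR undefined")
    if erp_magnitude == "max_abs":
        mag = float(np.max(np.abs(post)))
    elif erp_magnitude == "peak_to_peak":
        mag = float(post.max() - post.min())
    else:
        raise ValueError(f"unknown ERP magnitude convention {erp_magnitude!r}")
    return mag / sd


# ---------------------------------------------------------------------------
# subgroup accuracy

def accuracy_by_subgroup(
    pred: np.ndarray,
    truth: np.ndarray,
    groups: list,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[object, tuple[float, float, float]]:
    """Balanced accuracy per subgroup with a percentile bootstrap CI.

    Groups missing one of the classes are skipped with a warning.
    Returns ``{group: (balanced_accuracy, ci_lo, ci_hi)}``.
    """
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    groups_arr = np.asarray(groups)
    rng = np.random.default_rng(seed)
    out: dict[object, tuple[float, float, float]] = {}
    for g in dict.fromkeys(groups):
        mask = groups_arr == g
        t, p = truth[mask], pred[mask]
        if len(np.unique(t)) < 2:
            logger.warning("subgroup %r lacks one class; skipped", g)
            continue
        point = confusion_metrics(p, t).balanced_accuracy
        boots = []
        n = len(t)
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            tb, pb = t[idx], p[idx]
            if len(np.unique(tb)) < 2:
                continue
            boots.append(confusion_metrics(pb, tb).balanced_accuracy)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        out[g] = (point, float(lo), float(hi))
    return out
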