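"""Ground truth from multi-rater panels and inter-rater agreement.

Seven raters independently label each epoch artefact (1) or clean (0);
the ground truth is the majority vote, and each epoch carries a
certainty weight — the fraction of raters agreeing with the majority —
used later as an observation weight during training.  Agreement between
rater pairs is quantified with Cohen's kappa, and leave-one-rater-out
consensus lets a model be scored exactly like a human rater.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RaterMatrix:
    """Binary labels, epochs x raters (1 = artefact)."""

    labels: np.ndarray
    rater_ids: list[str] = field(default_factory=list)
    rater_tiers: list[str] = field(default_factory=list)  # "experienced" | "expert"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.shape[1] < 2:
            raise ValueError("rater matrix must be epochs x (>=2) raters")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("rater labels must be 0/1 with no missing cells")
        self.labels = self.labels.astype(int)
        if not self.rater_ids:
            self.rater_ids = [chr(ord("A") + i) for i in range(self.n_raters)]
        if len(self.rater_ids) != self.n_raters:
            raise ValueError("rater_ids length mismatch")
        if self.rater_tiers and len(self.rater_tiers) != self.n_raters:
            raise ValueError("rater_tiers length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]

    @property
    def n_raters(self) -> int:
        return self.labels.shape[1]


@dataclass(frozen=True)
class ConsensusLabel:
    """Majority label with its agreement count and certainty weight."""

    label: int
    n_agree: int
    weight: float
    tied: bool = False


def majority_vote(matrix: RaterMatrix) -> list[ConsensusLabel]:
    """Per-epoch modal rating; weight = fraction of raters agreeing.

    With an even rater count an exact split is flagged ``tied`` (label
    reported as 0 by convention but callers must honour the flag).
    """
    out: list[ConsensusLabel] = []
    n = matrix.n_raters
    for row in matrix.labels:
        ones = int(row.sum())
        zeros = n - ones
        if ones == zeros:
            out.append(ConsensusLabel(label=0, n_agree=ones, weight=0.5, tied=True))
        else:
            label = int(ones > zeros)
            n_agree = max(ones, zeros)
            out.append(ConsensusLabel(label=label, n_agree=n_agree, weight=n_agree / n))
    return out


def cohens_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa between two binary label vectors.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement from the
    marginals.  Degenerate case p_e = 1 (both raters constant): defined
    as 1 when the raters agree everywhere, else 0.
    """
    a = np.asarray(a).astype(int)
    b = np.asarray(b).astype(int)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("need two equal-length label vectors")
    n = len(a)
    p_o = float(np.mean(a == b))
    pa1, pb1 = float(a.mean()), float(b.mean())
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if abs(1.0 - p_e) < 1e-15:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def pairwise_kappa(matrix: RaterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric rater x rater kappa table and per-rater mean.

    The per-rater mean excludes the diagonal: it is each rater's average
    agreement with all other raters, an index of how well their
    decisions align with the group.
    """
    r = matrix.n_raters
    table = np.ones((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            k = cohens_kappa(matrix.labels[:, i], matrix.labels[:, j])
            table[i, j] = table[j, i] = k
    means = (table.sum(axis=1) - np.diag(table)) / (r - 1)
    return table, means


def tier_mean_kappa(matrix: RaterMatrix) -> dict[str, float]:
    """Mean pairwise kappa within each rater tier."""
    if not matrix.rater_tiers:
        raise ValueError("rater matrix has no tier annotations")
    table, _ = pairwise_kappa(matrix)
    out: dict[str, float] = {}
    for tier in sorted(set(matrix.rater_tiers)):
        idx = [i for i, t in enumerate(matrix.rater_tiers) if t == tier]
        vals = [table[i, j] for i in idx for j in idx if j > i]
        if vals:
            out[tier] = float(np.mean(vals))
    return out


def loro_truth(matrix: RaterMatrix, held_out_rater: int | str) -> list[ConsensusLabel]:
    """Leave-one-rater-out consensus: majority among the remaining raters.

    Exact splits among the remaining (even) raters are flagged ``tied``
    and should be excluded from that rater's accuracy computation — the
    held-out rater's own decisions never form part of their ground truth.
    """
    if matrix.n_raters < 3:
        raise ValueError("leave-one-rater-out needs at least 3 raters")
    if isinstance(held_out_rater, str):
        held_out_rater = matrix.rater_ids.index(held_out_rater)
    keep = [i for i in range(matrix.n_raters) if i != held_out_rater]
    sub = RaterMatrix(
        labels=matrix.labels[:, keep],
        rater_ids=[matrix.rater_ids[i] for i in keep],
        rater_tiers=[matrix.rater_tiers[i] for i in keep] if matrix.rater_tiers else [],
    )
    return majority_vote(sub)


def score_as_rater(
    predictions: np.ndarray, matrix: RaterMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Truth/prediction pair for scoring a model like an eighth rater.

    The model's ground truth is the full-panel consensus (the model's
    own decisions are not part of any panel), with tied epochs — only
    possible for even panels — excluded.  Returns aligned (truth, pred).
    """
    cons = majority_vote(matrix)
    keep = np.array([not c.tied for c in cons])
    truth = np.array([c.label for c in cons])[keep]
    return truth, np.asarray(predictions).astype(int)[keep]
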