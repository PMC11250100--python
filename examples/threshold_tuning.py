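"""Trading sensitivity against specificity with the posterior threshold.

The forest's posterior is the estimated probability that the rater
panel would reject an epoch.  Sweeping the decision threshold moves
the operating point along the ROC curve; this prints a few points so
a user can pick a balance for their application (e.g. high specificity
for clinical decisions, low rejection rates for trials).
"""

import numpy as np

from epochsift.classifier import ForestConfig, classify, predict_proba, train
from epochsift.consensus import ConsensusLabel
from epochsift.evaluate import confusion_metrics, roc
from epochsift.features import extract_table
from epochsift.synthetic import ARTEFACT_KINDS, GeneratorSpec, gen_clean_epoch, inject_artefact

spec = GeneratorSpec(seed=21)


def make(seed, n_each, severity):
    rng = np.random.default_rng(seed)
    eps, y = [], []
    for i in range(2 * n_each):
        ep = gen_clean_epoch(spec, rng)
        if i % 2:
            ep = inject_artefact(ep, ARTEFACT_KINDS[i % 6], rng, severity=severity)
        eps.append(ep)
        y.append(i % 2)
    return extract_table(eps), np.array(y)


# mild artefacts (severity 0.25) make the trade-off visible
X_tr, y_tr = make(21, 60, 0.25)
X_te, y_te = make(22, 40, 0.25)
cons = [ConsensusLabel(int(v), 7, 1.0) for v in y_tr]
model = train(X_tr, cons, ForestConfig(seed=21))
post = predict_proba(model, X_te)
_, auc = roc(post, y_te)

print(f"{'threshold':>10}{'sensitivity':>13}{'specificity':>13}{'rejected':>10}")
for thr in (0.2, 0.35, 0.5, 0.65, 0.8):
    pred = classify(model, X_te, threshold=thr)
    rep = confusion_metrics(pred, y_te)
    print(f"{thr:>10.2f}{rep.sensitivity:>13.2f}{rep.specificity:>13.2f}"
          f"{int(pred.sum()):>10}")
print(f"\nROC AUC {auc:.2f}.  Raising the threshold rejects fewer epochs")
print("(higher specificity, lower sensitivity); lowering it catches more")
print("artefact at the cost of discarding clean data.")
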