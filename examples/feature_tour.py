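"""How each artefact class moves its designated feature.

Injects every artefact kind into the same clean epoch and prints the
feature the injection is designed to shift, next to its clean value.
"""

import numpy as np

from epochsift.features import extract_all
from epochsift.synthetic import ARTEFACT_KINDS, GeneratorSpec, gen_clean_epoch, inject_artefact

DESIGNATED = {
    "movement_burst": "amplitude_change_50ms",
    "step": "amplitude_change_50ms",
    "spike": "amplitude_change_50ms",
    "mains_50hz": "bandpower_gamma",
    "flatline": "amplitude_variance",
    "slow_drift": "power_below_0p5hz",
}

spec = GeneratorSpec(seed=7)
rng = np.random.default_rng(7)
clean = gen_clean_epoch(spec, rng)
fv_clean = extract_all(clean)

print(f"{'artefact':<16}{'feature':<24}{'clean':>12}{'artefactual':>14}{'ratio':>9}")
for kind in ARTEFACT_KINDS:
    feat = DESIGNATED[kind]
    fv = extract_all(inject_artefact(clean, kind, rng))
    a, b = fv_clean[feat], fv[feat]
    print(f"{kind:<16}{feat:<24}{a:>12.3g}{b:>14.3g}{b / a:>9.2f}")

print()
print("Each kind shifts its designated descriptor by the factor shown —")
print("mains breakthrough inflates gamma power, detachment collapses the")
print("amplitude variance (ratio << 1), drift loads the sub-0.5 Hz band,")
print("and transient artefacts inflate the 50 ms amplitude change.")
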