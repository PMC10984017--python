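"""Pseudo-simultaneous population decoding of alcohol vs water drinking.

Builds pseudo-populations from two simulated animals, decodes drinking
class with a cross-validated linear SVM, and compares the observed
accuracy with a label-shuffle null.
"""

import numpy as np

from isoensemble.decoding import build_pseudopopulation, decode, shuffle_control
from isoensemble.neural import align_events, zscore_baseline
from isoensemble.synth import gen_calcium_population

animals = []
for seed in (31, 32):
    events = {
        "alcohol": np.arange(15) * 50.0 + 20.0,
        "water": np.arange(15) * 50.0 + 45.0,
    }
    traces, ft, _ = gen_calcium_population(
        40, events, duration_s=800.0, frac_excited=0.25, frac_inhibited=0.1,
        amplitude_z=3.0, seed=seed,
    )
    animals.append({
        cls: zscore_baseline(align_events(traces, ft, t, event_class=cls))
        for cls, t in events.items()
    })

dataset = build_pseudopopulation(
    animals, classes=("alcohol", "water"),
    n_trials_per_class=20, n_resamples=30, seed=33,
)
accuracy = decode(dataset, folds=5)
null = shuffle_control(dataset, n_shuffles=50, observed=accuracy, seed=34)

print(f"Neurons pooled across animals: {dataset.n_neurons}")
print(f"Mean cross-validated accuracy: {accuracy['accuracy'].mean():.3f}")
print(f"Label-shuffle null mean:       {null['null_mean']:.3f}")
print(f"Empirical p-value:             {null['p_empirical']:.4f}")
print("\nAccuracy well above the ~0.5 shuffle null means population activity")
print("carries enough information to tell alcohol from water drinking.")
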