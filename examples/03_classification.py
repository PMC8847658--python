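"""Discriminating two cohorts from the six stability metrics.

Each subject is reduced to six numbers — (min ln_pi, best window) for the
strongest link, the most central node and the highest-clustering node — and
a random forest is scored by leave-one-out cross-validation, against a
shuffled-label chance baseline.  Feature relevance is the accuracy drop when
a metric is withheld.
"""

import numpy as np

from netstab import (
    PlantedPair,
    SyntheticSpec,
    feature_importance_drop,
    generate_group,
    generate_null,
    loo_accuracy,
    subject_summary,
)

grid = np.round(np.logspace(1, 2.4, 8), 1)

template = SyntheticSpec(
    n_channels=8, duration_s=8.0, sampling_rate_hz=500.0,
    planted_pairs=(PlantedPair(0, 1, rho=0.9, q=0.8, epoch_ms=30.0),), seed=42,
)
planted = [rec for rec, _ in generate_group(10, template, shared_structure=False)]
nulls = [
    generate_null(SyntheticSpec(n_channels=8, duration_s=8.0, sampling_rate_hz=500.0, seed=900 + i), f"null{i}")
    for i in range(10)
]
summaries = [subject_summary(r, grid) for r in planted + nulls]
labels = ["planted"] * 10 + ["null"] * 10

rep = loo_accuracy(summaries, labels, mode="stability", n_realisations=10, seed=0)
base = loo_accuracy(summaries, labels, mode="shuffled_labels", n_realisations=10, seed=0)
print(f"stability features : LOO accuracy {rep.mean_accuracy:.2f} ± {rep.sd_accuracy:.2f}")
print(f"shuffled labels    : LOO accuracy {base.mean_accuracy:.2f} ± {base.sd_accuracy:.2f}")

drops = feature_importance_drop(summaries, labels, n_realisations=5, seed=1)
print("\naccuracy drop when withheld:")
for name, drop in drops.items():
    print(f"  {name:45s} {drop:+.3f}")
print(
    "\nPlanted subjects carry a persistent link, so their stability metrics are\n"
    "far from the noise subjects' — the forest separates the groups while the\n"
    "shuffled baseline stays at chance.  Drops near zero mean the metrics are\n"
    "redundant here: the planted coupling deepens the link, node-strength and\n"
    "clustering metrics together, so any five still separate the groups."
)
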