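"""Group-level aggregation: mean profiles, jackknife envelopes, pooling.

Builds two small cohorts — one sharing a planted link across subjects, one
of pure-noise subjects — and compares group-mean stability, the sensitivity
of the group summary to single subjects, and the pooled intra-group
probability of the same link being strongest in every subject.
"""

import numpy as np

from netstab import (
    Feature,
    PlantedPair,
    SyntheticSpec,
    compare_best_windows,
    generate_group,
    generate_null,
    group_mean_profile,
    intra_group_stability,
    stability_profile,
)

grid = [15.0, 30.0, 60.0, 120.0, 240.0]
link = Feature.strongest_link()

template = SyntheticSpec(
    n_channels=8, duration_s=12.0, sampling_rate_hz=500.0,
    planted_pairs=(PlantedPair(2, 5, rho=0.9, q=0.9, epoch_ms=30.0),), seed=5,
)
stable_cohort = [rec for rec, _ in generate_group(6, template, shared_structure=True)]
noise_cohort = [
    generate_null(SyntheticSpec(n_channels=8, duration_s=12.0, sampling_rate_hz=500.0, seed=100 + i), f"noise{i}")
    for i in range(6)
]

for name, cohort in [("planted", stable_cohort), ("noise", noise_cohort)]:
    profiles = [stability_profile(r, link, grid) for r in cohort]
    gp = group_mean_profile(profiles, group=name)
    lo, hi = gp.envelope["min_ln_pi"]
    print(f"group {name!r}: peak of mean curve at {gp.best_window_ms} ms, "
          f"mean min ln_pi {gp.min_ln_pi:.1f} (jackknife [{lo:.1f}, {hi:.1f}])")
    pooled = intra_group_stability(cohort, link, [30.0], group=name).grid[0][1]
    print(f"  pooled across subjects at 30 ms: modal {pooled.modal_identity}, "
          f"k/n = {pooled.k}/{pooled.n}, ln_pi = {pooled.ln_pi:.1f}")

stat, p = compare_best_windows(
    [stability_profile(r, link, grid).best_window_ms for r in stable_cohort],
    [stability_profile(r, link, grid).best_window_ms for r in noise_cohort],
)
print(f"KS test on optimal window lengths, planted vs noise: D = {stat:.2f}, p = {p:.3f}")
print()
print(
    "The planted group pools to one deeply improbable modal link (the shared\n"
    "pair (2, 5)); the noise group's pooled ln_pi stays near 0.  The jackknife\n"
    "interval shows how much one subject can move the group summary."
)
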