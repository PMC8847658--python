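"""Stability of the strongest link on one subject, and its timescale.

Generates a recording with one planted coupling (channels 0–1, correlation
0.9, switched on/off in 30 ms epochs with 80% persistence), scans window
lengths, and prints the stability profile.  The planted pair should be the
modal strongest link, with the optimal window near the 30 ms epoch.
"""

import numpy as np

from netstab import Feature, PlantedPair, SyntheticSpec, generate_planted, stability_profile

spec = SyntheticSpec(
    n_channels=8,
    duration_s=24.0,
    sampling_rate_hz=500.0,
    planted_pairs=(PlantedPair(0, 1, rho=0.9, q=0.8, epoch_ms=30.0),),
    seed=11,
)
recording, truth = generate_planted(spec)
grid = np.round(np.logspace(1, 2.7, 12), 1)  # 10–500 ms

profile = stability_profile(recording, Feature.strongest_link(), grid)

print("window_ms  modal_link   k/n      ln_pi")
for window_ms, res in profile.grid:
    print(f"{window_ms:8.1f}  {str(res.modal_identity):10s}  {res.k:4d}/{res.n:<4d}  {res.ln_pi:10.1f}")
print()
print(f"optimal window: {profile.best_window_ms} ms   min ln_pi: {profile.min_ln_pi:.1f}")
print(
    "The modal link matches the planted pair (0, 1); ln_pi is the log\n"
    "probability of a modal count this extreme under independent networks —\n"
    "values this negative mean the link's dominance is not chance.  The\n"
    "minimising window falls within a factor of two of the planted 30 ms\n"
    "epoch: shorter windows buy more trials n until correlation estimates\n"
    "become too noisy to keep the planted link on top."
)
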