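"""Relating stability metrics to subject covariates.

Builds a synthetic cohort whose 'age' is constructed to track the stability
of the strongest link, then computes the Spearman table (α = 0.01 flags) and
the OLS R² of each covariate on the six metrics.
"""

import numpy as np

from netstab import SubjectMetadata, ols_r2, spearman_table
from netstab.stability import SIX_METRIC_FEATURES, SubjectStabilitySummary

rng = np.random.default_rng(3)
names = [str(f) for f in SIX_METRIC_FEATURES]

summaries, metadata = [], []
for i in range(30):
    vec = np.concatenate([[-rng.uniform(5, 120), rng.choice([20.0, 40.0, 80.0])] for _ in range(3)])
    sid = f"s{i:02d}"
    summaries.append(
        SubjectStabilitySummary(
            subject_id=sid,
            min_ln_pi={n: vec[2 * j] for j, n in enumerate(names)},
            best_window_ms={n: vec[2 * j + 1] for j, n in enumerate(names)},
        )
    )
    metadata.append(
        SubjectMetadata(
            subject_id=sid,
            group="g",
            age=55 - 0.3 * vec[0] + rng.normal(0, 4),  # tracks link stability
            education=rng.uniform(5, 20),
            cognitive_scores={"MMSE": rng.uniform(20, 30)},
        )
    )

table = spearman_table(summaries, metadata, ["age", "education", "MMSE"])
print(table.to_string(index=False, float_format=lambda v: f"{v: .3f}"))
for cov in ("age", "education"):
    fit = ols_r2(summaries, metadata, cov)
    print(f"\nOLS R² for {cov}: {fit.r_squared:.3f} (n = {fit.n})")
print(
    "\n'age' was built to follow the strongest-link ln_pi, so its Spearman rho\n"
    "with that metric is large and flagged significant, and its R² is high;\n"
    "'education' and 'MMSE' are independent noise and should show small rho\n"
    "and R² near zero."
)
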