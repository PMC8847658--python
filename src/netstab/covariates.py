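"""Relating the six stability metrics to demographic/cognitive covariates.

Spearman rank correlations (one ρ per covariate × metric, flagged at a
configurable significance level) and, per covariate, the coefficient of
determination R² of an ordinary-least-squares fit of the covariate on all
six metrics plus intercept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import SubjectMetadata
from .stability import SubjectStabilitySummary

__all__ = ["spearman_table", "ols_r2", "OlsFit", "covariate_frame"]


def covariate_frame(
    summaries: Sequence[SubjectStabilitySummary],
    metadata: Sequence[SubjectMetadata],
) -> pd.DataFrame:
    """Join the six metrics with covariates on subject_id (inner join)."""
    meta = {m.subject_id: m for m in metadata}
    rows = []
    for s in summaries:
        m = meta.get(s.subject_id)
        if m is None:
            continue
        row = {"subject_id": s.subject_id, "group": m.group, "age": m.age, "education": m.education}
        row.update(m.cognitive_scores)
        row.update(dict(zip(SubjectStabilitySummary.feature_names(), s.as_vector())))
        rows.append(row)
    if not rows:
        raise ValueError("no subjects shared between summaries and metadata")
    return pd.DataFrame(rows).set_index("subject_id")


def spearman_table(
    summaries: Sequence[SubjectStabilitySummary],
    metadata: Sequence[SubjectMetadata],
    covariates: Sequence[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Spearman ρ between each covariate and each of the six metrics.

    Missing covariate values are dropped pairwise; each cell needs ≥ 3 paired
    observations.  Raw p-values are reported with a significance flag at
    ``alpha``.
    """
    df = covariate_frame(summaries, metadata)
    metric_cols = SubjectStabilitySummary.feature_names()
    rows = []
    for cov in covariates:
        if cov not in df.columns:
            raise KeyError(f"unknown covariate {cov!r}")
        for metric in metric_cols:
            pair = df[[cov, metric]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"covariate {cov!r} × {metric}: only {len(pair)} paired "
                    "observations (need ≥ 3)"
                )
            rho, p = stats.spearmanr(pair[cov], pair[metric])
            rows.append(
                {
                    "covariate": cov,
                    "metric": metric,
                    "rho": float(rho),
                    "p": float(p),
                    "significant": bool(p < alpha),
                    "n": len(pair),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class OlsFit:
    """R² of response ~ six metrics + intercept, with degeneracy flags."""

    response: str
    r_squared: float
    n: int
    degenerate: bool = False
    note: str = ""


def ols_r2(
    summaries: Sequence[SubjectStabilitySummary],
    metadata: Sequence[SubjectMetadata],
    response: str,
) -> OlsFit:
    """Least-squares fit of one covariate on the six metrics (complete cases).

    A constant response or rank-deficient design is reported with R² = 0 and
    a degeneracy flag rather than an error.
    """
    df = covariate_frame(summaries, metadata)
    metric_cols = SubjectStabilitySummary.feature_names()
    sub = df[[response] + metric_cols].dropna()
    n = len(sub)
    if n < len(metric_cols) + 2:
        raise ValueError(
            f"{n} complete cases for {response!r}; need more observations than "
            f"{len(metric_cols)} predictors + intercept"
        )
    y = sub[response].to_numpy(float)
    if np.ptp(y) == 0.0:
        return OlsFit(response=response, r_squared=0.0, n=n, degenerate=True, note="constant response")
    x = sm.add_constant(sub[metric_cols].to_numpy(float))
    fit = sm.OLS(y, x).fit()
    degenerate = np.linalg.matrix_rank(x) < x.shape[1]
    return OlsFit(
        response=response,
        r_squared=float(min(max(fit.rsquared, 0.0), 1.0)),
        n=n,
        degenerate=bool(degenerate),
        note="rank-deficient design" if degenerate else "",
    )
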