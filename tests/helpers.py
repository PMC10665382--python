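"""Independent oracles used by the test suite.

These deliberately avoid the package's own computational paths: the nested
ANOVA estimator works from raw sums of squares, the Benjamini-Hochberg
oracle enumerates the step-up definition directly, and the binomial tail is
summed from math.comb.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def ems_nested_anova(df: pd.DataFrame, trait: str) -> tuple[float, float, float]:
    """Closed-form expected-mean-squares estimators for a balanced nested design.

    Returns (v_population, v_family, v_residual); valid only for balanced
    population x family x plant layouts with no fixed effects beyond the
    grand mean.  Estimates may be negative (no truncation) — callers decide
    how to treat boundary cases.
    """
    P = df["population_id"].nunique()
    F = int(df.groupby("population_id")["family_id"].nunique().iloc[0])
    K = int(df.groupby("family_id").size().iloc[0])
    y = df[trait]
    gm = y.mean()
    pop_means = df.groupby("population_id")[trait].mean()
    fam_means = df.groupby("family_id")[trait].mean()
    fam_pop = df.groupby("family_id")["population_id"].first()

    ss_p = F * K * ((pop_means - gm) ** 2).sum()
    ss_f = K * ((fam_means - pop_means[fam_pop].values) ** 2).sum()
    ss_w = ((y - fam_means[df["family_id"]].values) ** 2).sum()
    ms_p = ss_p / (P - 1)
    ms_f = ss_f / (P * (F - 1))
    ms_w = ss_w / (P * F * (K - 1))
    return (ms_p - ms_f) / (F * K), (ms_f - ms_w) / K, ms_w


def bh_stepup_bruteforce(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by direct step-up enumeration."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    for rank_idx in range(n):
        i = order[rank_idx]
        # smallest n*p_(j)/j over all j at or above this rank
        candidates = [
            n * p[order[j]] / (j + 1) for j in range(rank_idx, n)
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


def binom_upper_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0), summed exactly from math.comb."""
    return sum(
        math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1)
    )
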