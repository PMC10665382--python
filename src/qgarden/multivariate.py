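"""Multivariate phenotype vs urbanization: a sum-of-statistics permutation test.

Population-level BLUPs from the per-trait nested mixed models are assembled
into a populations x traits response matrix.  Each trait contributes the
likelihood-ratio statistic of regressing its BLUP column on the urbanization
metric (against an intercept-only model); the global statistic is the sum
over traits.  Its null distribution is obtained by permuting the metric
vector across populations with the same permutation applied to every column,
which preserves the inter-trait correlation structure of the rows, in the
style of resampling-based multivariate-abundance tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .varcomp import VarianceComponents, blup_family, blup_population


@dataclass
class BlupMatrix:
    """Populations x traits matrix of predicted random effects."""

    values: pd.DataFrame  # rows: populations, columns: traits
    metadata: pd.DataFrame  # per-population distance_km, urb_score, subtransect
    zero_variance_traits: tuple[str, ...] = ()
    imputed: int = 0


@dataclass
class MultivariateTestResult:
    statistic: float
    p_perm: float
    n_perm: int
    per_trait_stats: pd.Series
    metric: str


def build_blup_matrix(
    fits: dict[str, VarianceComponents],
    data=None,
    level: str = "population",
) -> BlupMatrix:
    """Assemble per-trait population BLUPs into a response matrix.

    Traits fitted with zero population variance contribute all-zero columns
    (retained and flagged).  Populations missing from a trait's fit are
    imputed at 0, the BLUP prior mean, and counted in ``imputed``.  Column
    order follows the ``fits`` mapping order deterministically.
    """
    if level not in ("population", "family"):
        raise ValueError("level must be 'population' or 'family'")
    if not fits:
        raise ValueError("no fits supplied")
    extractor = blup_population if level == "population" else blup_family
    cols = {trait: extractor(vc) for trait, vc in fits.items()}
    index: pd.Index | None = None
    for s in cols.values():
        index = s.index if index is None else index.union(s.index)
    if index is None or len(index) == 0:
        raise ValueError("fits share no populations")
    shared = None
    for s in cols.values():
        shared = s.index if shared is None else shared.intersection(s.index)
    if shared is not None and len(shared) == 0:
        raise ValueError("fits share no populations")

    mat = pd.DataFrame(index=index)
    imputed = 0
    zero_cols = []
    for trait, s in cols.items():
        col = s.reindex(index)
        imputed += int(col.isna().sum())
        mat[trait] = col.fillna(0.0)
        if np.allclose(mat[trait].to_numpy(), 0.0):
            zero_cols.append(trait)

    meta = pd.DataFrame(index=index)
    if data is not None and level == "population":
        records = getattr(data, "records", data)
        per_pop = (
            records.groupby("population_id")[["distance_km", "urb_score"]].first()
        )
        sub = records.groupby("population_id")["subtransect"].first()
        meta = per_pop.join(sub).reindex(index)
    return BlupMatrix(
        values=mat,
        metadata=meta,
        zero_variance_traits=tuple(zero_cols),
        imputed=imputed,
    )


def _sum_lr_stats(Y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-trait LR statistics n*log(RSS0/RSS1) for simple regression on x."""
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    xc = x - x.mean()
    Sxx = float(xc @ xc)
    Syy = np.einsum("ij,ij->j", Yc, Yc)
    Sxy = xc @ Yc
    rss1 = np.maximum(Syy - Sxy**2 / Sxx, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        stats_ = n * np.log(np.where(Syy > 0, Syy / rss1, 1.0))
    return np.where(Syy > 0, stats_, 0.0)


def multivariate_urbanization_test(
    m: BlupMatrix,
    metric: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> MultivariateTestResult:
    """Permutation test of multivariate phenotype against an urbanization metric.

    ``p = (1 + #{perm stat >= observed}) / (1 + n_perm)``.  An all-zero BLUP
    matrix returns p = 1 with a warning (no resolvable signal).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if metric not in m.metadata.columns:
        raise ValueError(f"metric {metric!r} missing from BlupMatrix metadata")
    x = m.metadata[metric].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"metric {metric!r} is constant across populations")
    Y = m.values.to_numpy(dtype=float)
    traits = list(m.values.columns)

    if np.allclose(Y, 0.0):
        warnings.warn("all BLUPs are zero; multivariate test has no signal")
        return MultivariateTestResult(
            statistic=0.0,
            p_perm=1.0,
            n_perm=n_perm,
            per_trait_stats=pd.Series(0.0, index=traits),
            metric=metric,
        )

    per_trait = _sum_lr_stats(Y, x)
    observed = float(per_trait.sum())

    rng = np.random.default_rng(seed)
    n = len(x)
    count = 0
    for _ in range(n_perm):
        stat = float(_sum_lr_stats(Y, x[rng.permutation(n)]).sum())
        if stat >= observed:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return MultivariateTestResult(
        statistic=observed,
        p_perm=p,
        n_perm=n_perm,
        per_trait_stats=pd.Series(per_trait, index=traits),
        metric=metric,
    )
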