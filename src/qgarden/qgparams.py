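"""Quantitative-genetic statistics derived from nested variance components.

For full-sib families the total genetic variance is estimated as twice the
family-level variance, giving the broad-sense heritability

    H^2 = 2 * v_fam / (v_fam + v_pop + v_res),

the among-population differentiation of a quantitative trait

    Q_ST = v_pop / (v_pop + 2 * (2 * v_fam)),

the coefficient of genetic variation CV_G = sqrt(2 * v_fam) / trait_mean,
and the per-effect percent variance explained PVE = v / (v + v_res).

H^2 as defined can exceed 1 when 2*v_fam exceeds the total phenotypic
variance; it is reported as computed, never capped.  Undefined statistics
(zero denominators) raise, and report assembly converts them to
not-available markers rather than silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .exceptions import UndefinedStatisticError
from .varcomp import VarianceComponents


@dataclass
class QGEstimates:
    """Derived quantitative-genetic quantities for one trait."""

    trait: str
    H2: float
    CVg: float | None
    Qst: float | None
    PVE_family: float
    PVE_population: float
    genetic_variance: float


def heritability(vc: VarianceComponents) -> float:
    """Full-sib broad-sense heritability 2*v_fam / total phenotypic variance."""
    total = vc.total_variance
    if total <= 0:
        raise UndefinedStatisticError("total phenotypic variance is zero")
    return 2.0 * vc.v_family / total


def qst(vc: VarianceComponents) -> float:
    """Among-population differentiation v_pop / (v_pop + 4*v_fam).

    Equals 1 when all genetic variance is among populations (v_fam = 0,
    v_pop > 0) and 0 when none is (v_pop = 0, v_fam > 0).
    """
    denom = vc.v_population + 2.0 * (2.0 * vc.v_family)
    if denom <= 0:
        raise UndefinedStatisticError(
            "population and family variances are both zero; Q_ST undefined"
        )
    return vc.v_population / denom


def coefficient_genetic_variation(
    vc: VarianceComponents, mean: float | None = None
) -> float:
    """CV_G = sqrt(genetic variance) / trait mean (dimensionless).

    By default the mean of the analyzed (possibly transformed) response is
    used; pass ``mean`` to divide by a raw-scale mean instead.
    """
    m = vc.trait_mean if mean is None else mean
    if m == 0:
        raise UndefinedStatisticError("trait mean is zero; CV_G undefined")
    return math.sqrt(2.0 * vc.v_family) / m


def pve(v_effect: float, v_residual: float) -> float:
    """Percent variance explained v / (v + v_res), in [0, 1]."""
    if v_effect < 0 or v_residual < 0:
        raise ValueError("variances must be nonnegative")
    denom = v_effect + v_residual
    if denom <= 0:
        raise UndefinedStatisticError("both variances zero; PVE undefined")
    return v_effect / denom


def qg_estimates(vc: VarianceComponents) -> QGEstimates:
    """All derived statistics for one fit; undefined entries become None."""

    def _try(f):
        try:
            return f(vc)
        except UndefinedStatisticError:
            return None

    return QGEstimates(
        trait=vc.trait,
        H2=heritability(vc),
        CVg=_try(coefficient_genetic_variation),
        Qst=_try(qst),
        PVE_family=pve(vc.v_family, vc.v_residual),
        PVE_population=pve(vc.v_population, vc.v_residual),
        genetic_variance=2.0 * vc.v_family,
    )


def relative_growth_rate(
    height_before: float, height_after: float, days: float
) -> float:
    """RGR = (ln h_after - ln h_before) / days, per day.

    Natural log.  The analysis set is restricted upstream to plants with
    positive growth between measurements; non-positive inputs are domain
    errors, never clamped.
    """
    if height_before <= 0 or height_after <= 0:
        raise ValueError("heights must be positive")
    if days <= 0:
        raise ValueError("days must be positive")
    return (math.log(height_after) - math.log(height_before)) / days


def positive_growth_mask(
    height_before: np.ndarray, height_after: np.ndarray
) -> np.ndarray:
    """Boolean mask selecting plants with positive growth (RGR analysis set)."""
    hb = np.asarray(height_before, dtype=float)
    ha = np.asarray(height_after, dtype=float)
    with np.errstate(invalid="ignore"):
        return (hb > 0) & (ha > hb)


def hurdle_split(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a zero-inflated vector into occurrence and positive parts.

    Returns ``(occurrence, positive)`` where occurrence is the 0/1 indicator
    of a positive value for every record (NaN preserved) and positive holds
    the positive values only; each part is then modeled separately.  An
    all-zero input yields an empty positive part, which downstream fitting
    flags rather than errors.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size and finite.min() < 0:
        raise ValueError("hurdle traits must be nonnegative")
    occurrence = np.where(np.isnan(v), np.nan, (v > 0).astype(float))
    positive = v[np.isfinite(v) & (v > 0)]
    return occurrence, positive


def summarize_traits(
    table: pd.DataFrame,
    field: str,
    alpha: float = 0.05,
    p_field: str | None = None,
) -> dict:
    """Column summary across traits: mean, SE, min, max, count significant.

    ``field`` is one of the derived-statistic columns (``H2``, ``CVg``,
    ``Qst``); the standard error is the sample (n-1) standard deviation over
    sqrt(n).  Undefined (NaN) entries are excluded and counted.  If
    ``p_field`` is given (defaults to the matching p column), significance
    is counted as p <= alpha.
    """
    if len(table) == 0:
        raise ValueError("empty trait table")
    vals = pd.to_numeric(table[field], errors="coerce")
    ok = vals.dropna()
    if len(ok) < 2:
        raise ValueError("need >= 2 defined values to summarize")
    if p_field is None:
        p_field = {"H2": "p_family", "CVg": "p_family", "Qst": "p_population"}.get(field)
    n_sig = None
    if p_field is not None and p_field in table.columns:
        n_sig = int((pd.to_numeric(table[p_field], errors="coerce") <= alpha).sum())
    n = len(ok)
    return {
        "mean": float(ok.mean()),
        "se": float(ok.std(ddof=1) / math.sqrt(n)),
        "min": float(ok.min()),
        "max": float(ok.max()),
        "n": n,
        "n_excluded": int(len(vals) - n),
        "n_significant": n_sig,
    }
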