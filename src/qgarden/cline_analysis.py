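"""Urbanization-cline and green-corridor models for common-garden traits.

The cline model adds an urbanization metric (distance to the city center or
an urbanization score) as a fixed effect to the nested mixed model; the
corridor model, fitted on the two urban subtransects only, adds a
subtransect factor and its interaction with the metric.  Fixed-effect
chi-square tests are maximum-likelihood likelihood-ratio drops: type II
drops each main effect from the no-interaction model; type III (sum-to-zero
contrasts) drops each term, mains included, from the full model.  Full
(with interaction) and reduced models are ranked by AIC, ties going to the
reduced model; type III is used only when the AIC-best model contains an
interaction with p <= 0.1, otherwise type II on the reduced model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDesignError
from .varcomp import (
    NestedLMMEngine,
    VarianceComponents,
    _maximize,
    build_design,
    fit_nested_lmm,
)

URBAN_SUBTRANSECTS = ("urban_corridor", "urban_noncorridor")


@dataclass
class FixedEffectTest:
    """Likelihood-ratio chi-square test of one fixed-effect term."""

    term: str
    chi2: float
    df: int
    p: float
    ss_type: str  # "II" or "III"


@dataclass
class ClineModelResult:
    trait: str
    metric: str
    tests: dict[str, FixedEffectTest]
    marginal_r2: float
    vc: VarianceComponents
    n_individuals: int
    n_populations: int


@dataclass
class CorridorModelResult(ClineModelResult):
    subtransect_test: FixedEffectTest | None = None
    interaction_test: FixedEffectTest | None = None
    aic_full: float = float("nan")
    aic_reduced: float = float("nan")
    selected: str = "reduced"


def _complete_case(data, trait: str, columns: Sequence[str]) -> pd.DataFrame:
    records = getattr(data, "records", data)
    df = records.loc[records[trait].notna()].copy()
    for c in columns:
        df = df.loc[df[c].notna()]
    if df["population_id"].nunique() < 2 or df["family_id"].nunique() < 2:
        raise DegenerateDesignError("too few populations/families after filtering")
    return df


def _codes(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    pop = pd.Categorical(
        df["population_id"], categories=pd.unique(df["population_id"])
    ).codes.astype(int)
    fam = pd.Categorical(
        df["family_id"], categories=pd.unique(df["family_id"])
    ).codes.astype(int)
    return pop, fam


def _ml_loglik(
    df: pd.DataFrame,
    y: np.ndarray,
    terms: Sequence[str],
    pop: np.ndarray,
    fam: np.ndarray,
    coding: str = "treatment",
) -> tuple[float, int]:
    """Maximized ML log-likelihood and parameter count (fixed + 3 variances)."""
    X, _ = build_design(df, terms, coding=coding)
    engine = NestedLMMEngine(X, y, pop, fam)
    sol = _maximize(engine, reml=False)
    return sol["loglik"], X.shape[1] + 3


def _lrt(ll_full: float, ll_drop: float, df: int, term: str, ss_type: str) -> FixedEffectTest:
    chi2 = max(0.0, 2.0 * (ll_full - ll_drop))
    return FixedEffectTest(
        term=term, chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)), ss_type=ss_type
    )


def _term_df(df: pd.DataFrame, term: str) -> int:
    if ":" in term:
        a, b = term.split(":", 1)
        return _term_df(df, a) * _term_df(df, b)
    if term in ("block", "subtransect") or df[term].dtype == object:
        return df[term].nunique() - 1
    return 1


def _marginal_r2(vc: VarianceComponents) -> float:
    """Fixed-effect variance over fixed + random + residual variance."""
    engine = vc._context["engine"]
    fitted = engine.X @ vc.fixed_effects
    v_fixed = float(np.var(fitted))
    denom = v_fixed + vc.v_population + vc.v_family + vc.v_residual
    return v_fixed / denom if denom > 0 else 0.0


def fit_cline_model(data, trait: str, metric: str) -> ClineModelResult:
    """Test for a genetic cline in one trait along one urbanization metric.

    Variance components are reported from the REML fit including the metric;
    the chi-square tests for block and metric are ML likelihood-ratio drops
    from the no-interaction model (type II convention).
    """
    if metric not in ("distance_km", "urb_score"):
        raise ValueError("metric must be 'distance_km' or 'urb_score'")
    df = _complete_case(data, trait, [metric])
    if np.ptp(df[metric].to_numpy(dtype=float)) == 0:
        raise DegenerateDesignError(f"metric {metric!r} is constant")
    y = df[trait].to_numpy(dtype=float)
    pop, fam = _codes(df)
    has_block = df["block"].nunique() > 1
    base = ["block"] if has_block else []
    terms = base + [metric]

    ll_full, _ = _ml_loglik(df, y, terms, pop, fam)
    tests: dict[str, FixedEffectTest] = {}
    for term in terms:
        others = [t for t in terms if t != term]
        ll_drop, _ = _ml_loglik(df, y, others, pop, fam)
        tests[term] = _lrt(ll_full, ll_drop, _term_df(df, term), term, "II")

    vc = fit_nested_lmm(df, trait, covariates=[metric])
    return ClineModelResult(
        trait=trait,
        metric=metric,
        tests=tests,
        marginal_r2=_marginal_r2(vc),
        vc=vc,
        n_individuals=len(df),
        n_populations=int(df["population_id"].nunique()),
    )


def restrict_to_urban(data) -> pd.DataFrame:
    records = getattr(data, "records", data)
    return records.loc[records["subtransect"].isin(URBAN_SUBTRANSECTS)].copy()


def fit_corridor_model(data, trait: str, metric: str) -> CorridorModelResult:
    """Test corridor vs urban-matrix divergence in one trait.

    Fits full (metric + subtransect + metric:subtransect) and reduced (no
    interaction) models under ML on the two urban subtransects, selects by
    AIC (ties to reduced), then reports type III tests when the selected
    model carries an interaction with p <= 0.1 and type II tests on the
    reduced model otherwise.
    """
    urban = restrict_to_urban(data)
    df = _complete_case(urban, trait, [metric])
    present = sorted(df["subtransect"].unique())
    if len(present) < 2:
        raise DegenerateDesignError(
            f"corridor model needs both urban subtransects, found {present}"
        )
    if np.ptp(df[metric].to_numpy(dtype=float)) == 0:
        raise DegenerateDesignError(f"metric {metric!r} is constant")
    y = df[trait].to_numpy(dtype=float)
    pop, fam = _codes(df)
    has_block = df["block"].nunique() > 1
    base = ["block"] if has_block else []
    inter = f"{metric}:subtransect"
    terms_red = base + [metric, "subtransect"]
    terms_full = terms_red + [inter]

    ll_red, k_red = _ml_loglik(df, y, terms_red, pop, fam)
    ll_full, k_full = _ml_loglik(df, y, terms_full, pop, fam)
    aic_red = -2.0 * ll_red + 2.0 * k_red
    aic_full = -2.0 * ll_full + 2.0 * k_full
    selected = "full" if aic_full < aic_red else "reduced"

    df_int = _term_df(df, inter)
    interaction_test = _lrt(ll_full, ll_red, df_int, inter, "III")

    tests: dict[str, FixedEffectTest] = {}
    if selected == "full" and interaction_test.p <= 0.1:
        # type III: sum-to-zero contrasts, every term dropped from the full model
        ll_full3, _ = _ml_loglik(df, y, terms_full, pop, fam, coding="sum")
        for term in terms_full:
            others = [t for t in terms_full if t != term]
            ll_drop, _ = _ml_loglik(df, y, others, pop, fam, coding="sum")
            tests[term] = _lrt(ll_full3, ll_drop, _term_df(df, term), term, "III")
        keep_interaction = True
    else:
        for term in terms_red:
            others = [t for t in terms_red if t != term]
            ll_drop, _ = _ml_loglik(df, y, others, pop, fam)
            tests[term] = _lrt(ll_red, ll_drop, _term_df(df, term), term, "II")
        keep_interaction = False

    vc = fit_nested_lmm(
        df,
        trait,
        covariates=[metric, "subtransect"] + ([inter] if keep_interaction else []),
    )
    return CorridorModelResult(
        trait=trait,
        metric=metric,
        tests=tests,
        marginal_r2=_marginal_r2(vc),
        vc=vc,
        n_individuals=len(df),
        n_populations=int(df["population_id"].nunique()),
        subtransect_test=tests.get("subtransect"),
        interaction_test=interaction_test if keep_interaction else interaction_test,
        aic_full=aic_full,
        aic_reduced=aic_red,
        selected=selected,
    )


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Adjusted values are monotone in the raw ordering, >= raw, <= 1, and
    invariant to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
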