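"""REML variance components for the nested model ``trait ~ block + (1|pop/family)``.

The marginal covariance of a plant-level trait vector is

    V = v_res * I + v_fam * Z_f Z_f' + v_pop * Z_p Z_p'

with family indicators nested within population indicators, so V is block
diagonal by population.  Each population block is ``sigma^2 (I + U Delta U')``
where U holds that population's family indicators plus a column of ones and
``Delta = diag(gamma_fam, ..., gamma_pop)`` are variance *ratios*.  The
restricted (or full) log-likelihood is evaluated with the Woodbury identity
on the small (families+1) core matrices, with the residual scale profiled
out, so one evaluation costs a handful of batched small-matrix operations
regardless of the number of plants.

Maximization runs over log variance ratios with Nelder-Mead, but every fit
also evaluates the boundary candidates explicitly (family variance pinned at
zero, population variance pinned at zero, both) and keeps the best, because
boundary estimates are common in real common-garden data and a box-
constrained optimizer alone tends to stall against them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DegenerateDesignError, UnreliableResultError

_LOG_2PI = float(np.log(2.0 * np.pi))
_SIGMA2_FLOOR = 1e-12
_RATIO_TINY = 1e-8  # below this a fitted ratio is reported as a boundary zero
_LOG_G_LO, _LOG_G_HI = -16.0, 12.0


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

_CATEGORICAL_TERMS = {"block", "subtransect"}


def build_design(
    df: pd.DataFrame,
    terms: Sequence[str],
    coding: str = "treatment",
) -> tuple[np.ndarray, list[str]]:
    """Build a fixed-effect design matrix with an intercept.

    ``terms`` are column names; ``block`` and ``subtransect`` are coded as
    categorical factors, anything else enters as a numeric column, and
    ``a:b`` denotes an interaction (elementwise products of the coded
    columns).  ``coding`` is ``"treatment"`` (drop-first dummies) or
    ``"sum"`` (sum-to-zero contrasts, used for type III tests).
    """
    if coding not in ("treatment", "sum"):
        raise ValueError(f"unknown coding {coding!r}")
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]

    def coded(term: str) -> tuple[list[np.ndarray], list[str]]:
        if term in _CATEGORICAL_TERMS or df[term].dtype == object:
            levels = sorted(pd.unique(df[term].astype(str)))
            if len(levels) < 2:
                raise DegenerateDesignError(
                    f"factor {term!r} has a single level; design is rank deficient"
                )
            vals = df[term].astype(str).to_numpy()
            out_c, out_n = [], []
            for lev in levels[1:]:
                col = (vals == lev).astype(float)
                if coding == "sum":
                    col = col - (vals == levels[0]).astype(float)
                out_c.append(col)
                out_n.append(f"{term}[{lev}]")
            return out_c, out_n
        x = df[term].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise DegenerateDesignError(f"covariate {term!r} is constant")
        # centered so main effects and type III tests are evaluated at the
        # covariate mean rather than at 0 (slopes are unaffected)
        return [x - x.mean()], [term]

    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            ca, na = coded(a)
            cb, nb = coded(b)
            for xa, sa in zip(ca, na):
                for xb, sb in zip(cb, nb):
                    cols.append(xa * xb)
                    names.append(f"{sa}:{sb}")
        else:
            c, nm = coded(term)
            cols.extend(c)
            names.extend(nm)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("fixed-effect design matrix is rank deficient")
    return X, names


# ---------------------------------------------------------------------------
# likelihood engine
# ---------------------------------------------------------------------------


class NestedLMMEngine:
    """Profiled (restricted) log-likelihood for one trait on a fixed design.

    The engine precomputes population-blocked Gram matrices once; a new
    response vector (for bootstrap refits) only refreshes the cheap
    y-dependent cross products via :meth:`set_response`.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        pop_codes: np.ndarray,
        fam_codes: np.ndarray,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.pop_codes = np.asarray(pop_codes)
        self.n_pops = int(self.pop_codes.max()) + 1
        # family slot index within each population
        fam_codes = np.asarray(fam_codes)
        self.n_fams = int(fam_codes.max()) + 1
        fam_pop = np.full(self.n_fams, -1, dtype=int)
        fam_pop[fam_codes] = self.pop_codes
        slot_of_fam = np.zeros(self.n_fams, dtype=int)
        fams_per_pop = np.zeros(self.n_pops, dtype=int)
        for f in range(self.n_fams):
            p = fam_pop[f]
            if p >= 0:
                slot_of_fam[f] = fams_per_pop[p]
                fams_per_pop[p] += 1
        self.fams_per_pop = fams_per_pop
        self.m = int(fams_per_pop.max()) + 1  # family slots + ones column
        slot = slot_of_fam[fam_codes]

        P, m, p = self.n_pops, self.m, self.p
        # row -> (pop, slot) flat indices for the family columns and ones column
        self._fam_flat = self.pop_codes * m + slot
        self._one_flat = self.pop_codes * m + (m - 1)

        G = np.zeros((P, m, m))
        cnt = np.bincount(self._fam_flat, minlength=P * m).reshape(P, m)
        npop = np.bincount(self.pop_codes, minlength=P).astype(float)
        for k in range(m - 1):
            G[:, k, k] = cnt[:, k]
            G[:, k, m - 1] = cnt[:, k]
            G[:, m - 1, k] = cnt[:, k]
        G[:, m - 1, m - 1] = npop
        self.G = G
        self.n_per_pop = npop

        A = np.zeros((P * m, p))
        np.add.at(A, self._fam_flat, self.X)
        np.add.at(A, self._one_flat, self.X)
        self.A = A.reshape(P, m, p)
        self.XtX = self.X.T @ self.X

        # per-(pop,slot) real-family mask for building Delta
        self._fam_mask = np.zeros((P, m), dtype=bool)
        for pi in range(P):
            self._fam_mask[pi, : fams_per_pop[pi]] = True

        self.set_response(y)

    def set_response(self, y: np.ndarray) -> None:
        y = np.asarray(y, dtype=float)
        P, m = self.n_pops, self.m
        b = np.bincount(self._fam_flat, weights=y, minlength=P * m)
        b += np.bincount(self._one_flat, weights=y, minlength=P * m)
        self.b = b.reshape(P, m)
        self.AB = np.concatenate([self.A, self.b[:, :, None]], axis=2)
        self.Xty = self.X.T @ y
        self.yty = float(y @ y)
        self.y = y

    # -- core evaluation ----------------------------------------------------

    def _delta(self, g_pop: float, g_fam: float) -> np.ndarray:
        d = np.where(self._fam_mask, g_fam, 0.0)
        d[:, -1] = g_pop
        return d

    def profiled(
        self, g_pop: float, g_fam: float, reml: bool = True, grad: bool = False
    ) -> dict:
        """Profiled log-likelihood at variance ratios (g_pop, g_fam).

        Returns the log-likelihood with beta and the residual scale profiled
        out, plus the implied GLS beta and sigma^2.  With ``grad=True`` the
        analytic gradient with respect to (g_pop, g_fam) is included; it is
        assembled from the same Woodbury pieces (the columns of each
        population's U matrix are exactly the random-effect design columns).
        """
        m, p, q = self.m, self.p, self.p + 1
        d = self._delta(g_pop, g_fam)
        s = np.sqrt(d)
        C = s[:, :, None] * self.G * s[:, None, :]
        C[:, np.arange(m), np.arange(m)] += 1.0
        L = np.linalg.cholesky(C)
        logdetV0 = 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
        if grad:
            RHS = np.concatenate([self.AB, self.G], axis=2)
        else:
            RHS = self.AB
        T = np.linalg.solve(C, s[:, :, None] * RHS)
        Tab = T[:, :, :q]
        S = np.einsum("pij,pik->jk", s[:, :, None] * self.AB, Tab)
        XtV0X = self.XtX - S[:p, :p]
        XtV0y = self.Xty - S[:p, p]
        ytV0y = self.yty - S[p, p]

        beta = np.linalg.solve(XtV0X, XtV0y)
        Q = max(float(ytV0y - beta @ XtV0y), 0.0)
        dof = self.n - self.p if reml else self.n
        sigma2 = max(Q / dof, _SIGMA2_FLOOR)
        ll = -0.5 * (dof * (_LOG_2PI + np.log(sigma2) + Q / (dof * sigma2)) + logdetV0)
        if reml:
            sign, ld = np.linalg.slogdet(XtV0X)
            if sign <= 0:
                raise DegenerateDesignError("X'V^-1X is singular")
            ll -= 0.5 * ld
        out = {
            "loglik": float(ll),
            "sigma2": sigma2,
            "beta": beta,
            "g_pop": g_pop,
            "g_fam": g_fam,
            "_state": (d, s, C),
        }
        if grad:
            # U'V0^-1 [X|y] and diag(U'V0^-1 U), batched per population
            H = self.AB - np.einsum("pij,pjk->pik", self.G, s[:, :, None] * Tab)
            HX, Hy = H[:, :, :p], H[:, :, p]
            UVU_diag = np.diagonal(self.G, axis1=1, axis2=2) - np.einsum(
                "pij,pji->pi", self.G, s[:, :, None] * T[:, :, q:]
            )
            K = np.linalg.inv(XtV0X)
            w = np.einsum("pij,jk,pik->pi", HX, K, HX)
            r_u = Hy - HX @ beta
            fam_mask = self._fam_mask
            Qsafe = max(Q, _SIGMA2_FLOOR)
            grads = []
            for which in ("pop", "fam"):
                if which == "pop":
                    tr_v = float(UVU_diag[:, -1].sum())
                    tr_x = float(w[:, -1].sum())
                    dQ = -float((r_u[:, -1] ** 2).sum())
                else:
                    tr_v = float((UVU_diag[:, :-1] * fam_mask[:, :-1]).sum())
                    tr_x = float((w[:, :-1] * fam_mask[:, :-1]).sum())
                    dQ = -float(((r_u[:, :-1] ** 2) * fam_mask[:, :-1]).sum())
                g = dof * dQ / Qsafe + tr_v - (tr_x if reml else 0.0)
                grads.append(-0.5 * g)
            out["grad"] = np.array(grads)
        return out

    def loglik_at(
        self, v_pop: float, v_fam: float, v_res: float, reml: bool = True
    ) -> float:
        """Unprofiled (restricted) log-likelihood at given variance components.

        Uses the identity ll(v) = ll_profiled(gamma) - dof/2 * [log(v_res /
        sigma2_hat) + sigma2_hat/v_res - 1] where gamma are the ratios
        v_pop/v_res, v_fam/v_res and sigma2_hat is the profiled scale at
        those ratios.
        """
        if v_res <= 0 or v_pop < 0 or v_fam < 0:
            raise ValueError("variance components must be nonnegative, v_res > 0")
        sol = self.profiled(v_pop / v_res, v_fam / v_res, reml=reml)
        dof = self.n - self.p if reml else self.n
        s2 = sol["sigma2"]
        return float(
            sol["loglik"]
            - 0.5 * dof * (np.log(v_res / s2) + s2 / v_res - 1.0)
        )

    def blups(self, sol: dict) -> tuple[np.ndarray, np.ndarray]:
        """(population BLUPs, per-(pop,slot) family BLUPs) at a profiled solution."""
        d, s, C = sol["_state"]
        t = self.b - np.einsum("pij,j->pi", self.A, sol["beta"])
        w = np.linalg.solve(C, (s * t)[:, :, None])[:, :, 0]
        u = d * (t - np.einsum("pij,pj->pi", self.G, s * w))
        return u[:, -1].copy(), u[:, :-1].copy()


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    """REML (or ML) variance-component estimates for one trait."""

    trait: str
    v_family: float
    v_population: float
    v_residual: float
    fixed_effects: np.ndarray
    fixed_effect_names: list[str]
    trait_mean: float
    n_obs: int
    n_populations: int
    n_families: int
    reml_loglik: float
    converged: bool
    method: str = "reml"
    boundary: tuple[str, ...] = ()
    population_ids: list[str] = field(default_factory=list, repr=False)
    _context: Any = field(default=None, repr=False, compare=False)

    @property
    def total_variance(self) -> float:
        return self.v_family + self.v_population + self.v_residual


@dataclass
class RandomEffectTest:
    """One-sided test of a variance component (family or population)."""

    component: str
    lrt_stat: float
    p_one_sided: float
    method: str
    n_sim: int = 0
    seed: int | None = None
    n_failed: int = 0
    n_exceed: int = 0  # bootstrap statistics strictly above the observed one
    n_tie: int = 0  # bootstrap statistics tied with the observed one


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------


def _as_frame(data) -> pd.DataFrame:
    records = getattr(data, "records", data)
    if not isinstance(records, pd.DataFrame):
        raise TypeError("expected a GardenDataset or DataFrame")
    return records


def _prepare(
    data, trait: str, covariates: Sequence[str], coding: str = "treatment"
):
    df = _as_frame(data)
    if trait not in df.columns:
        raise KeyError(f"trait column {trait!r} not found")
    df = df.loc[df[trait].notna()].copy()
    y = df[trait].to_numpy(dtype=float)
    pops = pd.unique(df["population_id"])
    fams = pd.unique(df["family_id"])
    if len(pops) < 2:
        raise DegenerateDesignError("need >= 2 populations to estimate v_population")
    if len(fams) < 2:
        raise DegenerateDesignError("need >= 2 families to estimate v_family")
    pop_codes = pd.Categorical(df["population_id"], categories=pops).codes.astype(int)
    fam_codes = pd.Categorical(df["family_id"], categories=fams).codes.astype(int)
    terms = ["block"] if df["block"].nunique() > 1 else []
    terms += list(covariates)
    X, names = build_design(df, terms, coding=coding)
    return df, y, X, names, pop_codes, fam_codes, list(map(str, pops))


# ---------------------------------------------------------------------------
# maximization with boundary candidates
# ---------------------------------------------------------------------------


def _moment_start(engine: NestedLMMEngine) -> tuple[float, float]:
    """Crude moment-based start for the variance ratios."""
    y = engine.y
    flat = engine._fam_flat
    cnt = np.bincount(flat, minlength=engine.n_pops * engine.m).astype(float)
    tot = np.bincount(flat, weights=y, minlength=engine.n_pops * engine.m)
    fam_mean = np.divide(tot, cnt, out=np.zeros_like(tot), where=cnt > 0)
    resid = y - fam_mean[flat]
    mse = float(resid @ resid) / max(engine.n - engine.n_fams, 1)
    pop_cnt = np.bincount(engine.pop_codes, minlength=engine.n_pops).astype(float)
    pop_tot = np.bincount(engine.pop_codes, weights=y, minlength=engine.n_pops)
    pop_mean = pop_tot / pop_cnt
    kbar = engine.n / max(engine.n_fams, 1)
    fm = fam_mean[cnt > 0]
    pm_of_fam = pop_mean[np.repeat(np.arange(engine.n_pops), engine.fams_per_pop)]
    v_fam = float(np.var(fm - pm_of_fam)) - mse / kbar if engine.n_fams > engine.n_pops else 0.0
    v_pop = float(np.var(pop_mean, ddof=1)) - max(v_fam, 0.0) / max(
        engine.n_fams / engine.n_pops, 1.0
    ) - mse / max(kbar * engine.n_fams / engine.n_pops, 1.0)
    mse = max(mse, _SIGMA2_FLOOR)
    g_fam = float(np.clip(np.nan_to_num(v_fam) / mse, 1e-3, 50.0))
    g_pop = float(np.clip(np.nan_to_num(v_pop) / mse, 1e-3, 50.0))
    return g_pop, g_fam


def _maximize(
    engine: NestedLMMEngine,
    include_pop: bool = True,
    include_fam: bool = True,
    reml: bool = True,
    start: tuple[float, float] | None = None,
    fast: bool = False,
) -> dict:
    """Maximize the profiled likelihood over the requested variance ratios.

    Evaluates the zero-boundary candidates explicitly and polishes the best
    interior/edge solution; returns the profiled solution dict augmented
    with ``boundary`` flags and ``converged``.
    """

    def f(g_pop: float, g_fam: float) -> float:
        return engine.profiled(g_pop, g_fam, reml=reml)["loglik"]

    candidates: list[tuple[float, float, float]] = []  # (ll, g_pop, g_fam)
    candidates.append((f(0.0, 0.0), 0.0, 0.0))
    converged = True
    ftol, gtol = (1e-9, 1e-6) if fast else (1e-13, 1e-10)

    def edge(which: str) -> None:
        def negf(t: np.ndarray):
            g = float(np.exp(t[0]))
            sol = engine.profiled(
                g if which == "pop" else 0.0,
                g if which == "fam" else 0.0,
                reml=reml,
                grad=True,
            )
            k = 0 if which == "pop" else 1
            return -sol["loglik"], np.array([-sol["grad"][k] * g])

        res = optimize.minimize(
            negf,
            np.array([np.log(0.2)]),
            jac=True,
            method="L-BFGS-B",
            bounds=[(_LOG_G_LO, _LOG_G_HI)],
            options={"ftol": ftol, "gtol": gtol, "maxiter": 200},
        )
        g = float(np.exp(res.x[0]))
        if which == "pop":
            candidates.append((-res.fun, g, 0.0))
        else:
            candidates.append((-res.fun, 0.0, g))

    if include_pop:
        edge("pop")
    if include_fam:
        edge("fam")

    if include_pop and include_fam:

        def negf2(t: np.ndarray):
            g = np.exp(t)
            sol = engine.profiled(float(g[0]), float(g[1]), reml=reml, grad=True)
            return -sol["loglik"], -sol["grad"] * g

        x0 = np.log(np.clip(start if start is not None else _moment_start(engine), 1e-6, None))
        best = None
        rng_jitter = (
            ((0.0, 0.0),)
            if fast
            else ((0.0, 0.0), (1.5, -1.5), (-3.0, -3.0), (2.0, 2.0), (-1.0, 3.0))
        )
        for attempt, jit in enumerate(rng_jitter):
            res = optimize.minimize(
                negf2,
                x0 + np.asarray(jit),
                jac=True,
                method="L-BFGS-B",
                bounds=[(_LOG_G_LO, _LOG_G_HI)] * 2,
                options={"ftol": ftol, "gtol": gtol, "maxiter": 300},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            if best.success and attempt >= 0 and best.fun < min(
                -c[0] for c in candidates
            ) + 1e-6:
                break
        else:
            if not best.success:
                # Nelder-Mead fallback polish
                res = optimize.minimize(
                    lambda t: -f(float(np.exp(t[0])), float(np.exp(t[1]))),
                    best.x,
                    method="Nelder-Mead",
                    options={"xatol": 1e-8, "fatol": 1e-11, "maxiter": 500},
                )
                if res.fun < best.fun:
                    best = res
                converged = bool(res.success or best.success)
        candidates.append(
            (-best.fun, float(np.exp(best.x[0])), float(np.exp(best.x[1])))
        )

    ll, g_pop, g_fam = max(candidates, key=lambda c: c[0])
    if g_pop < _RATIO_TINY:
        g_pop = 0.0
    if g_fam < _RATIO_TINY:
        g_fam = 0.0
    sol = engine.profiled(g_pop, g_fam, reml=reml)
    boundary = []
    if include_pop and g_pop == 0.0:
        boundary.append("population")
    if include_fam and g_fam == 0.0:
        boundary.append("family")
    sol["boundary"] = tuple(boundary)
    sol["converged"] = converged
    # restricted-model maxima fall out of the same candidate sweep:
    # (pop-only model = best of corner/pop edge, and symmetrically)
    sol["ll_corner"] = candidates[0][0]
    sol["ll_pop_only"] = max(
        (c[0] for c in candidates if c[2] == 0.0), default=candidates[0][0]
    )
    sol["ll_fam_only"] = max(
        (c[0] for c in candidates if c[1] == 0.0), default=candidates[0][0]
    )
    return sol


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def fit_nested_lmm(
    data,
    trait: str,
    covariates: Sequence[str] = (),
    *,
    reml: bool = True,
    include_population: bool = True,
    include_family: bool = True,
) -> VarianceComponents:
    """Fit ``trait ~ block [+ covariates] + (1|population/family)``.

    Rows with a missing response are dropped (complete case per trait).
    Binary responses are fitted on the 0/1 scale; transformed responses are
    the caller's responsibility (see the trait registry).  Estimates on the
    nonnegative boundary are legitimate solutions and are flagged in
    ``boundary``.
    """
    df, y, X, names, pop_codes, fam_codes, pop_ids = _prepare(data, trait, covariates)
    engine = NestedLMMEngine(X, y, pop_codes, fam_codes)
    sol = _maximize(
        engine,
        include_pop=include_population,
        include_fam=include_family,
        reml=reml,
    )
    sigma2 = sol["sigma2"]
    vc = VarianceComponents(
        trait=trait,
        v_family=sol["g_fam"] * sigma2,
        v_population=sol["g_pop"] * sigma2,
        v_residual=sigma2,
        fixed_effects=sol["beta"],
        fixed_effect_names=names,
        trait_mean=float(np.mean(y)),
        n_obs=engine.n,
        n_populations=engine.n_pops,
        n_families=engine.n_fams,
        reml_loglik=sol["loglik"],
        converged=sol["converged"],
        method="reml" if reml else "ml",
        boundary=sol["boundary"],
        population_ids=pop_ids,
        _context={"engine": engine, "sol": sol},
    )
    return vc


def reml_objective(
    params: Sequence[float],
    data,
    trait: str,
    covariates: Sequence[str] = (),
    *,
    reml: bool = True,
) -> float:
    """Restricted log-likelihood at candidate ``(v_population, v_family, v_residual)``.

    Exposed so that the optimizer can be audited against grid/candidate
    evaluations: the fitted solution must attain an objective value no worse
    than any user-supplied point.
    """
    v_pop, v_fam, v_res = (float(v) for v in params)
    _, y, X, _, pop_codes, fam_codes, _ = _prepare(data, trait, covariates)
    engine = NestedLMMEngine(X, y, pop_codes, fam_codes)
    return engine.loglik_at(v_pop, v_fam, v_res, reml=reml)


def lrt_random_effect(
    data,
    trait: str,
    component: str,
    covariates: Sequence[str] = (),
    *,
    halve: bool = True,
) -> RandomEffectTest:
    """One-sided likelihood-ratio test of a variance component.

    The chi-square(1) upper-tail p-value is halved because the alternative is
    one-sided (a variance is >= 0); a statistic of exactly 0 (component
    estimated on the boundary) reports p = 0.5.
    """
    if component not in ("family", "population"):
        raise ValueError("component must be 'family' or 'population'")
    full = fit_nested_lmm(data, trait, covariates)
    reduced = fit_nested_lmm(
        data,
        trait,
        covariates,
        include_family=component != "family",
        include_population=component != "population",
    )
    stat = max(0.0, 2.0 * (full.reml_loglik - reduced.reml_loglik))
    if stat == 0.0:
        p = 0.5 if halve else 1.0
    else:
        p = float(stats.chi2.sf(stat, df=1))
        if halve:
            p /= 2.0
    return RandomEffectTest(
        component=component, lrt_stat=stat, p_one_sided=p, method="chi2_halved"
    )


def _simulate_null_responses(
    engine: NestedLMMEngine,
    sol: dict,
    keep_pop: bool,
    keep_fam: bool,
    n_sim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate responses from a fitted reduced model; shape (n_sim, n)."""
    mu = engine.X @ sol["beta"]
    sigma = float(np.sqrt(sol["sigma2"]))
    v_pop = sol["g_pop"] * sol["sigma2"] if keep_pop else 0.0
    v_fam = sol["g_fam"] * sol["sigma2"] if keep_fam else 0.0
    n = engine.n
    Y = mu + rng.normal(0.0, sigma, size=(n_sim, n))
    if v_pop > 0:
        u = rng.normal(0.0, np.sqrt(v_pop), size=(n_sim, engine.n_pops))
        Y += u[:, engine.pop_codes]
    if v_fam > 0:
        # fam_flat indexes (pop, slot) pairs uniquely across the data
        u = rng.normal(0.0, np.sqrt(v_fam), size=(n_sim, engine.n_pops * engine.m))
        Y += u[:, engine._fam_flat]
    return Y


def parametric_bootstrap_test(
    data,
    trait: str,
    component: str,
    covariates: Sequence[str] = (),
    n_sim: int = 1000,
    seed: int | None = None,
    *,
    halve: bool = False,
) -> RandomEffectTest:
    """Parametric-bootstrap LRT of a variance component.

    Simulates ``n_sim`` datasets from the fitted reduced model (the tested
    component removed), refits full and reduced models on each, and compares
    the observed restricted-likelihood-ratio statistic with its simulated
    null distribution: ``p = (1 + #{sim >= obs}) / (1 + n_sim)``.  The +1
    correction keeps p strictly positive.  ``halve`` optionally halves the
    bootstrap p as well, mirroring the one-sided chi-square convention; the
    default reports the bootstrap tail probability as is.
    """
    if component not in ("family", "population"):
        raise ValueError("component must be 'family' or 'population'")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    df, y, X, names, pop_codes, fam_codes, _ = _prepare(data, trait, covariates)
    engine = NestedLMMEngine(X, y, pop_codes, fam_codes)
    keep_pop = component != "population"
    keep_fam = component != "family"
    sol_full = _maximize(engine, include_pop=True, include_fam=True)
    sol_red = _maximize(engine, include_pop=keep_pop, include_fam=keep_fam)
    obs = max(0.0, 2.0 * (sol_full["loglik"] - sol_red["loglik"]))

    rng = np.random.default_rng(seed)
    Y = _simulate_null_responses(engine, sol_red, keep_pop, keep_fam, n_sim, rng)
    start = (max(sol_full["g_pop"], 1e-3), max(sol_full["g_fam"], 1e-3))
    red_key = "ll_pop_only" if component == "family" else "ll_fam_only"
    n_gt, n_tie, n_failed = 0, 0, 0
    tie_tol = 1e-9 * max(1.0, abs(obs))
    for i in range(n_sim):
        engine.set_response(Y[i])
        try:
            s_full = _maximize(engine, True, True, start=start, fast=True)
        except (DegenerateDesignError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        stat = max(0.0, 2.0 * (s_full["loglik"] - s_full[red_key]))
        if stat > obs + tie_tol:
            n_gt += 1
        elif stat >= obs - tie_tol:
            n_tie += 1
    engine.set_response(y)
    n_ok = n_sim - n_failed
    if n_failed > 0.1 * n_sim:
        raise UnreliableResultError(
            f"{n_failed}/{n_sim} bootstrap refits failed; result unreliable"
        )
    if n_failed:
        warnings.warn(f"{n_failed} bootstrap refits failed and were excluded")
    p = (1.0 + n_gt + n_tie) / (1.0 + n_ok)
    if halve:
        p /= 2.0
    return RandomEffectTest(
        component=component,
        lrt_stat=obs,
        p_one_sided=p,
        method="parametric_bootstrap",
        n_sim=n_sim,
        seed=seed,
        n_failed=n_failed,
        n_exceed=n_gt,
        n_tie=n_tie,
    )


def blup_population(vc: VarianceComponents) -> pd.Series:
    """Best linear unbiased predictions of the population random effects.

    Conditional means of the population effects given the data at the fitted
    variance components; shrunken toward zero relative to raw population
    mean deviations.
    """
    if vc._context is None:
        raise ValueError("fit context missing; refit with fit_nested_lmm")
    engine: NestedLMMEngine = vc._context["engine"]
    pops, _ = engine.blups(vc._context["sol"])
    return pd.Series(pops, index=pd.Index(vc.population_ids, name="population_id"))


def blup_family(vc: VarianceComponents) -> pd.Series:
    """BLUPs of the family-within-population random effects."""
    if vc._context is None:
        raise ValueError("fit context missing; refit with fit_nested_lmm")
    engine: NestedLMMEngine = vc._context["engine"]
    _, fams = engine.blups(vc._context["sol"])
    vals, idx = [], []
    for p in range(engine.n_pops):
        for s in range(engine.fams_per_pop[p]):
            vals.append(fams[p, s])
            idx.append((vc.population_ids[p], s))
    return pd.Series(
        vals, index=pd.MultiIndex.from_tuples(idx, names=["population_id", "family_slot"])
    )
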