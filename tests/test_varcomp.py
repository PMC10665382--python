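"""REML estimator, objective optimality, one-sided tests, BLUPs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import qgarden as qg

from conftest import make_balanced_dataset
from helpers import ems_nested_anova


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


def test_reml_equals_ems_estimators_on_balanced_interior_fits():
    """On balanced designs REML must coincide with the closed-form
    expected-mean-squares nested-ANOVA estimators whenever those are positive."""
    checked = 0
    for seed in range(8):
        ds = make_balanced_dataset(seed=seed)
        v_pop, v_fam, v_res = ems_nested_anova(ds.records, "y")
        if v_pop <= 0 or v_fam <= 0:
            continue
        vc = qg.fit_nested_lmm(ds, "y")
        assert vc.v_population == pytest.approx(v_pop, abs=1e-4)
        assert vc.v_family == pytest.approx(v_fam, abs=1e-4)
        assert vc.v_residual == pytest.approx(v_res, abs=1e-4)
        checked += 1
    assert checked >= 5


def test_constant_response_collapses_to_boundary():
    ds = make_balanced_dataset(seed=0)
    df = ds.records.copy()
    df["y"] = 5.0
    vc = qg.fit_nested_lmm(df, "y")
    assert vc.v_family == 0.0
    assert vc.v_population == 0.0
    assert vc.v_residual <= 1e-8
    assert vc.fixed_effects[0] == pytest.approx(5.0, abs=1e-8)


def test_matches_statsmodels_mixedlm_on_unbalanced_data():
    """Cross-check against an independent REML implementation."""
    smf = pytest.importorskip("statsmodels.formula.api")
    cfg = qg.GardenDesignConfig(
        n_populations_per_subtransect=(6, 6, 8),
        families_per_population=4,
        plants_per_family=None,
        n_blocks=4,
        seed=7,
    )
    truth = qg.SimTruth(
        traits={"y": qg.TraitTruth(
            grand_mean=5.0, v_population=0.5, v_family=0.25, v_residual=1.0,
            block_effects=(0.1, -0.2, 0.3, 0.0),
        )},
        seed=77,
    )
    ds = qg.simulate_garden(cfg, truth)
    vc = qg.fit_nested_lmm(ds, "y")
    md = smf.mixedlm(
        "y ~ C(block)", ds.records, groups="population_id",
        re_formula="1", vc_formula={"fam": "0 + C(family_id)"},
    )
    mf = md.fit(reml=True)
    assert vc.v_population == pytest.approx(float(mf.cov_re.iloc[0, 0]), abs=1e-5)
    assert vc.v_family == pytest.approx(float(mf.vcomp[0]), abs=1e-5)
    assert vc.v_residual == pytest.approx(float(mf.scale), abs=1e-5)
    assert vc.reml_loglik == pytest.approx(mf.llf, abs=1e-6)


def test_solution_invariant_to_row_order_and_relabeling(balanced_ds, balanced_fit):
    df = balanced_ds.records.sample(frac=1.0, random_state=3).reset_index(drop=True)
    mapping_pop = {p: f"Z{i}" for i, p in enumerate(sorted(df["population_id"].unique(), reverse=True))}
    df["family_id"] = df["population_id"].map(mapping_pop) + "/" + df["family_id"]
    df["population_id"] = df["population_id"].map(mapping_pop)
    vc2 = qg.fit_nested_lmm(df, "y")
    for a, b in (
        (vc2.v_population, balanced_fit.v_population),
        (vc2.v_family, balanced_fit.v_family),
        (vc2.v_residual, balanced_fit.v_residual),
        (vc2.reml_loglik, balanced_fit.reml_loglik),
    ):
        assert a == pytest.approx(b, rel=1e-6)


def test_mean_estimates_recover_truth_over_replicates():
    est = []
    for seed in range(40):
        ds = make_balanced_dataset(seed=100 + seed)
        vc = qg.fit_nested_lmm(ds, "y")
        est.append((vc.v_population, vc.v_family, vc.v_residual))
    mean = np.mean(est, axis=0)
    assert mean[0] == pytest.approx(0.5, rel=0.15)
    assert mean[1] == pytest.approx(0.25, rel=0.15)
    assert mean[2] == pytest.approx(1.0, rel=0.05)


def test_degenerate_designs_raise():
    ds = make_balanced_dataset(n_pops=2, seed=0)
    single = ds.records[ds.records["population_id"] == ds.records["population_id"].iloc[0]]
    with pytest.raises(qg.DegenerateDesignError):
        qg.fit_nested_lmm(single, "y")


# ---------------------------------------------------------------------------
# restricted-likelihood objective
# ---------------------------------------------------------------------------


def test_fit_beats_perturbed_candidates(balanced_ds, balanced_fit):
    vc = balanced_fit
    at_fit = qg.reml_objective(
        (vc.v_population, vc.v_family, vc.v_residual), balanced_ds, "y"
    )
    assert at_fit == pytest.approx(vc.reml_loglik, abs=1e-6)
    perturbed = qg.reml_objective(
        (vc.v_population * 1.1, vc.v_family * 1.1, vc.v_residual * 1.1),
        balanced_ds,
        "y",
    )
    assert at_fit >= perturbed - 1e-9


def test_no_lattice_point_beats_the_optimizer(balanced_ds, balanced_fit):
    """5x5x5 grid around the truth never exceeds the fitted optimum."""
    best = balanced_fit.reml_loglik
    for vp in np.linspace(0.1, 1.2, 5):
        for vf in np.linspace(0.05, 0.8, 5):
            for vr in np.linspace(0.6, 1.6, 5):
                assert qg.reml_objective((vp, vf, vr), balanced_ds, "y") <= best + 1e-6


def test_population_free_objective_close_on_null_population_data():
    ds = make_balanced_dataset(v_pop=0.0, seed=8)
    full = qg.fit_nested_lmm(ds, "y")
    reduced = qg.fit_nested_lmm(ds, "y", include_population=False)
    assert full.reml_loglik >= reduced.reml_loglik - 1e-9
    assert full.reml_loglik - reduced.reml_loglik < 3.0


# ---------------------------------------------------------------------------
# one-sided tests
# ---------------------------------------------------------------------------


def test_halved_chi2_lrt_matches_tail_formula_and_boundary_convention():
    seen_boundary = False
    seen_interior = False
    for seed in range(6):
        ds = make_balanced_dataset(v_pop=0.5, v_fam=0.0, seed=200 + seed)
        t = qg.lrt_random_effect(ds, "y", "family")
        assert t.method == "chi2_halved"
        assert t.lrt_stat >= 0.0
        if t.lrt_stat == 0.0:
            assert t.p_one_sided == 0.5
            seen_boundary = True
        else:
            assert t.p_one_sided == pytest.approx(
                stats.chi2.sf(t.lrt_stat, 1) / 2.0
            )
            assert t.p_one_sided < 0.5
            seen_interior = True
    assert seen_boundary and seen_interior


def test_strong_family_signal_detected():
    ds = make_balanced_dataset(v_pop=0.1, v_fam=1.0, seed=4)
    t = qg.lrt_random_effect(ds, "y", "family")
    assert t.p_one_sided < 1e-4


def test_bootstrap_p_floor_under_strong_signal():
    """All null statistics fall below the observed one: p = 1/(n_sim+1)."""
    ds = make_balanced_dataset(v_pop=0.1, v_fam=1.0, v_res=1.0, seed=21)
    t = qg.parametric_bootstrap_test(ds, "y", "family", n_sim=99, seed=5)
    assert t.method == "parametric_bootstrap"
    assert t.p_one_sided == pytest.approx(1.0 / 100.0)


def test_bootstrap_reproducible_under_seed():
    ds = make_balanced_dataset(v_pop=0.5, v_fam=0.1, seed=22)
    a = qg.parametric_bootstrap_test(ds, "y", "family", n_sim=49, seed=9)
    b = qg.parametric_bootstrap_test(ds, "y", "family", n_sim=49, seed=9)
    assert a.p_one_sided == b.p_one_sided
    assert a.lrt_stat == pytest.approx(b.lrt_stat)


def test_bootstrap_decision_stable_across_simulation_counts():
    """More simulations refine the p-value but not the alpha=0.05 decision."""
    ds = make_balanced_dataset(
        n_pops=10, n_fams=4, n_plants=4, v_pop=0.2, v_fam=0.6, seed=23
    )
    p100 = qg.parametric_bootstrap_test(ds, "y", "family", n_sim=100, seed=3).p_one_sided
    p1000 = qg.parametric_bootstrap_test(ds, "y", "family", n_sim=1000, seed=3).p_one_sided
    assert (p100 <= 0.05) == (p1000 <= 0.05)


def test_component_argument_validated(balanced_ds):
    with pytest.raises(ValueError):
        qg.lrt_random_effect(balanced_ds, "y", "plot")


# ---------------------------------------------------------------------------
# BLUPs
# ---------------------------------------------------------------------------


def test_blups_are_zero_when_population_variance_is_zero():
    for seed in range(6):
        ds = make_balanced_dataset(v_pop=0.0, v_fam=0.3, seed=300 + seed)
        vc = qg.fit_nested_lmm(ds, "y")
        if vc.v_population == 0.0:
            assert (qg.blup_population(vc) == 0.0).all()
            return
    pytest.fail("no boundary fit encountered across seeds")


def test_blups_approach_raw_means_under_large_signal():
    ds = make_balanced_dataset(v_pop=2.0, v_fam=0.1, v_res=0.2, seed=4)
    vc = qg.fit_nested_lmm(ds, "y")
    bl = qg.blup_population(vc)
    raw = ds.records.groupby("population_id")["y"].mean() - ds.records["y"].mean()
    rel = np.abs(bl - raw[bl.index]) / np.abs(raw[bl.index])
    assert float(rel.max()) < 0.02


def test_blups_center_and_shrink(balanced_ds, balanced_fit):
    bl = qg.blup_population(balanced_fit)
    assert abs(bl.sum()) < 1e-8
    raw = (
        balanced_ds.records.groupby("population_id")["y"].mean()
        - balanced_ds.records["y"].mean()
    )
    assert (bl.abs() <= raw[bl.index].abs() + 1e-9).all()
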