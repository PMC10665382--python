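"""Dataset I/O round trips, validation, binomial meta-test, report assembly."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import qgarden as qg
from qgarden.cli import main as cli_main
from qgarden.reporting import load_config, read_report_rows

from helpers import binom_upper_tail


def _small_ds(seed=0, missing=0.0):
    cfg = qg.GardenDesignConfig(
        n_populations_per_subtransect=(4, 4, 4),
        families_per_population=3,
        plants_per_family=4,
        missing_rate=missing,
        seed=seed,
    )
    truth = qg.SimTruth(
        traits={"y": qg.TraitTruth(
            grand_mean=3.0, v_population=0.2, v_family=0.3, v_residual=1.0,
            block_effects=(0.0, 0.1, -0.1, 0.2),
        )},
        seed=seed,
    )
    return qg.simulate_garden(cfg, truth)


# ---------------------------------------------------------------------------
# binomial meta-test
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n", [5, 17, 27, 30])
def test_binomial_tail_matches_bruteforce_enumeration(n):
    for k in range(n + 1):
        assert qg.binomial_expansion_test(k, n, 0.05) == pytest.approx(
            binom_upper_tail(k, n, 0.05), abs=1e-12
        )


def test_binomial_edge_cases_and_domain_errors():
    assert qg.binomial_expansion_test(0, 27, 0.05) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        qg.binomial_expansion_test(5, 3, 0.05)
    with pytest.raises(ValueError):
        qg.binomial_expansion_test(1, 3, 1.5)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------


def test_dataset_round_trip_preserves_values_and_missingness(tmp_path):
    ds = _small_ds(seed=1, missing=0.15)
    path = tmp_path / "garden.csv"
    qg.write_dataset(ds, path)
    back = qg.read_dataset(path)
    pd.testing.assert_frame_equal(back.records, ds.records, check_dtype=False)
    assert back.trait_columns == ["y"]
    assert back.records["y"].isna().sum() == ds.records["y"].isna().sum()


def test_validator_names_duplicate_plant(tmp_path):
    ds = _small_ds(seed=2)
    df = pd.concat([ds.records, ds.records.iloc[[0]]], ignore_index=True)
    path = tmp_path / "dup.csv"
    df.to_csv(path, index=False)
    with pytest.raises(qg.ValidationError, match="plant_id"):
        qg.read_dataset(path)


def test_validator_names_family_shared_across_populations(tmp_path):
    ds = _small_ds(seed=3)
    df = ds.records.copy()
    bad_family = df["family_id"].iloc[0]
    other_pop_row = df[df["population_id"] != df["population_id"].iloc[0]].index[0]
    df.loc[other_pop_row, "family_id"] = bad_family
    path = tmp_path / "nest.csv"
    df.to_csv(path, index=False)
    with pytest.raises(qg.ValidationError, match=bad_family):
        qg.read_dataset(path)


def test_validator_rejects_metric_varying_within_population(tmp_path):
    ds = _small_ds(seed=4)
    df = ds.records.copy()
    df.loc[df.index[0], "urb_score"] += 1.0
    path = tmp_path / "metric.csv"
    df.to_csv(path, index=False)
    with pytest.raises(qg.ValidationError, match="urb_score"):
        qg.read_dataset(path)


def test_truth_round_trip(tmp_path):
    truth = qg.SimTruth(
        traits={
            "a": qg.TraitTruth(grand_mean=1.0, v_population=0.1, v_family=0.2,
                               v_residual=0.9, block_effects=(0.0, 0.5),
                               cline_slope_score=0.3),
            "b": qg.TraitTruth(grand_mean=0.0, v_family=0.4, v_residual=1.0,
                               occurrence=qg.TraitTruth(grand_mean=-0.2)),
        },
        seed=11,
    )
    path = tmp_path / "truth.txt"
    qg.write_truth(truth, path)
    back = qg.read_truth(path)
    assert back.seed == 11
    assert back.traits["a"].cline_slope_score == pytest.approx(0.3)
    assert back.traits["a"].block_effects == (0.0, 0.5)
    assert back.traits["b"].occurrence.grand_mean == pytest.approx(-0.2)


# ---------------------------------------------------------------------------
# trait report
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def mixed_report():
    registry = [
        qg.TraitSpec("height", "growth", "gaussian"),
        qg.TraitSpec("damage", "defense_damage", "zero_inflated_continuous",
                     transform="log"),
    ]
    truth = qg.SimTruth(
        traits={
            "height": qg.TraitTruth(grand_mean=40.0, v_population=0.5,
                                    v_family=2.0, v_residual=8.0,
                                    block_effects=(0.0, 1.0, -1.0, 0.5)),
            "damage": qg.TraitTruth(grand_mean=1.0, v_population=0.1,
                                    v_family=0.3, v_residual=0.5,
                                    occurrence=qg.TraitTruth(grand_mean=0.0,
                                                             v_family=0.3)),
        },
        seed=21,
    )
    cfg = qg.GardenDesignConfig(seed=21)
    ds = qg.simulate_garden(cfg, truth, registry=registry)
    return qg.build_trait_report(ds, registry, qg.PipelineConfig(seed=21)), ds, registry


def test_report_expands_hurdle_traits_and_records_metadata(mixed_report):
    report, _, _ = mixed_report
    assert list(report.rows["trait"]) == [
        "height", "damage (binary)", "damage (quantitative)"
    ]
    assert set(report.meta_tests) == {"family", "population"}
    assert report.metadata["seed"] == 21
    assert "config_hash" in report.metadata
    ps = report.rows["p_family"].dropna()
    assert ((ps > 0) & (ps <= 0.5)).all()


def test_report_round_trips_through_disk(tmp_path, mixed_report):
    report, _, _ = mixed_report
    qg.write_report(report, tmp_path)
    back = read_report_rows(tmp_path)
    assert list(back["trait"]) == list(report.rows["trait"])
    # serialized at 3 decimals, matching the published table display
    assert np.allclose(back["H2"], report.rows["H2"].astype(float).round(3))


def test_report_is_deterministic_under_seed(mixed_report):
    report, ds, registry = mixed_report
    again = qg.build_trait_report(ds, registry, qg.PipelineConfig(seed=21))
    pd.testing.assert_frame_equal(report.rows, again.rows)


def test_meta_test_counts_match_row_pvalues(mixed_report):
    report, _, _ = mixed_report
    for component, col in (("family", "p_family"), ("population", "p_population")):
        ps = report.rows[col].dropna()
        assert report.meta_tests[component]["n_significant"] == int((ps <= 0.05).sum())
        assert report.meta_tests[component]["n_traits"] == len(ps)


def test_27_trait_report_recovers_the_planted_signal_structure():
    """With 9 of 27 traits given real family variance, the report counts
    close to 9 family-significant traits and its family meta-test is
    decisive, while the population meta-test stays null-like."""
    registry = [qg.TraitSpec(f"t{i:02d}", "growth") for i in range(27)]
    truth = qg.SimTruth(
        traits={
            f"t{i:02d}": qg.TraitTruth(
                grand_mean=1.0,
                v_population=0.0,
                v_family=0.6 if i < 9 else 0.0,
                v_residual=1.0,
                block_effects=(0.0, 0.1, -0.1, 0.2),
            )
            for i in range(27)
        },
        seed=31,
    )
    cfg = qg.GardenDesignConfig(seed=31)
    ds = qg.simulate_garden(cfg, truth)
    report = qg.build_trait_report(ds, registry, qg.PipelineConfig(seed=31))
    fam = report.meta_tests["family"]
    pop = report.meta_tests["population"]
    assert 7 <= fam["n_significant"] <= 11
    assert fam["p"] < 0.001
    assert pop["n_significant"] <= 5


def test_config_validation_and_load(tmp_path):
    with pytest.raises(ValueError):
        qg.PipelineConfig(alpha=1.5)
    path = tmp_path / "cfg.yaml"
    path.write_text("alpha: 0.01\nseed: 5\n")
    cfg = load_config(path)
    assert cfg.alpha == 0.01 and cfg.seed == 5
    assert cfg.digest() == qg.PipelineConfig(alpha=0.01, seed=5).digest()


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def test_cli_simulate_then_fit_round_trip(tmp_path):
    runner = CliRunner()
    out = tmp_path / "sim"
    r = runner.invoke(
        cli_main, ["simulate", "--seed", "3", "--n-traits", "1", "--out", str(out)]
    )
    assert r.exit_code == 0, r.output
    assert (out / "garden.csv").exists() and (out / "truth.txt").exists()
    fit_out = tmp_path / "fit.json"
    r = runner.invoke(
        cli_main,
        ["fit", str(out / "garden.csv"), "--trait", "trait_1", "--out", str(fit_out)],
    )
    assert r.exit_code == 0, r.output
    import json

    payload = json.loads(fit_out.read_text())
    assert payload["n_populations"] == 52
    assert payload["converged"] is True


def test_cli_rejects_invalid_dataset(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text("plant_id,population_id\n1,P1\n")
    r = CliRunner().invoke(
        cli_main, ["fit", str(bad), "--trait", "y", "--out", str(tmp_path / "o.json")]
    )
    assert r.exit_code == 2
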