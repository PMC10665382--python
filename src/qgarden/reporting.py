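"""Dataset I/O, trait-level report assembly and trait-set meta-tests.

The per-trait report mirrors the published table layout: one row per
analyzed trait (zero-inflated traits expand into an occurrence part and a
positive "quantitative" part), with H^2, CV_G, Q_ST and one-sided p-values
for the family and population variance components, followed by a binomial
meta-test asking whether the number of significant traits exceeds the
number expected from the false-positive rate alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__ as _version
from .exceptions import ValidationError
from .qgparams import hurdle_split, qg_estimates
from .synthetic_data import (
    SUBTRANSECTS,
    GardenDataset,
    SimTruth,
    TraitSpec,
    TraitTruth,
)
from .varcomp import fit_nested_lmm, lrt_random_effect, parametric_bootstrap_test

DESIGN_COLUMNS = [
    "plant_id",
    "population_id",
    "family_id",
    "block",
    "subtransect",
    "distance_km",
    "urb_score",
]


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def _rank_normal(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


TRANSFORMS = {
    None: lambda x: x,
    "identity": lambda x: x,
    "log1p": np.log1p,
    "log": np.log,
    "sqrt": np.sqrt,
    "rank_normal": _rank_normal,
}


def apply_transform(values: np.ndarray, transform: str | None) -> np.ndarray:
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    return TRANSFORMS[transform](np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# dataset I/O and validation
# ---------------------------------------------------------------------------


def validate_dataset(df: pd.DataFrame) -> None:
    """Check structural invariants; raise ValidationError naming the culprit."""
    for col in DESIGN_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    dup = df["plant_id"][df["plant_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicated plant_id {dup.iloc[0]!r}")
    fam_pops = df.groupby("family_id")["population_id"].nunique()
    bad = fam_pops[fam_pops > 1]
    if len(bad):
        raise ValidationError(
            f"family {bad.index[0]!r} appears in {bad.iloc[0]} populations; "
            "families must be nested within a single population"
        )
    for col in ("subtransect", "distance_km", "urb_score"):
        per_pop = df.groupby("population_id")[col].nunique()
        bad = per_pop[per_pop > 1]
        if len(bad):
            raise ValidationError(
                f"column {col!r} varies within population {bad.index[0]!r}"
            )
    unknown = set(df["subtransect"].unique()) - set(SUBTRANSECTS)
    if unknown:
        raise ValidationError(f"unknown subtransect labels {sorted(unknown)}")


def write_dataset(dataset: GardenDataset | pd.DataFrame, path: str | Path) -> None:
    """Write plant records as CSV (UTF-8, header row, empty field = missing)."""
    records = getattr(dataset, "records", dataset)
    records.to_csv(path, index=False, encoding="utf-8")


def read_dataset(path: str | Path) -> GardenDataset:
    """Read and validate a plant-record CSV; loss-free round trip."""
    df = pd.read_csv(path, encoding="utf-8")
    validate_dataset(df)
    traits = [c for c in df.columns if c not in DESIGN_COLUMNS]
    for c in traits:
        df[c] = pd.to_numeric(df[c], errors="raise")
    return GardenDataset(records=df, truth=None, trait_columns=traits)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Write generating parameters as a flat key-value file."""
    flat: dict[str, object] = {"seed": truth.seed}

    def put(prefix: str, tt: TraitTruth) -> None:
        for key, val in asdict(tt).items():
            if key == "occurrence":
                if tt.occurrence is not None:
                    put(f"{prefix}.occurrence", tt.occurrence)
            elif key == "block_effects":
                if val is not None:
                    flat[f"{prefix}.{key}"] = ",".join(str(v) for v in val)
            else:
                flat[f"{prefix}.{key}"] = val

    for name, tt in truth.traits.items():
        put(f"trait.{name}", tt)
    Path(path).write_text(
        "\n".join(f"{k}: {v}" for k, v in flat.items()) + "\n", encoding="utf-8"
    )


def read_truth(path: str | Path) -> SimTruth:
    """Read a flat key-value truth file written by :func:`write_truth`."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        key, _, val = line.partition(":")
        kv[key.strip()] = val.strip()

    seed = int(kv.pop("seed", "0"))
    nested: dict[str, dict] = {}
    for key, val in kv.items():
        parts = key.split(".")
        if parts[0] != "trait":
            continue
        name = parts[1]
        d = nested.setdefault(name, {})
        if parts[2] == "occurrence":
            d = d.setdefault("occurrence", {})
            fieldname = parts[3]
        else:
            fieldname = parts[2]
        if fieldname == "block_effects":
            d[fieldname] = tuple(float(v) for v in val.split(",")) if val else None
        else:
            d[fieldname] = float(val) if val not in ("None", "") else None

    def build(d: dict) -> TraitTruth:
        occ = d.pop("occurrence", None)
        return TraitTruth(**d, occurrence=build(occ) if occ else None)

    return SimTruth(traits={k: build(v) for k, v in nested.items()}, seed=seed)


# ---------------------------------------------------------------------------
# binomial meta-test
# ---------------------------------------------------------------------------


def binomial_expansion_test(k_successes: int, n_trials: int, p0: float = 0.05) -> float:
    """Exact one-sided binomial tail probability P(X >= k | n, p0).

    Computed by direct summation of the binomial mass function; used to ask
    whether the count of significant traits exceeds the count expected from
    the per-trait false-positive rate alone.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if k_successes < 0 or n_trials < 0 or k_successes > n_trials:
        raise ValueError("need 0 <= k <= n")
    ks = np.arange(k_successes, n_trials + 1)
    return float(np.sum(stats.binom.pmf(ks, n_trials, p0)))


# ---------------------------------------------------------------------------
# trait report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Run-level settings recorded in every report."""

    alpha: float = 0.05
    n_sim: int = 0  # parametric-bootstrap simulations; 0 = halved-chi2 only
    n_perm: int = 999
    seed: int = 0
    use_bootstrap_for_nongaussian: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class TraitReportRow:
    trait: str
    category: str
    H2: float | None
    CVg: float | None
    p_family: float | None
    Qst: float | None
    p_population: float | None
    n_obs: int
    flags: str = ""


@dataclass
class TraitReport:
    rows: pd.DataFrame
    meta_tests: dict[str, dict]
    metadata: dict


def _analysis_parts(
    data: GardenDataset, spec: TraitSpec
) -> list[tuple[str, pd.DataFrame]]:
    """Expand a trait into its analyzed parts (hurdle traits into two)."""
    records = data.records
    if not spec.zero_inflated:
        return [(spec.name, records)]
    occurrence, _ = hurdle_split(records[spec.name].to_numpy())
    occ_df = records.copy()
    occ_name = f"{spec.name} (binary)"
    occ_df[occ_name] = occurrence
    pos_df = records.loc[records[spec.name] > 0].copy()
    pos_name = f"{spec.name} (quantitative)"
    pos_df[pos_name] = pos_df[spec.name]
    return [(occ_name, occ_df), (pos_name, pos_df)]


def build_trait_report(
    data: GardenDataset,
    registry: Sequence[TraitSpec],
    config: PipelineConfig = PipelineConfig(),
) -> TraitReport:
    """Fit the nested model per trait and assemble the published-table layout.

    Per-trait fit failures become flagged rows and never abort the report.
    The meta-tests count traits with one-sided p <= alpha for each variance
    component and compare that count against a Binomial(n_traits, alpha)
    null by exact summation.  Traits whose correlations are unknown are
    treated as independent trials; correlated traits can inflate the
    meta-test's type I error, and reports carry that caveat in metadata.
    """
    for spec in registry:
        if spec.name not in data.records.columns:
            raise ValidationError(f"registry trait {spec.name!r} missing from data")

    rows: list[TraitReportRow] = []
    for spec in registry:
        for part_name, frame in _analysis_parts(data, spec):
            flags = []
            sub = frame.loc[frame[part_name].notna()].copy()
            if len(sub) == 0:
                rows.append(
                    TraitReportRow(
                        part_name, spec.category, None, None, None, None, None, 0,
                        "empty",
                    )
                )
                continue
            y = sub[part_name].to_numpy(dtype=float)
            is_part = part_name.endswith("(quantitative)")
            if spec.transform and (not spec.zero_inflated or is_part):
                sub[part_name] = apply_transform(y, spec.transform)
                flags.append(f"transform={spec.transform}")
            try:
                vc = fit_nested_lmm(sub, part_name)
                est = qg_estimates(vc)
                use_pb = (
                    config.use_bootstrap_for_nongaussian
                    and spec.family != "gaussian"
                    and config.n_sim > 0
                )
                ps = {}
                for component in ("family", "population"):
                    if use_pb:
                        t = parametric_bootstrap_test(
                            sub,
                            part_name,
                            component,
                            n_sim=config.n_sim,
                            seed=config.seed,
                        )
                    else:
                        t = lrt_random_effect(sub, part_name, component)
                    ps[component] = t.p_one_sided
                if vc.boundary:
                    flags.append("boundary:" + "+".join(vc.boundary))
                if not vc.converged:
                    flags.append("not_converged")
                if est.Qst is None:
                    flags.append("Qst_undefined")
                rows.append(
                    TraitReportRow(
                        trait=part_name,
                        category=spec.category,
                        H2=est.H2,
                        CVg=est.CVg,
                        p_family=ps["family"],
                        Qst=est.Qst,
                        p_population=ps["population"],
                        n_obs=vc.n_obs,
                        flags=";".join(flags),
                    )
                )
            except Exception as exc:  # noqa: BLE001 - flagged row, never abort
                rows.append(
                    TraitReportRow(
                        part_name, spec.category, None, None, None, None, None,
                        int(len(sub)), f"fit_failed:{type(exc).__name__}",
                    )
                )

    table = pd.DataFrame([asdict(r) for r in rows])
    meta = {}
    for component, col in (("family", "p_family"), ("population", "p_population")):
        ps = pd.to_numeric(table[col], errors="coerce").dropna()
        k = int((ps <= config.alpha).sum())
        n = int(len(ps))
        meta[component] = {
            "n_significant": k,
            "n_traits": n,
            "p": binomial_expansion_test(k, n, config.alpha) if n else None,
        }
    metadata = {
        "seed": config.seed,
        "alpha": config.alpha,
        "config_hash": config.digest(),
        "version": _version,
        "n_rows": len(table),
        "caveat": (
            "meta-tests assume independent traits; correlations among traits "
            "can inflate the type I error of the binomial test"
        ),
    }
    return TraitReport(rows=table, meta_tests=meta, metadata=metadata)


def write_report(report: TraitReport, directory: str | Path) -> None:
    """Serialize a report: rows as CSV (3-decimal display), meta as JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = report.rows.copy()
    for col in ("H2", "CVg", "p_family", "Qst", "p_population"):
        rows[col] = pd.to_numeric(rows[col], errors="coerce").round(3)
    rows.to_csv(directory / "trait_report.csv", index=False)
    payload = {"meta_tests": report.meta_tests, "metadata": report.metadata}
    (directory / "meta_tests.json").write_text(
        json.dumps(payload, indent=2, default=float), encoding="utf-8"
    )


def read_report_rows(directory: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(directory) / "trait_report.csv")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return PipelineConfig(**raw)
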