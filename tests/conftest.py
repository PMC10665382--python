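import numpy as np
import pytest

import qgarden as qg


def make_balanced_dataset(
    n_pops: int = 20,
    n_fams: int = 5,
    n_plants: int = 4,
    v_pop: float = 0.5,
    v_fam: float = 0.25,
    v_res: float = 1.0,
    seed: int = 0,
    n_blocks: int = 1,
    grand_mean: float = 10.0,
    **truth_kwargs,
) -> qg.GardenDataset:
    """Balanced single-trait Gaussian dataset on the rural subtransect."""
    cfg = qg.GardenDesignConfig(
        n_populations_per_subtransect=(0, 0, n_pops),
        families_per_population=n_fams,
        plants_per_family=n_plants,
        n_blocks=n_blocks,
        seed=seed,
    )
    truth = qg.SimTruth(
        traits={
            "y": qg.TraitTruth(
                grand_mean=grand_mean,
                v_population=v_pop,
                v_family=v_fam,
                v_residual=v_res,
                block_effects=tuple(np.zeros(n_blocks)),
                **truth_kwargs,
            )
        },
        seed=seed,
    )
    return qg.simulate_garden(cfg, truth)


@pytest.fixture(scope="session")
def balanced_ds() -> qg.GardenDataset:
    return make_balanced_dataset(seed=42)


@pytest.fixture(scope="session")
def balanced_fit(balanced_ds) -> qg.VarianceComponents:
    return qg.fit_nested_lmm(balanced_ds, "y")
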