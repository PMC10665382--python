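"""Published reference values from the Toronto common-milkweed common garden.

A four-year common garden of *Asclepias syriaca* grown from seed collected in
52 populations along a 67 km urban--rural gradient in the Greater Toronto
Area (three subtransects: an urban green corridor, an urban non-corridor
transect, and a rural transect) reported per-trait quantitative-genetic
estimates for 27 traits.  Those published per-trait numbers are transcribed
here so that table-level summaries (column means, standard errors, counts of
significant traits, binomial meta-tests) can be recomputed from them, and so
the simulator's defaults can mirror the study design.

p-values printed as "< 0.001" are stored at the printed bound 0.001; every
use here (counting p <= 0.05) is insensitive to that choice.
"""

from __future__ import annotations

import pandas as pd

# Study design constants (defaults for the simulator).
N_POPULATIONS_CORRIDOR = 19
N_POPULATIONS_NONCORRIDOR = 17
N_POPULATIONS_RURAL = 16
N_POPULATIONS = 52
N_FAMILIES = 208
N_PLANTS = 954
MEAN_FAMILIES_PER_POPULATION = 4.0
MEAN_PLANTS_PER_FAMILY = 4.55
N_BLOCKS = 4
GRADIENT_LENGTH_KM = 67.0
URB_SCORE_RANGE = (-3.56, 3.37)
#: Adjusted R^2 between distance-to-city-center and urbanization score.
METRIC_CORRELATION_R2 = 0.709

# Per-trait H^2, CV_G, one-sided p for family variance, Q_ST, one-sided p for
# population variance, as published (3 decimals).
_ROWS = [
    # (trait, category, H2, CVg, p_family, Qst, p_population)
    ("Latex exudation", "defense_damage", 0.092, 0.015, 0.077, 0.174, 0.016),
    ("Herbivory before flowering (binary)", "defense_damage", 0.021, 0.271, 0.490, 0.000, 0.500),
    ("Herbivory before flowering (quantitative)", "defense_damage", 0.000, 0.000, 0.500, 1.000, 0.500),
    ("Herbivory after flowering (binary)", "defense_damage", 0.588, 0.948, 0.004, 0.000, 0.496),
    ("Herbivory after flowering (quantitative)", "defense_damage", 0.043, 4.456, 0.260, 0.000, 0.500),
    ("Milkweed stem weevil damage (binary)", "defense_damage", 0.418, 0.995, 0.030, 0.000, 0.500),
    ("Milkweed stem weevil damage (quantitative)", "defense_damage", 0.080, 0.031, 0.138, 0.116, 0.136),
    ("Flowering success", "reproduction", 0.102, 0.309, 0.302, 0.492, 0.014),
    ("Flowers per inflorescence", "reproduction", 0.000, 0.000, 0.500, 1.000, 0.180),
    ("Flower size", "reproduction", 0.082, 0.042, 0.370, 0.305, 0.134),
    ("Flowering duration", "reproduction", 0.000, 0.000, 0.500, 0.555, 0.500),
    ("Date of first flower", "reproduction", 0.000, 0.010, 0.001, 0.000, 0.500),
    ("Pollinaria removed", "reproduction", 0.544, 0.299, 0.034, 0.009, 0.449),
    ("Follicles", "reproduction", 0.000, 0.000, 0.500, 0.287, 0.500),
    ("Date of first follicle", "reproduction", 0.235, 0.034, 0.001, 0.002, 0.500),
    ("Inflorescences", "reproduction", 0.000, 0.000, 0.496, 1.000, 0.035),
    ("Monarch butterfly abundance", "herbivore_abundance", 0.003, 0.767, 0.021, 0.052, 0.396),
    ("Milkweed leaf-mining fly abundance", "herbivore_abundance", 0.055, 0.140, 0.142, 0.162, 0.106),
    ("Swamp milkweed leaf beetle abundance", "herbivore_abundance", 0.000, 0.011, 0.500, 0.122, 0.500),
    ("LDMC", "growth", 0.000, 0.000, 0.500, 0.011, 0.380),
    ("SLA", "growth", 0.000, 0.000, 0.500, 1.000, 0.404),
    ("Height before flowering", "growth", 0.069, 0.004, 0.112, 0.000, 0.500),
    ("Height after flowering", "growth", 0.132, 0.008, 0.009, 0.052, 0.189),
    ("Relative growth rate", "growth", 0.021, 3.643, 0.394, 0.000, 0.500),
    ("Ramets before flowering", "growth", 0.161, 0.127, 0.001, 0.009, 0.429),
    ("Ramets after flowering", "growth", 0.138, 0.189, 0.001, 0.017, 0.364),
    ("Mortality", "growth", 0.178, 0.320, 0.189, 0.139, 0.186),
]


def milkweed_trait_table() -> pd.DataFrame:
    """Return the published 27-trait table as a DataFrame.

    Columns: ``trait``, ``category``, ``H2``, ``CVg``, ``p_family``, ``Qst``,
    ``p_population``.
    """
    return pd.DataFrame(
        _ROWS,
        columns=["trait", "category", "H2", "CVg", "p_family", "Qst", "p_population"],
    )
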