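import numpy as np
import pandas as pd
import pytest

from epidrift import CohortConfig, generate_cohort
from epidrift.cohort import CELL_TYPES


def small_config(**overrides) -> CohortConfig:
    defaults = dict(
        n_cases=20,
        n_controls=20,
        n_chromosomes=2,
        probes_per_chromosome=500,
        probes_per_gene=10,
        seed=11,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


NO_FLAGS = {k: 0.0 for k in
            ("high_detection_p", "low_beadcount", "not_cpg_start",
             "masked_list", "sex_chromosome")}


@pytest.fixture(scope="session")
def small_cohort():
    """20+20 subjects x 1,000 probes, QC flags present."""
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def clean_cohort():
    """Same scale but no QC flags, so probe sets survive filtering intact."""
    return generate_cohort(small_config(flag_rates=NO_FLAGS, seed=13))


def toy_sheet(n_cases: int, n_controls: int, seed: int = 0) -> pd.DataFrame:
    """Minimal hand-size sample sheet with valid cell fractions."""
    rng = np.random.default_rng(seed)
    ids = [f"case_{i}" for i in range(n_cases)] + [f"ctrl_{i}" for i in range(n_controls)]
    sheet = pd.DataFrame(
        {
            "phenotype": ["case"] * n_cases + ["control"] * n_controls,
            "sex": rng.choice(["F", "M"], size=len(ids)),
            "age": rng.normal(50, 8, len(ids)).round(1),
            "batch": "b1",
        },
        index=pd.Index(ids, name="subject_id"),
    )
    cells = rng.dirichlet(np.ones(len(CELL_TYPES)) * 20, len(ids))
    for j, cell in enumerate(CELL_TYPES):
        sheet[cell] = cells[:, j]
    return sheet
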