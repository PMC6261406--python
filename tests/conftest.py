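import importlib.resources as importlib_resources

import pandas as pd
import pytest

from cnvcase.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (23 cases / 110 controls)."""
    cfg = SimulationConfig(seed=1)
    samples, segs1, segs2, panels, truth = simulate_cohort(cfg)
    return cfg, samples, segs1, segs2, panels, truth


@pytest.fixture(scope="session")
def rare_catalog() -> pd.DataFrame:
    """The shipped 21-row rare-CNV catalog (printed coordinates and sizes)."""
    path = importlib_resources.files("cnvcase") / "data" / "rare_cnv_catalog.tsv"
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
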