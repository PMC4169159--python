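import numpy as np
import pandas as pd
import pytest

from biofilmscreen.synthetic import SimulationConfig, generate_screen


@pytest.fixture(scope="session")
def small_screen():
    """A small screen with planted hits at a strong (4σ) effect size."""
    cfg = SimulationConfig(
        n_mutants=150,
        n_parental_wells=96,
        frac_less=0.1,
        frac_more=0.1,
        effect_less=4.0,
        effect_more=4.0,
        seed=20,
    )
    measurements, truth = generate_screen(cfg)
    return cfg, measurements, truth


@pytest.fixture()
def wells_three_reps():
    """Three replicate wells of one strain at one timepoint, one under the
    biomass threshold, engineered so the two valid scores are 0.4 and 0.6."""
    return pd.DataFrame(
        {
            "strain_id": ["s1"] * 3,
            "gene_id": ["g1"] * 3,
            "timepoint_hr": [46.0] * 3,
            "replicate": [1, 2, 3],
            "od_biomass": [0.5, 0.009, 0.5],
            "od_stain": [0.5 * np.exp(0.4), 0.02, 0.5 * np.exp(0.6)],
        }
    )
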