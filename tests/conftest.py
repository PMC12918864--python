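import warnings

import numpy as np
import pandas as pd
import pytest

from mechanoscreen import synthetic as syn

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_library() -> pd.DataFrame:
    """20 genes x 4 guides, enough to exercise counting and enrichment."""
    return syn.make_guide_library(20, 4, seed=7)


@pytest.fixture(scope="session")
def screen_counts(small_library):
    """Small simulated screen with one strongly enriched gene in outlet4."""
    design = syn.ScreenDesign(outlets=("outlet4",), replicates=3)
    truth = syn.make_screen_truth(
        small_library, {"GENE0003": {"outlet4": 8.0}}, dispersion=0.1, seed=11
    )
    counts, truth = syn.simulate_screen_counts(
        small_library, design, truth, depth=300 * len(small_library)
    )
    return counts, truth, design


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
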