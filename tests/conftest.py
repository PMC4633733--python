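import numpy as np
import pandas as pd
import pytest

from lscsig import (generate_manifest, generate_two_group_study)


@pytest.fixture(scope="session")
def small_manifest():
    """1,000-probe manifest with islands and genes (seeded, session-wide)."""
    return generate_manifest(1000, seed=101)


@pytest.fixture(scope="session")
def small_study(small_manifest):
    """Small two-group study with 25 planted regions."""
    manifest, islands, genes = small_manifest
    beta, expr, samples, truth = generate_two_group_study(
        manifest, islands, genes, n_lsc=8, n_blast=8, n_planted=25, seed=202)
    return beta, expr, samples, truth


@pytest.fixture(scope="session")
def study_groups(small_study):
    _, _, samples, _ = small_study
    g1 = samples.loc[samples["group"] == "LSC", "sample_id"].tolist()
    g2 = samples.loc[samples["group"] == "Blast", "sample_id"].tolist()
    return g1, g2
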