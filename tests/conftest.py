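import numpy as np
import pandas as pd
import pytest

from episcan import BetaMatrix, IslandSet, ProbeManifest, SimulationConfig, simulate_cohort


@pytest.fixture
def small_manifest() -> ProbeManifest:
    return ProbeManifest(
        pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(8)],
                "chrom": ["chr1"] * 5 + ["chr2"] * 3,
                "pos": [100, 200, 300, 400, 500, 100, 200, 300],
            }
        )
    )


@pytest.fixture
def small_islands() -> IslandSet:
    return IslandSet(
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr2"],
                "start": [99, 99],
                "end": [310, 210],
                "name": ["CGI_A", "CGI_B"],
            }
        )
    )


@pytest.fixture
def null_cohort() -> BetaMatrix:
    """20 samples x 8 probes of tight background methylation, no outliers."""
    rng = np.random.default_rng(7)
    vals = rng.beta(0.05 * 200, 0.95 * 200, size=(20, 8))
    return BetaMatrix(
        pd.DataFrame(
            vals,
            index=[f"S{i:02d}" for i in range(20)],
            columns=[f"cg{i}" for i in range(8)],
        )
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort with its spike truth, shared across tests."""
    return simulate_cohort(SimulationConfig(seed=11))
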