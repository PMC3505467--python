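import numpy as np
import pytest

from gelbayes import GelMatrix, ModelConstants, preset, simulate


@pytest.fixture
def tiny_gel_matrix():
    """3 spots x 4 gels (2 control + 2 case) with two missing cells."""
    values = np.array(
        [
            [-5.0, -4.5, -3.9, -4.2],
            [-6.1, np.nan, -5.8, -6.3],
            [np.nan, -2.2, -2.0, -2.4],
        ]
    )
    mask = np.isnan(values)
    return GelMatrix(
        values=values,
        missing_mask=mask,
        spot_ids=["s1", "s2", "s3"],
        gel_ids=["g1", "g2", "g3", "g4"],
        groups=["control", "control", "case", "case"],
        constants=ModelConstants(d=-8.67),
    )


@pytest.fixture(scope="session")
def sim1_small():
    """Small intensity-model validation dataset (20 spots, 12 + 12 gels)."""
    return simulate(preset("sim1", S=20), seed=7)


@pytest.fixture(scope="session")
def sim1_small_trace(sim1_small):
    from gelbayes import ChainConfig, run_chain

    cfg = ChainConfig(iterations=60_000, thin=100, burnin_frac=0.1, seed=3)
    return run_chain(sim1_small.gel_matrix, cfg)
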