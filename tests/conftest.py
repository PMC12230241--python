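import numpy as np
import pandas as pd
import pytest

from sdlscreen import shrna, synthdata


def make_tensor(trajectories: dict, gene_of: dict | None = None) -> shrna.ScreenTensor:
    """Build a ScreenTensor from {hairpin: {(arm, timepoint, replicate): value}}.

    All hairpins must share the same sample grid.
    """
    first = next(iter(trajectories.values()))
    cols = sorted(first, key=lambda k: (k[0], k[1], k[2]))
    names = [shrna.sample_name(*c) for c in cols]
    values = pd.DataFrame(
        {n: [trajectories[h][c] for h in trajectories] for n, c in zip(names, cols)},
        index=pd.Index(list(trajectories), name="hairpin"),
    )
    samples = pd.DataFrame(
        [(n, c[0], c[1], c[2]) for n, c in zip(names, cols)],
        columns=["sample", "arm", "timepoint", "replicate"],
    ).set_index("sample")
    gene_of = gene_of or {h: f"gene_{h}" for h in trajectories}
    genes = pd.Series([gene_of[h] for h in trajectories], index=values.index, name="gene")
    return shrna.ScreenTensor(values, samples, genes)


def two_arm_trajectory(induced, uninduced, timepoints=(0, 8, 16), replicates=(1,)):
    """Sample dict for one hairpin with identical values across replicates."""
    out = {}
    for r in replicates:
        for t, v in zip(timepoints, induced):
            out[("induced", t, r)] = v
        for t, v in zip(timepoints, uninduced):
            out[("uninduced", t, r)] = v
    return out


@pytest.fixture(scope="session")
def default_screen():
    """The default synthetic screen (seed 7), shared across tests."""
    return synthdata.simulate_shrna_screen(synthdata.ScreenSimConfig(seed=7))


@pytest.fixture(scope="session")
def default_screen_scored(default_screen):
    cfg = shrna.WDCConfig(seed=7, fold_threshold_log2=synthdata.RECOVERY_FOLD_THRESHOLD)
    res = shrna.score_screen(default_screen.tensor, cfg)
    return default_screen, cfg, res


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
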