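import numpy as np
import pandas as pd
import pytest

from fetalmeth.config import PlantedSignal, SimulationConfig
from fetalmeth.simulate import simulate_dataset


def small_planted(effect=0.30, background=0.5, block_size=5,
                  n_blocks_per_kind=5,
                  tissues=("amnion", "muscle", "adrenal", "pancreas")):
    low = background - effect
    mid = background - effect / 2
    out = []
    for t in tissues:
        for _ in range(n_blocks_per_kind):
            out.append(PlantedSignal("tissue_hypo", t, block_size,
                                     (low, low, low), background))
            out.append(PlantedSignal("gom", t, block_size,
                                     (low, mid, background), background))
            out.append(PlantedSignal("lom", t, block_size,
                                     (background, mid, low), background))
    return out


def small_config(seed=0, **kwargs):
    defaults = dict(n_chromosomes=2, n_cpgs=4_000, n_genes=80, n_cgis=40,
                    planted=small_planted(), seed=seed)
    defaults.update(kwargs)
    cfg = SimulationConfig(**defaults)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_data():
    """A 4,000-probe synthetic dataset with 300 planted CpGs, shared
    read-only across tests."""
    return simulate_dataset(small_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def exact_beta(values_by_sample, probe_ids, meta_rows):
    """Noise-free beta matrix + sample sheet from explicit per-sample vectors.

    ``meta_rows`` is a list of (sample_id, tissue, week, replicate) tuples;
    ``values_by_sample`` maps sample_id to a per-probe value list.
    """
    beta = pd.DataFrame({sid: values_by_sample[sid] for sid, *_ in meta_rows},
                        index=pd.Index(probe_ids, name="probe_id"))
    meta = pd.DataFrame(
        [(sid, t, w, r, "unknown") for sid, t, w, r in meta_rows],
        columns=["sample_id", "tissue", "week", "replicate", "sex"],
    ).set_index("sample_id")
    return beta, meta
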