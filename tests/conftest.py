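import numpy as np
import pandas as pd
import pytest

from ribofuse.quantify import CountMatrix
from ribofuse.simulate import (
    SimConfig,
    make_ground_truth,
    simulate_counts,
    simulate_population,
    simulate_transcript_models,
)


def make_count_matrix(values: dict, samples: list[tuple]) -> CountMatrix:
    """values: sample_id -> counts list; samples: (id, tissue, breed, rep, modality)."""
    sheet = pd.DataFrame(
        samples, columns=["sample_id", "tissue", "breed", "replicate", "modality"]
    )
    genes = [f"g{i + 1}" for i in range(len(next(iter(values.values()))))]
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene"))
    return CountMatrix(vals[list(sheet["sample_id"])], sheet)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=200, n_tfs=8, n_tissues=2, n_variants=80, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    models = simulate_transcript_models(small_config)
    truth = make_ground_truth(small_config, models)
    expr = simulate_counts(small_config, truth, models)
    pop = simulate_population(small_config, truth, models)
    return {"config": small_config, "models": models, "truth": truth, "expr": expr, "pop": pop}
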