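import warnings

import numpy as np
import pandas as pd
import pytest

import integromics as ig
from integromics.model import DEFAULT_STAGES, ExpressionMatrix, StageDesign


def make_design(n_replicates: int = 3, stages=DEFAULT_STAGES) -> StageDesign:
    assignments = {
        f"{stage}_{rep}": (stage, rep)
        for stage in stages
        for rep in range(1, n_replicates + 1)
    }
    return StageDesign(assignments, stages=stages)


def make_matrix(rows: dict[str, list[float]], design: StageDesign, kind="gene"):
    data = pd.DataFrame.from_dict(rows, orient="index", columns=design.sample_ids)
    return ExpressionMatrix(data, kind=kind)


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture(scope="session")
def printed_style_matrix(design):
    """The hand-checkable 4x3 layout: groups (0,1,2), (4,5,6), (0,1,2), (0,1,2)."""
    return make_matrix({"feat": [0, 1, 2, 4, 5, 6, 0, 1, 2, 0, 1, 2]}, design)


@pytest.fixture(scope="session")
def zero_noise_study():
    """Small zero-noise synthetic study with planted truth (session-cached)."""
    cfg = ig.small_config(seed=5, noise_sd=0.0)
    mirna, gene, design, truth = ig.generate_progression_dataset(cfg)
    predictions = ig.generate_target_map(truth, cfg)
    gene_sets = ig.generate_gene_sets(truth, cfg)
    return cfg, mirna, gene, design, truth, predictions, gene_sets


@pytest.fixture(scope="session")
def zero_noise_pipeline(zero_noise_study):
    cfg, mirna, gene, design, truth, predictions, gene_sets = zero_noise_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = ig.run_pipeline(
            mirna, gene, design, predictions, gene_sets,
            ig.PipelineConfig(seed=3, quantile_normalize_genes=False),
        )
    return truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
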