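"""Shared fixtures: simulated batches at two scales.

The session-scoped "preset" fixtures use the default study configuration
(23 haploid sperm-like samples from two families, 20,000 SNPs, heavy
drop-in noise) and a model trained on an independent batch; the small
batch keeps unit tests fast.
"""

import hypothesis
import pytest

from scsnp import (
    SimulationConfig,
    assemble_table,
    calculate_ma,
    filter_informative,
    read_cluster,
    read_manifest,
    read_samplesheet,
    refit_gda,
    score,
    simulate_batch,
    train_model,
    truth_labels,
)

hypothesis.settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("suite")


def load_table(paths, informative_only=True):
    table = assemble_table(
        read_samplesheet(paths["samplesheet"]),
        read_manifest(paths["manifest"]),
        read_cluster(paths["cluster"]),
    )
    if informative_only:
        table = filter_informative(table)
    return calculate_ma(table)


@pytest.fixture(scope="session")
def small_batch(tmp_path_factory):
    cfg = SimulationConfig(
        n_samples=6, n_snps=1500, families=(("F1", 3), ("F2", 3)), seed=7
    )
    paths, truth = simulate_batch(cfg, tmp_path_factory.mktemp("small"))
    return cfg, paths, truth


@pytest.fixture(scope="session")
def small_table(small_batch):
    _, paths, _ = small_batch
    return load_table(paths)


@pytest.fixture(scope="session")
def preset_batch(tmp_path_factory):
    cfg = SimulationConfig(seed=101)
    paths, truth = simulate_batch(cfg, tmp_path_factory.mktemp("preset"))
    return cfg, paths, truth


@pytest.fixture(scope="session")
def preset_table(preset_batch):
    _, paths, _ = preset_batch
    return load_table(paths)


@pytest.fixture(scope="session")
def trained_model(tmp_path_factory):
    """RF-GDA model trained on a batch independent of ``preset_batch``."""
    cfg = SimulationConfig(seed=202)
    paths, truth = simulate_batch(cfg, tmp_path_factory.mktemp("train"))
    table = load_table(paths)
    return train_model(table, truth_labels(table, truth), seed=202)


@pytest.fixture(scope="session")
def preset_scored(preset_table, trained_model):
    model = refit_gda(trained_model, preset_table)
    return score(preset_table, model)
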