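"""Shared fixtures: one planted synthetic dataset reused across the suite.

Everything is generated programmatically at test time from fixed seeds, so
the suite needs no data files and is fully deterministic.
"""

from types import SimpleNamespace

import pytest

from curesmir import discovery, preprocess
from curesmir import synthetic_data as sd

SEED = 20240


@pytest.fixture(scope="session")
def dataset():
    """Planted genome/transcripts/truth with one diverged paralog per hairpin."""
    cfg = sd.GeneratorConfig(n_paralog_copies=1)
    genome, transcripts, ann_records, truth = sd.generate_genome_and_transcripts(
        cfg, seed=SEED)
    return SimpleNamespace(config=cfg, genome=genome, transcripts=transcripts,
                           ann_records=ann_records, truth=truth)


@pytest.fixture(scope="session")
def noisefree_libraries(dataset):
    libs, design = sd.generate_srna_libraries(
        dataset.truth, depth=100_000, noise=sd.NoiseSettings.off(), seed=SEED + 1)
    return libs, design


@pytest.fixture(scope="session")
def sampled_libraries(dataset):
    libs, design = sd.generate_srna_libraries(
        dataset.truth, depth=120_000, noise=sd.NoiseSettings(), seed=SEED + 2)
    return libs, design


@pytest.fixture(scope="session")
def clean_noisefree(dataset, noisefree_libraries):
    libs, _design = noisefree_libraries
    table, report = preprocess.clean_reads(libs)
    return table, report


@pytest.fixture(scope="session")
def residual_noisefree(dataset, clean_noisefree):
    table, _ = clean_noisefree
    _breakdown, residual = preprocess.annotate_reads(table, dataset.truth.annotation_seqs)
    return residual


@pytest.fixture(scope="session")
def discovered(dataset, clean_noisefree, residual_noisefree):
    """Full discovery pass (homology + folding + validation) on clean data."""
    table, _ = clean_noisefree
    candidates, hairpins = discovery.discover_mirnas(
        residual_noisefree, dataset.truth.reference_matures, dataset.transcripts,
        srna_reads=set(table.sequences()))
    return candidates, hairpins


@pytest.fixture(scope="session")
def degradome_exact(dataset):
    return sd.generate_degradome(dataset.truth, depth=100_000, seed=SEED + 3,
                                 sample=False)["DEG1"]


@pytest.fixture(scope="session")
def degradome_sampled(dataset):
    return sd.generate_degradome(dataset.truth, depth=100_000, seed=SEED + 4)["DEG1"]
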