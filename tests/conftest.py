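"""Shared fixtures: seeded references and small synthetic libraries."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference260():
    from rtquant.simulate import random_reference

    return random_reference(260, seed=7)


@pytest.fixture(scope="session")
def small_library(reference260, tmp_path_factory):
    """A small end-to-end library with elevated error rates, written to disk.

    Returns (products, amplicons, run, paths) where paths is a dict with
    r1/r2/ref file locations.
    """
    from rtquant.io import write_reference_fasta
    from rtquant.simulate import SimConfig, simulate_library

    cfg = SimConfig(
        reference_sequence=reference260,
        n_molecules=300,
        reads_per_library=6000,
        rt_sub_rate=1e-3,
        rt_indel_rate=1e-4,
        seq_error_rate=2e-3,
        seed=17,
    )
    products, amplicons, run = simulate_library(cfg)
    d = tmp_path_factory.mktemp("small_library")
    paths = {
        "r1": d / "r1.fastq",
        "r2": d / "r2.fastq",
        "ref": d / "reference.fa",
        "manifest": d / "manifest.tsv",
    }
    run.write(paths["r1"], paths["r2"], paths["manifest"])
    write_reference_fasta(reference260, paths["ref"])
    return products, amplicons, run, paths


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
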