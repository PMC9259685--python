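"""Shared fixtures: one session-scoped mini reference and cached simulations."""

from __future__ import annotations

import numpy as np
import pytest

from paralocus import synthetic_data as sd
from paralocus.pipeline import call_sample

REF_SEED = 7


@pytest.fixture(scope="session")
def workdir(tmp_path_factory):
    return tmp_path_factory.mktemp("sims")


@pytest.fixture(scope="session")
def mini_ref():
    return sd.build_mini_reference(seed=REF_SEED)


@pytest.fixture(scope="session")
def mini_fasta(mini_ref, workdir):
    return mini_ref.write_fasta(workdir / "mini.fa")


@pytest.fixture(scope="session")
def sim_cache(mini_ref, mini_fasta, workdir):
    """Lazily simulate one sample per requested class; cache BAM + truth."""
    cache: dict[str, tuple] = {}

    def get(class_name: str, seed: int = 1000):
        key = f"{class_name}_{seed}"
        if key not in cache:
            rng = np.random.default_rng(seed)
            specs = sd.class_allele_specs(mini_ref, class_name, rng)
            bam, truth = sd.simulate_sample(
                mini_ref,
                specs,
                sd.SimulationConfig(seed=seed + 1),
                workdir / key,
            )
            cache[key] = (bam, truth)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def report_cache(mini_ref, mini_fasta, sim_cache):
    """Lazily run the full pipeline per class; cache the SampleReport."""
    cache: dict[str, object] = {}

    def get(class_name: str, seed: int = 1000):
        key = f"{class_name}_{seed}"
        if key not in cache:
            bam, _ = sim_cache(class_name, seed)
            cache[key] = call_sample(
                bam, mini_ref.model, mini_fasta, sample_id=key
            )
        return cache[key]

    return get
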