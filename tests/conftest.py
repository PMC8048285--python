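from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests._oracles imports

from founderscan import GenotypeMatrix, SimulationConfig, simulate_dataset


def make_matrix(
    calls,
    populations: list[str] | None = None,
    depth=None,
    chrom: str = "chr1",
    start_pos: int = 100,
    spacing: int = 100,
) -> GenotypeMatrix:
    """Build a small GenotypeMatrix from a nested list of calls.

    ``populations`` is an optional per-sample list of labels; by default the
    first half of the samples is popA and the rest popB.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_loci = calls.shape
    samples = [f"s{i + 1}" for i in range(n_samples)]
    if populations is None:
        half = n_samples // 2
        labels = ["popA"] * half + ["popB"] * (n_samples - half)
    else:
        labels = list(populations)
    populations = dict(zip(samples, labels))
    loci = pd.DataFrame(
        {
            "chrom": [chrom] * n_loci,
            "pos": [start_pos + spacing * j for j in range(n_loci)],
            "ref": ["A"] * n_loci,
            "alt": ["G"] * n_loci,
        }
    )
    return GenotypeMatrix(samples, populations, loci, calls, depth)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_chromosomes=4,
        chromosome_length_bp=300_000,
        n_genes=60,
        snps_per_gene_mean=25,
        ancestral_n_loci=1_500,
        n_selected_loci=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def emitted_small_dataset(small_dataset, tmp_path_factory):
    from founderscan import emit_dataset

    out = tmp_path_factory.mktemp("emitted")
    return emit_dataset(small_dataset, out)
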