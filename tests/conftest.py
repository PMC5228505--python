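from __future__ import annotations

from importlib import resources

import pytest

from oudphylo.seqio import TranscriptRecord, TranscriptSet, read_retention_table
from oudphylo.simulate import SimulationConfig, simulate_dataset


def make_ts(strain: str, seqs: dict[str, str]) -> TranscriptSet:
    """Build a TranscriptSet from {id: sequence}."""
    return TranscriptSet(
        strain=strain,
        records=[TranscriptRecord(id=i, sequence=s) for i, s in seqs.items()],
    )


@pytest.fixture(scope="session")
def retention_records():
    """The 18 chrysophyte sequencing libraries' raw/clean read-pair counts."""
    path = resources.files("oudphylo") / "data" / "chrysophyte_retention.tsv"
    return read_retention_table(str(path))


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset shared by pipeline-level tests."""
    cfg = SimulationConfig(
        n_taxa=5, n_genes=40, gene_len_bounds=(600, 900), subst_rate=0.05, seed=11
    )
    return simulate_dataset(cfg)
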