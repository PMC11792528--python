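import numpy as np
import pytest

from peptaxa import (
    SimulationConfig,
    deduplicate_exact,
    simulate_peptide_table,
    simulate_reference,
)
from peptaxa.taxonomy import Lineage


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def reference(config):
    collection, truth = simulate_reference(config)
    return collection, truth


@pytest.fixture(scope="session")
def dedup(reference):
    collection, _ = reference
    return deduplicate_exact(collection)


@pytest.fixture(scope="session")
def peptide_data(config, reference):
    collection, _ = reference
    table, truth = simulate_peptide_table(collection, config)
    return table, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240907)


def make_lineage(*names):
    """Lineage from sub-root names (Root prepended)."""
    return Lineage(("Root", *names))


@pytest.fixture
def gut_lineages():
    """A small, hand-written set of realistic lineages."""
    return {
        "ecoli": make_lineage(
            "Bacteria", "Pseudomonadota", "Gammaproteobacteria",
            "Enterobacterales", "Enterobacteriaceae", "Escherichia",
            "Escherichia coli",
        ),
        "btheta": make_lineage(
            "Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales",
            "Bacteroidaceae", "Bacteroides", "Bacteroides thetaiotaomicron",
        ),
        "bfragilis": make_lineage(
            "Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales",
            "Bacteroidaceae", "Bacteroides", "Bacteroides fragilis",
        ),
        "blongum": make_lineage(
            "Bacteria", "Actinomycetota", "Actinomycetes",
            "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium",
            "Bifidobacterium longum",
        ),
        "fprau_legacy": make_lineage(
            "Bacteria", "Firmicutes", "Clostridia", "Eubacteriales",
            "Oscillospiraceae", "Faecalibacterium",
            "Faecalibacterium prausnitzii",
        ),
    }
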