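import numpy as np
import pandas as pd
import pytest

from microherit import genoqc, synthdata, varcomp
from microherit.features import TaxonCountTable


@pytest.fixture(scope="session")
def cohort():
    """A medium half-sib cohort shared across genetics tests:
    20 sires x 10 offspring, 800 markers, with metadata and design."""
    panel = synthdata.simulate_genotypes(
        synthdata.PedigreeStructure(n_sires=20, offspring_per_sire=10),
        n_markers=800, seed=11)
    grm = genoqc.build_grm(panel)
    meta = synthdata.simulate_metadata(panel.sample_ids, seed=12)
    design = varcomp.build_design(meta)
    return {"panel": panel, "grm": grm, "meta": meta, "design": design}


@pytest.fixture
def lineage_table():
    """Tiny count table with a two-rank lineage (family, genus)."""
    counts = pd.DataFrame(
        [[3, 4, 5, 0],
         [1, 2, 0, 6],
         [2, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["g1", "g2", "g3", "g4"],
    )
    lineage = pd.DataFrame(
        {"family": ["F1", "F1", "F2", "F2"],
         "genus": ["GenA", "GenB", "GenC", ""]},
        index=["g1", "g2", "g3", "g4"],
    )
    return TaxonCountTable(counts, lineage)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
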