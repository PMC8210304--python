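import numpy as np
import pytest

from trfscape import SimulationConfig, simulate_study
from trfscape.annotation import TrnaGene


def make_gene(family="IleAAT-8-1", length=73, seed=0, mito=False,
              trailer="A" * 17 + "TTTT" + "G" * 29):
    rng = np.random.default_rng(seed)
    body = "".join(rng.choice(list("ACGT"), size=length))
    return TrnaGene(
        family_name=family,
        isotype=family[:3],
        anticodon=family[3:6] if family[3:6].isupper() else "AAT",
        is_mitochondrial=mito,
        gene_sequence=body,
        mature_sequence=body + "CCA",
        trailer_sequence=trailer,
    )


@pytest.fixture(scope="session")
def toy_genes():
    return [
        make_gene("IleAAT-8-1", 73, seed=1),
        make_gene("LysCTT-4-1", 70, seed=2, mito=True),
        make_gene("ArgACG-2-1", 76, seed=3),
    ]


@pytest.fixture(scope="session")
def small_study():
    """Two-cohort study, modest depth; shared by read-level tests."""
    return simulate_study(
        SimulationConfig(
            seed=7, n_cohorts=2, n_tumor=8, n_normal=6,
            n_trna_genes=6, library_size=20_000,
        )
    )


@pytest.fixture(scope="session")
def small_matrix(small_study):
    return small_study.expression_matrix()
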