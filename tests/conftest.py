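import pytest

from kinvar.io import Variant
from kinvar.simulate import SimConfig, simulate_cohorts


def make_variant(ref="R", alt="W", gene="GRK4", pos=275, af=0.12, pop="POP"):
    return Variant(gene=gene, protein_pos=pos, ref_aa=ref, alt_aa=alt, af=af, population=pop)


@pytest.fixture(scope="session")
def small_cohorts():
    """A small two-population synthetic study shared across tests."""
    cfg = SimConfig(
        n_genes=12,
        protein_length_range=(120, 300),
        n_variants_per_population=800,
        populations=("POP1", "POP2"),
        seed=7,
    )
    return simulate_cohorts(cfg)
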