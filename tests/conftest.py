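import pytest

from mitocomp import (
    EvolutionConfig,
    GeneFeature,
    MitogenomeRecord,
    SimulationConfig,
    simulate_mitogenome,
)


def make_record(sequence, features, circular=True, rid="toy"):
    return MitogenomeRecord(rid, "toy record", sequence, circular,
                            [GeneFeature(*f) if isinstance(f, tuple) else f
                             for f in features])


@pytest.fixture(scope="session")
def sim_record():
    """One default synthetic mitogenome, shared read-only across tests."""
    record, _ = simulate_mitogenome(SimulationConfig(seed=11))
    return record


@pytest.fixture(scope="session")
def sim_pair():
    """Ancestor and a derivative at 1% divergence, substitutions only."""
    from mitocomp import evolve

    record, _ = simulate_mitogenome(SimulationConfig(seed=11))
    derived, log = evolve(record, EvolutionConfig(d=0.01, indel_rate=0.0,
                                                  seed=17))
    return record, derived, log


MINIMAL_GENBANK = """\
LOCUS       TOY0001                   24 bp    DNA     circular INV 01-JAN-2020
DEFINITION  toy mitogenome fragment.
ACCESSION   TOY0001
FEATURES             Location/Qualifiers
     source          1..24
                     /organism="toy"
     CDS             1..9
                     /gene="g1"
ORIGIN
        1 atgaaataat tttttttttt tttt
//
"""

WRAPPING_GENBANK = """\
LOCUS       TOY0002                   20 bp    DNA     circular INV 01-JAN-2020
DEFINITION  toy wrapping feature.
ACCESSION   TOY0002
FEATURES             Location/Qualifiers
     CDS             join(16..20,1..4)
                     /gene="wrapper"
     tRNA            complement(6..12)
                     /product="tRNA-Phe"
ORIGIN
        1 atgcatgcat gcatgcatgc
//
"""


@pytest.fixture
def minimal_gb(tmp_path):
    p = tmp_path / "minimal.gb"
    p.write_text(MINIMAL_GENBANK)
    return p


@pytest.fixture
def wrapping_gb(tmp_path):
    p = tmp_path / "wrapping.gb"
    p.write_text(WRAPPING_GENBANK)
    return p
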