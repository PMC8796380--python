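import pytest

from satmut.assembly import AssemblyOptions
from satmut.codons import load_codon_table
from satmut.engine import SgeConfig, run_sge
from satmut.fixtures import generate_fixture
from satmut.mutators import build_tables

FIXTURE_SEED = 7

P5 = "AATGATACGGCGACCACCGA"
P7 = "CAAGCAGAAGACGGCATACGAGAT"


@pytest.fixture(scope="session")
def fx(tmp_path_factory):
    """The deterministic synthetic mini-genome fixture set."""
    return generate_fixture(FIXTURE_SEED, tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def freq_table():
    return load_codon_table()


@pytest.fixture(scope="session")
def tables(freq_table):
    return build_tables(freq_table, ["+", "-"])


@pytest.fixture(scope="session")
def sge_run(fx, tmp_path_factory):
    """A full genomic run over the fixture, with adapters and revcomp."""
    out_dir = tmp_path_factory.mktemp("sge_out")
    config = SgeConfig(
        targeton_file=str(fx.paths["targeton_file"]),
        fasta=str(fx.paths["fasta"]),
        gtf=str(fx.paths["gtf"]),
        protection_vcf=str(fx.paths["protection_vcf"]),
        manifest=str(fx.paths["manifest"]),
        adapter_5=P5,
        adapter_3=P7,
        revcomp_minus_strand=True,
        out_dir=str(out_dir),
    )
    return run_sge(config), out_dir
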