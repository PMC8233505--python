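import pytest

from cnsvar import SynthConfig, derive_accession, generate_reference
from cnsvar.caller import call_accession


def small_config(**overrides) -> SynthConfig:
    """Desk-scale world shared by the unit tests: 1 x 120 kb chromosome."""
    base = dict(
        n_chroms=1,
        chrom_len=120_000,
        n_genes=60,
        gene_len=800,
        n_cns=250,
        n_accessions=2,
        pav_per_accession=8,
        posv_per_accession=15,
        n_repeats=25,
        n_peaks=60,
        seed=42,
    )
    base.update(overrides)
    return SynthConfig(**base)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_ref(small_cfg):
    return generate_reference(small_cfg)


@pytest.fixture(scope="session")
def small_acc(small_ref, small_cfg):
    return derive_accession(small_ref, small_cfg, 0)


@pytest.fixture(scope="session")
def small_calls(small_ref, small_acc, small_cfg):
    calls, summary = call_accession(
        small_ref.cns_records(),
        small_acc.genome,
        small_acc.genes,
        small_acc.orthologs,
        accession=small_acc.name,
    )
    return calls, summary


@pytest.fixture(scope="session")
def clean_cfg():
    """No background mutation, every PosV landing biased next to a repeat."""
    return small_config(snp_rate=0.0, indel_rate=0.0, te_bias=1.0, te_window=300)


@pytest.fixture(scope="session")
def clean_ref(clean_cfg):
    return generate_reference(clean_cfg)


@pytest.fixture(scope="session")
def clean_acc(clean_ref, clean_cfg):
    return derive_accession(clean_ref, clean_cfg, 0)
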