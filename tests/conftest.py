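import pytest

from repairguide.fixtures import FixtureSpec, generate_orf, preset_orf


@pytest.fixture(scope="session")
def h2bgfp():
    """Synthetic 400-codon reporter ORF with the opal stop at codon 190."""
    return preset_orf("h2bgfp-opal")


@pytest.fixture(scope="session")
def cftr():
    """Synthetic 1500-codon ORF with the opal stop at codon 1282 (g.3846G>A)."""
    return preset_orf("cftr-w1282x")


@pytest.fixture(scope="session")
def trace_template():
    """60-nt template with the editable opal adenosine centered (position 30)."""
    return generate_orf(
        FixtureSpec(n_codons=20, ptc_codon_index=10, ptc_codon="TGA", seed=7),
        record_id="trace_template",
    )
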