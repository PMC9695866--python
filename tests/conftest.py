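import pytest

from coidiag.reference import synthetic_barcoding_alignment, synthetic_reference_panel


@pytest.fixture(scope="session")
def reference_panel():
    """(targets, nontargets): the bundled synthetic COI reference panel."""
    return synthetic_reference_panel()


@pytest.fixture(scope="session")
def plep_reference(reference_panel):
    """The primary P. leporinus-like synthetic COI template."""
    return reference_panel[0][0]


@pytest.fixture(scope="session")
def barcoding():
    """(alignment, groups, outgroups): synthetic 341-bp barcoding panel."""
    return synthetic_barcoding_alignment()
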