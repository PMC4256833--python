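import pytest

from itsmap.fixtures import (
    diels_alder_reaction,
    kegg_reactions,
    meisenheimer_reaction,
)


@pytest.fixture(scope="session")
def kegg():
    return kegg_reactions()


@pytest.fixture(scope="session")
def diels_alder():
    """Hydrogen-suppressed Diels-Alder example, gated on the reference multisets."""
    return diels_alder_reaction(explicit_hydrogens=False, validate=True)


@pytest.fixture(scope="session")
def meisenheimer():
    return meisenheimer_reaction()
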