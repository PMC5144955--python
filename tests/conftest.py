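import pytest

from synbreak.fixtures import paper_genomes, run_paper_demo


@pytest.fixture(scope="session")
def genomes():
    return paper_genomes()


@pytest.fixture(scope="session")
def demo():
    """One end-to-end run of the curated-fixture pipeline, shared by tests."""
    return run_paper_demo()
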