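import pytest

from pfvmkit import assemble_pfvm, worked_example_table


@pytest.fixture(scope="session")
def worked_table():
    return worked_example_table()


@pytest.fixture(scope="session")
def worked_pfvm(worked_table):
    # Covers the four consecutive worked-example windows MEDSQ..SQSDM.
    return assemble_pfvm("MEDSQSDM", worked_table)
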