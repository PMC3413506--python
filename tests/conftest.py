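import warnings

import pytest

from fluxscreen import fixtures as fx
from fluxscreen.sbml_io import read_sbml, write_sbml


@pytest.fixture
def chain():
    return fx.make_chain_fixture(3, 10.0)


@pytest.fixture
def branched():
    return fx.make_branched_fixture()


@pytest.fixture
def two_branch():
    return fx.make_two_branch_fixture()


@pytest.fixture
def roundtrip(tmp_path):
    """Write a document to SBML and read it back, exercising the parser."""

    def _roundtrip(doc, name="model.xml"):
        path = tmp_path / name
        write_sbml(doc, str(path))
        return read_sbml(str(path))

    return _roundtrip


@pytest.fixture
def cobra_model(tmp_path):
    """Load a document into cobrapy (the independent solver oracle)."""
    cobra = pytest.importorskip("cobra")

    def _load(doc, name="oracle.xml"):
        path = tmp_path / name
        write_sbml(doc, str(path))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import logging

            logging.getLogger("cobra").setLevel(logging.ERROR)
            return cobra.io.read_sbml_model(str(path))

    return _load
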