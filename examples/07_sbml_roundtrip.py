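"""Writing and re-reading SBML, and validating encoding conventions."""

import tempfile
from pathlib import Path

import fluxscreen as fs
from fluxscreen import fixtures

doc = fixtures.make_branched_fixture()
path = Path(tempfile.mkdtemp()) / "branched.xml"
fs.write_sbml(doc, str(path))
back = fs.read_sbml(str(path))
print(f"re-read {len(back.reactions)} reactions, {len(back.genes)} genes, "
      f"objective {back.objective_id}")

report = fs.validate_conventions(back)
print(f"convention violations: {report.violations or 'none'}")

# break a convention on purpose: a reversible isa reaction would let the
# generic class species act as a source of specific compounds
back.reaction("ISA1").lower_bound = -10.0
print(fs.validate_conventions(back).violations)
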