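"""Auxotrophy classification: minimal versus supplemented media.

An auxotroph cannot synthesise a required compound but grows when it is
supplied; a lesion in an unsuppliable pathway stays dead either way.
"""

import fluxscreen as fs
from fluxscreen import fixtures

doc = fixtures.make_branched_fixture()
calls = fs.auxotrophy_screen(doc, ["GAux", "GS", "GOR1"])
for c in calls:
    print(
        f"  {c.gene}: minimal {c.objective_minimal:.3g}, "
        f"supplemented {c.objective_supplemented:.3g} -> {c.category}"
    )
# GAux (alanine synthesis) is rescued by opening the alanine exchange:
# auxotroph_confirmed.  GS (sterol synthesis) cannot be rescued because no
# exchange supplies sterol: inviable_in_supplemented.  GOR1 has an
# isoenzyme: viable_in_minimal.
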