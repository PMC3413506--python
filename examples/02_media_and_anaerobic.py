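"""Growth media and the anaerobic shift.

The branched fixture mirrors yeast-model logic: sterol synthesis needs
oxygen, and anaerobic growth needs supplemented sterol plus a modified
lipid definition.
"""

import fluxscreen as fs
from fluxscreen import fixtures

doc = fixtures.make_branched_fixture()
print(f"aerobic growth: {fs.solve_fba(doc).objective_value:.4g}")  # 2.5

# closing oxygen alone kills growth: the aerobic lipid route needs sterol
closed = doc.copy()
closed.reaction("EX_o2").lower_bound = 0.0
print(f"oxygen closed only: {fs.solve_fba(closed).objective_value:.4g}")  # 0

# the full shift (close O2, open sterol uptake, swap the lipid variant)
ana = fs.anaerobic_transform(doc)
print(f"anaerobic growth: {fs.solve_fba(ana).objective_value:.4g}")  # 3.333

# a leaner medium: less glucose, same oxygen — growth scales with carbon
lean = fs.MediumSpec(bounds={"EX_glc": (-5.0, 0.0), "EX_o2": (-1000.0, 0.0)})
print(f"half glucose: {fs.solve_fba(fs.apply_medium(doc, lean)).objective_value:.4g}")
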