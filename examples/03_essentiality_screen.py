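"""Single-gene deletion screen scored against curated gene lists.

Positive means predicted growth: a true positive is an unlisted gene whose
deletion still grows, a true negative a listed gene whose deletion does not.
"""

import fluxscreen as fs
from fluxscreen import fixtures

doc = fixtures.make_branched_fixture()
screen = fs.single_deletion_screen(doc)
for gene, (objective, viable) in sorted(screen.results.items()):
    print(f"  {gene}: growth {objective:.3g} -> {'viable' if viable else 'inviable'}")

lists = fs.GeneLists(
    essential=set(fixtures.BRANCHED_ESSENTIAL),
    auxotroph_inducing=set(fixtures.BRANCHED_AUXOTROPHIC),
)
cm = fs.score_essentiality(screen, lists)
print(f"TP {cm.tp}  FN {cm.fn}  FP {cm.fp}  TN {cm.tn}")
print(f"sensitivity {cm.sensitivity:.3f}  specificity {cm.specificity:.3f}")
print(f"combined accuracy (sens x spec): {cm.combined_accuracy:.3f}")
# The fixture's phenotypes match its lists exactly, so every metric is 1:
# isoenzyme pairs survive single deletions, the AND-gated complex and the
# sole-pathway genes do not.
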