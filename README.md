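# fluxscreen

Constraint-based evaluation of genome-scale metabolic models (GEMs) of the
kind used for *Saccharomyces cerevisiae*: flux balance analysis, growth-media
and gene-deletion simulation, essentiality and auxotrophy scoring, pairwise
epistasis screens, and derivation of the evidence-only network reconstruction
(GENRE) that underlies a model.

It is written for systems biologists who receive a stoichiometric model as an
SBML file and want to ask: does it grow on the right media, does it predict
the right knockout phenotypes, which reactions are dead weight, and how do
gene pairs interact?

## The model and the metrics

A metabolic model is a stoichiometric matrix **S** (rows: metabolites,
columns: reactions) with flux bounds **lb ≤ v ≤ ub** and boolean
gene–protein–reaction (GPR) rules attaching genes to reactions.  FBA solves

```
max  c·v   subject to   S v = 0,  lb ≤ v ≤ ub
```

with **c** selecting the biomass exchange flux, the proxy for growth rate.
On top of that linear program the package provides:

- **Flux variability analysis** — per-reaction flux ranges at a fixed
  objective level; the fraction-0 regime detects *blocked* reactions
  (reactions that can never carry flux under an exchange regime).
- **Geometric FBA** — the unique centred point of the optimal face, found by
  iterating FVA range-midpoint centring with an L1 deviation objective.  It
  makes flux reports and restriction references independent of solver
  tie-breaking.
- **Deletion screens** — one FBA per gene with the GPR-disabled reactions
  closed; calls are scored against curated gene lists as a confusion matrix
  with *positive = predicted growth* (sensitivity, specificity, PPV, NPV,
  and their product as a combined accuracy).
- **Auxotrophy screens** — each candidate gene is classified by growth in a
  minimal versus a fully supplemented medium: `auxotroph_confirmed`,
  `viable_in_minimal`, or `inviable_in_supplemented`.
- **Epistasis** — non-scaled multiplicative interaction
  `ε = W_xy − W_x·W_y`, where fitness W is biomass flux relative to wild
  type and perturbations limit each gene's reactions to a fraction of their
  wild-type geometric-FBA flux.
- **GENRE derivation** — reactions annotated SBO:395 (encapsulating "isa")
  or SBO:397 (omitted process: biomass, hypothetical transport) are removed,
  bounds lifted, and orphaned species pruned, leaving the evidence-only
  reconstruction.

SBML input accepts both Level-3 `fbc` gene associations and COBRA-style
`GENE_ASSOCIATION` notes; exchange reactions follow the convention that
positive flux exports and negative flux imports a compound, with `_b`
boundary placeholders excluded from **S**.

## Worked example

```python
import fluxscreen as fs
from fluxscreen import fixtures

doc = fixtures.make_branched_fixture()      # toy model with yeast-like logic
print(fs.solve_fba(doc).objective_value)    # 2.5   (aerobic growth)
ana = fs.anaerobic_transform(doc)           # close O2, open sterol uptake,
print(fs.solve_fba(ana).objective_value)    # 3.3333...  swap lipid variant

screen = fs.single_deletion_screen(doc)
cm = fs.score_essentiality(screen, fs.GeneLists(
    essential={"GB", "GC1", "GC2", "GS"}, auxotroph_inducing={"GAux"}))
print(cm.tp, cm.fn, cm.fp, cm.tn)           # 4 0 0 5
print(cm.sensitivity, cm.combined_accuracy) # 1.0 1.0

res = fs.pairwise_screen(fixtures.make_chain_fixture(), fraction=0.5)
print(res.pairs)                            # [('G1', 'G2', 0.5, 0.25)]
```

The last line says: with both chain genes restricted to 50% of wild-type
flux the double-perturbation fitness is 0.5 — equal to each single fitness,
because the genes sit on the same linear pathway — so ε = 0.5 − 0.25 = +0.25,
a buffering interaction.  The `examples/` directory holds one short script
per capability; each prints the numbers it computes and what they mean.
A thin CLI exposes the same workflows (`fluxscreen evaluate|derive|flux|
epistasis|blocked|fixtures`).

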