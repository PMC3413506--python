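# Methods

## The constraint-based model

A model document holds species, reactions (signed stoichiometry, flux
bounds, an optional SBO term, a GPR rule) and one objective reaction.  The
steady-state assumption S·v = 0 is imposed only over non-boundary species:
placeholder species carrying the `_b` suffix (or the SBML boundary-condition
attribute) are kept in the document for round-trip fidelity but never reach
the solver, which is what lets exchange reactions act as net sources and
sinks.  Exchange reactions are recognised structurally — exactly one
non-boundary participant — rather than by naming conventions, and encode the
internal species with coefficient −1 so that positive flux means export and
negative flux uptake.  (The written convention in the consensus-yeast
literature states a +1 matrix entry together with the same sign semantics;
the two are inconsistent, and this package follows the sign semantics.)

GPR rules are immutable AND/OR trees over gene identifiers; a reaction with
no association is unaffected by any deletion.  Two SBML dialects are read
(structured `fbc` gene-product associations first, COBRA-style
`GENE_ASSOCIATION` notes text as fallback); writing emits Level 2 Version 4
with kinetic-law bound parameters and notes-field GPRs, which round-trips
every modelled field including infinite bounds (serialised as IEEE `INF`).

## Linear programming

The backend is HiGHS through `scipy.optimize.linprog`.  Documents keep true
infinities; a finite stand-in (default magnitude 1000, the conventional
COBRA bound) is substituted only at solver hand-off and is configurable.
Solver feasibility is HiGHS's default (~1e-9); package-level contract checks
(objective agreement, convergence, clamping) use 1e-6.  A model that cannot
grow but admits v = 0 reports `optimal` with objective 0 rather than
`infeasible`, so screens can always compare against a viability threshold;
`infeasible` is reserved for genuinely empty polytopes (e.g. forced
production with no consumer).

Geometric FBA fixes the objective at its optimum and then iterates: delimit
every reaction's range by FVA inside the current constraint set, minimise
the summed absolute deviation from the range midpoints (an LP in [v, d]
with d ≥ |v − m|), constrain the total deviation to that minimum, and
re-delimit.  Iteration stops when the widest residual range falls below
1e-6 (or after 50 rounds), and the returned vector is the residual box's
midpoint — within tolerance of a feasible optimum and invariant under
reaction reordering.  The deviation norm is L1; the scheme's description in
the literature leaves the norm implicit, and L1 keeps every step linear.

For networks of at most ~12 reactions an exact oracle is available:
enumeration of every vertex of {S v = 0, lb ≤ v ≤ ub} by fixing
n − rank(S) variables at bounds and solving the remaining square system.
It shares nothing with the LP path and anchors the solver tests.

## Perturbations

All perturbation operations return modified copies.  Media replace listed
exchange bounds verbatim and close every unlisted exchange to uptake while
leaving export open; application is idempotent.  The supplemented medium of
the auxotrophy screen opens every exchange to uptake at the default
magnitude — the operational reading of "supplemented/maximal media", since
no explicit composition is stated for it.  Deletions close every reaction
whose GPR evaluates false.  The anaerobic shift closes oxygen uptake, opens
uptake of ergosterol, lanosterol, zymosterol and phosphatidate (the
compounds yeast must be given under strict anaerobiosis), disables the
aerobic lipid pseudoreaction and enables the anaerobic variant that omits
the two oxygen-dependent sterols from the biomass lipid definition.
Reactions are located by explicit ids when supplied, else by species-name
patterns; anything unlocatable is reported in a single error because a
partial shift silently simulates the wrong condition.

Fractional flux restriction intersects the bounds of every reaction
carrying a gene with the symmetric band [−f·|v*|, +f·|v*|], v* being the
wild-type geometric-FBA flux.  The symmetric band is the default because
the source procedure specifies only "limiting flux by a fixed amount";
a sign-preserving mode (restrict to the interval between 0 and f·v*) is
available behind a flag.  Fraction 0 reproduces hard deletion; fraction 1
never loosens existing bounds.

## Screens and metrics

The single-deletion screen solves the wild type once and one LP per gene
against a compiled problem (bounds are overridden per deletion; S is built
once).  Viability means objective > 1e-6 × wild type; the threshold is
configurable and deliberately far below any biologically meaningful growth
difference.  Scoring uses *positive = predicted growth*; condition-negative
genes are those on either curated list (essential or auxotroph-inducing),
so the matrix denominator is the full screened gene set.  The combined
accuracy is the product sensitivity × specificity.  The model-comparison
literature prints this quantity under the name "geometric mean", but the
printed values match the plain product, so the product is what is
implemented and the naming mismatch is noted here rather than hidden.

The auxotrophy screen classifies each candidate gene by two LPs (minimal,
supplemented): dead in minimal but alive when supplemented is the expected
auxotroph behaviour; alive in minimal means the auxotrophy was missed;
dead in both means supplementation cannot rescue the lesion in silico.

Pairwise epistasis uses ε = W_xy − W_x·W_y with fitness clamped into
[0, 1] at solver tolerance and infeasible perturbed problems scored 0.
|ε| > 1e-4 counts as an interaction; the threshold is configurable, the
count's sensitivity to it is queryable (`count_at_tolerance`), and pairs
are unordered with a reaction shared by both genes restricted once (bounds
are set, not compounded).  The restriction grid runs 0–90% in 10% steps;
long screens write a per-pair checkpoint file and resume deterministically
because gene order is sorted.

## Reconstruction derivation and blocked reactions

Derivation removes reactions tagged SBO:395 (encapsulating "isa") and
SBO:397 (omitted process), lifts all remaining bounds, prunes species left
without reactions (boundary placeholders, generic class species, biomass),
and drops the objective.  A document with no SBO terms at all is rejected —
the derivation would be the identity, which almost surely means missing
markup, not an assumption-free model — except when the document is already
flagged as a reconstruction, which makes derivation idempotent.

Blocked-reaction detection runs FVA with the objective unconstrained; a
reaction is blocked iff its range is (0, 0) within 1e-7.  The default
exchange regime opens every exchange in both directions so blockage
reflects network gaps rather than medium choices; any medium can be passed
to ask the condition-specific question, and reports record the regime used.

## Synthetic fixtures: what they emulate and what they don't

The generators produce real SBML (tests write and re-read them) with the
full encoding conventions: `_b` placeholders, SBO-tagged pseudoreactions,
irreversible isa reactions.  The chain fixture makes fitness exactly
proportional to a restriction fraction; the two-branch fixture's spare
unannotated capacity makes its gene pair exactly non-interacting; the
branched fixture packs isoenzyme redundancy, an AND-gated cofactor loop,
isa-encapsulated lipid classes, oxygen-dependent sterol synthesis, a
supplementable amino-acid auxotrophy and both lipid pseudoreaction variants
into 21 reactions; the multigene fixture's saturated parallel branches give
analytic interaction signs (serial pairs buffer, cross-branch pairs
aggravate).  Random networks are built around a strictly feasible backbone
so their optimum is provably nonzero and small enough for vertex
enumeration.

What passing on these fixtures shows: the algebra, conventions, screens and
derivation behave exactly as specified on networks whose answers are known
in closed form.  What it does not show: numerical behaviour at genome scale
(thousands of reactions, degenerate optimal faces, near-singular bases) or
agreement with published yeast phenotype tables, which require the
distributed multi-megabyte model files as inputs.  Problem sizes used
throughout — 100 random networks of ≤8 reactions, a 100-gene / 4950-pair
epistasis screen — were chosen as the smallest sizes at which every
contract (enumeration agreement, symmetry, tolerance stability,
checkpointed resumption) is exercised meaningfully.

## Known limitations

- Geometric FBA rebuilds dense FVA subproblems per iteration; it is meant
  for reference-flux computation, not for repeated calls inside hot loops
  at genome scale.
- The anaerobic shift's name-pattern defaults assume consensus-yeast
  species naming; other models need explicit ids via `AnaerobicSpec`.
- No regulatory constraints, kinetic rate laws, thermodynamic (loopless)
  analysis beyond directionality bounds, or temperature effects.
- The "average additional interactions per additional gene" summary
  sometimes quoted alongside interaction counts has no reconstructible
  definition from published counts and is deliberately not implemented.
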