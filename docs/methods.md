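# Methods

## Model

A network is an oriented hypergraph: species are nodes, reactions are
hyperedges with signed rational stoichiometric coefficients (negative =
consumed).  Species flagged *internal* must be mass-balanced at steady
state; *external* species are sources/sinks exempt from balancing.  The
stoichiometric matrix `S` has one row per internal species and one column
per reaction, and the flux cone is `C = {v : S v = 0, v_r ≥ 0 for every
irreversible r}`.

An **elementary flux mode** is a support-minimal non-zero element of `C`,
unique up to positive scaling.  The package uses the standard algebraic
characterisation: a feasible `v ≠ 0` is elementary iff the nullspace of
`S` restricted to the columns of `supp(v)` is one-dimensional
(`rank(S_supp) = |supp| − 1`).  This is exactly what `is_elementary`
tests, and it is equivalent to support minimality: a second independent
nullspace direction within the support could always be used to cancel a
coordinate while staying feasible.

### Functional-domain networks

A domain-level network refines each enzyme into the elementary steps its
domains carry.  The conventions, chosen to match how such diagrams are
drawn and read:

* **catalytic** domains are annotations on steps (`Reaction.catalysts`);
  they never enter the stoichiometry;
* **binding** domains are species: a free domain binds its ligand in an
  explicit complex-formation step (e.g. `R23: ADP + SucC1 → SucC1·ADP`),
  and the complex participates in the chemical step;
* **regulatory** domains stay annotation-only and touch no reaction;
* enzyme-bound intermediates (hydroxyethyl-TPP, acyl-dihydrolipoamide,
  enzyme-bound cofactors) are ordinary internal species.

`reactions_of_domain` resolves a domain label to the reactions it touches
through either route (catalyst annotation, free species, or membership of
a declared complex).  Domain inhibition is modelled as deletion of all
those reactions; `inhibit` partitions the mode set by support
intersection, which provably agrees with re-enumerating the reduced
network (removing a reaction can only remove modes, never create them —
this is also property-tested).

## Enumeration algorithm

`enumerate_efms` follows the nullspace-seeded double-description lineage
of the classical EFM tools:

1. Every reversible reaction is split into an irreversible
   forward/backward pair, giving a pointed cone `{w ≥ 0 : S' w = 0}`
   whose extreme rays correspond one-to-one to the EFMs (plus one futile
   forward+backward two-cycle per split reaction).
2. The tableau is seeded with a reduced-row-echelon nullspace basis of
   `S'`.  Its identity block on the free columns makes every seed ray an
   extreme ray of the cone restricted to those coordinates, so the
   double-description iteration starts from a minimal representation.
3. The remaining non-negativity constraints are enforced one at a time:
   rays violating the constraint are dropped, and each adjacent
   (positive, negative) pair is combined into a new boundary ray.
   Adjacency uses the combinatorial zero-set test (no third ray's zero
   set may contain the pair's common zero set), which is exact while the
   representation stays minimal — guaranteed here by induction from the
   seeded start.
4. Rays are mapped back to signed flux vectors; the futile two-cycles of
   the internal splitting vanish in the mapping and are discarded.  A
   genuine two-cycle of two *distinct* antiparallel reactions is kept —
   only the artifacts of the internal split are removed.
5. Each vector is canonicalised to coprime integers; a mode whose support
   is entirely reversible is reported once, oriented so that its first
   support entry (declaration order) is positive.  Modes are ordered by
   (support size, declaration order); mode numbering is therefore an
   artifact of this deterministic ordering, and the packaged fixtures map
   their labels to modes by support, not by position.

As a guard, every returned ray is re-verified with the rank criterion;
a failure would be a bug, not a data issue, and raises immediately.

All arithmetic is `fractions.Fraction`-exact.  The small rational
linear-algebra kernel (RREF, rank, nullspace) lives in `_exact` and is
cross-checked against sympy in the test suite; supports and coefficients
carry no rounding, so no tolerance parameter exists in the package.

### Oracle

`brute_force_efms` is an independent check: it enumerates candidate
supports exhaustively, keeps those whose restricted nullspace is
one-dimensional with a full-support, sign-feasible generator, and is
guarded to ≤ 15 reactions.  The test suite requires exact signed-support
agreement with the double-description enumerator on 200+ seeded random
networks as well as on the packaged fixtures.

## Packaged networks

The fixtures are reconstructed from standard *B. subtilis* TCA-cycle
biochemistry under one hard constraint: **the enumerated mode catalogue
is the committed ground truth**, and each bundle re-verifies it on demand
(`FixtureBundle.self_test`).  Where the
chemistry admits variants, the variant consistent with that catalogue was
chosen:

* succinyl-CoA synthetase is written with ATP/ADP (not GTP/GDP), so the
  two oxidative modes that run it in the Suc→ATP direction are the ATP
  producers;
* aconitase is a single lumped step (no explicit cis-aconitate);
* phosphate is not tracked (acetyl-phosphate and ATP/ADP bookkeeping are
  net); NAD(P) specificity is lumped to NAD;
* the glycolytic pyruvate input and the acetyl-phosphate exchange are
  single lumped reactions (`Glyco`/`R22`, `Pta`/`R21`);
* in the domain TCA network the PDH and ODH complexes share the lipoamide
  dehydrogenase steps R5–R7 and a common enzyme-bound lipoamide pool
  (`LA_E`/`DHA_E`); the succinyl analogue of hydroxyethyl-TPP required by
  the ODH step sequence is named `SHE_TPP`;
* the CoA-binding domain `SucD1` is external, so its CoA loading step
  (R25) appears in mode supports;
* cofactors bound inside lipoamide dehydrogenase (`FAD_E`, `NAD_E`, ...)
  cycle internally and exchange with free pools only through R7 — which
  is why the PDH complex alone has the overall reaction
  `Pyr + NAD + CoA → AcCoA + CO2 + NADH` with no net FAD term.

Reversibility is declared per reaction: in the classical network `mdh`,
`SucCD` and `Pta` are reversible (they occur in both directions across
the mode catalogue); in the domain network the reversible set is
`R18, R21, R25, R28, R29, R31`.  Binding steps that only ever occur in
one direction across the catalogue are declared irreversible — a model
commitment, not a thermodynamic claim.

The classical and domain representations use one shared external
vocabulary (`Glc`, `AcP`, `CO2`, `NAD(H)`, `FAD(H2)`, `ATP`, `ADP`), so
`compare_representations` needs no alias table for the packaged pair; the
alias mechanism exists for representations whose lumped species are named
differently.

## Random-network generator

`random_network(n_internal, n_reactions, p_reversible, seed)` emulates
small sparse metabolic networks for property testing: every internal
species is threaded onto a substrate chain from an external source to an
external sink (so no internal species dangles and the network always
validates), the remaining reaction budget becomes random cross-links,
coefficients are drawn from {1, 2} and reversibility is Bernoulli per
reaction.  Identical seeds give byte-identical networks.  These networks
exercise the enumerator's combinatorics (including blocked reactions,
futile candidates and all-reversible cycles); they do not emulate
realistic degree distributions, cofactor usage or compartments, so
passing the sweep demonstrates algorithmic correctness on small cones,
not biological realism.  The default test sweep uses 200 networks of 3–8
reactions and 0–4 internal species — sizes at which the brute-force
oracle is exhaustive and the whole sweep stays in seconds.

## Numerical and design choices

* Declaration order is never silently sorted; matrices, listings and
  canonical orientations all derive from it, making every output
  reproducible byte-for-byte.
* Canonical form: coprime integer coefficients; orientation fixed by the
  irreversible members of the support, or by the first support entry when
  all members are reversible.
* Degenerate inputs: a network with no internal species yields one mode
  per irreversible reaction plus one (positively oriented) per reversible
  reaction; an isolated reversible internal conversion yields no mode;
  an empty network yields an empty mode set.
* Knockouts keep every species still referenced by a remaining reaction;
  species referenced by nothing are dropped, which leaves the flux
  algebra unchanged (an all-zero row imposes no constraint).
* SBML import maps `boundaryCondition="true"` *or* membership of a
  compartment id/name `external` to the external flag, accepting both
  conventions found in practice.

## Limitations

* Enumeration is exponential in the worst case; the implementation
  targets curated pathway-scale networks (tens of reactions), not
  genome-scale models, and does no compression, parallelism or bit-level
  optimisation.
* Domain decompositions are curated inputs; the package does not assign
  domains from sequence or structure.
* No kinetics, thermodynamics, concentrations or objective functions:
  conclusions are purely topological/stoichiometric.
* SBML support is import-only (core constructs); rules, events and
  constraints are rejected explicitly rather than ignored.
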