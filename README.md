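# domainflux

Elementary flux mode analysis of metabolic networks described at the
resolution of enzyme **functional domains**.

## The problem

Metabolic pathway analysis usually treats each enzyme as a single reaction.
But an enzyme is a composition of functional domains — catalytic sites,
cofactor-binding folds, regulatory sites — and two different enzymes can
share a domain or even a whole subunit.  In *Bacillus subtilis*, the
pyruvate dehydrogenase (PDH) and α-ketoglutarate dehydrogenase (ODH)
multienzyme complexes share the lipoamide dehydrogenase component (pdhD)
and exchange acyl groups through the same enzyme-bound lipoamide pool.
A whole-enzyme network cannot see this coupling; a functional-domain
network can, and conclusions about inhibition change qualitatively once it
is visible.

`domainflux` enumerates **elementary flux modes** (EFMs) of such networks.
An EFM is a flux vector `v` with

* `S v = 0` over the internal (steady-state-balanced) metabolites, where
  `S` is the stoichiometric matrix,
* `v_r ≥ 0` for every irreversible reaction `r`,
* minimal support: no other vector satisfying both conditions uses a strict
  subset of its reactions.

EFMs are the elementary generators of the flux cone
`{v : S v = 0, v_irr ≥ 0}`: every steady-state flux distribution is a
non-negative combination of them.  The enumerator is a nullspace-seeded
double-description algorithm over **exact rational arithmetic** — supports
and coefficients are exact, and there are no tolerance parameters anywhere.

The package also provides:

* a data model for networks whose species include enzyme-bound
  intermediates and cofactor-binding domains (binding domains are species
  that form ligand complexes; catalytic domains annotate reactions);
* domain-level knockout analysis: block one domain, remove every reaction
  it touches, and report which modes survive and which external products
  become unreachable;
* matching of two network representations by the overall reactions of
  their modes;
* metatool `.dat` reading/writing, a native YAML schema, SBML import;
* three packaged, self-validating *B. subtilis* networks: the classical
  TCA cycle (13 reactions, 6 EFMs), the functional-domain TCA cycle
  (33 steps R1–R33, 6 EFMs), and the PDH complex alone (7 steps, 1 EFM);
* a brute-force EFM oracle and a seeded random-network generator for
  property testing.

## Worked example

Which domain of the TCA cycle is indispensable for ATP production?
Block the NAD/FAD-binding domain of lipoamide dehydrogenase (label
`PdhD2`, SCOP fold c.4.1) in the functional-domain TCA network:

```sh
$ domainflux inhibit fixtures:tca_domain --target PdhD2
target: PdhD2 -> reactions {R5, R6, R7}
removed 5 of 6 modes
  - R1 R2 R3 R4 R5 R6 R7 R21 R22
  - R5 R6 R7 R8 R9 R10 R11 R12 R13 R14 R15 R16 R17 R18 -R21 R23 R24 -R25 R26 R27 R28 R29
  - R5 R6 R7 R8 R9 R10 R11 R12 R13 R14 R15 R16 R17 R19 R20 -R21 R23 R24 -R25 R26 R27 R30 -R31 R32 R33
  - R1 R2 R3 R4 (2 R5) (2 R6) (2 R7) R8 R9 R10 R11 R12 R13 R14 R15 R16 R17 R18 R22 R23 R24 -R25 R26 R27 R28 R29
  - R1 R2 R3 R4 (2 R5) (2 R6) (2 R7) R8 R9 R10 R11 R12 R13 R14 R15 R16 R17 R19 R20 R22 R23 R24 -R25 R26 R27 R30 -R31 R32 R33
surviving 1 modes
  + -R18 R19 R20 -R28 -R29 R30 -R31 R32 R33
lost production capabilities: ATP, AcP, CO2, FADH2, NADH
```

`PdhD2` touches the three shared lipoamide-dehydrogenase steps R5–R7.
Because PDH *and* ODH run through them, 5 of the 6 modes die — including
both ATP producers — and only the ATP-*consuming* anaplerotic cycle
(pyruvate carboxylase + malic enzyme, with malate dehydrogenase in
reverse) survives.  The `(2 R5)` entries show the doubled flux the shared
steps carry when both complexes are active in one mode.

The classical whole-enzyme network cannot reach this conclusion: knocking
out the lumped `pdh` reaction there removes only the three pdh-containing
modes, and an ATP-producing mode survives:

```sh
$ domainflux inhibit fixtures:tca_classical --target pdh | tail -5
surviving 3 modes
  + -mdh ywka pyc
  + citA citB icd odh -SucCD SucABC fumC mdh -Pta
  + citA citB icd odh -SucCD SucABC fumC ywka pyc -Pta
lost production capabilities: AcP
```

ATP is not among the lost products: the acetyl-phosphate-fed oxidative
mode still makes it.

Other entry points: `domainflux efm` (mode listing + JSON report),
`domainflux compare` (match two representations by overall reactions —
the classical and domain TCA mode sets are in exact bijection),
`domainflux convert` (metatool ↔ YAML, SBML import).  The same
functionality is available as library calls (`enumerate_efms`,
`inhibit`, `compare_representations`, ...).

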