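"""Packaged reference networks and a random-network generator for testing.

Three networks of the *Bacillus subtilis* central carbon metabolism ship with
the package:

``tca_classical``
    The TCA cycle with whole enzymes as reactions (13 reactions), including
    the anaplerotic pyruvate carboxylase / malic enzyme shunt, the
    acetyl-phosphate exchange (Pta) and a lumped glycolytic pyruvate input.
``tca_domain``
    The same metabolism at functional-domain resolution (33 elementary steps
    R1-R33): the PDH and ODH multienzyme complexes share their lipoamide
    dehydrogenase steps, and binding domains appear as species forming
    ligand complexes.
``pdh_domain``
    The pyruvate dehydrogenase complex alone (7 steps), whose single
    elementary mode performs Pyr + NAD + CoA -> AcCoA + CO2 + NADH.

Each :class:`FixtureBundle` carries the expected elementary-mode signed
supports the fixture commits to; :meth:`FixtureBundle.self_test` enumerates
and verifies them.

The networks here are reconstructed from standard TCA biochemistry under the
constraint that they reproduce the expected mode supports exactly (see each
bundle's ``notes``).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from fractions import Fraction
from importlib.resources import files
from typing import Mapping

from .domains import DomainNetworkSpec, build_domain_network
from .efm import EFMSet, FluxMode, enumerate_efms
from .io_formats import read_yaml
from .netcore import Metabolite, Network, Reaction

__all__ = ["FixtureBundle", "fixture", "FIXTURE_NAMES", "random_network"]

FIXTURE_NAMES = ("pdh_domain", "tca_classical", "tca_domain")

SignedSupport = frozenset[tuple[str, int]]


def _parse_support(entries: list[str]) -> SignedSupport:
    out = set()
    for e in entries:
        if e.startswith("-"):
            out.add((e[1:], -1))
        else:
            out.add((e, 1))
    return frozenset(out)


@dataclass(frozen=True)
class FixtureBundle:
    """A packaged network plus the mode supports it is committed to."""

    name: str
    network: Network
    expected_efm_supports: tuple[SignedSupport, ...]
    efm_label_map: Mapping[str, SignedSupport]
    expected_coefficients: Mapping[str, Mapping[str, int]]
    aliases: Mapping[str, str]
    notes: str = ""
    spec: DomainNetworkSpec | None = None

    def enumerate(self) -> EFMSet:
        return enumerate_efms(self.network)

    def labelled_mode(self, label: str, efms: EFMSet | None = None) -> FluxMode:
        """The enumerated mode carrying a given fixture label (by support)."""
        support = self.efm_label_map[label]
        efms = efms if efms is not None else self.enumerate()
        mode = efms.find_by_support(support)
        if mode is None:
            raise AssertionError(f"{self.name}: no enumerated mode has support of {label}")
        return mode

    def self_test(self, efms: EFMSet | None = None) -> EFMSet:
        """Verify the enumerated modes against the committed expectations."""
        efms = efms if efms is not None else self.enumerate()
        got = efms.signed_supports
        want = set(self.expected_efm_supports)
        if got != want:
            raise AssertionError(
                f"fixture {self.name!r}: enumerated supports differ from expected\n"
                f"unexpected: {got - want}\nmissing: {want - got}"
            )
        for label, coeffs in self.expected_coefficients.items():
            mode = self.labelled_mode(label, efms)
            for rid, c in coeffs.items():
                if mode.coefficient(rid) != Fraction(c):
                    raise AssertionError(
                        f"fixture {self.name!r} {label}: coefficient of {rid} is "
                        f"{mode.coefficient(rid)}, expected {c}"
                    )
        return efms


def _data_text(filename: str) -> str:
    return files("domainflux.data").joinpath(filename).read_text()


def fixture(name: str) -> FixtureBundle:
    """Load a packaged fixture by name (see :data:`FIXTURE_NAMES`)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    loaded = read_yaml(_data_text(f"{name}.yaml"))
    if isinstance(loaded, DomainNetworkSpec):
        spec, network, notes = loaded, build_domain_network(loaded), loaded.notes
    else:
        spec, network, notes = None, loaded, ""
    expected = json.loads(_data_text("expected_efms.json"))[name]
    label_map = {lab: _parse_support(sup) for lab, sup in expected["labels"].items()}
    return FixtureBundle(
        name=name,
        network=network,
        expected_efm_supports=tuple(label_map.values()),
        efm_label_map=label_map,
        expected_coefficients=expected.get("coefficients", {}),
        aliases=expected.get("aliases", {}),
        notes=notes,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# random sparse networks for oracle-based property testing


def random_network(
    n_internal: int,
    n_reactions: int,
    p_reversible: float = 0.3,
    seed: int = 0,
) -> Network:
    """A connected sparse random network with external source and sink.

    The construction threads every internal metabolite onto a substrate
    chain from the external source ``Xin`` to the external sink ``Xout``,
    then spends the remaining reaction budget on random cross-links.
    Coefficients are drawn from {1, 2}; reversibility is Bernoulli
    ``p_reversible`` per reaction.  The same seed always yields the same
    network (identical serialisation included).
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    if not 0 <= p_reversible <= 1:
        raise ValueError("p_reversible must be in [0, 1]")
    if n_internal < 0:
        raise ValueError("n_internal must be >= 0")
    if n_internal > 2 * n_reactions:
        raise ValueError(
            f"infeasible size: {n_internal} internal metabolites cannot all "
            f"participate in {n_reactions} reactions"
        )
    rng = random.Random(seed)
    internals = [f"M{i + 1}" for i in range(n_internal)]
    mets = [Metabolite(m) for m in internals]
    mets += [Metabolite("Xin", external=True), Metabolite("Xout", external=True)]

    reactions: list[Reaction] = []

    def coeff() -> int:
        return rng.choice((1, 2))

    if n_internal > 0 and n_reactions == 1:
        # budget of one: a single source reaction touching every internal
        stoich = {"Xin": Fraction(-1)}
        stoich.update({m: Fraction(coeff()) for m in internals})
        reactions.append(Reaction("R1", stoich, reversible=rng.random() < p_reversible))
        return Network(tuple(mets), tuple(reactions), name=f"random_{seed}")

    n_groups = min(n_internal, n_reactions - 1) if n_internal > 0 else 0
    groups: list[list[str]] = [[] for _ in range(n_groups)]
    for i, m in enumerate(internals):
        groups[i % len(groups)].append(m)
    layers: list[list[str]] = [["Xin"]] + groups + [["Xout"]]

    for k in range(len(layers) - 1):
        stoich: dict[str, Fraction] = {}
        for m in layers[k]:
            stoich[m] = stoich.get(m, Fraction(0)) - coeff()
        for m in layers[k + 1]:
            stoich[m] = stoich.get(m, Fraction(0)) + coeff()
        reactions.append(
            Reaction(f"R{len(reactions) + 1}", stoich,
                     reversible=rng.random() < p_reversible)
        )

    species = internals + ["Xin", "Xout"]
    while len(reactions) < n_reactions:
        subs = rng.sample(species, min(rng.choice((1, 2)), len(species) - 1))
        rest = [s for s in species if s not in subs]
        prods = rng.sample(rest, min(rng.choice((1, 2)), len(rest)))
        stoich = {m: Fraction(-coeff()) for m in subs}
        stoich.update({m: Fraction(coeff()) for m in prods})
        reactions.append(
            Reaction(f"R{len(reactions) + 1}", stoich,
                     reversible=rng.random() < p_reversible)
        )
    return Network(tuple(mets), tuple(reactions), name=f"random_{seed}")
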