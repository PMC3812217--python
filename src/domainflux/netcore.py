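"""Core metabolic-network data model and stoichiometric accounting.

A :class:`Network` is an oriented hypergraph: metabolites (and, in
functional-domain networks, enzyme-bound intermediates and free binding
domains) are nodes, reactions are hyperedges with signed rational
stoichiometric coefficients.  Internal metabolites are mass-balanced at steady
state; external metabolites are sources/sinks exempt from balancing.

Catalytic domains are *annotations* on reactions (``Reaction.catalysts``) and
never enter the stoichiometry; binding domains, by contrast, are genuine
species that participate in complex-formation steps.  This mirrors the usual
diagram convention in which catalytic activities decorate an arrow while
binding activities are nodes connecting arrows.

Declaration order is significant everywhere: the stoichiometric matrix and
all mode listings follow it, and nothing is ever sorted silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence, Union

Coeff = Union[int, str, Fraction]


class NetworkError(ValueError):
    """Raised when a network definition is inconsistent."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species, enzyme-bound moiety, or free binding domain.

    ``external=True`` exempts the species from the steady-state balance.
    ``domains`` optionally names the functional domains bound within this
    species (e.g. an enzyme--cofactor complex), used to resolve which
    reactions a binding domain touches.
    """

    id: str
    name: str = ""
    external: bool = False
    domains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A reaction: signed stoichiometry map plus reversibility flag.

    Negative coefficients are consumed species, positive are produced.
    ``catalysts`` lists the labels of catalytic domains annotating the
    reaction; they have no stoichiometric effect.
    """

    id: str
    stoich: Mapping[str, Fraction]
    reversible: bool = False
    catalysts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("reaction id must be non-empty")
        clean: dict[str, Fraction] = {}
        for met, c in dict(self.stoich).items():
            c = Fraction(c)
            if c == 0:
                raise NetworkError(
                    f"reaction {self.id!r}: zero coefficient for {met!r}"
                )
            clean[met] = c
        if not clean:
            raise NetworkError(f"reaction {self.id!r} has empty stoichiometry")
        object.__setattr__(self, "stoich", clean)
        object.__setattr__(self, "catalysts", tuple(self.catalysts))


@dataclass(frozen=True)
class Network:
    """A validated collection of metabolites and reactions.

    ``domains`` optionally carries the functional-domain vocabulary of a
    domain-level network (annotation objects with a ``label`` attribute);
    plain networks leave it empty.
    """

    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    name: str = ""
    domains: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "domains", tuple(self.domains))
        seen: set[str] = set()
        for m in self.metabolites:
            if m.id in seen:
                raise NetworkError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
        rseen: set[str] = set()
        for r in self.reactions:
            if r.id in rseen:
                raise NetworkError(f"duplicate reaction id {r.id!r}")
            if r.id in seen:
                raise NetworkError(f"id {r.id!r} used for both a metabolite and a reaction")
            rseen.add(r.id)
        declared = {m.id for m in self.metabolites}
        used: set[str] = set()
        for r in self.reactions:
            for met in r.stoich:
                if met not in declared:
                    raise NetworkError(
                        f"reaction {r.id!r} references undeclared metabolite {met!r}"
                    )
                used.add(met)
        for m in self.metabolites:
            if not m.external and m.id not in used:
                raise NetworkError(
                    f"internal metabolite {m.id!r} participates in no reaction"
                )

    # -- convenience lookups -------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.external]

    @property
    def external_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.external]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def reaction_index(self, rid: str) -> int:
        for i, r in enumerate(self.reactions):
            if r.id == rid:
                return i
        raise KeyError(rid)


@dataclass(frozen=True)
class StoichMatrix:
    """Exact stoichiometric matrix over the internal metabolites.

    ``entries[i][j]`` is the coefficient of internal metabolite ``rows[i]``
    in reaction ``cols[j]``; external metabolites contribute no row.
    """

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    entries: tuple[tuple[Fraction, ...], ...]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.rows), len(self.cols))

    def as_lists(self) -> list[list[Fraction]]:
        return [list(row) for row in self.entries]


def build_network(
    metabolites: Iterable[Metabolite],
    reactions: Iterable[Reaction],
    name: str = "",
    domains: Sequence = (),
) -> Network:
    """Validate and assemble a :class:`Network`, preserving declaration order."""
    return Network(tuple(metabolites), tuple(reactions), name=name, domains=tuple(domains))


def stoichiometric_matrix(net: Network) -> StoichMatrix:
    """Exact rational stoichiometric matrix of the internal metabolites."""
    rows = tuple(net.internal_ids)
    cols = tuple(net.reaction_ids)
    row_index = {m: i for i, m in enumerate(rows)}
    entries = [[Fraction(0)] * len(cols) for _ in rows]
    for j, r in enumerate(net.reactions):
        for met, c in r.stoich.items():
            i = row_index.get(met)
            if i is not None:
                entries[i][j] = c
    return StoichMatrix(rows, cols, tuple(tuple(row) for row in entries))


def overall_reaction(mode, net: Network) -> dict[str, Fraction]:
    """Net external stoichiometry of a flux vector: one traversal of the mode.

    ``mode`` is a mapping reaction-id -> rational flux (a
    :class:`~domainflux.efm.FluxMode` works too, via its ``coeffs``).
    Zero net coefficients are omitted.  Unknown reaction ids raise
    :class:`NetworkError`.
    """
    coeffs = getattr(mode, "coeffs", mode)
    known = set(net.reaction_ids)
    for rid in coeffs:
        if rid not in known:
            raise NetworkError(f"flux vector references unknown reaction {rid!r}")
    external = set(net.external_ids)
    net_stoich: dict[str, Fraction] = {}
    for r in net.reactions:
        v = Fraction(coeffs.get(r.id, 0))
        if v == 0:
            continue
        for met, c in r.stoich.items():
            if met in external:
                net_stoich[met] = net_stoich.get(met, Fraction(0)) + v * c
    return {m: c for m, c in net_stoich.items() if c != 0}


def remove_reactions(net: Network, rids: Iterable[str]) -> Network:
    """Knockout helper: a copy of ``net`` without the given reactions.

    Metabolites no longer referenced by any remaining reaction are dropped
    (an unreferenced internal species imposes no constraint, so this is
    semantically neutral for flux analysis).
    """
    gone = set(rids)
    unknown = gone - set(net.reaction_ids)
    if unknown:
        raise NetworkError(f"cannot remove unknown reactions {sorted(unknown)!r}")
    kept = [r for r in net.reactions if r.id not in gone]
    used = {met for r in kept for met in r.stoich}
    mets = [m for m in net.metabolites if m.id in used]
    return Network(tuple(mets), tuple(kept), name=net.name, domains=net.domains)
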