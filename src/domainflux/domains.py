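"""Functional-domain networks and domain-inhibition analysis.

An enzyme's overall activity is decomposed into elementary steps carried by
its functional domains (identified by SCOP fold).  Domains play three roles:

* ``catalytic`` domains annotate the steps they catalyse (no stoichiometry);
* ``binding`` domains are genuine species that enter ligand complexes
  (e.g. an ATP-grasp domain binding ADP before the transfer step);
* ``regulatory`` domains carry no reaction at all and stay annotation-only.

A :class:`DomainNetworkSpec` is a *curated* description — transcribing which
steps realise each enzyme and which intermediates (hydroxyethyl-TPP,
acyl-dihydrolipoamide, ...) connect them — from which
:func:`build_domain_network` assembles an ordinary :class:`~domainflux.netcore.Network`
amenable to elementary-flux-mode analysis.

The pay-off of the finer resolution is inhibition analysis at the domain
level: blocking one domain's activity removes every reaction that domain
touches, and :func:`inhibit` reports which modes survive and which external
products the network can no longer make.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence, Union

from .efm import EFMSet, FluxMode
from .netcore import Metabolite, Network, NetworkError, Reaction, remove_reactions

__all__ = [
    "DomainAnnotation",
    "DomainNetworkSpec",
    "InhibitionReport",
    "RepresentationMatch",
    "DomainError",
    "build_domain_network",
    "reactions_of_domain",
    "inhibit",
    "producing_modes",
    "compare_representations",
]

ROLES = ("catalytic", "binding", "regulatory")


class DomainError(ValueError):
    """Raised for inconsistent domain specifications or unknown labels."""


@dataclass(frozen=True)
class DomainAnnotation:
    """One functional domain of an enzyme.

    ``scop_fold`` is the SCOP fold identifier (e.g. ``c.4.1`` for the
    NAD/FAD-binding Rossmann-like fold); ``role`` is one of
    ``catalytic | binding | regulatory``.
    """

    label: str
    gene: str = ""
    scop_fold: str = ""
    function: str = ""
    role: str = "catalytic"

    def __post_init__(self) -> None:
        if not self.label:
            raise DomainError("domain label must be non-empty")
        if self.role not in ROLES:
            raise DomainError(
                f"domain {self.label!r}: role must be one of {ROLES}, got {self.role!r}"
            )


@dataclass(frozen=True)
class DomainNetworkSpec:
    """Curated decomposition of enzymes into domain-level elementary steps.

    ``species`` includes ordinary metabolites, enzyme-bound intermediates and
    free binding domains (a complex species declares the domains it contains
    via ``Metabolite.domains``).  ``steps`` are the elementary reactions,
    their ``catalysts`` referencing catalytic-domain labels.  ``enzyme_map``
    records which steps realise each enzyme-level reaction.
    """

    name: str
    domains: tuple[DomainAnnotation, ...]
    species: tuple[Metabolite, ...]
    steps: tuple[Reaction, ...]
    enzyme_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "steps", tuple(self.steps))
        object.__setattr__(
            self, "enzyme_map", {k: tuple(v) for k, v in dict(self.enzyme_map).items()}
        )
        labels = [d.label for d in self.domains]
        if len(labels) != len(set(labels)):
            raise DomainError(f"duplicate domain labels in spec {self.name!r}")
        declared = set(labels)
        step_ids: set[str] = set()
        for s in self.steps:
            if s.id in step_ids:
                raise DomainError(f"duplicate step id {s.id!r}")
            step_ids.add(s.id)
            for cat in s.catalysts:
                if cat not in declared:
                    raise DomainError(
                        f"step {s.id!r} cites undeclared domain {cat!r}"
                    )
        for sp in self.species:
            for d in sp.domains:
                if d not in declared:
                    raise DomainError(
                        f"species {sp.id!r} contains undeclared domain {d!r}"
                    )
        for enz, steps in self.enzyme_map.items():
            if not steps:
                raise DomainError(f"enzyme {enz!r} maps to no step")
            for sid in steps:
                if sid not in step_ids:
                    raise DomainError(f"enzyme {enz!r} maps to unknown step {sid!r}")

    def domain(self, label: str) -> DomainAnnotation:
        for d in self.domains:
            if d.label == label:
                return d
        raise DomainError(f"unknown domain label {label!r}")


def build_domain_network(spec: DomainNetworkSpec) -> Network:
    """Assemble the functional-domain :class:`Network` from a curated spec."""
    return Network(spec.species, spec.steps, name=spec.name, domains=spec.domains)


def _known_labels(net: Network) -> set[str]:
    labels = {d.label for d in net.domains}
    for r in net.reactions:
        labels.update(r.catalysts)
    for m in net.metabolites:
        labels.update(m.domains)
    return labels


def reactions_of_domain(net: Network, label: str) -> set[str]:
    """All reactions a domain touches.

    A catalytic domain appears in reaction ``catalysts``; a binding domain
    appears in the stoichiometry, either as the free-domain species itself or
    inside a complex that declares it.  A regulatory domain typically touches
    nothing and yields the empty set.
    """
    if label not in _known_labels(net):
        raise DomainError(f"unknown domain label {label!r}")
    hits: set[str] = set()
    bearing = {m.id for m in net.metabolites if m.id == label or label in m.domains}
    for r in net.reactions:
        if label in r.catalysts or bearing & set(r.stoich):
            hits.add(r.id)
    return hits


@dataclass(frozen=True)
class InhibitionReport:
    """Partition of an EFM set under a knockout, with lost capabilities.

    ``lost_capabilities`` lists the external metabolites that some removed
    mode produced but no surviving mode can produce.
    """

    target: str
    target_reactions: tuple[str, ...]
    removed_modes: tuple[FluxMode, ...]
    surviving_modes: tuple[FluxMode, ...]
    lost_capabilities: tuple[str, ...]

    def to_json_dict(self) -> dict:
        return {
            "target": self.target,
            "target_reactions": list(self.target_reactions),
            "n_removed": len(self.removed_modes),
            "n_surviving": len(self.surviving_modes),
            "removed_modes": [m.describe() for m in self.removed_modes],
            "surviving_modes": [m.describe() for m in self.surviving_modes],
            "lost_capabilities": list(self.lost_capabilities),
        }

    def summary(self) -> str:
        lines = [
            f"target: {self.target} -> reactions {{{', '.join(self.target_reactions)}}}",
            f"removed {len(self.removed_modes)} of "
            f"{len(self.removed_modes) + len(self.surviving_modes)} modes",
        ]
        for m in self.removed_modes:
            lines.append(f"  - {m.describe()}")
        lines.append(f"surviving {len(self.surviving_modes)} modes")
        for m in self.surviving_modes:
            lines.append(f"  + {m.describe()}")
        if self.lost_capabilities:
            lines.append("lost production capabilities: " + ", ".join(self.lost_capabilities))
        else:
            lines.append("no production capability lost")
        return "\n".join(lines)


def inhibit(
    net: Network, efms: EFMSet, targets: Union[str, Iterable[str]]
) -> InhibitionReport:
    """Partition ``efms`` by a domain or reaction knockout.

    ``targets`` is a domain label, a reaction id, or an iterable of reaction
    ids.  A mode is removed iff its support intersects the resolved reaction
    set.  Filtering the mode list this way agrees with re-enumerating the
    reduced network (knockouts cannot create new modes).
    """
    known_reactions = set(net.reaction_ids)
    if isinstance(targets, str):
        label = targets
        if targets in known_reactions:
            resolved = {targets}
        else:
            resolved = reactions_of_domain(net, targets)
    else:
        label = "+".join(targets)
        resolved = set(targets)
        unknown = resolved - known_reactions
        if unknown:
            raise DomainError(f"unknown target reactions {sorted(unknown)!r}")
    if not resolved:
        raise DomainError(f"target {label!r} resolves to no reaction")

    removed = tuple(m for m in efms if m.support_ids & resolved)
    surviving = tuple(m for m in efms if not (m.support_ids & resolved))
    produced_before = {s for m in removed for s, c in m.overall.items() if c > 0}
    produced_after = {s for m in surviving for s, c in m.overall.items() if c > 0}
    lost = tuple(sorted(produced_before - produced_after))
    return InhibitionReport(
        target=label,
        target_reactions=tuple(sorted(resolved)),
        removed_modes=removed,
        surviving_modes=surviving,
        lost_capabilities=lost,
    )


def knockout_network(net: Network, targets: Union[str, Iterable[str]]) -> Network:
    """The reduced network with the resolved target reactions deleted."""
    if isinstance(targets, str):
        resolved = {targets} if targets in set(net.reaction_ids) else reactions_of_domain(net, targets)
    else:
        resolved = set(targets)
    return remove_reactions(net, resolved)


def producing_modes(
    efms: EFMSet,
    metabolite: str,
    direction: str = "produce",
    net: Network | None = None,
) -> list[FluxMode]:
    """Modes whose overall reaction strictly produces (or consumes) a species.

    When the parent ``net`` is given, the metabolite must be one of its
    external species (internal species have no net overall stoichiometry).
    """
    if direction not in ("produce", "consume"):
        raise ValueError(f"direction must be 'produce' or 'consume', got {direction!r}")
    if net is not None:
        try:
            m = net.metabolite(metabolite)
        except KeyError:
            raise DomainError(f"unknown metabolite {metabolite!r}") from None
        if not m.external:
            raise DomainError(
                f"{metabolite!r} is internal: it has no net overall stoichiometry"
            )
    sign = 1 if direction == "produce" else -1
    return [m for m in efms if sign * m.overall.get(metabolite, 0) > 0]


@dataclass(frozen=True)
class RepresentationMatch:
    """Overall-reaction matching between two EFM sets.

    ``pairs`` maps each matched mode of the first set to the modes of the
    second set with the same (alias-normalised) overall reaction.
    """

    pairs: tuple[tuple[FluxMode, tuple[FluxMode, ...]], ...]
    unmatched_left: tuple[FluxMode, ...]
    unmatched_right: tuple[FluxMode, ...]

    @property
    def is_bijection(self) -> bool:
        return (
            not self.unmatched_left
            and not self.unmatched_right
            and all(len(ms) == 1 for _, ms in self.pairs)
        )

    def as_table(self) -> str:
        lines = []
        for left, rights in self.pairs:
            for r in rights:
                lines.append(f"{left.describe()}\t~\t{r.describe()}")
        for m in self.unmatched_left:
            lines.append(f"{m.describe()}\t~\t(unmatched)")
        for m in self.unmatched_right:
            lines.append(f"(unmatched)\t~\t{m.describe()}")
        return "\n".join(lines)


def _normalised_overall(
    mode: FluxMode, aliases: Mapping[str, str]
) -> tuple[tuple[str, Fraction], ...]:
    merged: dict[str, Fraction] = {}
    for s, c in mode.overall.items():
        key = aliases.get(s, s)
        merged[key] = merged.get(key, Fraction(0)) + c
    return tuple(sorted((s, c) for s, c in merged.items() if c != 0))


def compare_representations(
    left: EFMSet, right: EFMSet, aliases: Mapping[str, str] | None = None
) -> RepresentationMatch:
    """Match modes of two network representations by equal overall reactions.

    ``aliases`` renames external species before comparison (e.g. a lumped
    classical species versus its domain-level counterpart).  Unmatched modes
    on either side are reported, never raised.  Swapping the arguments
    inverts the mapping.
    """
    aliases = dict(aliases or {})
    right_by_overall: dict[tuple, list[FluxMode]] = {}
    for m in right:
        right_by_overall.setdefault(_normalised_overall(m, aliases), []).append(m)
    pairs: list[tuple[FluxMode, tuple[FluxMode, ...]]] = []
    unmatched_left: list[FluxMode] = []
    matched_right: set[int] = set()
    for m in left:
        key = _normalised_overall(m, aliases)
        found = right_by_overall.get(key, [])
        if found:
            pairs.append((m, tuple(found)))
            matched_right.update(id(x) for x in found)
        else:
            unmatched_left.append(m)
    unmatched_right = [m for m in right if id(m) not in matched_right]
    return RepresentationMatch(tuple(pairs), tuple(unmatched_left), tuple(unmatched_right))
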