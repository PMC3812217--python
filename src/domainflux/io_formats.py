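"""Network file formats: metatool ``.dat``, a native YAML schema, SBML import.

The metatool dialect is the plain-text format of the classical EFM software:
five sections introduced by header lines

.. code-block:: text

    -ENZREV      reversible reaction ids
    -ENZIRREV    irreversible reaction ids
    -METINT      internal metabolite ids
    -METEXT      external metabolite ids
    -CAT         equations, one per line:  id : 2 A + B = C .

Stoichiometric multipliers precede species; the trailing ``.`` is optional;
blank lines and ``#`` comments are ignored; section structure is strict and
parse errors carry line numbers.

The native YAML schema is the package's own editable network definition; it
round-trips everything the data model holds, including domain annotations
(which metatool cannot express).  SBML import (Level 2/3 core, read-only)
maps ``boundaryCondition=true`` or membership of a compartment named
``external`` to the external flag; documents using rules or events are
rejected with an explicit list of the unsupported constructs.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as _ET
from fractions import Fraction
from typing import Union

import yaml

from .domains import DomainAnnotation, DomainNetworkSpec, build_domain_network
from .netcore import Metabolite, Network, NetworkError, Reaction

__all__ = [
    "MetatoolError",
    "SBMLImportError",
    "read_metatool",
    "write_metatool",
    "read_sbml",
    "read_yaml",
    "write_yaml",
]

_SECTIONS = ("-ENZREV", "-ENZIRREV", "-METINT", "-METEXT", "-CAT")


class MetatoolError(ValueError):
    """Metatool parse error; the message carries the offending line number."""


class SBMLImportError(ValueError):
    """SBML document uses constructs this importer does not support."""


# ---------------------------------------------------------------------------
# metatool


def _parse_side(side: str, rid: str, lineno: int) -> dict[str, Fraction]:
    stoich: dict[str, Fraction] = {}
    side = side.strip()
    if not side:
        return stoich
    for term in side.split("+"):
        tokens = term.split()
        if not tokens:
            raise MetatoolError(f"line {lineno}: empty term in equation for {rid!r}")
        if len(tokens) == 1:
            coeff, met = Fraction(1), tokens[0]
        elif len(tokens) == 2:
            try:
                coeff = Fraction(tokens[0])
            except ValueError:
                raise MetatoolError(
                    f"line {lineno}: bad coefficient {tokens[0]!r} for {rid!r}"
                ) from None
            met = tokens[1]
        else:
            raise MetatoolError(
                f"line {lineno}: cannot parse term {term.strip()!r} for {rid!r}"
            )
        stoich[met] = stoich.get(met, Fraction(0)) + coeff
    return stoich


def read_metatool(text: str) -> Network:
    """Parse metatool ``.dat`` text into a :class:`Network`.

    Reversibility comes from ENZREV/ENZIRREV membership, externality from
    METEXT; declaration order (METINT, then METEXT; CAT equation order) is
    preserved.
    """
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.upper() in _SECTIONS:
            current = line.upper()
            if current in sections:
                raise MetatoolError(f"line {lineno}: duplicate section {current}")
            sections[current] = []
            continue
        if line.startswith("-") and line.split()[0].upper() not in _SECTIONS:
            raise MetatoolError(f"line {lineno}: unknown section header {line!r}")
        if current is None:
            raise MetatoolError(f"line {lineno}: content before any section header")
        sections[current].append((lineno, line))
    missing = [s for s in _SECTIONS if s not in sections]
    if missing:
        raise MetatoolError(f"missing section header(s): {', '.join(missing)}")

    def tokens(section: str) -> list[tuple[int, str]]:
        out: list[tuple[int, str]] = []
        for lineno, line in sections[section]:
            out.extend((lineno, tok) for tok in line.split())
        return out

    enzrev = tokens("-ENZREV")
    enzirrev = tokens("-ENZIRREV")
    metint = tokens("-METINT")
    metext = tokens("-METEXT")

    rev_ids = [t for _, t in enzrev]
    irrev_ids = [t for _, t in enzirrev]
    overlap = set(rev_ids) & set(irrev_ids)
    if overlap:
        lineno = next(l for l, t in enzirrev if t in overlap)
        raise MetatoolError(
            f"line {lineno}: reaction(s) {sorted(overlap)} in both -ENZREV and -ENZIRREV"
        )
    both = {t for _, t in metint} & {t for _, t in metext}
    if both:
        lineno = next(l for l, t in metext if t in both)
        raise MetatoolError(
            f"line {lineno}: metabolite(s) {sorted(both)} in both -METINT and -METEXT"
        )

    declared = set(rev_ids) | set(irrev_ids)
    reactions: list[Reaction] = []
    seen: set[str] = set()
    for lineno, line in sections["-CAT"]:
        line = line.rstrip()
        if line.endswith("."):
            line = line[:-1].rstrip()
        m = re.match(r"^(\S+)\s*:\s*(.*?)\s*=\s*(.*)$", line)
        if not m:
            raise MetatoolError(f"line {lineno}: cannot parse CAT equation {line!r}")
        rid, lhs, rhs = m.group(1), m.group(2), m.group(3)
        if rid not in declared:
            raise MetatoolError(
                f"line {lineno}: reaction {rid!r} in -CAT is absent from -ENZREV/-ENZIRREV"
            )
        if rid in seen:
            raise MetatoolError(f"line {lineno}: duplicate CAT equation for {rid!r}")
        seen.add(rid)
        stoich: dict[str, Fraction] = {}
        for met, c in _parse_side(lhs, rid, lineno).items():
            stoich[met] = stoich.get(met, Fraction(0)) - c
        for met, c in _parse_side(rhs, rid, lineno).items():
            stoich[met] = stoich.get(met, Fraction(0)) + c
        stoich = {k: v for k, v in stoich.items() if v != 0}
        if not stoich:
            raise MetatoolError(f"line {lineno}: equation for {rid!r} cancels to nothing")
        reactions.append(Reaction(rid, stoich, reversible=rid in set(rev_ids)))
    undeclared = declared - seen
    if undeclared:
        raise MetatoolError(
            f"reaction(s) {sorted(undeclared)} declared but have no -CAT equation"
        )

    metabolites = [Metabolite(t) for _, t in metint]
    metabolites += [Metabolite(t, external=True) for _, t in metext]
    try:
        return Network(tuple(metabolites), tuple(reactions))
    except NetworkError as exc:
        raise MetatoolError(str(exc)) from exc


def _fmt_coeff(c: Fraction) -> str:
    c = abs(c)
    return "" if c == 1 else f"{c} "


def write_metatool(net: Network) -> str:
    """Serialise a network to metatool ``.dat`` text (canonical section order)."""
    rev = [r.id for r in net.reactions if r.reversible]
    irrev = [r.id for r in net.reactions if not r.reversible]
    lines = ["-ENZREV", " ".join(rev), "", "-ENZIRREV", " ".join(irrev), ""]
    lines += ["-METINT", " ".join(net.internal_ids), ""]
    lines += ["-METEXT", " ".join(net.external_ids), ""]
    lines.append("-CAT")
    for r in net.reactions:
        lhs = " + ".join(
            f"{_fmt_coeff(c)}{m}" for m, c in r.stoich.items() if c < 0
        )
        rhs = " + ".join(
            f"{_fmt_coeff(c)}{m}" for m, c in r.stoich.items() if c > 0
        )
        lines.append(f"{r.id} : {lhs} = {rhs} .")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SBML import (read-only, optional)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_sbml(text: Union[str, bytes]) -> Network:
    """Import an SBML Level 2/3 core document as a :class:`Network`.

    External status: ``boundaryCondition="true"`` or compartment id/name
    ``external``.  Reversibility from the reaction attribute (SBML Level 2
    defaults to reversible).  Rules, events and other unsupported constructs
    raise :class:`SBMLImportError` listing them.
    """
    root = _ET.fromstring(text)
    model = next((el for el in root.iter() if _local(el.tag) == "model"), None)
    if model is None:
        raise SBMLImportError("document has no <model> element")

    unsupported = sorted(
        {
            _local(el.tag)
            for el in model.iter()
            if _local(el.tag)
            in ("algebraicRule", "assignmentRule", "rateRule", "event", "constraint")
        }
    )
    if unsupported:
        raise SBMLImportError(f"unsupported SBML construct(s): {', '.join(unsupported)}")

    external_compartments = set()
    for el in model.iter():
        if _local(el.tag) == "compartment":
            if "external" in (el.get("id", "").lower(), el.get("name", "").lower()):
                external_compartments.add(el.get("id"))

    metabolites: list[Metabolite] = []
    for el in model.iter():
        if _local(el.tag) != "species":
            continue
        boundary = el.get("boundaryCondition", "false").lower() == "true"
        external = boundary or el.get("compartment") in external_compartments
        metabolites.append(
            Metabolite(el.get("id"), name=el.get("name", ""), external=external)
        )

    reactions: list[Reaction] = []
    for el in model.iter():
        if _local(el.tag) != "reaction":
            continue
        reversible = el.get("reversible", "true").lower() == "true"
        stoich: dict[str, Fraction] = {}
        for child in el:
            role = _local(child.tag)
            if role not in ("listOfReactants", "listOfProducts"):
                continue
            sign = -1 if role == "listOfReactants" else 1
            for ref in child:
                if _local(ref.tag) != "speciesReference":
                    continue
                sid = ref.get("species")
                c = Fraction(ref.get("stoichiometry", "1"))
                stoich[sid] = stoich.get(sid, Fraction(0)) + sign * c
        stoich = {k: v for k, v in stoich.items() if v != 0}
        reactions.append(Reaction(el.get("id"), stoich, reversible=reversible))
    return Network(tuple(metabolites), tuple(reactions), name=model.get("id", ""))


# ---------------------------------------------------------------------------
# native YAML schema


def _met_from_dict(d: dict) -> Metabolite:
    return Metabolite(
        id=d["id"],
        name=d.get("name", ""),
        external=bool(d.get("external", False)),
        domains=tuple(d.get("contains", ())),
    )


def _rxn_from_dict(d: dict) -> Reaction:
    return Reaction(
        id=d["id"],
        stoich={m: Fraction(c) for m, c in d["stoich"].items()},
        reversible=bool(d.get("reversible", False)),
        catalysts=tuple(d.get("catalysts", ())),
    )


def read_yaml(text: str) -> Union[Network, DomainNetworkSpec]:
    """Load a native network definition.

    ``kind: network`` documents yield a :class:`Network`; ``kind:
    domain_network`` documents yield a :class:`DomainNetworkSpec` (build the
    network with :func:`~domainflux.domains.build_domain_network`).
    """
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "kind" not in doc:
        raise NetworkError("native network document must be a mapping with a 'kind' key")
    kind = doc["kind"]
    name = doc.get("name", "")
    if kind == "network":
        mets = tuple(_met_from_dict(d) for d in doc.get("metabolites", ()))
        rxns = tuple(_rxn_from_dict(d) for d in doc.get("reactions", ()))
        return Network(mets, rxns, name=name)
    if kind == "domain_network":
        domains = tuple(
            DomainAnnotation(
                label=d["label"],
                gene=d.get("gene", ""),
                scop_fold=d.get("scop_fold", ""),
                function=d.get("function", ""),
                role=d.get("role", "catalytic"),
            )
            for d in doc.get("domains", ())
        )
        species = tuple(_met_from_dict(d) for d in doc.get("species", ()))
        steps = tuple(_rxn_from_dict(d) for d in doc.get("steps", ()))
        return DomainNetworkSpec(
            name=name,
            domains=domains,
            species=species,
            steps=steps,
            enzyme_map=doc.get("enzyme_map", {}),
            notes=doc.get("notes", ""),
        )
    raise NetworkError(f"unknown document kind {kind!r}")


def _met_to_dict(m: Metabolite) -> dict:
    d: dict = {"id": m.id}
    if m.name:
        d["name"] = m.name
    if m.external:
        d["external"] = True
    if m.domains:
        d["contains"] = list(m.domains)
    return d


def _rxn_to_dict(r: Reaction) -> dict:
    d: dict = {"id": r.id, "stoich": {m: int(c) if c.denominator == 1 else str(c)
                                      for m, c in r.stoich.items()}}
    if r.reversible:
        d["reversible"] = True
    if r.catalysts:
        d["catalysts"] = list(r.catalysts)
    return d


def write_yaml(obj: Union[Network, DomainNetworkSpec]) -> str:
    """Serialise a network or domain spec to the native YAML schema."""
    if isinstance(obj, Network):
        doc = {
            "kind": "network",
            "name": obj.name,
            "metabolites": [_met_to_dict(m) for m in obj.metabolites],
            "reactions": [_rxn_to_dict(r) for r in obj.reactions],
        }
    elif isinstance(obj, DomainNetworkSpec):
        doc = {
            "kind": "domain_network",
            "name": obj.name,
            "domains": [
                {
                    "label": d.label,
                    "gene": d.gene,
                    "scop_fold": d.scop_fold,
                    "function": d.function,
                    "role": d.role,
                }
                for d in obj.domains
            ],
            "species": [_met_to_dict(m) for m in obj.species],
            "steps": [_rxn_to_dict(r) for r in obj.steps],
            "enzyme_map": {k: list(v) for k, v in obj.enzyme_map.items()},
            "notes": obj.notes,
        }
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__}")
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=False)
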