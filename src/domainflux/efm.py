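"""Elementary flux mode enumeration over exact rational arithmetic.

An elementary flux mode (EFM) of a network with stoichiometric matrix S
(rows = internal metabolites, columns = reactions) is a flux vector v with

* ``S v = 0``            (steady state),
* ``v_r >= 0``           for every irreversible reaction r,
* minimal support: no other vector satisfying the two conditions above has a
  support strictly contained in supp(v).

Equivalently, v is feasible and the nullspace of S restricted to the columns
of supp(v) is one-dimensional.  EFMs are the elementary generators of the
flux cone ``{v : S v = 0, v_irr >= 0}``.

The enumerator follows the classical nullspace-seeded double-description
lineage: reversible reactions are split into forward/backward columns, the
tableau is seeded with a reduced-echelon nullspace basis of the split matrix
(whose free-column identity block makes every seed ray extreme from the
start), and the remaining non-negativity constraints are enforced one by one,
combining adjacent rays of opposite sign.  The futile forward+backward
two-cycles created by splitting are discarded when mapping back, and a mode
whose support is entirely reversible is reported in one orientation only.

Everything is exact (:class:`fractions.Fraction`); no tolerances exist.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from ._exact import integerize, nullspace_basis, nullspace_with_free, rank
from .netcore import (
    Metabolite,
    Network,
    NetworkError,
    Reaction,
    overall_reaction,
    stoichiometric_matrix,
)

__all__ = [
    "FluxMode",
    "EFMSet",
    "enumerate_efms",
    "brute_force_efms",
    "is_elementary",
    "canonicalize",
    "split_reversible",
]


@dataclass(frozen=True)
class FluxMode:
    """An elementary mode: canonical coprime-integer flux vector.

    ``support`` lists ``(reaction_id, sign)`` pairs in network declaration
    order; ``overall`` is the net external stoichiometry of one traversal.
    """

    coeffs: Mapping[str, Fraction]
    support: tuple[tuple[str, int], ...]
    overall: Mapping[str, Fraction]

    @property
    def support_ids(self) -> frozenset[str]:
        return frozenset(rid for rid, _ in self.support)

    @property
    def signed_support(self) -> frozenset[tuple[str, int]]:
        return frozenset(self.support)

    def coefficient(self, rid: str) -> Fraction:
        return Fraction(self.coeffs.get(rid, 0))

    def format_entry(self, rid: str) -> str:
        c = self.coefficient(rid)
        if c == 1:
            return rid
        if c == -1:
            return f"-{rid}"
        return f"({c} {rid})"

    def describe(self) -> str:
        return " ".join(self.format_entry(rid) for rid, _ in self.support)


@dataclass(frozen=True)
class EFMSet:
    """Ordered, deduplicated collection of elementary flux modes."""

    modes: tuple[FluxMode, ...]
    network: str = ""

    def __len__(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def __getitem__(self, i: int) -> FluxMode:
        return self.modes[i]

    @property
    def signed_supports(self) -> set[frozenset[tuple[str, int]]]:
        return {m.signed_support for m in self.modes}

    def find_by_support(self, signed_support: Iterable[tuple[str, int]]):
        want = frozenset(signed_support)
        for m in self.modes:
            if m.signed_support == want:
                return m
        return None

    def as_table(self) -> str:
        """Plain-text listing, one numbered line per mode."""
        return "\n".join(
            f"EFM {i + 1}\t{m.describe()}" for i, m in enumerate(self.modes)
        )

    def to_json_dict(self) -> dict:
        return {
            "network": self.network,
            "n_modes": len(self.modes),
            "modes": [
                {
                    "index": i + 1,
                    "coefficients": {r: str(c) for r, c in m.coeffs.items()},
                    "support": [[rid, sign] for rid, sign in m.support],
                    "overall_reaction": {s: str(c) for s, c in m.overall.items()},
                }
                for i, m in enumerate(self.modes)
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_json_dict(), indent=indent)


# ---------------------------------------------------------------------------
# canonical form


def canonicalize(v: Mapping[str, Fraction], net: Network) -> dict[str, Fraction]:
    """Scale a flux vector to coprime integers with a fixed orientation.

    If every support reaction is reversible the orientation is chosen so that
    the first support entry (network declaration order) is positive;
    otherwise the vector's own orientation is kept (feasibility is the
    business of :func:`is_elementary`, not of the canonical form).
    """
    order = net.reaction_ids
    known = set(order)
    for rid in v:
        if rid not in known:
            raise NetworkError(f"flux vector references unknown reaction {rid!r}")
    vec = [Fraction(v.get(rid, 0)) for rid in order]
    if all(x == 0 for x in vec):
        raise ValueError("cannot canonicalize the zero vector")
    vec = integerize(vec)
    support = [i for i, x in enumerate(vec) if x != 0]
    if all(net.reactions[i].reversible for i in support):
        if vec[support[0]] < 0:
            vec = [-x for x in vec]
    return {order[i]: vec[i] for i in support}


def _make_mode(v: Mapping[str, Fraction], net: Network) -> FluxMode:
    coeffs = canonicalize(v, net)
    support = tuple(
        (rid, 1 if coeffs[rid] > 0 else -1) for rid in net.reaction_ids if rid in coeffs
    )
    return FluxMode(coeffs=coeffs, support=support, overall=overall_reaction(coeffs, net))


def _sort_key(mode: FluxMode, net: Network):
    idx = {rid: i for i, rid in enumerate(net.reaction_ids)}
    return (
        len(mode.support),
        tuple((idx[rid], -sign) for rid, sign in mode.support),
    )


def _finish(vectors: Iterable[Mapping[str, Fraction]], net: Network) -> EFMSet:
    seen: set[tuple] = set()
    modes: list[FluxMode] = []
    for v in vectors:
        m = _make_mode(v, net)
        key = tuple(sorted((r, c) for r, c in m.coeffs.items()))
        if key not in seen:
            seen.add(key)
            modes.append(m)
    modes.sort(key=lambda m: _sort_key(m, net))
    return EFMSet(tuple(modes), network=net.name)


# ---------------------------------------------------------------------------
# reversible-reaction splitting


def split_reversible(net: Network, suffixes: tuple[str, str] = ("__f", "__b")) -> Network:
    """Rewrite every reversible reaction as an irreversible forward/backward pair."""
    fs, bs = suffixes
    reactions: list[Reaction] = []
    for r in net.reactions:
        if not r.reversible:
            reactions.append(r)
            continue
        reactions.append(Reaction(r.id + fs, dict(r.stoich), False, r.catalysts))
        reactions.append(
            Reaction(r.id + bs, {m: -c for m, c in r.stoich.items()}, False, r.catalysts)
        )
    return Network(net.metabolites, tuple(reactions), name=net.name, domains=net.domains)


# ---------------------------------------------------------------------------
# double description on the split (pointed) cone


def _extreme_rays_nonneg(S: list[list[Fraction]], n: int) -> list[list[Fraction]]:
    """Extreme rays of ``{w >= 0 : S w = 0}`` (w of length ``n``).

    Double description seeded with the reduced-echelon nullspace basis: the
    identity block on the free columns makes the seed rays extreme for the
    cone restricted to those coordinates, after which the pivot-column
    constraints are enforced one at a time with the combinatorial adjacency
    test of Fukuda & Prodon.
    """
    if n == 0:
        return []
    basis, free = nullspace_with_free(S, n)
    if not basis:
        return []
    # The identity block on the free columns makes each seed ray the unique
    # (hence extreme) ray of its own face of the cone restricted to those
    # coordinates, and every seed is non-negative on all free coordinates.
    processed = sorted(free)
    remaining = [j for j in range(n) if j not in set(processed)]
    rays: list[list[Fraction]] = [list(b) for b in basis]

    for j in remaining:
        pos = [r for r in rays if r[j] > 0]
        zero = [r for r in rays if r[j] == 0]
        neg = [r for r in rays if r[j] < 0]
        if not neg:
            rays = pos + zero
            processed.append(j)
            continue
        masks = {id(r): _zero_mask(r, processed) for r in rays}
        new_rays = pos + zero
        for p in pos:
            for q in neg:
                meet = masks[id(p)] & masks[id(q)]
                adjacent = True
                for other in rays:
                    if other is p or other is q:
                        continue
                    if masks[id(other)] & meet == meet:
                        adjacent = False
                        break
                if adjacent:
                    t = [p[j] * qq - q[j] * pp for pp, qq in zip(p, q)]
                    new_rays.append(integerize(t))
        # degenerate pivots can produce the same ray from two pairs
        uniq: dict[tuple, list[Fraction]] = {}
        for r in new_rays:
            uniq.setdefault(tuple(r), r)
        rays = list(uniq.values())
        processed.append(j)
    return rays


def _zero_mask(vec: Sequence[Fraction], coords: Iterable[int]) -> int:
    mask = 0
    for c in coords:
        if vec[c] == 0:
            mask |= 1 << c
    return mask


def enumerate_efms(net: Network) -> EFMSet:
    """Enumerate the complete set of elementary flux modes of ``net``.

    Reversible reactions may carry negative flux; a mode whose support is
    entirely reversible is reported once, oriented so its first support entry
    is positive.  Modes are ordered by (support size, declaration order).
    """
    if not net.reactions:
        return EFMSet((), network=net.name)
    # split reversible reactions into signed columns, tracked structurally
    columns: list[tuple[str, int]] = []
    for r in net.reactions:
        columns.append((r.id, 1))
        if r.reversible:
            columns.append((r.id, -1))
    internal = set(net.internal_ids)
    row_ids = [m for m in net.metabolite_ids if m in internal]
    row_index = {m: i for i, m in enumerate(row_ids)}
    S = [[Fraction(0)] * len(columns) for _ in row_ids]
    for j, (rid, sign) in enumerate(columns):
        for met, c in net.reaction(rid).stoich.items():
            i = row_index.get(met)
            if i is not None:
                S[i][j] = sign * c
    rays = _extreme_rays_nonneg(S, len(columns))

    vectors: list[dict[str, Fraction]] = []
    for w in rays:
        v: dict[str, Fraction] = {}
        for j, (rid, sign) in enumerate(columns):
            if w[j] != 0:
                v[rid] = v.get(rid, Fraction(0)) + sign * w[j]
        v = {rid: c for rid, c in v.items() if c != 0}
        if v:  # the futile two-cycle of a split reversible maps to zero
            vectors.append(v)
    result = _finish(vectors, net)
    for m in result:  # exactness guard; never expected to fire
        if not is_elementary(m.coeffs, net):
            raise AssertionError(f"enumerator produced a non-elementary ray: {m.coeffs}")
    return result


# ---------------------------------------------------------------------------
# elementarity test and brute-force oracle


def is_elementary(v: Mapping[str, Fraction], net: Network) -> bool:
    """True iff ``v`` is a valid elementary flux mode of ``net``.

    Checks, in order: non-zero; steady state ``S v = 0``; sign feasibility on
    irreversible reactions; and the rank criterion — the nullspace of S
    restricted to supp(v) is one-dimensional.
    """
    known = set(net.reaction_ids)
    for rid in v:
        if rid not in known:
            raise NetworkError(f"flux vector references unknown reaction {rid!r}")
    vec = {rid: Fraction(c) for rid, c in v.items() if Fraction(c) != 0}
    if not vec:
        return False
    for rid, c in vec.items():
        if not net.reaction(rid).reversible and c < 0:
            return False
    smat = stoichiometric_matrix(net)
    col = {rid: j for j, rid in enumerate(smat.cols)}
    for row in smat.entries:
        if sum(row[col[rid]] * c for rid, c in vec.items()) != 0:
            return False
    support_cols = [col[rid] for rid in smat.cols if rid in vec]
    sub = [[row[j] for j in support_cols] for row in smat.entries]
    return rank(sub) == len(support_cols) - 1


def brute_force_efms(net: Network, max_support: int | None = None) -> EFMSet:
    """Independent oracle: enumerate EFMs by exhaustive support search.

    For every candidate support the restricted nullspace is computed; the
    support is an EFM support iff that nullspace is one-dimensional with a
    generator of full support and feasible signs.  Exponential in the number
    of reactions, hence guarded to small networks.
    """
    from itertools import combinations

    n = len(net.reactions)
    if n > 15:
        raise ValueError(f"brute force refused for {n} > 15 reactions")
    if max_support is None:
        max_support = n
    smat = stoichiometric_matrix(net)
    S = smat.as_lists()
    vectors: list[dict[str, Fraction]] = []
    for size in range(1, max_support + 1):
        for cols in combinations(range(n), size):
            sub = [[row[j] for j in cols] for row in S]
            basis = nullspace_basis(sub, size)
            if len(basis) != 1:
                continue
            g = basis[0]
            if any(x == 0 for x in g):
                continue  # true support is a proper subset; found at its own size
            irr_signs = {
                1 if g[k] > 0 else -1
                for k, j in enumerate(cols)
                if not net.reactions[j].reversible
            }
            if irr_signs == {1, -1}:
                continue
            if irr_signs == {-1}:
                g = [-x for x in g]
            vectors.append({net.reactions[j].id: g[k] for k, j in enumerate(cols)})
    return _finish(vectors, net)
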