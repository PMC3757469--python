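"""Combinatorial mutant space: point mutations, multi-mutants, libraries.

A multi-mutant is identified by the unordered set of its point substitutions
(at most one per residue position); its canonical text form joins the
substitutions with ``-`` in ascending position order, e.g.
``G39A-T103G-W104F-L278A``.  Counting combinations from a substitution
library uses elementary symmetric polynomials of the per-position
multiplicities g_i: the number of order-o mutants is e_o(g_1, ..., g_N).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_TOKEN_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True, order=True)
class PointMutation:
    """A single substitution, e.g. G39A: wild-type G at position 39 becomes A."""

    position: int
    wt_residue: str
    new_residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for code in (self.wt_residue, self.new_residue):
            if code not in AMINO_ACIDS:
                raise ValueError(f"{code!r} is not a standard one-letter residue code")
        if self.wt_residue == self.new_residue:
            raise ValueError(
                f"substitution at position {self.position} does not change the "
                f"residue ({self.wt_residue})"
            )

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.new_residue}"

    @classmethod
    def parse(cls, token: str) -> "PointMutation":
        m = _TOKEN_RE.match(token.strip())
        if m is None:
            raise ValueError(f"malformed mutation token {token!r}")
        wt, pos, new = m.groups()
        return cls(position=int(pos), wt_residue=wt.upper(), new_residue=new.upper())


@dataclass(frozen=True)
class MutantID:
    """Canonical identity of a variant: its substitutions sorted by position.

    Order 0 (no mutations) denotes the wild type; it is a valid reference
    identity but is never produced by enumeration.
    """

    mutations: tuple[PointMutation, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.mutations, key=lambda m: m.position))
        positions = [m.position for m in ordered]
        if len(set(positions)) != len(positions):
            dupes = {p for p in positions if positions.count(p) > 1}
            raise ValueError(f"duplicate position(s) {sorted(dupes)} in mutant")
        object.__setattr__(self, "mutations", ordered)

    @property
    def order(self) -> int:
        return len(self.mutations)

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)

    def contains(self, mutation: PointMutation) -> bool:
        return mutation in self.mutations

    def __str__(self) -> str:
        return "-".join(str(m) for m in self.mutations) if self.mutations else "WT"

    def __hash__(self) -> int:
        return hash(self.mutations)


def parse_mutant(text: str) -> MutantID:
    """Parse a ``-``-separated mutant string into its canonical identity.

    Token order in the input is irrelevant; the result is always sorted by
    position.  Raises ``ValueError`` on malformed tokens, duplicate
    positions, or a token whose wild-type and new residues coincide.
    """
    text = text.strip()
    if not text or text.upper() == "WT":
        return MutantID(())
    return MutantID(tuple(PointMutation.parse(tok) for tok in text.split("-")))


@dataclass(frozen=True)
class MutationLibrary:
    """Allowed substitutions per position; multiplicity g_i per position i."""

    entries: Mapping[int, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for pos, (wt, subs) in self.entries.items():
            if not subs:
                raise ValueError(f"position {pos} has no allowed substitutions")
            for s in subs:
                # construction validates codes and wt != new
                PointMutation(position=pos, wt_residue=wt, new_residue=s)
            if len(set(subs)) != len(subs):
                raise ValueError(f"duplicate substitutions at position {pos}")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.entries))

    @property
    def multiplicities(self) -> tuple[int, ...]:
        return tuple(len(self.entries[p][1]) for p in self.positions)

    def mutations_at(self, position: int) -> tuple[PointMutation, ...]:
        wt, subs = self.entries[position]
        return tuple(
            PointMutation(position=position, wt_residue=wt, new_residue=s) for s in subs
        )

    def __contains__(self, mutation: PointMutation) -> bool:
        entry = self.entries.get(mutation.position)
        return (
            entry is not None
            and entry[0] == mutation.wt_residue
            and mutation.new_residue in entry[1]
        )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[int, str, Sequence[str]]]
    ) -> "MutationLibrary":
        entries: dict[int, tuple[str, tuple[str, ...]]] = {}
        for pos, wt, subs in records:
            if pos in entries:
                raise ValueError(f"position {pos} listed twice")
            entries[pos] = (wt, tuple(subs))
        return cls(entries=entries)


@dataclass(frozen=True)
class ExclusionConstraint:
    """Unordered pairs of substitutions that may not co-occur in one mutant."""

    forbidden_pairs: frozenset[frozenset[PointMutation]] = field(
        default_factory=frozenset
    )

    def __post_init__(self) -> None:
        pairs = frozenset(frozenset(p) for p in self.forbidden_pairs)
        for pair in pairs:
            if len(pair) != 2 or len({m.position for m in pair}) != 2:
                raise ValueError("each forbidden pair must span two distinct positions")
        object.__setattr__(self, "forbidden_pairs", pairs)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[PointMutation | str, PointMutation | str]]
    ) -> "ExclusionConstraint":
        norm = []
        for a, b in pairs:
            ma = PointMutation.parse(a) if isinstance(a, str) else a
            mb = PointMutation.parse(b) if isinstance(b, str) else b
            norm.append(frozenset((ma, mb)))
        return cls(forbidden_pairs=frozenset(norm))

    def allows(self, mutant: MutantID) -> bool:
        """True iff the mutant contains no forbidden pair as a subset."""
        muts = set(mutant.mutations)
        return not any(pair <= muts for pair in self.forbidden_pairs)


def count_by_order(library: MutationLibrary, order: int) -> int:
    """Number of order-``order`` combination mutants from the library.

    Equals the order-th elementary symmetric polynomial of the multiplicities
    {g_i}: each choice of ``order`` positions contributes the product of
    their multiplicities.  Returns 0 when ``order`` exceeds the number of
    positions (one cannot pick two substitutions at the same position).
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    g = library.multiplicities
    if order > len(g):
        return 0
    # e_k recurrence: prepend one g at a time, e_k += g * e_{k-1}
    e = [1] + [0] * order
    for gi in g:
        for k in range(min(order, len(e) - 1), 0, -1):
            e[k] += gi * e[k - 1]
    return e[order]


def enumerate_mutants(
    library: MutationLibrary,
    max_order: int,
    exclusions: ExclusionConstraint | None = None,
) -> list[MutantID]:
    """All mutants of order 1..max_order, at most one substitution per position.

    Mutants containing any forbidden pair are omitted.  The result is
    duplicate-free and sorted by (order, canonical string).
    """
    if max_order < 1:
        raise ValueError(f"max_order must be >= 1, got {max_order}")
    exclusions = exclusions or ExclusionConstraint()
    out: list[MutantID] = []
    positions = library.positions
    for order in range(1, min(max_order, len(positions)) + 1):
        for pos_combo in itertools.combinations(positions, order):
            pools = [library.mutations_at(p) for p in pos_combo]
            for muts in itertools.product(*pools):
                mutant = MutantID(muts)
                if exclusions.allows(mutant):
                    out.append(mutant)
    out.sort(key=lambda m: (m.order, str(m)))
    return out


def count_containing_pair(
    library: MutationLibrary,
    pair: tuple[PointMutation, PointMutation],
    order: int,
) -> int:
    """Number of order-``order`` combinations containing both pair members.

    Closed form: fix the two substitutions, then multiply by the
    (order-2)-th elementary symmetric polynomial of the remaining positions'
    multiplicities.
    """
    a, b = pair
    if a.position == b.position:
        raise ValueError("pair must span two distinct positions")
    for m in (a, b):
        if m not in library:
            raise ValueError(f"mutation {m} not present in library")
    if order < 2:
        return 0
    remaining = [
        len(library.entries[p][1])
        for p in library.positions
        if p not in (a.position, b.position)
    ]
    rest = MutationLibrary.from_records(
        [
            (p, library.entries[p][0], library.entries[p][1])
            for p in library.positions
            if p not in (a.position, b.position)
        ]
    )
    if order == 2:
        return 1
    if order - 2 > len(remaining):
        return 0
    return count_by_order(rest, order - 2)


def intersect_sets(
    a: Iterable[MutantID], b: Iterable[MutantID]
) -> list[MutantID]:
    """Canonical-identity intersection of two mutant collections.

    Identity is the full substitution set — a single mutant does not match a
    double mutant that contains it.
    """
    common = set(a) & set(b)
    return sorted(common, key=lambda m: (m.order, str(m)))
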