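"""Schema layer for typed heterogeneous networks (hetnets).

A hetnet's schema — its *metagraph* — declares the node types (metanodes)
and edge types (metaedges).  A *metapath* is a type-level path: an ordered,
orientation-aware sequence of metaedges, conventionally written as a compact
abbreviation such as ``CbGpPWpG`` (Compound–binds–Gene–participates–Pathway–
participates–Gene).  Everything downstream (path counting, permutation,
significance) is keyed by these objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Mapping, Sequence


class SchemaError(ValueError):
    """Raised for malformed or inconsistent metagraph definitions."""


class MetapathParseError(ValueError):
    """Raised when a metapath abbreviation cannot be resolved."""


@dataclass(frozen=True)
class Metanode:
    """A node type, e.g. Gene (abbreviation ``G``) or Pathway (``PW``)."""

    identifier: str
    abbreviation: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise SchemaError("metanode identifier must be nonempty")
        if not self.abbreviation or not self.abbreviation[0].isupper():
            raise SchemaError(
                f"metanode abbreviation must be uppercase-leading: {self.abbreviation!r}"
            )

    def __str__(self) -> str:
        return self.identifier


@dataclass(frozen=True)
class Metaedge:
    """An edge type joining two metanodes.

    An undirected metaedge is its own inverse; a directed one (e.g. Gene–
    regulates→Gene) has a distinct inverse orientation, written with ``>`` /
    ``<`` markers in abbreviations (``Gr>G`` forward, ``G<rG`` reversed).
    """

    source: Metanode
    target: Metanode
    kind: str
    kind_abbreviation: str
    directed: bool = False

    def __post_init__(self) -> None:
        if not self.kind_abbreviation.islower():
            raise SchemaError(
                f"metaedge kind abbreviation must be lowercase: {self.kind_abbreviation!r}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source.abbreviation, self.kind_abbreviation, self.target.abbreviation)

    @property
    def abbreviation(self) -> str:
        marker = ">" if self.directed else ""
        return f"{self.source.abbreviation}{self.kind_abbreviation}{marker}{self.target.abbreviation}"

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target

    def __str__(self) -> str:
        arrow = ">" if self.directed else "–"
        return f"{self.source}–{self.kind}{arrow}{self.target}"


@dataclass(frozen=True)
class Step:
    """A metaedge traversed in a particular orientation.

    ``inverted`` is always False for undirected self-loop metaedges (GiG),
    whose two orientations are indistinguishable.
    """

    metaedge: Metaedge
    inverted: bool = False

    def __post_init__(self) -> None:
        if self.inverted and self.metaedge.is_self_loop and not self.metaedge.directed:
            object.__setattr__(self, "inverted", False)

    @property
    def source(self) -> Metanode:
        return self.metaedge.target if self.inverted else self.metaedge.source

    @property
    def target(self) -> Metanode:
        return self.metaedge.source if self.inverted else self.metaedge.target

    @property
    def token(self) -> str:
        """The edge part of the abbreviation, including direction markers."""
        kab = self.metaedge.kind_abbreviation
        if not self.metaedge.directed:
            return kab
        return f"<{kab}" if self.inverted else f"{kab}>"

    @property
    def reversed(self) -> "Step":
        return Step(self.metaedge, not self.inverted)


@dataclass(frozen=True)
class Metapath:
    """An ordered sequence of oriented metaedges with chained endpoints."""

    steps: tuple[Step, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("metapath must have length >= 1")
        for a, b in zip(self.steps, self.steps[1:]):
            if a.target != b.source:
                raise ValueError(
                    f"incompatible adjacent steps: {a.target} != {b.source}"
                )

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self) -> Iterator[Step]:
        return iter(self.steps)

    def __getitem__(self, item):
        if isinstance(item, slice):
            return Metapath(self.steps[item])
        return self.steps[item]

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def source(self) -> Metanode:
        return self.steps[0].source

    @property
    def target(self) -> Metanode:
        return self.steps[-1].target

    @cached_property
    def abbreviation(self) -> str:
        parts = [self.source.abbreviation]
        for step in self.steps:
            parts.append(step.token)
            parts.append(step.target.abbreviation)
        return "".join(parts)

    @cached_property
    def metanodes(self) -> tuple[Metanode, ...]:
        """The length+1 metanode sequence visited by the metapath."""
        return (self.source,) + tuple(step.target for step in self.steps)

    @property
    def reverse(self) -> "Metapath":
        return Metapath(tuple(step.reversed for step in reversed(self.steps)))

    @property
    def is_canonical(self) -> bool:
        """True when this orientation is the representative of its
        reversal-equivalence class (lexicographically smaller abbreviation)."""
        return self.abbreviation <= self.reverse.abbreviation

    def __str__(self) -> str:
        return self.abbreviation

    def __add__(self, other: "Metapath") -> "Metapath":
        return Metapath(self.steps + other.steps)


class Metagraph:
    """A hetnet schema: metanodes, metaedges, and abbreviation lookup."""

    def __init__(self, metanodes: Iterable[Metanode], metaedges: Iterable[Metaedge]):
        self.metanodes: dict[str, Metanode] = {}
        for mn in metanodes:
            if mn.abbreviation in self.metanodes:
                raise SchemaError(f"duplicate metanode abbreviation {mn.abbreviation!r}")
            self.metanodes[mn.abbreviation] = mn
        by_id = {mn.identifier for mn in self.metanodes.values()}
        if len(by_id) != len(self.metanodes):
            raise SchemaError("duplicate metanode identifier")
        self.metaedges: dict[tuple[str, str, str], Metaedge] = {}
        for me in metaedges:
            for endpoint in (me.source, me.target):
                if self.metanodes.get(endpoint.abbreviation) != endpoint:
                    raise SchemaError(
                        f"metaedge {me.abbreviation} references undeclared metanode "
                        f"{endpoint.identifier!r}"
                    )
            if me.key in self.metaedges:
                raise SchemaError(f"duplicate metaedge {me.abbreviation!r}")
            self.metaedges[me.key] = me

    # -- lookup ----------------------------------------------------------

    def metanode(self, abbreviation: str) -> Metanode:
        try:
            return self.metanodes[abbreviation]
        except KeyError:
            # fall back to identifier lookup for convenience
            for mn in self.metanodes.values():
                if mn.identifier == abbreviation:
                    return mn
            raise KeyError(f"unknown metanode {abbreviation!r}") from None

    def metaedge(self, source_ab: str, kind_ab: str, target_ab: str) -> Metaedge:
        return self.metaedges[(source_ab, kind_ab, target_ab)]

    @cached_property
    def steps_by_source(self) -> dict[str, tuple[Step, ...]]:
        """All oriented traversal steps grouped by source metanode abbreviation,
        deterministically ordered."""
        out: dict[str, list[Step]] = {ab: [] for ab in self.metanodes}
        for me in self.metaedges.values():
            steps = [Step(me, False)]
            if not (me.is_self_loop and not me.directed):
                steps.append(Step(me, True))
            for step in steps:
                out[step.source.abbreviation].append(step)
        return {
            ab: tuple(sorted(steps, key=lambda s: (s.token, s.target.abbreviation)))
            for ab, steps in out.items()
        }

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        metanodes = sorted(self.metanodes.values(), key=lambda mn: mn.identifier)
        metaedges = sorted(self.metaedges.values(), key=lambda me: me.key)
        kind_to_abbrev: dict[str, str] = {}
        for mn in metanodes:
            kind_to_abbrev[mn.identifier] = mn.abbreviation
        for me in metaedges:
            prior = kind_to_abbrev.setdefault(me.kind, me.kind_abbreviation)
            if prior != me.kind_abbreviation:
                raise SchemaError(
                    f"metaedge kind {me.kind!r} maps to conflicting abbreviations"
                )
        return {
            "metanode_kinds": [mn.identifier for mn in metanodes],
            "metaedge_tuples": [
                [
                    me.source.identifier,
                    me.target.identifier,
                    me.kind,
                    "forward" if me.directed else "both",
                ]
                for me in metaedges
            ],
            "kind_to_abbrev": kind_to_abbrev,
        }

    @classmethod
    def from_dict(cls, schema: Mapping) -> "Metagraph":
        try:
            metanode_kinds = schema["metanode_kinds"]
            metaedge_tuples = schema["metaedge_tuples"]
            kind_to_abbrev = schema["kind_to_abbrev"]
        except KeyError as exc:
            raise SchemaError(f"metagraph schema missing key {exc}") from exc
        metanodes = {}
        for kind in metanode_kinds:
            try:
                ab = kind_to_abbrev[kind]
            except KeyError:
                raise SchemaError(f"no abbreviation for metanode kind {kind!r}")
            metanodes[kind] = Metanode(kind, ab)
        metaedges = []
        for source_kind, target_kind, kind, direction in metaedge_tuples:
            for endpoint in (source_kind, target_kind):
                if endpoint not in metanodes:
                    raise SchemaError(
                        f"metaedge kind {kind!r} references undeclared metanode {endpoint!r}"
                    )
            if direction not in ("both", "forward"):
                raise SchemaError(f"unsupported metaedge direction {direction!r}")
            try:
                kind_ab = kind_to_abbrev[kind]
            except KeyError:
                raise SchemaError(f"no abbreviation for metaedge kind {kind!r}")
            metaedges.append(
                Metaedge(
                    source=metanodes[source_kind],
                    target=metanodes[target_kind],
                    kind=kind,
                    kind_abbreviation=kind_ab,
                    directed=(direction == "forward"),
                )
            )
        return cls(metanodes.values(), metaedges)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Metagraph):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return (
            f"Metagraph({len(self.metanodes)} metanodes, "
            f"{len(self.metaedges)} metaedges)"
        )

    # -- metapath parsing ------------------------------------------------

    def parse_metapath(self, abbreviation: str) -> Metapath:
        """Parse an abbreviation like ``CbGpPWpG`` into a :class:`Metapath`.

        Undirected kinds are bare lowercase tokens; directed kinds carry
        ``>`` (forward) or ``<`` (inverted) markers.  All tokenizations are
        explored; an input admitting more than one valid metapath raises a
        :class:`MetapathParseError` listing the candidates.
        """
        parses = self._parse_all(abbreviation)
        if not parses:
            raise MetapathParseError(f"cannot parse metapath {abbreviation!r}")
        if len(parses) > 1:
            candidates = ", ".join(
                "-".join(step.metaedge.abbreviation for step in p) for p in parses
            )
            raise MetapathParseError(
                f"ambiguous metapath {abbreviation!r}; candidates: {candidates}"
            )
        return Metapath(tuple(parses[0]))

    def _parse_all(self, text: str) -> list[list[Step]]:
        node_abbrevs = sorted(self.metanodes, key=len, reverse=True)
        results: list[list[Step]] = []

        def match_nodes(pos: int):
            for ab in node_abbrevs:
                if text.startswith(ab, pos):
                    yield ab, pos + len(ab)

        def edge_steps(prev_ab: str, pos: int):
            """Yield (step, new_pos) for every edge token + next node."""
            i = pos
            inverted_marker = False
            if i < len(text) and text[i] == "<":
                inverted_marker = True
                i += 1
            start = i
            while i < len(text) and text[i].islower():
                i += 1
            # try every nonempty prefix of the lowercase run as the kind token
            for end in range(start + 1, i + 1):
                kind_ab = text[start:end]
                j = end
                forward_marker = False
                if not inverted_marker and j < len(text) and text[j] == ">":
                    forward_marker = True
                    j += 1
                for next_ab, k in match_nodes(j):
                    for step in self._resolve_step(
                        prev_ab, kind_ab, next_ab, inverted_marker, forward_marker
                    ):
                        yield step, next_ab, k

        def resolve(prev_ab: str, pos: int, acc: list[Step]) -> None:
            if pos == len(text):
                if acc:
                    results.append(list(acc))
                return
            for step, next_ab, new_pos in edge_steps(prev_ab, pos):
                acc.append(step)
                resolve(next_ab, new_pos, acc)
                acc.pop()

        for first_ab, pos in match_nodes(0):
            resolve(first_ab, pos, [])
        return results

    def _resolve_step(
        self, prev_ab: str, kind_ab: str, next_ab: str, inverted: bool, forward: bool
    ) -> list[Step]:
        steps = []
        if inverted:
            me = self.metaedges.get((next_ab, kind_ab, prev_ab))
            if me is not None and me.directed:
                steps.append(Step(me, True))
        elif forward:
            me = self.metaedges.get((prev_ab, kind_ab, next_ab))
            if me is not None and me.directed:
                steps.append(Step(me, False))
        else:
            me = self.metaedges.get((prev_ab, kind_ab, next_ab))
            if me is not None and not me.directed:
                steps.append(Step(me, False))
            me_rev = self.metaedges.get((next_ab, kind_ab, prev_ab))
            if me_rev is not None and not me_rev.directed and me_rev.key != (
                prev_ab,
                kind_ab,
                next_ab,
            ):
                steps.append(Step(me_rev, True))
        return steps

    # -- metapath enumeration --------------------------------------------

    def enumerate_metapaths(
        self,
        max_length: int,
        source: Metanode | str | None = None,
        target: Metanode | str | None = None,
    ) -> list[Metapath]:
        """All metapaths of length 1..max_length, one per reversal class.

        With both endpoints unspecified, each {mp, reverse(mp)} class is
        represented once by its lexicographically smaller abbreviation.  With
        (source, target) given, each class contributes its source→target
        orientation.  Ordering is deterministic: by length, then abbreviation.
        """
        if max_length < 1:
            raise ValueError("max_length must be >= 1")
        if isinstance(source, str):
            source = self.metanode(source)
        if isinstance(target, str):
            target = self.metanode(target)
        steps_by_source = self.steps_by_source
        found: list[Metapath] = []
        seen: set[tuple[Step, ...]] = set()

        start_nodes = [source] if source is not None else list(self.metanodes.values())

        def walk(acc: list[Step]) -> None:
            if acc:
                mp = Metapath(tuple(acc))
                if target is None or mp.target == target:
                    if source is None and target is None:
                        keep = mp.is_canonical
                    else:
                        # one per reversal class: if the reverse also matches
                        # the endpoint constraint, keep the smaller abbreviation
                        rev = mp.reverse
                        rev_matches = (
                            (source is None or rev.source == source)
                            and (target is None or rev.target == target)
                        )
                        keep = (not rev_matches) or mp.abbreviation <= rev.abbreviation
                    if keep and mp.steps not in seen:
                        seen.add(mp.steps)
                        found.append(mp)
                if len(acc) == max_length:
                    return
                tail_ab = acc[-1].target.abbreviation
            else:
                tail_ab = None
            next_sources = (
                [tail_ab]
                if tail_ab is not None
                else [mn.abbreviation for mn in start_nodes]
            )
            for ab in next_sources:
                for step in steps_by_source[ab]:
                    acc.append(step)
                    walk(acc)
                    acc.pop()

        walk([])
        found.sort(key=lambda mp: (mp.length, mp.abbreviation))
        return found


def parse_metagraph(text: str) -> Metagraph:
    """Parse a serialized metagraph schema (JSON) into a :class:`Metagraph`."""
    return Metagraph.from_dict(json.loads(text))


def load_metagraph(path) -> Metagraph:
    with open(path, encoding="utf-8") as handle:
        return Metagraph.from_dict(json.load(handle))
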