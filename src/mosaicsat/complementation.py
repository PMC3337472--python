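"""Locus inference from pairwise complementation tests.

Two recessive lethal mutations are crossed; a mutant trans-heterozygote
(dead, or derepressing the reporter) means the pair *fails to complement*
and the mutations are alleles of one gene. Grouping is therefore graph
connectivity: mutations are nodes, noncomplementing pairs are edges, and
complementation groups (putative loci) are the connected components.

Real screens also produce *complex* (intransitive) complementation —
typically an isoform-restricted hypomorph that complements other alleles
of its own gene while failing against a deficiency that removes the locus.
This module detects and flags those patterns instead of silently merging
or splitting on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Literal, Mapping

import networkx as nx

from .errors import ValidationError

__all__ = [
    "COMPLEMENTS",
    "FAILS",
    "PARTIAL",
    "UNTESTED",
    "ComplementationMatrix",
    "LocusPartition",
    "Flag",
    "build_groups",
    "find_intransitive_triangles",
    "flag_hypomorph_candidates",
]

COMPLEMENTS = "complements"
FAILS = "fails"
PARTIAL = "partial"
UNTESTED = "untested"
_RESULTS = frozenset({COMPLEMENTS, FAILS, PARTIAL, UNTESTED})
_CHANNELS = frozenset({"lethality", "reporter_fluorescence", "both"})

PartialPolicy = Literal["as_complement", "as_fail", "flag_only"]


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ComplementationMatrix:
    """Symmetric pairwise complementation results over a set of mutations.

    ``results`` maps canonically ordered pairs to one of the result states;
    pairs absent from the mapping are untested. The diagonal is ``fails``
    by definition (a self-cross is homozygous mutant). Scoring is an OR
    over phenotype channels — lethality or reporter derepression each count
    as noncomplementation — and the channel that produced each call can be
    recorded per edge. Deficiency (chromosomal deletion) tests are carried
    separately as (mutation, deficiency_id) -> result.
    """

    mutation_ids: tuple[str, ...]
    results: Mapping[tuple[str, str], str] = field(default_factory=dict)
    channels: Mapping[tuple[str, str], str] = field(default_factory=dict)
    deficiency_tests: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.mutation_ids)) != len(self.mutation_ids):
            raise ValidationError("duplicate mutation_id")
        known = set(self.mutation_ids)
        for (a, b), res in self.results.items():
            if a not in known or b not in known:
                raise ValidationError(f"result for unknown mutation in pair ({a}, {b})")
            if a == b:
                raise ValidationError(f"self-pair ({a}, {a}) may not be set explicitly")
            if (a, b) != _pair(a, b):
                raise ValidationError(f"pair ({a}, {b}) is not canonically ordered")
            if res not in _RESULTS:
                raise ValidationError(f"pair ({a}, {b}): unknown result {res!r}")
        for key, channel in self.channels.items():
            if key not in self.results:
                raise ValidationError(f"channel for untested pair {key}")
            if channel not in _CHANNELS:
                raise ValidationError(f"pair {key}: unknown channel {channel!r}")
        for (m, _df), res in self.deficiency_tests.items():
            if m not in known:
                raise ValidationError(f"deficiency test for unknown mutation {m!r}")
            if res not in _RESULTS:
                raise ValidationError(f"deficiency test ({m}, {_df}): bad result {res!r}")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        mutation_ids: Iterable[str] | None = None,
        deficiency_records: Iterable[tuple[str, str, str]] = (),
    ) -> "ComplementationMatrix":
        """Build from long-format rows ``(a, b, result[, channel])``.

        A pair listed in both orientations must agree; a contradiction is a
        validation error naming the offending pair.
        """
        results: dict[tuple[str, str], str] = {}
        channels: dict[tuple[str, str], str] = {}
        ids: list[str] = list(mutation_ids) if mutation_ids is not None else []
        seen = set(ids)
        for rec in records:
            a, b, res = rec[0], rec[1], rec[2]
            channel = rec[3] if len(rec) > 3 and rec[3] else None
            for m in (a, b):
                if m not in seen:
                    seen.add(m)
                    ids.append(m)
            if a == b:
                if res != FAILS:
                    raise ValidationError(
                        f"self-cross ({a}, {a}) must fail to complement, got {res!r}"
                    )
                continue
            key = _pair(a, b)
            if key in results and results[key] != res:
                raise ValidationError(
                    f"asymmetric results for pair ({key[0]}, {key[1]}): "
                    f"{results[key]!r} vs {res!r}"
                )
            results[key] = res
            if channel is not None:
                channels[key] = channel
        deficiencies = {(m, df): res for m, df, res in deficiency_records}
        return cls(
            mutation_ids=tuple(ids),
            results=results,
            channels=channels,
            deficiency_tests=deficiencies,
        )

    def result(self, a: str, b: str) -> str:
        if a == b:
            return FAILS
        return self.results.get(_pair(a, b), UNTESTED)

    @property
    def n_mutations(self) -> int:
        return len(self.mutation_ids)

    @property
    def testing_completeness(self) -> float:
        """Fraction of off-diagonal pairs with a recorded (non-untested) result.

        Full pairwise testing of n lines is n(n-1)/2 crosses; screens rarely
        do all of them, and a sparse matrix over-splits silently unless this
        is reported alongside the partition.
        """
        n = self.n_mutations
        if n < 2:
            return 1.0
        tested = sum(1 for res in self.results.values() if res != UNTESTED)
        return tested / (n * (n - 1) // 2)

    def deficiencies_of(self, mutation: str) -> dict[str, str]:
        return {df: res for (m, df), res in self.deficiency_tests.items() if m == mutation}


@dataclass(frozen=True)
class Flag:
    """An annotation attached to a mutation/group pair, with evidence."""

    mutation_id: str
    group: str  # group label = lexicographically smallest member
    flag_type: str  # hypomorph_candidate | intransitive_triangle | conflict_with_deficiency
    evidence: tuple[str, ...]


@dataclass(frozen=True)
class LocusPartition:
    """Disjoint complementation groups covering all mutations, plus flags."""

    groups: tuple[tuple[str, ...], ...]
    flags: tuple[Flag, ...] = ()
    testing_completeness: float = 1.0

    def __post_init__(self) -> None:
        members = [m for g in self.groups for m in g]
        if len(members) != len(set(members)):
            raise ValidationError("groups are not disjoint")
        known = set(members)
        for f in self.flags:
            if f.mutation_id not in known:
                raise ValidationError(f"flag references unknown mutation {f.mutation_id!r}")
            if f.group not in {g[0] for g in self.groups}:
                raise ValidationError(f"flag references unknown group {f.group!r}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self, mutation: str) -> tuple[str, ...]:
        for g in self.groups:
            if mutation in g:
                return g
        raise KeyError(mutation)

    def group_label(self, mutation: str) -> str:
        return self.group_of(mutation)[0]

    def as_mapping(self) -> dict[str, str]:
        """mutation_id -> group label."""
        return {m: g[0] for g in self.groups for m in g}


def build_groups(
    matrix: ComplementationMatrix, partial_policy: PartialPolicy = "flag_only"
) -> LocusPartition:
    """Connected components of the noncomplementation graph.

    Edges are ``fails`` pairs; ``partial`` pairs are edges only under
    ``partial_policy="as_fail"`` (under the default ``flag_only`` they do
    not merge groups — flagging is done by :func:`flag_hypomorph_candidates`
    — and ``as_complement`` ignores them entirely). ``untested`` pairs
    contribute no edge; see ``testing_completeness`` for how saturated the
    matrix actually is. Output ordering is deterministic: members sorted
    within groups, groups sorted by smallest member.
    """
    if partial_policy not in ("as_complement", "as_fail", "flag_only"):
        raise ValidationError(f"unknown partial_policy {partial_policy!r}")
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(matrix.mutation_ids)
    merge_states = {FAILS, PARTIAL} if partial_policy == "as_fail" else {FAILS}
    for (a, b), res in matrix.results.items():
        if res in merge_states:
            graph.add_edge(a, b)
    groups = sorted(
        (tuple(sorted(component)) for component in nx.connected_components(graph)),
        key=lambda g: g[0],
    )
    return LocusPartition(
        groups=tuple(groups),
        flags=(),
        testing_completeness=matrix.testing_completeness,
    )


def find_intransitive_triangles(
    matrix: ComplementationMatrix,
) -> list[tuple[str, str, str]]:
    """Triples (a, b, c) with fails(a,b), fails(b,c) but complements(a,c).

    These are the signature of complex complementation: transitive
    noncomplementation cannot produce them under one-gene-one-group logic.
    Triples are normalized (a < c) and returned sorted; a fully transitive
    matrix yields an empty list.
    """
    fails_adj: dict[str, set[str]] = {m: set() for m in matrix.mutation_ids}
    for (a, b), res in matrix.results.items():
        if res == FAILS:
            fails_adj[a].add(b)
            fails_adj[b].add(a)
    triangles: set[tuple[str, str, str]] = set()
    for b in matrix.mutation_ids:
        for a, c in combinations(sorted(fails_adj[b]), 2):
            if matrix.result(a, c) == COMPLEMENTS:
                triangles.add((a, b, c))
    return sorted(triangles)


def _noncomplementing(res: str) -> bool:
    return res in (FAILS, PARTIAL)


def flag_hypomorph_candidates(
    matrix: ComplementationMatrix, partition: LocusPartition
) -> LocusPartition:
    """Annotate the partition with complex-complementation flags.

    A mutation m is a ``hypomorph_candidate`` for group g when it shows the
    isoform-restricted pattern: it fails (fully or partially) either a
    deficiency anchored to g or some member of g, yet complements at least
    one other member of g. A ``partial`` pairwise result against a member
    of g counts as evidence the same way. Intransitive triangles whose
    members all sit in one group raise ``intransitive_triangle`` flags on
    the complementing endpoints; a mutation that complements a deficiency
    its groupmates fail raises ``conflict_with_deficiency``.
    """
    label_of = partition.as_mapping()
    # deficiencies anchored to a group: a member FULLY fails the deletion
    # (protein-null-like evidence the deletion removes that locus); a
    # merely partial failure is itself the hypomorph signature and must
    # not anchor the deficiency to the hypomorph's own group
    group_deficiencies: dict[str, set[str]] = {}
    for (m, df), res in matrix.deficiency_tests.items():
        if res == FAILS and m in label_of:
            group_deficiencies.setdefault(label_of[m], set()).add(df)

    flags: dict[tuple[str, str, str], list[str]] = {}

    def add(mutation: str, group: str, flag_type: str, *evidence: str) -> None:
        flags.setdefault((mutation, group, flag_type), []).extend(evidence)

    groups_by_label = {g[0]: g for g in partition.groups}
    for m in matrix.mutation_ids:
        for label, members in groups_by_label.items():
            others = [x for x in members if x != m]
            if not others:
                continue
            complemented = [x for x in others if matrix.result(m, x) == COMPLEMENTS]
            if not complemented:
                continue
            failed_members = [x for x in others if _noncomplementing(matrix.result(m, x))]
            failed_dfs = [
                df
                for df, res in matrix.deficiencies_of(m).items()
                if _noncomplementing(res) and df in group_deficiencies.get(label, set())
            ]
            if failed_members or failed_dfs:
                evidence = (
                    [f"{m}~{x}:{matrix.result(m, x)}" for x in failed_members]
                    + [f"{m}~Df({df}):{matrix.deficiencies_of(m)[df]}" for df in failed_dfs]
                    + [f"{m}~{x}:complements" for x in complemented]
                )
                add(m, label, "hypomorph_candidate", *evidence)

    for a, b, c in find_intransitive_triangles(matrix):
        if label_of[a] == label_of[b] == label_of[c]:
            label = label_of[a]
            evidence = (f"fails:{a}~{b}", f"fails:{b}~{c}", f"complements:{a}~{c}")
            add(a, label, "intransitive_triangle", *evidence)
            add(c, label, "intransitive_triangle", *evidence)

    for (m, df), res in matrix.deficiency_tests.items():
        if res != COMPLEMENTS or m not in label_of:
            continue
        label = label_of[m]
        if df in group_deficiencies.get(label, set()):
            groupmates = [
                x
                for x in groups_by_label[label]
                if x != m and _noncomplementing(matrix.deficiency_tests.get((x, df), UNTESTED))
            ]
            add(
                m,
                label,
                "conflict_with_deficiency",
                f"{m}~Df({df}):complements",
                *[f"{x}~Df({df}):{matrix.deficiency_tests[(x, df)]}" for x in groupmates],
            )

    new_flags = tuple(
        Flag(mutation_id=m, group=g, flag_type=t, evidence=tuple(dict.fromkeys(ev)))
        for (m, g, t), ev in sorted(flags.items())
    )
    return replace(partition, flags=partition.flags + new_flags)
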