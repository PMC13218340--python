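"""Genomic position-based grouping schemes for grouped FDR control.

miRNAs are partitioned hierarchically by genomic position: (a) chromosome,
(b) chromosome + strand, (c) chromosome + strand + arm.  Finer schemes are
derived from level (c) by chunking any group larger than a maximum size *k*
into adjacent sub-groups of size *k* along the chromosome (the last chunk may
be smaller; a last chunk of size 1 is folded back into its neighbour, so one
chunk may hold *k*+1 members).

Two normalisation rules apply to every scheme: keys with no member never
materialise, and single-miRNA groups are merged into their nearest
neighbouring group.  Nearness is tiered and deterministic — same chromosome
first, then increasing chromosome distance in the order 1..22, X, Y — with
the minimum start-coordinate difference deciding within a tier and the
lexicographically smaller group id breaking exact ties.  Grouping uses no
randomness anywhere: identical annotations always give identical schemes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

from groupfdr.io_model import AnnotationRecord, chromosome_order

Level = Literal["chrom", "chrom_strand", "chrom_strand_arm", "refined"]


class MissingAnnotationError(ValueError):
    """A miRNA to be grouped has no annotation record."""


class CannotMergeError(ValueError):
    """A singleton group exists but there is no other group to merge into."""


@dataclass
class GroupingScheme:
    """A partition of miRNA identifiers with genomic metadata.

    ``groups`` maps group id to its member list, ordered by ascending start
    coordinate (ties by identifier); ``assignment`` is the inverse map.
    """

    assignment: dict[str, str]
    groups: dict[str, list[str]]
    level: Level
    k: int | None = None

    def __post_init__(self) -> None:
        members = [m for mem in self.groups.values() for m in mem]
        if len(members) != len(set(members)):
            raise ValueError("groups overlap: not a partition")
        if set(members) != set(self.assignment):
            raise ValueError("assignment and groups disagree")
        for gid, mem in self.groups.items():
            if not mem:
                raise ValueError(f"empty group {gid!r}")
            for m in mem:
                if self.assignment[m] != gid:
                    raise ValueError(f"assignment mismatch for {m!r}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def sizes(self) -> list[int]:
        return [len(mem) for mem in self.groups.values()]

    def group_of(self, mirna_id: str) -> str:
        return self.assignment[mirna_id]


@dataclass
class SchemeSummary:
    n_groups: int
    size_histogram: dict[int, int]
    min_size: int
    max_size: int


def _key_for(rec: AnnotationRecord, level: Level) -> str:
    if level == "chrom":
        return f"chr{rec.chrom}"
    if level == "chrom_strand":
        return f"chr{rec.chrom}:{rec.strand}"
    if level == "chrom_strand_arm":
        return f"chr{rec.chrom}:{rec.strand}:{rec.arm}"
    raise ValueError(f"cannot key level {level!r}")


def _sorted_members(members: Sequence[str], ann: dict[str, AnnotationRecord]) -> list[str]:
    return sorted(members, key=lambda m: (ann[m].start, m))


def _annotation_index(annotation: Sequence[AnnotationRecord]) -> dict[str, AnnotationRecord]:
    return {rec.mirna_id: rec for rec in annotation}


def build_scheme(
    annotation: Sequence[AnnotationRecord],
    level: Level,
    mirna_ids: Sequence[str] | None = None,
) -> GroupingScheme:
    """Group miRNAs by genomic key at the requested level.

    ``mirna_ids`` restricts grouping to the miRNAs actually tested; every one
    of them must be annotated.  Singletons are merged via
    :func:`merge_singletons` before the scheme is returned.
    """
    ann = _annotation_index(annotation)
    ids = list(mirna_ids) if mirna_ids is not None else [r.mirna_id for r in annotation]
    unannotated = [m for m in ids if m not in ann]
    if unannotated:
        raise MissingAnnotationError(f"no annotation for: {unannotated}")
    groups: dict[str, list[str]] = {}
    for m in ids:
        groups.setdefault(_key_for(ann[m], level), []).append(m)
    groups = {gid: _sorted_members(mem, ann) for gid, mem in sorted(groups.items())}
    assignment = {m: gid for gid, mem in groups.items() for m in mem}
    scheme = GroupingScheme(assignment=assignment, groups=groups, level=level)
    return merge_singletons(scheme, annotation)


def _group_chrom(gid: str, members: Sequence[str], ann: dict[str, AnnotationRecord]) -> str:
    return ann[members[0]].chrom


def merge_singletons(
    scheme: GroupingScheme, annotation: Sequence[AnnotationRecord]
) -> GroupingScheme:
    """Fold every single-member group into its nearest neighbouring group.

    Applied iteratively until no singleton remains; two lone singletons merge
    with each other.  See the module docstring for the nearness rule.
    """
    ann = _annotation_index(annotation)
    groups = {gid: list(mem) for gid, mem in scheme.groups.items()}
    total = sum(len(mem) for mem in groups.values())
    if total == 1:
        raise CannotMergeError("cannot merge: only one miRNA in total")

    def merge_cost(singleton_gid: str, cand_gid: str) -> tuple:
        s_rec = ann[groups[singleton_gid][0]]
        cand_members = groups[cand_gid]
        cand_chrom = _group_chrom(cand_gid, cand_members, ann)
        same_chrom = 0 if cand_chrom == s_rec.chrom else 1
        s_ord = chromosome_order(s_rec.chrom)
        c_ord = chromosome_order(cand_chrom)
        chrom_dist = abs(s_ord[0] - c_ord[0])
        start_dist = min(abs(ann[m].start - s_rec.start) for m in cand_members)
        return (same_chrom, chrom_dist, start_dist, cand_gid)

    while True:
        singletons = sorted(gid for gid, mem in groups.items() if len(mem) == 1)
        if not singletons:
            break
        gid = singletons[0]
        candidates = [c for c in groups if c != gid]
        target = min(candidates, key=lambda c: merge_cost(gid, c))
        groups[target] = _sorted_members(groups[target] + groups[gid], ann)
        del groups[gid]

    assignment = {m: gid for gid, mem in groups.items() for m in mem}
    return GroupingScheme(assignment=assignment, groups=groups, level=scheme.level, k=scheme.k)


def split_scheme(
    scheme_c: GroupingScheme,
    k: int,
    annotation: Sequence[AnnotationRecord],
) -> GroupingScheme:
    """Refine a level-(c) scheme by chunking groups larger than *k*.

    Chunks run in ascending start-coordinate order; a trailing chunk of size
    1 is merged into the preceding chunk (allowing one chunk of size k+1).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ann = _annotation_index(annotation)
    groups: dict[str, list[str]] = {}
    for gid, members in scheme_c.groups.items():
        if len(members) <= k:
            groups[gid] = list(members)
            continue
        ordered = _sorted_members(members, ann)
        chunks = [ordered[i : i + k] for i in range(0, len(ordered), k)]
        if len(chunks[-1]) == 1:
            chunks[-2].extend(chunks.pop())
        for idx, chunk in enumerate(chunks, start=1):
            groups[f"{gid}#{idx}"] = chunk
    assignment = {m: gid for gid, mem in groups.items() for m in mem}
    return GroupingScheme(assignment=assignment, groups=groups, level="refined", k=k)


def scheme_family(
    annotation: Sequence[AnnotationRecord],
    k_values: Sequence[int] = (),
    mirna_ids: Sequence[str] | None = None,
) -> list[GroupingScheme]:
    """The full hierarchy: levels (a), (b), (c), then refined(k) per k value."""
    a = build_scheme(annotation, "chrom", mirna_ids)
    b = build_scheme(annotation, "chrom_strand", mirna_ids)
    c = build_scheme(annotation, "chrom_strand_arm", mirna_ids)
    family = [a, b, c]
    for k in k_values:
        family.append(split_scheme(c, int(k), annotation))
    return family


def scheme_label(scheme: GroupingScheme) -> str:
    """Short display label: 'a', 'b', 'c' or 'k=<k>'."""
    if scheme.level == "refined":
        return f"k={scheme.k}"
    return {"chrom": "a", "chrom_strand": "b", "chrom_strand_arm": "c"}[scheme.level]


def scheme_summary(scheme: GroupingScheme) -> SchemeSummary:
    sizes = scheme.sizes()
    return SchemeSummary(
        n_groups=scheme.n_groups,
        size_histogram=dict(sorted(Counter(sizes).items())),
        min_size=min(sizes),
        max_size=max(sizes),
    )
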