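"""Perfect, unambiguous, strand-aware exact matching of small-RNA
inserts against a host + virus reference union.

A short insert is informative for viRNA profiling only when it has
exactly one perfect match position across the entire reference union
("unambiguous mapping"): category ``virus_sense`` / ``virus_antisense``
when that single hit lies on a viral segment (+ / - strand), ``host``
when it lies on a host record. Two or more hits anywhere — including a
virus hit plus a host hit, or a palindromic insert matching both strands
of one locus — make the insert ``ambiguous`` and exclude it from viral
profiles; zero hits is ``unmapped``.

Matching is seed-and-verify: a k-mer (default k=12, below the minimum
insert length) positional index over the + strand of every record, with
full string verification of each candidate, so results are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from virna._seq import normalize_nt, revcomp
from virna.errors import ConfigError, InputError
from virna.smallrna_pipeline import UniqueInsert

CATEGORIES = ("virus_sense", "virus_antisense", "host", "ambiguous", "unmapped")


@dataclass(frozen=True)
class ReferenceRecord:
    id: str
    sequence: str
    ref_class: str  # host | virus
    role: str = "unknown"  # segment role for virus records

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_nt(self.sequence))
        if self.ref_class not in {"host", "virus"}:
            raise ConfigError(f"record {self.id!r}: class must be host or virus")


@dataclass(frozen=True)
class ReferenceSet:
    records: tuple[ReferenceRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate reference ids")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True, order=True)
class Hit:
    """One perfect match: 0-based start on the + strand of a record.

    For a ``-`` strand hit the *reverse complement* of the query matches
    the + strand at ``position``.
    """

    reference_id: str
    strand: str
    position: int


@dataclass(frozen=True)
class MappedSequence:
    insert: UniqueInsert
    category: str
    hit: Optional[Hit] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InputError(f"unknown category {self.category!r}")
        has_hit = self.category in {"virus_sense", "virus_antisense", "host"}
        if (self.hit is not None) != has_hit:
            raise InputError(
                f"category {self.category} inconsistent with hit presence"
            )


class ReferenceIndex:
    """k-mer seed index over the + strands of a reference union."""

    def __init__(self, refs: ReferenceSet, k: int = 12):
        if len(refs) == 0:
            raise ConfigError("empty reference set")
        if k < 1:
            raise ConfigError("k must be positive")
        self.refs = refs
        self.k = k
        self._by_id = {r.id: r for r in refs.records}
        self._seeds: dict[str, list[tuple[int, int]]] = {}
        for ridx, rec in enumerate(refs.records):
            seq = rec.sequence
            for pos in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[pos : pos + k], []).append((ridx, pos))

    def record(self, reference_id: str) -> ReferenceRecord:
        return self._by_id[reference_id]

    def _plus_strand_occurrences(self, query: str) -> list[tuple[int, int]]:
        out = []
        for ridx, pos in self._seeds.get(query[: self.k], ()):
            rec = self.refs.records[ridx]
            if rec.sequence[pos : pos + len(query)] == query:
                out.append((ridx, pos))
        return out

    def find(self, query: str) -> list[Hit]:
        """All perfect occurrences of *query* on either strand.

        Deterministic order: record, then + strand before -, then
        position.
        """
        q = normalize_nt(query)
        if len(q) < self.k:
            raise InputError(f"query shorter than seed size k={self.k}")
        hits = []
        for ridx, pos in self._plus_strand_occurrences(q):
            hits.append((ridx, 0, pos))
        for ridx, pos in self._plus_strand_occurrences(revcomp(q)):
            hits.append((ridx, 1, pos))
        hits.sort()
        return [
            Hit(
                reference_id=self.refs.records[ridx].id,
                strand="+" if s == 0 else "-",
                position=pos,
            )
            for ridx, s, pos in hits
        ]


def build_reference_index(refs: ReferenceSet, k: int = 12) -> ReferenceIndex:
    """Build an exact-substring index over both strands of every record."""
    return ReferenceIndex(refs, k=k)


def find_exact_matches(query: str, index: ReferenceIndex) -> list[Hit]:
    return index.find(query)


def classify_sequence(insert: UniqueInsert, index: ReferenceIndex) -> MappedSequence:
    """Assign one mapping category to a unique insert (see module doc)."""
    hits = index.find(insert.sequence)
    if not hits:
        return MappedSequence(insert=insert, category="unmapped")
    if len(hits) > 1:
        return MappedSequence(insert=insert, category="ambiguous")
    hit = hits[0]
    rec = index.record(hit.reference_id)
    if rec.ref_class == "host":
        return MappedSequence(insert=insert, category="host", hit=hit)
    category = "virus_sense" if hit.strand == "+" else "virus_antisense"
    return MappedSequence(insert=insert, category=category, hit=hit)


def classify_all(
    inserts: Iterable[UniqueInsert], index: ReferenceIndex
) -> list[MappedSequence]:
    return [classify_sequence(u, index) for u in inserts]


def category_tally(mapped: Iterable[MappedSequence]) -> dict[str, int]:
    tally = {c: 0 for c in CATEGORIES}
    for m in mapped:
        tally[m.category] += 1
    return tally


def write_mapped_tsv(mapped: Iterable[MappedSequence], handle) -> None:
    """Per-insert TSV: sequence, count, category, reference, position, strand."""
    own = isinstance(handle, (str, bytes))
    fh = open(handle, "w") if own else handle
    try:
        fh.write("barcode\tsequence\tread_count\tcategory\treference_id\tposition\tstrand\n")
        for m in mapped:
            ref = m.hit.reference_id if m.hit else "."
            pos = str(m.hit.position) if m.hit else "."
            strand = m.hit.strand if m.hit else "."
            fh.write(
                f"{m.insert.barcode}\t{m.insert.sequence}\t{m.insert.read_count}"
                f"\t{m.category}\t{ref}\t{pos}\t{strand}\n"
            )
    finally:
        if own:
            fh.close()
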