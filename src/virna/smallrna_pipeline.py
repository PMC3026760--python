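"""Raw small-RNA FASTQ to collapsed unique inserts.

The processing chain mirrors how barcoded Illumina small-RNA libraries
of 18–30 nt species are handled: reads carrying a 4-nt library barcode
are demultiplexed by exact prefix match (reads with any missing base N,
or with an unrecognized prefix, are excluded), trimmed by removing the
barcode and any 3' A-tail, collapsed to unique insert sequences with
read counts, and filtered to the expected 18–30 nt size range.

Stage order is demultiplex -> trim -> filter -> collapse; the length
filter therefore applies *after* A-tail removal, so inserts trimmed
below 18 nt are dropped. The unconditional 3' A rule also removes
genuine terminal As — a known bias of this style of processing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from virna.errors import ConfigError, FormatError, InputError


@dataclass(frozen=True)
class RawRead:
    """One FASTQ record; quality scores are carried but unused."""

    read_id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FormatError(
                f"read {self.read_id!r}: sequence and quality lengths differ"
            )


@dataclass(frozen=True)
class UniqueInsert:
    """A collapsed unique insert with its read count and library barcode."""

    sequence: str
    read_count: int
    barcode: str


def parse_fastq(stream: TextIO, phred_offset: int = 33) -> Iterator[RawRead]:
    """Lazily parse 4-line FASTQ records.

    Raises :class:`FormatError` (with an approximate line number) on
    truncated or malformed records.
    """
    it = FastqGeneralIterator(stream)
    n = 0
    while True:
        try:
            title, seq, qual = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FormatError(
                f"malformed FASTQ near line {4 * n + 1}: {exc}"
            ) from exc
        n += 1
        yield RawRead(
            read_id=title.split()[0] if title else f"read{n}",
            sequence=seq.upper(),
            quality=tuple(ord(c) - phred_offset for c in qual),
        )


@dataclass
class DemuxResult:
    """Per-barcode read bins plus the exclusion tally."""

    assigned: dict[str, list[RawRead]]
    n_parsed: int
    n_excluded_n: int
    n_excluded_barcode: int

    def tally(self) -> dict[str, int]:
        return {
            "parsed": self.n_parsed,
            "assigned": sum(len(v) for v in self.assigned.values()),
            "excluded_missing_base": self.n_excluded_n,
            "excluded_unmatched_barcode": self.n_excluded_barcode,
        }


def demultiplex(reads: Iterable[RawRead], barcodes: Iterable[str]) -> DemuxResult:
    """Assign reads to libraries by exact match of the first 4 bases.

    Reads containing N anywhere are excluded (missing bases), as are
    reads whose 4-nt prefix matches no expected barcode.
    """
    bcs = list(barcodes)
    if not bcs:
        raise ConfigError("no barcodes supplied")
    for bc in bcs:
        if len(bc) != 4:
            raise ConfigError(f"barcode {bc!r} is not 4 nt")
    if len(set(bcs)) != len(bcs):
        raise ConfigError("barcodes are not pairwise distinct")

    result = DemuxResult(
        assigned={bc: [] for bc in bcs},
        n_parsed=0, n_excluded_n=0, n_excluded_barcode=0,
    )
    bcset = set(bcs)
    for read in reads:
        result.n_parsed += 1
        if "N" in read.sequence:
            result.n_excluded_n += 1
        elif read.sequence[:4] in bcset:
            result.assigned[read.sequence[:4]].append(read)
        else:
            result.n_excluded_barcode += 1
    return result


def trim_insert(read_sequence: str) -> str:
    """Remove the 4-nt barcode prefix and the maximal trailing run of A.

    May return an empty string (e.g. a pure A-tail read).
    """
    if len(read_sequence) < 4:
        raise InputError(f"read shorter than 4 nt: {read_sequence!r}")
    return read_sequence[4:].rstrip("A")


def collapse_and_filter(
    inserts: Iterable[tuple[str, str]],
    min_len: int = 18,
    max_len: int = 30,
) -> list[UniqueInsert]:
    """Collapse (barcode, insert) pairs to unique sequences with counts.

    Inserts outside the inclusive [min_len, max_len] range are dropped.
    Output order is deterministic: barcode, then sequence.
    """
    if min_len > max_len:
        raise ConfigError("min_len exceeds max_len")
    counts: dict[tuple[str, str], int] = {}
    for barcode, seq in inserts:
        if min_len <= len(seq) <= max_len:
            counts[(barcode, seq)] = counts.get((barcode, seq), 0) + 1
    return [
        UniqueInsert(sequence=seq, read_count=c, barcode=bc)
        for (bc, seq), c in sorted(counts.items())
    ]


def run_collapse_pipeline(
    stream: TextIO,
    barcodes: Iterable[str],
    min_len: int = 18,
    max_len: int = 30,
    pool: bool = False,
) -> tuple[list[UniqueInsert], dict[str, int]]:
    """Full chain: parse, demultiplex, trim, filter, collapse.

    With ``pool`` the barcode libraries are merged before collapsing
    (the collapsed records then carry barcode ``*``). Returns the
    collapsed inserts and a read-conservation tally.
    """
    demux = demultiplex(parse_fastq(stream), barcodes)
    pairs = [
        ("*" if pool else bc, trim_insert(read.sequence))
        for bc, reads in demux.assigned.items()
        for read in reads
    ]
    collapsed = collapse_and_filter(pairs, min_len=min_len, max_len=max_len)
    tally = demux.tally()
    tally["in_range"] = sum(u.read_count for u in collapsed)
    tally["out_of_range"] = tally["assigned"] - tally["in_range"]
    return collapsed, tally


def write_collapsed_tsv(inserts: Iterable[UniqueInsert], handle) -> None:
    """Write the collapsed table: barcode, sequence, length, read_count."""
    own = isinstance(handle, (str, bytes))
    fh = open(handle, "w") if own else handle
    try:
        fh.write("barcode\tsequence\tlength\tread_count\n")
        for u in inserts:
            fh.write(f"{u.barcode}\t{u.sequence}\t{len(u.sequence)}\t{u.read_count}\n")
    finally:
        if own:
            fh.close()


def read_collapsed_tsv(handle) -> list[UniqueInsert]:
    """Read a collapsed table written by :func:`write_collapsed_tsv`."""
    own = isinstance(handle, (str, bytes))
    fh = open(handle) if own else handle
    try:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["barcode", "sequence"]:
            raise FormatError("not a collapsed-insert TSV (bad header)")
        out = []
        for line in fh:
            bc, seq, _length, count = line.rstrip("\n").split("\t")
            out.append(UniqueInsert(sequence=seq, read_count=int(count), barcode=bc))
        return out
    finally:
        if own:
            fh.close()
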