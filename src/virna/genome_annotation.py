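"""Viral segment representation, ORF scanning and bipartite genome
organization.

Nodavirus-like genomes consist of two positive-sense RNA segments:
RNA1 (~3.1 kb in classical nodaviruses) encodes the RNA-dependent RNA
polymerase (RdRP), often with a B2 RNAi-suppressor ORF overlapping the
RdRP C-terminus in the +1 reading frame; RNA2 (~1.4 kb) carries a single
5' capsid ORF. The *Caenorhabditis* viruses deviate from this plan: no
B2-like ORF on RNA1 and an extra 3' ORF ("ORF delta") on an oversized
RNA2. This module detects all of those features.

Conventions
-----------
* ORF = first ATG after the previous in-frame stop, through the next
  in-frame stop (alternative internal starts are not reported).
* Coordinates are 0-based half-open on the + strand internally; text
  reports use 1-based closed coordinates.
* ``frame`` is the offset (0/1/2) of the ORF start on its own reading
  strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio import SeqIO

from virna._seq import normalize_nt, revcomp, translate_codons
from virna.errors import AlphabetError, ConsistencyError, InputError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Classical nodavirus RNA2 length convention (nt).
RNA2_CONVENTION_NT = 1400


def translate(nt: str, require_triplet: bool = True) -> str:
    """Translate a nucleotide string with the standard genetic code.

    Stop codons yield ``*``. With ``require_triplet`` a non-triplet
    length is an error; otherwise the trailing partial codon is ignored.
    """
    s = normalize_nt(nt)
    if len(s) % 3:
        if require_triplet:
            raise InputError(f"length {len(s)} is not a multiple of 3")
        s = s[: len(s) - len(s) % 3]
    return translate_codons(s)


@dataclass(frozen=True)
class ViralSegment:
    """A named viral nucleotide sequence with an optional segment role."""

    id: str
    sequence: str
    role: str = "unknown"  # RNA1 | RNA2 | unknown

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"segment {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", normalize_nt(self.sequence))
        if self.role not in {"RNA1", "RNA2", "unknown"}:
            raise InputError(f"segment {self.id!r}: invalid role {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "ViralSegment":
        return replace(self, sequence=revcomp(self.sequence))


@dataclass(frozen=True)
class OrfCall:
    """A predicted open reading frame.

    ``start``/``end`` are 0-based half-open on the + strand; for
    ``-`` strand calls the reading direction is right-to-left, so the
    initiator ATG sits at ``end`` and the stop at ``start``.
    ``aa_length`` excludes the stop codon; ``protein`` starts with M for
    complete calls. ``partial_3prime`` marks ATG-initiated runs that hit
    the sequence end with no in-frame stop.
    """

    segment_id: str
    strand: str
    frame: int
    start: int
    end: int
    aa_length: int
    protein: str
    partial_3prime: bool = False

    @property
    def nt_length(self) -> int:
        return self.end - self.start


def _scan_strand(
    seq: str, segment_id: str, strand: str, min_aa: int, allow_partial: bool
) -> list[OrfCall]:
    """Scan the given reading strand (``seq`` already oriented 5'->3')."""
    n = len(seq)
    calls: list[OrfCall] = []
    for frame in range(3):
        start_codon: Optional[int] = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if start_codon is not None:
                    aa = (pos - start_codon) // 3
                    if aa >= min_aa:
                        calls.append(
                            _make_call(
                                seq, segment_id, strand, frame,
                                start_codon, pos + 3, partial=False,
                            )
                        )
                    start_codon = None
            elif codon == "ATG" and start_codon is None:
                start_codon = pos
        if start_codon is not None and allow_partial:
            end = start_codon + 3 * ((n - start_codon) // 3)
            aa = (end - start_codon) // 3
            if aa >= min_aa and aa > 0:
                calls.append(
                    _make_call(
                        seq, segment_id, strand, frame,
                        start_codon, end, partial=True,
                    )
                )
    return calls


def _make_call(
    seq: str, segment_id: str, strand: str, frame: int,
    start: int, end: int, partial: bool,
) -> OrfCall:
    protein = translate_codons(seq[start:end])
    if not partial:
        protein = protein[:-1]  # drop terminator
    aa = len(protein)
    if strand == "-":
        n = len(seq)
        start, end = n - end, n - start
    return OrfCall(
        segment_id=segment_id, strand=strand, frame=frame,
        start=start, end=end, aa_length=aa, protein=protein,
        partial_3prime=partial,
    )


def scan_orfs(
    segment: ViralSegment,
    min_aa: int = 0,
    allow_partial: bool = False,
    both_strands: bool = True,
) -> list[OrfCall]:
    """Predict ORFs (ATG to in-frame stop) with >= *min_aa* amino acids.

    Returns one call per (strand, frame, stop) region — the maximal run
    from the first ATG — sorted by + strand start coordinate.
    """
    if min_aa < 0:
        raise InputError("min_aa must be >= 0")
    if not segment.sequence:
        raise InputError("empty sequence")
    calls = _scan_strand(segment.sequence, segment.id, "+", min_aa, allow_partial)
    if both_strands:
        calls += _scan_strand(
            revcomp(segment.sequence), segment.id, "-", min_aa, allow_partial
        )
    return sorted(calls, key=lambda c: (c.start, c.end, c.strand))


def find_overlapping_plus1_orf(
    orfs: Iterable[OrfCall],
    anchor: OrfCall,
    min_aa: int = 0,
    cterm_window: int = 300,
) -> Optional[OrfCall]:
    """Longest + strand ORF in frame (anchor.frame + 1) mod 3 whose span
    intersects the final *cterm_window* nt of the anchor.

    This is the search pattern of nodavirus B2 proteins, which overlap
    the RdRP C-terminus in the +1 frame. Returns ``None`` when nothing
    qualifies.
    """
    if anchor.strand != "+":
        raise InputError("anchor must be on the + strand")
    if cterm_window > anchor.nt_length:
        raise InputError("cterm_window exceeds anchor length")
    window_start = anchor.end - cterm_window
    target_frame = (anchor.frame + 1) % 3
    best: Optional[OrfCall] = None
    for orf in orfs:
        if orf.strand != "+" or orf.frame != target_frame:
            continue
        if orf.segment_id != anchor.segment_id:
            raise ConsistencyError(
                f"ORF on segment {orf.segment_id!r} scanned against anchor "
                f"on {anchor.segment_id!r}"
            )
        if orf.aa_length < min_aa:
            continue
        if orf.end > window_start and orf.start < anchor.end:
            if best is None or orf.aa_length > best.aa_length:
                best = orf
    return best


@dataclass
class OrganizationReport:
    """Bipartite genome organization relative to nodavirus conventions."""

    segments: dict[str, str]  # segment id -> assigned role
    orfs: dict[str, list[OrfCall]]  # segment id -> ORF calls
    rdrp_candidate: Optional[OrfCall] = None
    b2_like: Optional[OrfCall] = None
    capsid_candidate: Optional[OrfCall] = None
    orf_delta_candidate: Optional[OrfCall] = None
    rna2_oversize: bool = False
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def orf_dict(o: Optional[OrfCall]) -> Optional[dict]:
            if o is None:
                return None
            d = o.__dict__.copy()
            d.pop("protein")
            return d

        return {
            "segment_roles": self.segments,
            "orf_table": [
                orf_dict(o) for calls in self.orfs.values() for o in calls
            ],
            "rdrp": orf_dict(self.rdrp_candidate),
            "b2_like": orf_dict(self.b2_like),
            "orf_delta": orf_dict(self.orf_delta_candidate),
            "capsid": orf_dict(self.capsid_candidate),
            "rna2_oversize": self.rna2_oversize,
            "warnings": self.warnings,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _longest(orfs: Iterable[OrfCall]) -> Optional[OrfCall]:
    best = None
    for o in orfs:
        if best is None or o.aa_length > best.aa_length:
            best = o
    return best


def classify_organization(
    segments: list[ViralSegment],
    min_aa: int = 50,
    *,
    cterm_window: int = 300,
    rna2_convention: int = RNA2_CONVENTION_NT,
    oversize_margin: int = 500,
    allow_partial: bool = True,
) -> OrganizationReport:
    """Assign RNA1/RNA2 roles and annotate RdRP, capsid, B2-like and
    ORF-delta candidates.

    Role assignment: the segment carrying the longest + strand ORF is
    RNA1 (the polymerase segment); pre-assigned roles on the inputs are
    respected. ``rna2_oversize`` flags an RNA2 exceeding the classical
    ~1.4 kb convention by at least *oversize_margin* nt.
    """
    if not 1 <= len(segments) <= 2:
        raise InputError(f"expected 1-2 segments, got {len(segments)}")

    orfs = {
        s.id: [
            o
            for o in scan_orfs(s, min_aa=min_aa, allow_partial=allow_partial)
            if o.strand == "+"
        ]
        for s in segments
    }
    report = OrganizationReport(segments={}, orfs=orfs)
    if not any(orfs.values()):
        report.warnings.append(f"no ORF with >= {min_aa} aa on any segment")
        report.segments = {s.id: s.role for s in segments}
        return report

    # Role assignment.
    by_id = {s.id: s for s in segments}
    preassigned = {s.id: s.role for s in segments if s.role != "unknown"}
    if len(preassigned) == len(segments) and len(set(preassigned.values())) == len(
        segments
    ):
        roles = preassigned
    else:
        longest_per_seg = {sid: _longest(calls) for sid, calls in orfs.items()}
        rna1_id = max(
            (sid for sid, o in longest_per_seg.items() if o is not None),
            key=lambda sid: longest_per_seg[sid].aa_length,
        )
        roles = {
            sid: ("RNA1" if sid == rna1_id else "RNA2") for sid in by_id
        }
    report.segments = roles

    rna1_id = next((sid for sid, r in roles.items() if r == "RNA1"), None)
    rna2_id = next((sid for sid, r in roles.items() if r == "RNA2"), None)

    if rna1_id is not None and orfs[rna1_id]:
        report.rdrp_candidate = _longest(orfs[rna1_id])
        window = min(cterm_window, report.rdrp_candidate.nt_length)
        report.b2_like = find_overlapping_plus1_orf(
            [o for o in orfs[rna1_id] if o is not report.rdrp_candidate],
            report.rdrp_candidate,
            min_aa=min_aa,
            cterm_window=window,
        )

    if rna2_id is not None:
        rna2 = by_id[rna2_id]
        half = len(rna2) / 2
        report.capsid_candidate = _longest(
            o for o in orfs[rna2_id] if o.start < half
        )
        cap = report.capsid_candidate
        if cap is not None:
            report.orf_delta_candidate = _longest(
                o
                for o in orfs[rna2_id]
                if o is not cap and o.start > cap.start and o.end > cap.end
            )
        report.rna2_oversize = len(rna2) >= rna2_convention + oversize_margin

    return report


def read_segments(path, fmt: str = "fasta") -> list[ViralSegment]:
    """Load viral segments from FASTA or GenBank flat files.

    Roles are inferred from record descriptions containing "RNA1"/"RNA2"
    (case-insensitive, optional space) when present.
    """
    segments = []
    for rec in SeqIO.parse(path, fmt):
        desc = rec.description.upper().replace(" ", "")
        role = "unknown"
        if "RNA1" in desc:
            role = "RNA1"
        elif "RNA2" in desc:
            role = "RNA2"
        segments.append(ViralSegment(id=rec.id, sequence=str(rec.seq), role=role))
    if not segments:
        raise InputError(f"no records in {path}")
    return segments


def write_segments_fasta(segments: Iterable[ViralSegment], handle) -> None:
    """Write segments as 60-column wrapped FASTA."""
    own = isinstance(handle, (str, bytes))
    fh = open(handle, "w") if own else handle
    try:
        for s in segments:
            fh.write(f">{s.id} {s.role}\n")
            for i in range(0, len(s.sequence), 60):
                fh.write(s.sequence[i : i + 60] + "\n")
    finally:
        if own:
            fh.close()
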