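"""End-to-end convenience chain: FASTQ -> collapsed inserts -> mapping
-> profiles and signature summary."""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Optional

from virna.exact_mapper import (
    MappedSequence,
    ReferenceIndex,
    ReferenceRecord,
    ReferenceSet,
    category_tally,
    classify_all,
)
from virna.genome_annotation import ViralSegment
from virna.smallrna_pipeline import UniqueInsert, run_collapse_pipeline
from virna.virna_profile import (
    LengthNucMatrix,
    SignatureSummary,
    VirnaProfile,
    length_firstnt_matrix,
    position_profile,
    signature_summary,
)


@dataclass
class PipelineResult:
    collapsed: list[UniqueInsert]
    tally: dict[str, int]
    mapped: list[MappedSequence]
    category_tally: dict[str, int]
    profiles: list[VirnaProfile]
    sense_matrix: LengthNucMatrix
    antisense_matrix: LengthNucMatrix
    summary: SignatureSummary


def build_union_index(
    virus_segments: Iterable[ViralSegment],
    host: Optional[str] = None,
    host_id: str = "host",
    k: int = 12,
) -> ReferenceIndex:
    records = [
        ReferenceRecord(id=s.id, sequence=s.sequence, ref_class="virus", role=s.role)
        for s in virus_segments
    ]
    if host is not None:
        records.append(ReferenceRecord(id=host_id, sequence=host, ref_class="host"))
    return ReferenceIndex(ReferenceSet(records=tuple(records)), k=k)


def run_library(
    fastq_text: str,
    barcodes: Iterable[str],
    virus_segments: list[ViralSegment],
    host: Optional[str] = None,
    host_id: str = "host",
    min_len: int = 18,
    max_len: int = 30,
) -> PipelineResult:
    """Process one FASTQ through the whole viRNA chain."""
    collapsed, tally = run_collapse_pipeline(
        io.StringIO(fastq_text), barcodes, min_len=min_len, max_len=max_len
    )
    index = build_union_index(virus_segments, host=host, host_id=host_id)
    mapped = classify_all(collapsed, index)
    profiles = [
        position_profile(mapped, s.id, len(s)) for s in virus_segments
    ]
    return PipelineResult(
        collapsed=collapsed,
        tally=tally,
        mapped=mapped,
        category_tally=category_tally(mapped),
        profiles=profiles,
        sense_matrix=length_firstnt_matrix(mapped, "sense"),
        antisense_matrix=length_firstnt_matrix(mapped, "antisense"),
        summary=signature_summary(mapped),
    )
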