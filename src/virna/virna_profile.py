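"""Per-position viRNA profiles and the 22G antisense signature.

In *C. elegans*, an antiviral RNAi response produces virus-derived
small RNAs whose antisense species resemble 22G RNAs: mostly 22 nt with
a 5' guanosine bias. This module builds per-position sense/antisense
coverage profiles of unique sequences along each viral segment, the
length x first-nucleotide signature matrices, and a summary that flags
the 22G signature.

All counting is in units of *unique sequences* by default (every
distinct sequence contributes 1 regardless of read depth); a
read-weighted mode is available. Per-position counting uses full
coverage (each covered reference position is incremented); a 5'-end
mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from virna.errors import ConsistencyError, InputError
from virna.exact_mapper import MappedSequence

LENGTH_RANGE = range(18, 31)
RNA_BASES = ("A", "C", "G", "U")


@dataclass
class VirnaProfile:
    """Unique-sequence counts per reference position, by orientation."""

    segment_id: str
    sense_counts: np.ndarray
    antisense_counts: np.ndarray

    def __post_init__(self) -> None:
        if self.sense_counts.shape != self.antisense_counts.shape:
            raise InputError("sense/antisense vectors differ in length")


@dataclass
class LengthNucMatrix:
    """Unique-sequence counts by (length 18..30, first nucleotide A/C/G/U).

    First nucleotides are reported in the RNA alphabet (U for T).
    """

    orientation: str
    counts: np.ndarray  # shape (13, 4)

    def __getitem__(self, key: tuple[int, str]) -> int:
        length, base = key
        return int(self.counts[length - LENGTH_RANGE.start, RNA_BASES.index(base)])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def length_marginal(self) -> dict[int, int]:
        return {
            l: int(self.counts[i].sum()) for i, l in enumerate(LENGTH_RANGE)
        }

    def base_marginal(self) -> dict[str, int]:
        return {
            b: int(self.counts[:, j].sum()) for j, b in enumerate(RNA_BASES)
        }


@dataclass
class SignatureSummary:
    """Library-level summary of the viral small-RNA signature."""

    n_unique_virus_sense: int
    n_unique_virus_antisense: int
    n_unique_unambiguous_total: int
    viral_fraction: float
    antisense_modal_length: Optional[int]
    antisense_fraction_len22: Optional[float]
    antisense_fraction_5primeG: Optional[float]
    sense_fraction_5primeG: Optional[float]
    flag_22G: bool
    undefined_antisense_fields: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _weights(mapped: Iterable[MappedSequence], read_weighted: bool):
    for m in mapped:
        yield m, (m.insert.read_count if read_weighted else 1)


def position_profile(
    mapped: Iterable[MappedSequence],
    segment_id: str,
    segment_length: int,
    *,
    mode: str = "coverage",
    read_weighted: bool = False,
) -> VirnaProfile:
    """Accumulate per-position counts along one viral segment.

    ``mode="coverage"`` increments every reference position covered by
    a sequence; ``mode="five_prime"`` increments only the position of
    the sequence's 5' end (leftmost reference position for sense hits,
    rightmost for antisense).
    """
    if mode not in {"coverage", "five_prime"}:
        raise InputError(f"unknown mode {mode!r}")
    sense = np.zeros(segment_length, dtype=np.int64)
    anti = np.zeros(segment_length, dtype=np.int64)
    for m, w in _weights(mapped, read_weighted):
        if m.category not in {"virus_sense", "virus_antisense"}:
            continue
        if m.hit.reference_id != segment_id:
            continue
        start, span = m.hit.position, len(m.insert.sequence)
        if start < 0 or start + span > segment_length:
            raise ConsistencyError(
                f"hit at {start}+{span} outside segment {segment_id!r} "
                f"of length {segment_length}"
            )
        vec = sense if m.category == "virus_sense" else anti
        if mode == "coverage":
            vec[start : start + span] += w
        else:
            five_prime = start if m.category == "virus_sense" else start + span - 1
            vec[five_prime] += w
    return VirnaProfile(segment_id=segment_id, sense_counts=sense, antisense_counts=anti)


def length_firstnt_matrix(
    mapped: Iterable[MappedSequence],
    orientation: str,
    *,
    read_weighted: bool = False,
) -> LengthNucMatrix:
    """Tabulate (length, first nucleotide) over one orientation's
    unique sequences. The first nucleotide is the 5' base of the small
    RNA itself (as sequenced), reported as U for T.
    """
    if orientation not in {"sense", "antisense"}:
        raise InputError("orientation must be sense or antisense")
    category = "virus_sense" if orientation == "sense" else "virus_antisense"
    counts = np.zeros((len(LENGTH_RANGE), len(RNA_BASES)), dtype=np.int64)
    for m, w in _weights(mapped, read_weighted):
        if m.category != category:
            continue
        seq = m.insert.sequence
        if len(seq) not in LENGTH_RANGE:
            raise ConsistencyError(
                f"insert length {len(seq)} outside the 18-30 nt range"
            )
        base = "U" if seq[0] == "T" else seq[0]
        counts[len(seq) - LENGTH_RANGE.start, RNA_BASES.index(base)] += w
    return LengthNucMatrix(orientation=orientation, counts=counts)


def signature_summary(mapped: Iterable[MappedSequence]) -> SignatureSummary:
    """Summarize the viral signature over all mapped unique sequences.

    ``viral_fraction`` is (sense + antisense viral uniques) over all
    unambiguously mapped uniques (viral + host; ambiguous and unmapped
    excluded). ``flag_22G`` is set when the antisense modal length is
    22 nt *and* G is the modal antisense first base. With zero antisense
    sequences the modal fields are None and flagged undefined.
    """
    mapped = list(mapped)
    n_sense = sum(1 for m in mapped if m.category == "virus_sense")
    n_anti = sum(1 for m in mapped if m.category == "virus_antisense")
    n_host = sum(1 for m in mapped if m.category == "host")
    n_unamb = n_sense + n_anti + n_host

    viral_fraction = (n_sense + n_anti) / n_unamb if n_unamb else 0.0

    sense_m = length_firstnt_matrix(mapped, "sense")
    anti_m = length_firstnt_matrix(mapped, "antisense")

    sense_g = (
        sense_m.base_marginal()["G"] / n_sense if n_sense else None
    )
    if n_anti:
        lmarg, bmarg = anti_m.length_marginal(), anti_m.base_marginal()
        modal_length = max(lmarg, key=lambda l: (lmarg[l], -l))
        modal_base = max(bmarg, key=lambda b: bmarg[b])
        frac22 = lmarg[22] / n_anti
        frac_g = bmarg["G"] / n_anti
        flag = modal_length == 22 and modal_base == "G"
        undefined = False
    else:
        modal_length, frac22, frac_g = None, None, None
        flag, undefined = False, True

    return SignatureSummary(
        n_unique_virus_sense=n_sense,
        n_unique_virus_antisense=n_anti,
        n_unique_unambiguous_total=n_unamb,
        viral_fraction=viral_fraction,
        antisense_modal_length=modal_length,
        antisense_fraction_len22=frac22,
        antisense_fraction_5primeG=frac_g,
        sense_fraction_5primeG=sense_g,
        flag_22G=flag,
        undefined_antisense_fields=undefined,
    )


def write_profile_tsv(profiles: Iterable[VirnaProfile], handle) -> None:
    """Profile TSV: segment, position (0-based), sense, antisense."""
    own = isinstance(handle, (str, bytes))
    fh = open(handle, "w") if own else handle
    try:
        fh.write("segment\tposition\tsense\tantisense\n")
        for p in profiles:
            for i in range(len(p.sense_counts)):
                fh.write(
                    f"{p.segment_id}\t{i}\t{p.sense_counts[i]}\t{p.antisense_counts[i]}\n"
                )
    finally:
        if own:
            fh.close()


def write_matrix_tsv(matrix: LengthNucMatrix, handle) -> None:
    own = isinstance(handle, (str, bytes))
    fh = open(handle, "w") if own else handle
    try:
        fh.write("length\t" + "\t".join(RNA_BASES) + "\n")
        for i, l in enumerate(LENGTH_RANGE):
            fh.write(f"{l}\t" + "\t".join(str(int(c)) for c in matrix.counts[i]) + "\n")
    finally:
        if own:
            fh.close()


def plot_signature(
    profiles: list[VirnaProfile],
    sense_matrix: LengthNucMatrix,
    antisense_matrix: LengthNucMatrix,
    path,
) -> None:
    """Figure with per-segment coverage tracks (sense up, antisense
    down) and length x first-base bars per orientation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(profiles)
    fig, axes = plt.subplots(n + 1, 1, figsize=(8, 3 * (n + 1)))
    axes = np.atleast_1d(axes)
    for ax, p in zip(axes[:n], profiles):
        x = np.arange(len(p.sense_counts))
        ax.fill_between(x, p.sense_counts, step="mid", color="tab:blue", label="sense")
        ax.fill_between(
            x, -p.antisense_counts, step="mid", color="tab:red", label="antisense"
        )
        ax.set_title(p.segment_id)
        ax.set_ylabel("unique sequences")
        ax.legend(loc="upper right", fontsize=8)
    ax = axes[n]
    lengths = list(LENGTH_RANGE)
    bottom_s = np.zeros(len(lengths))
    bottom_a = np.zeros(len(lengths))
    width = 0.4
    colors = dict(zip(RNA_BASES, ["#4daf4a", "#377eb8", "#e41a1c", "#984ea3"]))
    for j, b in enumerate(RNA_BASES):
        s = sense_matrix.counts[:, j].astype(float)
        a = antisense_matrix.counts[:, j].astype(float)
        ax.bar(np.array(lengths) - width / 2, s, width, bottom=bottom_s,
               color=colors[b], label=f"5' {b}")
        ax.bar(np.array(lengths) + width / 2, -a, width, bottom=-bottom_a,
               color=colors[b])
        bottom_s += s
        bottom_a += a
    ax.set_xlabel("length (nt); sense up / antisense down")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
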