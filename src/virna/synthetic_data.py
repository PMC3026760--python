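"""Synthetic genomes, host stand-ins, small-RNA libraries and symptom
tables with full truth records.

The generator emulates the statistical structure the analysis modules
assume, at desk scale:

* bipartite genomes — RNA1 with a long planted ORF (RdRP surrogate)
  and, optionally, a +1-frame ORF overlapping its 3' end (B2
  surrogate); RNA2 with a 5' ORF (capsid surrogate) and, optionally, a
  downstream 3' ORF (ORF-delta surrogate); uniform-random background;
* a host stand-in: uniform-random sequence rejection-sampled to share
  no >= 18-mer with the viral segments, so planted-read classification
  is unambiguous;
* small-RNA libraries: reads = 4-nt barcode + insert + optional 3'
  A-tail; antisense viral inserts are reverse complements of genome
  windows, concentrated at 22 nt with a 5' G probability enforced by
  window shifting (reads stay exact genome substrings); sense viral
  inserts have broad uniform 18-30 nt lengths and no 5' preference;
  host background inserts; junk reads exercising barcode/N exclusion.

Every emitted insert is guaranteed unique in the library and uniquely
mappable in the host+virus union (enforced by rejection against an
exact-match index), inserts never end in A (so the unconditional 3'
A-trim removes only the planted artifact tails), and unplanned ORFs
that would collide with the B2/delta detection rules are scrubbed from
the genome background. All outputs are pure functions of the config,
seed included.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from virna._seq import revcomp
from virna.errors import ConfigError, GenerationError
from virna.exact_mapper import ReferenceIndex, ReferenceRecord, ReferenceSet
from virna.genome_annotation import STOP_CODONS, ViralSegment, scan_orfs
from virna.infection_stats import ContingencyTable2x2

BASES = "ACGT"
_NONSTOP = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulator; the seed fixes every draw."""

    seed: int = 0
    # genome geometry (nt / aa)
    rna1_length: int = 3600
    rna2_length: int = 2650
    rdrp_aa: int = 950
    capsid_aa: int = 380
    b2_aa: int = 100
    delta_aa: int = 300
    b2_overlap_nt: int = 150
    plant_b2: bool = False
    plant_delta: bool = True
    min_orf_aa: int = 50  # detection threshold the scrubber honours
    host_length: int = 50_000
    # library composition (unique inserts)
    n_antisense: int = 400
    n_sense: int = 200
    n_host: int = 29_400
    n_control_viral: int = 0
    n_junk: int = 50
    antisense_spill: float = 0.2  # prob of 21/23 nt instead of 22
    p_5primeG_antisense: float = 0.5
    p_a_tail: float = 0.2
    read_count_geom_p: float = 0.5
    barcodes: tuple[str, ...] = ("ACGT", "TGCA", "GATC", "CTAG")

    def __post_init__(self) -> None:
        for p in (
            self.antisense_spill, self.p_5primeG_antisense,
            self.p_a_tail, self.read_count_geom_p,
        ):
            if not 0 <= p <= 1:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if min(self.rna1_length, self.rna2_length, self.host_length) <= 0:
            raise ConfigError("lengths must be positive")


@dataclass(frozen=True)
class PlantedOrf:
    start: int
    end: int  # 0-based half-open, + strand
    frame: int

    @property
    def aa_length(self) -> int:
        return (self.end - self.start) // 3 - 1


@dataclass
class GenomeTruth:
    rdrp: PlantedOrf
    capsid: PlantedOrf
    b2: Optional[PlantedOrf]
    delta: Optional[PlantedOrf]


@dataclass(frozen=True)
class InsertTruth:
    sequence: str
    origin: str  # virus | host
    orientation: str  # sense | antisense
    reference_id: str
    position: int
    read_count: int
    barcode: str
    expected_category: str

    @property
    def first_base(self) -> str:
        return "U" if self.sequence[0] == "T" else self.sequence[0]


@dataclass
class LibraryTruth:
    library: str
    barcode: str
    inserts: list[InsertTruth]
    n_junk_n: int
    n_junk_barcode: int

    def n_unique(self, expected_category: Optional[str] = None) -> int:
        if expected_category is None:
            return len(self.inserts)
        return sum(
            1 for t in self.inserts if t.expected_category == expected_category
        )

    @property
    def viral_fraction(self) -> float:
        n_virus = sum(1 for t in self.inserts if t.origin == "virus")
        return n_virus / len(self.inserts) if self.inserts else 0.0

    def coverage_truth(self, reference_id: str, length: int):
        """Expected (sense, antisense) coverage vectors for a segment."""
        sense = np.zeros(length, dtype=np.int64)
        anti = np.zeros(length, dtype=np.int64)
        for t in self.inserts:
            if t.reference_id != reference_id or t.origin != "virus":
                continue
            vec = sense if t.orientation == "sense" else anti
            vec[t.position : t.position + len(t.sequence)] += 1
        return sense, anti


# ---------------------------------------------------------------------------
# genome construction


class _SeqBuilder:
    """Mutable sequence with fixed positions and planted reading frames
    whose in-frame codons must stay stop-free."""

    def __init__(self, length: int, rng: np.random.Generator):
        self.seq = list(rng.choice(list(BASES), size=length))
        self.fixed: set[int] = set()
        self.frames: list[PlantedOrf] = []  # stop-free codon regions

    def text(self) -> str:
        return "".join(self.seq)

    def write_fixed(self, pos: int, s: str) -> None:
        for i, ch in enumerate(s):
            self.seq[pos + i] = ch
            self.fixed.add(pos + i)

    def plant_orf(self, orf: PlantedOrf, rng: np.random.Generator) -> None:
        """ATG + non-stop codons + stop; interior codons resampled from
        the non-stop codon table, ATG/stop marked fixed."""
        self.write_fixed(orf.start, "ATG")
        for p in range(orf.start + 3, orf.end - 3, 3):
            self._write_codon_nonstop(p, rng)
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
        self.write_fixed(orf.end - 3, stop)
        # the body (minus ATG/stop) stays editable but this frame region
        # must remain stop-free under any later edit
        self.frames.append(orf)

    def _write_codon_nonstop(self, pos: int, rng: np.random.Generator) -> None:
        codon = _NONSTOP[int(rng.integers(len(_NONSTOP)))]
        for i in range(3):
            self.seq[pos + i] = codon[i]

    def _frame_ok(self, lo: int, hi: int) -> bool:
        """All planted-frame body codons overlapping [lo, hi) are
        non-stop (the region's own terminal stop codon is exempt)."""
        for reg in self.frames:
            if hi <= reg.start or lo >= reg.end - 3:
                continue
            first = reg.start + 3 * ((max(lo, reg.start) - reg.start) // 3)
            for p in range(first, min(hi, reg.end - 3), 3):
                if "".join(self.seq[p : p + 3]) in STOP_CODONS:
                    return False
        return True

    def resample(self, lo: int, hi: int, rng: np.random.Generator, ok) -> None:
        """Resample free positions in [lo, hi) until planted frames stay
        stop-free and the predicate *ok* holds."""
        free = [p for p in range(lo, hi) if p not in self.fixed]
        if not free:
            raise GenerationError(
                f"cannot edit fully fixed window [{lo}, {hi})"
            )
        saved = [self.seq[p] for p in free]
        for _ in range(2000):
            for p in free:
                self.seq[p] = BASES[int(rng.integers(4))]
            if self._frame_ok(lo, hi) and ok():
                return
        for p, ch in zip(free, saved):
            self.seq[p] = ch
        raise GenerationError(f"resampling failed in window [{lo}, {hi})")

    def kill_atg(self, pos: int, frame: int, rng: np.random.Generator) -> None:
        """Remove the ATG at *pos* (known to sit in reading offset
        *frame*) without breaking planted frames."""
        self.resample(
            pos, pos + 3, rng,
            ok=lambda: "".join(self.seq[pos : pos + 3]) != "ATG",
        )

    def clear_frame_stops(
        self, lo: int, hi: int, frame: int, rng: np.random.Generator
    ) -> None:
        """Remove stop codons read in offset *frame* within [lo, hi)."""
        for _ in range(2000):
            first = lo + ((frame - lo) % 3)
            bad = None
            for p in range(first, hi - 2, 3):
                if "".join(self.seq[p : p + 3]) in STOP_CODONS:
                    bad = p
                    break
            if bad is None:
                return
            self.resample(
                bad, bad + 3, rng,
                ok=lambda: "".join(self.seq[bad : bad + 3]) not in STOP_CODONS,
            )
        raise GenerationError("could not clear reading-frame stops")


def _scrub_orfs(
    builder: _SeqBuilder,
    segment_id: str,
    offending,
    min_aa: int,
    rng: np.random.Generator,
) -> None:
    """Repeatedly rescan and kill the start ATG of every + strand ORF
    (>= min_aa aa, partials included) for which *offending* is true."""
    for _ in range(500):
        seg = ViralSegment(id=segment_id, sequence=builder.text())
        calls = [
            o
            for o in scan_orfs(seg, min_aa=min_aa, allow_partial=True,
                               both_strands=False)
            if offending(o)
        ]
        if not calls:
            return
        orf = calls[0]
        builder.kill_atg(orf.start, orf.frame, rng)
    raise GenerationError("ORF scrubbing did not converge")


def simulate_viral_genome(cfg: SimConfig) -> tuple[list[ViralSegment], GenomeTruth]:
    """Generate the RNA1/RNA2 segment pair and its planted-ORF truth."""
    rng = np.random.default_rng([cfg.seed, 101])

    # --- RNA1: RdRP surrogate (+ optional overlapping B2 surrogate)
    rdrp_start = 30 + int(rng.integers(3))
    rdrp_end = rdrp_start + 3 * (cfg.rdrp_aa + 1)
    b2_span = 3 * (cfg.b2_aa + 1)
    tail_needed = (
        max(0, b2_span - cfg.b2_overlap_nt) if cfg.plant_b2 else 0
    )
    if rdrp_end + tail_needed + 30 > cfg.rna1_length:
        raise ConfigError("infeasible geometry: RNA1 too short for planted ORFs")
    if cfg.plant_b2 and not 3 < cfg.b2_overlap_nt < rdrp_end - rdrp_start:
        raise ConfigError("infeasible geometry: bad B2 overlap")

    b1 = _SeqBuilder(cfg.rna1_length, rng)
    rdrp = PlantedOrf(rdrp_start, rdrp_end, rdrp_start % 3)
    b1.plant_orf(rdrp, rng)

    b2_truth: Optional[PlantedOrf] = None
    if cfg.plant_b2:
        b2_start = rdrp_end - cfg.b2_overlap_nt
        b2_start -= (b2_start - rdrp_start - 1) % 3  # frame = rdrp + 1
        b2_end = b2_start + b2_span
        b2_truth = PlantedOrf(b2_start, b2_end, b2_start % 3)
        # Plant only the B2 ATG and stop directly (neither can create an
        # RdRP-frame stop), then clear B2-frame stops from the body by
        # constrained resampling so the overlapped RdRP frame survives.
        b1.write_fixed(b2_start, "ATG")
        b1.write_fixed(b2_end - 3, ("TAA", "TAG", "TGA")[int(rng.integers(3))])
        b1.frames.append(b2_truth)
        b1.clear_frame_stops(b2_start + 3, b2_end - 3, b2_start % 3, rng)

    window_start = rdrp_end - min(300, rdrp_end - rdrp_start)
    b2_frame = (rdrp.frame + 1) % 3

    def b2_offender(o) -> bool:
        if o.strand != "+":
            return False
        # upstream in-frame ATG extending the detected RdRP 5' of truth
        if o.frame == rdrp.frame and o.end == rdrp.end and o.start < rdrp.start:
            return True
        if o.frame != b2_frame:
            return False
        if b2_truth is not None and o.start >= b2_truth.start:
            return False  # the planted B2 itself (or its tail)
        return o.end > window_start and o.start < rdrp_end

    _scrub_orfs(b1, "RNA1_sim", b2_offender, cfg.min_orf_aa, rng)

    # --- RNA2: capsid surrogate (+ optional downstream delta surrogate)
    cap_start = 24 + int(rng.integers(3))
    cap_end = cap_start + 3 * (cfg.capsid_aa + 1)
    if cap_start >= cfg.rna2_length / 2:
        raise ConfigError("infeasible geometry: capsid start beyond 5' half")
    delta_span = 3 * (cfg.delta_aa + 1)
    if cfg.plant_delta and cap_end + 30 + delta_span + 10 > cfg.rna2_length:
        raise ConfigError("infeasible geometry: RNA2 too short for ORF delta")

    b2b = _SeqBuilder(cfg.rna2_length, rng)
    capsid = PlantedOrf(cap_start, cap_end, cap_start % 3)
    b2b.plant_orf(capsid, rng)

    delta_truth: Optional[PlantedOrf] = None
    if cfg.plant_delta:
        d_start = cap_end + 30 + int(rng.integers(3))
        delta_truth = PlantedOrf(d_start, d_start + delta_span, d_start % 3)
        b2b.plant_orf(delta_truth, rng)

    def delta_offender(o) -> bool:
        if o.strand != "+":
            return False
        if o.frame == capsid.frame and o.end == capsid.end and o.start < capsid.start:
            return True
        if delta_truth is not None and (o.start, o.end) == (
            delta_truth.start, delta_truth.end,
        ):
            return False
        return o.start > capsid.start and o.end > capsid.end

    _scrub_orfs(b2b, "RNA2_sim", delta_offender, cfg.min_orf_aa, rng)

    segments = [
        ViralSegment(id="RNA1_sim", sequence=b1.text(), role="RNA1"),
        ViralSegment(id="RNA2_sim", sequence=b2b.text(), role="RNA2"),
    ]
    return segments, GenomeTruth(
        rdrp=rdrp, capsid=capsid, b2=b2_truth, delta=delta_truth
    )


# ---------------------------------------------------------------------------
# host stand-in


def simulate_host(cfg: SimConfig, segments: Iterable[ViralSegment]) -> str:
    """Uniform-random host sequence sharing no >= 18-mer with the
    viral segments (either strand), enforced by patching collisions."""
    rng = np.random.default_rng([cfg.seed, 202])
    k = 18
    viral_kmers: set[str] = set()
    for seg in segments:
        for s in (seg.sequence, revcomp(seg.sequence)):
            viral_kmers.update(
                s[i : i + k] for i in range(len(s) - k + 1)
            )
    host = list(rng.choice(list(BASES), size=cfg.host_length))
    for _ in range(50):
        text = "".join(host)
        collisions = [
            i for i in range(len(text) - k + 1)
            if text[i : i + k] in viral_kmers
        ]
        if not collisions:
            return text
        for i in collisions:
            for j in range(i, i + k):
                host[j] = BASES[int(rng.integers(4))]
    raise GenerationError("host rejection sampling did not converge")


# ---------------------------------------------------------------------------
# small-RNA libraries


def _pick_window(
    rng: np.random.Generator,
    seq: str,
    length: int,
    accept,
    max_tries: int = 4000,
) -> int:
    """Random window start whose window satisfies *accept*; scans
    forward from a random anchor (the 'window shift' strategy)."""
    n = len(seq) - length + 1
    if n <= 0:
        raise GenerationError("reference shorter than requested window")
    start = int(rng.integers(n))
    for t in range(max_tries):
        pos = (start + t) % n
        if accept(seq[pos : pos + length]):
            return pos
    raise GenerationError("window selection failed after bounded retries")


def simulate_smallrna_library(
    cfg: SimConfig,
    segments: list[ViralSegment],
    host: str,
    library: str = "infected",
) -> tuple[str, LibraryTruth]:
    """Emit a FASTQ text for one library plus its per-insert truth.

    The infected library contains ``n_antisense`` + ``n_sense`` viral
    inserts plus ``n_host`` host inserts; the control library contains
    ``n_control_viral`` viral inserts (default 0) plus ``n_host`` host
    inserts. Reads are barcode + insert + optional 1-4 nt A-tail, with
    per-insert read counts drawn geometric(read_count_geom_p).
    """
    if library not in {"infected", "control"}:
        raise ConfigError(f"unknown library {library!r}")
    for bc in cfg.barcodes:
        if len(bc) != 4:
            raise ConfigError(f"barcode {bc!r} is not 4 nt")
    rng = np.random.default_rng(
        [cfg.seed, 303 if library == "infected" else 404]
    )
    barcode = cfg.barcodes[0] if library == "infected" else cfg.barcodes[1]

    refs = ReferenceSet(
        records=tuple(
            [
                ReferenceRecord(id=s.id, sequence=s.sequence,
                                ref_class="virus", role=s.role)
                for s in segments
            ]
            + [ReferenceRecord(id="host_sim", sequence=host, ref_class="host")]
        )
    )
    unambiguous = ReferenceIndex(refs, k=18)

    used: set[str] = set()
    truths: list[InsertTruth] = []

    def admissible(insert: str) -> bool:
        return (
            insert not in used
            and insert[-1] != "A"  # keep the 3' A-trim truth-exact
            and len(unambiguous.find(insert)) == 1
        )

    seg_weights = np.array([len(s) for s in segments], dtype=float)
    seg_weights /= seg_weights.sum()

    def add_insert(origin: str, orientation: str) -> None:
        for _ in range(200):
            if origin == "virus":
                seg = segments[int(rng.choice(len(segments), p=seg_weights))]
                ref_id, ref_seq = seg.id, seg.sequence
            else:
                ref_id, ref_seq = "host_sim", host
            if orientation == "antisense":
                u = rng.random()
                length = 22 if u >= cfg.antisense_spill else (
                    21 if u < cfg.antisense_spill / 2 else 23
                )
                want_g = rng.random() < cfg.p_5primeG_antisense
                # antisense first base = complement of the window's last
                # base: G iff the window ends in C
                def accept(win: str, want_g=want_g) -> bool:
                    if (win[-1] == "C") != want_g:
                        return False
                    return admissible(revcomp(win))
            else:
                length = int(rng.integers(18, 31))

                def accept(win: str) -> bool:
                    return admissible(win)

            try:
                pos = _pick_window(rng, ref_seq, length, accept)
            except GenerationError:
                continue
            win = ref_seq[pos : pos + length]
            insert = revcomp(win) if orientation == "antisense" else win
            used.add(insert)
            if origin == "virus":
                expected = (
                    "virus_sense" if orientation == "sense" else "virus_antisense"
                )
            else:
                expected = "host"
            truths.append(
                InsertTruth(
                    sequence=insert, origin=origin, orientation=orientation,
                    reference_id=ref_id, position=pos,
                    read_count=int(rng.geometric(cfg.read_count_geom_p)),
                    barcode=barcode, expected_category=expected,
                )
            )
            return
        raise GenerationError("insert sampling failed after bounded retries")

    if library == "infected":
        for _ in range(cfg.n_antisense):
            add_insert("virus", "antisense")
        for _ in range(cfg.n_sense):
            add_insert("virus", "sense")
    else:
        for _ in range(cfg.n_control_viral):
            add_insert("virus", "antisense")
    for _ in range(cfg.n_host):
        add_insert("host", "sense")

    # junk reads exercising the exclusion rules
    n_junk_n = cfg.n_junk // 2
    n_junk_bc = cfg.n_junk - n_junk_n
    bad_bc = next(
        bc for bc in ("AAAA", "CCCC", "GGGG", "TTTT") if bc not in cfg.barcodes
    )

    out = io.StringIO()
    idx = 0

    def emit(seq: str) -> None:
        nonlocal idx
        out.write(f"@{library}_{idx}\n{seq}\n+\n{'I' * len(seq)}\n")
        idx += 1

    for t in truths:
        for _ in range(t.read_count):
            tail = "A" * int(rng.integers(1, 5)) if rng.random() < cfg.p_a_tail else ""
            emit(barcode + t.sequence + tail)
    for _ in range(n_junk_n):
        body = "".join(rng.choice(list(BASES), size=22))
        j = int(rng.integers(len(body)))
        emit(barcode + body[:j] + "N" + body[j + 1 :])
    for _ in range(n_junk_bc):
        emit(bad_bc + "".join(rng.choice(list(BASES), size=22)))

    return out.getvalue(), LibraryTruth(
        library=library, barcode=barcode, inserts=truths,
        n_junk_n=n_junk_n, n_junk_barcode=n_junk_bc,
    )


# ---------------------------------------------------------------------------
# symptom tables


def simulate_symptom_tables(
    p_infected: float,
    p_control: float,
    n_per_arm: int,
    seed: int = 0,
) -> tuple[ContingencyTable2x2, dict]:
    """Binomial symptomatic counts per arm, as a 2x2 table plus truth."""
    if not (0 <= p_infected <= 1 and 0 <= p_control <= 1):
        raise ConfigError("probabilities must lie in [0, 1]")
    if n_per_arm < 1:
        raise ConfigError("n_per_arm must be >= 1")
    rng = np.random.default_rng([seed, 505])
    a = int(rng.binomial(n_per_arm, p_infected))
    b = int(rng.binomial(n_per_arm, p_control))
    table = ContingencyTable2x2(a=a, b=b, c=n_per_arm - a, d=n_per_arm - b)
    truth = {
        "p_infected": p_infected,
        "p_control": p_control,
        "n_per_arm": n_per_arm,
        "seed": seed,
    }
    return table, truth
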