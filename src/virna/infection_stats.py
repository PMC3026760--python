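"""Symptom-scoring statistics for infection assays.

Worms are scored for four intestinal-cell symptoms (gut-granule loss,
nuclear degeneration, cytoplasm liquefaction, cell fusion); the unit of
analysis is the proportion of animals showing at least k symptoms, and
conditions are compared with a two-sided Fisher's exact test on the
2x2 table of symptomatic (>= 1 symptom) vs asymptomatic animals.

The Fisher test enumerates every table with the observed margins using
exact integer binomial coefficients, so the p-value is rational-safe:
p = (sum of C(r1,k)·C(r2,c1-k) over tables no more probable than the
observed one) / C(n,c1), following the standard two-sided convention of
summing all tables whose hypergeometric probability does not exceed
that of the observed table.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

from virna.errors import InputError

SYMPTOMS = (
    "granule_loss",
    "nuclear_degeneration",
    "cytoplasm_liquefaction",
    "cell_fusion",
)


@dataclass(frozen=True)
class SymptomRecord:
    """Per-worm boolean flags for the four scored symptoms."""

    worm_id: str
    granule_loss: bool = False
    nuclear_degeneration: bool = False
    cytoplasm_liquefaction: bool = False
    cell_fusion: bool = False

    @property
    def n_symptoms(self) -> int:
        return sum(getattr(self, s) for s in SYMPTOMS)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a,b / c,d: symptomatic & asymptomatic per condition.

    Rows are outcomes (symptomatic, asymptomatic), columns conditions.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("negative cell count")
        if self.total == 0:
            raise InputError("all-zero contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def symptom_proportions(
    records_by_condition: Mapping[str, Sequence[SymptomRecord]],
) -> dict:
    """Proportion of worms with >= k symptoms (k = 1..4) per condition.

    Proportions are monotone non-increasing in k by construction. When
    exactly two conditions are supplied, the 2x2 table of (>= 1 symptom)
    vs none across conditions is included under ``"table_ge1"`` (columns
    ordered as the input mapping).
    """
    if not records_by_condition:
        raise InputError("no conditions supplied")
    proportions: dict[str, dict[int, float]] = {}
    for cond, records in records_by_condition.items():
        if not records:
            raise InputError(f"condition {cond!r} has no records")
        n = len(records)
        proportions[cond] = {
            k: sum(1 for r in records if r.n_symptoms >= k) / n
            for k in range(1, 5)
        }
    out: dict = {"proportions": proportions}
    if len(records_by_condition) == 2:
        (ca, ra), (cb, rb) = records_by_condition.items()
        a = sum(1 for r in ra if r.n_symptoms >= 1)
        c2 = sum(1 for r in rb if r.n_symptoms >= 1)
        out["table_ge1"] = ContingencyTable2x2(
            a=a, b=c2, c=len(ra) - a, d=len(rb) - c2
        )
        out["conditions"] = (ca, cb)
    return out


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value by full enumeration.

    All tables sharing the margins of *t* are enumerated; the p-value is
    the hypergeometric probability mass of tables no more probable than
    the observed one. Computed with exact integers, so there is no
    floating-point tie ambiguity.
    """
    a, b, c, d = t.cells
    r1, r2 = a + b, c + d
    c1 = a + c
    n = t.total
    # Table with first cell k has weight C(r1,k)*C(r2,c1-k); probability
    # is weight / C(n,c1). Compare weights exactly.
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    observed = comb(r1, a) * comb(r2, c)
    numer = 0
    for k in range(k_min, k_max + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= observed:
            numer += w
    return numer / comb(n, c1)


def read_symptom_records(handle) -> dict[str, list[SymptomRecord]]:
    """Read a TSV of worm_id, condition and the four symptom flags
    (0/1), grouped by condition."""
    own = isinstance(handle, (str, bytes))
    fh = open(handle) if own else handle
    try:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["worm_id", "condition", *SYMPTOMS]
        if header != expected:
            raise InputError(f"expected columns {expected}, got {header}")
        out: dict[str, list[SymptomRecord]] = {}
        for line in fh:
            worm_id, cond, *flags = line.rstrip("\n").split("\t")
            rec = SymptomRecord(
                worm_id, *(bool(int(f)) for f in flags)
            )
            out.setdefault(cond, []).append(rec)
        return out
    finally:
        if own:
            fh.close()
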