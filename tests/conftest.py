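"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from virna.genome_annotation import ViralSegment
from virna.synthetic_data import (
    SimConfig,
    simulate_host,
    simulate_smallrna_library,
    simulate_viral_genome,
)

BASES = "ACGT"


def random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


# ---------------------------------------------------------------------------
# independent oracles

# Standard genetic code as the classic TCAG-ordered string: an oracle
# that shares no code with the implementation's Biopython-backed path.
_ORACLE_BASES = "TCAG"
_ORACLE_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODON_ORACLE = {
    b1 + b2 + b3: _ORACLE_AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_ORACLE_BASES)
    for j, b2 in enumerate(_ORACLE_BASES)
    for k, b3 in enumerate(_ORACLE_BASES)
}


def revcomp_oracle(s: str) -> str:
    return "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[c] for c in reversed(s))


def orf_oracle(seq: str, min_aa: int, allow_partial: bool, both_strands: bool):
    """Brute force: enumerate every ATG on each strand, walk codons to
    the next stop, keep the earliest start per (strand, frame, stop).

    Returns a set of (strand, frame, start, end, aa_length, partial)
    with start/end on the + strand.
    """
    found = {}
    strands = [("+", seq)] + ([("-", revcomp_oracle(seq))] if both_strands else [])
    for strand, s in strands:
        n = len(s)
        for atg in range(n - 2):
            if s[atg : atg + 3] != "ATG":
                continue
            pos = atg
            stop = None
            while pos + 3 <= n:
                if CODON_ORACLE[s[pos : pos + 3]] == "*":
                    stop = pos
                    break
                pos += 3
            if stop is not None:
                end, aa, partial = stop + 3, (stop - atg) // 3, False
            elif allow_partial:
                end = atg + 3 * ((n - atg) // 3)
                aa, partial = (end - atg) // 3, True
                if aa == 0:
                    continue
            else:
                continue
            if aa < min_aa:
                continue
            key = (strand, atg % 3, end)
            if key not in found or atg < found[key][0]:
                found[key] = (atg, aa, partial)
    out = set()
    for (strand, frame, end), (start, aa, partial) in found.items():
        if strand == "-":
            start, end = len(seq) - end, len(seq) - start
        out.add((strand, frame, start, end, aa, partial))
    return out


def naive_hits_oracle(records, query):
    """All-position scan of every record, both strands.

    *records* is a list of (id, sequence); returns a set of
    (reference_id, strand, position).
    """
    hits = set()
    rc = revcomp_oracle(query)
    for rid, seq in records:
        for probe, strand in ((query, "+"), (rc, "-")):
            start = 0
            while True:
                p = seq.find(probe, start)
                if p == -1:
                    break
                hits.add((rid, strand, p))
                start = p + 1
    return hits


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p-value by exact Fraction enumeration."""
    from fractions import Fraction
    from math import comb

    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(a + b + c + d, c1)
    obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    p = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if pk <= obs:
            p += pk
    return float(p)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    """Small, fast configuration shared by the unit tests."""
    return SimConfig(
        seed=11, n_antisense=300, n_sense=150, n_host=600,
        p_5primeG_antisense=0.6,
    )


@pytest.fixture(scope="session")
def sim_genomes(sim_cfg):
    return simulate_viral_genome(sim_cfg)


@pytest.fixture(scope="session")
def sim_host(sim_cfg, sim_genomes) -> str:
    segments, _ = sim_genomes
    return simulate_host(sim_cfg, segments)


@pytest.fixture(scope="session")
def sim_library(sim_cfg, sim_genomes, sim_host):
    segments, _ = sim_genomes
    return simulate_smallrna_library(sim_cfg, segments, sim_host, "infected")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)


@pytest.fixture()
def toy_segment() -> ViralSegment:
    return ViralSegment(id="toy", sequence="ATGAAATAG")
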