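"""Low-level nucleotide helpers shared by the sequence modules."""

from __future__ import annotations

from Bio.Seq import Seq

from virna.errors import AlphabetError

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def normalize_nt(seq: str, *, allow_n: bool = False) -> str:
    """Uppercase, U->T normalization; reject ambiguity codes.

    Raises :class:`AlphabetError` on anything outside {A,C,G,T}
    (plus N when *allow_n*).
    """
    s = seq.upper().replace("U", "T")
    allowed = DNA_ALPHABET | {"N"} if allow_n else DNA_ALPHABET
    bad = set(s) - allowed
    if bad:
        raise AlphabetError(
            f"sequence contains characters outside {{A,C,G,T}}: {sorted(bad)}"
        )
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codons(nt: str) -> str:
    """Translate a triplet-length ACGT string with the standard code.

    Stop codons appear as ``*``. Input must already be normalized.
    """
    return str(Seq(nt).translate(table=1))
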