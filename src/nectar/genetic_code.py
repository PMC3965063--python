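"""Standard genetic code lookups and the substitution-consequence vocabulary.

Every downstream module reasons about single-base substitutions of a codon,
so the whole consequence taxonomy lives here: a substitution of a sense
codon is *synonymous* (same residue), *missense* (different residue) or
*nonsense* (stop gained). The three labels are exhaustive and mutually
exclusive for any single-base change of a non-stop reference codon.

Only the standard nuclear genetic code (translation table 1) is supported:
the annotation sources this package models are nuclear human proteins.
Stop reference codons are rejected rather than given a stop-loss category,
because every annotation anchor is an amino-acid residue of a translated
protein and can never sit on a stop codon.
"""

from __future__ import annotations

import enum

from Bio.Data import CodonTable

__all__ = [
    "STOP",
    "BASES",
    "CODON_TABLE",
    "SENSE_CODONS",
    "STOP_CODONS",
    "Consequence",
    "GeneticCodeError",
    "InvalidCodonError",
    "InvalidPairError",
    "UnsupportedReferenceError",
    "translate_codon",
    "classify_substitution",
    "is_stop",
]

#: One-letter stop marker used throughout (HGVS three-letter form is "Ter").
STOP = "*"

#: The four DNA bases, in the fixed enumeration order used everywhere.
BASES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid (or ``STOP``), total over all 64 codons.
CODON_TABLE: dict[str, str] = dict(_standard.forward_table)
CODON_TABLE.update({c: STOP for c in _standard.stop_codons})

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TABLE if c not in STOP_CODONS)
)

assert len(CODON_TABLE) == 64 and len(SENSE_CODONS) == 61


class GeneticCodeError(ValueError):
    """Base class for genetic-code level input errors."""


class InvalidCodonError(GeneticCodeError):
    """Raised for strings that are not an upper-case ACGT triplet."""


class InvalidPairError(GeneticCodeError):
    """Raised when ref/alt codons do not differ at exactly one position."""


class UnsupportedReferenceError(GeneticCodeError):
    """Raised when the reference codon is a stop codon."""


class Consequence(str, enum.Enum):
    """Consequence of a single-base substitution on the encoded residue."""

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _check_codon(codon: str) -> str:
    if not isinstance(codon, str) or len(codon) != 3 or any(
        b not in BASES for b in codon
    ):
        raise InvalidCodonError(
            f"not a valid codon: {codon!r} (expected 3 uppercase ACGT bases)"
        )
    return codon


def translate_codon(codon: str) -> str:
    """Translate a codon to its one-letter amino acid, or ``"*"`` for stop.

    Deterministic and total over all 64 codons; raises
    :class:`InvalidCodonError` for anything that is not an ACGT triplet
    (ambiguity codes such as R/Y are deliberately not expanded).
    """
    return CODON_TABLE[_check_codon(codon)]


def is_stop(codon: str) -> bool:
    """True if ``codon`` is one of the three standard stop codons."""
    return _check_codon(codon) in STOP_CODONS


def classify_substitution(ref: str, alt: str) -> Consequence:
    """Classify the single-base substitution ``ref`` -> ``alt``.

    Parameters
    ----------
    ref, alt : str
        Codons differing at exactly one position. ``ref`` must be a sense
        (non-stop) codon.

    Returns
    -------
    Consequence
        ``SYNONYMOUS`` iff both codons encode the same residue, ``NONSENSE``
        iff ``alt`` is a stop codon, ``MISSENSE`` otherwise.

    Raises
    ------
    UnsupportedReferenceError
        If ``ref`` is a stop codon.
    InvalidPairError
        If ``ref`` and ``alt`` do not differ at exactly one position.
    """
    _check_codon(ref)
    _check_codon(alt)
    if ref in STOP_CODONS:
        raise UnsupportedReferenceError(
            f"reference codon {ref} is a stop codon; annotation anchors are "
            "amino-acid residues, so stop references are unsupported"
        )
    if sum(a != b for a, b in zip(ref, alt)) != 1:
        raise InvalidPairError(
            f"{ref}->{alt}: codons must differ at exactly one position"
        )
    ref_aa = CODON_TABLE[ref]
    alt_aa = CODON_TABLE[alt]
    if alt_aa == STOP:
        return Consequence.NONSENSE
    if alt_aa == ref_aa:
        return Consequence.SYNONYMOUS
    return Consequence.MISSENSE
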