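"""Standard genetic code: translation, synonymous families, CDS validation.

The code table (NCBI translation table 1) is the ground truth used by every
other module: 61 sense codons map onto the 20 canonical amino acids, three
codons (TAA, TAG, TGA) signal stop, and each amino acid's synonymous family
has between one (Met, Trp) and six (Leu, Ser, Arg) members.  Only the DNA
alphabet is used; ``U`` in input is normalised to ``T`` by :func:`normalize_dna`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Dict, FrozenSet, Mapping

from Bio.Data import CodonTable as _CodonTable

logger = logging.getLogger("codonlm")

DNA_ALPHABET = frozenset("ACGT")
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
STOP_SYMBOL = "*"


class CdsError(ValueError):
    """Base class for coding-sequence validation failures."""


class NonTripletError(CdsError):
    """CDS length is not a multiple of three."""


class InvalidCharacterError(CdsError):
    """CDS contains a character outside {A, C, G, T}."""


class InternalStopError(CdsError):
    """A stop codon occurs before the final codon."""


class UnknownResidueError(ValueError):
    """Protein symbol outside the 20 canonical amino acids."""


def _build_standard_code() -> tuple[Dict[str, str], Dict[str, FrozenSet[str]], FrozenSet[str]]:
    std = _CodonTable.unambiguous_dna_by_id[1]
    table: Dict[str, str] = dict(std.forward_table)
    stops = frozenset(std.stop_codons)
    for codon in stops:
        table[codon] = STOP_SYMBOL
    families: Dict[str, FrozenSet[str]] = {}
    for aa in AMINO_ACIDS:
        families[aa] = frozenset(c for c, a in std.forward_table.items() if a == aa)
    return table, families, stops


@dataclass(frozen=True)
class GeneticCode:
    """Codon→amino-acid mapping plus synonymous-family index."""

    table: Mapping[str, str]
    families: Mapping[str, FrozenSet[str]]
    stop_codons: FrozenSet[str]

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, a in self.table.items() if a != STOP_SYMBOL))

    def amino_acid(self, codon: str) -> str:
        """Amino-acid symbol for a sense codon, or ``*`` for a stop codon."""
        try:
            return self.table[codon]
        except KeyError:
            raise InvalidCharacterError(f"not a codon over {{A,C,G,T}}: {codon!r}") from None

    def synonymous_codons(self, aa: str) -> FrozenSet[str]:
        """The full synonymous family of one canonical amino acid (size 1–6)."""
        try:
            return self.families[aa]
        except KeyError:
            raise UnknownResidueError(f"unknown amino-acid symbol: {aa!r}") from None

    def translate(self, cds: str) -> str:
        """Translate a CDS; a terminal stop codon is dropped, an internal one raises.

        Raises :class:`NonTripletError`, :class:`InvalidCharacterError` or
        :class:`InternalStopError` on malformed input.
        """
        if len(cds) % 3 != 0:
            raise NonTripletError(f"CDS length {len(cds)} is not a multiple of 3")
        bad = set(cds) - DNA_ALPHABET
        if bad:
            raise InvalidCharacterError(f"invalid characters in CDS: {sorted(bad)}")
        n_codons = len(cds) // 3
        out = []
        for k in range(n_codons):
            codon = cds[3 * k : 3 * k + 3]
            aa = self.table[codon]
            if aa == STOP_SYMBOL:
                if k != n_codons - 1:
                    raise InternalStopError(f"stop codon {codon} at codon position {k}")
                break
            out.append(aa)
        return "".join(out)


STANDARD_CODE = GeneticCode(*_build_standard_code())

STOP_CODONS: FrozenSet[str] = STANDARD_CODE.stop_codons
SENSE_CODONS: tuple[str, ...] = STANDARD_CODE.sense_codons


def translate(cds: str) -> str:
    """Translate under the standard genetic code (module-level convenience)."""
    return STANDARD_CODE.translate(cds)


def synonymous_codons(aa: str) -> FrozenSet[str]:
    return STANDARD_CODE.synonymous_codons(aa)


def codons_of(cds: str, drop_terminal_stop: bool = True) -> list[str]:
    """Split a triplet-length CDS into codons, optionally dropping a trailing stop."""
    if len(cds) % 3 != 0:
        raise NonTripletError(f"CDS length {len(cds)} is not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if drop_terminal_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons


def normalize_dna(seq: str) -> str:
    """Uppercase and convert RNA ``U`` to DNA ``T`` (logged when it happens)."""
    seq = seq.upper()
    if "U" in seq:
        logger.warning("RNA alphabet detected; converting U->T")
        seq = seq.replace("U", "T")
    return seq


class Verdict(str, Enum):
    PASS = "PASS"
    NON_TRIPLET = "non-triplet length"
    AMBIGUOUS_BASE = "ambiguous base"
    INTERNAL_STOP = "internal stop codon"
    TRANSLATION_MISMATCH = "translation mismatch"
    NON_CANONICAL_RESIDUE = "non-canonical residue"

    @property
    def ok(self) -> bool:
        return self is Verdict.PASS


def validate_cds(cds: str, protein: str, code: GeneticCode = STANDARD_CODE) -> Verdict:
    """Check that ``cds`` is a clean coding sequence for ``protein``.

    The verdict names the first failed rule; a terminal stop codon on the CDS
    is optional.  Never raises — failures are encoded in the verdict.
    """
    if any(sym not in code.families for sym in protein):
        return Verdict.NON_CANONICAL_RESIDUE
    if len(cds) % 3 != 0:
        return Verdict.NON_TRIPLET
    if set(cds) - DNA_ALPHABET:
        return Verdict.AMBIGUOUS_BASE
    try:
        observed = code.translate(cds)
    except InternalStopError:
        return Verdict.INTERNAL_STOP
    if observed != protein:
        return Verdict.TRANSLATION_MISMATCH
    return Verdict.PASS
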