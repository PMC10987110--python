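"""Amino-acid substitutions and single-nucleotide accessibility.

Positions are 1-based residue indices throughout; only the 20 canonical
amino acids are handled.  Substitutions reachable by a single nucleotide
change are enumerated with the standard genetic code, because score
databases for rare missense variants typically cover only those.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Data.IUPACData import protein_letters_1to3, protein_letters_3to1

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

AA1 = frozenset(protein_letters_1to3)
_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}

_VARIANT_RE = re.compile(
    r"^(?:p\.)?([A-Za-z]{3}|[A-Za-z])(\d+)([A-Za-z]{3}|[A-Za-z])$"
)


class VariantParseError(ValueError):
    """Raised when a protein-variant string cannot be parsed."""


@dataclass(frozen=True, order=True)
class AminoAcidSubstitution:
    """A single amino-acid substitution at a 1-based protein position."""

    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for field in ("ref_aa", "alt_aa"):
            aa = getattr(self, field)
            if aa not in AA1:
                raise ValueError(f"{field} {aa!r} is not a canonical amino acid")
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"ref and alt residues are both {self.ref_aa!r} (synonymous)"
            )

    def short(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    def long(self) -> str:
        return (
            f"p.{protein_letters_1to3[self.ref_aa]}{self.position}"
            f"{protein_letters_1to3[self.alt_aa]}"
        )


def _residue_code(token: str) -> str:
    if len(token) == 1:
        code = token.upper()
        if code not in AA1:
            raise VariantParseError(f"unknown residue code {token!r}")
        return code
    code = _THREE_TO_ONE.get(token.upper())
    if code is None:
        raise VariantParseError(f"unknown residue code {token!r}")
    return code


def parse_variant_name(text: str) -> AminoAcidSubstitution:
    """Parse ``p.Arg123Cys`` or ``R123C`` into an :class:`AminoAcidSubstitution`.

    One- and three-letter residue codes are accepted (an optional ``p.``
    prefix with either); the result always stores one-letter codes.
    """
    m = _VARIANT_RE.match(text.strip())
    if m is None:
        raise VariantParseError(f"malformed variant name {text!r}")
    ref, pos, alt = m.groups()
    ref_aa = _residue_code(ref)
    alt_aa = _residue_code(alt)
    if ref_aa == alt_aa:
        raise VariantParseError(
            f"variant {text!r} is synonymous ({ref_aa} -> {alt_aa})"
        )
    return AminoAcidSubstitution(position=int(pos), ref_aa=ref_aa, alt_aa=alt_aa)


def accessible_substitutions(codon: str) -> frozenset[str]:
    """Amino acids reachable from ``codon`` by one nucleotide change.

    Enumerates the nine single-nucleotide neighbours of the codon under the
    standard genetic code and returns the distinct encoded residues,
    excluding the reference residue itself and stop codons (missense only).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"invalid codon {codon!r}: need 3 letters over ACGT")
    if codon in _STANDARD_TABLE.stop_codons:
        raise ValueError(f"codon {codon!r} is a stop codon")
    ref = _STANDARD_TABLE.forward_table[codon]
    reachable = set()
    for i in range(3):
        for base in "ACGT":
            if base == codon[i]:
                continue
            neighbor = codon[:i] + base + codon[i + 1 :]
            if neighbor in _STANDARD_TABLE.stop_codons:
                continue
            aa = _STANDARD_TABLE.forward_table[neighbor]
            if aa != ref:
                reachable.add(aa)
    return frozenset(reachable)
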