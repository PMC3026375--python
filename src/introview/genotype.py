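"""Diploid SNP genotypes.

A genotype is an unordered pair of nucleotide alleles (A/C/G/T) or the
missing sentinel ``--``.  Allele order carries no information, so pairs are
stored canonically sorted: ``GA`` and ``AG`` are the same genotype and both
serialize as ``"AG"``.  Partially missing tokens such as ``A-`` are invalid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .errors import ParseError

ALLELES = frozenset("ACGT")
MISSING_TOKEN = "--"


@dataclass(frozen=True, order=True)
class Genotype:
    """An unordered diploid allele pair, or missing.

    ``alleles`` is a sorted two-tuple of nucleotide symbols, or ``None``
    for a missing call.
    """

    alleles: Optional[Tuple[str, str]]

    def __post_init__(self):
        if self.alleles is not None:
            a, b = self.alleles
            if a not in ALLELES or b not in ALLELES:
                raise ValueError(f"invalid alleles {self.alleles!r}")
            if a > b:
                object.__setattr__(self, "alleles", (b, a))

    @classmethod
    def from_token(cls, token: str) -> "Genotype":
        """Parse a two-character cell token ("AA", "AG", "--")."""
        token = token.strip()
        if token == MISSING_TOKEN:
            return MISSING
        if len(token) == 2 and token[0] in ALLELES and token[1] in ALLELES:
            return cls((token[0], token[1]))
        raise ParseError(f"invalid genotype token {token!r}")

    @property
    def token(self) -> str:
        return MISSING_TOKEN if self.alleles is None else "".join(self.alleles)

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]

    def hom_allele(self) -> str:
        """The single allele of a homozygous genotype."""
        if not self.is_hom:
            raise ValueError(f"{self.token} is not homozygous")
        return self.alleles[0]

    def __str__(self) -> str:
        return self.token

    def __repr__(self) -> str:
        return f"Genotype({self.token!r})"


#: The missing-call sentinel ("--").
MISSING = Genotype(None)


def hom(allele: str) -> Genotype:
    """Homozygous genotype for one allele."""
    return Genotype((allele, allele))


def het(a: str, b: str) -> Genotype:
    """Heterozygous genotype for two distinct alleles."""
    if a == b:
        raise ValueError("heterozygote needs two distinct alleles")
    return Genotype((a, b))
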