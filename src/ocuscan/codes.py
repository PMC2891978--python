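"""Genetic-code bookkeeping shared across the package.

Everything here is derived from Biopython's NCBI codon tables. The package
works with *degenerate codon families*: the synonymous-codon sets of amino
acids encoded by two or more codons, excluding stop codons. Under the
bacterial/archaeal code (translation table 11) this leaves 18 families
covering 59 sense codons (Met/ATG and Trp/TGG are non-degenerate and carry
no synonymous choice, so they are excluded from codon-usage features and
metrics).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

NUCLEOTIDES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """Codon families of one NCBI translation table.

    Attributes
    ----------
    table_id : NCBI translation table number.
    codon_to_aa : map of all 64 codons to one-letter amino acid or '*'.
    families : ordered map amino acid -> tuple of synonymous codons, for
        degenerate amino acids only (>=2 codons, stops excluded).
    family_codons : flat ordered tuple of the codons of all families; this
        fixed order defines the codon-attribute block of feature tables.
    stop_codons : tuple of stop codons.
    """

    table_id: int
    codon_to_aa: dict
    families: dict
    family_codons: tuple
    stop_codons: tuple

    @property
    def twofold_amino_acids(self) -> tuple:
        """Amino acids with exactly two synonymous codons."""
        return tuple(a for a, cs in self.families.items() if len(cs) == 2)

    def family_of(self, codon: str) -> str | None:
        aa = self.codon_to_aa.get(codon)
        if aa is None or aa == "*":
            return None
        return aa if aa in self.families else None


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 11) -> GeneticCode:
    """Build the degenerate-family view of an NCBI translation table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = dict(table.forward_table)
    for stop in table.stop_codons:
        codon_to_aa[stop] = "*"
    by_aa: dict[str, list[str]] = {}
    for codon in sorted(codon_to_aa):
        aa = codon_to_aa[codon]
        if aa != "*":
            by_aa.setdefault(aa, []).append(codon)
    families = {
        aa: tuple(codons)
        for aa, codons in sorted(by_aa.items())
        if len(codons) >= 2
    }
    flat = tuple(c for codons in families.values() for c in codons)
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        families=families,
        family_codons=flat,
        stop_codons=tuple(table.stop_codons),
    )


def split_codons(cds: str) -> list[str]:
    """Split a CDS string into codons; length must be a multiple of 3."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]
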