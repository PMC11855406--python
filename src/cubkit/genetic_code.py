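"""Plastid genetic code and synonymous-family structure.

All statistics in this package are defined over the 61 sense codons of the
bacterial/plastid code (NCBI translation table 11, whose sense-codon -> amino
acid mapping is identical to the standard code).  Synonymous families are the
sets of codons translating to the same amino acid; their sizes (degeneracy
classes) drive Wright's effective-number-of-codons statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

BASES = "TCAG"

STOP_CODONS = ("TAA", "TAG", "TGA")

# NCBI translation table 11, written out by codon.  Kept as an explicit literal
# so the mapping is auditable at a glance; tests cross-check it against
# Biopython's CodonTable.
CODON_TO_AA: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

ALL_CODONS: tuple[str, ...] = tuple(b1 + b2 + b3 for b1 in BASES for b2 in BASES for b3 in BASES)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if CODON_TO_AA[c] != "*")


def _families() -> dict[str, tuple[str, ...]]:
    fams: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        fams.setdefault(CODON_TO_AA[codon], []).append(codon)
    return {aa: tuple(cods) for aa, cods in fams.items()}


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino acid mapping plus the synonymous-family partition.

    Attributes
    ----------
    codon_to_aa
        Mapping of all 64 codons to one-letter amino acids, stops as ``"*"``.
    families
        Amino acid -> tuple of its sense codons (the synonymous family).
    """

    codon_to_aa: dict[str, str] = field(default_factory=lambda: dict(CODON_TO_AA))
    families: dict[str, tuple[str, ...]] = field(default_factory=_families)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return SENSE_CODONS

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return STOP_CODONS

    def family_of(self, aa: str) -> int:
        """Degeneracy class (1, 2, 3, 4 or 6) of an amino acid."""
        return len(self.families[aa])

    def degenerate_codons(self) -> tuple[str, ...]:
        """Sense codons whose amino acid has at least two synonyms.

        These 59 codons (Met and Trp excluded) are the domain of RSCU and of
        the GC3s denominator.
        """
        return tuple(c for c in SENSE_CODONS if len(self.families[CODON_TO_AA[c]]) >= 2)

    def translate(self, sequence: str) -> str:
        """Translate an in-frame nucleotide string; stops appear as ``*``."""
        if len(sequence) % 3:
            raise ValueError("sequence length is not a multiple of 3")
        seq = sequence.upper().replace("U", "T")
        return "".join(self.codon_to_aa[seq[i:i + 3]] for i in range(0, len(seq), 3))


@lru_cache(maxsize=1)
def default_code() -> GeneticCode:
    return GeneticCode()


def to_rna(codon: str) -> str:
    """DNA codon spelling -> RNA spelling (reports use U, as is conventional)."""
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")
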