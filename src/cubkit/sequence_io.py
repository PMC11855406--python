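"""Reading genomes and filtering coding sequences.

A plastome GenBank record yields one raw CDS per annotated CDS feature
(exons joined, minus-strand features reverse-complemented).  The analysis gene
set is then produced by :func:`filter_cds`, which enforces the conventional
quality rules for codon-usage work: length strictly greater than 300 nt and a
multiple of 3, ATG start, a single terminal stop (TAA/TAG/TGA), no premature
stop, no ambiguity characters, and one copy per gene name (plastid
inverted-repeat duplicates such as ndhB or rps12 would otherwise be counted
twice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .genetic_code import GeneticCode, STOP_CODONS, default_code

logger = logging.getLogger(__name__)

MIN_CDS_LENGTH = 300  # exclusive bound: retained genes are > 300 nt

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class RawCds:
    """A coding sequence as annotated, before quality filtering."""

    gene_id: str
    species_id: str
    sequence: str
    order: int  # genomic order of the feature, used to collapse IR duplicates


@dataclass(frozen=True)
class CdsRecord:
    """A filtered protein-coding sequence entering the codon analysis.

    Invariants: length > 300 nt and divisible by 3; starts with ATG; ends with
    a stop codon; no internal stop; A/C/G/T alphabet only.
    """

    gene_id: str
    species_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Exclusion:
    gene_id: str
    reason: str


class NoGenesPassFilterError(ValueError):
    """Raised when quality filtering removes every CDS."""


def _species_from_record(record: SeqRecord, fallback: str) -> str:
    organism = record.annotations.get("organism")
    return organism if organism else fallback


def read_genome(path: str | Path, species_id: str | None = None) -> list[RawCds]:
    """Extract raw CDSs from a GenBank plastome or a FASTA of coding sequences.

    GenBank CDS features are spliced according to their location (``join``,
    ``complement``) so the returned sequence is always the coding strand.
    FASTA entries are taken verbatim, the first whitespace-delimited token of
    the header serving as ``gene_id``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    fmt = _sniff_format(path)
    raw: list[RawCds] = []
    if fmt == "genbank":
        for record in SeqIO.parse(str(path), "genbank"):
            species = species_id or _species_from_record(record, path.stem)
            order = 0
            for feature in record.features:
                if feature.type != "CDS":
                    continue
                gene = feature.qualifiers.get("gene", feature.qualifiers.get("locus_tag", ["?"]))[0]
                try:
                    seq = str(feature.extract(record.seq)).upper()
                except Exception:  # malformed location: record it, let filtering report it
                    logger.warning("could not extract CDS %s from %s", gene, path)
                    seq = ""
                raw.append(RawCds(gene_id=gene, species_id=species, sequence=seq, order=order))
                order += 1
    else:
        species = species_id or path.stem
        for order, record in enumerate(SeqIO.parse(str(path), "fasta")):
            raw.append(
                RawCds(
                    gene_id=record.id,
                    species_id=species,
                    sequence=str(record.seq).upper(),
                    order=order,
                )
            )
    if not raw:
        raise ValueError(f"no CDS records found in {path}")
    return raw


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.startswith(">") else "genbank"
    raise ValueError(f"empty input file: {path}")


def check_cds(sequence: str, code: GeneticCode | None = None,
              min_length: int = MIN_CDS_LENGTH) -> str | None:
    """Return the reason a sequence fails the CDS filter, or None if it passes."""
    code = code or default_code()
    seq = sequence.upper()
    if not seq:
        return "empty or unextractable sequence"
    if set(seq) - _VALID_BASES:
        return "ambiguity or non-ACGT characters"
    if len(seq) % 3 != 0:
        return "length not a multiple of 3"
    if len(seq) <= min_length:
        return f"length {len(seq)} nt not greater than {min_length} nt"
    if not seq.startswith("ATG"):
        return f"start codon {seq[:3]} is not ATG"
    if seq[-3:] not in STOP_CODONS:
        return f"terminal codon {seq[-3:]} is not a stop"
    for i in range(0, len(seq) - 3, 3):
        if seq[i:i + 3] in STOP_CODONS:
            return f"internal stop codon at nt {i + 1}"
    return None


def filter_cds(
    raw: Iterable[RawCds | CdsRecord],
    code: GeneticCode | None = None,
    min_length: int = MIN_CDS_LENGTH,
) -> tuple[list[CdsRecord], list[Exclusion]]:
    """Apply the CDS quality rules and collapse duplicate gene names.

    Duplicates (inverted-repeat genes annotated twice) keep the first
    occurrence in genomic order.  Returns the retained records together with an
    exclusion report, one entry per rejected feature with the reason.

    Raises
    ------
    NoGenesPassFilterError
        If nothing survives; codon statistics would be undefined.
    """
    code = code or default_code()
    retained: list[CdsRecord] = []
    excluded: list[Exclusion] = []
    seen: dict[tuple[str, str], str] = {}
    records = sorted(raw, key=lambda r: getattr(r, "order", 0))
    for rec in records:
        reason = check_cds(rec.sequence, code, min_length)
        if reason is not None:
            excluded.append(Exclusion(rec.gene_id, reason))
            continue
        key = (rec.species_id, rec.gene_id)
        if key in seen:
            excluded.append(Exclusion(rec.gene_id, "duplicate gene name (IR copy); first kept"))
            continue
        seen[key] = rec.gene_id
        retained.append(CdsRecord(rec.gene_id, rec.species_id, rec.sequence.upper()))
    if not retained:
        raise NoGenesPassFilterError(
            f"no genes pass filters ({len(excluded)} excluded)"
        )
    return retained, excluded


def write_fasta(records: Sequence[CdsRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description=r.species_id)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_exclusion_report(exclusions: Sequence[Exclusion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\treason\n")
        for exc in exclusions:
            fh.write(f"{exc.gene_id}\t{exc.reason}\n")
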