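"""Per-gene and pooled codon-usage statistics.

The quantities computed here are the classical descriptors of codon usage
bias:

* **RSCU** — relative synonymous codon usage, the observed count of a codon
  divided by the mean count over its synonymous family (``x * k / n`` for a
  family of size *k* with total *n*).  1 means no bias within the family.
* **Positional GC** — GC1/GC2/GC3 are the G+C fractions at the three codon
  positions over sense codons; GC12 is the mean of the first two, GCall of all
  three.  GC3s restricts the third-position count to codons of amino acids
  with at least two synonyms (Met, Trp and stops excluded), the denominator
  relevant to synonymous choice.
* **ENC** — Wright's effective number of codons,
  ``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6`` where ``Fk`` averages, over the
  amino-acid families of degeneracy *k*, the finite-sample codon homozygosity
  ``F = (n * sum(p_i^2) - 1) / (n - 1)``.  ENC runs from 20 (one codon per
  amino acid) to 61 (uniform usage).
* **Expected ENC** — the mutation-only expectation
  ``ENC_exp = 2 + s + 29 / (s^2 + (1 - s)^2)`` at third-position synonymous
  GC content *s*, the reference curve of the ENC plot.

Stop codons are carried in the count vectors but excluded from every
statistic; the initial ATG is an ordinary Met codon and is counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode, SENSE_CODONS, STOP_CODONS, default_code
from .sequence_io import CdsRecord

ENC_MAX = 61.0
ENC_MIN = 20.0

#: display rounding used by the table writers: 3 decimals for fractions, 2 for ENC
FRACTION_DECIMALS = 3
ENC_DECIMALS = 2


@dataclass
class CodonCounts:
    """Codon occurrence counts for one scope (a gene, a pool, or a species)."""

    scope_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def sense_total(self, code: GeneticCode | None = None) -> int:
        code = code or default_code()
        return sum(self.counts.get(c, 0) for c in code.sense_codons)

    def stop_total(self) -> int:
        return sum(self.counts.get(c, 0) for c in STOP_CODONS)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = dict(self.counts)
        for codon, n in other.counts.items():
            merged[codon] = merged.get(codon, 0) + n
        return CodonCounts(scope_id=f"{self.scope_id}+{other.scope_id}", counts=merged)


@dataclass
class GeneStats:
    """Composition and bias statistics for one gene (or pooled scope)."""

    gene_id: str
    species_id: str
    n_codons: int
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc_all: float
    gc3s: float
    a3: int
    t3: int
    g3: int
    c3: int
    enc_obs: float
    enc_exp: float
    enc_ratio: float


@dataclass
class RscuProfile:
    """RSCU values per sense codon for one scope.

    ``unobserved`` lists amino acids whose family had zero occurrences; their
    codons carry RSCU 0 by convention and should be read as missing.
    """

    scope_id: str
    rscu: dict[str, float]
    unobserved: tuple[str, ...] = ()


def count_codons(cds: CdsRecord | str, scope_id: str | None = None) -> CodonCounts:
    """Tally codons of an in-frame coding sequence.

    The terminal stop is counted (and carried in the vector) but the sense
    total is ``length/3 - 1`` for a valid CDS.
    """
    seq = cds.sequence if isinstance(cds, CdsRecord) else str(cds)
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError("sequence length is not a multiple of 3")
    scope = scope_id or (cds.gene_id if isinstance(cds, CdsRecord) else "seq")
    counts: dict[str, int] = {}
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(scope_id=scope, counts=counts)


def pool_counts(counts: Iterable[CodonCounts], scope_id: str) -> CodonCounts:
    pooled: dict[str, int] = {}
    for cc in counts:
        for codon, n in cc.counts.items():
            pooled[codon] = pooled.get(codon, 0) + n
    return CodonCounts(scope_id=scope_id, counts=pooled)


def rscu(counts: CodonCounts, code: GeneticCode | None = None) -> RscuProfile:
    """Relative synonymous codon usage of a count vector.

    Within each observed family of size *k*, values sum to *k* exactly;
    single-codon families (Met, Trp) are identically 1 when observed.
    """
    code = code or default_code()
    values: dict[str, float] = {}
    unobserved: list[str] = []
    for aa, family in code.families.items():
        k = len(family)
        total = sum(counts.counts.get(c, 0) for c in family)
        if total == 0:
            unobserved.append(aa)
            for c in family:
                values[c] = 0.0
            continue
        for c in family:
            values[c] = counts.counts.get(c, 0) * k / total
    return RscuProfile(scope_id=counts.scope_id, rscu=values,
                       unobserved=tuple(sorted(unobserved)))


def composition(counts: CodonCounts, code: GeneticCode | None = None) -> dict[str, float]:
    """Positional GC content and third-position base counts over sense codons.

    Returns a dict with keys ``gc1, gc2, gc3, gc12, gc_all, gc3s, a3, t3, g3,
    c3, n_codons``.
    """
    code = code or default_code()
    n = 0
    gc_pos = [0, 0, 0]
    third: dict[str, int] = {"A": 0, "T": 0, "G": 0, "C": 0}
    gc3s_num = 0
    gc3s_den = 0
    degenerate = set(code.degenerate_codons())
    for codon in code.sense_codons:
        x = counts.counts.get(codon, 0)
        if x == 0:
            continue
        n += x
        for p in range(3):
            if codon[p] in "GC":
                gc_pos[p] += x
        third[codon[2]] += x
        if codon in degenerate:
            gc3s_den += x
            if codon[2] in "GC":
                gc3s_num += x
    if n == 0:
        raise ValueError(f"no sense codons in scope {counts.scope_id}")
    gc1, gc2, gc3 = (g / n for g in gc_pos)
    return {
        "n_codons": n,
        "gc1": gc1,
        "gc2": gc2,
        "gc3": gc3,
        "gc12": (gc1 + gc2) / 2.0,
        "gc_all": (gc1 + gc2 + gc3) / 3.0,
        "gc3s": gc3s_num / gc3s_den if gc3s_den else math.nan,
        "a3": third["A"],
        "t3": third["T"],
        "g3": third["G"],
        "c3": third["C"],
    }


def _family_homozygosity(family_counts: Sequence[int]) -> float | None:
    """Wright's F for one amino-acid family; None when not computable (n < 2
    or non-positive F)."""
    n = int(sum(family_counts))
    if n < 2:
        return None
    p2 = sum((x / n) ** 2 for x in family_counts)
    f = (n * p2 - 1.0) / (n - 1.0)
    if f <= 0.0:
        return None
    return f


def enc_observed(counts: CodonCounts, code: GeneticCode | None = None) -> float:
    """Wright's observed effective number of codons.

    Family homozygosities are averaged within each degeneracy class; an
    uncomputable 3-fold mean (Ile being the only 3-fold family) is imputed as
    the mean of the 2-fold and 4-fold class means, the CodonW convention.  The
    result is capped at 61.  NaN when a 2-, 4- or 6-fold class mean cannot be
    formed at all.
    """
    code = code or default_code()
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, family in code.families.items():
        k = len(family)
        if k < 2:
            continue
        f = _family_homozygosity([counts.counts.get(c, 0) for c in family])
        if f is not None:
            by_class[k].append(f)
    means = {k: (sum(v) / len(v) if v else None) for k, v in by_class.items()}
    if means[2] is None or means[4] is None or means[6] is None:
        return math.nan
    if means[3] is None:
        means[3] = (means[2] + means[4]) / 2.0
    enc = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(enc, ENC_MAX)


def enc_expected(gc3s: float) -> float:
    """Mutation-only expected ENC at synonymous third-position GC content."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must lie in [0, 1], got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s ** 2 + (1.0 - gc3s) ** 2)


def enc_ratio(enc_obs: float, enc_exp: float) -> float:
    """(ENC_exp - ENC_obs) / ENC_exp; near 0 when mutation alone explains usage."""
    return (enc_exp - enc_obs) / enc_exp


def gene_stats(cds: CdsRecord, code: GeneticCode | None = None) -> GeneStats:
    """All per-gene statistics for one filtered CDS."""
    code = code or default_code()
    counts = count_codons(cds)
    comp = composition(counts, code)
    e_obs = enc_observed(counts, code)
    e_exp = enc_expected(comp["gc3s"]) if not math.isnan(comp["gc3s"]) else math.nan
    return GeneStats(
        gene_id=cds.gene_id,
        species_id=cds.species_id,
        n_codons=comp["n_codons"],
        gc1=comp["gc1"],
        gc2=comp["gc2"],
        gc3=comp["gc3"],
        gc12=comp["gc12"],
        gc_all=comp["gc_all"],
        gc3s=comp["gc3s"],
        a3=comp["a3"],
        t3=comp["t3"],
        g3=comp["g3"],
        c3=comp["c3"],
        enc_obs=e_obs,
        enc_exp=e_exp,
        enc_ratio=enc_ratio(e_obs, e_exp) if not (math.isnan(e_obs) or math.isnan(e_exp)) else math.nan,
    )


def genes_table(records: Sequence[CdsRecord], code: GeneticCode | None = None) -> pd.DataFrame:
    """Per-gene statistics table, one row per CDS, sorted by (species, gene)."""
    rows = [vars(gene_stats(r, code)) for r in records]
    df = pd.DataFrame(rows)
    return df.sort_values(["species_id", "gene_id"], kind="mergesort").reset_index(drop=True)


def species_summary(records: Sequence[CdsRecord], code: GeneticCode | None = None) -> pd.DataFrame:
    """One aggregate row per species: pooled composition, pooled ENC, and the
    mean of per-gene ENCs.

    N is the total sense-codon count of the gene set.  Composition is
    recomputed on pooled counts (not averaged over genes).  Both species-level
    ENC readings are reported: ``enc_pooled`` treats the gene set as one long
    sequence, ``enc_mean`` averages the per-gene values.
    """
    code = code or default_code()
    by_species: dict[str, list[CdsRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species_id, []).append(rec)
    rows = []
    for species in sorted(by_species):
        recs = by_species[species]
        pooled = pool_counts((count_codons(r) for r in recs), scope_id=species)
        comp = composition(pooled, code)
        per_gene_enc = [enc_observed(count_codons(r), code) for r in recs]
        finite = [e for e in per_gene_enc if not math.isnan(e)]
        rows.append({
            "species_id": species,
            "n_genes": len(recs),
            "n_codons": comp["n_codons"],
            "gc1": comp["gc1"],
            "gc2": comp["gc2"],
            "gc3": comp["gc3"],
            "gc_all": comp["gc_all"],
            "gc3s": comp["gc3s"],
            "enc_pooled": enc_observed(pooled, code),
            "enc_mean": float(np.mean(finite)) if finite else math.nan,
        })
    return pd.DataFrame(rows)


def rscu_matrix(
    scoped_counts: Mapping[str, CodonCounts] | Sequence[CodonCounts],
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """RSCU values as a codon x scope table (sense codons only, RNA spelling)."""
    from .genetic_code import to_rna

    code = code or default_code()
    if isinstance(scoped_counts, Mapping):
        items = list(scoped_counts.items())
    else:
        items = [(cc.scope_id, cc) for cc in scoped_counts]
    data = {}
    for scope, cc in items:
        profile = rscu(cc, code)
        data[scope] = {to_rna(c): profile.rscu[c] for c in code.sense_codons}
    df = pd.DataFrame(data)
    df.index.name = "codon"
    df.insert(0, "amino_acid", [code.codon_to_aa[c.replace("U", "T")] for c in df.index])
    return df
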