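"""Optimal codon identification from expression-proxy gene pools.

Genes are ranked by observed ENC; the lowest-ENC tenth (strongest bias, the
conventional proxy for high expression) forms the high-expression pool and the
highest-ENC tenth the low-expression pool.  RSCU is computed on the pooled
codon counts of each pool, and a codon is called optimal when it is
high-frequency in the high pool (RSCU > 1) and enriched there relative to the
low pool (deltaRSCU >= 0.08).  Single-codon families (Met, Trp) and stops are
never optimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .genetic_code import GeneticCode, default_code, to_rna
from .metrics import CodonCounts, count_codons, pool_counts, rscu
from .sequence_io import CdsRecord

POOL_FRACTION = 0.10
DELTA_RSCU_MIN = 0.08


@dataclass
class OptimalCodonResult:
    species_id: str
    high_pool: tuple[str, ...]
    low_pool: tuple[str, ...]
    rscu_high: dict[str, float]
    rscu_low: dict[str, float]
    delta_rscu: dict[str, float]
    optimal: frozenset[str] = field(default_factory=frozenset)

    def table(self, code: GeneticCode | None = None) -> pd.DataFrame:
        """Per-codon report (RNA spelling) over the degenerate sense codons."""
        code = code or default_code()
        rows = []
        for codon in code.degenerate_codons():
            rows.append({
                "codon": to_rna(codon),
                "amino_acid": code.codon_to_aa[codon],
                "rscu_high": self.rscu_high[codon],
                "rscu_low": self.rscu_low[codon],
                "delta_rscu": self.delta_rscu[codon],
                "optimal": codon in self.optimal,
            })
        return pd.DataFrame(rows)


def pool_size(n_genes: int, fraction: float = POOL_FRACTION) -> int:
    """Round-half-up of fraction * n, at least 1."""
    import math
    return max(1, int(math.floor(fraction * n_genes + 0.5)))


def build_pools(
    gene_stats: pd.DataFrame,
    fraction: float = POOL_FRACTION,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Split one species' genes into high/low-expression pools by ENC rank.

    Genes are sorted by (ENC_obs ascending, gene_id) — ties broken
    deterministically by gene_id — and the first/last ``round(fraction * n)``
    genes form the high- and low-expression pools respectively.

    Raises
    ------
    ValueError
        Fewer than 10 genes, or pools that would overlap.
    """
    df = gene_stats.dropna(subset=["enc_obs"])
    n = len(df)
    if n < 10:
        raise ValueError(f"need at least 10 genes to build expression pools, got {n}")
    size = pool_size(n, fraction)
    if 2 * size > n:
        raise ValueError(f"pools of {size} genes would overlap in a set of {n}")
    ordered = df.sort_values(["enc_obs", "gene_id"], kind="mergesort")
    high = tuple(ordered["gene_id"].iloc[:size])
    low = tuple(ordered["gene_id"].iloc[-size:])
    enc = ordered["enc_obs"].to_numpy(float)
    if enc[size - 1] == enc[size] or enc[n - size] == enc[n - size - 1]:
        warnings.warn(
            "ENC ties span a pool boundary; membership resolved by gene_id",
            stacklevel=2,
        )
    return high, low


def identify_optimal(
    rscu_high: dict[str, float],
    rscu_low: dict[str, float],
    delta_min: float = DELTA_RSCU_MIN,
    code: GeneticCode | None = None,
) -> tuple[frozenset[str], dict[str, float]]:
    """Apply the RSCU > 1 and deltaRSCU >= threshold criteria.

    Returns the optimal codon set (DNA spelling) and the deltaRSCU mapping
    over degenerate sense codons.
    """
    code = code or default_code()
    delta = {c: rscu_high[c] - rscu_low[c] for c in code.degenerate_codons()}
    optimal = frozenset(
        c for c in code.degenerate_codons()
        if rscu_high[c] > 1.0 and delta[c] >= delta_min
    )
    return optimal, delta


def optimal_codons(
    records: list[CdsRecord],
    gene_stats: pd.DataFrame,
    fraction: float = POOL_FRACTION,
    delta_min: float = DELTA_RSCU_MIN,
    code: GeneticCode | None = None,
    species_id: str | None = None,
) -> OptimalCodonResult:
    """Full optimal-codon analysis for one species' gene set."""
    code = code or default_code()
    if species_id is None:
        species = {r.species_id for r in records}
        species_id = species.pop() if len(species) == 1 else "pooled"
    high_ids, low_ids = build_pools(gene_stats, fraction)
    by_id = {r.gene_id: r for r in records}
    high_counts = pool_counts((count_codons(by_id[g]) for g in high_ids), "high")
    low_counts = pool_counts((count_codons(by_id[g]) for g in low_ids), "low")
    r_high = rscu(high_counts, code).rscu
    r_low = rscu(low_counts, code).rscu
    optimal, delta = identify_optimal(r_high, r_low, delta_min, code)
    return OptimalCodonResult(
        species_id=species_id,
        high_pool=high_ids,
        low_pool=low_ids,
        rscu_high=r_high,
        rscu_low=r_low,
        delta_rscu=delta,
        optimal=optimal,
    )


def shared_optimal(results: list[OptimalCodonResult]) -> tuple[frozenset[str], int]:
    """Intersection of per-species optimal sets and its count of A/U-ending codons."""
    if len(results) < 2:
        raise ValueError("need results from at least 2 species to intersect")
    shared = frozenset.intersection(*(r.optimal for r in results))
    au_ending = sum(1 for c in shared if c[2] in "AT")
    return shared, au_ending
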