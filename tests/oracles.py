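"""Independent brute-force reference implementations used to cross-check the
package's codon statistics.

Deliberately coded from scratch against the written formulas, with the genetic
code taken from Biopython's CodonTable (translation table 11) rather than the
package's own mapping.  Shared conventions (stop exclusion, Wright F with
n >= 2 and positive F, 3-fold mean imputed from the 2- and 4-fold means,
cap at 61) are re-stated here explicitly.
"""

from __future__ import annotations

import math

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[11]

_BASES = "ACGT"
ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
SENSE = [c for c in ALL_CODONS if c not in _TABLE.stop_codons]

FAMILIES: dict[str, list[str]] = {}
for codon in SENSE:
    FAMILIES.setdefault(_TABLE.forward_table[codon], []).append(codon)


def brute_rscu(counts: dict[str, int]) -> dict[str, float]:
    out = {}
    for aa, fam in FAMILIES.items():
        total = 0
        for c in fam:
            total += counts.get(c, 0)
        for c in fam:
            if total == 0:
                out[c] = 0.0
            else:
                out[c] = counts.get(c, 0) * len(fam) / total
    return out


def brute_composition(counts: dict[str, int]) -> dict[str, float]:
    # expand to an explicit base string and count characters
    bases = "".join(c * counts.get(c, 0) for c in SENSE)
    n = len(bases) // 3
    if n == 0:
        raise ValueError("no sense codons")
    pos = {1: "", 2: "", 3: ""}
    for i in range(0, len(bases), 3):
        pos[1] += bases[i]
        pos[2] += bases[i + 1]
        pos[3] += bases[i + 2]
    gc = {p: (s.count("G") + s.count("C")) / n for p, s in pos.items()}
    third_deg = ""
    for aa, fam in FAMILIES.items():
        if len(fam) < 2:
            continue
        for c in fam:
            third_deg += c[2] * counts.get(c, 0)
    gc3s = (
        (third_deg.count("G") + third_deg.count("C")) / len(third_deg)
        if third_deg else math.nan
    )
    return {
        "n_codons": n,
        "gc1": gc[1], "gc2": gc[2], "gc3": gc[3],
        "gc12": (gc[1] + gc[2]) / 2, "gc_all": (gc[1] + gc[2] + gc[3]) / 3,
        "gc3s": gc3s,
        "a3": pos[3].count("A"), "t3": pos[3].count("T"),
        "g3": pos[3].count("G"), "c3": pos[3].count("C"),
    }


def brute_enc(counts: dict[str, int]) -> float:
    f_by_k: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in FAMILIES.items():
        k = len(fam)
        if k == 1:
            continue
        xs = [counts.get(c, 0) for c in fam]
        n = sum(xs)
        if n < 2:
            continue
        s = sum((x / n) ** 2 for x in xs)
        f = (n * s - 1) / (n - 1)
        if f > 0:
            f_by_k[k].append(f)
    mean = {k: sum(v) / len(v) if v else None for k, v in f_by_k.items()}
    if mean[2] is None or mean[4] is None or mean[6] is None:
        return math.nan
    if mean[3] is None:
        mean[3] = (mean[2] + mean[4]) / 2
    enc = 2 + 9 / mean[2] + 1 / mean[3] + 5 / mean[4] + 3 / mean[6]
    return min(enc, 61.0)


def brute_ols(x, y) -> tuple[float, float]:
    """Closed-form simple least squares: slope and intercept."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    return slope, my - slope * mx


def brute_pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    syy = sum((yi - my) ** 2 for yi in y)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    return sxy / math.sqrt(sxx * syy)
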