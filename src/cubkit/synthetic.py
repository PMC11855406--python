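"""Synthetic coding sequences with known codon-usage structure.

Every analysis stage in this package can be exercised offline against gene
sets whose ground truth is known by construction.  Genes always satisfy the
CDS filter (ATG start, single terminal stop, no internal stop, length > 300 nt
and a multiple of 3), so the generator's output enters the pipeline with zero
exclusions.

Four regimes are provided:

``uniform``
    Amino acids i.i.d. from ``aa_freqs``, synonymous codons i.i.d. from
    ``family_probs`` (uniform by default).  Genome-wide RSCU tends to 1 and
    per-gene ENC to its maximum of 61 as coding length grows.

``mutation``
    One per-gene GC pressure parameter g (spread across ``gc3_gradient``)
    drives all three codon positions: each codon is drawn from the
    mutation-equilibrium distribution over sense codons with per-base
    P(G) = P(C) = g/2.  GC12 then tracks GC3 gene-to-gene, so the neutrality
    regression has slope near 1.  (Drawing from the stop-free categorical is
    exactly i.i.d. mutational base sampling with stop-prone draws resampled.)

``selection``
    Amino-acid composition is held fixed while a per-gene parameter t reweights
    synonymous codons by their third base (weight t for G/C-ending, 1 - t for
    A/T-ending).  GC3 sweeps the gradient while expected GC12 stays constant
    (within the 6-fold families the first-position composition is invariant to
    this reweighting), so the neutrality slope is near 0.

``planted-optimal``
    A designated tenth of the genes ("planted", the putative high-expression
    pool) uses the planted codon exclusively within each planted codon's
    family; all other usage is allocated by deterministic largest-remainder
    quota from ``family_probs``, identical across genes.  Planted genes are
    therefore the unique lowest-ENC genes and the high/low pool contrast in
    deltaRSCU is exactly the planted set — the optimal-codon procedure must
    recover it exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genetic_code import GeneticCode, SENSE_CODONS, STOP_CODONS, default_code
from .sequence_io import CdsRecord

REGIMES = ("uniform", "mutation", "selection", "planted-optimal")

DEFAULT_PLANTED_CODONS = ("GCT", "AAA", "CCT", "TCT", "GTA")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic gene set.

    ``family_probs`` maps amino acid -> probability vector over its codons (in
    genetic-code order); ``aa_freqs`` maps amino acid -> frequency.  Both
    default to uniform.  ``gc3_gradient`` is the range swept by the per-gene
    pressure parameter of the mutation/selection regimes.
    """

    n_genes: int = 51
    length_range: tuple[int, int] = (303, 1500)
    regime: str = "uniform"
    seed: int = 0
    gc3_gradient: tuple[float, float] = (0.2, 0.8)
    aa_freqs: Mapping[str, float] | None = None
    family_probs: Mapping[str, Sequence[float]] | None = None
    planted_codons: tuple[str, ...] = DEFAULT_PLANTED_CODONS
    planted_fraction: float = 0.10
    species_id: str = "synthetic"

    def validate(self, code: GeneticCode | None = None) -> None:
        code = code or default_code()
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.length_range
        if lo > hi or lo <= 300 or lo % 3 or hi % 3:
            raise ValueError(
                "length_range must be multiples of 3 with 300 < lo <= hi"
            )
        if not 0.0 <= self.gc3_gradient[0] <= self.gc3_gradient[1] <= 1.0:
            raise ValueError("gc3_gradient must be an ordered pair in [0, 1]")
        if self.aa_freqs is not None:
            if abs(sum(self.aa_freqs.values()) - 1.0) > 1e-9:
                raise ValueError("aa_freqs must sum to 1")
        if self.family_probs is not None:
            for aa, probs in self.family_probs.items():
                if len(probs) != len(code.families[aa]):
                    raise ValueError(f"family_probs[{aa}] has wrong length")
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ValueError(f"family_probs[{aa}] must sum to 1")
        for codon in self.planted_codons:
            if codon not in SENSE_CODONS or len(code.families[code.codon_to_aa[codon]]) < 2:
                raise ValueError(f"planted codon {codon} is not a degenerate sense codon")


@dataclass
class GeneTruth:
    gene_id: str
    regime: str
    pressure: float  # g (mutation) or t (selection); NaN otherwise
    planted: bool
    codon_probs: dict[str, float]  # realized sense-codon distribution


@dataclass
class GroundTruth:
    spec: SyntheticSpec
    genes: list[GeneTruth]
    planted_codons: tuple[str, ...] = ()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "regime": g.regime,
                    "pressure": g.pressure,
                    "planted": g.planted,
                }
                for g in self.genes
            ]
        )


def _aa_vector(code: GeneticCode, aa_freqs: Mapping[str, float] | None) -> dict[str, float]:
    aas = sorted(code.families)
    if aa_freqs is None:
        return {aa: 1.0 / len(aas) for aa in aas}
    return {aa: aa_freqs.get(aa, 0.0) for aa in aas}


def _family_vector(
    code: GeneticCode, family_probs: Mapping[str, Sequence[float]] | None, aa: str
) -> np.ndarray:
    fam = code.families[aa]
    if family_probs is not None and aa in family_probs:
        return np.asarray(family_probs[aa], dtype=float)
    return np.full(len(fam), 1.0 / len(fam))


def _codon_distribution_uniform(code, aa_freqs, family_probs) -> np.ndarray:
    p = np.zeros(len(SENSE_CODONS))
    aa_p = _aa_vector(code, aa_freqs)
    index = {c: i for i, c in enumerate(SENSE_CODONS)}
    for aa, fam in code.families.items():
        fp = _family_vector(code, family_probs, aa)
        for c, w in zip(fam, fp):
            p[index[c]] = aa_p[aa] * w
    return p / p.sum()


def _codon_distribution_mutation(g: float) -> np.ndarray:
    """Mutation-equilibrium sense-codon distribution at GC pressure g."""
    base_w = {"G": g / 2.0, "C": g / 2.0, "A": (1.0 - g) / 2.0, "T": (1.0 - g) / 2.0}
    w = np.array([math.prod(base_w[b] for b in codon) for codon in SENSE_CODONS])
    return w / w.sum()


def _codon_distribution_selection(code, aa_freqs, t: float) -> np.ndarray:
    p = np.zeros(len(SENSE_CODONS))
    aa_p = _aa_vector(code, aa_freqs)
    index = {c: i for i, c in enumerate(SENSE_CODONS)}
    for aa, fam in code.families.items():
        w = np.array([t if c[2] in "GC" else 1.0 - t for c in fam])
        if w.sum() == 0.0:
            w = np.full(len(fam), 1.0)
        w = w / w.sum()
        for c, wc in zip(fam, w):
            p[index[c]] = aa_p[aa] * wc
    return p / p.sum()


def _quota(n: int, probs: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    """Largest-remainder allocation of n items to categories with the given
    probabilities; remainder ties broken by category order (deterministic) or
    randomised when an rng is supplied."""
    exact = n * probs
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        frac = exact - counts
        if rng is None:
            order = np.argsort(-frac, kind="stable")
        else:
            order = np.argsort(-(frac + rng.uniform(0, 1e-9, len(frac))), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def _planted_gene_codons(
    code: GeneticCode,
    spec: SyntheticSpec,
    n_internal: int,
    planted: bool,
) -> tuple[list[str], dict[str, float]]:
    """Deterministic quota codon multiset for one planted-regime gene."""
    aa_p = _aa_vector(code, spec.aa_freqs)
    aas = sorted(code.families)
    aa_counts = _quota(n_internal, np.array([aa_p[a] for a in aas]), rng=None)
    planted_by_aa = {code.codon_to_aa[c]: c for c in spec.planted_codons}
    codons: list[str] = []
    probs: dict[str, float] = {}
    for aa, n_aa in zip(aas, aa_counts):
        fam = list(code.families[aa])
        if planted and aa in planted_by_aa:
            fam_counts = [n_aa if c == planted_by_aa[aa] else 0 for c in fam]
        else:
            fp = _family_vector(code, spec.family_probs, aa)
            fam_counts = _quota(int(n_aa), fp, rng=None)
        for c, k in zip(fam, fam_counts):
            codons.extend([c] * int(k))
            probs[c] = (k / n_aa) if n_aa else 0.0
    return codons, probs


def generate(
    spec: SyntheticSpec, code: GeneticCode | None = None
) -> tuple[list[CdsRecord], GroundTruth]:
    """Generate a synthetic gene set and its ground truth.

    The same spec (including seed) always yields byte-identical sequences.
    """
    code = code or default_code()
    spec.validate(code)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    lo, hi = spec.length_range
    n_choices = (hi - lo) // 3 + 1
    lengths = lo + 3 * rng.integers(0, n_choices, size=n)

    if spec.regime in ("mutation", "selection"):
        g_lo, g_hi = spec.gc3_gradient
        pressures = (
            np.linspace(g_lo, g_hi, n) if n > 1 else np.array([(g_lo + g_hi) / 2.0])
        )
    else:
        pressures = np.full(n, math.nan)

    if spec.regime == "planted-optimal":
        # fixed length so every gene shares the same quota allocation
        lengths = np.full(n, lo)
        n_planted = max(1, int(math.floor(spec.planted_fraction * n + 0.5)))
        planted_flags = np.zeros(n, dtype=bool)
        planted_flags[:n_planted] = True
    else:
        planted_flags = np.zeros(n, dtype=bool)

    width = len(str(n))
    sense = np.array(SENSE_CODONS)
    records: list[CdsRecord] = []
    truths: list[GeneTruth] = []
    for i in range(n):
        gene_id = f"gene_{i + 1:0{width}d}"
        n_internal = int(lengths[i]) // 3 - 2
        if spec.regime == "uniform":
            p = _codon_distribution_uniform(code, spec.aa_freqs, spec.family_probs)
            internal = list(sense[rng.choice(len(sense), size=n_internal, p=p)])
        elif spec.regime == "mutation":
            p = _codon_distribution_mutation(float(pressures[i]))
            internal = list(sense[rng.choice(len(sense), size=n_internal, p=p)])
        elif spec.regime == "selection":
            p = _codon_distribution_selection(code, spec.aa_freqs, float(pressures[i]))
            internal = list(sense[rng.choice(len(sense), size=n_internal, p=p)])
        else:  # planted-optimal
            internal, probs = _planted_gene_codons(
                code, spec, n_internal, bool(planted_flags[i])
            )
            rng.shuffle(internal)
            p = None
        stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
        sequence = "ATG" + "".join(internal) + stop
        codon_probs = (
            probs if p is None else {c: float(pi) for c, pi in zip(SENSE_CODONS, p)}
        )
        records.append(CdsRecord(gene_id, spec.species_id, sequence))
        truths.append(
            GeneTruth(
                gene_id=gene_id,
                regime=spec.regime,
                pressure=float(pressures[i]),
                planted=bool(planted_flags[i]),
                codon_probs=codon_probs,
            )
        )
    truth = GroundTruth(
        spec=spec,
        genes=truths,
        planted_codons=spec.planted_codons if spec.regime == "planted-optimal" else (),
    )
    return records, truth


def regime_presets(name: str, **overrides) -> SyntheticSpec:
    """Named generator configurations for the three structured regimes.

    ``mutation`` sweeps a broad GC gradient coupling all codon positions
    (neutrality slope near 1); ``selection`` sweeps GC3 only (slope near 0);
    ``planted-optimal`` plants a known optimal-codon set in the low-ENC tenth
    of the genes.  Keyword overrides replace any spec field.
    """
    presets = {
        "mutation": SyntheticSpec(
            regime="mutation", n_genes=51, length_range=(903, 1503),
            gc3_gradient=(0.2, 0.8), species_id="sim_mutation",
        ),
        "selection": SyntheticSpec(
            regime="selection", n_genes=51, length_range=(903, 1503),
            gc3_gradient=(0.1, 0.9), species_id="sim_selection",
        ),
        "planted-optimal": SyntheticSpec(
            regime="planted-optimal", n_genes=50, length_range=(999, 999),
            species_id="sim_planted",
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return replace(presets[name], **overrides)


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
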