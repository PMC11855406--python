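"""End-to-end orchestration: extract -> stats -> diagnostics -> optimal codons.

Given one input file per species (GenBank plastome or FASTA of CDSs) the
pipeline writes the full set of result tables as TSV.  Output is
deterministic: tables are sorted by (species, gene) and floats are written at
fixed precision (3 decimals for fractions and RSCU, 2 for ENC, 4 for
regression and correlation quantities), so re-running a configuration
reproduces byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diagnostics, metrics, optimal as optimal_mod
from .genetic_code import default_code, to_rna
from .sequence_io import CdsRecord, filter_cds, read_genome, write_exclusion_report

logger = logging.getLogger(__name__)

MIN_GENES_FOR_OPTIMAL = 10

_DECIMALS = {
    "gc1": 3, "gc2": 3, "gc3": 3, "gc12": 3, "gc_all": 3, "gc3s": 3,
    "enc_obs": 2, "enc_exp": 2, "enc_pooled": 2, "enc_mean": 2,
    "enc_ratio": 4, "slope": 4, "intercept": 4, "r_squared": 4,
    "r": 4, "p": 4, "x": 4, "y": 4, "pct_in_band": 1,
    "rscu_high": 3, "rscu_low": 3, "delta_rscu": 3, "pressure": 4,
}


@dataclass
class RunConfig:
    """Plain-text round-trippable configuration of one pipeline run."""

    inputs: dict[str, str] = field(default_factory=dict)  # species_id -> path
    out_dir: str = "results"
    min_len: int = 301  # minimum retained CDS length in nt (inclusive)
    pool_fraction: float = 0.10
    delta_min: float = 0.08
    pooled_optimal: bool = False
    plots: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.inputs:
            raise ValueError("config lists no input files")
        if self.min_len <= 0 or not 0 < self.pool_fraction < 0.5 or self.delta_min < 0:
            raise ValueError("thresholds must be positive (pool fraction below 0.5)")

    def to_file(self, path: str | Path) -> None:
        lines = []
        for species, p in sorted(self.inputs.items()):
            lines.append(f"input.{species}={p}")
        lines += [
            f"out_dir={self.out_dir}",
            f"min_len={self.min_len}",
            f"pool_fraction={self.pool_fraction}",
            f"delta_min={self.delta_min}",
            f"pooled_optimal={str(self.pooled_optimal).lower()}",
            f"plots={str(self.plots).lower()}",
            f"seed={self.seed}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cfg = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key.startswith("input."):
                cfg.inputs[key[len("input."):]] = value
            elif key == "out_dir":
                cfg.out_dir = value
            elif key == "min_len":
                cfg.min_len = int(value)
            elif key == "pool_fraction":
                cfg.pool_fraction = float(value)
            elif key == "delta_min":
                cfg.delta_min = float(value)
            elif key == "pooled_optimal":
                cfg.pooled_optimal = value.lower() in ("true", "1", "yes")
            elif key == "plots":
                cfg.plots = value.lower() in ("true", "1", "yes")
            elif key == "seed":
                cfg.seed = int(value)
            else:
                raise ValueError(f"unknown config key: {key}")
        return cfg


@dataclass
class RunResult:
    genes: pd.DataFrame
    species: pd.DataFrame
    neutrality: pd.DataFrame
    enc_ratio_genes: pd.DataFrame
    enc_ratio_summary: pd.DataFrame
    pr2_genes: pd.DataFrame
    pr2_summary: pd.DataFrame
    correlations: pd.DataFrame
    optimal_results: list
    optimal_table: pd.DataFrame
    shared_optimal: frozenset[str]
    shared_au_ending: int
    records: dict[str, list[CdsRecord]]
    manifest: pd.DataFrame


def _format_tsv(df: pd.DataFrame, path: Path) -> int:
    out = df.copy()
    for col, dec in _DECIMALS.items():
        if col in out.columns:
            out[col] = out[col].map(
                lambda v, d=dec: "" if pd.isna(v) else f"{v:.{d}f}"
            )
    out.to_csv(path, sep="\t", index=False)
    return len(out)


def analyze_records(
    records_by_species: dict[str, list[CdsRecord]],
    pool_fraction: float = 0.10,
    delta_min: float = 0.08,
    pooled_optimal: bool = False,
) -> RunResult:
    """Run all statistics and diagnostics on already-filtered gene sets."""
    code = default_code()
    all_records = [r for recs in records_by_species.values() for r in recs]
    genes = metrics.genes_table(all_records, code)
    species = metrics.species_summary(all_records, code)

    fits = []
    for sp in sorted(records_by_species):
        try:
            fit = diagnostics.neutrality_fit(genes, species_id=sp)
            fits.append({
                "species_id": fit.species_id, "slope": fit.slope,
                "intercept": fit.intercept, "r_squared": fit.r_squared,
                "n_genes": fit.n_genes,
            })
        except ValueError as exc:
            logger.warning("neutrality fit skipped for %s: %s", sp, exc)
    neutrality = pd.DataFrame(fits)

    ratio_genes, ratio_summary = diagnostics.enc_ratio_classify(genes)
    pr2 = diagnostics.pr2_points(genes)
    pr2_sum = diagnostics.pr2_summary(pr2)
    corr = diagnostics.correlation_matrix(genes)

    optimal_results = []
    if pooled_optimal:
        pooled_records = [
            CdsRecord(f"{r.species_id}:{r.gene_id}", "pooled", r.sequence)
            for r in all_records
        ]
        pooled_genes = metrics.genes_table(pooled_records, code)
        optimal_results.append(
            optimal_mod.optimal_codons(
                pooled_records, pooled_genes, pool_fraction, delta_min, code, "pooled"
            )
        )
    else:
        for sp in sorted(records_by_species):
            recs = records_by_species[sp]
            if len(recs) < MIN_GENES_FOR_OPTIMAL:
                logger.warning(
                    "optimal-codon stage skipped for %s: only %d genes", sp, len(recs)
                )
                continue
            sp_genes = genes[genes["species_id"] == sp]
            optimal_results.append(
                optimal_mod.optimal_codons(
                    recs, sp_genes, pool_fraction, delta_min, code, sp
                )
            )

    tables = []
    for res in optimal_results:
        t = res.table(code)
        t.insert(0, "species_id", res.species_id)
        tables.append(t)
    optimal_table = (
        pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    )
    if len(optimal_results) >= 2:
        shared, au = optimal_mod.shared_optimal(optimal_results)
    elif optimal_results:
        shared = optimal_results[0].optimal
        au = sum(1 for c in shared if c[2] in "AT")
    else:
        shared, au = frozenset(), 0
    return RunResult(
        genes=genes, species=species, neutrality=neutrality,
        enc_ratio_genes=ratio_genes, enc_ratio_summary=ratio_summary,
        pr2_genes=pr2, pr2_summary=pr2_sum, correlations=corr,
        optimal_results=optimal_results, optimal_table=optimal_table,
        shared_optimal=shared, shared_au_ending=au,
        records=records_by_species, manifest=pd.DataFrame(),
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis described by a configuration and write TSVs."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records_by_species: dict[str, list[CdsRecord]] = {}
    exclusion_rows = []
    for species in sorted(config.inputs):
        path = config.inputs[species]
        raw = read_genome(path, species_id=species)
        retained, excluded = filter_cds(raw, min_length=config.min_len - 1)
        records_by_species[species] = retained
        for exc in excluded:
            exclusion_rows.append(
                {"species_id": species, "gene": exc.gene_id, "reason": exc.reason}
            )
        logger.info("%s: %d genes retained, %d excluded", species, len(retained), len(excluded))

    result = analyze_records(
        records_by_species,
        pool_fraction=config.pool_fraction,
        delta_min=config.delta_min,
        pooled_optimal=config.pooled_optimal,
    )

    code = default_code()
    pooled_by_species = {
        sp: metrics.pool_counts(
            (metrics.count_codons(r) for r in recs), scope_id=sp
        )
        for sp, recs in sorted(records_by_species.items())
    }
    rscu_tab = metrics.rscu_matrix(pooled_by_species, code).reset_index()
    for col in rscu_tab.columns:
        if col not in ("codon", "amino_acid"):
            rscu_tab[col] = rscu_tab[col].map(lambda v: f"{v:.3f}")

    shared_tab = pd.DataFrame(
        [
            {"codon": to_rna(c), "amino_acid": code.codon_to_aa[c],
             "ends_a_or_u": c[2] in "AT"}
            for c in sorted(result.shared_optimal)
        ],
        columns=["codon", "amino_acid", "ends_a_or_u"],
    )

    written = {
        "exclusions.tsv": pd.DataFrame(
            exclusion_rows, columns=["species_id", "gene", "reason"]
        ),
        "genes.tsv": result.genes,
        "species_summary.tsv": result.species,
        "neutrality.tsv": result.neutrality,
        "enc_ratio_genes.tsv": result.enc_ratio_genes,
        "enc_ratio_summary.tsv": result.enc_ratio_summary,
        "pr2_genes.tsv": result.pr2_genes,
        "pr2_summary.tsv": result.pr2_summary,
        "correlations.tsv": result.correlations,
        "optimal_codons.tsv": result.optimal_table,
        "shared_optimal.tsv": shared_tab,
    }
    manifest_rows = []
    for name, df in written.items():
        n = _format_tsv(df, out_dir / name)
        manifest_rows.append({"file": name, "n_rows": n})
    rscu_tab.to_csv(out_dir / "rscu_species.tsv", sep="\t", index=False)
    manifest_rows.append({"file": "rscu_species.tsv", "n_rows": len(rscu_tab)})

    if config.plots:
        from . import plots

        fig_dir = out_dir / "figures"
        fig_dir.mkdir(exist_ok=True)
        for name in plots.save_all(result, fig_dir):
            manifest_rows.append({"file": f"figures/{name}", "n_rows": 0})

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    result.manifest = manifest
    return result
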