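"""Diagnostics separating mutation pressure from natural selection.

Four classical views of a gene set's codon usage:

* **Neutrality plot** — ordinary least squares of GC12 on GC3 across genes.
  A slope near 1 means the first two codon positions track the third, i.e.
  directional mutation pressure dominates; a slope near 0 means selection
  holds the protein-coding positions while the third drifts.
* **ENC ratio** — (ENC_exp - ENC_obs) / ENC_exp per gene; genes within
  +/- 0.05 of zero are consistent with mutation alone, larger positive values
  mean usage is more biased than composition predicts.
* **PR2 plot** — per-gene point (G3/(G3+C3), A3/(A3+T3)) over third positions
  of sense codons; (0.5, 0.5) is the mutational-equilibrium centre where
  A = T and G = C within a strand.
* **Correlation matrix** — Pearson correlations (two-sided p) among the
  composition parameters, ENC and gene length in codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PR2_CENTER = 0.5
ENC_RATIO_BAND = 0.05
ENC_RATIO_BIN_WIDTH = 0.05

CORRELATION_VARIABLES = ("gc1", "gc2", "gc3", "gc_all", "enc_obs", "n_codons")


@dataclass(frozen=True)
class NeutralityFit:
    species_id: str
    slope: float
    intercept: float
    r_squared: float
    n_genes: int

    @property
    def mutation_share(self) -> float:
        """The slope read as the relative contribution of mutation pressure."""
        return self.slope

    @property
    def selection_share(self) -> float:
        return 1.0 - self.slope


def neutrality_fit(gene_stats: pd.DataFrame, species_id: str | None = None) -> NeutralityFit:
    """OLS regression of GC12 on GC3 over the genes of one species.

    Raises
    ------
    ValueError
        Fewer than 3 usable genes, or zero variance in GC3 (undefined slope).
    """
    df = gene_stats.dropna(subset=["gc12", "gc3"])
    if species_id is not None and "species_id" in df.columns:
        df = df[df["species_id"] == species_id]
    elif species_id is None:
        species = df["species_id"].unique() if "species_id" in df.columns else ["?"]
        species_id = species[0] if len(species) == 1 else "pooled"
    if len(df) < 3:
        raise ValueError(f"need at least 3 genes for a neutrality fit, got {len(df)}")
    x = df["gc3"].to_numpy(float)
    y = df["gc12"].to_numpy(float)
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in GC3: neutrality slope undefined")
    fit = stats.linregress(x, y)
    return NeutralityFit(
        species_id=str(species_id),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        n_genes=len(df),
    )


def enc_ratio_classify(gene_stats: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene ENC ratios with histogram bins, plus the class summary.

    Bins are width 0.05 with edges at multiples of 0.05, closed on the left.
    The summary reports, per species, how many genes fall inside the
    mutation-consistent band |ratio| <= 0.05 and the corresponding percentage.
    """
    df = gene_stats[["species_id", "gene_id", "enc_obs", "enc_exp", "enc_ratio"]].copy()
    ratios = df["enc_ratio"].to_numpy(float)
    lower = np.floor(ratios / ENC_RATIO_BIN_WIDTH) * ENC_RATIO_BIN_WIDTH
    df["bin"] = [
        f"[{lo:.2f},{lo + ENC_RATIO_BIN_WIDTH:.2f})" if not math.isnan(lo) else "NA"
        for lo in lower
    ]
    df["in_band"] = np.abs(ratios) <= ENC_RATIO_BAND
    summary_rows = []
    for species, grp in df.groupby("species_id", sort=True):
        n = int(grp["enc_ratio"].notna().sum())
        n_in = int(grp["in_band"].sum())
        summary_rows.append({
            "species_id": species,
            "n_genes": n,
            "n_in_band": n_in,
            "pct_in_band": 100.0 * n_in / n if n else math.nan,
        })
    return df, pd.DataFrame(summary_rows)


def pr2_points(gene_stats: pd.DataFrame) -> pd.DataFrame:
    """Parity-rule-2 coordinates per gene.

    x = G3/(G3+C3), y = A3/(A3+T3); a zero denominator flags the point
    undefined (NaN coordinates).  Quadrants are labelled relative to
    (0.5, 0.5); the ``quadrant`` column is e.g. ``lower-right`` for y < 0.5,
    x > 0.5 (T over A, G over C).
    """
    df = gene_stats[["species_id", "gene_id", "a3", "t3", "g3", "c3"]].copy()
    gc = df["g3"] + df["c3"]
    at = df["a3"] + df["t3"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["x"] = np.where(gc > 0, df["g3"] / gc, np.nan)
        df["y"] = np.where(at > 0, df["a3"] / at, np.nan)

    def quadrant(x: float, y: float) -> str:
        if math.isnan(x) or math.isnan(y):
            return "undefined"
        vert = "upper" if y > PR2_CENTER else ("lower" if y < PR2_CENTER else "center")
        horiz = "right" if x > PR2_CENTER else ("left" if x < PR2_CENTER else "center")
        return f"{vert}-{horiz}"

    df["quadrant"] = [quadrant(x, y) for x, y in zip(df["x"], df["y"])]
    return df


def pr2_summary(points: pd.DataFrame) -> pd.DataFrame:
    """Quadrant occupancy per species for the PR2 plot."""
    rows = []
    for species, grp in points.groupby("species_id", sort=True):
        counts = grp["quadrant"].value_counts()
        rows.append({
            "species_id": species,
            "n_genes": len(grp),
            "lower_half": int((grp["y"] < PR2_CENTER).sum()),
            "upper_half": int((grp["y"] > PR2_CENTER).sum()),
            **{q: int(counts.get(q, 0))
               for q in ("lower-left", "lower-right", "upper-left", "upper-right")},
        })
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_matrix(
    gene_stats: pd.DataFrame,
    variables: tuple[str, ...] = CORRELATION_VARIABLES,
    species_id: str | None = None,
) -> pd.DataFrame:
    """Pearson correlations among codon parameters, long format.

    One row per unordered variable pair per species: r, the two-sided p-value
    from the t distribution with n - 2 degrees of freedom, n, and the star
    annotation (** p < 0.01, * p < 0.05).  Zero-variance variables yield NaN
    and are flagged in the ``note`` column.
    """
    df = gene_stats
    if species_id is not None:
        df = df[df["species_id"] == species_id]
    groups = (
        df.groupby("species_id", sort=True)
        if "species_id" in df.columns else [("?", df)]
    )
    rows = []
    for species, grp in groups:
        for i, v1 in enumerate(variables):
            for v2 in variables[i + 1:]:
                sub = grp[[v1, v2]].dropna()
                n = len(sub)
                note = ""
                if n < 3:
                    r, p, note = math.nan, math.nan, "n < 3"
                elif sub[v1].nunique() == 1 or sub[v2].nunique() == 1:
                    r, p, note = math.nan, math.nan, "zero variance"
                else:
                    r, p = stats.pearsonr(sub[v1], sub[v2])
                rows.append({
                    "species_id": species,
                    "var1": v1,
                    "var2": v2,
                    "r": float(r),
                    "p": float(p),
                    "n": n,
                    "stars": significance_stars(float(p)),
                    "note": note,
                })
    return pd.DataFrame(rows)
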