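"""Optional figures mirroring the standard codon-usage diagnostics.

Plots are conveniences; the TSV tables are the contract.  All functions take
the pipeline's data frames and an output path and save PNG files via the Agg
backend.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .metrics import enc_expected  # noqa: E402


def plot_neutrality(genes, path) -> None:
    """GC12 vs GC3 scatter with the per-species OLS line and the diagonal."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for sp, grp in genes.groupby("species_id"):
        ax.scatter(grp["gc3"], grp["gc12"], s=12, alpha=0.6, label=sp)
    lim = [0, 1]
    ax.plot(lim, lim, "k--", lw=0.8, label="GC12 = GC3")
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.set_title("Neutrality plot")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_enc(genes, path) -> None:
    """ENC vs GC3 scatter with the mutation-only expectation curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = np.linspace(0.0, 1.0, 201)
    ax.plot(xs, [enc_expected(x) for x in xs], "k-", lw=1, label="expected")
    for sp, grp in genes.groupby("species_id"):
        ax.scatter(grp["gc3"], grp["enc_obs"], s=12, alpha=0.6, label=sp)
    ax.set_xlabel("GC3")
    ax.set_ylabel("ENC")
    ax.set_ylim(15, 65)
    ax.set_title("ENC plot")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_enc_ratio_hist(ratio_genes, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ratios = ratio_genes["enc_ratio"].dropna()
    lo = np.floor(ratios.min() / 0.05) * 0.05
    hi = np.ceil(ratios.max() / 0.05) * 0.05
    bins = np.arange(lo, hi + 0.05, 0.05)
    ax.hist(ratios, bins=bins, edgecolor="black")
    ax.set_xlabel("(ENC_exp - ENC_obs) / ENC_exp")
    ax.set_ylabel("genes")
    ax.set_title("ENC ratio distribution")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pr2(pr2_genes, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for sp, grp in pr2_genes.groupby("species_id"):
        ax.scatter(grp["x"], grp["y"], s=12, alpha=0.6, label=sp)
    ax.axhline(0.5, color="k", lw=0.8)
    ax.axvline(0.5, color="k", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + T3)")
    ax.set_title("PR2 bias plot")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_all(result, fig_dir: Path) -> list[str]:
    fig_dir = Path(fig_dir)
    made = []
    for name, fn, df in [
        ("neutrality.png", plot_neutrality, result.genes),
        ("enc_plot.png", plot_enc, result.genes),
        ("enc_ratio_hist.png", plot_enc_ratio_hist, result.enc_ratio_genes),
        ("pr2.png", plot_pr2, result.pr2_genes),
    ]:
        fn(df, fig_dir / name)
        made.append(name)
    return made
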