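"""Neutrality regression, ENC-ratio classes, PR2 geometry, correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cubkit.diagnostics import (
    correlation_matrix,
    enc_ratio_classify,
    neutrality_fit,
    pr2_points,
    pr2_summary,
    significance_stars,
)

from oracles import brute_ols, brute_pearson


def _stats_frame(gc3, gc12, species="sp"):
    n = len(gc3)
    return pd.DataFrame({
        "species_id": [species] * n,
        "gene_id": [f"g{i}" for i in range(n)],
        "gc3": gc3,
        "gc12": gc12,
    })


class TestNeutrality:
    def test_identity_line(self):
        x = [0.1, 0.3, 0.5, 0.7]
        fit = neutrality_fit(_stats_frame(x, x))
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.selection_share == pytest.approx(0.0)

    def test_constant_gc12(self):
        fit = neutrality_fit(_stats_frame([0.1, 0.4, 0.8], [0.5, 0.5, 0.5]))
        assert fit.slope == pytest.approx(0.0)

    def test_agrees_with_closed_form(self, rng):
        x = rng.uniform(0.2, 0.8, size=40)
        y = 0.3 * x + 0.2 + rng.normal(0, 0.02, size=40)
        fit = neutrality_fit(_stats_frame(x, y))
        slope, intercept = brute_ols(list(x), list(y))
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        r = brute_pearson(list(x), list(y))
        assert fit.r_squared == pytest.approx(r * r, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            neutrality_fit(_stats_frame([0.1, 0.2], [0.1, 0.2]))  # n < 3
        with pytest.raises(ValueError):
            neutrality_fit(_stats_frame([0.4, 0.4, 0.4], [0.1, 0.2, 0.3]))


class TestEncRatio:
    def test_band_membership_and_bins(self):
        df = pd.DataFrame({
            "species_id": ["sp"] * 4,
            "gene_id": list("abcd"),
            "enc_obs": [60.5, 45.0, 58.0, 63.0],
            "enc_exp": [60.5, 60.5, 60.5, 60.5],
        })
        df["enc_ratio"] = (df["enc_exp"] - df["enc_obs"]) / df["enc_exp"]
        genes, summary = enc_ratio_classify(df)
        assert genes.loc[0, "in_band"] and not genes.loc[1, "in_band"]
        assert genes.loc[1, "enc_ratio"] == pytest.approx(0.2562, abs=1e-4)
        assert genes.loc[1, "bin"] == "[0.25,0.30)"
        assert genes.loc[3, "bin"].startswith("[-0.05")
        row = summary.iloc[0]
        assert row["n_in_band"] == 3 and row["pct_in_band"] == pytest.approx(75.0)


class TestPr2:
    def _frame(self, a, t, g, c):
        return pd.DataFrame({
            "species_id": ["sp"], "gene_id": ["g"],
            "a3": [a], "t3": [t], "g3": [g], "c3": [c],
        })

    def test_center_point(self):
        pt = pr2_points(self._frame(30, 30, 20, 20)).iloc[0]
        assert (pt["x"], pt["y"]) == (0.5, 0.5)

    def test_biased_point(self):
        pt = pr2_points(self._frame(10, 30, 30, 10)).iloc[0]
        assert pt["x"] == pytest.approx(0.75)
        assert pt["y"] == pytest.approx(0.25)
        assert pt["quadrant"] == "lower-right"

    def test_zero_denominator_flagged(self):
        pt = pr2_points(self._frame(5, 5, 0, 0)).iloc[0]
        assert math.isnan(pt["x"]) and pt["quadrant"] == "undefined"

    @settings(derandomize=True, max_examples=50)
    @given(st.tuples(*(st.integers(0, 50) for _ in range(4))))
    def test_complement_symmetry(self, abc):
        """Swapping A3<->T3 and G3<->C3 maps (x, y) to (1-x, 1-y)."""
        a, t, g, c = abc
        p = pr2_points(self._frame(a, t, g, c)).iloc[0]
        q = pr2_points(self._frame(t, a, c, g)).iloc[0]
        for v, w in ((p["x"], q["x"]), (p["y"], q["y"])):
            if math.isnan(v):
                assert math.isnan(w)
            else:
                assert v == pytest.approx(1.0 - w, abs=1e-12)

    def test_summary_counts_lower_half(self):
        df = pd.concat(
            [self._frame(10, 30, 30, 10), self._frame(30, 10, 10, 30),
             self._frame(5, 25, 20, 10)],
            ignore_index=True,
        )
        df["gene_id"] = ["g1", "g2", "g3"]
        summary = pr2_summary(pr2_points(df)).iloc[0]
        assert summary["lower_half"] == 2
        assert summary["lower-right"] == 2
        assert summary["upper-left"] == 1


class TestCorrelations:
    def _gene_frame(self, rng, n=30):
        gc1 = rng.uniform(0.3, 0.6, n)
        return pd.DataFrame({
            "species_id": ["sp"] * n,
            "gene_id": [f"g{i}" for i in range(n)],
            "gc1": gc1,
            "gc2": 2.0 * gc1 + 0.1,        # exact positive affine map
            "gc3": -gc1,                   # exact negative map
            "gc_all": rng.uniform(0.3, 0.5, n),
            "enc_obs": rng.uniform(40, 61, n),
            "n_codons": rng.integers(100, 900, n),
        })

    def test_affine_pairs_hit_plus_minus_one(self, rng):
        corr = correlation_matrix(self._gene_frame(rng))
        corr = corr.set_index(["var1", "var2"])
        assert corr.loc[("gc1", "gc2"), "r"] == pytest.approx(1.0)
        assert corr.loc[("gc1", "gc3"), "r"] == pytest.approx(-1.0)
        assert corr.loc[("gc1", "gc2"), "stars"] == "**"

    def test_pearson_matches_closed_form(self, rng):
        df = self._gene_frame(rng)
        corr = correlation_matrix(df).set_index(["var1", "var2"])
        r = brute_pearson(list(df["gc_all"]), list(df["enc_obs"]))
        assert corr.loc[("gc_all", "enc_obs"), "r"] == pytest.approx(r, abs=1e-10)

    def test_pearson_affine_invariance(self, rng):
        df = self._gene_frame(rng)
        df2 = df.copy()
        df2["gc_all"] = 3.0 * df2["gc_all"] + 1.0   # positive affine: r unchanged
        df2["enc_obs"] = -2.0 * df2["enc_obs"] + 5  # negative: r flips sign
        c1 = correlation_matrix(df).set_index(["var1", "var2"])
        c2 = correlation_matrix(df2).set_index(["var1", "var2"])
        assert c2.loc[("gc_all", "enc_obs"), "r"] == pytest.approx(
            -c1.loc[("gc_all", "enc_obs"), "r"], abs=1e-12
        )

    def test_zero_variance_flagged(self, rng):
        df = self._gene_frame(rng)
        df["gc3"] = 0.3
        corr = correlation_matrix(df).set_index(["var1", "var2"])
        assert math.isnan(corr.loc[("gc1", "gc3"), "r"])
        assert corr.loc[("gc1", "gc3"), "note"] == "zero variance"

    def test_stars(self):
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.2) == ""
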