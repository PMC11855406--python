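"""Codon counting, RSCU, positional composition, and Wright's ENC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cubkit.genetic_code import SENSE_CODONS, default_code
from cubkit.metrics import (
    CodonCounts,
    composition,
    count_codons,
    enc_expected,
    enc_observed,
    enc_ratio,
    gene_stats,
    pool_counts,
    rscu,
    species_summary,
    _family_homozygosity,
)
from cubkit.sequence_io import CdsRecord
from cubkit.synthetic import SyntheticSpec, generate

from conftest import make_cds, random_counts

CODE = default_code()


class TestCountCodons:
    def test_counts_and_stop_carried(self):
        cc = count_codons(CdsRecord("g", "s", "ATGAAATAA"))
        assert cc.counts == {"ATG": 1, "AAA": 1, "TAA": 1}
        assert cc.sense_total() == 2
        assert cc.stop_total() == 1

    def test_leucine_pair(self):
        cc = count_codons(CdsRecord("g", "s", "ATGTTATTGTAA"))
        assert cc.counts["TTA"] == 1 and cc.counts["TTG"] == 1 and cc.counts["ATG"] == 1

    def test_sense_total_is_length_over_three_minus_one(self):
        records, _ = generate(SyntheticSpec(n_genes=1, length_range=(999, 999), seed=5))
        cc = count_codons(records[0])
        assert cc.sense_total() == 999 // 3 - 1 == 332

    def test_frame_error(self):
        with pytest.raises(ValueError):
            count_codons("ATGAA")


class TestRscu:
    def test_equal_counts_give_unit_rscu(self):
        cc = CodonCounts("x", {c: 7 for c in SENSE_CODONS})
        values = rscu(cc).rscu
        assert all(math.isclose(v, 1.0) for v in values.values())

    def test_leucine_worked_example(self):
        cc = CodonCounts("x", {"TTA": 6, "TTG": 3, "CTT": 2, "CTC": 1})
        values = rscu(cc).rscu
        expected = {"TTA": 3.0, "TTG": 1.5, "CTT": 1.0, "CTC": 0.5, "CTA": 0.0, "CTG": 0.0}
        for codon, want in expected.items():
            assert values[codon] == pytest.approx(want)

    def test_unobserved_family_flagged_zero(self):
        cc = CodonCounts("x", {"TTA": 2})
        profile = rscu(cc)
        assert "K" in profile.unobserved
        assert profile.rscu["AAA"] == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_family_sums_equal_family_size(self, seed):
        """Sum of RSCU over each observed family equals the family size."""
        cc = random_counts(np.random.default_rng(seed))
        profile = rscu(cc)
        for aa, fam in CODE.families.items():
            total = sum(cc.counts.get(c, 0) for c in fam)
            if total == 0:
                continue
            assert sum(profile.rscu[c] for c in fam) == pytest.approx(len(fam), abs=1e-12)

    def test_scaling_invariance(self, rng):
        cc = random_counts(rng)
        scaled = CodonCounts("x", {c: 10 * n for c, n in cc.counts.items()})
        r1, r2 = rscu(cc).rscu, rscu(scaled).rscu
        for c in SENSE_CODONS:
            assert r1[c] == pytest.approx(r2[c], abs=1e-12)


class TestComposition:
    def test_two_codon_hand_count(self):
        comp = composition(CodonCounts("x", {"ATG": 1, "GAA": 1}))
        assert comp["gc1"] == pytest.approx(0.5)
        assert comp["gc2"] == pytest.approx(0.0)
        assert comp["gc3"] == pytest.approx(0.5)
        # six bases ATGGAA hold two G/C: overall GC is 1/3
        assert comp["gc_all"] == pytest.approx(1 / 3)

    def test_all_gcg(self):
        comp = composition(CodonCounts("x", {"GCG": 11}))
        assert comp["gc1"] == comp["gc2"] == comp["gc3"] == 1.0

    def test_gc3s_excludes_met_trp(self):
        # ATG and TGG third positions are G but must not enter GC3s
        comp = composition(CodonCounts("x", {"ATG": 5, "TGG": 5, "AAA": 5, "AAG": 5}))
        assert comp["gc3s"] == pytest.approx(0.5)
        assert comp["gc3"] == pytest.approx(15 / 20)

    def test_third_position_counts_partition(self, rng):
        cc = random_counts(rng)
        comp = composition(cc)
        assert comp["a3"] + comp["t3"] + comp["g3"] + comp["c3"] == comp["n_codons"]

    def test_gc_all_matches_direct_base_count(self, rng):
        for _ in range(10):
            cc = random_counts(rng)
            comp = composition(cc)
            bases = "".join(c * cc.counts.get(c, 0) for c in SENSE_CODONS)
            direct = (bases.count("G") + bases.count("C")) / len(bases)
            assert comp["gc_all"] == pytest.approx(direct, abs=1e-12)

    def test_zero_sense_codons_error(self):
        with pytest.raises(ValueError):
            composition(CodonCounts("x", {"TAA": 1}))


class TestEnc:
    def test_uniform_usage_caps_at_61(self):
        cc = CodonCounts("x", {c: 50 for c in SENSE_CODONS})
        assert enc_observed(cc) == 61.0

    def test_single_codon_per_family_is_20(self):
        counts = {fam[0]: 10 for fam in CODE.families.values()}
        assert enc_observed(CodonCounts("x", counts)) == pytest.approx(20.0)

    def test_family_homozygosity_worked_example(self):
        # counts (3, 1): F = (4 * 0.625 - 1) / 3 = 0.5
        assert _family_homozygosity([3, 1]) == pytest.approx(0.5)
        assert _family_homozygosity([1, 0]) is None  # n < 2
        assert _family_homozygosity([1, 1]) is None  # F = 0 dropped

    def test_missing_isoleucine_mean_imputed(self):
        """Without any Ile codons, the 3-fold mean is (F2 + F4) / 2."""
        counts = {}
        for aa, fam in CODE.families.items():
            if aa in ("I", "M", "W"):
                continue
            for c in fam:
                counts[c] = 4
        enc = enc_observed(CodonCounts("x", counts))
        f = {k: None for k in (2, 4, 6)}
        for k, n_fam in ((2, 9), (4, 5), (6, 3)):
            n = 4 * k
            s = k * (1 / k) ** 2
            f[k] = (n * s - 1) / (n - 1)
        f3 = (f[2] + f[4]) / 2
        expected = min(61.0, 2 + 9 / f[2] + 1 / f3 + 5 / f[4] + 3 / f[6])
        assert enc == pytest.approx(expected, abs=1e-12)

    def test_undefined_when_class_mean_missing(self):
        assert math.isnan(enc_observed(CodonCounts("x", {"TTT": 3, "TTC": 1})))

    def test_enc_decreases_monotonically_toward_large_n_limit(self):
        base = {"TTT": 3, "TTC": 1, "ATT": 2, "ATC": 1, "ATA": 1,
                "GTT": 4, "GTC": 1, "GTA": 1, "GTG": 2,
                "TTA": 5, "TTG": 2, "CTT": 1, "CTC": 1, "CTA": 1, "CTG": 2}
        encs = [
            enc_observed(CodonCounts("x", {c: m * n for c, n in base.items()}))
            for m in (1, 2, 4, 8, 64)
        ]
        assert all(a > b for a, b in zip(encs, encs[1:]))

    @pytest.mark.parametrize(
        "gc3s, expected",
        [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0), (0.302, 52.44)],
    )
    def test_enc_expected_curve(self, gc3s, expected):
        assert enc_expected(gc3s) == pytest.approx(expected, abs=0.005)

    def test_enc_expected_domain(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)

    def test_enc_ratio_arithmetic(self):
        assert enc_ratio(45.0, 60.5) == pytest.approx(0.2562, abs=1e-4)
        assert enc_ratio(60.5, 60.5) == 0.0


class TestSpeciesSummary:
    def test_single_gene_species_equals_gene_stats(self):
        rec = make_cds(["AAA", "AAG", "GAA", "GCT", "GCC", "TTA", "CTT"] * 20)
        stats = gene_stats(rec)
        summary = species_summary([rec]).iloc[0]
        assert summary["n_codons"] == stats.n_codons
        assert summary["gc_all"] == pytest.approx(stats.gc_all)
        assert summary["enc_pooled"] == pytest.approx(stats.enc_obs)
        assert summary["enc_mean"] == pytest.approx(stats.enc_obs)

    def test_two_identical_genes_pool_to_same_composition(self):
        a = make_cds(["AAA", "GGG", "TTA"] * 40, gene_id="a")
        b = make_cds(["AAA", "GGG", "TTA"] * 40, gene_id="b")
        summary = species_summary([a, b]).iloc[0]
        assert summary["gc1"] == pytest.approx(gene_stats(a).gc1)
        assert summary["n_codons"] == 2 * gene_stats(a).n_codons

    def test_pooled_counts_equal_sum_of_gene_counts(self, uniform_records):
        records, _ = uniform_records
        pooled = pool_counts((count_codons(r) for r in records), "all")
        assert pooled.sense_total() == sum(
            count_codons(r).sense_total() for r in records
        )
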