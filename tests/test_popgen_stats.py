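"""Site-frequency-spectrum statistics against hand calculations and a
brute-force reference."""

import math

import numpy as np
import pytest
from oracles import brute_force_sfs_stats

from conftest import random_binary_matrix
from pollenscreen.popgen_stats import (
    HaplotypeMatrix,
    empirical_tails,
    expected_heterozygosity,
    fay_wu_h,
    filter_sites,
    site_frequency_spectrum,
    tajima_coefficients,
    tajimas_d,
)


class TestTajimaCoefficients:
    def test_hand_values_n4(self):
        c = tajima_coefficients(4)
        assert c.a1 == pytest.approx(11 / 6)
        assert c.a2 == pytest.approx(1 + 1 / 4 + 1 / 9)
        # exact fractions: c1 = 1/99, c2 = 23/54 - 9/11 + 49/121
        assert c.e1 == pytest.approx((1 / 99) / (11 / 6), abs=1e-12)
        assert c.e2 == pytest.approx((23 / 54 - 9 / 11 + 49 / 121) / (170 / 36), abs=1e-12)

    @pytest.mark.parametrize("n", [4, 10, 56])
    def test_positive_variance_constants(self, n):
        c = tajima_coefficients(n)
        assert c.e1 > 0 and c.e2 > 0


class TestTajimasD:
    def test_worked_example(self, example_matrix):
        st = tajimas_d(example_matrix)
        assert st.S == 3
        assert st.pi == pytest.approx(5 / 3)
        assert st.theta_w == pytest.approx(3 / (11 / 6))
        assert st.D == pytest.approx(0.16766, abs=1e-4)

    def test_undefined_at_no_polymorphism(self):
        m = HaplotypeMatrix("mono", np.full((4, 2), "0", dtype="U1"), [1, 2])
        assert math.isnan(tajimas_d(m).D)

    def test_singleton_excess_is_negative(self, rng):
        n, s = 20, 40
        alleles = np.full((n, s), "0", dtype="U1")
        for j in range(s):
            alleles[int(rng.integers(n)), j] = "1"
        assert tajimas_d(HaplotypeMatrix("sing", alleles, np.arange(1, s + 1))).D < 0


class TestFayWuH:
    def test_worked_example(self, example_matrix):
        st = fay_wu_h(example_matrix, "og")
        assert st.theta_h == pytest.approx(7 / 3)
        assert st.H == pytest.approx(-2 / 3)
        assert list(st.sfs) == [1, 1, 1]

    def test_all_singletons_nonnegative(self, rng):
        n, s = 10, 10
        alleles = np.full((n, s), "0", dtype="U1")
        for j in range(s):
            alleles[int(rng.integers(n)), j] = "1"
        m = HaplotypeMatrix(
            "sing", alleles, np.arange(1, s + 1), outgroups={"og": np.full(s, "0", dtype="U1")}
        )
        assert fay_wu_h(m, "og").H >= 0

    def test_normalized_variant_orders_like_original(self, example_matrix):
        """The variance-standardized H has the same sign as the original
        (pi - theta_H = 2 * (pi - theta_L)) and is finite on a polarizable
        locus."""
        plain = fay_wu_h(example_matrix, "og")
        norm = fay_wu_h(example_matrix, "og", normalized=True)
        assert math.isfinite(norm.H)
        assert (norm.H < 0) == (plain.H < 0)
        assert norm.H != plain.H

    def test_unpolarizable_everywhere_is_undefined(self):
        alleles = np.array([list("01"), list("01"), list("10"), list("10")])
        m = HaplotypeMatrix(
            "x", alleles, [1, 2], outgroups={"og": np.full(2, ".", dtype="U1")}
        )
        assert math.isnan(fay_wu_h(m, "og").H)


class TestBruteForceAgreement:
    def test_two_hundred_random_matrices(self):
        """D, H, pi, theta_W, theta_H match an independent loop-based
        implementation to 1e-9."""
        rng = np.random.default_rng(77)
        for _ in range(200):
            m = random_binary_matrix(rng)
            ours = fay_wu_h(m, "og")
            ref = brute_force_sfs_stats(m.alleles, m.outgroups["og"])
            assert ours.S == ref["S"]
            assert ours.pi == pytest.approx(ref["pi"], abs=1e-9)
            assert ours.theta_w == pytest.approx(ref["theta_w"], abs=1e-9)
            assert ours.D == pytest.approx(ref["D"], abs=1e-9)
            if math.isnan(ref["H"]):
                assert math.isnan(ours.H)
            else:
                assert ours.theta_h == pytest.approx(ref["theta_h"], abs=1e-9)
                assert ours.H == pytest.approx(ref["H"], abs=1e-9)

    def test_pi_equals_sfs_identity(self):
        """pi from pairwise differences equals sum 2i(n-i)S_i/(n(n-1)) on
        fully polarizable loci."""
        rng = np.random.default_rng(78)
        for _ in range(50):
            m = random_binary_matrix(rng)
            m.outgroups["og"] = np.full(m.n_sites, "0", dtype="U1")
            st = tajimas_d(m)
            sfs, n_pol = site_frequency_spectrum(m, "og")
            n = m.n_chrom
            i = np.arange(1, n)
            if n_pol == st.S:  # every site polarizable
                pi_sfs = float(np.sum(2.0 * sfs * i * (n - i)) / (n * (n - 1)))
                assert st.pi == pytest.approx(pi_sfs, abs=1e-9)


class TestFilterSites:
    def test_missing_and_triallelic_removed_biallelic_kept(self):
        alleles = np.array(
            [list("AAA"), list("ACA"), list("TGC"), list(".AC")], dtype="U1"
        )
        # columns: (A,A,T,.) missing; (A,C,G,A) triallelic; (A,A,C,C) biallelic
        m = HaplotypeMatrix("f", alleles, [1, 2, 3])
        filt = filter_sites(m)
        assert list(filt.positions) == [3]
        assert filt.n_sites == 1

    def test_monomorphic_columns_retained(self):
        alleles = np.array([list("AA"), list("AA"), list("AC")], dtype="U1")
        m = HaplotypeMatrix("f", alleles, [1, 2])
        assert filter_sites(m).n_sites == 2


class TestExpectedHeterozygosity:
    def test_hand_value_n4(self):
        alleles = np.array([["1"], ["0"], ["0"], ["0"]], dtype="U1")
        per_site, mean = expected_heterozygosity(HaplotypeMatrix("h", alleles, [1]))
        assert per_site[0] == pytest.approx(0.5)
        assert mean == pytest.approx(0.5)

    def test_monomorphic_zero_and_correction_flag(self):
        alleles = np.array([["1", "0"], ["1", "1"], ["1", "0"], ["1", "1"]], dtype="U1")
        m = HaplotypeMatrix("h", alleles, [1, 2])
        per_site, _ = expected_heterozygosity(m, sample_size_correction=False)
        assert per_site[0] == 0.0
        assert per_site[1] == pytest.approx(0.5)


class TestEmpiricalTails:
    def test_floor_counts_per_tail(self, rng):
        values = {f"l{i:03d}": float(v) for i, v in enumerate(rng.normal(size=100))}
        results, _ = empirical_tails(values, alpha=0.05)
        assert sum(t.tail == "lower" for t in results) == 2
        assert sum(t.tail == "upper" for t in results) == 2

    def test_flagged_are_order_statistic_extremes(self, rng):
        values = {f"l{i:04d}": float(v) for i, v in enumerate(rng.normal(size=400))}
        results, (lo, hi) = empirical_tails(values, alpha=0.05)
        lower = {t.locus_id for t in results if t.tail == "lower"}
        for t in results:
            if t.tail == "lower":
                assert t.value < lo
            else:
                assert t.value > hi
        assert len(lower) == 10

    def test_tie_break_is_deterministic(self):
        values = {f"l{i}": 1.0 for i in range(50)}
        results, _ = empirical_tails(values, alpha=0.1)
        lower = sorted(t.locus_id for t in results if t.tail == "lower")
        results2, _ = empirical_tails(dict(reversed(values.items())), alpha=0.1)
        lower2 = sorted(t.locus_id for t in results2 if t.tail == "lower")
        assert lower == lower2

    def test_too_few_loci_raises(self):
        with pytest.raises(ValueError):
            empirical_tails({"a": 1.0, "b": 2.0}, alpha=0.05)
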