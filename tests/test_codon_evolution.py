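"""Codon-model machinery: NG86 counting, NJ trees, GY94 likelihoods and the
M8-vs-M8a LRT."""

import math

import numpy as np
import pytest
from oracles import brute_force_pruning_loglik

from pollenscreen import codon_evolution as ce
from pollenscreen import synthetic_data as sd
from pollenscreen.io_formats import read_newick


@pytest.fixture(scope="module")
def small_gene():
    """One 150-codon five-taxon alignment simulated under omega = 0.2, with
    its NJ tree."""
    cfg = sd.CodonSimConfig(n_genes=1, n_codons=150, seed=5, omega0=0.2)
    alignments, _, _ = sd.gen_codon_fixture(cfg)
    aln = ce.validate_alignment(alignments["gene_1"])
    return aln, ce.nj_tree(aln)


class TestValidateAlignment:
    def test_low_quality_taxon_dropped(self):
        records = [
            ("a", "ATGAAACCC"), ("b", "ATGAAACCG"), ("c", "ATGAAGCCC"),
            ("d", "NNNNNNACC"),  # 33% unambiguous
        ]
        aln = ce.validate_alignment(records)
        assert aln.dropped_taxa == ["d"]
        assert aln.n_taxa == 3 and aln.site_model_eligible

    def test_two_taxa_pairwise_only(self):
        records = [("a", "ATGAAA"), ("b", "ATGAAG")]
        aln = ce.validate_alignment(records)
        assert not aln.site_model_eligible
        with pytest.raises(ValueError, match=">= 3 taxa"):
            ce.fit_m0(aln, None)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            ce.validate_alignment([("a", "ATGTAAAAACCC"), ("b", "ATGAAAAAACCC")])

    def test_out_of_frame_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            ce.validate_alignment([("a", "ATGA"), ("b", "ATGA")])

    def test_clean_alignment_unchanged(self):
        records = [("a", "ATGAAA"), ("b", "ATGAAG"), ("c", "ATGAAC")]
        aln = ce.validate_alignment(records)
        assert aln.n_taxa == 3
        assert aln.clean_columns.all()


class TestNg86:
    def test_identical_sequences(self):
        r = ce.ng86("ATGAAACCC", "ATGAAACCC")
        assert r.dn == 0.0 and r.ds == 0.0

    def test_hand_enumerated_example(self):
        r = ce.ng86("AAACCCGGG", "AAGCCCGGG")
        assert r.s_sites == pytest.approx(7 / 3)
        assert r.n_sites == pytest.approx(20 / 3)
        assert r.s_diffs == 1.0 and r.n_diffs == 0.0
        assert r.dn == 0.0
        assert r.ds == pytest.approx(-0.75 * math.log(1 - 4 / 3 * (3 / 7)), abs=1e-9)
        assert r.ds == pytest.approx(0.6355, abs=1e-4)

    def test_omega_undefined_without_synonymous_change(self):
        # AAA (Lys) -> ACA (Thr): nonsynonymous only
        r = ce.ng86("AAAGGG", "ACAGGG")
        assert r.ds == 0.0
        assert math.isnan(r.omega)

    def test_symmetry(self, rng):
        codons = [c for c in ce.CODONS]
        for _ in range(10):
            s1 = "".join(rng.choice(codons, size=30))
            s2 = "".join(rng.choice(codons, size=30))
            a = ce.ng86(s1, s2)
            b = ce.ng86(s2, s1)
            assert a.dn == pytest.approx(b.dn, abs=1e-12)
            assert a.ds == pytest.approx(b.ds, abs=1e-12)


class TestNjTree:
    def test_three_point_formula(self):
        # d(a,b)=0.2, d(a,c)=0.3, d(b,c)=0.3 -> branches 0.1, 0.1, 0.2
        from skbio import DistanceMatrix
        from skbio.tree import nj

        dm = DistanceMatrix(
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.3], [0.3, 0.3, 0]]), ids=list("abc")
        )
        tree = nj(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.1)
        assert lengths["c"] == pytest.approx(0.2)

    def test_recovers_generating_topology(self):
        """NJ on the JC distances of a simulated alignment groups the sister
        taxa of the generating tree."""
        cfg = sd.CodonSimConfig(n_genes=1, n_codons=400, seed=9, omega0=0.3)
        alignments, _, _ = sd.gen_codon_fixture(cfg)
        aln = ce.validate_alignment(alignments["gene_1"])
        tree = ce.nj_tree(aln)
        # tax1+tax2 and tax3+tax4 are cherries in the generating topology
        names = {t.name for t in tree.tips()}
        assert names == {"tax1", "tax2", "tax3", "tax4", "tax5"}
        for pair in ({"tax1", "tax2"}, {"tax3", "tax4"}):
            clades = [
                {t.name for t in node.tips()} for node in tree.non_tips(include_self=True)
            ]
            assert any(c == pair or (names - c) == pair for c in clades)

    def test_two_taxa_error(self):
        aln = ce.validate_alignment([("a", "ATGAAA"), ("b", "ATGAAG")])
        with pytest.raises(ValueError, match="3 taxa"):
            ce.nj_tree(aln)


class TestRateMatrix:
    def test_rows_sum_to_zero_and_stationarity(self):
        freqs = np.full(61, 1 / 61)
        q = ce.gy94_rate_matrix(2.5, 0.4, freqs)
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        assert np.abs(freqs @ q).max() < 1e-12

    def test_detailed_balance(self, small_gene):
        aln, _ = small_gene
        freqs = ce.f1x4_frequencies(aln)
        q = ce.gy94_rate_matrix(2.0, 0.5, freqs)
        flux = freqs[:, None] * q
        assert np.abs(flux - flux.T).max() < 1e-12


class TestGy94Loglik:
    def test_zero_branch_limit_identical_sequences(self):
        """With all branch lengths 0 the likelihood of identical sequences
        is the product of the root-state frequencies."""
        records = [("a", "ATGAAA"), ("b", "ATGAAA"), ("c", "ATGAAA")]
        aln = ce.validate_alignment(records)
        tree = read_newick("(a:0.0,b:0.0,c:0.0);")
        freqs = np.full(61, 1 / 61)
        lnl = ce.gy94_loglik(aln, tree, 1.0, [1.0], [1.0], codon_freqs=freqs)
        assert lnl == pytest.approx(2 * math.log(1 / 61), abs=1e-9)

    def test_matches_brute_force_enumeration(self):
        """Pruning equals explicit summation over internal states on a
        3-taxon, 2-codon toy."""
        records = [("a", "ATGAAA"), ("b", "ATGAAG"), ("c", "ACGAAA")]
        aln = ce.validate_alignment(records)
        tree = read_newick("(a:0.1,b:0.25,c:0.4);")
        freqs = ce.f1x4_frequencies(aln)
        kappa, omega = 2.0, 0.5
        lnl = ce.gy94_loglik(aln, tree, kappa, [omega], [1.0], codon_freqs=freqs)
        q = ce.gy94_rate_matrix(kappa, omega, freqs)
        leaf_codons = [aln.codons[aln.names.index(n)] for n in ("a", "b", "c")]
        ref = brute_force_pruning_loglik(leaf_codons, [0.1, 0.25, 0.4], q, freqs)
        assert lnl == pytest.approx(ref, abs=1e-9)

    def test_invariant_to_taxon_order_and_rerooting(self, small_gene):
        aln, tree = small_gene
        freqs = ce.f1x4_frequencies(aln)
        lnl = ce.gy94_loglik(aln, tree, 2.0, [0.2], [1.0], codon_freqs=freqs)
        # reorder taxa
        records = [(n, aln.sequence(n)) for n in reversed(aln.names)]
        aln2 = ce.validate_alignment(records)
        lnl2 = ce.gy94_loglik(aln2, tree, 2.0, [0.2], [1.0], codon_freqs=freqs)
        assert lnl2 == pytest.approx(lnl, abs=1e-8)
        # reroot at a different internal node
        rerooted = tree.root_at(list(tree.non_tips())[0])
        lnl3 = ce.gy94_loglik(aln, rerooted, 2.0, [0.2], [1.0], codon_freqs=freqs)
        assert lnl3 == pytest.approx(lnl, abs=1e-8)

    def test_random_sequence_lowers_likelihood(self, small_gene, rng):
        aln, tree = small_gene
        freqs = ce.f1x4_frequencies(aln)
        base = ce.gy94_loglik(aln, tree, 2.0, [0.2], [1.0], codon_freqs=freqs)
        for _ in range(5):
            records = [(n, aln.sequence(n)) for n in aln.names]
            scrambled = "".join(rng.choice(ce.CODONS, size=aln.n_codons))
            records[0] = (records[0][0], scrambled)
            aln2 = ce.validate_alignment(records)
            lnl = ce.gy94_loglik(aln2, tree, 2.0, [0.2], [1.0], codon_freqs=freqs)
            assert lnl < base


class TestSiteClasses:
    def test_m8a_weights_and_boundary(self):
        omegas, weights = ce.m8_site_classes(0.8, 0.5, 2.0, 1.0)
        assert len(omegas) == 11
        assert weights.sum() == pytest.approx(1.0)
        assert weights[-1] == pytest.approx(0.2)
        assert omegas[-1] == 1.0
        assert np.all(omegas[:-1] < 1.0) and np.all(np.diff(omegas[:-1]) >= 0)


class TestFitting:
    def test_nesting_inequality(self, small_gene):
        aln, tree = small_gene
        m0, m8a, m8 = ce.fit_site_models(aln, tree, n_restarts=1)
        assert m8.lnl >= m8a.lnl - 1e-6
        assert m0.converged and m8a.converged and m8.converged

    def test_m0_recovery_on_informative_gene(self):
        cfg = sd.CodonSimConfig(n_genes=1, n_codons=800, seed=21, omega0=0.25)
        alignments, _, _ = sd.gen_codon_fixture(cfg)
        aln = ce.validate_alignment(alignments["gene_1"])
        fit = ce.fit_m0(aln, ce.nj_tree(aln), n_restarts=1)
        assert fit.omega == pytest.approx(0.25, abs=0.08)


class TestLrt:
    def _fits(self, lnl0, lnl1):
        null = ce.CodonModelFit(model="M8a", lnl=lnl0, kappa=2, scale=1)
        alt = ce.CodonModelFit(model="M8", lnl=lnl1, kappa=2, scale=1)
        return null, alt

    def test_zero_delta_gives_p_one(self):
        r = ce.lrt_m8_vs_m8a(*self._fits(-100.0, -100.0))
        assert r.stat == 0.0 and r.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("stat,p", [(3.841, 0.050), (6.635, 0.010)])
    def test_chi2_quantiles(self, stat, p):
        r = ce.lrt_m8_vs_m8a(*self._fits(-100.0, -100.0 + stat / 2))
        assert r.p_value == pytest.approx(p, abs=5e-4)

    def test_boundary_mixture_halves_p(self):
        plain = ce.lrt_m8_vs_m8a(*self._fits(-100.0, -98.0))
        mixed = ce.lrt_m8_vs_m8a(*self._fits(-100.0, -98.0), boundary_mixture=True)
        assert mixed.p_value == pytest.approx(plain.p_value / 2)

    def test_meaningfully_negative_delta_raises(self):
        with pytest.raises(ValueError, match="refit"):
            ce.lrt_m8_vs_m8a(*self._fits(-100.0, -101.0))
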