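"""Multiple testing, Fisher's exact test and candidate-table assembly."""

import numpy as np
import pandas as pd
import pytest
from oracles import fisher_exact_enumeration

from pollenscreen import candidate_screen as screen


class TestQvalues:
    def test_all_ones(self):
        assert list(screen.qvalues([1.0, 1.0, 1.0], "bh")) == [1.0, 1.0, 1.0]

    def test_bh_step_up_arithmetic(self):
        q = screen.qvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_itself(self):
        assert screen.qvalues([0.2], "bh")[0] == pytest.approx(0.2)

    def test_storey_pi0_scales_bh(self):
        p = [0.001, 0.01, 0.6, 0.7, 0.8, 0.9]
        bh = screen.qvalues(p, "bh")
        st = screen.qvalues(p, "storey")
        pi0 = 4 / (0.5 * 6)  # 4 of 6 p-values exceed lambda = 0.5
        assert pi0 > 1  # capped
        assert np.allclose(st, bh)  # cap at 1 makes them equal here
        p2 = [0.001, 0.01, 0.02, 0.03, 0.6, 0.9]
        st2 = screen.qvalues(p2, "storey")
        bh2 = screen.qvalues(p2, "bh")
        assert np.all(st2 <= bh2 + 1e-12)

    def test_never_exceeds_bonferroni(self, rng):
        p = rng.uniform(size=50)
        q = screen.qvalues(p, "bh")
        assert np.all(q <= np.minimum(1.0, len(p) * p) + 1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = np.sort(rng.uniform(size=40))
        q = screen.qvalues(p, "storey")
        assert np.all(np.diff(q) >= -1e-12)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            screen.qvalues([], "bh")
        with pytest.raises(ValueError):
            screen.qvalues([1.5], "bh")


class TestFisherExact:
    def test_hand_enumerated_example(self):
        assert screen.fisher_exact_2x2([[3, 1], [1, 3]], "greater") == pytest.approx(17 / 70)

    def test_minimal_overlap_is_one(self):
        assert screen.fisher_exact_2x2([[0, 5], [5, 0]], "greater") == pytest.approx(1.0)

    def test_matches_enumeration_small_margins(self, rng):
        """Agreement with full enumeration over all tables with the observed
        margins, for margins up to 12."""
        for _ in range(40):
            a, b, c, d = (int(x) for x in rng.integers(0, 7, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            table = [[a, b], [c, d]]
            for tail in ("greater", "less", "two"):
                assert screen.fisher_exact_2x2(table, tail) == pytest.approx(
                    fisher_exact_enumeration(table, tail), abs=1e-9
                )

    def test_tail_complement_identity(self, rng):
        from scipy.stats import hypergeom

        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 8, size=4))
            g = screen.fisher_exact_2x2([[a, b], [c, d]], "greater")
            l = screen.fisher_exact_2x2([[a, b], [c, d]], "less")
            point = hypergeom.pmf(a, a + b + c + d, a + b, a + c)
            assert g + l - point == pytest.approx(1.0, abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            screen.fisher_exact_2x2([[0, 0], [1, 2]], "two")


class TestCandidateTable:
    def _tails(self, n_sweep, n_balancing, sim_p=0.001):
        rows = [
            {"gene_id": f"sw{i:03d}", "tail": "lower", "sim_p": sim_p}
            for i in range(n_sweep)
        ] + [
            {"gene_id": f"ba{i:03d}", "tail": "upper", "sim_p": sim_p}
            for i in range(n_balancing)
        ]
        return pd.DataFrame(rows)

    def test_headline_tally(self):
        """58 sweep + 58 balancing + 43 adaptive with one overlap: the sum
        tally reports 159, the union tally 158."""
        tails = self._tails(58, 58)
        lrt = pd.DataFrame(
            [{"gene_id": f"ad{i:03d}", "q_value": 0.01} for i in range(42)]
            + [{"gene_id": "ba000", "q_value": 0.01}]
        )
        table, summary = screen.build_candidate_table(tails, None, lrt, tally="sum")
        assert summary["n_population"] == 116
        assert summary["n_sweep"] == 58 and summary["n_balancing"] == 58
        assert summary["n_adaptive"] == 43
        assert summary["overlap"] == 1
        assert summary["n_total"] == 159
        _, summary_u = screen.build_candidate_table(tails, None, lrt, tally="union")
        assert summary_u["n_total"] == 158

    def test_simulation_gate(self):
        tails = pd.DataFrame(
            [
                {"gene_id": "a", "tail": "lower", "sim_p": 0.001},
                {"gene_id": "b", "tail": "lower", "sim_p": 0.2},
            ]
        )
        table, summary = screen.build_candidate_table(tails, None, None)
        assert summary["n_sweep"] == 1
        assert list(table["gene_id"]) == ["a"]

    def test_no_flags_empty(self):
        table, summary = screen.build_candidate_table(self._tails(0, 0), None, None)
        assert len(table) == 0 and summary["n_total"] == 0

    def test_h_union_semantics(self):
        tails = self._tails(2, 0)
        h = pd.DataFrame(
            [
                {"gene_id": "sw000", "outgroup": "tilingii", "p": 0.01},
                {"gene_id": "sw001", "outgroup": "cupriphilus", "p": 0.04},
                {"gene_id": "sw001", "outgroup": "tilingii", "p": 0.5},
            ]
        )
        _, summary = screen.build_candidate_table(tails, h, None)
        assert summary["n_h_confirmed_any"] == 2
        assert summary["n_h_confirmed_tilingii"] == 1
        assert summary["n_h_confirmed_cupriphilus"] == 1

    def test_manual_exclusion_drops_adaptive_flag(self):
        lrt = pd.DataFrame(
            [{"gene_id": "g1", "q_value": 0.01}, {"gene_id": "g2", "q_value": 0.01}]
        )
        _, summary = screen.build_candidate_table(
            self._tails(0, 0), None, lrt, manual_exclude={"g2"}
        )
        assert summary["n_adaptive"] == 1

    def test_duplicate_gene_ids_rejected(self):
        tails = pd.DataFrame(
            [
                {"gene_id": "a", "tail": "lower", "sim_p": 0.001},
                {"gene_id": "a", "tail": "upper", "sim_p": 0.001},
            ]
        )
        with pytest.raises(ValueError, match="duplicate"):
            screen.build_candidate_table(tails, None, None)
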