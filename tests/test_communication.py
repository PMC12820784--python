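import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import cellcircuit as cc
from cellcircuit.communication import apply_specificity_filter
from cellcircuit.errors import DegenerateInputError, IntegrityError


def _de_up(genes_by_group):
    rows = []
    for grp, genes in genes_by_group.items():
        for g in genes:
            rows.append((g, grp, 2.0, 1e-4, 1e-3, 0.9, 0.05))
    return cc.DETable(
        pd.DataFrame(
            rows,
            columns=[
                "gene", "group", "log_fold_change", "p_value", "adjusted_p",
                "frac_fg", "frac_bg",
            ],
        )
    )


def _lrdb(pairs):
    return cc.LRDatabase(pd.DataFrame(pairs, columns=["ligand", "receptor"]))


class TestDetectMarkers:
    def test_exclusive_gene_is_top_marker(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, size=(5, 40))
        labels = np.array(["A"] * 20 + ["B"] * 20)
        counts[0, :20] = rng.poisson(20, 20) + 1  # gene0: all A cells positive
        counts[0, 20:] = 0
        expr = cc.ExpressionMatrix(
            [f"g{i}" for i in range(5)], [f"c{i}" for i in range(40)],
            sp.csr_matrix(counts),
        )
        de = cc.detect_markers(expr, labels)
        a = de.df[de.df["group"] == "A"].sort_values("p_value")
        assert a.iloc[0]["gene"] == "g0"
        assert a.iloc[0]["frac_fg"] == 1.0 and a.iloc[0]["frac_bg"] == 0.0

    def test_label_permutation_null_rate(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(2.0, size=(40, 60))
        expr = cc.ExpressionMatrix(
            [f"g{i}" for i in range(40)], [f"c{i}" for i in range(60)],
            sp.csr_matrix(counts),
        )
        frac_sig = []
        for _ in range(20):
            labels = rng.permutation(["A"] * 30 + ["B"] * 30)
            de = cc.detect_markers(expr, labels)
            frac_sig.append((de.df["p_value"] < 0.05).mean())
        assert np.mean(frac_sig) <= 0.075

    def test_single_type_rejected(self):
        expr = cc.ExpressionMatrix(
            ["g"], ["c1", "c2"], sp.csr_matrix(np.array([[1, 2]]))
        )
        with pytest.raises(DegenerateInputError):
            cc.detect_markers(expr, np.array(["A", "A"]))

    def test_specificity_filter_hand_oracle(self):
        # 6 constructed rows; exactly 2 built to pass the stringent filter
        rows = [
            ("gPass1", "A", 3.5, 0.001, 0.01, 0.60, 0.05),
            ("gPass2", "A", 4.0, 0.010, 0.05, 0.30, 0.09),
            ("gLowLfc", "A", 2.0, 0.001, 0.01, 0.60, 0.05),
            ("gHighP", "A", 3.5, 0.200, 0.40, 0.60, 0.05),
            ("gLowFg", "A", 3.5, 0.001, 0.01, 0.20, 0.05),
            ("gHighBg", "A", 3.5, 0.001, 0.01, 0.60, 0.30),
        ]
        de = cc.DETable(
            pd.DataFrame(
                rows,
                columns=[
                    "gene", "group", "log_fold_change", "p_value",
                    "adjusted_p", "frac_fg", "frac_bg",
                ],
            )
        )
        kept = apply_specificity_filter(de, cc.MarkerConfig())
        assert set(kept.df["gene"]) == {"gPass1", "gPass2"}


class TestScoreInteractions:
    def test_silent_ligand_not_relevant(self, toy_expr):
        expr, labels = toy_expr
        de = _de_up({"A": ["L1"], "B": ["R1"]})
        scores = cc.score_interactions(expr, labels, de, _lrdb([("L2", "R2")]))
        # L2 is expressed in 0% of A cells -> no (A, *) interaction for L2
        assert not any(s.sender_type == "A" for s in scores)

    def test_scaling_endpoints_give_score_one(self, toy_expr):
        expr, labels = toy_expr
        de = _de_up({"A": ["L1"]})
        scores = cc.score_interactions(expr, labels, de, _lrdb([("L1", "R1")]))
        ab = [s for s in scores if (s.sender_type, s.receiver_type) == ("A", "B")]
        assert len(ab) == 1
        assert ab[0].score == pytest.approx(1.0)
        assert ab[0].significant

    def test_toy_table_matches_closed_form(self, toy_expr):
        # equal 20-count libraries: normalized value = log1p(500*count);
        # min-max scaled means are exact closed forms
        expr, labels = toy_expr
        de = _de_up({"B": ["L2"]})
        scores = cc.score_interactions(expr, labels, de, _lrdb([("L2", "R2")]))
        v = lambda c: np.log1p(500 * c)
        l2 = {"A": 0.0, "B": v(5) / v(10), "C": 1.0}
        r2 = {"A": 1.0, "B": v(5) / v(10), "C": 0.0}
        got = {(s.sender_type, s.receiver_type): s.score for s in scores}
        for (s, r), sc in got.items():
            assert sc == pytest.approx(l2[s] * r2[r]), (s, r)
        # relevance: L2 silent in A, R2 silent in C
        assert all(s != "A" and r != "C" for s, r in got)

    def test_absent_gene_skipped_with_warning(self, toy_expr):
        expr, labels = toy_expr
        de = _de_up({})
        with pytest.warns(UserWarning, match="GHOST"):
            scores = cc.score_interactions(
                expr, labels, de, _lrdb([("GHOST", "R1")])
            )
        assert scores == []

    def test_raising_tau_never_adds_interactions(self, toy_expr):
        expr, labels = toy_expr
        de = _de_up({"A": ["L1"], "B": ["L2"]})
        db = _lrdb([("L1", "R1"), ("L2", "R2")])
        lo = cc.score_interactions(expr, labels, de, db, tau_expr=0.01)
        hi = cc.score_interactions(expr, labels, de, db, tau_expr=0.6)
        key = lambda s: (s.sender_type, s.ligand, s.receiver_type, s.receptor)
        assert {key(s) for s in hi} <= {key(s) for s in lo}


def _enrichment(flags):
    """Build an EnrichmentTable stub from {(niche, type): flag}."""
    rows = [
        (n, t, 0, 0, 0.0, 1.0, 1.0, f) for (n, t), f in flags.items()
    ]
    table = pd.DataFrame(
        rows,
        columns=[
            "niche", "cell_type", "observed", "expected", "std_residual",
            "p_raw", "p_bonferroni", "enriched_flag",
        ],
    )
    return cc.EnrichmentTable(table, chi2_total=0.0, dof=0, p_global=1.0)


class TestNicheConstraint:
    def _score(self, s, r):
        return cc.InteractionScore(s, "L", r, "R", 0.5, True, True)

    def test_disjoint_niches_removed(self):
        enr = _enrichment({(1, "S"): True, (2, "R"): True})
        assert cc.constrain_by_niche([self._score("S", "R")], enr) == []

    def test_shared_niche_retained(self):
        enr = _enrichment({(1, "S"): True, (1, "R"): True, (2, "R"): True})
        kept = cc.constrain_by_niche([self._score("S", "R")], enr)
        assert len(kept) == 1

    def test_matches_set_oracle_on_random_flags(self):
        rng = np.random.default_rng(6)
        types = [f"T{i}" for i in range(8)]
        niches = list(range(5))
        flags = {
            (n, t): bool(rng.random() < 0.3) for n in niches for t in types
        }
        enr = _enrichment(flags)
        scores = [
            self._score(rng.choice(types), rng.choice(types))
            for _ in range(50)
        ]
        kept = cc.constrain_by_niche(scores, enr)
        member = {
            t: {n for n in niches if flags[(n, t)]} for t in types
        }
        oracle = [
            s for s in scores
            if member[s.sender_type] & member[s.receiver_type]
        ]
        assert kept == oracle

    def test_unknown_type_retained_nowhere(self):
        enr = _enrichment({(1, "R"): True})
        with pytest.warns(UserWarning, match="GHOST"):
            kept = cc.constrain_by_niche([self._score("GHOST", "R")], enr)
        assert kept == []


class TestBuildNetwork:
    def test_weights_sum(self):
        scores = [
            cc.InteractionScore("S", "L1", "R", "R1", 0.4, True, True),
            cc.InteractionScore("S", "L2", "R", "R2", 0.25, True, True),
        ]
        net = cc.build_network(scores)
        assert net.weight("S", "R") == pytest.approx(0.65)
        assert net.graph["S"]["R"]["n_interactions"] == 2

    def test_non_significant_contribute_nothing(self):
        scores = [cc.InteractionScore("S", "L", "R", "R1", 0.9, True, False)]
        net = cc.build_network(scores)
        assert net.graph.number_of_edges() == 0

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        scores = [
            cc.InteractionScore(
                f"S{i%3}", f"L{i}", f"R{i%2}", f"Rc{i}", rng.random(), True, True
            )
            for i in range(20)
        ]
        n1 = cc.build_network(scores)
        n2 = cc.build_network(list(reversed(scores)))
        e1, e2 = n1.edges(), n2.edges()
        assert [(u, v, n) for u, v, _, n in e1] == [
            (u, v, n) for u, v, _, n in e2
        ]
        assert np.allclose([w for *_, w, _ in e1], [w for *_, w, _ in e2])

    def test_removing_constraint_never_decreases_weights(self, toy_expr):
        expr, labels = toy_expr
        de = _de_up({"A": ["L1"], "B": ["L2"]})
        db = _lrdb([("L1", "R1"), ("L2", "R2")])
        scores = cc.score_interactions(expr, labels, de, db)
        enr = _enrichment({(1, "A"): True, (1, "B"): True})
        with pytest.warns(UserWarning, match="enriched nowhere"):
            constrained = cc.constrain_by_niche(scores, enr)
        full = cc.build_network(scores)
        part = cc.build_network(constrained)
        for u, v, w, _ in part.edges():
            assert full.weight(u, v) >= w - 1e-12


class TestProximityProfile:
    def _cells(self):
        df = pd.DataFrame(
            {
                "cell_id": ["src", "t1", "t2", "t3"],
                "x_um": [0.0, 5.0, 10.0, 20.0],
                "y_um": [0.0, 0.0, 0.0, 0.0],
                "cell_type": ["S", "T", "T", "T"],
                "sample_id": ["s1"] * 4,
                "condition": ["x"] * 4,
            }
        )
        counts = sp.csr_matrix(np.array([[0, 5, 3, 1]]))
        return cc.CellTable(df), cc.ExpressionMatrix(
            ["G"], list(df["cell_id"]), counts
        )

    def test_all_targets_in_first_bin(self):
        cells, expr = self._cells()
        prof = cc.proximity_profile(cells, expr, "S", "T", "G")
        assert prof.n[0] == 3 and prof.n[1:].sum() == 0
        assert np.isnan(prof.mean_expression[1:]).all()

    def test_no_sources_anywhere_is_error(self):
        cells, expr = self._cells()
        with pytest.raises(IntegrityError, match="source"):
            cc.proximity_profile(cells, expr, "NOPE", "T", "G")

    def test_counts_partition_targets(self):
        cells, expr = self._cells()
        prof = cc.proximity_profile(
            cells, expr, "S", "T", "G", bin_edges=(0, 7, 15, np.inf)
        )
        assert prof.n.tolist() == [1, 1, 1]
        assert prof.n.sum() == 3
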