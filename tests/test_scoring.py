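import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import cellcircuit as cc
from cellcircuit.errors import ConfigError, SchemaError
from cellcircuit.scoring import DeconvMarkerConfig, score_cohort


class TestSynergy:
    def test_printed_formula_arithmetic(self):
        res = cc.synergy_statistic(
            cc.SynergyInput(100.0, 200.0, 100.0, observed_dual=650.0)
        )
        assert res.e_additive == pytest.approx(400.0)
        assert res.e_synergistic == pytest.approx(600.0)
        assert res.e_synergistic - res.e_additive == pytest.approx(
            200.0 * 100.0 / 100.0
        )
        assert res.classification == "super-additive/synergistic"

    def test_zero_increment_collapses_expectations(self):
        res = cc.synergy_statistic(
            cc.SynergyInput(50.0, 0.0, 123.0, observed_dual=170.0)
        )
        assert res.e_synergistic == pytest.approx(res.e_additive)

    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(0.1, 1e4),
        st.floats(0.0, 1e4),
        st.floats(0.0, 1e4),
    )
    def test_product_and_expanded_forms_agree(self, x, da, db):
        res = cc.synergy_statistic(
            cc.SynergyInput(x, da, db, observed_dual=x)
        )
        product_form = x * (1 + da / x) * (1 + db / x)
        expanded = x + da + db + da * db / x
        assert res.e_synergistic == pytest.approx(product_form, rel=1e-12)
        assert res.e_synergistic == pytest.approx(expanded, rel=1e-12)
        assert res.e_synergistic - res.e_additive == pytest.approx(
            da * db / x, rel=1e-9, abs=1e-9
        )

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ConfigError):
            cc.SynergyInput(0.0, 1.0, 1.0, observed_dual=1.0)

    def test_classification_bands(self):
        mk = lambda obs: cc.synergy_statistic(
            cc.SynergyInput(100.0, 100.0, 100.0, observed_dual=obs)
        ).classification
        assert mk(300.0) == "additive"
        assert mk(200.0) == "sub-additive"
        assert mk(400.0) == "super-additive/synergistic"


def _de(rows):
    return cc.DETable(
        pd.DataFrame(
            rows,
            columns=[
                "gene", "group", "log_fold_change", "p_value", "adjusted_p",
                "frac_fg", "frac_bg",
            ],
        )
    )


class TestDeriveSignature:
    def test_disjoint_sets_empty_effector(self):
        ko = _de([("gA", "ko", -2.0, 1e-4, 1e-3, 0.5, 0.1)])
        act = _de([("gB", "act", 2.0, 1e-4, 1e-3, 0.5, 0.1)])
        sig = cc.derive_signature(ko, act, {"gA", "gB"}, {"gA", "gB"})
        assert sig.effector_genes == set()

    def test_rule_application(self):
        ko = _de([("g1", "ko", -1.5, 1e-3, 0.01, 0.5, 0.1)])
        act = _de([("g1", "act", 1.2, 1e-3, 0.03, 0.5, 0.1)])
        sig = cc.derive_signature(ko, act, {"g1"}, {"g1"})
        assert sig.core_signature == {"g1"}

    def test_random_tables_match_set_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(500)]
        ko_rows, act_rows = [], []
        for g in genes:
            ko_rows.append(
                (g, "ko", rng.normal(), 0.5, rng.uniform(0, 0.2), 0.5, 0.1)
            )
            act_rows.append(
                (g, "act", rng.normal(), 0.5, rng.uniform(0, 0.2), 0.5, 0.1)
            )
        bound = set(rng.choice(genes, 200, replace=False))
        spec = set(rng.choice(genes, 200, replace=False))
        ko, act = _de(ko_rows), _de(act_rows)
        sig = cc.derive_signature(ko, act, bound, spec)
        down = {
            r[0] for r in ko_rows if r[4] < 0.05 and r[2] < 0
        }
        up = {r[0] for r in act_rows if r[4] < 0.05 and r[2] > 0}
        assert sig.effector_genes == down & up
        assert sig.core_signature == down & up & bound & spec
        assert sig.core_signature <= sig.effector_genes

    def test_missing_adjusted_p_is_schema_error(self):
        bad = pd.DataFrame({"gene": ["g"], "group": ["x"]})
        with pytest.raises(SchemaError):
            cc.DETable(bad)


class TestSsgsea:
    def test_top_ranked_set_is_exhaustive_maximum(self):
        rng = np.random.default_rng(0)
        prof = pd.Series(
            rng.normal(size=10), index=[f"g{i}" for i in range(10)]
        )
        top3 = set(prof.sort_values(ascending=False).index[:3])
        best = cc.ssgsea_score(prof, top3)
        for s in itertools.combinations(prof.index, 3):
            assert cc.ssgsea_score(prof, set(s)) <= best + 1e-12

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        prof = pd.Series(
            rng.normal(size=30), index=[f"g{i}" for i in range(30)]
        )
        gs = {"g3", "g7", "g20"}
        base = cc.ssgsea_score(prof, gs)
        assert cc.ssgsea_score(np.exp(prof), gs) == pytest.approx(base)
        assert cc.ssgsea_score(prof * 100 - 5, gs) == pytest.approx(base)

    def test_hand_worked_running_sum(self):
        # 6 genes, set {a, c}; descending order a>b>c>d>e>f with ranks 6..1
        prof = pd.Series(
            {"a": 6.0, "b": 5.0, "c": 4.0, "d": 3.0, "e": 2.0, "f": 1.0}
        )
        alpha = 0.25
        wa, wc = 6**alpha, 4**alpha
        wt = wa + wc
        ecdf_in = np.cumsum([wa, 0, wc, 0, 0, 0]) / wt
        ecdf_out = np.cumsum([0, 1, 0, 1, 1, 1]) / 4
        expected = float(np.sum(ecdf_in - ecdf_out))
        assert cc.ssgsea_score(prof, {"a", "c"}, alpha) == pytest.approx(expected)
        # second set, disjoint ranks
        wb, wf = 5**alpha, 1**alpha
        ecdf_in = np.cumsum([0, wb, 0, 0, 0, wf]) / (wb + wf)
        ecdf_out = np.cumsum([1, 0, 1, 1, 1, 0]) / 4
        expected2 = float(np.sum(ecdf_in - ecdf_out))
        assert cc.ssgsea_score(prof, {"b", "f"}, alpha) == pytest.approx(expected2)

    def test_degenerate_sets_rejected(self):
        prof = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ConfigError):
            cc.ssgsea_score(prof, set())
        with pytest.raises(ConfigError):
            cc.ssgsea_score(prof, {"a", "b"})


class TestOrderedProbit:
    def test_recovery_of_planted_slope(self):
        betas = []
        for seed in range(20):
            _, sev, truth = cc.generate_cohort(
                cc.CohortConfig(n_subjects=500, beta_true=1.5, seed=seed)
            )
            betas.append(cc.ordered_probit(truth.s, sev).beta)
        assert abs(np.mean(betas) - 1.5) <= 0.15

    def test_binary_reduction_matches_independent_probit(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=400)
        y = (0.8 * z + rng.normal(size=400) > 0.2).astype(int)
        fit = cc.ordered_probit(z, y)
        oracle = sm.Probit(y, sm.add_constant(z)).fit(disp=0)
        assert fit.beta == pytest.approx(oracle.params[1], abs=1e-4)
        assert fit.cutpoints[0] == pytest.approx(-oracle.params[0], abs=1e-4)

    def test_cutpoints_strictly_increasing(self):
        _, sev, truth = cc.generate_cohort(
            cc.CohortConfig(n_subjects=300, n_categories=5, seed=3)
        )
        fit = cc.ordered_probit(truth.s, sev)
        assert np.all(np.diff(fit.cutpoints) > 0)
        assert fit.J == 5

    def test_predictor_scale_equivariance(self):
        _, sev, truth = cc.generate_cohort(
            cc.CohortConfig(n_subjects=300, seed=4)
        )
        f1 = cc.ordered_probit(truth.s, sev)
        f2 = cc.ordered_probit(truth.s * 10, sev)
        assert f2.beta == pytest.approx(f1.beta / 10, rel=1e-3)
        assert f2.p_one_sided == pytest.approx(f1.p_one_sided, rel=1e-2)


class TestRefineSignature:
    def test_refined_subset_of_core_and_planted_recovery(self):
        cfg = cc.CohortConfig(n_subjects=400, beta_true=2.0, seed=0)
        profiles, sev, truth = cc.generate_cohort(cfg)
        core = set(truth.signature_genes[:20]) | {"g0300", "g0301"}
        refined = cc.refine_signature(core, profiles, sev)
        assert refined <= core
        # decoys are not individually predictive
        assert "g0300" not in refined and "g0301" not in refined

    def test_zero_thresholds_return_core(self):
        cfg = cc.CohortConfig(n_subjects=100, beta_true=1.0, seed=1)
        profiles, sev, truth = cc.generate_cohort(cfg)
        core = set(truth.signature_genes[:5])
        got = cc.refine_signature(
            core, profiles, sev, alpha=1.1, beta_min=-np.inf
        )
        assert got == core


class TestDeconvMarkers:
    def test_printed_thresholds_applied(self):
        rows = [
            ("keep", "T1", 0.8, 1e-9, 1e-8, 0.9, 0.10),
            ("highbg", "T1", 2.0, 1e-12, 1e-11, 0.9, 0.50),
            ("lowlfc", "T1", 0.5, 1e-12, 1e-11, 0.9, 0.10),
            ("highp", "T1", 0.8, 1e-7, 1e-6, 0.9, 0.10),
            ("edge_lfc", "T2", 0.75, 1e-9, 1e-8, 0.9, 0.19),
        ]
        de = _de(rows)
        markers = cc.select_deconv_markers(de)
        assert markers == {"T1": ["keep"], "T2": ["edge_lfc"]}

    def test_hand_filter_oracle_on_8_genes(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(8):
            rows.append(
                (
                    f"g{i}", "T",
                    float(rng.uniform(0, 2)),
                    float(10.0 ** rng.uniform(-12, -4)),
                    0.5, 0.9,
                    float(rng.uniform(0, 0.4)),
                )
            )
        de = _de(rows)
        cfg = DeconvMarkerConfig()
        got = cc.select_deconv_markers(de, cfg)
        oracle = sorted(
            r[0] for r in rows
            if r[3] < cfg.p_max and r[2] >= cfg.min_lfc and r[6] < cfg.max_frac_bg
        )
        assert got.get("T", []) == oracle


class TestCohortScoring:
    def test_planted_signature_scores_track_latent_level(self):
        profiles, sev, truth = cc.generate_cohort(
            cc.CohortConfig(n_subjects=100, beta_true=2.0, seed=5)
        )
        scores = score_cohort(profiles, truth.signature_genes)
        assert np.corrcoef(scores.values, truth.s)[0, 1] > 0.8
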