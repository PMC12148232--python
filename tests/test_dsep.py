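"""Path-model set, basis sets, claim tests, Fisher's C, information
criteria, bootstrap coefficients, and nested likelihood-ratio tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import asrpath as ap
from asrpath.paths import (
    PathError,
    VERTICES,
    model_loglik,
    saturated_model,
)

MODELS = ap.build_model_set()

# expected structure per model (edge count, hardenberg k and q, santos k, q)
EXPECTED = {
    "m1.b": dict(edges=5, k_h=5, q_h=10, k_s=2, q_s=9),
    "m1.a": dict(edges=4, k_h=6, q_h=9, k_s=3, q_s=8),
    "m2.b": dict(edges=6, k_h=4, q_h=11, k_s=3, q_s=12),
    "m3.b": dict(edges=6, k_h=4, q_h=11, k_s=3, q_s=12),
    "m2.a": dict(edges=5, k_h=5, q_h=10, k_s=4, q_s=11),
    "m3.a": dict(edges=5, k_h=5, q_h=10, k_s=4, q_s=11),
    "m4.b": dict(edges=7, k_h=3, q_h=12, k_s=3, q_s=15),
    "m4.a": dict(edges=6, k_h=4, q_h=11, k_s=4, q_s=14),
}


class TestModelSet:
    def test_ids_and_edge_counts(self):
        assert set(MODELS) == set(EXPECTED)
        for mid, exp in EXPECTED.items():
            assert len(MODELS[mid].edges) == exp["edges"]

    def test_shared_backbone_and_direct_link(self):
        for mid, model in MODELS.items():
            for edge in (("AMB", "ASR"), ("JMB", "ASR"), ("MAT", "ASR"),
                         ("GSD", "AMB")):
                assert edge in model.edges
            assert (("GSD", "ASR") in model.edges) == mid.endswith(".b")

    def test_nesting_relations(self):
        assert MODELS["m1.a"].is_nested_in(MODELS["m1.b"])
        for mid in ("m2.b", "m3.b", "m4.b"):
            assert MODELS["m1.b"].is_nested_in(MODELS[mid])
        assert not MODELS["m2.b"].is_nested_in(MODELS["m3.b"])

    def test_all_acyclic(self):
        for model in MODELS.values():
            assert len(model.causal_order()) == 5

    def test_cycle_rejected(self):
        with pytest.raises(PathError, match="cyclic"):
            ap.PathModel("bad", (("ASR", "GSD"), ("GSD", "AMB"), ("AMB", "ASR")))


class TestBasisSets:
    @pytest.mark.parametrize("mid", sorted(EXPECTED))
    def test_counts_both_styles(self, mid):
        model = MODELS[mid]
        assert len(ap.basis_set(model, "hardenberg")) == EXPECTED[mid]["k_h"]
        assert len(ap.basis_set(model, "santos")) == EXPECTED[mid]["k_s"]
        assert ap.hardenberg_q(model) == EXPECTED[mid]["q_h"]
        assert ap.santos_q(model) == EXPECTED[mid]["q_s"]

    def test_m1b_santos_claims(self):
        claims = {
            (c.response, c.other, c.cond)
            for c in ap.basis_set(MODELS["m1.b"], "santos")
        }
        assert claims == {
            ("JMB", "AMB", ("GSD",)),
            ("MAT", "AMB", ("GSD",)),
        }

    def test_claims_are_non_adjacent(self):
        for mid, model in MODELS.items():
            for style in ("santos", "hardenberg"):
                for c in ap.basis_set(model, style):
                    assert not model.adjacent(c.response, c.other)

    def test_conditioning_excludes_tested_pair(self):
        with pytest.raises(PathError, match="conditioning"):
            ap.IndependenceClaim("ASR", "JMB", ("JMB",))


class TestFisherC:
    def test_all_ones(self):
        C, df, p = ap.fisher_c([1.0, 1.0, 1.0])
        assert C == pytest.approx(0.0)
        assert (df, p) == (6, 1.0)

    def test_chi_square_survival_values(self):
        # C = 8.5 on 4 df and C = 14.2 on 6 df
        assert stats.chi2.sf(8.5, 4) == pytest.approx(0.0749, abs=5e-4)
        _, df1, p1 = ap.fisher_c([math.exp(-8.5 / 4)] * 2)
        assert df1 == 4
        assert p1 == pytest.approx(stats.chi2.sf(8.5, 4), abs=1e-12)
        _, _, p2 = ap.fisher_c([math.exp(-14.2 / 6)] * 3)
        assert p2 == pytest.approx(0.027, abs=5e-4)

    def test_zero_pvalue_flags_rejection(self):
        C, df, p = ap.fisher_c([0.0, 0.5])
        assert math.isinf(C) and p == 0.0

    def test_monotone_in_C(self):
        _, _, p_small = ap.fisher_c([0.5, 0.5])
        _, _, p_large = ap.fisher_c([0.01, 0.01])
        assert p_large < p_small


class TestInformationCriterion:
    def test_printed_values(self):
        assert ap.information_criterion(13.0, 10, 95, "CICc") == pytest.approx(
            35.6, abs=0.05
        )
        assert ap.information_criterion(8.5, 9, 95, "AICc") == pytest.approx(
            28.6, abs=0.05
        )

    def test_zero_parameters_limit(self):
        assert ap.information_criterion(4.2, 0, 95) == pytest.approx(4.2)

    def test_small_sample_guard(self):
        with pytest.raises(PathError, match="too small"):
            ap.information_criterion(5.0, 94, 95)


class TestSantosTransform:
    def test_lambda_recovery(self):
        """Per-variable λ̂ has its median near the generating λ = 0.3."""
        from asrpath.synthetic import lambda_noise

        lams = []
        for seed in range(100):
            rng = np.random.default_rng(3_000 + seed)
            tree = ap.simulate_tree(95, rng=rng)
            y = lambda_noise(tree, 0.3, rng)
            data = pd.DataFrame({"X": y}, index=tree.tip_labels)
            _, lam = ap.santos_transform(data, tree)
            lams.append(lam["X"])
        assert 0.15 <= np.median(lams) <= 0.45

    def test_constant_variable_rejected(self, yule50):
        data = pd.DataFrame(
            {"X": np.zeros(50)}, index=yule50.tip_labels
        )
        with pytest.raises(PathError, match="no variance"):
            ap.santos_transform(data, yule50)

    def test_alignment_across_variables(self, small_dataset):
        data, tree = ap.prepare_path_data(
            small_dataset.table, small_dataset.tree
        )
        tdata, lams = ap.santos_transform(data, tree)
        assert list(tdata.columns) == list(VERTICES)
        assert len(tdata) == tree.n_tips - 1
        assert set(lams) == set(VERTICES)


class TestClaimTests:
    def test_strong_violation_detected(self):
        rng = np.random.default_rng(17)
        n = 95
        g = rng.normal(size=n)
        amb = -0.5 * g + rng.normal(size=n) * 0.8
        jmb = 0.8 * amb + rng.normal(size=n) * 0.6  # violates JMB _||_ AMB
        data = pd.DataFrame({"GSD": g, "AMB": amb, "JMB": jmb})
        claim = ap.IndependenceClaim("JMB", "AMB", ("GSD",))
        assert ap.test_claim(claim, data, "santos") < 0.001

    def test_satisfied_claim_large_p(self):
        rng = np.random.default_rng(18)
        n = 400
        g = rng.normal(size=n)
        amb = -0.5 * g + rng.normal(size=n) * 0.8
        jmb = rng.normal(size=n)
        data = pd.DataFrame({"GSD": g, "AMB": amb, "JMB": jmb})
        claim = ap.IndependenceClaim("JMB", "AMB", ("GSD",))
        assert ap.test_claim(claim, data, "santos") > 0.01

    def test_hardenberg_requires_covariance(self, small_dataset):
        data, tree = ap.prepare_path_data(
            small_dataset.table, small_dataset.tree
        )
        claim = ap.IndependenceClaim("JMB", "AMB", ("GSD",))
        with pytest.raises(PathError, match="covariance"):
            ap.test_claim(claim, data, "hardenberg")


class TestPathCoefficients:
    def test_seed_reproducibility(self, small_dataset):
        data, tree = ap.prepare_path_data(
            small_dataset.table, small_dataset.tree
        )
        tdata, _ = ap.santos_transform(data, tree)
        a = ap.fit_path_coefficients(MODELS["m1.b"], tdata, "santos",
                                     n_boot=100, seed=5)
        b = ap.fit_path_coefficients(MODELS["m1.b"], tdata, "santos",
                                     n_boot=100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_null_effect_ci_covers_zero(self):
        """Single-edge model with zero effect: bootstrap CI covers 0 at
        roughly its nominal rate."""
        single = ap.PathModel("single", (("GSD", "AMB"),) + tuple())
        cover = 0
        n_reps = 100
        for seed in range(n_reps):
            rng = np.random.default_rng(7_000 + seed)
            data = pd.DataFrame(
                {v: rng.normal(size=80) for v in VERTICES}
            )
            out = ap.fit_path_coefficients(
                single, data, "santos", n_boot=200, seed=seed
            )
            row = out.iloc[0]
            cover += row["lower"] <= 0.0 <= row["upper"]
        assert cover / n_reps >= 0.88

    def test_standardized_scale(self):
        rng = np.random.default_rng(19)
        g = rng.normal(size=2000)
        amb = -0.5 * g * 2.0 + rng.normal(size=2000)  # raw slope -1.0
        data = pd.DataFrame({v: rng.normal(size=2000) for v in VERTICES})
        data["GSD"], data["AMB"] = g, amb
        single = ap.PathModel("single", (("GSD", "AMB"),))
        out = ap.fit_path_coefficients(single, data, "santos", n_boot=0)
        expect = -1.0 * g.std(ddof=1) / amb.std(ddof=1)
        assert out["coef"].iloc[0] == pytest.approx(expect, abs=0.01)


class TestLRT:
    def test_identical_models(self, small_dataset):
        data, tree = ap.prepare_path_data(
            small_dataset.table, small_dataset.tree
        )
        tdata, _ = ap.santos_transform(data, tree)
        chi2, ddf, p = ap.lrt_nested(MODELS["m1.b"], MODELS["m1.b"], tdata)
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert p == 1.0

    def test_non_nested_rejected(self, small_dataset):
        data, tree = ap.prepare_path_data(
            small_dataset.table, small_dataset.tree
        )
        with pytest.raises(PathError, match="not nested"):
            ap.lrt_nested(MODELS["m2.b"], MODELS["m3.b"], data)

    def test_direct_link_detected(self):
        """Data generated with a real GSD->ASR effect: m1.b beats m1.a."""
        rng = np.random.default_rng(20)
        n = 95
        g = rng.normal(size=n)
        amb = -0.5 * g + 0.87 * rng.normal(size=n)
        jmb = rng.normal(size=n)
        mat = rng.normal(size=n)
        asr = (0.6 * g - 0.2 * amb - 0.25 * jmb - 0.2 * mat
               + 0.6 * rng.normal(size=n))
        data = pd.DataFrame(
            {"GSD": g, "JMB": jmb, "AMB": amb, "MAT": mat, "ASR": asr}
        )
        chi2, ddf, p = ap.lrt_nested(MODELS["m1.a"], MODELS["m1.b"], data)
        assert ddf == 1
        assert p < 0.001

    def test_null_calibration_against_chi2(self):
        """Saturated vs generating model: the LRT statistic follows the
        chi-square reference distribution (500 replicates)."""
        sat = saturated_model()
        m1b = MODELS["m1.b"]
        _, q_sat = None, sat.n_free_parameters()
        ddf_expected = sat.n_free_parameters() - m1b.n_free_parameters()
        stats_ = []
        for seed in range(500):
            rng = np.random.default_rng(40_000 + seed)
            n = 95
            g = rng.normal(size=n)
            jmb = rng.normal(size=n)
            mat = rng.normal(size=n)
            amb = -0.5 * g + 0.87 * rng.normal(size=n)
            asr = (0.6 * g - 0.2 * amb - 0.25 * jmb - 0.2 * mat
                   + 0.6 * rng.normal(size=n))
            data = pd.DataFrame(
                {"GSD": g, "JMB": jmb, "AMB": amb, "MAT": mat, "ASR": asr}
            )
            chi2, ddf, _ = ap.lrt_nested(m1b, sat, data)
            assert ddf == ddf_expected
            stats_.append(chi2)
        ks = stats.kstest(stats_, stats.chi2(ddf_expected).cdf)
        assert ks.pvalue > 0.01


class TestPathAnalysis:
    @pytest.mark.parametrize("style", ["santos", "hardenberg"])
    def test_nested_models_C_monotone(self, small_dataset, style):
        """Whenever a larger model's claim set is a subset of a smaller
        model's, its Fisher's C cannot be larger.  (For the santos flavor an
        added edge can create new claims by making a vertex endogenous, so
        only claim-subset pairs are comparable.)"""
        analysis = ap.PathAnalysis(
            small_dataset.table, small_dataset.tree, style=style
        )
        res = analysis.fit()
        checked = 0
        for small, large in [("m1.a", "m1.b"), ("m1.b", "m2.b"),
                             ("m1.b", "m4.b"), ("m2.a", "m2.b")]:
            claims_small = set(map(str, res.reports[small].claims))
            claims_large = set(map(str, res.reports[large].claims))
            if claims_large <= claims_small:
                assert res.reports[large].C <= res.reports[small].C + 1e-9
                checked += 1
        assert checked >= 2

    def test_best_model_delta_zero(self, small_dataset):
        res = ap.PathAnalysis(
            small_dataset.table, small_dataset.tree, style="santos"
        ).fit()
        table = res.table()
        assert table.iloc[0]["dAICc"] == pytest.approx(0.0)
        assert (table["dAICc"] >= 0).all()

    def test_selects_generating_model_on_one_draw(self, small_dataset):
        res = ap.PathAnalysis(
            small_dataset.table, small_dataset.tree, style="santos"
        ).fit()
        assert res.best_model in {"m1.b", "m2.b", "m3.b", "m4.b"}
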