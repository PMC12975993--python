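"""Variance components, heritability, BLUP and Wald oracles."""

import numpy as np
import pandas as pd
import pytest

from canalbedo import genstats, synthgen
from canalbedo.errors import InsufficientDesign


def _rcbd_frame(values_by_genotype):
    rows = []
    for geno, vals in values_by_genotype.items():
        for j, v in enumerate(vals):
            rows.append((2018, 1, geno, f"R{j+1}", "albedo_noon", v))
    return pd.DataFrame(rows, columns=["year", "tos", "genotype", "replicate",
                                       "trait_name", "value"])


class TestFitRcbd:
    def test_hand_anova_example(self):
        # g1 blocks (1, 3), g2 blocks (5, 7): SST 20, SSG 16, SSB 4, SSE 0
        df = _rcbd_frame({"g1": [1.0, 3.0], "g2": [5.0, 7.0]})
        vc, _ = genstats.fit_rcbd(df)
        assert vc.sigma2_e == pytest.approx(0.0, abs=1e-12)
        assert vc.sigma2_g == pytest.approx(8.0)   # (MSG - MSE)/r = (16 - 0)/2

    def test_all_equal(self):
        df = _rcbd_frame({"g1": [2.0, 2.0], "g2": [2.0, 2.0]})
        vc, _ = genstats.fit_rcbd(df)
        assert vc.sigma2_g == 0.0 and vc.sigma2_e == 0.0

    def test_too_few_replicates(self):
        df = _rcbd_frame({"g1": [1.0], "g2": [2.0]})
        with pytest.raises(InsufficientDesign):
            genstats.fit_rcbd(df)

    def test_simulation_recovery_of_sigma2_g(self):
        """Mean estimate over seeded balanced trials hits the true component."""
        cfg = synthgen.SynthConfig(seed=21)
        ests = []
        for i in range(120):
            df, _ = synthgen.gen_rcbd(cfg, rng=synthgen.substream(21, f"rec/{i}"))
            vc, _ = genstats.fit_rcbd(df)
            ests.append(vc.sigma2_g)
        sem = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - cfg.sigma2_g) < 3 * sem + 1e-6

    def test_truncation_atom_at_zero_under_null(self):
        """With sigma2_g = 0 truth the truncated estimator piles up at 0."""
        cfg = synthgen.SynthConfig(seed=22, sigma2_g=0.0)
        zeros = 0
        for i in range(60):
            df, _ = synthgen.gen_rcbd(cfg, rng=synthgen.substream(22, f"null/{i}"))
            vc, _ = genstats.fit_rcbd(df)
            assert vc.sigma2_g >= 0.0
            zeros += vc.sigma2_g == 0.0
        assert zeros >= 10

    def test_reml_equals_anova_on_balanced_data(self):
        cfg = synthgen.SynthConfig(seed=23)
        df, _ = synthgen.gen_rcbd(cfg)
        mom, _ = genstats.fit_rcbd(df, method="anova")
        reml, _ = genstats.fit_rcbd(df, method="reml")
        assert reml.sigma2_g == pytest.approx(mom.sigma2_g, abs=1e-8)
        assert reml.sigma2_e == pytest.approx(mom.sigma2_e, abs=1e-8)

    def test_reml_unbalanced_matches_mixedlm(self):
        """Independent cross-check of the unbalanced REML path."""
        statsmodels = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        cfg = synthgen.SynthConfig(seed=24, n_genotypes=12)
        df, _ = synthgen.gen_rcbd(cfg)
        df = df.drop(index=df.index[[1, 7, 20]]).reset_index(drop=True)
        vc, _ = genstats.fit_rcbd(df)
        assert vc.method == "reml"
        md = statsmodels.MixedLM.from_formula(
            "value ~ 1",
            groups=np.ones(len(df)),
            vc_formula={"genotype": "0 + C(genotype)", "replicate": "0 + C(replicate)"},
            data=df,
        )
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = md.fit(reml=True)
        comps = dict(zip(md.exog_vc.names, fit.vcomp))
        assert vc.sigma2_e == pytest.approx(fit.scale, rel=5e-3)
        assert vc.sigma2_g == pytest.approx(comps["genotype"], rel=5e-3, abs=1e-5)


class TestHeritability:
    @pytest.mark.parametrize(
        "s2g,s2e,r,expected",
        [(0.0043, 0.0021, 3, 0.86), (0.0071, 0.0087, 3, 0.71)],
    )
    def test_closed_form_two_decimals(self, s2g, s2e, r, expected):
        vc = genstats.VarianceComponents(s2g, s2e, 0.0, r, "anova_mom")
        assert round(genstats.heritability(vc, r).H2, 2) == expected

    def test_noise_free_limit(self):
        vc = genstats.VarianceComponents(0.5, 0.0, 0.0, 3, "anova_mom")
        assert genstats.heritability(vc).H2 == 1.0

    def test_undefined_when_both_zero(self):
        vc = genstats.VarianceComponents(0.0, 0.0, 0.0, 3, "anova_mom")
        res = genstats.heritability(vc)
        assert res.H2 == 0.0 and res.undefined

    def test_cullis_equals_line_mean_when_balanced(self):
        vc = genstats.VarianceComponents(0.0043, 0.0021, 0.0, 3, "anova_mom")
        assert genstats.heritability(vc, basis="cullis").H2 == pytest.approx(
            genstats.heritability(vc).H2)


class TestBlup:
    def test_no_shrinkage_when_noise_free(self):
        vc = genstats.VarianceComponents(1.0, 0.0, 0.0, 3, "anova_mom")
        means = pd.Series({"g1": 1.0, "g2": 3.0})
        out = genstats.blup(vc, means, 2.0)
        assert out["g1"] == -1.0 and out["g2"] == 1.0

    def test_all_zero_when_no_genetic_variance(self):
        vc = genstats.VarianceComponents(0.0, 1.0, 0.0, 3, "anova_mom")
        means = pd.Series({"g1": 1.0, "g2": 3.0})
        assert (genstats.blup(vc, means, 2.0) == 0.0).all()

    def test_matches_henderson_equations(self, rng):
        """Shrinkage equals the mixed-model-equations solve on a small design."""
        g, r = 6, 3
        s2g, s2e = 0.0043, 0.0021
        geno_eff = rng.normal(0, np.sqrt(s2g), g)
        y = 0.2 + np.repeat(geno_eff, r) + rng.normal(0, np.sqrt(s2e), g * r)
        labels = np.repeat([f"g{i}" for i in range(g)], r)
        # Henderson MME: [X'X X'Z; Z'X Z'Z + lam I][b; u] = [X'y; Z'y]
        X = np.ones((g * r, 1))
        Z = np.zeros((g * r, g))
        Z[np.arange(g * r), np.repeat(np.arange(g), r)] = 1.0
        lam = s2e / s2g
        A = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * np.eye(g)]])
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol = np.linalg.solve(A, rhs)
        u_mme = sol[1:]
        vc = genstats.VarianceComponents(s2g, s2e, 0.0, r, "anova_mom")
        means = pd.Series(y.reshape(g, r).mean(axis=1), index=[f"g{i}" for i in range(g)])
        out = genstats.blup(vc, means, float(y.mean()))
        np.testing.assert_allclose(out.to_numpy(), u_mme, atol=1e-10)

    def test_shrinkage_identity_on_balanced_fit(self):
        cfg = synthgen.SynthConfig(seed=31)
        df, _ = synthgen.gen_rcbd(cfg)
        vc, eff = genstats.fit_rcbd(df)
        h2 = genstats.heritability(vc).H2
        out = genstats.blup(vc, eff["genotype_means"], eff["grand_mean"])
        expected = h2 * (eff["genotype_means"] - eff["grand_mean"])
        np.testing.assert_allclose(out.to_numpy(), expected.to_numpy(), atol=1e-12)


class TestMetWald:
    def test_sequential_f_matches_anova_oracle(self):
        """Fixed-effects-only fit reproduces classical sequential ANOVA F."""
        cfg = synthgen.SynthConfig(seed=41, n_genotypes=5,
                                   environments=((2018, 1), (2018, 2)))
        df, _ = synthgen.gen_trial(cfg)
        res = genstats.met_wald(df, random=None)
        # independent oracle: sequential sums of squares via lstsq projections
        def dummies(*cols):
            key = df[list(cols)].astype(str).agg(":".join, axis=1)
            return pd.get_dummies(key).to_numpy(dtype=float)
        y = df["value"].to_numpy()
        n = len(y)
        designs = [np.ones((n, 1))]
        for cols in (["year"], ["tos"], ["year", "tos"], ["genotype"],
                     ["genotype", "year", "tos"]):
            designs.append(np.column_stack([designs[-1], dummies(*cols)]))
        rss = [float(np.sum((y - D @ np.linalg.lstsq(D, y, rcond=None)[0]) ** 2))
               for D in designs]
        ranks = [np.linalg.matrix_rank(D) for D in designs]
        p_full = ranks[-1]
        mse = rss[-1] / (n - p_full)
        names = ["year", "environment", "year:environment", "genotype",
                 "genotype:environment"]
        oracle = {}
        for k, name in enumerate(names):
            dfk = ranks[k + 1] - ranks[k]
            if dfk:
                oracle[name] = ((rss[k] - rss[k + 1]) / dfk / mse, dfk)
        for w in res:
            if w.df == 0:
                assert w.term not in oracle
                continue
            f_exp, df_exp = oracle[w.term]
            assert w.df == df_exp
            assert w.wald_f == pytest.approx(f_exp, rel=1e-8)

    def test_genotype_effect_detected(self):
        cfg = synthgen.SynthConfig(seed=42)
        df, _ = synthgen.gen_trial(cfg)
        res = {w.term: w for w in genstats.met_wald(df)}
        assert res["genotype"].p_value < 1e-6
        assert res["genotype"].significance == "***"
        assert res["genotype"].df == cfg.n_genotypes - 1
        assert res["genotype:environment"].df == (cfg.n_genotypes - 1) * 2

    def test_rank_deficient_term_df_reduced(self):
        """Year:environment has no df left with only three (year, tos) cells."""
        cfg = synthgen.SynthConfig(seed=43)
        df, _ = synthgen.gen_trial(cfg)
        res = {w.term: w for w in genstats.met_wald(df)}
        assert res["year:environment"].df == 0

    def test_needs_two_environments(self):
        cfg = synthgen.SynthConfig(seed=44, environments=((2018, 1),))
        df, _ = synthgen.gen_trial(cfg)
        with pytest.raises(InsufficientDesign):
            genstats.met_wald(df)


class TestSignificanceCode:
    @pytest.mark.parametrize(
        "p,code",
        [(0.0000272, "***"), (0.2109097, "NS"), (0.049, "*"),
         (0.0099, "**"), (0.05, "NS"), (1.0, "NS")],
    )
    def test_thresholds(self, p, code):
        assert genstats.significance_code(p) == code

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            genstats.significance_code(0.0)
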