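"""Investment scores, group summaries, Kruskal-Wallis and phylogenetic ANCOVA."""

import numpy as np
import pandas as pd
import pytest

from frogeye.ecology import (
    ECOLOGICAL_TRAITS,
    group_summary,
    investment_scores,
    kruskal_wallis,
    phylo_ancova,
    validate_ecology,
)
from frogeye.pgls import design_matrix, gls_fit
from frogeye.phylo import PhyloCovariance, phylo_covariance
from frogeye.synthetic import (
    SimConfig,
    simulate_allometry,
    simulate_predictor,
    simulate_states,
    simulate_yule_tree,
)


def _fit_with_residuals(resids: dict):
    """A minimal PGLS-fit stand-in carrying chosen residuals."""
    from frogeye.pgls import PGLSFit

    s = pd.Series(resids, name="resid")
    return PGLSFit(
        params=pd.Series({"Intercept": 0.0}), bse=pd.Series({"Intercept": 0.0}),
        tvalues=pd.Series({"Intercept": 0.0}), pvalues=pd.Series({"Intercept": 1.0}),
        df_model=0, df_resid=len(s) - 1, r_squared=0.0, lambda_=1.0,
        sigma2=1.0, log_likelihood=0.0, residuals=s, fitted=0.0 * s,
    )


class TestInvestmentScores:
    def test_worked_example_point_two(self):
        fit = _fit_with_residuals({"a": 0.2})
        table = investment_scores(fit)
        assert table.loc["a", "investment_factor"] == pytest.approx(10**0.2)
        assert f"{table.loc['a', 'investment_factor']:.1f}" == "1.6"

    def test_zero_and_negative_residuals(self):
        fit = _fit_with_residuals({"a": 0.0, "b": -0.1})
        table = investment_scores(fit)
        assert table.loc["a", "investment_factor"] == 1.0
        assert table.loc["b", "investment_factor"] == pytest.approx(10**-0.1)

    def test_log10_is_identity_on_residuals(self, rng):
        resids = {f"s{i}": v for i, v in enumerate(rng.normal(scale=0.2, size=40))}
        table = investment_scores(_fit_with_residuals(resids))
        assert np.allclose(
            np.log10(table["investment_factor"]), table["residual"], atol=1e-14
        )


class TestGroupSummary:
    def test_single_species_per_state(self):
        fit = _fit_with_residuals({"a": 0.2, "b": -0.1})
        eco = pd.DataFrame(
            {"adult_habitat": ["fossorial", "scansorial"]}, index=["a", "b"]
        )
        table = investment_scores(fit, ecology=eco)
        summ = group_summary(table, "adult_habitat")
        assert summ.loc["fossorial", "mean_investment"] == pytest.approx(10**0.2)
        assert summ.loc["scansorial", "n"] == 1

    def test_planted_offsets_recover_ordering(self, rng):
        states = ["fossorial", "ground-dwelling", "scansorial"]
        offsets = {"fossorial": -0.19, "ground-dwelling": 0.0, "scansorial": 0.09}
        resids, eco = {}, {}
        for i in range(300):
            st = states[i % 3]
            resids[f"s{i}"] = offsets[st] + rng.normal(scale=0.05)
            eco[f"s{i}"] = st
        table = investment_scores(
            _fit_with_residuals(resids),
            ecology=pd.DataFrame({"adult_habitat": pd.Series(eco)}),
        )
        summ = group_summary(table, "adult_habitat")
        means = summ["mean_investment"]
        assert means["fossorial"] < means["ground-dwelling"] < means["scansorial"]
        assert means["fossorial"] == pytest.approx(10**-0.19, rel=0.05)

    def test_unknown_trait_errors(self):
        table = investment_scores(_fit_with_residuals({"a": 0.0}))
        with pytest.raises(KeyError):
            group_summary(table, "diet")

    def test_missing_states_excluded_per_trait(self):
        fit = _fit_with_residuals({"a": 0.1, "b": 0.2, "c": 0.3})
        eco = pd.DataFrame(
            {"adult_habitat": ["fossorial", None, "fossorial"]},
            index=["a", "b", "c"],
        )
        summ = group_summary(investment_scores(fit, ecology=eco), "adult_habitat")
        assert int(summ["n"].sum()) == 2


class TestValidateEcology:
    def test_unknown_state_errors(self):
        eco = pd.DataFrame({"adult_habitat": ["arboreal"]}, index=["a"])
        with pytest.raises(ValueError, match="arboreal"):
            validate_ecology(eco)

    def test_all_enumerated_states_pass(self):
        for trait, states in ECOLOGICAL_TRAITS.items():
            eco = pd.DataFrame({trait: list(states)},
                               index=[f"s{i}" for i in range(len(states))])
            validate_ecology(eco)


class TestKruskalWallis:
    def test_hand_rank_oracle(self):
        res = kruskal_wallis([1, 2, 3, 4], ["g1", "g1", "g2", "g2"])
        assert res.H == pytest.approx(2.4)
        assert res.df == 1

    def test_label_exchange_invariance(self, rng):
        v = rng.normal(size=30)
        g = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        g_swapped = ["b"] * 10 + ["a"] * 10 + ["c"] * 10
        assert kruskal_wallis(v, g).H == pytest.approx(kruskal_wallis(v, g_swapped).H)

    def test_all_identical_h_zero(self):
        res = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert res.H == 0.0
        assert res.p == 1.0

    def test_empty_group_after_missing_errors(self):
        with pytest.raises(ValueError, match="b"):
            kruskal_wallis([1.0, 2.0, np.nan], ["a", "a", "b"])

    def test_ties_use_correction(self):
        # with ties, uncorrected H underestimates; scipy applies the divisor
        res = kruskal_wallis([1, 1, 2, 2, 3, 3], ["a", "a", "a", "b", "b", "b"])
        assert res.H > 0

    def test_permutation_null_agreement(self, rng):
        v = rng.normal(size=24)
        g = np.array(["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        res = kruskal_wallis(v, g)
        n_perm, hits = 4000, 0
        for _ in range(n_perm):
            hits += kruskal_wallis(v, rng.permutation(g)).H >= res.H - 1e-12
        p_perm = hits / n_perm
        assert res.p == pytest.approx(p_perm, abs=0.05)


class TestPhyloAncova:
    @staticmethod
    def _dataset(n=60, seed=7, offsets=None, lam=0.96):
        cfg = SimConfig(n_species=n, lambda_true=lam, seed=seed)
        tree = simulate_yule_tree(n, 1.0, seed)
        x = simulate_predictor(tree, cfg.predictor_sigma2, seed + 1, mean=0.33)
        y = simulate_allometry(tree, x, cfg, seed=seed + 2)
        rng = np.random.default_rng(seed + 3)
        levels = ["aquatic", "fossorial", "scansorial"]
        f = pd.Series(rng.choice(levels, size=n, p=[0.3, 0.3, 0.4]), index=y.index)
        if offsets:
            y = y + f.map(lambda s: offsets.get(s, 0.0))
        data = pd.DataFrame({"ED_log": y, "RM_log": x, "adult_habitat": f})
        return tree, data

    def test_df_sum_and_ss_conservation(self):
        tree, data = self._dataset()
        table, fit = phylo_ancova(
            data, tree, response="ED_log", covariate="RM_log", factor="adult_habitat"
        )
        n = len(data)
        assert int(table["df"].sum()) == n - 1
        seq_ss = table.drop(index="Residual")["sum_sq"].sum()
        total_ss = seq_ss + table.loc["Residual", "sum_sq"]
        # total equals the whitened TSS about the GLS mean (intercept-only RSS)
        cov = phylo_covariance(tree)
        from frogeye.phylo import apply_lambda

        sub = data.loc[cov.taxa]
        X0 = design_matrix(sub, [])
        rss0 = gls_fit(X0, sub["ED_log"], apply_lambda(cov, table.attrs["lambda"]))
        assert total_ss == pytest.approx(float(rss0._resid_w @ rss0._resid_w))

    def test_sequential_table_matches_dense_oracle_at_lambda_zero(self, rng):
        # identity covariance: the ANCOVA must equal a textbook sequential
        # decomposition computed by brute-force projections
        n = 40
        taxa = [f"t{i:02d}" for i in range(n)]
        x = rng.normal(size=n)
        f = rng.choice(["a", "b", "c"], size=n)
        y = 1 + 0.5 * x + (f == "b") * 0.4 + rng.normal(scale=0.3, size=n)
        data = pd.DataFrame(
            {"ED_log": y, "RM_log": x, "adult_habitat": f}, index=taxa
        )
        cov = PhyloCovariance(taxa, np.eye(n), 1.0)
        table, fit = phylo_ancova(
            data, cov, response="ED_log", covariate="RM_log", factor="adult_habitat"
        )
        assert fit.lambda_ == 0.0 or fit.lambda_profile_flat or fit.lambda_ < 1e-6

        def proj_rss(cols):
            X = design_matrix(data, cols, interaction=("interaction" in cols))
            Xa = X.to_numpy()
            beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
            r = y - Xa @ beta
            return float(r @ r), Xa.shape[1]

        rss0, _ = proj_rss([])
        rss1, _ = proj_rss(["RM_log"])
        rss2, _ = proj_rss(["RM_log", "adult_habitat"])
        X3 = design_matrix(data, ["RM_log", "adult_habitat"], interaction=True)
        beta, *_ = np.linalg.lstsq(X3.to_numpy(), y, rcond=None)
        rss3 = float(((y - X3.to_numpy() @ beta)) @ (y - X3.to_numpy() @ beta))
        assert table.loc["RM_log", "sum_sq"] == pytest.approx(rss0 - rss1, abs=1e-8)
        assert table.loc["adult_habitat", "sum_sq"] == pytest.approx(rss1 - rss2, abs=1e-8)
        assert table.loc["RM_log:adult_habitat", "sum_sq"] == pytest.approx(
            rss2 - rss3, abs=1e-8
        )
        assert table.loc["Residual", "sum_sq"] == pytest.approx(rss3, abs=1e-8)

    def test_df_pattern_for_six_level_factor(self):
        cfg = SimConfig(n_species=220, seed=13)
        tree = simulate_yule_tree(220, 1.0, 13)
        x = simulate_predictor(tree, cfg.predictor_sigma2, 14, mean=0.33)
        y = simulate_allometry(tree, x, cfg, seed=15)
        eco, y = simulate_states(tree, cfg, response=y, seed=16)
        data = pd.DataFrame({"ED_log": y, "RM_log": x}).join(eco[["adult_habitat"]])
        table, _ = phylo_ancova(
            data, tree, response="ED_log", covariate="RM_log", factor="adult_habitat"
        )
        assert table.loc["adult_habitat", "df"] == 5
        assert table.loc["RM_log:adult_habitat", "df"] == 5
        assert table.loc["Residual", "df"] == 220 - 12

    def test_planted_effect_detected(self):
        tree, data = self._dataset(
            n=120, seed=21, offsets={"fossorial": -0.19}
        )
        table, _ = phylo_ancova(
            data, tree, response="ED_log", covariate="RM_log", factor="adult_habitat"
        )
        assert table.loc["adult_habitat", "p"] < 0.01

    def test_missing_species_dropped(self):
        tree, data = self._dataset()
        data = data.copy()
        data.loc[data.index[:5], "adult_habitat"] = None
        table, fit = phylo_ancova(
            data, tree, response="ED_log", covariate="RM_log", factor="adult_habitat"
        )
        assert fit.n == len(data) - 5
        assert int(table["df"].sum()) == len(data) - 5 - 1

    def test_single_level_factor_errors(self):
        tree, data = self._dataset()
        data["adult_habitat"] = "aquatic"
        with pytest.raises(ValueError, match="level"):
            phylo_ancova(
                data, tree, response="ED_log", covariate="RM_log",
                factor="adult_habitat",
            )
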