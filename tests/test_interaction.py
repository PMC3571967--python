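"""Interaction stage: prescreen, type-III ANOVA, classification."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nwstress.diffexpr import ttest_equal_var
from nwstress.interaction import (
    anova2_type3,
    anova2_type3_matrix,
    classify,
    interaction_analysis,
    pairwise_fold_changes,
    prescreen_pairwise_fc,
)
from nwstress.preprocess import log_and_baseline
from nwstress.simulate import SimulationConfig, simulate


def sequential_ss_oracle(y, n_labels, w_labels):
    """Type-I (sequential) sums of squares computed from nested OLS fits,
    order N, W, NxW."""
    y = np.asarray(y, dtype=float)
    xn = np.where(np.asarray(n_labels) == "optimal", 1.0, -1.0)
    xw = np.where(np.asarray(w_labels).astype(int) == 1, 1.0, -1.0)
    cols = [np.ones_like(xn), xn, xw, xn * xw]

    def rss(k):
        X = np.column_stack(cols[:k])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    r1, r2, r3, r4 = rss(1), rss(2), rss(3), rss(4)
    return {"N": r1 - r2, "W": r2 - r3, "NxW": r3 - r4, "err": r4}


def statsmodels_type3_oracle(y, n_labels, w_labels):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "N": n_labels, "W": [str(w) for w in w_labels]})
    model = smf.ols("y ~ C(N, Sum) * C(W, Sum)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    return {
        "N": tab.loc["C(N, Sum)"], "W": tab.loc["C(W, Sum)"],
        "NxW": tab.loc["C(N, Sum):C(W, Sum)"],
    }


def _labels(reps_per_cell):
    n_labels, w_labels = [], []
    for (nl, wl), r in reps_per_cell.items():
        n_labels += [nl] * r
        w_labels += [wl] * r
    return n_labels, w_labels


class TestTypeIIIAnova:
    def test_additive_cell_means_kill_interaction(self, rng):
        """Perfectly additive cell means with modest noise leave the
        interaction SS at noise level while both main effects dominate."""
        n_labels, w_labels = _labels(
            {("optimal", 1): 3, ("optimal", 3): 3, ("limiting", 1): 3, ("limiting", 3): 3}
        )
        xn = np.where(np.asarray(n_labels) == "optimal", 1.0, -1.0)
        xw = np.where(np.asarray(w_labels) == 1, 1.0, -1.0)
        y = 2.0 * xn - 1.5 * xw
        res = anova2_type3(y, n_labels, w_labels)
        assert res["F_NxW"] == 0.0 and res["p_NxW"] == 1.0
        assert res["p_N"] < 1e-50 and res["p_W"] < 1e-50
        # with noise, the interaction SS stays orders below the main effects
        y2 = y + rng.normal(0, 0.05, len(y))
        res2 = anova2_type3(y2, n_labels, w_labels)
        assert res2["F_N"] > 100 * res2["F_NxW"]
        assert res2["F_W"] > 100 * res2["F_NxW"]

    def test_balanced_type3_equals_sequential_type1(self, rng):
        """On balanced data the partial and sequential decompositions
        coincide exactly."""
        n_labels, w_labels = _labels(
            {("optimal", 1): 3, ("optimal", 3): 3, ("limiting", 1): 3, ("limiting", 3): 3}
        )
        for _ in range(5):
            y = rng.normal(size=12)
            res = anova2_type3(y, n_labels, w_labels)
            ss = sequential_ss_oracle(y, n_labels, w_labels)
            df_err = 12 - 4
            for term in ("N", "W", "NxW"):
                F_oracle = ss[term] / (ss["err"] / df_err)
                assert res[f"F_{term}"] == pytest.approx(F_oracle, abs=1e-10, rel=1e-10)

    @pytest.mark.parametrize(
        "reps", [
            {("optimal", 1): 3, ("optimal", 3): 3, ("limiting", 1): 3, ("limiting", 3): 3},
            {("optimal", 1): 3, ("optimal", 3): 2, ("limiting", 1): 3, ("limiting", 3): 2},
            {("optimal", 1): 4, ("optimal", 3): 2, ("limiting", 1): 3, ("limiting", 3): 3},
        ],
    )
    def test_matches_statsmodels_type3(self, reps, rng):
        """Against statsmodels anova_lm(typ=3) with sum-to-zero coding,
        balanced and unbalanced (dropped-array) layouts."""
        n_labels, w_labels = _labels(reps)
        y = rng.normal(size=len(n_labels)) + np.where(
            np.asarray(n_labels) == "optimal", 0.5, 0.0
        )
        res = anova2_type3(y, n_labels, w_labels)
        oracle = statsmodels_type3_oracle(y, n_labels, w_labels)
        for term in ("N", "W", "NxW"):
            assert res[f"F_{term}"] == pytest.approx(oracle[term]["F"], rel=1e-8)
            assert res[f"p_{term}"] == pytest.approx(oracle[term]["PR(>F)"], rel=1e-8)

    def test_single_water_level_reduces_to_t_squared(self, rng):
        """With water held fixed, the nitrogen F equals the squared pooled
        t statistic of the two nitrogen groups."""
        a = rng.normal(size=4)
        b = rng.normal(0.8, 1.0, size=4)
        t, _ = ttest_equal_var(a, b)
        # one-way layout expressed through the same projection machinery
        y = np.concatenate([a, b])
        xn = np.array([1.0] * 4 + [-1.0] * 4)
        X = np.column_stack([np.ones(8), xn])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss_full = float(((y - X @ beta) ** 2).sum())
        rss_red = float(((y - y.mean()) ** 2).sum())
        F = (rss_red - rss_full) / (rss_full / 6)
        assert F == pytest.approx(t**2, rel=1e-10)

    def test_ss_decomposition_on_balanced_data(self, rng):
        n_labels, w_labels = _labels(
            {("optimal", 1): 3, ("optimal", 3): 3, ("limiting", 1): 3, ("limiting", 3): 3}
        )
        y = rng.normal(size=12)
        ss = sequential_ss_oracle(y, n_labels, w_labels)
        total = float(((y - y.mean()) ** 2).sum())
        assert ss["N"] + ss["W"] + ss["NxW"] + ss["err"] == pytest.approx(total, rel=1e-10)

    def test_empty_cell_rejected(self):
        n_labels, w_labels = _labels(
            {("optimal", 1): 3, ("optimal", 3): 3, ("limiting", 1): 3}
        )
        with pytest.raises(ValueError, match="empty cell"):
            anova2_type3(np.zeros(9), n_labels, w_labels)

    def test_null_type_I_error_controlled(self):
        rng = np.random.default_rng(123)
        n_labels, w_labels = _labels(
            {("optimal", 1): 3, ("optimal", 3): 3, ("limiting", 1): 3, ("limiting", 3): 3}
        )
        alpha, total, rejections = 0.05, 0, {"N": 0, "W": 0, "NxW": 0}
        for _ in range(50):
            Y = rng.normal(size=(12, 500))
            res = anova2_type3_matrix(Y, n_labels, w_labels)
            for term in rejections:
                rejections[term] += int((res[f"p_{term}"] <= alpha).sum())
            total += 500
        mc_se = np.sqrt(alpha * (1 - alpha) / total)
        for term, k in rejections.items():
            assert k / total <= alpha + 2 * mc_se, term


class TestPrescreen:
    def test_all_cells_equal_rejected_and_single_fc_retained(self, noiseless_sim):
        matrix, metadata, truth = noiseless_sim
        logm = log_and_baseline(matrix)
        retained, lfc = prescreen_pairwise_fc(logm, metadata, "leaf", fc_threshold=2.0)
        flat = [e for e, c in zip(truth.entity_ids, truth.cluster_opt) if c == 1]
        assert not set(flat) & set(retained)

    def test_matches_bruteforce_max_of_four(self, small_sim):
        matrix, metadata, _ = small_sim
        logm = log_and_baseline(matrix)
        retained, lfc = prescreen_pairwise_fc(logm, metadata, "stem", fc_threshold=2.0)
        brute = set(lfc.index[(np.abs(lfc.to_numpy()) >= 1.0).any(axis=1)])
        assert set(retained) == brute


class TestClassify:
    def _frame(self, **cols):
        return pd.DataFrame(cols, index=["e0"])

    def test_exclusive_interaction_rule(self):
        anova = self._frame(p_N_adj=0.5, p_W_adj=0.7, p_NxW_adj=0.01)
        tt = self._frame(p_N_ttest_adj=0.5, p_W_ttest_adj=0.6)
        res = classify(anova, tt)
        assert bool(res.loc["e0", "exclusive_interaction"])
        assert bool(res.loc["e0", "interaction_responsive"])

    def test_all_ones_give_no_flags(self):
        anova = self._frame(p_N_adj=1.0, p_W_adj=1.0, p_NxW_adj=1.0)
        tt = self._frame(p_N_ttest_adj=1.0, p_W_ttest_adj=1.0)
        assert not classify(anova, tt).to_numpy().any()

    def test_exclusive_requires_quiet_main_effects(self):
        anova = self._frame(p_N_adj=0.5, p_W_adj=0.5, p_NxW_adj=0.01)
        tt = self._frame(p_N_ttest_adj=0.01, p_W_ttest_adj=0.6)
        res = classify(anova, tt)
        assert bool(res.loc["e0", "interaction_responsive"])
        assert not bool(res.loc["e0", "exclusive_interaction"])

    def test_missing_pvalues_rejected(self):
        anova = self._frame(p_N_adj=np.nan, p_W_adj=1.0, p_NxW_adj=1.0)
        tt = self._frame(p_N_ttest_adj=1.0, p_W_ttest_adj=1.0)
        with pytest.raises(ValueError):
            classify(anova, tt)


class TestPlantedInteractionRecovery:
    def test_pure_interaction_entities_flagged_exclusive(self):
        """Cross-over interaction entities (zero marginal means) are mostly
        recovered as exclusively interaction-responsive."""
        hits = total = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_entities=300, n_clusters=1, cluster_amplitude=0.0,
                noise_sigma=0.25, frac_interaction=0.2, interaction_effect=1.5,
                interaction_style="crossover", frac_trend_change=0.0, seed=seed,
            )
            matrix, metadata, truth = simulate(cfg)
            # prescreen threshold below the planted pairwise cell contrast
            # (effect/2 on the log2 scale) so the planted family is tested
            res = interaction_analysis(
                log_and_baseline(matrix), metadata, "leaf", fc_threshold=1.5
            )
            planted = {e for e, f in zip(truth.entity_ids, truth.is_interaction) if f}
            tested = planted & set(res.index)
            hits += sum(bool(res.loc[e, "exclusive_interaction"]) for e in tested)
            total += len(planted)
        assert total > 0
        assert hits / total >= 0.8
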