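"""Mann-Whitney, Holm-Sidak, mixed repeated-measures ANOVA and post hocs."""

import numpy as np
import pandas as pd
import pytest

from gapassr.group_stats import (
    gg_epsilon,
    holm_sidak_adjust,
    mann_whitney,
    rm_anova,
    sidak_adjust,
    sidak_posthoc,
)
from gapassr.synth import EffectSizes, simulate_cohort_measures

NULL_EFFECTS = EffectSizes(
    ko_n1_mult=1.0, ko_gamma_mult=1.0, ko_jitter_mult=1.0,
    nlx_jitter_mult=1.0, nlx_gamma_rescue_p30=False,
)


class TestMannWhitney:
    def test_fully_separated_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res["U"] == 0
        assert res["p"] == pytest.approx(0.1)
        assert res["method"] == "exact"

    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p"] == pytest.approx(1.0, abs=1e-6)

    def test_swap_symmetry(self, rng):
        u = rng.standard_normal(5)
        v = rng.standard_normal(6)
        r1 = mann_whitney(u, v)
        r2 = mann_whitney(v, u)
        assert r1["U"] + r2["U"] == pytest.approx(len(u) * len(v))
        assert r1["p"] == pytest.approx(r2["p"])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestHolmSidak:
    def test_hand_computed_stepdown(self):
        """p = {0.01, 0.04, 0.03}: sorted adjustments with monotonicity."""
        adj = holm_sidak_adjust([0.01, 0.04, 0.03])
        a1 = 1 - 0.99**3
        a2 = 1 - 0.97**2
        assert adj[0] == pytest.approx(a1)
        assert adj[2] == pytest.approx(a2)  # 0.03 is the 2nd smallest
        assert adj[1] == pytest.approx(max(a2, 1 - 0.96))  # step-down monotonicity
        assert np.all(adj >= [0.01, 0.04, 0.03])

    def test_single_and_degenerate(self):
        assert holm_sidak_adjust([0.2]) == pytest.approx([0.2])
        assert np.all(holm_sidak_adjust([0.0, 0.0]) == 0.0)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=8)
        ours = holm_sidak_adjust(p)
        ref = multipletests(p, method="holm-sidak")[1]
        assert np.allclose(ours, ref)

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            holm_sidak_adjust([0.5, 1.2])


class TestSidak:
    def test_closed_form(self):
        assert sidak_adjust(0.05, 2) == pytest.approx(0.0975)
        assert sidak_adjust(0.3, 1) == pytest.approx(0.3)

    def test_never_below_raw(self, rng):
        for p in rng.uniform(size=20):
            assert sidak_adjust(float(p), 4) >= p


def _balanced_table(rng, a=2, b=2, n=4, K=3, effect=0.0):
    rows = []
    widths = [3.0, 6.0, 9.0]
    for i, g in enumerate(["WT", "KO"][:a]):
        for j, t in enumerate(["saline", "NLX101"][:b]):
            for s in range(n):
                sid = f"{g}-{t}-{s}"
                subj_shift = rng.normal(0, 0.5)
                for k in range(K):
                    rows.append({
                        "animal_id": sid, "genotype": g, "treatment": t,
                        "gap_width_ms": widths[k],
                        "value": rng.normal(0, 1) + subj_shift
                        + effect * i + 0.2 * k + 0.1 * i * k,
                    })
    return pd.DataFrame(rows)


def _splitplot_oracle(df):
    """Direct sums-of-squares partition for a balanced a x b x (S) x K design."""
    d = df.copy()
    K = d["gap_width_ms"].nunique()
    m = d["value"].mean()
    n_subj = d["animal_id"].nunique()
    a_lv = d["genotype"].unique()
    b_lv = d["treatment"].unique()
    n_cell = n_subj // (len(a_lv) * len(b_lv))

    def ss_means(group_cols, count_per_mean):
        means = d.groupby(group_cols)["value"].mean()
        return count_per_mean * ((means - m) ** 2).sum()

    N = len(d)
    ss_total = ((d["value"] - m) ** 2).sum()
    ss_A = ss_means("genotype", N / len(a_lv))
    ss_B = ss_means("treatment", N / len(b_lv))
    ss_cells = ss_means(["genotype", "treatment"], N / (len(a_lv) * len(b_lv)))
    ss_AB = ss_cells - ss_A - ss_B
    ss_subj = ss_means("animal_id", K)
    ss_subj_within = ss_subj - ss_cells
    ss_W = ss_means("gap_width_ms", N / K)
    ss_AW = ss_means(["genotype", "gap_width_ms"], N / (len(a_lv) * K)) - ss_A - ss_W
    ss_BW = ss_means(["treatment", "gap_width_ms"], N / (len(b_lv) * K)) - ss_B - ss_W
    ss_cellsW = ss_means(["genotype", "treatment", "gap_width_ms"],
                         N / (len(a_lv) * len(b_lv) * K))
    ss_ABW = ss_cellsW - ss_cells - ss_W - ss_AW - ss_BW
    ss_err_w = ss_total - ss_subj - ss_W - ss_AW - ss_BW - ss_ABW

    cells = len(a_lv) * len(b_lv)
    df_sw = n_subj - cells
    df_err = df_sw * (K - 1)
    out = {}
    out["genotype"] = (ss_A, len(a_lv) - 1, ss_subj_within, df_sw)
    out["treatment"] = (ss_B, len(b_lv) - 1, ss_subj_within, df_sw)
    out["genotype:treatment"] = (ss_AB, (len(a_lv) - 1) * (len(b_lv) - 1), ss_subj_within, df_sw)
    out["gap_width_ms"] = (ss_W, K - 1, ss_err_w, df_err)
    out["gap_width_ms:genotype"] = (ss_AW, (len(a_lv) - 1) * (K - 1), ss_err_w, df_err)
    out["gap_width_ms:treatment"] = (ss_BW, (len(b_lv) - 1) * (K - 1), ss_err_w, df_err)
    out["gap_width_ms:genotype:treatment"] = (
        ss_ABW, (len(a_lv) - 1) * (len(b_lv) - 1) * (K - 1), ss_err_w, df_err)
    return {
        k: (ss, (ss / dfn) / (ss_e / dfe)) for k, (ss, dfn, ss_e, dfe) in out.items()
    }


class TestRmAnova:
    def test_matches_bruteforce_ss_partition(self, rng):
        df = _balanced_table(rng, effect=0.4)
        tab = rm_anova(df).set_index("effect")
        oracle = _splitplot_oracle(df)
        for effect, (ss, F) in oracle.items():
            assert tab.loc[effect, "SS"] == pytest.approx(ss, rel=1e-10, abs=1e-10)
            assert tab.loc[effect, "F"] == pytest.approx(F, rel=1e-10)

    def test_all_equal_values_give_zero_f(self):
        df = _balanced_table(np.random.default_rng(0))
        df["value"] = 5.0
        tab = rm_anova(df)
        assert np.allclose(tab["F"].fillna(0), 0.0, atol=1e-20)

    def test_two_level_within_factor_epsilon_is_one(self, rng):
        df = _balanced_table(rng)
        df = df[df["gap_width_ms"].isin([3.0, 6.0])]
        tab = rm_anova(df)
        eps = tab["gg_epsilon"].dropna().unique()
        assert np.allclose(eps, 1.0)

    def test_matches_pingouin_one_between(self, rng):
        import pingouin as pg

        df = _balanced_table(rng, effect=0.3)
        sub = df[df["treatment"] == "saline"]
        ours = rm_anova(sub, between=("genotype",)).set_index("effect")
        ref = pg.mixed_anova(sub, dv="value", within="gap_width_ms",
                             subject="animal_id", between="genotype").set_index("Source")
        assert ours.loc["genotype", "F"] == pytest.approx(ref.loc["genotype", "F"])
        assert ours.loc["gap_width_ms", "F"] == pytest.approx(ref.loc["gap_width_ms", "F"])
        assert ours.loc["gap_width_ms:genotype", "F"] == pytest.approx(
            ref.loc["Interaction", "F"]
        )
        assert ours.loc["genotype", "p"] == pytest.approx(ref.loc["genotype", "p_unc"])

    def test_incomplete_subjects_excluded(self, rng, caplog):
        df = _balanced_table(rng)
        df = df.drop(df[(df["animal_id"] == "WT-saline-0")
                        & (df["gap_width_ms"] == 3.0)].index)
        tab = rm_anova(df)
        assert np.isfinite(tab["F"]).all()

    def test_small_cells_rejected(self, rng):
        df = _balanced_table(rng, n=1)
        with pytest.raises(ValueError, match="two subjects"):
            rm_anova(df)


class TestGgEpsilon:
    def test_matches_pingouin_single_cell(self, rng):
        import pingouin as pg

        X = rng.standard_normal((12, 4)) @ np.diag([1.0, 1.5, 0.7, 2.0])
        ours = gg_epsilon(X, ["c"] * 12)
        ref = float(pg.epsilon(pd.DataFrame(X), correction="gg"))
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_bounds(self, rng):
        X = rng.standard_normal((10, 5))
        eps = gg_epsilon(X, ["c"] * 10)
        assert 1.0 / 4 <= eps <= 1.0


class TestSidakPosthoc:
    def test_contrast_table(self, rng):
        df = _balanced_table(rng, effect=1.0)
        tab = sidak_posthoc(df, contrasts=[(("WT", "saline"), ("KO", "saline"))])
        assert len(tab) == 1
        assert tab.loc[0, "p_sidak"] == pytest.approx(tab.loc[0, "p_raw"])  # m = 1

    def test_unknown_contrast_rejected(self, rng):
        df = _balanced_table(rng)
        with pytest.raises(ValueError, match="unknown"):
            sidak_posthoc(df, contrasts=[(("XX", "saline"), ("KO", "saline"))])

    def test_adjustment_grows_with_family(self, rng):
        df = _balanced_table(rng, effect=0.6)
        tab = sidak_posthoc(df)  # all pairwise: m = 6
        assert np.all(tab["p_sidak"] >= tab["p_raw"] - 1e-12)


class TestCalibrationOnSyntheticCohorts:
    def _design(self, n):
        return pd.DataFrame(
            [{"genotype": g, "treatment": t, "n": n}
             for g in ("WT", "KO") for t in ("saline", "NLX101")]
        )

    def test_null_genotype_rejection_rate(self):
        """No planted effects: genotype effect rejects at ~5% (alpha = 0.05)."""
        rejections = 0
        n_cohorts = 200
        for seed in range(n_cohorts):
            tab = simulate_cohort_measures(self._design(6), seed=seed, effects=NULL_EFFECTS)
            res = rm_anova(tab[tab["region"] == "AC"]).set_index("effect")
            if res.loc["genotype", "p_corrected"] < 0.05:
                rejections += 1
        rate = rejections / n_cohorts
        se = np.sqrt(0.05 * 0.95 / n_cohorts)
        assert abs(rate - 0.05) <= 3 * se + 1e-9

    def test_treatment_effect_power(self):
        """Planted jitter reduction: treatment effect detected with power >= 0.8."""
        hits = 0
        n_cohorts = 60
        for seed in range(n_cohorts):
            tab = simulate_cohort_measures(self._design(10), seed=1000 + seed)
            res = rm_anova(tab[tab["region"] == "AC"]).set_index("effect")
            if res.loc["treatment", "p_corrected"] < 0.05:
                hits += 1
        assert hits / n_cohorts >= 0.8
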