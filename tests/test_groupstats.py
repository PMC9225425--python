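"""Mixed models, Bonferroni, Kruskal-Wallis, Mann-Whitney U, Hedges' g."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qmri import phantom, pipeline
from qmri.groupstats import (MixedAnova, StatResult, fit_mixed_model, hedges_g,
                             kruskal_wallis, mann_whitney_u, pairwise_bonferroni)


def brute_force_mwu(x, y):
    """Independent enumeration oracle: U from direct pairwise comparisons,
    p from all assignments of the pooled values to the two samples."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])

    def u_min(xs, ys):
        wins = sum(1.0 if a > b else (0.5 if a == b else 0.0)
                   for a in xs for b in ys)
        return min(wins, n1 * n2 - wins)

    u_obs = u_min(x, y)
    count = total = 0
    for pos in itertools.combinations(range(n1 + n2), n1):
        sel = np.zeros(n1 + n2, bool)
        sel[list(pos)] = True
        total += 1
        if u_min(pooled[sel], pooled[~sel]) <= u_obs + 1e-9:
            count += 1
    return u_obs, count / total


def simulate_measurement_table(rng, n_per_cell=5, tau=0.3, sigma=0.2, day1_bump=0.0):
    rows, aid = [], 0
    for injury in ("CHIMERA", "Sham"):
        for sex in ("M", "F"):
            for _ in range(n_per_cell):
                a = rng.normal(0, tau)
                for day in ("Baseline", "Day1", "Day7"):
                    bump = day1_bump if (injury == "CHIMERA" and day == "Day1") else 0.0
                    rows.append(dict(animal_id=f"a{aid}", injury=injury, sex=sex,
                                     day=day, value=1.0 + a + bump + rng.normal(0, sigma)))
                aid += 1
    return pd.DataFrame(rows)


class TestKruskalWallis:
    def test_hand_computed_value(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)
        assert res.df == (2,)

    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_values_identical(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.statistic == 0.0 and res.p_raw == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_ties_match_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 5, rng.integers(4, 9)).astype(float)
                  for _ in range(rng.integers(2, 5))]
        if all(np.ptp(np.concatenate(groups)) == 0 for _ in [0]):
            return
        res = kruskal_wallis(groups)
        h_ref, p_ref = stats.kruskal(*groups)
        assert res.statistic == pytest.approx(h_ref, rel=1e-12)
        assert res.p_raw == pytest.approx(p_ref, rel=1e-9)

    def test_two_group_relation_to_rank_sum(self, rng):
        # without ties, H equals the squared standardized Wilcoxon statistic
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        h = kruskal_wallis([x, y]).statistic
        u = mann_whitney_u(x, y, mode="asymptotic")
        n1, n2 = len(x), len(y)
        mu, var = n1 * n2 / 2, n1 * n2 * (n1 + n2 + 1) / 12
        z = (u.statistic - mu) / np.sqrt(var)  # no tie/cc correction here
        assert h == pytest.approx(z ** 2, rel=1e-9)

    def test_h_nonnegative(self, rng):
        for _ in range(5):
            groups = [rng.normal(0, 1, 6) for _ in range(3)]
            assert kruskal_wallis(groups).statistic >= 0


class TestMannWhitney:
    def test_separated_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(2 / 20)  # 2 of C(6,3)=20 assignments

    def test_identical_sets_give_half_u(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4], mode="exact")
        assert res.statistic == 4 * 4 / 2

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 8, 2)
        x = rng.integers(0, 6, n1).astype(float)  # integers force ties
        y = rng.integers(0, 6, n2).astype(float)
        res = mann_whitney_u(x, y, mode="exact")
        u_ref, p_ref = brute_force_mwu(x, y)
        assert res.statistic == u_ref
        assert res.p_raw == p_ref  # bit-for-bit: both are exact fractions

    def test_exact_and_asymptotic_agree_at_n10(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0.3, 1, 10)
        p_ex = mann_whitney_u(x, y, mode="exact").p_raw
        p_as = mann_whitney_u(x, y, mode="asymptotic").p_raw
        assert abs(p_ex - p_as) < 0.02

    def test_auto_mode_switches(self):
        big = list(range(30))
        res = mann_whitney_u(big, [x + 0.5 for x in big], mode="auto")
        assert 0 <= res.p_raw <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestHedgesG:
    def test_identical_groups_zero(self):
        assert hedges_g([1, 2, 3], [1, 2, 3]) == 0.0

    def test_small_sample_correction(self, rng):
        # mean difference equal to the pooled SD at n1=n2=10 gives g = 1 - 3/71
        x = rng.normal(0, 1, 10)
        x = (x - x.mean()) / x.std(ddof=1)  # exact mean 0, sd 1
        y = x + 1.0
        assert hedges_g(y, x) == pytest.approx(1 - 3 / 71, rel=1e-12)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(1, 2, 9)
        assert hedges_g(x, y) == pytest.approx(-hedges_g(y, x), rel=1e-12)

    def test_zero_pooled_sd_flagged(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            g = hedges_g([2.0, 2.0], [3.0, 3.0])
        assert np.isnan(g)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y = rng.normal(0, 1, 15), rng.normal(0.7, 1.3, 12)
        ref = pingouin.compute_effsize(x, y, eftype="hedges")
        assert hedges_g(x, y) == pytest.approx(ref, rel=1e-6)


class TestBonferroni:
    def test_adjustment_arithmetic(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(dict(
            group=np.repeat(["a", "b", "c"], 10),
            value=np.concatenate([rng.normal(m, 1, 10) for m in (0, 1, 2)])))
        family = [(f"{i}-vs-{j}", {"group": i}, {"group": j})
                  for i, j in (("a", "b"), ("a", "c"), ("b", "c"))]
        out = pairwise_bonferroni(df, family)
        for r in out:
            assert r.p_adj == pytest.approx(min(1.0, 3 * r.p_raw))
            assert r.p_adj >= r.p_raw
            assert r.p_adj <= 1.0

    def test_single_comparison_identity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(dict(group=np.repeat(["a", "b"], 8),
                               value=rng.normal(0, 1, 16)))
        out = pairwise_bonferroni(df, [("a-vs-b", {"group": "a"}, {"group": "b"})])
        assert out[0].p_adj == pytest.approx(out[0].p_raw)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            pairwise_bonferroni(pd.DataFrame({"value": [1.0]}), [])

    def test_statresult_rejects_padj_below_praw(self):
        with pytest.raises(ValueError):
            StatResult(term="x", statistic=1.0, stat_name="t", df=(1,),
                       p_raw=0.5, p_adj=0.1)


class TestMixedAnova:
    def test_constant_response_rejected(self):
        df = simulate_measurement_table(np.random.default_rng(0))
        df["value"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            MixedAnova(df)

    def test_empty_cell_named(self):
        df = simulate_measurement_table(np.random.default_rng(0))
        df = df[~((df.injury == "Sham") & (df.day == "Day7"))]
        with pytest.raises(ValueError, match="injury=Sham.*day=Day7"):
            MixedAnova(df)

    def test_excluded_rows_rejected(self):
        df = simulate_measurement_table(np.random.default_rng(0))
        df["excluded"] = True
        with pytest.raises(ValueError, match="excluded"):
            MixedAnova(df)

    def test_detects_injected_interaction(self):
        df = simulate_measurement_table(np.random.default_rng(3), day1_bump=0.8)
        res = fit_mixed_model(df)
        at = res.anova_table.set_index("term")
        assert at.loc["injury x day", "p"] < 0.01

    def test_tolerates_missing_visit(self):
        df = simulate_measurement_table(np.random.default_rng(4))
        df = df[~((df.animal_id == "a0") & (df.day == "Day7"))]
        res = fit_mixed_model(df)
        assert len(res.anova_table) == 7

    def test_summary_mentions_terms(self):
        df = simulate_measurement_table(np.random.default_rng(5))
        text = fit_mixed_model(df).summary()
        assert "injury x sex x day" in text and "random intercept" in text

    def test_four_factor_layout(self):
        rng = np.random.default_rng(6)
        base = simulate_measurement_table(rng)
        frames = []
        for region in ("lgn", "superior_colliculus"):
            sub = base.copy()
            sub["region"] = region
            sub["value"] += rng.normal(0, 0.05, len(sub))
            frames.append(sub)
        df = pd.concat(frames, ignore_index=True)
        res = fit_mixed_model(df, between=("injury", "sex"),
                              within=("region", "day"))
        terms = set(res.anova_table.term)
        assert "injury x sex x region x day" in terms  # between-then-within order
        assert len(terms) == 15  # all mains + interactions of 4 factors

    def test_f_statistics_match_lmerTest(self, tmp_path):
        """Cross-check the Wald F tests against R's lmerTest on one table."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the mixed-model oracle")
        df = simulate_measurement_table(np.random.default_rng(42), day1_bump=0.5)
        res = fit_mixed_model(df)
        csv = tmp_path / "table.csv"
        out = tmp_path / "anova.csv"
        df.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lmerTest))
        d <- read.csv("{csv}")
        m <- lmer(value ~ injury*sex*day + (1|animal_id), data=d)
        a <- anova(m, ddf="Satterthwaite")
        write.csv(data.frame(term=rownames(a), F=a$`F value`), "{out}", row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out)
        ref["term"] = ref["term"].str.replace(":", " x ")
        merged = res.anova_table.merge(ref, on="term", suffixes=("", "_r"))
        assert len(merged) == 7
        np.testing.assert_allclose(merged["F"], merged["F_r"], rtol=0.02)


class TestPipelinePower:
    def test_injury_day_interaction_detected_on_phantom(self, tiny_acq, core_tissues):
        """A Day1 meningeal enhancement doubling should be detected in the
        overwhelming majority of simulated cohorts (scaled-down replicate count)."""
        detected = 0
        n_cohorts = 15
        for i in range(n_cohorts):
            design = phantom.DesignSpec(n_per_cell=10,
                                        injury_effects={("meninges", "Day1"): 2.0},
                                        seed=3000 + i)
            table = pipeline.run_cohort(design, tiny_acq, core_tissues,
                                        metrics=("auc_norm",))
            from qmri.roistats import require_clean
            sub = require_clean(table)
            sub = sub[(sub.roi == "meninges") & (sub.metric == "auc_norm")]
            res = fit_mixed_model(sub)
            at = res.anova_table.set_index("term")
            detected += at.loc["injury x day", "p"] < 0.05
        assert detected / n_cohorts > 0.8
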