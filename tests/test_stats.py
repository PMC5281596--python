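"""Repeated-measures ANOVA, Greenhouse–Geisser epsilon, Tukey HSD and
behavioural scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from vmmn import (ConfigurationError, DesignError, greenhouse_geisser_epsilon,
                  rm_anova, score_2afc, score_hits, tukey_hsd)
from vmmn.stats import anova_report, format_effect


def _mixed_table(values: np.ndarray) -> pd.DataFrame:
    """4 subjects (2 per group) x 2 ROI; values shaped (subjects, 2)."""
    rows = []
    for s in range(values.shape[0]):
        grp = "old" if s < values.shape[0] // 2 else "young"
        for j, roi in enumerate(("left", "right")):
            rows.append({"subject": f"s{s}", "group": grp, "roi": roi,
                         "y": values[s, j]})
    return pd.DataFrame(rows)


def mixed_2x2_ss_oracle(values: np.ndarray):
    """Hand decomposition of a balanced one-between (2 groups) x
    one-within (2 levels) design via cell/marginal means."""
    n_subj, k = values.shape
    g = 2
    n_per = n_subj // g
    grand = values.mean()
    groups = [values[:n_per], values[n_per:]]
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups)
    subj_means = values.mean(axis=1)
    group_of = np.repeat([0, 1], n_per)
    ss_subj_within = sum(k * (subj_means[i] - groups[group_of[i]].mean()) ** 2
                         for i in range(n_subj))
    level_means = values.mean(axis=0)
    ss_within = n_subj * ((level_means - grand) ** 2).sum()
    cell_means = np.array([v.mean(axis=0) for v in groups])  # (g, k)
    ss_cells = n_per * ((cell_means - grand) ** 2).sum()
    ss_interaction = ss_cells - ss_between - ss_within
    ss_total = ((values - grand) ** 2).sum()
    ss_error = ss_total - ss_between - ss_subj_within - ss_within - ss_interaction
    return dict(between=ss_between, subjects=ss_subj_within, within=ss_within,
                interaction=ss_interaction, error=ss_error, total=ss_total)


class TestRmAnova:
    def test_constant_data_gives_zero_f(self):
        table = _mixed_table(np.full((4, 2), 7.0))
        out = rm_anova(table, dv="y", subject="subject", within="roi",
                       between="group")
        assert (out["F"] == 0.0).all()
        assert (out["partial_eta_sq"] == 0.0).all()

    def test_two_level_within_has_unit_epsilon(self):
        rng = np.random.default_rng(0)
        table = _mixed_table(rng.normal(size=(8, 2)))
        out = rm_anova(table, dv="y", subject="subject", within="roi",
                       between="group").set_index("effect")
        assert out.loc["roi", "gg_epsilon"] == 1.0
        assert out.loc["roi", "p_gg"] == out.loc["roi", "p_uncorrected"]

    def test_ss_decomposition_matches_hand_oracle(self):
        """Brute-force sums of squares on a 4-subject 2 x 2 fixture."""
        values = np.array([[3.0, 5.0], [4.0, 7.0], [1.0, 2.0], [2.0, 2.0]])
        oracle = mixed_2x2_ss_oracle(values)
        out = rm_anova(_mixed_table(values), dv="y", subject="subject",
                       within="roi", between="group").set_index("effect")
        assert out.loc["group", "ss_effect"] == pytest.approx(oracle["between"])
        assert out.loc["group", "ss_error"] == pytest.approx(oracle["subjects"])
        assert out.loc["roi", "ss_effect"] == pytest.approx(oracle["within"])
        assert out.loc["group * roi", "ss_effect"] == pytest.approx(oracle["interaction"])
        assert out.loc["roi", "ss_error"] == pytest.approx(oracle["error"])

    def test_ss_conservation_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            values = rng.normal(size=(10, 2))
            oracle = mixed_2x2_ss_oracle(values)
            out = rm_anova(_mixed_table(values), dv="y", subject="subject",
                           within="roi", between="group").set_index("effect")
            recomposed = (out.loc["group", "ss_effect"] + out.loc["group", "ss_error"]
                          + out.loc["roi", "ss_effect"]
                          + out.loc["group * roi", "ss_effect"]
                          + out.loc["roi", "ss_error"])
            assert recomposed == pytest.approx(oracle["total"], rel=1e-9)

    def test_partial_eta_sq_affine_invariant(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(8, 2))
        a = rm_anova(_mixed_table(values), dv="y", subject="subject",
                     within="roi", between="group")
        b = rm_anova(_mixed_table(5.0 * values + 11.0), dv="y", subject="subject",
                     within="roi", between="group")
        np.testing.assert_allclose(a["partial_eta_sq"], b["partial_eta_sq"],
                                   atol=1e-10)
        np.testing.assert_allclose(a["F"], b["F"], atol=1e-9)

    def test_three_level_within_gets_gg_correction(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in range(12):
            base = rng.normal()
            for lev in ("a", "b", "c"):
                rows.append({"subject": s, "lev": lev,
                             "y": base + rng.normal(scale=1 + 2 * (lev == "c"))})
        out = rm_anova(pd.DataFrame(rows), dv="y", subject="subject",
                       within="lev").set_index("effect")
        eps = out.loc["lev", "gg_epsilon"]
        assert 0.5 <= eps <= 1.0
        expected = sstats.f.sf(out.loc["lev", "F"], eps * 2, eps * 22)
        assert out.loc["lev", "p_gg"] == pytest.approx(expected, rel=1e-6)

    def test_two_way_within_design(self):
        rng = np.random.default_rng(4)
        rows = [{"subject": s, "soa": soa, "roi": roi, "y": rng.normal()}
                for s in range(10) for soa in ("0", "30", "50")
                for roi in ("left", "right")]
        out = rm_anova(pd.DataFrame(rows), dv="y", subject="subject",
                       within=["soa", "roi"])
        assert set(out["effect"]) == {"soa", "roi", "soa * roi"}
        assert ((out["partial_eta_sq"] >= 0) & (out["partial_eta_sq"] <= 1)).all()

    def test_unbalanced_design_raises(self):
        table = _mixed_table(np.zeros((4, 2))).iloc[:-1]
        with pytest.raises(DesignError):
            rm_anova(table, dv="y", subject="subject", within="roi",
                     between="group")

    def test_null_rejection_rate_near_nominal(self):
        """One-way within ANOVA on null data rejects ≈ 5% of the time
        (uncorrected p) over 500 replicates."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            rows = [{"subject": s, "lev": lev, "y": rng.normal()}
                    for s in range(10) for lev in ("a", "b", "c")]
            out = rm_anova(pd.DataFrame(rows), dv="y", subject="subject",
                           within="lev")
            rejections += out.iloc[0]["p_uncorrected"] < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 0.03, f"null rejection rate {rate}"


class TestGreenhouseGeisser:
    def test_bounds_on_random_covariances(self):
        rng = np.random.default_rng(6)
        k = 4
        for _ in range(25):
            data = rng.normal(size=(20, k)) @ rng.normal(size=(k, k))
            eps = greenhouse_geisser_epsilon(data)
            assert 1.0 / (k - 1) - 1e-9 <= eps <= 1.0 + 1e-9

    def test_spherical_data_has_epsilon_one(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(4000, 3))  # iid -> compound symmetric
        assert greenhouse_geisser_epsilon(data) > 0.97

    def test_matches_pingouin_estimate(self):
        import pingouin as pg

        rng = np.random.default_rng(8)
        data = rng.normal(size=(12, 4)) @ rng.normal(size=(4, 4))
        rows = [{"subject": s, "lev": j, "y": data[s, j]}
                for s in range(12) for j in range(4)]
        ours = greenhouse_geisser_epsilon(data)
        theirs = pg.rm_anova(data=pd.DataFrame(rows), dv="y", within="lev",
                             subject="subject", correction=True,
                             detailed=True)["eps"].iloc[0]
        assert ours == pytest.approx(float(theirs), rel=1e-6)


class TestTukey:
    def test_identical_means_p_one(self):
        out = tukey_hsd({"a": 1.0, "b": 1.0}, ms_error=2.0, df_error=10,
                        n_per_cell=5)
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_separated_means_tiny_p(self):
        out = tukey_hsd({"a": 0.0, "b": 5.0}, ms_error=1e-4, df_error=20,
                        n_per_cell=8)
        assert out.iloc[0]["p"] < 0.001

    def test_q_matches_formula_oracle(self):
        means = {"g1": 1.0, "g2": 3.5, "g3": 2.0}
        ms_error, n = 2.0, 6
        out = tukey_hsd(means, ms_error=ms_error, df_error=15, n_per_cell=n)
        for _, row in out.iterrows():
            expect_q = abs(means[row["cell_a"]] - means[row["cell_b"]]) / \
                math.sqrt(ms_error / n)
            assert row["q"] == pytest.approx(expect_q)
            assert row["p"] == pytest.approx(
                sstats.studentized_range.sf(expect_q, 3, 15), rel=1e-9)


class TestScoring:
    def test_perfect_responder_scores_100(self):
        events = [0.0, 2000.0, 4000.0]
        responses = [e + 400.0 for e in events]
        out = score_hits(responses, events)
        assert out["hit_rate_percent"] == 100.0

    def test_no_responses_scores_0(self):
        assert score_hits([], [0.0, 1000.0])["hit_rate_percent"] == 0.0

    def test_each_response_counts_once(self):
        # one response cannot satisfy two events
        out = score_hits([900.0], [0.0, 500.0])
        assert out["n_hits"] == 1

    def test_binomial_concentration(self):
        """Simulated responder with hit probability 0.8 over 2,000
        events lands within 2 points of 80%."""
        rng = np.random.default_rng(9)
        events = np.arange(2000) * 2000.0
        responses = [e + 500.0 for e in events if rng.random() < 0.8]
        out = score_hits(np.array(responses), events)
        assert abs(out["hit_rate_percent"] - 80.0) < 2.0

    def test_2afc_all_correct(self):
        frame = pd.DataFrame({"soa_ms": [30.0, 50.0] * 4, "correct": True})
        out = score_2afc(frame)
        assert (out["proportion"] == 1.0).all()

    def test_2afc_unknown_soa_rejected(self):
        frame = pd.DataFrame({"soa_ms": [40.0], "correct": [True]})
        with pytest.raises(ConfigurationError):
            score_2afc(frame, soa_levels=(30.0, 50.0, 70.0))


def test_report_formatting():
    rng = np.random.default_rng(10)
    table = rm_anova(_mixed_table(rng.normal(size=(8, 2))), dv="y",
                     subject="subject", within="roi", between="group")
    text = anova_report(table)
    assert "F(" in text and "ηp²" in text
    assert format_effect(table.iloc[0]).startswith("F(1,")
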