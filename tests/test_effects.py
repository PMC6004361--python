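"""Subgroup splitting, ANOVA, and the verification-table statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sibqtl import effects


def _phen(weights, lengths=None, prefix="i"):
    weights = np.asarray(weights, dtype=float)
    if lengths is None:
        lengths = 90 + weights / 5.0
    return pd.DataFrame(
        {
            "individual_id": [f"{prefix}{k}" for k in range(len(weights))],
            "weight_g": weights,
            "length_mm": lengths,
        }
    )


class TestSplitSubgroups:
    def test_well_separated_clusters(self):
        """Two clusters at 190/1120 g: >= 99% of labels match the generating
        component."""
        rng = np.random.default_rng(42)
        comp = rng.random(442) < 0.58
        w = np.where(comp, rng.normal(1120, 100, 442), rng.normal(190, 100, 442))
        res = effects.split_subgroups(_phen(w))
        assert res.is_bimodal
        truth = np.where(comp, "fast", "slow")
        accuracy = (res.labels.to_numpy() == truth).mean()
        assert accuracy >= 0.99

    def test_unimodal_flagged(self):
        rng = np.random.default_rng(1)
        res = effects.split_subgroups(_phen(rng.normal(700, 80, 300)))
        assert not res.is_bimodal

    def test_partition_invariant(self):
        rng = np.random.default_rng(3)
        w = np.r_[rng.normal(190, 90, 180), rng.normal(1120, 170, 262)]
        res = effects.split_subgroups(_phen(w))
        assert res.is_bimodal
        slow = res.labels == "slow"
        assert w[slow.to_numpy()].max() < w[~slow.to_numpy()].min()
        assert res.slow_range[1] < res.threshold_weight < res.fast_range[0]

    def test_reported_subgroup_ranges(self):
        """Clusters shaped like the published subgroups (slow 27-528 g, fast
        530-1726 g): the threshold lands between the cluster bulks and nearly
        every individual keeps its generating subgroup."""
        rng = np.random.default_rng(7)
        slow = stats.truncnorm.rvs(
            (27 - 187) / 100, (528 - 187) / 100, 187, 100, size=184,
            random_state=rng,
        )
        fast = stats.truncnorm.rvs(
            (530 - 1120) / 230, (1726 - 1120) / 230, 1120, 230, size=258,
            random_state=rng,
        )
        w = np.r_[slow, fast]
        res = effects.split_subgroups(_phen(w))
        assert res.is_bimodal
        truth = np.r_[["slow"] * 184, ["fast"] * 258]
        assert (res.labels.to_numpy() == truth).mean() >= 0.99
        assert res.modes[0] < res.threshold_weight < res.modes[1]
        # reported boundary always separates the labeled subgroups
        assert res.slow_range[1] < res.threshold_weight < res.fast_range[0]

    def test_small_sample_error(self):
        with pytest.raises(ValueError):
            effects.split_subgroups(_phen([100, 900] * 5))

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        w = np.r_[rng.normal(200, 80, 150), rng.normal(1100, 150, 150)]
        a = effects.split_subgroups(_phen(w))
        b = effects.split_subgroups(_phen(w))
        assert a.threshold_weight == b.threshold_weight
        assert (a.labels == b.labels).all()


class TestAnova:
    def test_constant_groups_f_zero(self):
        res = effects.one_way_anova({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert res.F == 0.0 and res.p == 1.0

    def test_textbook_example(self):
        """Groups {1,2,3} and {2,3,4}: F = 1.5 on (1, 4) df."""
        res = effects.one_way_anova({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0]})
        assert res.F == pytest.approx(1.5)
        assert res.p == pytest.approx(stats.f.sf(1.5, 1, 4))

    def test_sums_of_squares_oracle(self, rng):
        """Matches a brute-force between/within sums-of-squares computation."""
        for _ in range(20):
            groups = {
                f"g{k}": rng.normal(10 * k, 5, rng.integers(3, 12))
                for k in range(rng.integers(2, 5))
            }
            res = effects.one_way_anova(groups)
            allv = np.concatenate(list(groups.values()))
            grand = allv.mean()
            ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
            ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
            dfb, dfw = len(groups) - 1, len(allv) - len(groups)
            F = (ssb / dfb) / (ssw / dfw)
            assert res.F == pytest.approx(F, rel=1e-10)

    def test_small_groups_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = effects.one_way_anova({"a": [1.0, 2.0, 3.0], "b": [9.0]})
        assert not res.testable

    def test_power_on_patterned_classes(self):
        """Three classes with the published mean/sd/n pattern give p < 0.01
        in >= 95% of replicates."""
        sig = 0
        for s in range(40):
            rng = np.random.default_rng(4000 + s)
            groups = {
                "GG": rng.normal(919.87, 461.77, 116),
                "TG": rng.normal(746.91, 510.23, 227),
                "TT": rng.normal(419.12, 437.46, 99),
            }
            if effects.one_way_anova(groups).p < 0.01:
                sig += 1
        assert sig / 40 >= 0.95


class TestSummaries:
    def test_genotype_summary_frequencies(self, table2_individuals):
        df = table2_individuals
        phen = df[["individual_id", "weight_g", "length_mm"]]
        gt = df.set_index("individual_id")["gt17"]
        out = effects.genotype_summary(gt, phen, site_label="17")
        by = out.set_index("label")
        assert by.loc["family", "frequency_over_threshold"] == 58.37
        assert by.loc["17GG", "frequency_over_threshold"] == 77.59
        assert by.loc["17TG", "frequency_over_threshold"] == 60.79
        assert by.loc["17TT", "frequency_over_threshold"] == 30.30

    def test_missing_genotypes_excluded(self, table2_individuals):
        df = table2_individuals
        phen = df[["individual_id", "weight_g", "length_mm"]]
        gt = df.set_index("individual_id")["gt17"].copy()
        gt.iloc[:10] = np.nan
        out = effects.genotype_summary(gt, phen, site_label="17")
        assert out[out.label != "family"].n.sum() == 432
        # family row still covers all phenotyped individuals
        assert out.set_index("label").loc["family", "n"] == 442

    def test_all_below_threshold(self):
        phen = _phen([100.0] * 30)
        gt = pd.Series(["AA"] * 30, index=phen.individual_id)
        out = effects.genotype_summary(gt, phen)
        assert out.set_index("label").loc["AA", "frequency_over_threshold"] == 0.0

    def test_combination_summary(self, table2_individuals):
        df = table2_individuals
        phen = df[["individual_id", "weight_g", "length_mm"]]
        out = effects.combination_summary(
            df.set_index("individual_id")["gt17"],
            df.set_index("individual_id")["gt14"],
            phen,
            site_labels=("17", "14"),
        )
        by = out.set_index("label")
        assert by.loc["17GG + 14CC", "frequency_over_threshold"] == 85.19
        assert by.loc["17GG + 14TT", "frequency_over_threshold"] == 89.29
        assert by.loc["17TT + 14TT", "frequency_over_threshold"] == 20.83

    def test_partition_identity(self, table2_individuals):
        """Two-locus class sizes sum to the single-locus class sizes."""
        df = table2_individuals
        phen = df[["individual_id", "weight_g", "length_mm"]]
        singles = effects.genotype_summary(
            df.set_index("individual_id")["gt17"], phen, site_label="17"
        ).set_index("label")
        combos = effects.combination_summary(
            df.set_index("individual_id")["gt17"],
            df.set_index("individual_id")["gt14"],
            phen,
            site_labels=("17", "14"),
        )
        for g in ("GG", "TG", "TT"):
            combo_n = combos[combos.label.str.startswith(f"17{g}")].n.sum()
            assert combo_n == singles.loc[f"17{g}", "n"]


class TestRankDominant:
    def test_advantages_match_published_arithmetic(self, table2_individuals):
        df = table2_individuals
        phen = df[["individual_id", "weight_g", "length_mm"]]
        singles = effects.genotype_summary(
            df.set_index("individual_id")["gt17"], phen, site_label="17"
        )
        ranked = effects.rank_dominant(singles)
        assert ranked.label.iloc[0] == "17GG"
        assert ranked.advantage_points.iloc[0] == pytest.approx(19.22)

    def test_combination_advantages(self, table2_individuals):
        df = table2_individuals
        phen = df[["individual_id", "weight_g", "length_mm"]]
        combos = effects.combination_summary(
            df.set_index("individual_id")["gt17"],
            df.set_index("individual_id")["gt14"],
            phen, site_labels=("17", "14"),
        )
        fam = effects.genotype_summary(
            df.set_index("individual_id")["gt17"], phen, site_label="17"
        ).set_index("label").loc["family"]
        ranked = effects.rank_dominant(combos, family_row=fam)
        by = ranked.set_index("label")
        assert by.loc["17GG + 14CC", "advantage_points"] == pytest.approx(26.82)
        assert by.loc["17GG + 14TT", "advantage_points"] == pytest.approx(30.92)
        assert list(ranked.label[:2]) == ["17GG + 14TT", "17GG + 14CC"]

    def test_tie_break_deterministic(self):
        summaries = pd.DataFrame(
            [
                {"label": "family", "n": 60, "n_over_threshold": 30,
                 "frequency_over_threshold": 50.0, "mean_length": 1.0,
                 "sd_length": 1.0, "mean_weight": 500.0, "sd_weight": 1.0},
                {"label": "b", "n": 30, "n_over_threshold": 15,
                 "frequency_over_threshold": 50.0, "mean_length": 1.0,
                 "sd_length": 1.0, "mean_weight": 500.0, "sd_weight": 1.0},
                {"label": "a", "n": 30, "n_over_threshold": 15,
                 "frequency_over_threshold": 50.0, "mean_length": 1.0,
                 "sd_length": 1.0, "mean_weight": 500.0, "sd_weight": 1.0},
            ]
        )
        ranked = effects.rank_dominant(summaries)
        assert list(ranked.label) == ["a", "b"]

    def test_small_sample_flagged(self, table2_individuals):
        df = table2_individuals
        phen = df[["individual_id", "weight_g", "length_mm"]]
        singles = effects.genotype_summary(
            df.set_index("individual_id")["gt17"], phen, site_label="17"
        )
        small = singles.copy()
        small.loc[len(small)] = ["17XX", 5, 5, 100.0, 1.0, 1.0, 1.0, 1.0]
        ranked = effects.rank_dominant(small)
        assert bool(ranked.set_index("label").loc["17XX", "small_sample"])


class TestLetters:
    def test_separated_groups_distinct_letters(self, rng):
        groups = {
            "hi": rng.normal(100, 1, 50),
            "mid": rng.normal(50, 1, 50),
            "lo": rng.normal(0, 1, 50),
        }
        letters = effects.letter_groups(groups)
        assert len({letters[k] for k in groups}) == 3
        assert letters["hi"] == "A"

    def test_indistinguishable_share_letter(self, rng):
        groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10)}
        letters = effects.letter_groups(groups)
        assert letters["a"] == letters["b"]
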