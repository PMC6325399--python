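"""Balanced split-plot ANOVA, cell means and Tukey comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rumenprof import (
    datasets,
    simulate_fermentation,
    split_plot_anova,
    summarize_means,
    tukey_pairwise,
)
from rumenprof.splitplot import significance_label


def brute_force_split_plot_ss(records):
    """Independent cell-means computation of the split-plot decomposition."""
    species = sorted(records["species"].unique())
    diets = sorted(records["diet"].unique())
    a, b = len(species), len(diets)
    animals = {
        sp: sorted(records.loc[records["species"] == sp, "animal_id"].unique())
        for sp in species
    }
    n = len(animals[species[0]])

    def value(sp, an, diet):
        row = records[
            (records["species"] == sp)
            & (records["animal_id"] == an)
            & (records["diet"] == diet)
        ]
        return float(row["value"].iloc[0])

    grand = np.mean([value(sp, an, d) for sp in species for an in animals[sp] for d in diets])
    sp_mean = {
        sp: np.mean([value(sp, an, d) for an in animals[sp] for d in diets]) for sp in species
    }
    an_mean = {
        (sp, an): np.mean([value(sp, an, d) for d in diets])
        for sp in species
        for an in animals[sp]
    }
    diet_mean = {d: np.mean([value(sp, an, d) for sp in species for an in animals[sp]]) for d in diets}
    cell_mean = {
        (sp, d): np.mean([value(sp, an, d) for an in animals[sp]])
        for sp in species
        for d in diets
    }

    ss = {}
    ss["species"] = n * b * sum((sp_mean[sp] - grand) ** 2 for sp in species)
    ss["animal(species)"] = b * sum(
        (an_mean[(sp, an)] - sp_mean[sp]) ** 2 for sp in species for an in animals[sp]
    )
    ss["diet"] = a * n * sum((diet_mean[d] - grand) ** 2 for d in diets)
    ss["species:diet"] = n * sum(
        (cell_mean[(sp, d)] - sp_mean[sp] - diet_mean[d] + grand) ** 2
        for sp in species
        for d in diets
    )
    ss["total"] = sum(
        (value(sp, an, d) - grand) ** 2 for sp in species for an in animals[sp] for d in diets
    )
    ss["residual"] = (
        ss["total"] - ss["species"] - ss["animal(species)"] - ss["diet"] - ss["species:diet"]
    )
    return ss


class TestSummarizeMeans:
    def test_planted_cell_means_recovered_exactly(self):
        cm = datasets.fermentation_cell_means("pH")
        recs = simulate_fermentation(cell_means=cm, sigma_animal=0.0, sigma_e=0.0, seed=0)
        table = summarize_means(recs, "pH")
        pd.testing.assert_frame_equal(
            table.means.sort_index()[["HF", "HC"]],
            cm.sort_index()[["HF", "HC"]],
            check_names=False,
        )
        assert table.sem == pytest.approx(0.0, abs=1e-6)

    def test_constant_data(self):
        recs = simulate_fermentation(mu=3.3, sigma_animal=0.0, sigma_e=0.0, seed=0)
        table = summarize_means(recs, "pH")
        assert (table.means.values == 3.3).all()
        assert table.sem == 0.0

    def test_two_records_per_cell_midpoint(self):
        rows = []
        for sp in ("A", "B", "C"):
            for j, v in ((1, 1.0), (2, 3.0)):
                for diet in ("HF", "HC"):
                    rows.append(
                        {"species": sp, "animal_id": f"{sp}{j}", "diet": diet,
                         "response": "x", "value": v}
                    )
        table = summarize_means(pd.DataFrame(rows), "x")
        assert (table.means.values == 2.0).all()


class TestSplitPlotAnova:
    def test_ss_matches_cell_means_oracle(self):
        recs = simulate_fermentation(
            cell_means=datasets.fermentation_cell_means("total_VFA"),
            sigma_animal=5.0,
            sigma_e=3.0,
            seed=7,
            response="total_VFA",
        )
        result = split_plot_anova(recs, "total_VFA")
        expected = brute_force_split_plot_ss(recs)
        for effect in ("species", "animal(species)", "diet", "species:diet", "residual"):
            assert result.table.loc[effect, "ss"] == pytest.approx(expected[effect], abs=1e-8)
        assert result.ss_total == pytest.approx(expected["total"], abs=1e-8)
        assert result.df_total == 23

    def test_error_strata_and_dfs(self):
        recs = simulate_fermentation(mu=1.0, seed=0)
        result = split_plot_anova(recs, "pH")
        t = result.table
        assert t.loc["species", "df"] == 2 and t.loc["animal(species)", "df"] == 9
        assert t.loc["diet", "df"] == 1 and t.loc["species:diet", "df"] == 2
        assert t.loc["residual", "df"] == 9
        assert t.loc["species", "error_stratum"] == "animal(species)"
        assert t.loc["diet", "error_stratum"] == "residual"

    def test_zero_residual_variance_pure_diet_effect(self):
        recs = simulate_fermentation(
            mu=5.0, diet_effects={"HC": 1.0}, sigma_animal=0.0, sigma_e=0.0, seed=0
        )
        result = split_plot_anova(recs, "pH")
        assert math.isinf(result.table.loc["diet", "F"])
        assert result.p("diet") == 0.0

    def test_unbalanced_rejected(self):
        recs = simulate_fermentation(mu=1.0, seed=0)
        with pytest.raises(ValueError, match="unbalanced"):
            split_plot_anova(recs.iloc[:-1], "pH")
        dropped_animal = recs[recs["animal_id"] != "Goat-4"]
        with pytest.raises(ValueError, match="unbalanced"):
            split_plot_anova(dropped_animal, "pH")

    def test_relabeling_invariance(self):
        recs = simulate_fermentation(
            cell_means=datasets.fermentation_cell_means("pH"), seed=5
        )
        base = split_plot_anova(recs, "pH")
        relabeled = recs.replace(
            {"species": {"Hanwoo": "sp1", "Holstein": "sp2", "Goat": "sp3"},
             "diet": {"HF": "d1", "HC": "d2"}}
        )
        relabeled["animal_id"] = relabeled["animal_id"].str.replace("Hanwoo", "sp1")
        same = split_plot_anova(relabeled, "pH")
        for effect in ("species", "diet", "species:diet"):
            assert same.p(effect) == pytest.approx(base.p(effect), rel=1e-12)

    def test_variance_components_recovered_at_large_n(self):
        recs = simulate_fermentation(
            mu=0.0, n_animals=200, sigma_animal=0.5, sigma_e=0.2, seed=11
        )
        result = split_plot_anova(recs, "pH")
        assert result.sigma2_animal == pytest.approx(0.25, rel=0.2)
        assert result.sigma2_residual == pytest.approx(0.04, rel=0.2)


class TestTukey:
    def test_identical_means_p_one(self):
        cm = pd.DataFrame([[1.0, 1.0]] * 3, index=list("ABC"), columns=["HF", "HC"])
        t = tukey_pairwise(cm, ms_error=1.0, df_error=9, n_per_cell=4)
        assert np.allclose(t["p_adj"], 1.0)

    def test_k2_collapses_to_t_test(self):
        cm = pd.DataFrame([[1.0, 2.5]], index=["A"], columns=["HF", "HC"])
        ms, df, n = 0.8, 6, 4
        t = tukey_pairwise(cm, ms_error=ms, df_error=df, n_per_cell=n)
        t_stat = abs(1.0 - 2.5) / math.sqrt(2 * ms / n)
        p_t = 2 * stats.t.sf(t_stat, df)
        assert t["p_adj"].iloc[0] == pytest.approx(p_t, rel=1e-9)

    def test_agrees_with_permutation_reference(self):
        # one-way layout: 6 cells x 4 iid normal obs with planted effects
        rng = np.random.default_rng(2024)
        effects = np.array([0.0, 0.4, 0.8, 0.0, 0.4, 0.8])
        data = effects[:, None] + rng.normal(0, 0.5, size=(6, 4))
        cell_means_flat = data.mean(axis=1)
        ms_within = data.var(axis=1, ddof=1).mean()
        df_error = 6 * (4 - 1)
        cm = pd.DataFrame(
            cell_means_flat.reshape(3, 2), index=list("ABC"), columns=["HF", "HC"]
        )
        t = tukey_pairwise(cm, ms_error=ms_within, df_error=df_error, n_per_cell=4)

        # permutation null of the max studentized range
        n_perm = 10_000
        se = math.sqrt(ms_within / 4)
        flat = data.ravel()
        q_max = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(flat).reshape(6, 4)
            means = perm.mean(axis=1)
            ms_p = perm.var(axis=1, ddof=1).mean()
            q_max[i] = (means.max() - means.min()) / math.sqrt(ms_p / 4)
        for _, row in t.iterrows():
            q_obs = abs(row["difference"]) / se
            p_perm = float((q_max >= q_obs).mean())
            assert abs(row["p_adj"] - p_perm) < 0.06

    def test_invalid_df_rejected(self):
        cm = pd.DataFrame([[1.0, 2.0]], index=["A"], columns=["HF", "HC"])
        with pytest.raises(ValueError):
            tukey_pairwise(cm, ms_error=1.0, df_error=0, n_per_cell=4)


def test_significance_labels():
    assert significance_label(0.01) == "significant"
    assert significance_label(0.07) == "trend"
    assert significance_label(0.5) == "ns"
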