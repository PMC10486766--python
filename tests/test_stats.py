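"""Sensory statistics: ANOVA decomposition, heritability, correlations."""

import numpy as np
import pandas as pd
import pytest

from riceq import (
    InputError,
    PUBLISHED_ANOVA,
    PUBLISHED_VARIETY_F,
    PanelSpec,
    anova_from_sums,
    anova_two_way,
    broad_sense_h2,
    make_panel,
    paired_t,
    pearson,
    published_variety_f,
    trait_correlation_matrix,
    validate_sensory_table,
)


def _tiny_table(values):
    """values[(variety, year)] -> score; one replicate, one trait."""
    rows = [
        {"variety": v, "year": y, "replicate": 1, "trait": "IVOE", "score": s}
        for (v, y), s in values.items()
    ]
    return pd.DataFrame(rows)


class TestAnova:
    def test_brute_force_oracle_on_known_cells(self):
        """Direct sums-of-squares loop over a small balanced layout."""
        rng = np.random.default_rng(3)
        varieties = [f"V{i}" for i in range(6)]
        years = [2020, 2021, 2022]
        vals = {(v, y): float(rng.uniform(-2.5, 1.0)) for v in varieties for y in years}
        res = anova_two_way(_tiny_table(vals), "IVOE")
        # oracle: textbook loops
        grand = np.mean(list(vals.values()))
        ss_var = sum(
            len(years) * (np.mean([vals[v, y] for y in years]) - grand) ** 2
            for v in varieties
        )
        ss_year = sum(
            len(varieties) * (np.mean([vals[v, y] for v in varieties]) - grand) ** 2
            for y in years
        )
        ss_tot = sum((x - grand) ** 2 for x in vals.values())
        assert res.loc["Variety", "ss"] == pytest.approx(ss_var, rel=1e-12)
        assert res.loc["Year", "ss"] == pytest.approx(ss_year, rel=1e-12)
        assert res.loc["Total", "ss"] == pytest.approx(ss_tot, rel=1e-12)
        assert list(res["df"][:3]) == [2, 5, 10]

    def test_statsmodels_cross_check(self, small_panel):
        """Independent route: OLS + anova_lm on the same cells."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        table, _ = small_panel
        res = anova_two_way(table, "viscosity")
        cells = (
            table[table["trait"] == "viscosity"]
            .groupby(["variety", "year"])["score"]
            .mean()
            .reset_index()
        )
        fit = smf.ols("score ~ C(year) + C(variety)", data=cells).fit()
        ref = anova_lm(fit)
        assert res.loc["Year", "ss"] == pytest.approx(ref.loc["C(year)", "sum_sq"])
        assert res.loc["Variety", "ss"] == pytest.approx(
            ref.loc["C(variety)", "sum_sq"]
        )
        assert res.loc["Error", "ss"] == pytest.approx(ref.loc["Residual", "sum_sq"])
        assert res.loc["Variety", "f"] == pytest.approx(ref.loc["C(variety)", "F"])
        assert res.loc["Variety", "p"] == pytest.approx(
            ref.loc["C(variety)", "PR(>F)"]
        )

    def test_conservation_of_ss_and_df(self, small_panel):
        table, _ = small_panel
        res = anova_two_way(table, "IVOE")
        assert res.loc["Total", "ss"] == pytest.approx(
            res.loc[["Year", "Variety", "Error"], "ss"].sum(), rel=1e-10
        )
        assert res.loc["Total", "df"] == res.loc[["Year", "Variety", "Error"], "df"].sum()

    def test_f_invariant_under_affine_rescaling(self, small_panel):
        table, _ = small_panel
        base = anova_two_way(table, "taste")
        scaled = table.copy()
        scaled["score"] = np.clip(scaled["score"] * 0.5 + 0.25, -3, 3)
        # avoid clipping interfering: scale keeps scores well inside the range
        res = anova_two_way(scaled, "taste")
        assert res.loc["Variety", "f"] == pytest.approx(
            base.loc["Variety", "f"], rel=1e-9
        )

    def test_zero_variance_input_flagged(self):
        vals = {(f"V{i}", y): 1.5 for i in range(4) for y in (2020, 2021)}
        res = anova_two_way(_tiny_table(vals), "IVOE")
        assert res.loc["Variety", "ss"] == 0
        assert np.isnan(res.loc["Variety", "f"])
        assert res.attrs["zero_error_variance"]

    def test_unbalanced_design_names_missing_cell(self):
        vals = {(f"V{i}", y): 0.1 for i in range(4) for y in (2020, 2021)}
        del vals[("V2", 2021)]
        with pytest.raises(InputError, match="V2.*2021"):
            anova_two_way(_tiny_table(vals), "IVOE")

    def test_replicates_averaged_before_decomposition(self):
        rows = []
        for v in ("A", "B", "C"):
            for y in (2020, 2021):
                for r, s in enumerate([0.1, 0.3, 0.2], start=1):
                    rows.append(
                        {"variety": v, "year": y, "replicate": r,
                         "trait": "IVOE",
                         "score": s + 0.5 * (v == "B") - 0.1 * (y == 2021)}
                    )
        res = anova_two_way(pd.DataFrame(rows), "IVOE")
        assert list(res["df"][:3]) == [1, 2, 2]


class TestPublishedTable:
    def test_variety_f_matches_printed_values(self):
        """SS_variety/SS_error with equal df reproduces the printed F for
        all six traits within ±0.01 after two-decimal rounding."""
        for trait, printed in PUBLISHED_VARIETY_F.items():
            recomputed = published_variety_f(trait)
            assert abs(round(recomputed, 2) - printed) <= 0.01 + 1e-12, trait

    def test_anova_from_sums_layout(self):
        tab = anova_from_sums(
            {s: ss for s, (d, ss) in PUBLISHED_ANOVA["IVOE"].items()},
            {s: d for s, (d, ss) in PUBLISHED_ANOVA["IVOE"].items()},
        )
        assert list(tab.index) == ["Year", "Variety", "Error", "Total"]
        assert tab.loc["Total", "df"] == 643
        assert tab.loc["Variety", "p"] < 0.01


class TestHeritability:
    def _anova(self, ms_v, ms_e, df=10):
        return pd.DataFrame(
            {"df": [df, df], "ss": [ms_v * df, ms_e * df], "ms": [ms_v, ms_e],
             "f": [np.nan] * 2, "p": [np.nan] * 2},
            index=pd.Index(["Variety", "Error"], name="source"),
        )

    def test_equal_mean_squares_gives_zero(self):
        assert broad_sense_h2(self._anova(0.2, 0.2)).h2 == 0.0

    def test_no_environmental_variance_gives_one(self):
        assert broad_sense_h2(self._anova(0.4, 0.0)).h2 == 1.0

    def test_truncation_at_negative_variance(self):
        res = broad_sense_h2(self._anova(0.1, 0.3))
        assert res.var_g == 0.0 and res.h2 == 0.0

    def test_h2_always_in_unit_interval(self, rng):
        for _ in range(200):
            ms_v, ms_e = rng.uniform(0, 1, 2)
            h2 = broad_sense_h2(self._anova(ms_v, ms_e), r_reps=int(rng.integers(1, 5))).h2
            assert 0.0 <= h2 <= 1.0

    def test_missing_rows_error(self):
        with pytest.raises(InputError, match="Variety"):
            broad_sense_h2(
                pd.DataFrame({"ms": [0.1]}, index=pd.Index(["Error"], name="source"))
            )

    def test_simulation_recovers_generating_h2(self):
        """30 seeded panels at the study shape recover h² = 0.75 on average
        (the full 200-panel study runs in the acceptance suite)."""
        h2s = []
        for s in range(30):
            table, truth = make_panel(
                PanelSpec(seed=s, n_reps=1, noise_sd=0.0)
            )
            res = broad_sense_h2(anova_two_way(table, "viscosity"), r_reps=2)
            h2s.append(res.h2)
        assert truth.h2 == pytest.approx(0.75)
        assert np.mean(h2s) == pytest.approx(0.75, abs=0.05)


class TestPearsonAndPairedT:
    def test_perfect_and_anti_correlation(self):
        x = np.arange(5.0)
        assert pearson(x, x).r == pytest.approx(1.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_oracle(self):
        x = np.array([1, 2, 3, 4, 5], float)
        y = np.array([2, 1, 4, 3, 5], float)
        # brute-force covariance formula
        r_hand = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert pearson(x, y).r == pytest.approx(r_hand, rel=1e-12)

    def test_zero_variance_flagged(self):
        res = pearson([1, 1, 1], [1, 2, 3])
        assert res.r is None and res.flagged == "zero variance"

    def test_paired_t_identical_vectors(self):
        res = paired_t([1.0, 2, 3], [1.0, 2, 3])
        assert res.mean_diff == 0.0
        assert res.flagged is not None  # zero-variance differences

    def test_paired_t_constant_shift_flagged(self):
        res = paired_t([2.0, 3, 4], [1.0, 2, 3])
        assert res.mean_diff == 1.0
        assert res.ci_low == res.ci_high == 1.0
        assert res.flagged is not None

    def test_paired_t_formula_oracle(self, rng):
        x = rng.normal(0.5, 1.0, 30)
        y = rng.normal(0.0, 1.0, 30)
        res = paired_t(x, y)
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(30))
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        assert res.ci_low < d.mean() < res.ci_high


class TestTraitCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, small_panel):
        table, _ = small_panel
        cm = trait_correlation_matrix(table)
        r = cm.r.to_numpy()
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T, equal_nan=True)

    def test_collinear_traits_give_unit_offdiagonal(self):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(10):
            v = float(rng.normal())
            for trait, s in (("taste", v), ("IVOE", np.clip(2 * v, -3, 3))):
                rows.append({"variety": f"V{i}", "year": 2020, "replicate": 1,
                             "trait": trait, "score": float(np.clip(s, -3, 3))})
        cm = trait_correlation_matrix(pd.DataFrame(rows))
        assert cm.r.loc["IVOE", "taste"] == pytest.approx(1.0)

    def test_generator_covariance_recovered(self):
        table, _ = make_panel(PanelSpec(seed=9, trait_corr=0.5, n_reps=1,
                                        noise_sd=0.0))
        cm = trait_correlation_matrix(table)
        # three component traits share genetic+environmental correlation 0.5
        for a, b in (("viscosity", "appearance"), ("viscosity", "taste"),
                     ("appearance", "taste")):
            assert cm.r.loc[a, b] == pytest.approx(0.5, abs=0.12)

    def test_constant_trait_flagged(self):
        rows = []
        for i in range(5):
            rows.append({"variety": f"V{i}", "year": 2020, "replicate": 1,
                         "trait": "hardness", "score": 0.0})
            rows.append({"variety": f"V{i}", "year": 2020, "replicate": 1,
                         "trait": "taste", "score": float(i) / 2 - 1})
        cm = trait_correlation_matrix(pd.DataFrame(rows))
        assert "hardness" in cm.flagged
        assert np.isnan(cm.r.loc["hardness", "taste"])


class TestValidation:
    def test_score_range_enforced(self):
        df = pd.DataFrame(
            [{"variety": "A", "year": 2020, "replicate": 1, "trait": "IVOE",
              "score": 3.4}]
        )
        with pytest.raises(InputError, match=r"\[-3, 3\]"):
            validate_sensory_table(df)

    def test_duplicate_key_rejected(self):
        row = {"variety": "A", "year": 2020, "replicate": 1, "trait": "IVOE",
               "score": 0.0}
        with pytest.raises(InputError, match="duplicate"):
            validate_sensory_table(pd.DataFrame([row, row]))
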