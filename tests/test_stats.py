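"""Pool accounting, replicate statistics, ANOVA screens and trajectories."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from salixnmr.quantify import PrepRecipe
from salixnmr.stats import (
    ExtractRecord,
    class_totals,
    genotype_screen,
    normalize_to_pool,
    oneway_anova,
    percent_extractable,
    technical_rsd,
    trajectory,
)


class TestPercentExtractable:
    def test_zero_mass(self):
        assert percent_extractable(ExtractRecord("s", 0.0)) == 0.0

    def test_worked_example(self):
        """3.15 mg dried from the 700 uL aliquot of a 1.0 mL extract of 15 mg
        tissue corresponds to 30% extractable."""
        assert percent_extractable(3.15) == pytest.approx(30.0)

    def test_zero_tissue_mass_rejected(self):
        with pytest.raises(ValueError):
            PrepRecipe(tissue_mass_mg=0.0)

    def test_negative_extract_mass_rejected(self):
        with pytest.raises(ValueError):
            ExtractRecord("s", -1.0)


class TestPoolNormalisation:
    def test_target_mass_unchanged(self):
        np.testing.assert_allclose(normalize_to_pool([1.0, 2.0], 3.0), [1.0, 2.0])

    def test_double_mass_halves(self):
        np.testing.assert_allclose(normalize_to_pool([4.0], 6.0), [2.0])

    def test_stem_bottom_factor(self):
        """11.9% extractable of 15 mg, 0.7 aliquot -> 1.25 mg -> factor 2.40."""
        mass = 0.119 * 15 * 0.7
        factor = float(normalize_to_pool([1.0], mass)[0])
        assert factor == pytest.approx(2.40, abs=0.005)

    def test_zero_mass_flagged_not_dropped(self):
        with pytest.raises(ValueError):
            normalize_to_pool([1.0], 0.0)

    def test_ratios_preserved(self):
        vals = np.array([1.0, 2.5, 4.0])
        out = normalize_to_pool(vals, 1.7)
        np.testing.assert_allclose(out / out[0], vals / vals[0])


class TestTechnicalRSD:
    @staticmethod
    def _table(values_by_rep):
        rows = []
        for bio, vals in values_by_rep.items():
            for tech, v in enumerate(vals):
                rows.append(
                    {"genotype": "g", "tissue": "leaf", "position": "top",
                     "biological_rep": bio, "technical_rep": tech,
                     "metabolite": "x", "conc_tube_mM": v}
                )
        return pd.DataFrame(rows)

    def test_identical_replicates_zero(self):
        out = technical_rsd(self._table({1: [5.0, 5.0, 5.0]}))
        assert out.mean_rsd_percent.iloc[0] == 0.0

    def test_worked_example_ten_percent(self):
        """Replicates {9, 10, 11}: sd 1, mean 10 -> 10% RSD."""
        out = technical_rsd(self._table({1: [9.0, 10.0, 11.0]}))
        assert out.mean_rsd_percent.iloc[0] == pytest.approx(10.0)

    def test_zero_mean_reported_missing(self):
        out = technical_rsd(self._table({1: [0.0, 0.0]}))
        assert np.isnan(out.mean_rsd_percent.iloc[0])


class TestOnewayAnova:
    def test_identical_groups(self):
        f, p = oneway_anova([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert f == 0.0 and p == 1.0

    def test_two_group_equals_t_squared(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 6)
        g = np.array(["a"] * 3 + ["b"] * 3)
        f, p = oneway_anova(x, g)
        t, pt = scipy.stats.ttest_ind(x[g == "a"], x[g == "b"])
        assert f == pytest.approx(t ** 2)
        assert p == pytest.approx(pt)

    def test_worked_example_f_1p5(self):
        """Groups {1,2,3} vs {2,3,4}: SSB=1.5, SSW=4 -> F(1,4)=1.5, p~0.288."""
        f, p = oneway_anova([1, 2, 3, 2, 3, 4], list("aaabbb"))
        assert f == pytest.approx(1.5)
        assert p == pytest.approx(scipy.stats.f.sf(1.5, 1, 4), rel=1e-12)
        assert p == pytest.approx(0.288, abs=5e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 12)
        g = np.repeat(["a", "b", "c"], 4)
        f, p = oneway_anova(x, g)
        ref = scipy.stats.f_oneway(x[g == "a"], x[g == "b"], x[g == "c"])
        assert f == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([1, 2, 3], ["a", "a", "a"])


def _screen_table(rng, n_metab=20, effect_on=None, effect=1.0, bio_cv=0.10):
    rows = []
    for metab in range(n_metab):
        name = f"m{metab:03d}"
        for genotype in ("Tora", "Resolution"):
            mean = 1.0
            if genotype == "Resolution" and name == effect_on:
                mean *= effect
            for bio in (1, 2):
                base = rng.normal(mean, bio_cv)
                for tech in (1, 2, 3):
                    rows.append(
                        {"genotype": genotype, "tissue": "leaf",
                         "position": "top", "biological_rep": bio,
                         "technical_rep": tech, "metabolite": name,
                         "conc_tube_mM": base + rng.normal(0, 0.01)}
                    )
    return pd.DataFrame(rows)


class TestGenotypeScreen:
    def test_single_genotype_empty(self):
        rng = np.random.default_rng(0)
        t = _screen_table(rng)
        t = t[t.genotype == "Tora"]
        out = genotype_screen(t)
        assert out.empty

    def test_planted_effect_detected_null_mostly_clean(self):
        hits, null_flags, null_total = 0, 0, 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = _screen_table(rng, effect_on="m000", effect=1.8)
            out = genotype_screen(t, alpha=0.05)
            top = out.iloc[0]
            if top.metabolite == "m000" and top.significant:
                hits += 1
            null = out[out.metabolite != "m000"]
            null_flags += int(null.significant.sum())
            null_total += len(null)
        assert hits >= 4
        assert null_flags / null_total < 0.12  # ~5% nominal on 2v2 ANOVA

    def test_sorted_ascending_by_p(self):
        rng = np.random.default_rng(2)
        out = genotype_screen(_screen_table(rng))
        assert (out.p.diff().dropna() >= 0).all()
        assert list(out.columns[:5]) == ["tissue", "position", "metabolite",
                                         "F", "p"]


class TestTrajectory:
    @staticmethod
    def _table(values, masses=None):
        """values: {(position, bio): value}"""
        rows = []
        for (pos, bio), v in values.items():
            rows.append(
                {"genotype": "g", "tissue": "stem", "position": pos,
                 "biological_rep": bio, "technical_rep": 1,
                 "metabolite": "x", "conc_tube_mM": v,
                 "extract_mass_mg": (masses or {}).get(pos, 3.0)}
            )
        return pd.DataFrame(rows)

    def test_constant_flat(self):
        vals = {(p, b): 2.0 for p in ("top", "middle", "bottom") for b in (1, 2)}
        out = trajectory(self._table(vals), "x")
        assert (out["mean"] == 2.0).all()
        assert list(out.position) == ["bottom", "middle", "top"]

    def test_unknown_metabolite(self):
        with pytest.raises(KeyError):
            trajectory(self._table({("top", 1): 1.0}), "nope")

    def test_normalised_differs_by_pool_factor_exactly(self):
        masses = {"top": 3.36, "middle": 1.93, "bottom": 1.25}
        vals = {(p, b): 1.0 for p in masses for b in (1, 2)}
        raw = trajectory(self._table(vals, masses), "x", normalised=False)
        norm = trajectory(self._table(vals, masses), "x", normalised=True)
        for pos in masses:
            r = raw[raw.position == pos]["mean"].iloc[0]
            n = norm[norm.position == pos]["mean"].iloc[0]
            assert n == pytest.approx(r * 3.0 / masses[pos])

    def test_three_fold_reversal_rule(self):
        """Under a ~2.7x top->bottom pool-mass gradient, a raw decrease
        smaller than the pool ratio reverses direction when normalised; a
        5-fold decrease keeps its direction."""
        masses = {"top": 3.36, "middle": 2.1, "bottom": 1.25}

        def norm_means(raw_by_pos):
            vals = {(p, b): raw_by_pos[p] for p in masses for b in (1, 2)}
            out = trajectory(self._table(vals, masses), "x", normalised=True)
            return dict(zip(out.position, out["mean"]))

        # 2-fold raw decrease (< pool ratio): reverses
        m = norm_means({"top": 1.0, "middle": 0.7, "bottom": 0.5})
        assert m["bottom"] > m["top"]
        # 5-fold raw decrease (> pool ratio): direction kept, attenuated
        m = norm_means({"top": 1.0, "middle": 0.45, "bottom": 0.2})
        assert m["bottom"] < m["top"]


class TestClassTotals:
    @staticmethod
    def _table(entries, pct=30.0):
        rows = []
        for metab, mg in entries.items():
            rows.append(
                {"sample_id": "s1", "metabolite": metab, "conc_mg_per_g": mg,
                 "percent_extractable": pct}
            )
        return pd.DataFrame(rows)

    def test_single_metabolite(self, library):
        out = class_totals(self._table({"sucrose": 45.0}), library)
        carb = out[out.compound_class == "carbohydrate"]
        assert carb.mg_per_g.iloc[0] == pytest.approx(45.0)

    def test_quantified_share_of_pool(self, library):
        """90 mg/g quantified at 30% extractable = 30% of the 300 mg/g pool."""
        out = class_totals(
            self._table({"sucrose": 50.0, "glucose": 40.0}, pct=30.0), library
        )
        quantified = out[out.compound_class != "unquantified/NMR-invisible"]
        assert quantified.pool_proportion.sum() == pytest.approx(0.30)

    def test_proportions_sum_to_one(self, library):
        out = class_totals(
            self._table({"sucrose": 50.0, "alanine": 5.0, "citrate": 8.0,
                         "catechin": 3.0}), library
        )
        assert out.pool_proportion.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unclassified_metabolite_rejected(self, library):
        with pytest.raises(KeyError, match="mystery"):
            class_totals(self._table({"mystery": 1.0}), library)
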