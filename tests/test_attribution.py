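"""Source attribution: Kovats band, enrichment filter, contribution factors."""

import math

import numpy as np
import pandas as pd
import pytest

from scentmark import (SimulationConfig, contribution_factors,
                       dufour_band_selection, estimate_bee_bouquet,
                       exogenous_filter, simulate_dataset)
from scentmark.attribution import (AttributionError, attribute_sources,
                                   mark_present_compounds, source_means)


def studentized_residuals_oracle(x, y):
    """Externally studentized (jackknife) OLS residuals from first
    principles: each residual is scaled by the error variance estimated
    with that observation left out."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    h = np.diag(X @ np.linalg.inv(X.T @ X) @ X.T)
    n = len(x)
    ssr = resid @ resid
    s2_loo = (ssr - resid ** 2 / (1 - h)) / (n - 3)
    return resid / np.sqrt(s2_loo * (1 - h))


class TestDufourBand:
    def test_quotients_on_a_line_all_retained(self):
        kovats = pd.Series({f"c{i}": 2000.0 + 100 * i for i in range(6)})
        gland = pd.Series({f"c{i}": 1.0 for i in range(6)})
        # quotient rises smoothly with kovats: ln q = 0.001*k
        mark = pd.Series({c: math.exp(0.001 * kovats[c]) for c in kovats.index})
        band = dufour_band_selection(mark, gland, kovats)
        assert band.retained == set(kovats.index)
        assert band.eliminated == set()
        assert band.slope == pytest.approx(0.001, rel=1e-9)

    def test_single_deserter_is_eliminated(self):
        kovats = pd.Series({f"c{i}": 2000.0 + 100 * i for i in range(6)})
        gland = pd.Series(1.0, index=kovats.index)
        mark = pd.Series({c: math.exp(0.001 * kovats[c]) for c in kovats.index})
        mark["c3"] *= 50.0  # 50-fold above the band at its Kovats index
        band = dufour_band_selection(mark, gland, kovats)
        assert band.eliminated == {"c3"}
        # verify against first-principles studentized residuals
        x = kovats.to_numpy()
        y = np.log(mark.to_numpy() / gland.to_numpy())
        t = studentized_residuals_oracle(x, y)
        expected = {c for c, ti in zip(kovats.index, t) if abs(ti) > 2}
        assert band.eliminated == expected

    def test_zero_gland_mean_excluded_from_fit_and_set(self):
        kovats = pd.Series({f"c{i}": 2000.0 + 100 * i for i in range(5)})
        gland = pd.Series([1, 1, 0, 1, 1.0], index=kovats.index)
        mark = pd.Series(1.0, index=kovats.index)
        band = dufour_band_selection(mark, gland, kovats)
        assert "c2" not in band.retained and "c2" not in band.eliminated

    def test_fewer_than_three_compounds_is_error(self):
        kovats = pd.Series({"a": 2000.0, "b": 2100.0})
        with pytest.raises(AttributionError, match="at least 3"):
            dufour_band_selection(pd.Series(1.0, index=kovats.index),
                                  pd.Series(1.0, index=kovats.index), kovats)


class TestExogenousFilter:
    @pytest.mark.parametrize("mark,expect_retained", [
        (1.0, True),    # ratio 1: mark equals bee sum
        (2.0, True),    # exactly two-fold: strict inequality retains
        (3.0, False),   # three-fold enriched: discarded
    ])
    def test_enrichment_boundaries(self, mark, expect_retained):
        marks = pd.Series({"c": mark})
        head = pd.Series({"c": 0.4})
        gland = pd.Series({"c": 0.6})
        retained, discarded, _ = exogenous_filter(marks, head, gland)
        assert ("c" in retained) is expect_retained

    def test_no_bee_source_discarded_with_reason(self):
        retained, discarded, reasons = exogenous_filter(
            pd.Series({"c": 1.0}), pd.Series({"c": 0.0}),
            pd.Series({"c": 0.0}))
        assert discarded == {"c"}
        assert reasons["c"] == "no bee source"


class TestContributionFactors:
    @pytest.mark.parametrize("head,gland,expected", [
        (1.0, 1.0, (1, 1)),   # symmetric: both sources contribute
        (5.0, 1.0, (1, 0)),   # ratio 5 > 2: head only
        (1.5, 1.0, (1, 1)),   # ratio in [1, 2]: proportional contribution
        (1.0, 3.0, (0, 1)),   # gland dominant
        (0.0, 2.0, (0, 1)),   # single-source compound
    ])
    def test_factor_assignment(self, head, gland, expected):
        factors, ratios = contribution_factors(pd.Series({"c": head}),
                                               pd.Series({"c": gland}))
        assert factors["c"] == expected

    def test_symmetric_under_label_exchange(self):
        rng = np.random.default_rng(1)
        h = pd.Series(np.exp(rng.normal(size=20)),
                      index=[f"c{i}" for i in range(20)])
        g = pd.Series(np.exp(rng.normal(size=20)), index=h.index)
        f1, _ = contribution_factors(h, g)
        f2, _ = contribution_factors(g, h)
        for c in h.index:
            assert f1[c] == (f2[c][1], f2[c][0])

    def test_both_zero_is_error(self):
        with pytest.raises(AttributionError, match="discarded"):
            contribution_factors(pd.Series({"c": 0.0}), pd.Series({"c": 0.0}))

    def test_ratio_distribution_exported(self):
        factors, ratios = contribution_factors(
            pd.Series({"a": 1.0, "b": 6.0}), pd.Series({"a": 2.0, "b": 1.0}))
        assert ratios["a"] == pytest.approx(2.0)
        assert ratios["b"] == pytest.approx(6.0)


class TestBouquet:
    def test_hand_computed_bouquet(self):
        contribution = {"a": (1, 1), "b": (1, 0), "c": (0, 1)}
        head = pd.Series({"a": 2.0, "b": 4.0, "c": 6.0})
        gland = pd.Series({"a": 1.0, "b": 3.0, "c": 5.0})
        bq = estimate_bee_bouquet("N1", head, gland, contribution)
        assert bq.values == {"a": 3.0, "b": 4.0, "c": 5.0}

    def test_all_proportional_is_elementwise_sum(self):
        head = pd.Series({"a": 2.0, "b": 4.0})
        gland = pd.Series({"a": 1.0, "b": 3.0})
        bq = estimate_bee_bouquet("N1", head, gland,
                                  {"a": (1, 1), "b": (1, 1)})
        assert bq.values == {"a": 3.0, "b": 7.0}

    def test_missing_extract_names_bee(self):
        with pytest.raises(AttributionError, match="N9"):
            estimate_bee_bouquet("N9", None, pd.Series({"a": 1.0}),
                                 {"a": (1, 1)})


class TestOnSyntheticData:
    def test_exact_head_gland_sum_discards_nothing(self):
        """Marks built as an exact bee-source sum carry no exogenous
        enrichment, so the two-fold filter must pass every compound."""
        cfg = SimulationConfig(seed=1, mix_gland=0.5, mix_cuticle=0.5,
                               env_enrichment=0.0, sigma_noise=0,
                               sigma_intensity=0, sigma_drift=0,
                               n_control_sleeves=0)
        t = simulate_dataset(cfg).peak_table
        universe = mark_present_compounds(t)
        means = source_means(t, universe)
        retained, discarded, _ = exogenous_filter(
            means["mark"], means["head"], means["gland"])
        assert discarded == set()
        assert retained == set(universe)

    def test_gland_proportional_marks_keep_full_band(self):
        """When marks are pure gland secretion, the mark/gland quotient is
        constant, residuals vanish and the band keeps every compound."""
        cfg = SimulationConfig(seed=1, mix_gland=1.0, mix_cuticle=0.0,
                               env_enrichment=0.0, sigma_noise=0,
                               sigma_intensity=0, sigma_drift=0,
                               n_control_sleeves=0)
        t = simulate_dataset(cfg).peak_table
        universe = mark_present_compounds(t)
        means = source_means(t, universe)
        band = dufour_band_selection(means["mark"], means["gland"],
                                     t.annotations["kovats"])
        assert band.eliminated == set()

    def test_environment_compounds_flagged_at_high_enrichment(self):
        ds = simulate_dataset(SimulationConfig(seed=9, env_enrichment=2.0))
        model, bouquets = attribute_sources(ds.peak_table)
        env = {c for c, s in ds.truth_source.items() if s == "environment"}
        assert env <= model.exogenous_discarded
        assert len(bouquets) == 25
        assert all(set(bq.values) == set(model.contribution)
                   for bq in bouquets.values())
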