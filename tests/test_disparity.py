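"""Gender disparity ratio, net changes, rankings, age gradients."""

import numpy as np
import pandas as pd
import pytest

from qcindex import (
    PanelValidationError,
    age_gradient,
    compute_gdr,
    correlate_reference,
    net_change,
    rank_locations,
    round_half_up,
)


def scores_frame(rows):
    """rows: (location, year, age_group, sex, qci)"""
    return pd.DataFrame(
        rows, columns=["location", "year", "age_group", "sex", "qci"]
    )


def paired_scores(pairs, age_group="age-standardized"):
    """pairs: (location, year, female_qci, male_qci)"""
    rows = []
    for loc, year, f, m in pairs:
        rows.append((loc, year, age_group, "female", f))
        rows.append((loc, year, age_group, "male", m))
    return scores_frame(rows)


class TestComputeGDR:
    def test_female_over_male_ratio(self):
        gdr = compute_gdr(paired_scores([("Global", 2019, 76.0, 82.4)]))
        assert gdr["gdr"].iloc[0] == 0.92
        assert gdr["gdr_raw"].iloc[0] == pytest.approx(76.0 / 82.4)

    def test_ratio_above_one_when_females_fare_better(self):
        gdr = compute_gdr(paired_scores([("CAR", 1990, 4.1, 3.1)]))
        assert gdr["gdr"].iloc[0] == 1.32

    def test_equal_scores_give_unity(self):
        gdr = compute_gdr(paired_scores([("X", 2000, 55.5, 55.5)]))
        assert gdr["gdr"].iloc[0] == 1.0

    def test_zero_male_score_is_missing_with_reason(self):
        gdr = compute_gdr(paired_scores([("X", 2000, 10.0, 0.0)]))
        assert np.isnan(gdr["gdr"].iloc[0])
        assert gdr["missing_reason"].iloc[0] == "zero_male_qci"

    def test_missing_side_flagged(self):
        scores = paired_scores([("X", 2000, 10.0, 20.0), ("Y", 2000, 5.0, 10.0)])
        scores = scores[~((scores["location"] == "Y") & (scores["sex"] == "male"))]
        gdr = compute_gdr(scores).set_index("location")
        assert gdr.loc["Y", "missing_reason"] == "missing_score"
        assert gdr.loc["X", "gdr"] == 0.5

    def test_disjoint_keys_error(self):
        scores = scores_frame(
            [("A", 2000, "age-standardized", "female", 10.0),
             ("B", 2000, "age-standardized", "male", 20.0)]
        )
        with pytest.raises(PanelValidationError, match="no shared"):
            compute_gdr(scores)

    def test_scale_invariance(self):
        pairs = [("A", 2019, 76.0, 82.4), ("B", 2019, 4.1, 3.1)]
        base = compute_gdr(paired_scores(pairs))
        scaled = paired_scores(pairs)
        scaled["qci"] *= 7.3
        assert np.allclose(compute_gdr(scaled)["gdr_raw"], base["gdr_raw"])


class TestNetChange:
    def _series(self, values):
        """values: {(location, year): qci} at age-standardized/both level."""
        return pd.DataFrame(
            [
                {"location": loc, "year": yr, "sex": "both",
                 "age_group": "age-standardized", "qci": v}
                for (loc, yr), v in values.items()
            ]
        )

    def test_five_year_qci_difference(self):
        out = net_change(self._series({("Low SDI", 2014): 25.5, ("Low SDI", 2019): 30.2}),
                         2014, 2019)
        assert out["net_change"].iloc[0] == 4.7

    def test_identical_years_give_zero(self):
        out = net_change(self._series({("High SDI", 2014): 90.1, ("High SDI", 2019): 90.1}),
                         2014, 2019)
        assert out["net_change"].iloc[0] == 0.0

    def test_gdr_change_on_gdr_table(self):
        gdr = compute_gdr(
            paired_scores([("Low SDI", 1990, 9.9, 14.5), ("Low SDI", 2019, 27.4, 31.9)])
        )
        # chained on unrounded values, rounded at the end
        out = net_change(gdr, 1990, 2019)
        assert out["metric"].iloc[0] == "gdr"
        assert out["net_change"].iloc[0] == round_half_up(27.4 / 31.9 - 9.9 / 14.5, 2)

    def test_antisymmetry(self):
        s = self._series({("A", 1990): 10.0, ("A", 2019): 30.2})
        fwd = net_change(s, 1990, 2019)["net_change_raw"].iloc[0]
        rev = net_change(s, 2019, 1990)["net_change_raw"].iloc[0]
        assert fwd == -rev

    def test_missing_year_flagged(self):
        out = net_change(self._series({("A", 1990): 10.0}), 1990, 2019)
        assert np.isnan(out["net_change"].iloc[0])
        assert out["missing_reason"].iloc[0] == "missing_year"


class TestRankLocations:
    def _scores(self, mapping, year=2019):
        return pd.DataFrame(
            [
                {"location": loc, "year": year, "sex": "both",
                 "age_group": "age-standardized", "qci": v}
                for loc, v in mapping.items()
            ]
        )

    def test_top_and_bottom_slices(self):
        ranked = rank_locations(
            self._scores({"Italy": 99.4, "Australia": 98.1, "CAR": 6.8}),
            2019, top_n=2, bottom_n=1,
        )
        top = ranked[ranked["group"] == "top"]["location"].tolist()
        bottom = ranked[ranked["group"] == "bottom"]["location"].tolist()
        assert top == ["Italy", "Australia"]
        assert bottom == ["CAR"]

    def test_ties_break_alphabetically(self):
        ranked = rank_locations(self._scores({"C": 50.0, "A": 50.0, "B": 50.0}), 2019)
        assert ranked["location"].tolist() == ["A", "B", "C"]

    def test_is_a_permutation(self):
        mapping = {f"L{i}": float(i) for i in range(10)}
        ranked = rank_locations(self._scores(mapping), 2019)
        assert sorted(ranked["location"]) == sorted(mapping)
        assert ranked["rank"].tolist() == list(range(1, 11))

    def test_n_larger_than_pool_clamps(self):
        ranked = rank_locations(self._scores({"A": 1.0, "B": 2.0}), 2019, top_n=10)
        assert len(ranked) == 2

    def test_absent_year_errors(self):
        with pytest.raises(PanelValidationError, match="2050"):
            rank_locations(self._scores({"A": 1.0}), 2050)


class TestAgeGradient:
    def _scores(self, band_values):
        return pd.DataFrame(
            [
                {"location": "G", "year": 2019, "sex": "both", "age_group": band,
                 "qci": v}
                for band, v in band_values.items()
            ]
        )

    def test_constant_profile_passes_through(self, weights):
        scores = self._scores({b: 66.0 for b in weights["age_group"]})
        _, coarse = age_gradient(scores, weights)
        assert np.allclose(coarse["qci"], 66.0)

    def test_hand_weighted_mean_in_one_bin(self):
        scores = self._scores({"75-79": 40.0, "80-84": 60.0})
        w = pd.DataFrame({"age_group": ["75-79", "80-84"], "weight": [0.5, 0.5]})
        _, coarse = age_gradient(scores, w, bins={"75+": ["75-79", "80-84"]})
        assert coarse["qci"].iloc[0] == pytest.approx(50.0)

    def test_monotone_bands_give_monotone_bins(self, weights):
        bands = list(weights["age_group"])
        scores = self._scores({b: 100.0 - 5.0 * i for i, b in enumerate(bands)})
        _, coarse = age_gradient(scores, weights)
        ordered = coarse.set_index("age_bin").loc[["15-49", "50-74", "75+"], "qci"]
        assert ordered.is_monotonic_decreasing

    def test_bins_bounded_by_member_bands(self, weights):
        rng = np.random.default_rng(0)
        bands = list(weights["age_group"])
        vals = dict(zip(bands, rng.uniform(0, 100, len(bands))))
        _, coarse = age_gradient(self._scores(vals), weights)
        from qcindex.disparity import DEFAULT_AGE_BINS
        for _, row in coarse.iterrows():
            members = [vals[b] for b in DEFAULT_AGE_BINS[row["age_bin"]]]
            assert min(members) <= row["qci"] <= max(members)


class TestCorrelateReference:
    def _scores(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"location": [f"L{i}" for i in range(n)], "year": 2019,
             "qci": rng.uniform(0, 100, n)}
        )

    def test_self_correlation_is_one(self):
        s = self._scores()
        ref = s.rename(columns={"qci": "haq"})
        r, n = correlate_reference(s, ref)
        assert r == pytest.approx(1.0)
        assert n == 50

    def test_negative_affine_gives_minus_one(self):
        s = self._scores()
        ref = s.assign(haq=100 - s["qci"])[["location", "year", "haq"]]
        r, _ = correlate_reference(s, ref)
        assert r == pytest.approx(-1.0)

    def test_attenuation_by_independent_noise(self):
        """ref = qci + e with known variances: r ~= sd(q)/sqrt(var(q)+var(e))."""
        rng = np.random.default_rng(42)
        n = 4000
        q = rng.normal(50, 10, n)
        e = rng.normal(0, 10, n)
        s = pd.DataFrame({"location": [f"L{i}" for i in range(n)], "year": 2019, "qci": q})
        ref = pd.DataFrame({"location": s["location"], "year": 2019, "haq": q + e})
        r, _ = correlate_reference(s, ref)
        assert r == pytest.approx(10 / np.sqrt(200), abs=0.03)

    def test_too_few_pairs_rejected(self):
        s = self._scores(n=2)
        with pytest.raises(ValueError, match=">= 3"):
            correlate_reference(s, s.rename(columns={"qci": "haq"}))


@pytest.mark.parametrize(
    "x,places,expected",
    [(0.925, 2, 0.93), (0.915, 2, 0.92), (4.65, 1, 4.7), (-0.005, 2, -0.01)],
)
def test_round_half_up(x, places, expected):
    assert round_half_up(x, places) == expected
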