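"""Surveillance summaries: censoring, rates, chi-square, percentiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import reference_values as ref
from ricerisk import (
    ConcentrationSample,
    ContingencyTable2x2,
    DegenerateDataError,
    InvalidInputError,
    MalformedRecordError,
    detection_and_exceedance_rates,
    pearson_chi2_2x2,
    shifted_lognormal,
    stratum_percentiles,
    substitute_below_lod,
    township_exceedance_summary,
)


def make_sample(value, below_lod=False, element="Cd", county="A", township="A-T1",
                source="rice", sample_id="s"):
    return ConcentrationSample(
        sample_id=sample_id, year=2020, county=county, township=township,
        source=source, element=element, value=value, below_lod=below_lod,
    )


class TestHalfLodSubstitution:
    def test_censored_become_half_lod(self, toxicology):
        samples = [make_sample(None, below_lod=True), make_sample(0.124)]
        out = substitute_below_lod(samples, toxicology["Cd"])
        assert out.tolist() == [0.0015, 0.124]

    def test_all_censored(self, toxicology):
        samples = [make_sample(None, below_lod=True) for _ in range(5)]
        out = substitute_below_lod(samples, toxicology["Cd"])
        assert np.allclose(out, 0.0015) and len(out) == 5

    def test_uncensored_without_value_rejected(self):
        with pytest.raises(MalformedRecordError):
            make_sample(None, below_lod=False)

    def test_element_mismatch_rejected(self, toxicology):
        with pytest.raises(InvalidInputError):
            substitute_below_lod([make_sample(0.1, element="Pb")], toxicology["Cd"])

    def test_substitution_never_creates_exceedances(self, toxicology):
        # LOD/2 < limit for every surveyed element
        for tox in toxicology.values():
            assert tox.lod / 2 < tox.limit


class TestDetectionExceedanceRates:
    @pytest.mark.parametrize("element", list(ref.DETECTION_COUNTS))
    def test_published_rates_from_counts(self, element, toxicology):
        n, detected, det_rate = ref.DETECTION_COUNTS[element]
        _, exceeded, exc_rate = ref.EXCEEDANCE_COUNTS[element]
        tox = toxicology[element]
        # construct a sample list with exactly these counts
        samples = (
            [make_sample(tox.limit * 1.5, element=element, sample_id=f"e{i}")
             for i in range(exceeded)]
            + [make_sample(tox.limit * 0.5, element=element, sample_id=f"d{i}")
               for i in range(detected - exceeded)]
            + [make_sample(None, below_lod=True, element=element, sample_id=f"c{i}")
               for i in range(n - detected)]
        )
        out = detection_and_exceedance_rates(samples, tox)
        assert round(out["detection_rate_pct"], 2) == det_rate
        assert round(out["exceedance_rate_pct"], 2) == exc_rate
        assert out["exceeded"] <= out["detected"] <= out["n"]

    def test_no_exceedances(self, toxicology):
        samples = [make_sample(0.01, sample_id=str(i)) for i in range(10)]
        out = detection_and_exceedance_rates(samples, toxicology["Cd"])
        assert out["exceedance_rate_pct"] == 0.0
        assert out["max_mg_kg"] == 0.01

    def test_exceedance_is_strict_inequality(self, toxicology):
        samples = [make_sample(0.2)]  # exactly at the Cd limit
        out = detection_and_exceedance_rates(samples, toxicology["Cd"])
        assert out["exceeded"] == 0


class TestChiSquare:
    @pytest.mark.parametrize("element", list(ref.CHI2_TABLE), ids=list(ref.CHI2_TABLE))
    def test_published_statistics(self, element):
        pe, pn, re_, rn, printed = ref.CHI2_TABLE[element]
        table = ContingencyTable2x2.from_group_totals(pe, pn, re_, rn)
        out = pearson_chi2_2x2(table)
        assert round(out["statistic"], 2) == printed
        assert out["dof"] == 1

    def test_identical_proportions_give_zero(self):
        out = pearson_chi2_2x2(ContingencyTable2x2.from_group_totals(10, 100, 20, 200))
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_table_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_chi2_2x2(ContingencyTable2x2(0, 10, 0, 20))

    @given(
        pe=st.integers(1, 50), pok=st.integers(1, 200),
        re_=st.integers(1, 50), rok=st.integers(1, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_expected_counts(self, pe, pok, re_, rok):
        """Pearson X^2 equals the literal sum of (O-E)^2/E over the four cells."""
        table = ContingencyTable2x2(pe, pok, re_, rok)
        obs = table.as_array()
        total = obs.sum()
        brute = 0.0
        for i in range(2):
            for j in range(2):
                e = obs[i].sum() * obs[:, j].sum() / total
                brute += (obs[i, j] - e) ** 2 / e
        assert pearson_chi2_2x2(table)["statistic"] == pytest.approx(brute, rel=1e-9)


class TestStratumPercentiles:
    def test_interpolated_medians(self):
        t = stratum_percentiles([1, 2, 3, 4, 5], ["a"] * 5)
        assert t.loc[t.stratum == "a", "P50"].item() == 3
        t = stratum_percentiles([1, 2, 3, 4], ["a"] * 4)
        assert t.loc[t.stratum == "a", "P50"].item() == 2.5

    def test_shifted_lognormal_median_matches_closed_form(self, rng, cd_distribution):
        """Large-sample P50 approaches tau + exp(mu_log) (~0.0868 mg/kg)."""
        draws = cd_distribution.ppf(rng.uniform(1e-9, 1 - 1e-9, 10_000))
        t = stratum_percentiles(draws, ["all"] * len(draws))
        p = cd_distribution.params
        analytic = p["tau"] + np.exp(p["mu_log"])
        assert t.loc[t.stratum == "all", "P50"].item() == pytest.approx(analytic, abs=3e-3)

    @given(st.lists(st.floats(0, 100), min_size=4, max_size=40), st.floats(0.1, 5))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance_and_shift_monotonicity(self, values, const):
        labels = ["s"] * len(values)
        base = stratum_percentiles(values, labels)
        perm = stratum_percentiles(list(reversed(values)), labels)
        assert np.allclose(base[["P25", "P50", "P75"]], perm[["P25", "P50", "P75"]])
        shifted = stratum_percentiles([v + const for v in values], labels)
        assert np.allclose(
            shifted[["P25", "P50", "P75"]], base[["P25", "P50", "P75"]] + const
        )
        row = base.iloc[0]
        assert row["P25"] <= row["P50"] <= row["P75"]


class TestTownshipExceedance:
    def test_single_hot_township(self, toxicology):
        samples = [
            make_sample(0.3, township="A-T1", sample_id="1"),
            make_sample(0.05, township="A-T2", sample_id="2"),
            make_sample(0.05, township="A-T3", sample_id="3"),
        ]
        t = township_exceedance_summary(samples, toxicology["Cd"])
        assert t.iloc[0].townships_tested == 3
        assert t.iloc[0].townships_exceeding == 1

    def test_no_exceedances(self, toxicology):
        samples = [make_sample(0.01, township=f"A-T{i}", sample_id=str(i)) for i in range(4)]
        t = township_exceedance_summary(samples, toxicology["Cd"])
        assert t.iloc[0].townships_exceeding == 0

    def test_counts_within_binomial_interval(self, rng, toxicology):
        """Townships exceeding with probability 1/2 -> count in the 99% band of Bin(20, .5)."""
        tox = toxicology["Cd"]
        samples = []
        for t in range(20):
            hot = rng.random() < 0.5
            value = 0.3 if hot else 0.05
            samples.append(make_sample(value, township=f"A-T{t}", sample_id=str(t)))
        out = township_exceedance_summary(samples, tox)
        lo, hi = stats.binom.ppf([0.005, 0.995], 20, 0.5)
        assert lo <= out.iloc[0].townships_exceeding <= hi
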