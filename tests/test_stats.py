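"""Summary statistics, group comparisons and derived-rate arithmetic."""

import math
import random

import numpy as np
import pytest

from radmut.events import merge_events
from radmut.filtering import HET, HOM
from radmut.stats import (SPECTRUM6_CLASSES, SPONTANEOUS_MF,
                          TAIR10_GENOME_LENGTH, category_table,
                          compare_groups, deletion_bin_counts, derived_rates,
                          fit_survival, het_hom_group_test, het_hom_stats,
                          locus_mf, mean_se, mendelian_expectation,
                          mutation_frequency, sbs_spectrum, summarize_group)

from conftest import make_call, make_filtered

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _sbs_event(ref, alt, pos=100, sample="s1", zyg=HET):
    fc = make_filtered(make_call(pos=pos, ref=ref, alt=alt, sample=sample), zyg)
    (ev,) = merge_events([fc])
    return ev


def _del_event(size, pos=100, sample="s1", zyg=HET):
    fc = make_filtered(
        make_call(pos=pos, ref="G" + "A" * size, alt="G", sample=sample), zyg
    )
    (ev,) = merge_events([fc])
    return ev


def _sv_event(sample="s1"):
    fc = make_filtered(make_call(pos=10, ref="A", alt="<DEL>", sv_end=4000,
                                 sample=sample))
    (ev,) = merge_events([fc])
    return ev


class TestMeanSe:
    def test_vector(self):
        m, se = mean_se([4, 1, 2, 64, 7, 2])
        assert m == pytest.approx(13.3333, abs=1e-3)
        assert se == pytest.approx(10.2, abs=0.05)

    def test_single_value_se_undefined(self):
        m, se = mean_se([5.0])
        assert m == 5.0 and math.isnan(se)

    def test_empty(self):
        m, se = mean_se([])
        assert math.isnan(m) and math.isnan(se)


class TestCategoryTable:
    def test_subtotals_and_percentages(self):
        counts = {"g": {"SBS": 50, "DEL1": 20, "DEL_GE2": 10, "INS1": 5,
                        "INS_GE2": 5, "COMPLEX": 10, "SV": 3}}
        (row,) = category_table(counts).to_dict("records")
        assert row["grand_total"] == 100  # SV excluded
        assert row["deletion_total"] == 30 and row["insertion_total"] == 10
        assert row["SBS_pct"] == 50 and row["deletion_pct"] == 30

    def test_missing_categories_default_zero(self):
        (row,) = category_table({"g": {"SBS": 4}}).to_dict("records")
        assert row["grand_total"] == 4 and row["deletion_total"] == 0


class TestMutationFrequency:
    def test_per_sample_counts_over_length(self):
        evs = {"a": [_sbs_event("A", "T", sample="a"),
                     _del_event(3, pos=500, sample="a"),
                     _sv_event(sample="a")],
               "b": []}
        df = mutation_frequency(evs, 1_000_000).set_index("sample")
        assert df.loc["a", "n_events"] == 2  # SV excluded
        assert df.loc["a", "mf"] == pytest.approx(2e-6)
        assert df.loc["b", "mf"] == 0.0

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            mutation_frequency({}, 0)


class TestSpectrum:
    def test_random_tally_matches_independent_oracle(self):
        rng = random.Random(31)
        events, oracle = [], {cls: 0 for cls in SPECTRUM6_CLASSES}
        for i in range(500):
            ref = rng.choice("ACGT")
            alt = rng.choice([b for b in "ACGT" if b != ref])
            events.append(_sbs_event(ref, alt, pos=10 * i + 1000))
            r, a = (ref, alt) if ref in "AG" else (_COMP[ref], _COMP[alt])
            oracle[f"{r}:{_COMP[r]}>{a}:{_COMP[a]}"] += 1
        spectrum, titv = sbs_spectrum(events)
        assert spectrum == oracle
        ti = oracle["G:C>A:T"] + oracle["A:T>G:C"]
        assert titv == pytest.approx(ti / (500 - ti))

    def test_non_sbs_ignored(self):
        spectrum, titv = sbs_spectrum([_del_event(3)])
        assert sum(spectrum.values()) == 0


class TestDeletionBins:
    def test_histogram(self):
        evs = [_del_event(s, pos=100 * i + 50)
               for i, s in enumerate([1, 1, 3, 9, 10, 49, 50, 200])]
        evs.append(_sbs_event("A", "G", pos=9000))
        assert deletion_bin_counts(evs) == {"1": 2, "2-9": 2, "10-49": 2,
                                            ">=50": 2}


class TestCompareGroups:
    def test_welch_t_matches_scipy(self):
        import scipy.stats as sps
        a, b = [1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 4.5, 6.0]
        res = compare_groups(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res["t"] == pytest.approx(ref.statistic)
        assert res["t_pvalue"] == pytest.approx(ref.pvalue)

    def test_chi2_hand_value(self):
        res = compare_groups([1, 2, 3], [1, 2, 3], table=[[10, 20], [20, 10]])
        assert res["chi2"] == pytest.approx(20 / 3, abs=1e-6)
        assert res["chi2_pvalue"] < 0.01
        assert res["chi2_low_expected"] is False

    def test_zero_column_dropped(self):
        res = compare_groups([1, 2], [1, 2], table=[[10, 0, 20], [20, 0, 10]])
        assert res["chi2"] == pytest.approx(20 / 3, abs=1e-6)

    def test_identical_constant_groups(self):
        res = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert (res["t"], res["t_pvalue"]) == (0.0, 1.0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestHetHom:
    def test_counts_and_ratio(self):
        evs = {"a": [_sbs_event("A", "T", pos=100, sample="a", zyg=HET),
                     _sbs_event("A", "G", pos=200, sample="a", zyg=HET),
                     _sbs_event("C", "T", pos=300, sample="a", zyg=HOM),
                     _sv_event(sample="a")],
               "b": [_sbs_event("A", "T", pos=100, sample="b", zyg=HET)]}
        df = het_hom_stats(evs).set_index("sample")
        assert (df.loc["a", "het"], df.loc["a", "hom"]) == (2, 1)
        assert df.loc["a", "ratio"] == 2.0
        assert math.isnan(df.loc["b", "ratio"])

    def test_group_test(self):
        out = het_hom_group_test([1.8, 2.1, 2.2, float("nan")])
        assert out["n_defined"] == 3 and out["n_undefined"] == 1
        assert out["mean"] == pytest.approx(2.0333, abs=1e-3)
        assert np.isfinite(out["pvalue"])


class TestMendelian:
    def test_large_sample_near_two(self):
        r = mendelian_expectation(100_000, seed=5)
        assert abs(r - 2.0) < 0.1

    def test_deterministic_per_seed(self):
        assert mendelian_expectation(10_000, 3) == mendelian_expectation(10_000, 3)
        assert (mendelian_expectation(10_000, 3)
                != mendelian_expectation(10_000, 4))

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            mendelian_expectation(0, 1)


class TestDerivedRates:
    def test_m1_extrapolation_and_fold(self):
        r = derived_rates(2.7e-7)
        assert r.mf_m1 == pytest.approx(3.6e-7, rel=1e-3)
        assert r.fold_over_spontaneous == pytest.approx(r.mf_m1 / SPONTANEOUS_MF)
        assert 50 < r.fold_over_spontaneous < 52

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            derived_rates(-1.0)
        with pytest.raises(ValueError):
            derived_rates(1e-7, spontaneous=0.0)


class TestLocusMf:
    def test_screen_arithmetic(self):
        mf, genes = locus_mf(88, 104_088, 12, 27_206)
        assert mf == pytest.approx(7.0e-5, abs=0.05e-5)
        assert genes == pytest.approx(1.9, abs=0.05)

    def test_invalid(self):
        with pytest.raises(ValueError):
            locus_mf(1, 0, 12, 100)


class TestSurvivalFit:
    def test_recovers_known_parameters(self):
        d0, n = 150.0, 4.0
        doses = np.array([0, 50, 100, 200, 300, 400, 500, 600], dtype=float)
        s = 1 - (1 - np.exp(-doses / d0)) ** n
        fit = fit_survival(doses, s)
        assert fit.d0 == pytest.approx(d0, rel=0.01)
        assert fit.n_extrapolation == pytest.approx(n, rel=0.01)
        assert fit.dq == pytest.approx(d0 * math.log(n), rel=0.01)

    def test_survival_method_round_trip(self):
        fit = fit_survival([0, 100, 200, 400],
                           [1.0, 0.95, 0.6, 0.05])
        assert fit.survival(0) == pytest.approx(1.0)
        assert 0 <= fit.survival(300) <= 1

    @pytest.mark.parametrize("doses,s", [
        ([0, 100], [1.0, 0.5]),                    # too few points
        ([100, 200, 300], [1.0, 0.5, 0.2]),        # no 0 Gy control
        ([0, 100, 200], [1.0, 1.0, 1.0]),          # no dose response
    ])
    def test_invalid_inputs(self, doses, s):
        with pytest.raises(ValueError):
            fit_survival(doses, s)


class TestSummarizeGroup:
    def test_backbone(self):
        evs = {"a": [_sbs_event("A", "T", pos=100, sample="a"),
                     _del_event(1, pos=900, sample="a", zyg=HOM)],
               "b": [_sbs_event("G", "A", pos=100, sample="b")]}
        gs = summarize_group("g", evs, TAIR10_GENOME_LENGTH)
        assert gs.group == "g"
        assert sorted(gs.per_sample_event_counts) == [1, 2]
        assert gs.category_counts["SBS"] == 2
        assert gs.mean_mf == pytest.approx(1.5 / TAIR10_GENOME_LENGTH)
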