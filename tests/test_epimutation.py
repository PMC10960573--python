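"""Epimutation calling, frequencies and differential testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pimsel import epimutation as em
from pimsel import methylome_io, synthetic_cohort
from tests.test_cohort_eval import fisher_enumeration


def _matrix(values, labels):
    vals = pd.DataFrame(values)
    vals.index.name = "embryo_id"
    cov = vals.notna().astype(int) * 100
    m = methylome_io.PromoterMatrix(vals, cov, min_coverage=30)
    return m, pd.Series(labels, index=vals.index)


class TestFilterCoveredPromoters:
    def _cohort_matrix(self):
        # 10 birth + 10 failed embryos; p1 covered in 1 birth embryo (10%),
        # p2 in none of birth below threshold combinations
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.random((20, 3)), columns=["p1", "p2", "p3"])
        vals.index = [f"e{i}" for i in range(20)]
        labels = pd.Series(["Birth"] * 10 + ["Failed"] * 10, index=vals.index)
        return vals, labels

    def test_low_birth_coverage_removed(self):
        vals, labels = self._cohort_matrix()
        vals.loc[[f"e{i}" for i in range(1, 10)], "p1"] = np.nan  # 9% -> 1/10 birth
        vals.loc["e0", "p1"] = 0.5
        cov = vals.notna().astype(int) * 100
        m = methylome_io.PromoterMatrix(vals, cov, min_coverage=30)
        kept = em.filter_covered_promoters(m, labels, min_fraction=0.10)
        assert "p1" in kept  # 10% exactly still passes (>= rule)
        vals.loc["e0", "p1"] = np.nan  # now 0% of birth
        m = methylome_io.PromoterMatrix(vals, vals.notna().astype(int) * 100,
                                        min_coverage=30)
        kept = em.filter_covered_promoters(m, labels, min_fraction=0.10)
        assert "p1" not in kept
        assert {"p2", "p3"} <= set(kept)

    def test_fully_covered_kept_and_manual_count(self):
        vals, labels = self._cohort_matrix()
        # mask p2 in 95% of failed -> 0.5/10 < 10%
        vals.loc[[f"e{i}" for i in range(10, 20)], "p2"] = np.nan
        m = methylome_io.PromoterMatrix(vals, vals.notna().astype(int) * 100,
                                        min_coverage=30)
        kept = em.filter_covered_promoters(m, labels, min_fraction=0.10)
        assert set(kept) == {"p1", "p3"}  # hand count of surviving promoters


class TestCallEpimutations:
    @pytest.mark.parametrize("value, mean, sd, am, rm, flag", [
        (0.40, 0.25, 0.04, 0.15, 3.75, True),
        (0.40, 0.25, 0.06, 0.15, 2.5, False),   # RM fails
        (0.34, 0.25, 0.01, 0.09, 9.0, False),   # AM fails
    ])
    def test_am_rm_cutoffs(self, value, mean, sd, am, rm, flag):
        m, labels = _matrix({"p": [mean, value]}, ["Birth", "Failed"])
        baselines = pd.DataFrame({"mean_birth": [mean], "sd_birth": [sd],
                                  "n_birth_covered": [5]},
                                 index=pd.Index(["p"], name="promoter_id"))
        calls = em.call_epimutations(m, baselines)
        row = calls[calls["embryo_id"] == 1].iloc[0]
        assert row["am"] == pytest.approx(am)
        assert row["rm"] == pytest.approx(rm)
        assert bool(row["is_epimutation"]) is flag

    def test_zero_sd_reduces_to_absolute_criterion(self):
        m, _ = _matrix({"p": [0.25, 0.40]}, ["Birth", "Failed"])
        baselines = pd.DataFrame({"mean_birth": [0.25], "sd_birth": [0.0],
                                  "n_birth_covered": [3]},
                                 index=pd.Index(["p"], name="promoter_id"))
        calls = em.call_epimutations(m, baselines)
        row = calls[calls["embryo_id"] == 1].iloc[0]
        assert np.isinf(row["rm"])
        assert bool(row["is_epimutation"])

    def test_flag_monotone_in_am_and_rm(self):
        # at fixed sd, growing deviation can only turn the flag on, never off
        sds = [0.02, 0.05]
        for sd in sds:
            flags = []
            for value in np.linspace(0.25, 0.8, 12):
                m, _ = _matrix({"p": [0.25, value]}, ["Birth", "Failed"])
                baselines = pd.DataFrame(
                    {"mean_birth": [0.25], "sd_birth": [sd],
                     "n_birth_covered": [4]},
                    index=pd.Index(["p"], name="promoter_id"))
                calls = em.call_epimutations(m, baselines)
                flags.append(bool(calls[calls["embryo_id"] == 1]
                                  ["is_epimutation"].iloc[0]))
            assert flags == sorted(flags)


class TestFrequencies:
    def _toy_calls(self):
        return pd.DataFrame({
            "embryo_id": ["e1"] * 100 + ["e2"] * 40,
            "promoter_id": [f"p{i}" for i in range(100)] + [f"p{i}" for i in range(40)],
            "is_epimutation": [True, True] + [False] * 98 + [False] * 40,
        })

    def test_embryo_frequency_simple(self):
        freq = em.embryo_epimutation_frequency(self._toy_calls())
        assert freq["e1"] == pytest.approx(0.02)
        assert freq["e2"] == 0.0

    def test_embryo_frequency_matches_recount(self):
        calls = self._toy_calls()
        freq = em.embryo_epimutation_frequency(calls)
        for e in ("e1", "e2"):
            sub = calls[calls["embryo_id"] == e]
            assert freq[e] == pytest.approx(
                sum(sub["is_epimutation"]) / len(sub))

    def test_group_frequency_and_relabel_symmetry(self):
        calls = pd.DataFrame({
            "embryo_id": ["b1", "b2", "f1", "f2", "f3"],
            "promoter_id": ["p"] * 5,
            "is_epimutation": [False, True, True, True, False],
        })
        labels = pd.Series({"b1": "Birth", "b2": "Birth", "f1": "Failed",
                            "f2": "Failed", "f3": "Failed"})
        tab = em.promoter_group_frequency(calls, labels)
        assert tab.loc["p", "birth_freq"] == pytest.approx(0.5)
        assert tab.loc["p", "failed_freq"] == pytest.approx(2 / 3)
        swapped = labels.map({"Birth": "Failed", "Failed": "Birth"})
        tab2 = em.promoter_group_frequency(calls, swapped)
        assert tab2.loc["p", "birth_freq"] == pytest.approx(2 / 3)
        assert tab2.loc["p", "failed_freq"] == pytest.approx(0.5)

    def test_uncovered_group_is_contract_error(self):
        calls = pd.DataFrame({"embryo_id": ["f1"], "promoter_id": ["p"],
                              "is_epimutation": [True]})
        labels = pd.Series({"f1": "Failed", "b1": "Birth"})
        with pytest.raises(ValueError, match="filter_covered_promoters"):
            em.promoter_group_frequency(calls, labels)


class TestDifferential:
    def _freqs(self, b_epi, b_cov, f_epi, f_cov):
        return pd.DataFrame({"birth_epi": [b_epi], "birth_covered": [b_cov],
                             "failed_epi": [f_epi], "failed_covered": [f_cov],
                             "birth_freq": [b_epi / b_cov],
                             "failed_freq": [f_epi / f_cov]},
                            index=pd.Index(["p"], name="promoter_id"))

    def test_matches_enumeration_oracle(self):
        out = em.differential_epimutation(self._freqs(0, 10, 5, 10))
        assert out.loc["p", "diff"] == pytest.approx(0.5)
        assert out.loc["p", "p_value"] == pytest.approx(
            fisher_enumeration(5, 5, 0, 10, "two-sided"))

    def test_identical_counts_p_one(self):
        out = em.differential_epimutation(self._freqs(3, 10, 3, 10))
        assert out.loc["p", "diff"] == 0.0
        assert out.loc["p", "p_value"] == pytest.approx(1.0)

    def test_swapping_groups_negates_difference(self):
        a = em.differential_epimutation(self._freqs(1, 12, 6, 11))
        b = em.differential_epimutation(self._freqs(6, 11, 1, 12))
        assert a.loc["p", "diff"] == pytest.approx(-b.loc["p", "diff"])
        assert a.loc["p", "p_value"] == pytest.approx(b.loc["p", "p_value"])


class TestOnSyntheticCohorts:
    def test_null_cohorts_control_false_positive_rate(self):
        # both groups drawn identically: share of p<0.05 promoters stays <=8%
        fracs = []
        for seed in range(20):
            cfg = synthetic_cohort.CohortConfig(
                n_patients=20, n_promoters=80, cpgs_per_promoter=4,
                n_background_cpgs=50, glm_slope=0.0,
                epimut_rate_birth=0.05, epimut_rate_failed=0.05,
                label_flip_rate=0.0, seed=300 + seed)
            cohort = synthetic_cohort.generate_cohort(cfg)
            m = cohort.promoter_matrix()
            labels = cohort.samples.set_index("embryo_id")["outcome"]
            if labels.value_counts().min() < 3:
                continue
            kept = em.filter_covered_promoters(m, labels)
            baselines = em.promoter_baselines(m, labels, promoters=kept)
            calls = em.call_epimutations(m, baselines)
            diff = em.differential_epimutation(
                em.promoter_group_frequency(calls, labels))
            fracs.append((diff["p_value"] < 0.05).mean())
        assert np.mean(fracs) <= 0.08

    def test_planted_signal_failed_excess(self):
        # defaults plant more epimutations in failed embryos; at n=160 the
        # per-embryo frequency difference is detectable by a rank-sum test
        cfg = synthetic_cohort.CohortConfig(
            n_patients=80, embryos_min=2, embryos_max=2,
            n_promoters=200, cpgs_per_promoter=4, n_background_cpgs=100,
            label_flip_rate=0.0, seed=77)
        cohort = synthetic_cohort.generate_cohort(cfg)
        m = cohort.promoter_matrix()
        labels = cohort.samples.set_index("embryo_id")["outcome"]
        kept = em.filter_covered_promoters(m, labels)
        baselines = em.promoter_baselines(m, labels, promoters=kept)
        calls = em.call_epimutations(m, baselines)
        freq = em.embryo_epimutation_frequency(calls)
        birth = freq[labels.loc[freq.index] == "Birth"]
        failed = freq[labels.loc[freq.index] == "Failed"]
        assert failed.mean() > birth.mean()
        p = stats.mannwhitneyu(failed, birth, alternative="two-sided").pvalue
        assert p < 0.05
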