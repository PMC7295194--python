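"""Analysis stage: tables, refractive gain, RM-ANOVA vs oracles, t-tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from blursim.analysis import (
    IncompleteDesignError,
    InvalidDataError,
    _pivot,
    compute_tables,
    gain_tests,
    posthoc_pairwise,
    refractive_gain,
    rm_anova_threeway,
)
from blursim.conditions import BLUR_LEVELS, CUE_LEVELS, LOCATIONS
from blursim.experiment import Dataset, ExperimentConfig


def projection_rm_anova(y):
    """Independent oracle: within-subject ANOVA via explicit orthonormal
    design-matrix projections (subject x A x B x C data cube)."""

    def centered_basis(levels):
        m = np.eye(levels) - 1.0 / levels
        u = np.linalg.svd(m)[0]
        return u[:, : levels - 1]

    def ones_basis(levels):
        return np.ones((levels, 1)) / np.sqrt(levels)

    shape = y.shape  # (n, la, lb, lc)
    yv = y.reshape(-1)
    names = ("location", "blur", "cue")
    out = {}
    for r in range(1, 4):
        for combo in itertools.combinations(range(1, 4), r):

            def block(subject_centered):
                mats = []
                for axis in range(4):
                    centered = (axis in combo) or (axis == 0 and subject_centered)
                    basis = centered_basis if centered else ones_basis
                    mats.append(basis(shape[axis]))
                z = mats[0]
                for m in mats[1:]:
                    z = np.kron(z, m)
                return z

            ss_effect = float(((block(False).T @ yv) ** 2).sum())
            ss_error = float(((block(True).T @ yv) ** 2).sum())
            df_effect = int(np.prod([shape[a] - 1 for a in combo]))
            df_error = df_effect * (shape[0] - 1)
            f_stat = (ss_effect / df_effect) / (ss_error / df_error)
            eta = ss_effect / (ss_effect + ss_error)
            key = ":".join(names[a - 1] for a in combo)
            out[key] = dict(F=f_stat, df=(df_effect, df_error), eta=eta)
    return out


def toy_table(n_subjects, locations, seed):
    gen = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for loc in locations:
            for blur in BLUR_LEVELS:
                for cue in CUE_LEVELS:
                    rows.append(
                        dict(subject=f"S{s + 1}", location=loc, blur=blur, cue=cue,
                             mad=gen.normal(5.0, 1.0), rt=gen.normal(400.0, 25.0))
                    )
    return pd.DataFrame(rows)


class TestComputeTables:
    def _dataset(self, session_mads):
        est_rows, trial_rows = [], []
        for s in range(2):
            for loc in LOCATIONS:
                for blur in BLUR_LEVELS:
                    for cue in CUE_LEVELS:
                        for sess, mad in enumerate(session_mads):
                            est_rows.append(
                                dict(subject=f"S{s + 1}", session=sess, location=loc,
                                     blur=blur, cue=cue, mad_arcmin=mad,
                                     n_reversals_used=8, n_trials=30)
                            )
                        for i, correct in enumerate([True, True, False]):
                            trial_rows.append(
                                dict(subject=f"S{s + 1}", session=0, trial=i,
                                     location=loc, blur=blur, cue=cue,
                                     cue_location=loc, level_arcmin=4.0,
                                     correct=correct, rt_ms=300.0 + 100 * i,
                                     cue_onset_ms=0.0, target_onset_ms=116.0,
                                     target_offset_ms=149.0, feedback="correct")
                            )
        return Dataset(pd.DataFrame(trial_rows), pd.DataFrame(est_rows),
                       ExperimentConfig())

    def test_mad_is_mean_over_sessions(self):
        table = compute_tables(self._dataset([2.0, 4.0]))
        assert np.allclose(table["mad"], 3.0)
        assert len(table) == 2 * 16

    def test_rt_uses_correct_trials_only(self):
        table = compute_tables(self._dataset([3.0]))
        # correct trials have RT 300 and 400; the 500 ms error trial is excluded
        assert np.allclose(table["rt"], 350.0)

    def test_missing_cell_rejected(self):
        dataset = self._dataset([2.0, 4.0])
        dataset.estimates = dataset.estimates.iloc[:-2]
        with pytest.raises(IncompleteDesignError):
            compute_tables(dataset)


class TestRefractiveGain:
    def test_equal_blur_levels_give_unit_gain(self):
        table = toy_table(3, LOCATIONS, seed=1)
        table["mad"] = 4.0
        gains = refractive_gain(table)
        assert np.allclose(gains["rx"], 1.0)

    def test_ratio_of_cue_averaged_mads(self):
        table = toy_table(1, LOCATIONS, seed=2)
        table["mad"] = np.where(table["blur"] == "blurred", 2.0, 1.0)
        gains = refractive_gain(table)
        assert np.allclose(gains["rx"], 2.0)
        assert len(gains) == len(LOCATIONS)

    def test_zero_clear_mad_rejected(self):
        table = toy_table(2, LOCATIONS, seed=3)
        table.loc[table["blur"] == "clear", "mad"] = 0.0
        with pytest.raises(InvalidDataError):
            refractive_gain(table)


class TestRmAnova:
    def test_reported_degrees_of_freedom(self, random_threshold_table):
        results = rm_anova_threeway(random_threshold_table, "mad")
        assert (results["location"].df_effect, results["location"].df_error) == (3, 12)
        assert (results["blur"].df_effect, results["blur"].df_error) == (1, 4)
        assert (results["cue"].df_effect, results["cue"].df_error) == (1, 4)
        assert (
            results["location:blur:cue"].df_effect,
            results["location:blur:cue"].df_error,
        ) == (3, 12)

    def test_constant_data_degenerates_to_zero_f(self):
        table = toy_table(3, LOCATIONS, seed=4)
        table["mad"] = 7.0
        results = rm_anova_threeway(table, "mad")
        for res in results.values():
            assert res.F == 0.0 and res.p == 1.0 and res.partial_eta_sq == 0.0

    @pytest.mark.parametrize(
        "n_subjects, locations, seed",
        [
            (2, ("nasal", "temporal"), 10),
            (5, LOCATIONS, 11),
            (4, ("nasal", "superior", "inferior"), 12),
        ],
    )
    def test_matches_projection_oracle(self, n_subjects, locations, seed):
        table = toy_table(n_subjects, locations, seed)
        y, _, _ = _pivot(table, "mad")
        oracle = projection_rm_anova(y)
        results = rm_anova_threeway(table, "mad")
        for name, expected in oracle.items():
            res = results[name]
            assert res.F == pytest.approx(expected["F"], abs=1e-10)
            assert (res.df_effect, res.df_error) == expected["df"]
            assert res.partial_eta_sq == pytest.approx(expected["eta"], abs=1e-10)

    def test_matches_statsmodels_anova_rm(self, random_threshold_table):
        AnovaRM = pytest.importorskip("statsmodels.stats.anova").AnovaRM
        sm = (
            AnovaRM(random_threshold_table, "mad", "subject",
                    within=["location", "blur", "cue"])
            .fit()
            .anova_table
        )
        results = rm_anova_threeway(random_threshold_table, "mad")
        for name, res in results.items():
            assert res.F == pytest.approx(sm.loc[name, "F Value"], abs=1e-9)
            assert res.df_effect == int(sm.loc[name, "Num DF"])
            assert res.df_error == int(sm.loc[name, "Den DF"])

    def test_within_subject_ss_decomposition(self, random_threshold_table):
        results = rm_anova_threeway(random_threshold_table, "mad")
        y, _, _ = _pivot(random_threshold_table, "mad")
        subject_means = y.mean(axis=(1, 2, 3), keepdims=True)
        total_within = float(((y - subject_means) ** 2).sum())
        decomposed = sum(r.ss_effect + r.ss_error for r in results.values())
        assert decomposed == pytest.approx(total_within, rel=1e-9)

    def test_incomplete_table_rejected(self, random_threshold_table):
        with pytest.raises(IncompleteDesignError):
            rm_anova_threeway(random_threshold_table.iloc[:-1], "mad")

    def test_sphericity_correction_adjusts_df_not_f(self, random_threshold_table):
        plain = rm_anova_threeway(random_threshold_table, "mad")
        corrected = rm_anova_threeway(
            random_threshold_table, "mad", sphericity_correction=True
        )
        for name in plain:
            assert corrected[name].F == pytest.approx(plain[name].F)
            if plain[name].df_effect == 1:  # two levels: epsilon is exactly 1
                assert corrected[name].p == pytest.approx(plain[name].p)
            elif plain[name].F > 1:  # df shrinkage can only raise p here
                assert corrected[name].p >= plain[name].p - 1e-12


class TestPosthoc:
    def test_identical_marginals_give_null_result(self):
        table = toy_table(4, LOCATIONS, seed=20)
        table["mad"] = 5.0
        for res in posthoc_pairwise(table, "location", "mad"):
            assert res.t == 0.0 and res.p == 1.0

    def test_four_level_factor_gives_six_comparisons(self, random_threshold_table):
        assert len(posthoc_pairwise(random_threshold_table, "location", "mad")) == 6

    def test_hand_computed_paired_t(self):
        # subject-level clear-blurred differences {1, 2, 3}: t = 2 sqrt(3), df 2
        table = toy_table(3, LOCATIONS, seed=21)
        table["mad"] = 5.0
        for i, subject in enumerate(["S1", "S2", "S3"]):
            rows = (table["subject"] == subject) & (table["blur"] == "clear")
            table.loc[rows, "mad"] = 5.0 + (i + 1)
        (res,) = posthoc_pairwise(table, "blur", "mad")
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert res.df == 2
        assert res.mean_diff == pytest.approx(2.0)

    def test_bonferroni_never_lowers_p(self, random_threshold_table):
        from scipy import stats

        marginals = (
            random_threshold_table.groupby(["subject", "location"])["mad"]
            .mean()
            .unstack("location")
        )
        for res in posthoc_pairwise(random_threshold_table, "location", "mad"):
            a, b = res.label.split(" vs ")
            raw = stats.ttest_rel(marginals[a], marginals[b]).pvalue
            assert res.p >= raw - 1e-12

    def test_single_subject_rejected(self):
        table = toy_table(1, LOCATIONS, seed=22)
        with pytest.raises(InvalidDataError):
            posthoc_pairwise(table, "location", "mad")


class TestGainTests:
    def test_unit_gains_give_null_statistics(self):
        gains = pd.DataFrame(
            [
                dict(subject=f"S{s}", location=loc, rx=1.0)
                for s in range(4)
                for loc in LOCATIONS
            ]
        )
        for res in gain_tests(gains):
            assert res.t == 0.0 and res.mean_diff == 0.0

    def test_hand_computed_one_sample_t(self):
        # rx {1.1..1.5} vs 1.0: mean diff 0.3, sd .1581, t = 4.2426, df 4
        gains = pd.DataFrame(
            [
                dict(subject=f"S{s}", location=loc, rx=1.1 + 0.1 * s)
                for s in range(5)
                for loc in LOCATIONS
            ]
        )
        res = next(r for r in gain_tests(gains) if "temporal" in r.label)
        assert res.mean_diff == pytest.approx(0.3)
        assert res.t == pytest.approx(0.3 / (np.std([1.1, 1.2, 1.3, 1.4, 1.5], ddof=1)
                                              / np.sqrt(5)), abs=1e-12)
        assert res.df == 4
        assert res.ci_low <= res.mean_diff <= res.ci_high

    def test_equal_meridians_give_zero_paired_t(self, rng):
        gains = pd.DataFrame(
            [
                dict(subject=f"S{s}", location=loc,
                     rx=1.2 + 0.05 * s)  # same value in all locations per subject
                for s in range(5)
                for loc in LOCATIONS
            ]
        )
        meridian = next(r for r in gain_tests(gains) if "meridian" in r.label)
        assert meridian.t == 0.0

    def test_missing_location_rejected(self):
        gains = pd.DataFrame(
            [dict(subject=f"S{s}", location="nasal", rx=1.2) for s in range(5)]
        )
        with pytest.raises(IncompleteDesignError):
            gain_tests(gains)
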