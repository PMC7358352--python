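"""Per-patient pipeline, exact signed-rank test, and cohort aggregation."""

import numpy as np
import pytest
from scipy import stats

from secmal import (
    DifferentialDVH,
    GeneratorConfig,
    PatientPair,
    PlanDose,
    REDModel,
    compute_patient,
    dasu_organ_risk,
    flag_rr_exceedances,
    generate_cohort,
    oed,
    paired_signed_rank,
    summarize_cohort,
)
from secmal.cohort import PatientResult
from secmal.errors import InsufficientDataError, NoInformationError, SecmalError

FEMALE_ORGANS = ("lung_right", "lung_left", "breast_right", "breast_left", "esophagus")


def uniform_plan(modality, dose_by_organ, n=18, rx=36.0):
    dvhs = {
        organ: DifferentialDVH(organ, np.array([float(dose)]), np.array([1.0]))
        for organ, dose in dose_by_organ.items()
    }
    return PlanDose(modality, n, rx, dvhs)


def make_pair(pid, proton_dose, photon_dose, organs=FEMALE_ORGANS, sex="female"):
    return PatientPair(
        pid,
        sex,
        uniform_plan("proton", {o: proton_dose for o in organs}),
        uniform_plan("photon", {o: photon_dose for o in organs}),
    )


# ---------------------------------------------------------------------------
# signed-rank test
# ---------------------------------------------------------------------------


def brute_force_signed_rank(x, y):
    """Exhaustive 2^n enumeration of the signed-rank null (independent oracle)."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    ws = np.array(
        [
            sum(r for i, r in enumerate(ranks) if (mask >> i) & 1)
            for mask in range(2**n)
        ]
    )
    cdf = np.mean(ws <= w_obs + 1e-9)
    sf = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(cdf, sf))


class TestPairedSignedRank:
    def test_all_positive_differences_hit_the_exact_floor(self):
        y = np.arange(23, dtype=float)
        assert paired_signed_rank(y + 1.0, y) == pytest.approx(2.0 / 2**23, rel=1e-12)

    def test_identical_samples_carry_no_information(self):
        with pytest.raises(NoInformationError):
            paired_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_too_few_informative_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [1.0, 2.0, 2.5, 3.5, 4.5, 5.5]  # only 4 nonzero differences
        with pytest.raises(InsufficientDataError):
            paired_signed_rank(x, y)

    def test_six_differences_match_enumeration(self):
        y = np.zeros(6)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -1.0])
        assert paired_signed_rank(x, y) == pytest.approx(
            brute_force_signed_rank(x, y), rel=1e-12
        )

    @pytest.mark.parametrize("trial", range(6))
    def test_random_vectors_with_ties_and_zeros_match_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(6, 13))
        d = rng.integers(-3, 4, size=n).astype(float)  # many ties, some zeros
        if np.count_nonzero(d) < 5:
            d[:5] = [1, -2, 2, 3, -1]
        y = rng.normal(size=n)
        assert paired_signed_rank(y + d, y) == pytest.approx(
            brute_force_signed_rank(y + d, y), rel=1e-12
        )

    def test_tie_free_case_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=15), rng.normal(size=15)
        expected = stats.wilcoxon(x, y, method="exact", alternative="two-sided").pvalue
        assert paired_signed_rank(x, y) == pytest.approx(expected, rel=1e-12)

    def test_large_sample_uses_corrected_normal_approximation(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(0.4, 1.0, size=40), rng.normal(size=40)
        expected = stats.wilcoxon(
            x, y, method="approx", correction=True, alternative="two-sided"
        ).pvalue
        assert paired_signed_rank(x, y) == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# per-patient computation
# ---------------------------------------------------------------------------


class TestComputePatient:
    def test_identical_plans_are_symmetric(self, coeffs):
        result = compute_patient(make_pair("p1", 10.0, 10.0), coeffs)
        assert all(v == pytest.approx(1.0) for v in result.rr.values())
        for organ in FEMALE_ORGANS:
            for kind in ("total", "fatal"):
                assert result.dasu_risk[(organ, "proton", kind)] == result.dasu_risk[
                    (organ, "photon", kind)
                ]

    def test_fully_spared_proton(self, coeffs):
        result = compute_patient(make_pair("p1", 0.0, 10.0), coeffs)
        assert all(v == 0.0 for v in result.rr.values())
        assert all(
            v == 0.0 for (_, m, _), v in result.dasu_risk.items() if m == "proton"
        )
        assert not result.rr_excluded

    def test_both_modalities_spared_excludes_rr(self, coeffs):
        result = compute_patient(make_pair("p1", 0.0, 0.0), coeffs)
        assert not result.rr
        assert len(result.rr_excluded) == 3 * len(FEMALE_ORGANS)

    def test_matches_componentwise_model_calls(self, coeffs):
        pairs, _ = generate_cohort(GeneratorConfig(n_patients=1, n_female=1, seed=1))
        pair = pairs[0]
        result = compute_patient(pair, coeffs)
        for organ in pair.organs:
            c = coeffs[organ]
            for modality, plan in (("proton", pair.proton), ("photon", pair.photon)):
                dvh = plan.dvhs[organ]
                for kind in ("total", "fatal"):
                    assert result.dasu_risk[(organ, modality, kind)] == pytest.approx(
                        dasu_organ_risk(dvh, plan.n_fractions, c, kind).risk, rel=1e-14
                    )
                for variant in REDModel:
                    assert result.oed[(organ, modality, variant.value)] == pytest.approx(
                        oed(dvh, variant, c, plan.n_fractions).oed, rel=1e-14
                    )
            for variant in REDModel:
                expected = result.oed[(organ, "proton", variant.value)] / result.oed[
                    (organ, "photon", variant.value)
                ]
                assert result.rr[(organ, variant.value)] == pytest.approx(expected)

    def test_combined_risks_are_sided_sums(self, coeffs):
        doses = {"lung_right": 4.0, "lung_left": 9.0, "breast_right": 2.0,
                 "breast_left": 7.0, "esophagus": 3.0}
        pair = PatientPair(
            "p1",
            "female",
            uniform_plan("proton", doses),
            uniform_plan("photon", {o: d * 2 for o, d in doses.items()}),
        )
        result = compute_patient(pair, coeffs)
        for group, (right, left) in (("lung", ("lung_right", "lung_left")),
                                     ("breast", ("breast_right", "breast_left"))):
            for modality in ("proton", "photon"):
                for kind in ("total", "fatal"):
                    assert abs(
                        result.combined[(group, modality, kind)]
                        - result.dasu_risk[(right, modality, kind)]
                        - result.dasu_risk[(left, modality, kind)]
                    ) < 1e-12


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------


class TestSummarizeCohort:
    def test_single_patient_degenerate_statistics(self, coeffs):
        summary = summarize_cohort([compute_patient(make_pair("p1", 3.0, 9.0), coeffs)])
        assert (summary.risk_stats["median"] == summary.risk_stats["min"]).all()
        assert (summary.risk_stats["median"] == summary.risk_stats["max"]).all()
        assert summary.tests["p_value"].isna().all()
        assert (summary.tests["note"] != "").all()

    def test_three_patient_median_is_middle_element(self, coeffs):
        results = [
            compute_patient(make_pair(f"p{i}", d, 2 * d), coeffs)
            for i, d in enumerate([2.0, 4.0, 8.0])
        ]
        summary = summarize_cohort(results)
        row = summary.oed_stats.query(
            "organ == 'esophagus' and variant == 'linear' and modality == 'proton'"
        ).iloc[0]
        assert (row["median"], row["min"], row["max"]) == (4.0, 2.0, 8.0)

    def test_combined_median_is_median_of_sums(self, coeffs):
        # per-side risks anti-correlated across patients: the median of the
        # per-patient sums differs from the sum of per-side medians
        doses = [(2.0, 20.0), (10.0, 10.0), (20.0, 2.0)]
        results = []
        for i, (dr, dl) in enumerate(doses):
            pair = PatientPair(
                f"p{i}",
                "female",
                uniform_plan("proton", {"lung_right": dr, "lung_left": dl,
                                        "breast_right": 1.0, "breast_left": 1.0,
                                        "esophagus": 1.0}),
                uniform_plan("photon", {"lung_right": 2 * dr, "lung_left": 2 * dl,
                                        "breast_right": 2.0, "breast_left": 2.0,
                                        "esophagus": 2.0}),
            )
            results.append(compute_patient(pair, coeffs))
        summary = summarize_cohort(results)
        sums = [r.combined[("lung", "proton", "total")] for r in results]
        row = summary.risk_stats.query(
            "organ == 'lung_combined' and quantity == 'total_risk' and modality == 'proton'"
        ).iloc[0]
        assert row["median"] == pytest.approx(float(np.median(sums)), rel=1e-14)
        side_medians = summary.risk_stats.query(
            "organ in ('lung_right', 'lung_left') and quantity == 'total_risk' "
            "and modality == 'proton'"
        )["median"].sum()
        assert row["median"] != pytest.approx(side_medians, rel=1e-6)

    def test_empty_cohort_rejected(self):
        with pytest.raises(SecmalError):
            summarize_cohort([])


class TestFlagExceedances:
    def test_strictly_greater_than_one(self):
        r1 = PatientResult("p1", "female")
        r1.rr[("esophagus", "linear")] = 1.0  # boundary: not flagged
        r1.rr[("breast_right", "linear")] = 0.4
        r2 = PatientResult("p2", "female")
        r2.rr[("esophagus", "linear")] = 1.01
        r2.rr[("esophagus", "plateau")] = 1.2
        assert flag_rr_exceedances([r1, r2]) == [
            ("p2", "esophagus", "linear"),
            ("p2", "esophagus", "plateau"),
        ]

    def test_all_below_one_is_empty(self):
        r = PatientResult("p1", "female")
        r.rr[("lung_left", "linear")] = 0.5
        assert flag_rr_exceedances([r]) == []
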