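"""Clinical evaluation statistics against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from oracles import (
    bland_altman,
    paired_t_p,
    pearson_r_p,
    welch_t_p,
    wilcoxon_exact_p,
)
from pulsesv.clineval import (
    AveragedPatient,
    PatientRecord,
    agreement,
    average_repeats,
    cohort_vs_population_tests,
    coherence_filter,
    compare_settings,
)


def make_record(**overrides) -> PatientRecord:
    base = dict(
        id="P001", age_group=">70", gender="F", height=162.0, weight=60.0,
        sbp_pwv=[120.0, 124.0, 122.0], dbp_pwv=[70.0, 72.0, 74.0],
        hr_pwv=[70.0, 72.0, 68.0], pwv=[9.5, 10.5],
        sbp_cath=[125.0, 127.0, 126.0], dbp_cath=[75.0, 77.0, 76.0],
        hr_cath=[62.0, 62.0, 62.0], co_thermo_lmin=4.6,
    )
    base.update(overrides)
    return PatientRecord(**base)


def make_averaged(i, map_pwv, map_cath, hr_pwv, hr_cath, sv=75.0,
                  **extra) -> AveragedPatient:
    kw = dict(
        id=f"P{i:03d}", age_group=">70", gender="M", height=170.0,
        weight=75.0, sbp_pwv=120.0, dbp_pwv=70.0, pp_pwv=50.0,
        map_pwv=map_pwv, hr_pwv=hr_pwv, cfpwv=10.0, sbp_cath=122.0,
        dbp_cath=72.0, pp_cath=50.0, map_cath=map_cath, hr_cath=hr_cath,
        sv_reference=sv,
    )
    kw.update(extra)
    return AveragedPatient(**kw)


class TestAverageRepeats:
    def test_means_and_derived_quantities(self):
        avg = average_repeats(make_record())
        assert avg.sbp_pwv == pytest.approx(122.0)
        assert avg.cfpwv == pytest.approx(10.0)
        # cuff MAP convention: DBP + PP/3
        assert avg.map_pwv == pytest.approx(72.0 + 50.0 / 3.0)
        # thermodilution SV = CO*1000/HR at catheterization
        assert avg.sv_reference == pytest.approx(4600.0 / 62.0)

    def test_single_repeat_tolerated(self):
        avg = average_repeats(make_record(hr_pwv=[71.0]))
        assert avg.hr_pwv == 71.0

    def test_empty_repeats_rejected(self):
        with pytest.raises(ValueError, match="no repeats"):
            average_repeats(make_record(sbp_cath=[]))
        with pytest.raises(ValueError, match="CO"):
            average_repeats(make_record(co_thermo_lmin=-1.0))


class TestCoherenceFilter:
    def test_small_discrepancies_kept(self):
        p = make_averaged(1, map_pwv=88.0, map_cath=91.0, hr_pwv=71.0,
                          hr_cath=68.0)
        diag = coherence_filter([p])
        assert diag.kept == [p] and diag.excluded == []
        assert diag.table["rel_diff_map"].iloc[0] == pytest.approx(3 / 91)
        assert diag.table["rel_diff_hr"].iloc[0] == pytest.approx(3 / 68)

    def test_large_map_discrepancy_excluded(self):
        p = make_averaged(1, map_pwv=60.0, map_cath=91.0, hr_pwv=70.0,
                          hr_cath=70.0)
        diag = coherence_filter([p])
        assert diag.excluded == [p]
        assert diag.table["rel_diff_map"].iloc[0] > 0.25

    def test_huge_threshold_keeps_everyone(self):
        ps = [
            make_averaged(i, 60.0 + i * 10, 95.0, 50.0 + i * 5, 80.0)
            for i in range(5)
        ]
        diag = coherence_filter(ps, threshold=np.inf)
        assert diag.kept == ps

    def test_partition_disjoint_exhaustive_idempotent(self):
        rng = np.random.default_rng(0)
        ps = [
            make_averaged(
                i, rng.uniform(60, 110), rng.uniform(60, 110),
                rng.uniform(50, 90), rng.uniform(50, 90),
            )
            for i in range(40)
        ]
        diag = coherence_filter(ps)
        assert len(diag.kept) + len(diag.excluded) == len(ps)
        assert not (set(map(id, diag.kept)) & set(map(id, diag.excluded)))
        again = coherence_filter(diag.kept)
        assert again.kept == diag.kept and again.excluded == []

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            coherence_filter([], threshold=0.0)


class TestAgreement:
    def test_identity_input(self):
        rep = agreement([60.0, 80.0, 100.0], [60.0, 80.0, 100.0])
        assert rep.pearson_r == 1.0
        assert rep.mae == rep.rmse == rep.bias == 0.0
        assert rep.loa_low == rep.loa_high == 0.0
        assert rep.wilcoxon_p == 1.0

    def test_hand_computed_example(self):
        rep = agreement([60.0, 80.0, 100.0], [50.0, 80.0, 110.0])
        assert rep.mae == pytest.approx(20.0 / 3.0)
        assert rep.rmse == pytest.approx(np.sqrt(200.0 / 3.0))
        assert rep.nrmse == pytest.approx(np.sqrt(200.0 / 3.0) / 40.0)
        assert rep.bias == pytest.approx(0.0)
        assert rep.loa_high == pytest.approx(1.96 * np.sqrt(200.0 / 3.0))
        assert rep.loa_high - rep.loa_low == pytest.approx(
            2 * 1.96 * np.sqrt(200.0 / 3.0)
        )

    def test_bias_sign_convention(self):
        """Predictions below the reference give a negative bias."""
        rng = np.random.default_rng(1)
        ref = rng.uniform(50, 110, 20)
        rep = agreement(ref, ref - 9.2)
        assert rep.bias == pytest.approx(-9.2)
        assert rep.mean_predicted < rep.mean_reference

    def test_matches_bruteforce_oracle_on_random_arrays(self):
        """agreement() equals direct formula evaluation to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(5, 14))
            ref = rng.uniform(40.0, 130.0, n)
            pred = ref + rng.normal(0, 12.0, n)
            rep = agreement(ref, pred)
            ba = bland_altman(ref, pred)
            for key, val in ba.items():
                assert getattr(rep, key) == pytest.approx(val, abs=1e-10)
            r, p = pearson_r_p(ref, pred)
            assert rep.pearson_r == pytest.approx(r, abs=1e-10)
            assert rep.p_value_r == pytest.approx(p, abs=1e-10)
            assert rep.wilcoxon_p == pytest.approx(
                wilcoxon_exact_p(pred, ref), abs=1e-10
            )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="range"):
            agreement([80.0, 80.0, 80.0], [70.0, 80.0, 90.0])
        with pytest.raises(ValueError, match="3"):
            agreement([80.0, 90.0], [70.0, 80.0])


class TestCompareSettings:
    def test_identical_settings(self):
        ps = [
            make_averaged(i, 90.0, 90.0, 70.0, 70.0,
                          sbp_pwv=120.0, sbp_cath=120.0,
                          dbp_pwv=70.0, dbp_cath=70.0)
            for i in range(5)
        ]
        table = compare_settings(ps).set_index("quantity")
        assert (table["mean_abs_diff"] == 0).all()
        assert table["paired_t_p"].isna().all()

    def test_constant_offset(self):
        ps = [
            make_averaged(i, 90.0, 90.0, 70.0, 70.0,
                          sbp_pwv=120.0 + i, sbp_cath=125.0 + i)
            for i in range(6)
        ]
        row = compare_settings(ps).set_index("quantity").loc["sbp"]
        assert row["mean_abs_diff"] == pytest.approx(5.0)
        assert row["sd_abs_diff"] == pytest.approx(0.0)
        assert row["min_abs_diff"] == row["max_abs_diff"] == 5.0

    def test_paired_t_matches_oracle(self):
        rng = np.random.default_rng(9)
        ps = [
            make_averaged(
                i, rng.uniform(80, 100), rng.uniform(80, 100),
                rng.uniform(60, 80), rng.uniform(60, 80),
            )
            for i in range(12)
        ]
        table = compare_settings(ps).set_index("quantity")
        x = np.array([p.map_pwv for p in ps])
        y = np.array([p.map_cath for p in ps])
        assert table.loc["map", "paired_t_p"] == pytest.approx(
            paired_t_p(x, y), abs=1e-10
        )
        assert ((table["paired_t_p"] >= 0) & (table["paired_t_p"] <= 1)).all()

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            compare_settings([make_averaged(1, 90, 90, 70, 70)])


class TestWelch:
    def test_identical_large_samples(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 5000)
        res = cohort_vs_population_tests(a, a.copy())
        assert res.pvalue == pytest.approx(1.0)

    def test_separated_populations_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, 9996)
        b = rng.normal(5.0, 1.0, 27)
        assert cohort_vs_population_tests(a, b).pvalue < 1e-3

    def test_symmetry_and_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(55.0, 18.0, 400)
        b = rng.normal(74.0, 26.0, 24)
        res_ab = cohort_vs_population_tests(a, b)
        res_ba = cohort_vs_population_tests(b, a)
        assert res_ab.pvalue == pytest.approx(res_ba.pvalue, abs=1e-12)
        t, p = welch_t_p(a, b)
        assert res_ab.statistic == pytest.approx(t, abs=1e-10)
        assert res_ab.pvalue == pytest.approx(p, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cohort_vs_population_tests([1.0, 1.0, 1.0], [1.0, 1.0])


def test_wilcoxon_variant_switches_at_sample_size_25():
    """Below n = 25 the implementation must use the exact null
    distribution; the continuity-corrected normal approximation differs."""
    rng = np.random.default_rng(7)
    ref = rng.uniform(50, 110, 20)
    pred = ref + rng.normal(3, 8, 20)
    rep = agreement(ref, pred)
    exact = stats.wilcoxon(pred, ref, method="exact").pvalue
    assert rep.wilcoxon_p == pytest.approx(exact, abs=1e-12)
    ref = rng.uniform(50, 110, 40)
    pred = ref + rng.normal(3, 8, 40)
    rep = agreement(ref, pred)
    approx = stats.wilcoxon(
        pred, ref, method="approx", correction=True
    ).pvalue
    assert rep.wilcoxon_p == pytest.approx(approx, abs=1e-12)
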