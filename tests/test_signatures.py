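"""Floor preprocessing, paired statistics, and the three selection methods."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from repscreen import (
    SimulationConfig,
    generate_paired_cohort,
    leave_one_out_signatures,
    paired_t,
    preprocess_floor,
    probe_log_ratios,
    select_sam,
    select_top_n,
    select_volcano,
)
from repscreen.errors import EmptySignatureError, InputError

from conftest import make_cohort


class TestFloor:
    def test_sub_floor_values_rounded_up_to_50(self):
        cohort = make_cohort([[10.0, 50.0], [50.0, 51.0], [51.0, 200.0]])
        out = preprocess_floor(cohort)
        assert np.array_equal(out.intensities[:, 0], [50.0, 50.0, 51.0])
        assert out.floor_applied

    def test_identity_when_all_above_floor(self):
        cohort = make_cohort([[60.0, 70.0], [80.0, 90.0]])
        out = preprocess_floor(cohort)
        assert np.array_equal(out.intensities, cohort.intensities)

    def test_floor_one_is_identity_on_positive_data(self):
        cohort = make_cohort([[2.0, 3.0], [4.0, 5.0]])
        out = preprocess_floor(cohort, floor=1.0)
        assert np.array_equal(out.intensities, cohort.intensities)


class TestLogRatios:
    def test_constant_twofold_change(self):
        cohort = make_cohort([[200.0, 100.0, 200.0, 100.0]])
        mean_ratio, diffs = probe_log_ratios(cohort)
        assert mean_ratio[0] == pytest.approx(1.0)
        assert np.allclose(diffs, 1.0)

    def test_no_change_gives_zero(self):
        cohort = make_cohort([[100.0, 100.0, 70.0, 70.0]])
        mean_ratio, _ = probe_log_ratios(cohort)
        assert mean_ratio[0] == 0.0

    def test_planted_noiseless_ratio_matches_ground_truth(self, noiseless_cohort):
        mean_ratio, _ = probe_log_ratios(noiseless_cohort)
        idx = {p: i for i, p in enumerate(noiseless_cohort.probe_ids)}
        for p in noiseless_cohort.planted_up:
            assert mean_ratio[idx[p]] == pytest.approx(1.5, abs=1e-9)
        for p in noiseless_cohort.planted_down:
            assert mean_ratio[idx[p]] == pytest.approx(-1.5, abs=1e-9)


class TestTopN:
    def test_six_probe_toy_oracle(self):
        # mean log2 ratios: 2.0, -1.8, 1.2, 0.5, -0.4, 0.0
        base = 100.0
        ratios = [2.0, -1.8, 1.2, 0.5, -0.4, 0.0]
        tumor = base * np.exp2(ratios)
        cohort = preprocess_floor(
            make_cohort(np.column_stack([tumor, [base] * 6, tumor, [base] * 6])),
            floor=1.0,
        )
        sig = select_top_n(cohort, n=3, min_fold=2.0)
        assert set(sig.up) == {"p0", "p2"}
        assert set(sig.down) == {"p1"}

    def test_no_signal_raises_empty_signature_error(self):
        cohort = preprocess_floor(make_cohort(np.full((5, 4), 100.0)), floor=1.0)
        with pytest.raises(EmptySignatureError):
            select_top_n(cohort)

    def test_planted_noiseless_exact_recovery(self, noiseless_cohort):
        sig = select_top_n(noiseless_cohort, n=20)
        assert set(sig.up) == set(noiseless_cohort.planted_up)
        assert set(sig.down) == set(noiseless_cohort.planted_down)

    @given(
        st.integers(min_value=1, max_value=40),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_size_cap_and_disjointness(self, n, seed):
        rng = np.random.default_rng(seed)
        mat = np.exp2(rng.normal(7, 2, size=(30, 8)))
        cohort = preprocess_floor(make_cohort(mat), floor=1.0)
        try:
            sig = select_top_n(cohort, n=n, min_fold=1.5)
        except EmptySignatureError:
            return
        assert sig.size <= n
        assert not set(sig.up) & set(sig.down)


class TestPairedT:
    def test_zero_mean_symmetric(self):
        t, p = paired_t(np.array([1.0, -1.0, 1.0, -1.0]))
        assert t == 0.0 and p == 1.0

    def test_zero_variance_nonzero_mean_degenerate(self):
        t, p = paired_t(np.array([1.0, 1.0, 1.0, 1.0]))
        assert p == 0.0 and np.isinf(t)

    def test_all_zero_differences(self):
        t, p = paired_t(np.zeros(5))
        assert t == 0.0 and p == 1.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_scipy_one_sample_t(self, seed):
        """Independent oracle: scipy's one-sample t on the differences."""
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=rng.integers(3, 30))
        t, p = paired_t(d)
        ref = stats.ttest_1samp(d, 0.0)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_textbook_vector(self):
        d = np.array([2.1, 1.9, 2.0, 2.2, 1.8])
        t, p = paired_t(d)
        # textbook formula: mean 2.0, sd sqrt(0.025), se sd/sqrt(5)
        se = np.sqrt(0.025) / np.sqrt(5)
        assert t == pytest.approx(2.0 / se, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(2.0 / se, df=4), rel=1e-12)


class TestVolcano:
    def test_vacuous_thresholds_select_every_changed_probe(self, noiseless_cohort):
        sig = select_volcano(noiseless_cohort, p_thresh=1.0, min_fold=1.0)
        changed = set(noiseless_cohort.planted_up) | set(noiseless_cohort.planted_down)
        assert set(sig.up) | set(sig.down) == changed

    def test_strong_planted_signal_fully_recovered(self):
        cfg = SimulationConfig(
            n_patients=24, n_probes=2000, n_up=25, n_down=25,
            effect_size=2.0, noise_sd=0.25,
            baseline_mean=10.0, baseline_sd=0.5, seed=17,
        )
        cohort = preprocess_floor(generate_paired_cohort(cfg))
        sig = select_volcano(cohort)
        assert set(sig.up) == set(cohort.planted_up)
        assert set(sig.down) == set(cohort.planted_down)

    def test_monotone_in_thresholds(self, planted_cohort):
        loose = select_volcano(planted_cohort, p_thresh=1.0, min_fold=1.0)
        strict = select_volcano(planted_cohort, p_thresh=1e-4, min_fold=2.0)
        assert set(strict.up) <= set(loose.up)
        assert set(strict.down) <= set(loose.down)


class TestLeaveOneOut:
    def test_one_signature_per_patient(self, planted_cohort):
        sigs = leave_one_out_signatures(planted_cohort)
        assert len(sigs) == planted_cohort.n_patients
        assert {s.source[1] for s in sigs} == set(planted_cohort.patients)

    def test_noiseless_signatures_identical(self, noiseless_cohort):
        sigs = leave_one_out_signatures(noiseless_cohort, p_thresh=1.0, min_fold=1.5)
        first = (set(sigs[0].up), set(sigs[0].down))
        assert all((set(s.up), set(s.down)) == first for s in sigs)
        assert first == (
            set(noiseless_cohort.planted_up),
            set(noiseless_cohort.planted_down),
        )

    def test_single_outlier_probe_dropped_from_exactly_one_signature(self):
        """A probe driven by one patient vanishes only when that patient is
        excluded; direct recomputation is the oracle."""
        rng = np.random.default_rng(0)
        n_pat = 8
        mat = np.exp2(rng.normal(10, 0.02, size=(30, 2 * n_pat)))
        mat[:, 0::2] = mat[:, 1::2]  # null probes: tumor == normal
        # probe 0: log2 ratio 0.9 in every patient except a 2.0 outlier in
        # patient 0 -- the two-fold gate (mean ratio >= 1) passes only while
        # the outlier is included, so leaving patient 0 out drops the probe
        d = 0.9 + rng.normal(0, 0.02, n_pat)
        d[0] = 2.0
        mat[0, 0::2] = mat[0, 1::2] * np.exp2(d)
        cohort = preprocess_floor(make_cohort(mat), floor=1.0)
        sigs = leave_one_out_signatures(cohort, p_thresh=0.01, min_fold=2.0)
        present = {}
        for s in sigs:
            present[s.source[1]] = "p0" in s.up
            # oracle: recompute on the reduced cohort directly
            sub = cohort.drop_patient(s.source[1])
            direct = select_volcano(sub, p_thresh=0.01, min_fold=2.0)
            assert set(direct.up) == set(s.up) and set(direct.down) == set(s.down)
        assert not present["pt0"]
        assert all(v for k, v in present.items() if k != "pt0")

    def test_too_few_patients_rejected(self):
        cohort = preprocess_floor(make_cohort(np.full((4, 6), 100.0)), floor=1.0)
        with pytest.raises(InputError):
            leave_one_out_signatures(cohort)


class TestSam:
    def test_all_zero_differences_calls_nothing(self):
        cohort = preprocess_floor(make_cohort(np.full((20, 10), 100.0)), floor=1.0)
        res, sig = select_sam(cohort, seed=0)
        assert np.all(res.d == 0.0)
        assert res.called == () and sig.is_empty

    def test_seeded_determinism(self, planted_cohort):
        res1, sig1 = select_sam(planted_cohort, seed=9)
        res2, sig2 = select_sam(planted_cohort, seed=9)
        assert res1.called == res2.called
        assert res1.delta == res2.delta
        assert np.array_equal(res1.d, res2.d)
        assert sig1.up == sig2.up and sig1.down == sig2.down

    def test_planted_recovery_below_size_cap(self, planted_cohort):
        res, sig = select_sam(planted_cohort, seed=1)
        planted = set(planted_cohort.planted_up) | set(planted_cohort.planted_down)
        recovered = len(set(res.called) & planted) / len(planted)
        assert recovered >= 0.9
        assert 0 < len(res.called) < 1000
        assert res.fdr_estimate == 0.0

    def test_global_relabel_mirrors_signature(self, planted_cohort):
        """Swapping tumor/normal globally flips every d, so up and down swap."""
        swapped = planted_cohort
        pairing = {p: (n, t) for p, (t, n) in swapped.pairing.items()}
        from dataclasses import replace

        mirrored = replace(planted_cohort, pairing=pairing)
        res_a, sig_a = select_sam(planted_cohort, seed=4)
        res_b, sig_b = select_sam(mirrored, seed=4)
        assert np.allclose(res_a.d, -res_b.d)
        assert set(sig_a.up) == set(sig_b.down)
        assert set(sig_a.down) == set(sig_b.up)

    def test_called_are_extreme_d_values(self, planted_cohort):
        res, sig = select_sam(planted_cohort, seed=2)
        idx = {p: i for i, p in enumerate(planted_cohort.probe_ids)}
        called_d = np.abs([res.d[idx[p]] for p in res.called])
        uncalled = set(planted_cohort.probe_ids) - set(res.called)
        max_uncalled_up = max(
            (res.d[idx[p]] for p in uncalled), default=-np.inf
        )
        assert called_d.min() > 0
        # every called-up probe exceeds every uncalled probe's d
        up_d = [res.d[idx[p]] for p in sig.up]
        assert min(up_d) >= max_uncalled_up
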