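import numpy as np
import pytest
from scipy import stats

from rowkinetics import evaluate as ev


# --- independent single-loop reference implementations ----------------------

def naive_mae(measured, estimated):
    C, T = measured.shape
    total = 0.0
    for c in range(C):
        for t in range(T):
            total += abs(measured[c, t] - estimated[c, t])
    return total / (C * T)


def naive_cmae(measured, estimated):
    C, T = measured.shape
    total = 0.0
    for t in range(T):
        s = 0.0
        for c in range(C):
            s += measured[c, t] - estimated[c, t]
        total += abs(s)
    return total / (C * T)


def naive_determinants(seq):
    peak_idx = 0
    for i in range(len(seq)):
        if seq[i] > seq[peak_idx]:
            peak_idx = i
    t2p = 100.0 * peak_idx / (len(seq) - 1)
    m2p = 100.0 * (sum(seq) / len(seq)) / seq[peak_idx]
    total_area = np.trapezoid(seq)
    before = np.trapezoid(seq[: peak_idx + 1]) if peak_idx > 0 else 0.0
    wr = 100.0 * before / total_area
    return t2p, m2p, wr


class TestInterpDriveGrid:
    def test_constant_sequence(self):
        out = ev.interp_drive_grid(np.full(17, 3.5))
        assert out.shape == (50,)
        np.testing.assert_allclose(out, 3.5)

    def test_linear_ramp_exact(self):
        out = ev.interp_drive_grid(np.linspace(2.0, 7.0, 23))
        np.testing.assert_allclose(out, np.linspace(2.0, 7.0, 50), atol=1e-12)

    def test_matches_dense_interpolation_oracle(self, rng):
        seq = np.sin(np.linspace(0, 2.2, 37)) + 0.1 * rng.normal(size=37)
        out = ev.interp_drive_grid(seq)
        dense_x = np.linspace(0, 36, 36 * 1000 + 1)
        dense = np.interp(dense_x, np.arange(37), seq)
        oracle = dense[:: (36 * 1000) // 49][:50]
        expected = np.interp(np.linspace(0, 36, 50), dense_x, dense)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_too_short_window_rejected(self):
        with pytest.raises(ev.EvaluationError):
            ev.interp_drive_grid(np.array([1.0]))


class TestMaeCmae:
    def test_perfect_estimate_gives_zero(self, rng):
        m = rng.normal(size=(8, 50))
        assert ev.mae_cmae(m, m) == (0.0, 0.0)

    def test_constant_bias(self, rng):
        m = rng.normal(size=(5, 50))
        mae, cmae = ev.mae_cmae(m, m - 2.5)
        assert mae == pytest.approx(2.5)
        assert cmae == pytest.approx(2.5)

    def test_opposite_residuals_cancel_in_cmae(self, rng):
        m = rng.normal(size=(2, 50))
        e = m.copy()
        e[0] -= 1.7
        e[1] += 1.7
        mae, cmae = ev.mae_cmae(m, e)
        assert mae == pytest.approx(1.7)
        assert cmae == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_reference_on_random_pairs(self, rng):
        for _ in range(50):
            C = int(rng.integers(1, 12))
            m = rng.normal(size=(C, 50)) * rng.uniform(0.5, 200)
            e = m + rng.normal(size=(C, 50))
            mae, cmae = ev.mae_cmae(m, e)
            assert mae == pytest.approx(naive_mae(m, e), rel=1e-12)
            assert cmae == pytest.approx(naive_cmae(m, e), rel=1e-12)

    def test_cmae_never_exceeds_mae(self, rng):
        for _ in range(100):
            m = rng.normal(size=(6, 50))
            e = m + rng.normal(size=(6, 50))
            mae, cmae = ev.mae_cmae(m, e)
            assert cmae <= mae + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ev.EvaluationError):
            ev.mae_cmae(np.empty((0, 50)), np.empty((0, 50)))


class TestNormalizeError:
    def test_five_watt_error_on_hundred_watt_curve(self):
        assert ev.normalize_error(5.0, np.full((3, 50), 100.0)) == pytest.approx(5.0)

    def test_zero_error_is_zero_percent(self, rng):
        assert ev.normalize_error(0.0, rng.uniform(1, 2, (4, 50))) == 0.0

    def test_matches_direct_recomputation(self, rng):
        m = rng.uniform(10, 400, (7, 50))
        err = 12.3
        assert ev.normalize_error(err, m) == pytest.approx(100.0 * err / m.mean())

    def test_degenerate_normalizer_rejected(self):
        with pytest.raises(ev.EvaluationError, match="degenerate_normalizer"):
            ev.normalize_error(1.0, np.zeros((2, 50)))


class TestDeterminants:
    def test_symmetric_triangle(self):
        seq = np.concatenate([np.linspace(0, 1, 26), np.linspace(1, 0, 26)[1:]])
        d = ev.determinants(seq)
        assert d.T2P == pytest.approx(50.0)
        assert d.M2P == pytest.approx(50.0, abs=2.0)
        assert d.WR == pytest.approx(50.0, abs=1e-9)

    def test_constant_positive_curve(self):
        d = ev.determinants(np.full(40, 2.0))
        assert d.M2P == pytest.approx(100.0)
        assert d.T2P == 0.0  # plateau peak resolves to the first index

    def test_monotone_ramp(self):
        d = ev.determinants(np.linspace(0, 5, 60))
        assert d.T2P == pytest.approx(100.0)
        assert d.WR == pytest.approx(100.0)

    def test_scale_invariance(self, rng):
        seq = np.abs(rng.normal(1, 0.5, 80)) + 0.1
        a = ev.determinants(seq).as_array()
        b = ev.determinants(37.5 * seq).as_array()
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_matches_naive_reference(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 120))
            seq = np.abs(rng.normal(0, 1, n)) + 1e-3
            got = ev.determinants(seq)
            t2p, m2p, wr = naive_determinants(seq)
            assert got.T2P == pytest.approx(t2p, rel=1e-9)
            assert got.M2P == pytest.approx(m2p, rel=1e-9)
            assert got.WR == pytest.approx(wr, rel=1e-9)

    def test_no_positive_peak_rejected(self):
        with pytest.raises(ev.EvaluationError, match="no_peak"):
            ev.determinants(np.zeros(30))


class TestIntraSubjectAccuracy:
    def test_identical_estimates_give_full_accuracy(self, rng):
        m = {f"s{i}": rng.normal(50, 5, 20) for i in range(5)}
        as_, _ = ev.intra_subject_accuracy(m, {k: v.copy() for k, v in m.items()})
        assert as_ == 100.0

    def test_half_biased_subjects_give_fifty_percent(self, rng):
        m = {f"s{i}": rng.normal(50, 1, 40) for i in range(6)}
        e = {k: v + (30.0 if i < 3 else 0.0) for i, (k, v) in enumerate(m.items())}
        e = {k: v + rng.normal(0, 1, len(v)) for k, v in e.items()}
        as_, dec = ev.intra_subject_accuracy(m, e)
        assert as_ == pytest.approx(50.0, abs=17.0)  # t-test noise on unbiased half

    def test_single_subject_identical(self, rng):
        v = rng.normal(0, 1, 10)
        as_, _ = ev.intra_subject_accuracy({"a": v}, {"a": v.copy()})
        assert as_ == 100.0


class TestInterSubjectAccuracy:
    def test_identical_estimates_agree_everywhere(self, rng):
        m = {f"s{i}": rng.normal(10 * i, 1, 15) for i in range(5)}
        ap, _ = ev.inter_subject_accuracy(m, {k: v.copy() for k, v in m.items()})
        assert ap == 100.0

    def test_common_shift_preserves_decisions(self, rng):
        """t-test decisions are invariant to one common offset per pair set."""
        m = {f"s{i}": rng.normal(5 * i, 1, 25) for i in range(4)}
        e = {k: v + 1000.0 for k, v in m.items()}
        ap, _ = ev.inter_subject_accuracy(m, e)
        # verify the invariance directly on one pair as well
        p_m = stats.ttest_ind(m["s0"], m["s1"]).pvalue
        p_e = stats.ttest_ind(e["s0"], e["s1"]).pvalue
        assert p_m == pytest.approx(p_e, rel=1e-9)
        assert ap == 100.0

    def test_collapsed_estimates_disagree(self, rng):
        m = {f"s{i}": rng.normal(20 * i, 0.5, 30) for i in range(5)}
        pooled = np.concatenate(list(m.values())).mean()
        e = {k: rng.normal(pooled, 0.01, 30) for k in m}
        ap, _ = ev.inter_subject_accuracy(m, e)
        # agreement only through chance alpha-level rejections on the
        # collapsed estimates, so Ap stays near zero
        assert ap <= 20.0

    def test_needs_two_subjects(self, rng):
        with pytest.raises(ev.EvaluationError):
            ev.inter_subject_accuracy({"a": rng.normal(0, 1, 5)},
                                      {"a": rng.normal(0, 1, 5)})
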