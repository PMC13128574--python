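"""State-space core: ZOH discretization, recurrence, kernel duality,
selective scan."""

import numpy as np
import pytest

from anisoseg.exceptions import (DimensionError, InvalidParameterError,
                                 NumericError)
from anisoseg.ssm import (SelectiveProjections, SequenceBatch, SSMParams,
                          default_ssm_params, discretize_zoh, kernel_convolve,
                          selective_scan, ssm_scan)


def _params(A, B, C, delta):
    A, B, C = np.atleast_2d(A), np.atleast_2d(B), np.atleast_2d(C)
    return SSMParams(A=A, B=B, C=C, delta=np.atleast_1d(delta))


class TestDiscretizeZoh:
    def test_zero_A_limit(self):
        """A = 0 hits the small-argument limit: Abar = 1, Bbar = delta*B."""
        p = _params([[0.0]], [[2.0]], [[1.0]], [0.3])
        Abar, Bbar = discretize_zoh(p)
        assert Abar[0, 0] == pytest.approx(1.0)
        assert Bbar[0, 0] == pytest.approx(0.3 * 2.0)

    def test_scalar_closed_form(self):
        """A=-1, B=1, delta=ln2: Abar=1/2 and Bbar=(-ln2)^-1 (1/2-1) ln2 = 1/2."""
        p = _params([[-1.0]], [[1.0]], [[1.0]], [np.log(2.0)])
        Abar, Bbar = discretize_zoh(p)
        assert Abar[0, 0] == pytest.approx(0.5, rel=1e-12)
        assert Bbar[0, 0] == pytest.approx(0.5, rel=1e-12)

    def test_vanishing_step(self):
        """delta -> 0 gives Abar -> 1 and Bbar -> 0 for any finite A, B."""
        p = _params([[-3.0, 2.0]], [[5.0, -1.0]], [[1.0, 1.0]], [1e-12])
        Abar, Bbar = discretize_zoh(p)
        np.testing.assert_allclose(Abar, 1.0, atol=1e-10)
        np.testing.assert_allclose(np.abs(Bbar), 0.0, atol=1e-10)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(InvalidParameterError):
            _params([[-1.0]], [[1.0]], [[1.0]], [0.0])
        with pytest.raises(InvalidParameterError):
            _params([[-1.0]], [[1.0]], [[1.0]], [-0.1])

    def test_abar_in_unit_interval_for_stable_A(self, rng):
        p = default_ssm_params(4, N=8, rng=rng)
        Abar, _ = discretize_zoh(p)
        assert np.all(Abar > 0) and np.all(Abar <= 1)

    def test_random_draws_match_scalar_closed_form(self, rng):
        """1000 random (A, delta) pairs, including the |dA| -> 0 regime."""
        A = np.concatenate([-np.exp(rng.uniform(-3, 3, 700)),
                            rng.uniform(-1e-9, 0, 300)])
        delta = np.exp(rng.uniform(np.log(1e-4), np.log(1.0), 1000))
        B = rng.standard_normal(1000)
        p = SSMParams(A=A[None, :].T.reshape(1000, 1), B=B.reshape(1000, 1),
                      C=np.ones((1000, 1)), delta=delta)
        Abar, Bbar = discretize_zoh(p)
        expect_A = np.exp(delta * A)
        dA = delta * A
        with np.errstate(divide="ignore", invalid="ignore"):
            expect_B = np.where(np.abs(dA) < 1e-8, delta * B,
                                (np.expm1(dA)) / A * B)
        np.testing.assert_allclose(Abar.ravel(), expect_A, rtol=1e-12)
        np.testing.assert_allclose(Bbar.ravel(), expect_B, rtol=1e-9, atol=1e-12)


class TestSsmScan:
    def test_zero_input_zero_output(self, rng):
        p = default_ssm_params(3, N=4, rng=rng)
        out = ssm_scan(p, SequenceBatch(x=np.zeros((2, 10, 3))))
        assert np.all(out.y == 0)

    def test_single_step_unrolls_to_CB(self, rng):
        p = default_ssm_params(2, N=4, rng=rng)
        x = rng.standard_normal((1, 1, 2))
        out = ssm_scan(p, SequenceBatch(x=x))
        _, Bbar = discretize_zoh(p)
        expect = x[0, 0] * np.sum(p.C * Bbar, axis=1)
        np.testing.assert_allclose(out.y[0, 0], expect, rtol=1e-10)

    def test_channel_mismatch_raises(self, rng):
        p = default_ssm_params(3, N=4, rng=rng)
        with pytest.raises(DimensionError):
            ssm_scan(p, SequenceBatch(x=np.zeros((1, 5, 2))))

    def test_matches_kernel_convolution(self, rng):
        p = default_ssm_params(2, N=8, rng=rng)
        x = rng.standard_normal((3, 32, 2))
        ys = ssm_scan(p, SequenceBatch(x=x)).y
        yk = kernel_convolve(p, SequenceBatch(x=x)).y
        np.testing.assert_allclose(ys, yk, atol=1e-6)


class TestKernelConvolve:
    def test_memoryless_kernel(self):
        """Abar = 0 (A -> -inf surrogate: huge negative A) gives y_t ~ C Bbar x_t."""
        p = _params([[-200.0]], [[1.0]], [[2.0]], [1.0])
        x = np.array([[[1.0], [3.0], [-2.0]]])
        y = kernel_convolve(p, SequenceBatch(x=x)).y
        _, Bbar = discretize_zoh(p)
        np.testing.assert_allclose(y[0, :, 0], 2.0 * Bbar[0, 0] * x[0, :, 0],
                                   rtol=1e-10)

    def test_hand_unrolled_geometric_kernel(self):
        """Abar=0.5, Bbar=1, C=1, x=(1,0,0) gives y=(1, 0.5, 0.25)."""
        # choose A, delta so that ZOH gives Abar=0.5; then rescale B so Bbar=1
        delta = np.log(2.0)
        A = -1.0
        Bbar_unit = (0.5 - 1.0) / A  # ZOH Bbar for B=1
        p = _params([[A]], [[1.0 / Bbar_unit]], [[1.0]], [delta])
        x = np.array([[[1.0], [0.0], [0.0]]])
        y = kernel_convolve(p, SequenceBatch(x=x)).y
        np.testing.assert_allclose(y[0, :, 0], [1.0, 0.5, 0.25], rtol=1e-10)


class TestSelectiveScan:
    def _frozen(self, p, b_B, b_C):
        C, N = p.A.shape
        return SelectiveProjections(
            W_delta=np.zeros((C, C)), b_delta=np.log(np.expm1(p.delta)),
            W_B=np.zeros((C, N)), W_C=np.zeros((C, N)), A=p.A, b_B=b_B, b_C=b_C)

    def test_frozen_projections_reduce_to_lti(self, rng):
        C, N = 3, 4
        b = rng.standard_normal(N)
        c = rng.standard_normal(N)
        delta = np.exp(rng.uniform(-4, -1, C))
        A = -np.exp(rng.uniform(-1, 1, (C, N)))
        p = SSMParams(A=A, B=np.tile(b, (C, 1)), C=np.tile(c, (C, 1)), delta=delta)
        x = rng.standard_normal((2, 20, C))
        ref = ssm_scan(p, SequenceBatch(x=x)).y
        sel = selective_scan(SequenceBatch(x=x), self._frozen(p, b, c)).y
        np.testing.assert_allclose(sel, ref, atol=1e-6)

    def test_zero_input_zero_output(self, rng):
        C, N = 2, 3
        proj = SelectiveProjections(
            W_delta=rng.standard_normal((C, C)), b_delta=np.zeros(C),
            W_B=rng.standard_normal((C, N)), W_C=rng.standard_normal((C, N)),
            A=-np.ones((C, N)))
        out = selective_scan(SequenceBatch(x=np.zeros((1, 8, C))), proj)
        assert np.all(out.y == 0)

    def test_matches_per_step_reference_loop(self, rng):
        """Per-step ZOH rediscretization oracle, recomputed independently."""
        C, N, L = 2, 3, 16
        proj = SelectiveProjections(
            W_delta=0.3 * rng.standard_normal((C, C)), b_delta=rng.standard_normal(C),
            W_B=rng.standard_normal((C, N)), W_C=rng.standard_normal((C, N)),
            A=-np.exp(rng.uniform(-1, 1, (C, N))))
        x = rng.standard_normal((1, L, C))
        got = selective_scan(SequenceBatch(x=x), proj).y

        def softplus(z):
            return np.log1p(np.exp(-abs(z))) + max(z, 0)

        expect = np.zeros((L, C))
        h = np.zeros((C, N))
        for t in range(L):
            dt = np.array([softplus(v) for v in x[0, t] @ proj.W_delta + proj.b_delta])
            Bt = x[0, t] @ proj.W_B + proj.b_B
            Ct = x[0, t] @ proj.W_C + proj.b_C
            for c in range(C):
                a = np.exp(dt[c] * proj.A[c])
                bb = (a - 1.0) / proj.A[c] * Bt
                h[c] = a * h[c] + bb * x[0, t, c]
                expect[t, c] = Ct @ h[c]
        np.testing.assert_allclose(got[0], expect, atol=1e-10)

    def test_nonfinite_delta_reports_index(self):
        C, N = 2, 2
        proj = SelectiveProjections(
            W_delta=np.full((C, C), np.inf), b_delta=np.zeros(C),
            W_B=np.zeros((C, N)), W_C=np.zeros((C, N)), A=-np.ones((C, N)))
        with pytest.raises(NumericError, match="index"):
            selective_scan(SequenceBatch(x=np.ones((1, 3, C))), proj)


class TestInvariants:
    def test_recurrence_convolution_duality_many_draws(self):
        """100 random LTI parameter draws at L in {1, 8, 64} agree to 1e-5."""
        rng = np.random.default_rng(0)
        worst = 0.0
        for i in range(100):
            C = int(rng.integers(1, 4))
            p = default_ssm_params(C, N=int(rng.integers(1, 9)), rng=rng)
            for L in (1, 8, 64):
                x = rng.standard_normal((1, L, C))
                ys = ssm_scan(p, SequenceBatch(x=x)).y
                yk = kernel_convolve(p, SequenceBatch(x=x)).y
                worst = max(worst, float(np.abs(ys - yk).max()))
        assert worst < 1e-5

    def test_impulse_response_decays_for_stable_A(self, rng):
        # positive B, C keep the modal terms from cancelling, so the decay of
        # each exp(A_n t) mode makes the impulse response monotone after t=0
        p = SSMParams(A=-np.exp(rng.uniform(-1, 1, (1, 6))),
                      B=np.exp(rng.standard_normal((1, 6))),
                      C=np.exp(rng.standard_normal((1, 6))),
                      delta=np.array([0.5]))
        L = 50
        x = np.zeros((1, L, 1))
        x[0, 0, 0] = 1.0
        y = np.abs(ssm_scan(p, SequenceBatch(x=x)).y[0, :, 0])
        assert np.all(np.diff(y) <= 1e-15)

    def test_causality(self, rng):
        p = default_ssm_params(2, N=4, rng=rng)
        x = rng.standard_normal((1, 24, 2))
        base = ssm_scan(p, SequenceBatch(x=x)).y
        t = 13
        x2 = x.copy()
        x2[0, t:] += rng.standard_normal(x2[0, t:].shape)
        pert = ssm_scan(p, SequenceBatch(x=x2)).y
        np.testing.assert_array_equal(base[0, :t], pert[0, :t])
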