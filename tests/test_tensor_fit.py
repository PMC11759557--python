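"""Tensor estimation, eigendecomposition and rotation-invariant scalars."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cdtikit.diffusion_model import GradientTable, builtin_directions
from cdtikit.synthetic_phantom import PhantomSpec, make_phantom
from cdtikit.tensor_fit import (
    adc_from_pair,
    compute_fa,
    compute_md,
    compute_mode,
    eigendecompose,
    fit_tensor,
    mean_adc,
)

LAM_TYPICAL = np.array([1.6e-3, 0.9e-3, 0.59e-3])


class TestFit:
    def test_noiseless_phantom_recovers_generating_tensor(self, noiseless_phantom, noiseless_result):
        _, _, truth = noiseless_phantom
        fitted = noiseless_result.tensor_field.tensors[truth.mask]
        ref = truth.tensors[truth.mask]
        rel = np.abs(fitted - ref).max() / np.abs(ref).max()
        assert rel < 1e-9

    def test_signal_scale_invariance(self, noiseless_phantom):
        stack, table, truth = noiseless_phantom
        a = fit_tensor(stack.data, table, truth.mask).tensors
        b = fit_tensor(stack.data * 2.0, table, truth.mask).tensors
        assert np.allclose(a, b, atol=1e-18)

    def test_five_directions_rejected(self, noiseless_phantom):
        stack, _, truth = noiseless_phantom
        g = builtin_directions(6)[:5]
        table = GradientTable(
            directions=np.vstack([g[:1], g]),
            b_values=[50.0] + [450.0] * 5,
        )
        with pytest.raises(ValueError, match="six"):
            fit_tensor(stack.data[:6], table, truth.mask)

    def test_rr_correction_removes_md_bias(self):
        """Under RR jitter, per-frame b correction keeps MD honest."""
        rng = np.random.default_rng(7)
        rr = tuple(rng.uniform(900.0, 1100.0, size=13))
        stack, table, truth = make_phantom(PhantomSpec(rr_profile=rr))
        md_true = LAM_TYPICAL.mean()

        corrected = fit_tensor(stack.data, table, truth.mask, rr_correction=True)
        uncorrected = fit_tensor(stack.data, table, truth.mask, rr_correction=False)
        md_c = compute_md(eigendecompose(corrected).eigenvalues)[truth.mask].mean()
        md_u = compute_md(eigendecompose(uncorrected).eigenvalues)[truth.mask].mean()
        bias_c = abs(md_c - md_true) / md_true
        bias_u = abs(md_u - md_true) / md_true
        assert bias_c < 0.005
        assert bias_c < bias_u

        # linear-algebra oracle for the uncorrected fit: fitting data
        # generated with the true per-frame design A_t against the nominal
        # design A_n maps coefficients through pinv(A_n) @ A_t
        from cdtikit.diffusion_model import design_matrix
        a_nom = np.column_stack(
            [np.ones(13), design_matrix(table.directions, table.b_values)]
        )
        a_true = np.column_stack(
            [np.ones(13), design_matrix(table.directions, table.effective_bvalues())]
        )
        transfer = np.linalg.pinv(a_nom) @ a_true
        d = truth.tensors[truth.mask]
        x_true = np.column_stack([
            np.zeros(d.shape[0]),  # intercept irrelevant to the oracle MD
            d[:, 0, 0], d[:, 1, 1], d[:, 2, 2],
            d[:, 0, 1], d[:, 0, 2], d[:, 1, 2],
        ])
        x_hat = x_true @ transfer.T
        md_oracle = x_hat[:, 1:4].mean(axis=1).mean()
        assert md_u == pytest.approx(md_oracle, rel=1e-9)


class TestEigendecomposition:
    def test_diagonal_case(self):
        eig = eigendecompose(np.diag(LAM_TYPICAL))
        assert np.allclose(eig.eigenvalues, LAM_TYPICAL)
        assert np.allclose(np.abs(eig.e1), [1, 0, 0])

    def test_rotated_tensor_oracle(self, rng):
        """Rotation moves eigenvectors, never eigenvalues."""
        for _ in range(20):
            r = Rotation.random(rng=rng).as_matrix()
            d = r @ np.diag(LAM_TYPICAL) @ r.T
            eig = eigendecompose(d)
            assert np.allclose(eig.eigenvalues, LAM_TYPICAL, atol=1e-15)
            assert abs(abs(eig.e1 @ r[:, 0]) - 1.0) < 1e-9

    def test_right_handed_and_orthonormal(self, rng):
        a = rng.normal(size=(3, 3))
        eig = eigendecompose(a + a.T)
        v = np.stack([eig.e1, eig.e2, eig.e3], axis=-1)
        assert np.allclose(v.T @ v, np.eye(3), atol=1e-12)
        assert np.linalg.det(v) == pytest.approx(1.0)

    def test_negative_eigenvalue_flagged_not_clamped(self):
        eig = eigendecompose(np.diag([1e-3, 5e-4, -1e-5]))
        assert eig.negative_flag
        assert eig.eigenvalues[2] == pytest.approx(-1e-5)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            eigendecompose(np.full((3, 3), np.nan))


class TestScalars:
    def test_md_typical(self):
        assert compute_md(LAM_TYPICAL) == pytest.approx(1.03e-3)

    def test_md_isotropic(self):
        assert compute_md(np.array([1e-3] * 3)) == pytest.approx(1e-3)

    @pytest.mark.parametrize(
        "lam,expected",
        [
            ([1e-3, 1e-3, 1e-3], 0.0),        # uniform diffusion
            ([1.0, 0.0, 0.0], 1.0),           # stick limit
            (LAM_TYPICAL, 0.465),             # typical myocardium
        ],
    )
    def test_fa(self, lam, expected):
        assert compute_fa(np.asarray(lam)) == pytest.approx(expected, abs=5e-4)

    def test_fa_all_zero_flagged(self):
        assert np.isnan(compute_fa(np.zeros(3)))

    @pytest.mark.parametrize(
        "lam,expected",
        [
            ([2.0, 1.0, 1.0], 1.0),   # stick
            ([2.0, 2.0, 1.0], -1.0),  # disk
            ([1.0, 1.0, 1.0], 0.0),   # degenerate convention
        ],
    )
    def test_mode_endpoints(self, lam, expected):
        assert compute_mode(np.asarray(lam)) == pytest.approx(expected)

    def test_rotation_invariance_of_scalars(self, rng):
        d0 = np.diag(LAM_TYPICAL)
        ref = (compute_md(LAM_TYPICAL), compute_fa(LAM_TYPICAL), compute_mode(LAM_TYPICAL))
        for _ in range(100):
            r = Rotation.random(rng=rng).as_matrix()
            eig = eigendecompose(r @ d0 @ r.T)
            got = (
                compute_md(eig.eigenvalues),
                compute_fa(eig.eigenvalues),
                compute_mode(eig.eigenvalues),
            )
            assert np.allclose(got, ref, atol=1e-9)


class TestAdc:
    def test_pair_example(self):
        assert adc_from_pair(800.0, 560.0, 50.0, 450.0) == pytest.approx(
            8.917e-4, abs=1e-7
        )

    def test_equal_signals_zero(self):
        assert adc_from_pair(700.0, 700.0, 50.0, 450.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            adc_from_pair(800.0, 560.0, 450.0, 50.0)
        with pytest.raises(ValueError):
            adc_from_pair(800.0, 0.0, 50.0, 450.0)

    def test_mean_adc_equals_md_for_tensor_data(self, rng):
        """Trace identity: mean ADC over any orthonormal triad equals MD."""
        a = rng.normal(size=(3, 3))
        d = a @ a.T * 1e-3  # SPD
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        s0, b_low, b_high = 1000.0, 50.0, 450.0
        adcs = []
        for k in range(3):
            g = q[:, k]
            s_l = s0 * np.exp(-b_low * g @ d @ g)
            s_h = s0 * np.exp(-b_high * g @ d @ g)
            adcs.append(adc_from_pair(s_l, s_h, b_low, b_high))
        assert mean_adc(np.array(adcs)) == pytest.approx(np.trace(d) / 3, rel=1e-12)

    def test_mean_adc_needs_three(self):
        with pytest.raises(ValueError):
            mean_adc(np.array([1e-3, 1e-3]))
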