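import numpy as np

from conftest import multiset_close
import pytest

from abpspectra import build_decay_operator, diagonalize, slowest_mode, track_branches
from abpspectra.operator import (
    InvalidParameterError,
    is_real_eigenvalue,
    real_form,
    two_mode_eigenvalues,
)


class TestBuildOperator:
    def test_printed_two_mode_matrix(self):
        """The printed Q=1 truncation: diag (0, 1) with -iq/2 bonds."""
        A = build_decay_operator(0.5, 1, fold="printed").matrix
        assert np.allclose(A, [[0, -0.25j], [-0.25j, 1]])

    def test_zero_activity_is_pure_fourier_relaxation(self):
        for fold in ("exact", "printed"):
            A = build_decay_operator(0.0, 3, fold).matrix
            assert np.array_equal(A, np.diag([0, 1, 4, 9]).astype(complex))

    @pytest.mark.parametrize("fold", ["exact", "printed"])
    def test_trace_is_activity_independent(self, fold):
        op = build_decay_operator(2.0, 5, fold)
        assert np.isclose(np.trace(op.matrix).real, 55.0)  # 5*6*11/6
        assert np.isclose(op.trace, 55.0)

    def test_complex_symmetric_tridiagonal(self):
        A = build_decay_operator(1.3, 8).matrix
        assert np.allclose(A, A.T)  # non-conjugate transpose
        assert np.allclose(np.triu(A, 2), 0) and np.allclose(np.tril(A, -2), 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_decay_operator(-0.1, 5)
        with pytest.raises(InvalidParameterError):
            build_decay_operator(1.0, 0)
        with pytest.raises(InvalidParameterError):
            build_decay_operator(1.0, 5, fold="nope")

    def test_real_form_is_similar(self):
        op = build_decay_operator(2.7, 12)
        w1 = np.linalg.eigvals(op.matrix)
        w2 = np.linalg.eigvals(real_form(op).astype(complex))
        assert multiset_close(w1, w2, atol=1e-10)


class TestDiagonalize:
    def test_two_mode_closed_form_below_ep(self):
        dec = diagonalize(build_decay_operator(0.5, 1, fold="printed"))
        assert np.allclose(dec.eigenvalues, [0.0669873, 0.9330127], atol=1e-6)
        assert np.allclose(dec.eigenvalues, two_mode_eigenvalues(0.5), atol=1e-12)

    def test_two_mode_closed_form_past_ep(self):
        dec = diagonalize(build_decay_operator(2.0, 1, fold="printed"))
        w = dec.eigenvalues
        assert np.allclose(w.real, 0.5, atol=1e-12)
        assert np.allclose(sorted(w.imag), [-0.8660254, 0.8660254], atol=1e-6)

    def test_diagonal_case_gives_coordinate_vectors(self):
        dec = diagonalize(build_decay_operator(0.0, 4))
        assert np.allclose(dec.eigenvalues, [0, 1, 4, 9, 16])
        assert np.allclose(dec.eigenvectors, np.eye(5))

    def test_eigenpair_residuals_and_trace(self):
        op = build_decay_operator(3.7, 60)
        dec = diagonalize(op)
        assert np.all(dec.residuals <= 1e-9 * np.linalg.norm(op.matrix))
        assert abs(dec.eigenvalues.sum() - op.trace) <= 1e-9 * op.trace

    def test_phase_convention_leading_component_real_positive(self):
        dec = diagonalize(build_decay_operator(1.2, 30))
        for j in range(31):
            v = dec.eigenvectors[:, j]
            lead = v[np.argmax(np.abs(v))]
            assert lead.imag == pytest.approx(0.0, abs=1e-12) and lead.real > 0


class TestSlowestMode:
    def test_stationary_uniform_state_at_zero_activity(self, slowest):
        lam, mags = slowest(0.0, 50)
        assert lam == 0
        assert mags[0] == pytest.approx(1.0) and np.allclose(mags[1:], 0.0)

    def test_small_activity_matches_perturbation_theory(self, slowest):
        lam, _ = slowest(0.01, 50)
        assert lam.real == pytest.approx(0.01**2 / 8, rel=1e-3)

    def test_high_activity_matches_mathieu_asymptotics(self, slowest):
        # Re a0 = sqrt(2q) - 1/4 at q=100 -> lambda0 ~ 3.473
        lam, _ = slowest(100.0, 200)
        assert lam.real == pytest.approx((np.sqrt(200) - 0.25) / 4, rel=5e-3)

    def test_projection_magnitudes_are_unit_norm(self, slowest):
        _, mags = slowest(2.5, 40)
        assert np.sum(mags**2) == pytest.approx(1.0, abs=1e-12)
        assert np.all((mags >= 0) & (mags <= 1))


class TestTrackBranches:
    def test_real_spectrum_below_first_ep(self):
        df = track_branches([0.1, 0.2], Q=3)
        assert df["branch"].nunique() == 4
        assert np.allclose(df["im_lambda"], 0.0, atol=1e-9)

    def test_conjugate_pair_shares_real_part_past_ep(self):
        # the first EP sits at q_c ~ 1.4688; straddle it
        grid = np.linspace(1.3, 1.7, 9)
        df = track_branches(grid, Q=60)
        last = df[df["q"] == grid[-1]].nsmallest(2, "re_lambda")
        assert np.isclose(last["re_lambda"].iloc[0], last["re_lambda"].iloc[1], atol=1e-9)
        assert not np.any(is_real_eigenvalue(last["re_lambda"] + 1j * last["im_lambda"]))

    def test_branch_continuity_labels_are_stable(self):
        grid = np.logspace(-1, 0.5, 12)
        df = track_branches(grid, Q=10)
        # each branch appears exactly once per grid point
        counts = df.groupby(["q", "branch"]).size()
        assert (counts == 1).all()

    def test_single_point_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            track_branches([0.0], Q=2)
        with pytest.raises(InvalidParameterError):
            track_branches([0.2, 0.1], Q=2)
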