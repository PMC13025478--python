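import numpy as np
import pytest

from abpspectra import build_decay_operator, diagonalize, slowest_mode


def sorted_complex(w):
    """Canonical (Re, Im)-lexicographic ordering for multiset comparison."""
    w = np.asarray(w)
    return w[np.lexsort((w.imag, w.real))]


def multiset_close(w1, w2, atol=1e-8):
    """Tolerance-aware complex multiset equality via optimal pairing.

    Lexicographic sorting is unstable when real parts differ only in the
    last ulp (conjugate pairs from a complex eigensolver), so compare by
    minimum-cost perfect matching instead.
    """
    from scipy.optimize import linear_sum_assignment

    w1, w2 = np.asarray(w1), np.asarray(w2)
    if w1.shape != w2.shape:
        return False
    cost = np.abs(w1[:, None] - w2[None, :])
    rows, cols = linear_sum_assignment(cost)
    return bool(np.all(cost[rows, cols] <= atol))


@pytest.fixture(scope="session")
def slowest():
    """Callable: (q, Q, fold) -> (lambda0, projection magnitudes)."""

    def _slowest(q, Q, fold="exact"):
        return slowest_mode(diagonalize(build_decay_operator(q, Q, fold)))

    return _slowest


@pytest.fixture(scope="session")
def low_sweep():
    """Q=50 sweep over the low-activity window, shared across tests."""
    from abpspectra.scaling import spectral_sweep

    return spectral_sweep(50, (1e-3, 1e-2), 20)


@pytest.fixture(scope="session")
def high_sweep():
    """Q=400 sweep over the intermediate/high-activity window (the slow one)."""
    from abpspectra.scaling import spectral_sweep

    return spectral_sweep(400, (1e3, 1e4), 15)


def mathieu_a0_continued_fraction(q: float, radius: float = 4.0, depth: int = 100) -> float:
    """Independent oracle: even pi-periodic Mathieu characteristic a0 at
    purely imaginary parameter, from the standard three-term continued
    fraction of the cosine-elliptic coefficient recurrence.

    With A_{2r} coefficients of ce and w_r = q_im * A_{2r}/A_{2r-2} the
    recurrence gives w_r = -q^2 / (a - 4 r^2 - w_{r+1}) (the imaginary
    parameter enters only through q^2), the doubled bottom coupling gives
    w_1 = -2 q^2 / (a - 4 - w_2), and the characteristic equation is
    F(a) = a - w_1 = 0.  Valid below the first double point (a0 real).
    """

    def F(a):
        w = 0.0
        for r in range(depth, 1, -1):
            w = -q * q / (a - 4.0 * r * r - w)
        return a + 2.0 * q * q / (a - 4.0 - w)

    from scipy.optimize import brentq

    grid = np.linspace(-radius, radius, 2000)
    vals = np.array([F(a) for a in grid])
    for i in range(len(grid) - 1):
        if np.sign(vals[i]) != np.sign(vals[i + 1]) and abs(vals[i]) < 5 and abs(vals[i + 1]) < 5:
            return brentq(F, grid[i], grid[i + 1], xtol=1e-13)
    raise RuntimeError(f"no bracketed root for q={q}")
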