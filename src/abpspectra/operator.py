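"""Truncated folded Fourier representation of the free Fokker-Planck operator.

In the even angular sector the eigenproblem for the decay rates ``lambda``
is a complex-symmetric tridiagonal matrix: diagonal ``m^2`` (pure Fourier
relaxation) and purely imaginary activity bonds.  Two bond conventions are
supported:

``fold="exact"``
    The exact folding of the even Fourier recurrence onto ``m >= 0``:
    interior bonds ``-i q/4`` and a sqrt(2)-weighted ``0<->1`` bond (the
    symmetrized form of the doubled boundary coupling).  Its eigenvalues are
    one quarter of the even pi-periodic Mathieu characteristic values at
    purely imaginary parameter; this is the physical convention used for
    every scaling and instability result in this package.

``fold="printed"``
    Uniform bonds ``-i q/2`` on every off-diagonal.  This is the convention
    in which the two-mode truncation ``Q=1`` is the textbook model
    exceptional point with coalescence at ``q* = 1`` and ``lambda* = 1/2``.

Because the operator is similar, via ``diag(i^m)``, to a *real* matrix, its
spectrum is closed under complex conjugation and real eigenvalues can be
counted exactly from the real form (LAPACK returns their imaginary parts as
exact zeros).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

#: an eigenvalue counts as real iff |Im| <= REAL_TOL * max(1, |lambda|)
REAL_TOL = 1e-9

_FOLDS = ("exact", "printed")


class InvalidParameterError(ValueError):
    """Raised for out-of-domain operator parameters."""


class DiagonalizationError(RuntimeError):
    """Raised when the dense eigensolver fails; carries (q, Q)."""

    def __init__(self, q: float, Q: int, msg: str):
        super().__init__(f"eigensolver failed for q={q}, Q={Q}: {msg}")
        self.q = q
        self.Q = Q


@dataclass(frozen=True)
class ActivityMap:
    """Relation between wave number, Peclet number and the activity q = 2 k Pe."""

    q: float
    k: float | None = None
    pe: float | None = None

    @classmethod
    def from_k_pe(cls, k: float, pe: float) -> "ActivityMap":
        if k < 0 or pe < 0:
            raise InvalidParameterError("k and Pe must be non-negative")
        return cls(q=2.0 * k * pe, k=k, pe=pe)

    @staticmethod
    def characteristic_value(lam: complex) -> complex:
        """Mathieu characteristic value a = 4 lambda for a decay rate."""
        return 4.0 * lam


@dataclass(frozen=True)
class DecayOperator:
    """The (Q+1)x(Q+1) complex-symmetric decay-rate matrix at activity q."""

    q: float
    Q: int
    fold: str = "exact"
    matrix: np.ndarray = field(repr=False, default=None)

    @property
    def trace(self) -> float:
        """Q(Q+1)(2Q+1)/6, independent of q."""
        return self.Q * (self.Q + 1) * (2 * self.Q + 1) / 6.0


def _bonds(q: float, Q: int, fold: str) -> np.ndarray:
    if fold == "exact":
        b = np.full(Q, q / 4.0)
        if Q >= 1:
            b[0] *= np.sqrt(2.0)
    elif fold == "printed":
        b = np.full(Q, q / 2.0)
    else:
        raise InvalidParameterError(f"unknown fold {fold!r}; expected one of {_FOLDS}")
    return b


def build_decay_operator(q: float, Q: int, fold: str = "exact") -> DecayOperator:
    """Assemble the truncated decay operator.

    Parameters
    ----------
    q : float
        Activity parameter ``q = 2 k Pe`` (dimensionless, >= 0).
    Q : int
        Truncation cutoff; the matrix acts on folded modes ``m = 0..Q``.
    fold : {"exact", "printed"}
        Bond convention, see module docstring.
    """
    if q < 0:
        raise InvalidParameterError(f"activity q must be >= 0, got {q}")
    if not isinstance(Q, (int, np.integer)) or Q < 1:
        raise InvalidParameterError(f"cutoff Q must be an integer >= 1, got {Q}")
    m = np.arange(Q + 1)
    A = np.diag(m * m).astype(complex)
    b = -1j * _bonds(q, Q, fold)
    idx = np.arange(Q)
    A[idx, idx + 1] = b
    A[idx + 1, idx] = b
    return DecayOperator(q=float(q), Q=int(Q), fold=fold, matrix=A)


def real_form(op: DecayOperator) -> np.ndarray:
    """Real matrix similar to ``op.matrix`` via the diagonal gauge diag(i^m).

    The transform maps the bonds ``-i b`` to ``+/- b``; the spectrum is
    unchanged, which proves conjugation closure and makes realness counting
    exact.
    """
    m = np.arange(op.Q + 1)
    A = np.diag(m * m).astype(float)
    b = _bonds(op.q, op.Q, op.fold)
    idx = np.arange(op.Q)
    A[idx, idx + 1] = b
    A[idx + 1, idx] = -b
    return A


def is_real_eigenvalue(lam: complex | np.ndarray) -> np.ndarray:
    """Realness predicate at the package-wide tolerance."""
    lam = np.asarray(lam)
    return np.abs(lam.imag) <= REAL_TOL * np.maximum(1.0, np.abs(lam))


@dataclass(frozen=True)
class SpectralDecomposition:
    """Sorted eigenpairs of a DecayOperator.

    Eigenvalues are sorted by ascending real part, then ascending imaginary
    part.  Eigenvectors (columns) have unit 2-norm with the phase fixed so
    the largest-magnitude component is real and positive.  ``residuals[i]``
    is ``||A v_i - lambda_i v_i||``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    source: DecayOperator = field(repr=False, default=None)


def _fix_phase(vecs: np.ndarray) -> np.ndarray:
    out = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    lead = np.argmax(np.abs(out), axis=0)
    phase = out[lead, np.arange(out.shape[1])]
    out = out * (np.abs(phase) / phase)[None, :]
    return out


def diagonalize(op: DecayOperator) -> SpectralDecomposition:
    """Dense eigendecomposition with sorting, phase and residual contracts."""
    try:
        w, v = np.linalg.eig(op.matrix)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - LAPACK rarely fails here
        raise DiagonalizationError(op.q, op.Q, str(exc)) from exc
    order = np.lexsort((w.imag, w.real))
    w, v = w[order], _fix_phase(v[:, order])
    residuals = np.linalg.norm(op.matrix @ v - v * w[None, :], axis=0)
    norm = np.linalg.norm(op.matrix)
    if np.any(residuals > 1e-9 * max(norm, 1.0)):
        raise DiagonalizationError(op.q, op.Q, "residual contract violated")
    return SpectralDecomposition(eigenvalues=w, eigenvectors=v, residuals=residuals, source=op)


def slowest_mode(dec: SpectralDecomposition) -> tuple[complex, np.ndarray]:
    """Slowest decay rate and the component magnitudes of its eigenvector.

    Returns the eigenvalue of minimal real part (ties broken toward minimal
    |Im|, then non-negative Im) together with ``|c_n|`` for ``n = 0..Q``;
    the magnitudes satisfy ``sum c_n^2 = 1``.
    """
    w = dec.eigenvalues
    if w.size == 0:
        raise InvalidParameterError("empty decomposition")
    key = np.lexsort((-np.sign(w.imag), np.abs(w.imag), w.real))
    i = key[0]
    return w[i], np.abs(dec.eigenvectors[:, i])


def track_branches(
    q_grid: np.ndarray,
    Q: int,
    fold: str = "exact",
    n_projections: int = 8,
) -> pd.DataFrame:
    """Follow eigenvalue branches along an activity sweep.

    Branches are matched between consecutive grid points by maximal
    eigenvector overlap (Hungarian assignment on ``|v_i^H v_j|``); an
    ambiguous assignment (two overlaps within 1e-6) is logged and resolved
    lexicographically by the assignment solver.

    Returns a table with columns ``q, branch, re_lambda, im_lambda,
    c0..c<n>`` where ``n = min(Q, n_projections)``.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.ndim != 1 or q_grid.size < 2:
        raise InvalidParameterError("q_grid must contain at least 2 points")
    if np.any(np.diff(q_grid) <= 0):
        raise InvalidParameterError("q_grid must be strictly increasing")
    np_ = min(Q, n_projections)
    rows = []
    prev_vecs = None
    branch_of = np.arange(Q + 1)
    for q in q_grid:
        dec = diagonalize(build_decay_operator(q, Q, fold))
        if prev_vecs is not None:
            overlap = np.abs(prev_vecs.conj().T @ dec.eigenvectors)
            srt = np.sort(overlap, axis=1)
            if np.any(srt[:, -1] - srt[:, -2] < 1e-6):
                logger.warning("ambiguous branch matching at q=%g (Q=%d)", q, Q)
            row_ind, col_ind = linear_sum_assignment(-overlap)
            new_branch = np.empty(Q + 1, dtype=int)
            new_branch[col_ind] = branch_of[row_ind]
            branch_of = new_branch
        for j in range(Q + 1):
            lam = dec.eigenvalues[j]
            mags = np.abs(dec.eigenvectors[: np_ + 1, j])
            rows.append((q, branch_of[j], lam.real, lam.imag, *mags))
        prev_vecs = dec.eigenvectors
    cols = ["q", "branch", "re_lambda", "im_lambda"] + [f"c{i}" for i in range(np_ + 1)]
    return pd.DataFrame(rows, columns=cols)


def slowest_sweep(q_grid: np.ndarray, Q: int, fold: str = "exact") -> pd.DataFrame:
    """Re lambda0 and projection magnitudes c0..c8 along an activity grid."""
    q_grid = np.asarray(q_grid, dtype=float)
    rows = []
    for q in q_grid:
        lam, mags = slowest_mode(diagonalize(build_decay_operator(q, Q, fold)))
        rows.append((q, lam.real, lam.imag, *mags[: min(Q, 8) + 1]))
    cols = ["q", "re_lambda0", "im_lambda0"] + [f"c{i}" for i in range(min(Q, 8) + 1)]
    return pd.DataFrame(rows, columns=cols)


def two_mode_eigenvalues(q: float) -> tuple[complex, complex]:
    """Closed form for the printed Q=1 truncation: lambda = (1 -+ sqrt(1-q^2))/2.

    The pair coalesces at the model exceptional point q* = 1, lambda* = 1/2.
    """
    s = np.sqrt(complex(1.0 - q * q))
    return (1 - s) / 2, (1 + s) / 2
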