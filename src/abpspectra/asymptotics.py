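"""Closed-form asymptotics used as analytic oracles against the numerics.

Three regimes are covered:

* low activity, ``q << 1``: non-degenerate second-order perturbation theory
  around pure Fourier relaxation (diffusion dominates),
* the advection limit ``q >> Q^2`` of the *printed* uniform-bond truncation,
  where the operator minus its diagonal is tridiagonal Toeplitz with a
  closed-form sine eigenbasis,
* high activity ``1 << q`` in the continuum sense: Poincare asymptotics of
  the even pi-periodic Mathieu characteristic values at purely imaginary
  parameter, and the ``q^(-1/8)`` law for the Fourier content of the slowest
  boundary-layer eigenmode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import factorial, pi, sqrt

import numpy as np

__all__ = [
    "AsymptoticPrediction",
    "lowq_characteristic",
    "lowq_mode_projection",
    "toeplitz_limit",
    "highq_characteristic",
    "highq_fourier_coefficients",
]


@dataclass(frozen=True)
class AsymptoticPrediction:
    regime: str  # "low_q" | "toeplitz" | "high_q"
    index: int
    value: complex
    validity: str


def lowq_characteristic(r: int, q: float) -> float:
    """Second-order small-q decay rate of folded mode ``r``.

    For ``r = 0`` and ``r >= 2`` this is ``r^2 - q^2 / (8 (4 r^2 - 1))``,
    one quarter of the standard small-q series of the even Mathieu
    characteristics ``a_{2r}`` continued to imaginary parameter.  For
    ``r = 1`` the boundary fold doubles the weight of the ``0<->1`` bond and
    the exact coefficient is ``5/48`` (a2 = 4 - 5 q^2/12), not the ``1/24``
    of the generic formula.
    """
    if r < 0:
        raise ValueError("mode index r must be >= 0")
    if r == 1:
        return 1.0 - 5.0 * q * q / 48.0
    return r * r - q * q / (8.0 * (4.0 * r * r - 1.0))


def lowq_mode_projection(m: int, q: float, Q: int | None = None) -> dict:
    """First-order eigenvector of mode ``m`` and its harmonic overlaps.

    The first-order corrected (unnormalized) eigenvector is
    ``|m> + sum_n b_n q |n>`` with the neighbour coefficients fixed by the
    exact folding; in particular the slowest mode acquires a polar
    ("density-order") component ``|<1|0>| = (sqrt(2)/4) q`` linear in the
    activity, and a nematic component ``|<2|0>| = (sqrt(2)/64) q^2`` only at
    second order.

    Returns a dict with the unit-norm first-order vector (length Q+1,
    default Q = m+2) and the overlap magnitudes ``c1`` and, for m = 0,
    ``c2``.
    """
    if m < 0:
        raise ValueError("mode index m must be >= 0")
    if q > 0.3:
        warnings.warn(f"lowq_mode_projection called at q={q} > 0.3; series accuracy degrades")
    Q = max(m + 2, 2) if Q is None else Q
    vec = np.zeros(Q + 1, dtype=complex)
    vec[m] = 1.0

    def bond(i: int) -> float:  # bond weight between folded modes i and i+1
        return q * sqrt(2.0) / 4.0 if i == 0 else q / 4.0

    if m + 1 <= Q:
        vec[m + 1] = 1j * bond(m) / (m * m - (m + 1) ** 2) * (-1.0)
    if m - 1 >= 0:
        vec[m - 1] = 1j * bond(m - 1) / (m * m - (m - 1) ** 2) * (-1.0)
    out = {"m": m, "q": q}
    if m == 0:
        # second-order path 0 -> 1 -> 2 for the nematic overlap
        if Q >= 2:
            vec[2] = (-1j * bond(1)) * (-1j * bond(0)) / ((0 - 1) * (0 - 4))
        out["c1"] = sqrt(2.0) / 4.0 * q
        out["c2"] = sqrt(2.0) / 64.0 * q * q
    else:
        out["c1"] = abs(vec[1]) if Q >= 1 else 0.0
    out["vector"] = vec / np.linalg.norm(vec)
    return out


def toeplitz_limit(Q: int, q: float) -> dict:
    """Advection spectrum of the uniform-bond truncation for ``q >> Q^2``.

    Zeroth order (diagonal dropped): tridiagonal Toeplitz closed form,
    eigenvalues ``-i q cos((n+1) pi / (Q+2))`` with sine eigenvectors
    ``v_n[m] = sin((m+1)(n+1) pi / (Q+2))``.  First order: the real
    correction is the contraction ``<v_n, diag(m^2) v_n> / <v_n, v_n>`` of
    the diffusive diagonal with the normalized advection eigenvector.

    Returns ``{"eigenvalues": lam0 - i..., "re_correction": ..., "eigenvectors": ...}``
    with modes ordered by ascending first-order real part.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    n = np.arange(Q + 1)
    m = np.arange(Q + 1)
    lam0 = -1j * q * np.cos((n + 1) * pi / (Q + 2))
    vecs = np.sin(np.outer(m + 1, n + 1) * pi / (Q + 2))
    vecs /= np.linalg.norm(vecs, axis=0, keepdims=True)
    re1 = np.einsum("mn,m,mn->n", vecs, (m * m).astype(float), vecs)
    order = np.argsort(re1, kind="stable")
    return {
        "eigenvalues": lam0[order],
        "re_correction": re1[order],
        "eigenvectors": vecs[:, order],
        "prediction": re1[order] + lam0[order],
    }


def highq_characteristic(m: int, q: float) -> complex:
    """Large-q Mathieu characteristic ``a_m`` in the decay convention.

    With ``s = 2m + 1``::

        Re a_m = s sqrt(2q) - (s^2 + 1)/8
        Im a_m = -(2q - s sqrt(2q))

    (the conjugate branch exists as well; the decay rate is ``a/4`` and
    ``Re a > 0`` fixes the branch).  Encodes ``alpha_high = 1/2``.
    """
    if m < 0:
        raise ValueError("mode index m must be >= 0")
    if q < 10:
        warnings.warn(f"highq_characteristic called at q={q} < 10; asymptotics unreliable")
    s = 2 * m + 1
    re = s * sqrt(2.0 * q) - (s * s + 1) / 8.0
    im = -(2.0 * q - s * sqrt(2.0 * q))
    return complex(re, im)


def highq_fourier_coefficients(l: int, q: float) -> float:
    """Asymptotic magnitude of the slowest mode's l-th harmonic content.

    Encodes the boundary-layer law: every Fourier projection of the slowest
    eigenmode decays as ``q^(-1/8)``, with an l-dependent combinatorial
    prefactor ``sqrt((2l)!)/(l! 4^l)``.  The q-scaling and its l-uniformity
    are the reliable content; the absolute prefactor is an asymptotic
    estimate that converges only slowly with q (see the methods note) and
    should not be used quantitatively at moderate activity.
    """
    if l < 0:
        raise ValueError("Fourier index l must be >= 0")
    if q < 10:
        warnings.warn(f"highq_fourier_coefficients called at q={q} < 10; asymptotics unreliable")
    pref = sqrt(factorial(2 * l)) / (factorial(l) * 4.0**l) * sqrt(2.0)
    return pref * (pi * pi * q) ** (-0.125)
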