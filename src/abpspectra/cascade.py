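"""Detection, localization and counting of exceptional points.

An exceptional point (EP) of the decay operator is an activity ``q*`` at
which two real eigenvalues coalesce and continue as a complex-conjugate
pair.  Detection is based on the number of real eigenvalues, which drops by
exactly 2 at each second-order EP: the operator is similar to a real matrix
(``diag(i^m)`` gauge), so LAPACK's real eigensolver reports real eigenvalues
with exactly zero imaginary part and the count is parity-exact — far more
robust than thresholding eigenvalue distances near avoided crossings.

Defectiveness at the EP itself is not certified (eigenvector condition
numbers diverge); the EP is characterized by the realness transition alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .operator import InvalidParameterError, build_decay_operator, real_form
from .scaling import ExponentFit, fit_loglog_slope

__all__ = [
    "ExceptionalPoint",
    "BracketError",
    "count_real_eigenvalues",
    "locate_ep",
    "scan_cascade",
    "ep_count_exponent",
    "pre_ep_gap_exponent",
]


class BracketError(ValueError):
    """Raised when a bisection bracket does not straddle exactly one EP."""


@dataclass(frozen=True)
class ExceptionalPoint:
    """A detected coalescence of branches (2r, 2r+1) at activity q_star."""

    pair_index: int
    q_star: float
    lambda_star: complex
    Q: int
    tol: float


def count_real_eigenvalues(q: float, Q: int, fold: str = "exact") -> int:
    """Number of exactly-real eigenvalues of the truncated operator."""
    ev = np.linalg.eigvals(real_form(build_decay_operator(q, Q, fold)))
    return int(np.count_nonzero(ev.imag == 0.0))


def n_exceptional_points(q: float, Q: int, fold: str = "exact") -> int:
    """N(q): number of EPs below activity q, from the real-eigenvalue count."""
    return (Q + 1 - count_real_eigenvalues(q, Q, fold)) // 2


def _lambda_at(q: float, Q: int, fold: str) -> complex:
    """Eigenvalue of the about-to-coalesce pair: the slowest real eigenvalue
    just below q* equals the pair's common value at coalescence to O(tol^1/2)."""
    ev = np.linalg.eigvals(real_form(build_decay_operator(q, Q, fold)))
    real = np.sort(ev[ev.imag == 0.0].real)
    if real.size >= 2:
        return complex(0.5 * (real[0] + real[1]))
    return complex(real[0]) if real.size else complex(np.nan)


def locate_ep(
    r: int,
    Q: int,
    bracket: tuple[float, float],
    tol: float = 1e-6,
    fold: str = "exact",
) -> ExceptionalPoint:
    """Bisect the realness transition of branch pair (2r, 2r+1).

    The bracket must straddle exactly one EP, i.e. the real-eigenvalue count
    must be ``Q+1-2r`` at ``q_lo`` and ``Q+1-2(r+1)`` at ``q_hi``.
    """
    q_lo, q_hi = bracket
    if not (0 <= q_lo < q_hi) or tol <= 0:
        raise InvalidParameterError("need 0 <= q_lo < q_hi and tol > 0")
    n_lo = count_real_eigenvalues(q_lo, Q, fold)
    n_hi = count_real_eigenvalues(q_hi, Q, fold)
    want_lo, want_hi = Q + 1 - 2 * r, Q + 1 - 2 * (r + 1)
    if (n_lo, n_hi) != (want_lo, want_hi):
        raise BracketError(
            f"bracket ({q_lo}, {q_hi}) has real counts ({n_lo}, {n_hi}); "
            f"expected ({want_lo}, {want_hi}) for pair r={r} at Q={Q}"
        )
    while q_hi - q_lo > tol:
        mid = 0.5 * (q_lo + q_hi)
        if count_real_eigenvalues(mid, Q, fold) <= want_hi:
            q_hi = mid
        else:
            q_lo = mid
    q_star = 0.5 * (q_lo + q_hi)
    return ExceptionalPoint(
        pair_index=r,
        q_star=q_star,
        lambda_star=_lambda_at(max(q_lo - tol, 0.0), Q, fold),
        Q=Q,
        tol=tol,
    )


def scan_cascade(
    Q: int,
    q_max: float,
    q_min: float = 1.0,
    grid_per_decade: int = 60,
    tol: float = 1e-6,
    fold: str = "exact",
    refine_floor: float = 1e-10,
) -> list[ExceptionalPoint]:
    """All EPs with ``q_star <= q_max`` from a log-grid sweep plus bisection.

    The real-eigenvalue count is evaluated on a log grid; every decrement is
    localized by recursive subdivision, so grid steps containing several EPs
    are split automatically until each sub-interval holds exactly one
    transition (or the relative refinement floor is reached).
    """
    if Q < 3:
        raise InvalidParameterError("scan_cascade requires Q >= 3")
    if q_max > 0.1 * Q * Q:
        warnings.warn(
            f"q_max={q_max} is not << Q^2={Q*Q}; truncation distorts the upper cascade"
        )
    n_pts = max(int(np.log10(q_max / q_min) * grid_per_decade), 2)
    grid = np.logspace(np.log10(q_min), np.log10(q_max), n_pts)
    counts = [count_real_eigenvalues(q, Q, fold) for q in grid]
    locations: list[float] = []
    stack = [
        (grid[i], grid[i + 1], counts[i], counts[i + 1])
        for i in range(n_pts - 1)
        if counts[i] > counts[i + 1]
    ]
    while stack:
        lo, hi, n_lo, n_hi = stack.pop()
        drop = (n_lo - n_hi) // 2
        if drop < 0:
            # real count rose with q: pseudospectral flicker of the strongly
            # non-normal crossover band (see methods); not a coalescence
            warnings.warn(
                f"real-eigenvalue count rose by {-2 * drop} in ({lo:g}, {hi:g}); "
                "counting is leaving its reliable activity range"
            )
            continue
        if drop == 0:
            continue
        if drop == 1:
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if count_real_eigenvalues(mid, Q, fold) <= n_hi:
                    hi = mid
                else:
                    lo = mid
            locations.append(0.5 * (lo + hi))
            continue
        if (hi - lo) < refine_floor * hi:
            # multiple apparent transitions inside a floor-width interval can
            # only be count flicker; keep one representative location
            warnings.warn(
                f"refinement floor reached in ({lo:g}, {hi:g}) with {drop} "
                "apparent transitions; recording one (count flicker)"
            )
            locations.append(0.5 * (lo + hi))
            continue
        mid = np.sqrt(lo * hi)
        n_mid = count_real_eigenvalues(mid, Q, fold)
        stack.append((lo, mid, n_lo, n_mid))
        stack.append((mid, hi, n_mid, n_hi))
    merged: list[float] = []
    for q_star in sorted(locations):
        if merged and (q_star - merged[-1]) < 3e-3 * q_star:
            continue  # flicker duplicates of one transition
        merged.append(q_star)
    eps = []
    for r, q_star in enumerate(merged):
        eps.append(
            ExceptionalPoint(
                pair_index=r,
                q_star=q_star,
                lambda_star=_lambda_at(max(q_star - tol, q_min), Q, fold),
                Q=Q,
                tol=tol,
            )
        )
    return eps


def ep_count_exponent(
    eps: list[ExceptionalPoint],
    window: tuple[float, float] | None = None,
    sample: str = "events",
    grid_per_decade: int = 30,
) -> ExponentFit:
    """Density exponent of the cascade: d log N / d log q minus one.

    ``sample="events"`` fits ``log N(q_r) = log (r+1)`` at the EP locations
    inside ``window`` (default: the full cascade) — exact for a power-law
    location sequence.  ``sample="grid"`` evaluates the counting step
    function N(q) on a log-uniform grid across the window before fitting —
    the way a count-versus-activity curve is read off a log-log plot; event
    sampling crowds where EPs are dense, grid sampling weights every decade
    equally.  Reports ``slope - 1``, the exponent of ``rho_q = dN/dq``.
    """
    qs = np.array([ep.q_star for ep in eps])
    if window is None:
        window = (qs[0] * 0.999, qs[-1] * 1.001) if len(qs) else (0.0, 0.0)
    mask = (qs >= window[0]) & (qs <= window[1])
    if mask.sum() < 5:
        raise InvalidParameterError(
            f"need >= 5 exceptional points in window, found {int(mask.sum())}"
        )
    if sample == "events":
        N = np.arange(1, len(eps) + 1, dtype=float)
        fit = fit_loglog_slope(qs[mask], N[mask], window=window, quantity="ep_count")
    elif sample == "grid":
        n_pts = max(int(np.log10(window[1] / window[0]) * grid_per_decade), 5)
        grid = np.logspace(np.log10(window[0]), np.log10(window[1]), n_pts)
        Ngrid = np.searchsorted(qs, grid, side="right").astype(float)
        keep = Ngrid > 0
        fit = fit_loglog_slope(grid[keep], Ngrid[keep], window=window, quantity="ep_count")
    else:
        raise InvalidParameterError(f"unknown sample mode {sample!r}")
    return ExponentFit(
        slope=fit.slope - 1.0,
        stderr=fit.stderr,
        window=fit.window,
        n_points=fit.n_points,
        quantity="ep_density",
    )


def pre_ep_gap_exponent(
    r: int,
    Q: int,
    q_star: float,
    decades: tuple[float, float] = (1e-5, 1e-2),
    n_points: int = 12,
    fold: str = "exact",
) -> ExponentFit:
    """Scaling of the real-eigenvalue gap just below an EP.

    For activity ``q = q* - delta`` the coalescing pair are the two slowest
    *real* eigenvalues (all lower pairs are already complex); their gap
    closes as ``delta^(1/2)`` — the generic square-root approach to a
    second-order exceptional point.
    """
    deltas = np.logspace(np.log10(decades[0]), np.log10(decades[1]), n_points) * q_star
    gaps = []
    for d in deltas:
        ev = np.linalg.eigvals(real_form(build_decay_operator(q_star - d, Q, fold)))
        real = np.sort(ev[ev.imag == 0.0].real)
        if real.size < 2:
            raise BracketError(f"no real pair below q*={q_star} at delta={d}")
        gaps.append(real[1] - real[0])
    fit = fit_loglog_slope(deltas, np.asarray(gaps), quantity=f"gap_r{r}")
    return fit
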