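"""Seeded Langevin simulation of free active Brownian particles.

The free dynamics in rescaled units (time in units of the rotational
diffusion time, lengths in units of the interaction length) are

    dphi = sqrt(2) dW,        dr = Pe (cos phi, sin phi) dt,

so the Peclet number is the only parameter.  The angular process is exactly
Gaussian per step; Euler-Maruyama integration therefore only carries an
O(dt) positional bias, and the step size is capped at dt = 0.05 to keep the
per-step angular variance 2 dt small.

The decay rate of the intermediate scattering function
``F(k, t) = <exp(i k (x(t0+t) - x(t0)))>`` at wave number k is governed by
the spectrum of the folded Fokker-Planck operator at activity q = 2 k Pe;
``estimate_mode_decay`` recovers it from trajectories and provides the
closed-loop check of the spectral predictions.

Seeding uses counter-based Philox streams per block of 1024 particles, so
enlarging the ensemble never reshuffles the trajectories of existing
particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ABPParams",
    "TrajectoryEnsemble",
    "DecayEstimate",
    "InsufficientSignalError",
    "simulate_abp",
    "estimate_mode_decay",
]

_CHUNK = 1024  # particles per Philox stream
_TIME_BLOCK = 4096  # integration steps per vectorized block

DT_MAX = 0.05


class InsufficientSignalError(RuntimeError):
    """The correlation tail is below the statistical noise floor."""


@dataclass(frozen=True)
class ABPParams:
    pe: float
    n_particles: int = 10_000
    dt: float = 0.02
    t_total: float = 100.0
    seed: int = 0
    sample_every: int | None = None  # steps between stored frames (default ~200 frames)

    def __post_init__(self):
        if self.pe < 0:
            raise ValueError("Pe must be >= 0")
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > DT_MAX:
            raise ValueError(
                f"dt={self.dt} exceeds the cap {DT_MAX}; the angular increment "
                "variance 2*dt must stay small — reduce dt"
            )
        if self.t_total <= 0:
            raise ValueError("t_total must be positive")


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Sampled trajectories: arrays of shape (n_frames, n_particles)."""

    times: np.ndarray
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)
    params: ABPParams = None

    @property
    def frame_dt(self) -> float:
        return float(self.times[1] - self.times[0])


def simulate_abp(params: ABPParams) -> TrajectoryEnsemble:
    """Integrate the free dynamics; bit-reproducible for a given seed."""
    n_steps = int(round(params.t_total / params.dt))
    s = params.sample_every or max(1, n_steps // 200)
    sample_steps = np.arange(0, n_steps + 1, s)
    n_frames = sample_steps.size
    n = params.n_particles
    x = np.zeros((n_frames, n))
    y = np.zeros((n_frames, n))
    phi = np.zeros((n_frames, n))
    root = np.sqrt(2.0 * params.dt)
    for c0 in range(0, n, _CHUNK):
        chunk_id = c0 // _CHUNK
        width = min(_CHUNK, n - c0)
        rng = np.random.Generator(np.random.Philox(key=[params.seed, chunk_id]))
        ph = rng.uniform(0.0, 2.0 * np.pi, _CHUNK)
        cx = np.zeros(_CHUNK)
        cy = np.zeros(_CHUNK)
        phi[0, c0 : c0 + width] = ph[:width]
        frame = 1
        step = 0
        while step < n_steps:
            block = min(_TIME_BLOCK, n_steps - step)
            dphi = root * rng.standard_normal((block, _CHUNK))
            ang = ph[None, :] + np.cumsum(dphi, axis=0)
            dx = params.pe * params.dt * np.cos(ang)
            dy = params.pe * params.dt * np.sin(ang)
            bx = cx[None, :] + np.cumsum(dx, axis=0)
            by = cy[None, :] + np.cumsum(dy, axis=0)
            while frame < n_frames and sample_steps[frame] <= step + block:
                j = sample_steps[frame] - step - 1
                x[frame, c0 : c0 + width] = bx[j, :width]
                y[frame, c0 : c0 + width] = by[j, :width]
                phi[frame, c0 : c0 + width] = ang[j, :width]
                frame += 1
            cx, cy, ph = bx[-1].copy(), by[-1].copy(), ang[-1].copy()
            step += block
    times = sample_steps * params.dt
    return TrajectoryEnsemble(times=times, x=x, y=y, phi=phi, params=params)


@dataclass(frozen=True)
class DecayEstimate:
    rate: float
    stderr: float
    ci: tuple[float, float]
    k: float
    q: float
    lam_hat: complex
    n_boot: int
    lags: np.ndarray = field(repr=False, default=None)
    correlation: np.ndarray = field(repr=False, default=None)


def _reference_eigenvalues(q: float, Q: int = 60) -> np.ndarray:
    from .operator import build_decay_operator, diagonalize

    return diagonalize(build_decay_operator(q, Q)).eigenvalues


def _fit_rates(t: np.ndarray, G: np.ndarray, z_init: np.ndarray, target: complex) -> float:
    """Variable-projection least squares for a sum of complex exponentials.

    Amplitudes are solved linearly at every iterate; only the (complex)
    rates are free parameters.  Returns the real part of the fitted rate
    closest to the spectral target.
    """
    K = len(z_init)

    def resid(p):
        z = p[:K] + 1j * p[K:]
        ex = -np.outer(t, z)
        # keep the design matrix finite when the optimizer probes growing modes
        ex.real = np.clip(ex.real, -700.0, 50.0)
        E = np.exp(ex)
        if not np.all(np.isfinite(E)):
            return np.full(2 * len(G), 1e6)
        B, *_ = np.linalg.lstsq(E, G, rcond=None)
        r = G - E @ B
        if not np.all(np.isfinite(r)):
            return np.full(2 * len(G), 1e6)
        return np.concatenate([r.real, r.imag])

    p0 = np.concatenate([np.real(z_init), np.imag(z_init)])
    sol = least_squares(resid, p0, method="lm", max_nfev=4000)
    z = sol.x[:K] + 1j * sol.x[K:]
    return float(z[np.argmin(np.abs(z - target))].real)


def estimate_mode_decay(
    traj: TrajectoryEnsemble,
    k: float,
    lam_hat: complex | None = None,
    window: tuple[float, float] = (0.3, 5.0),
    n_boot: int = 1000,
    seed: int = 0,
) -> DecayEstimate:
    """Slowest decay rate of F(k, t) from a trajectory ensemble.

    The complex correlation ``F(k, t)`` is averaged over particles and over
    time origins strided by half a relaxation time, then fitted over
    ``t in [window[0]/r, window[1]/r]`` (r = expected rate) by a two-mode
    complex-exponential model with rates initialized from the spectral
    module — below the first exceptional point the two slowest real modes,
    above it the conjugate pair.  Uncertainty is a seeded bootstrap over
    particles.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    q = 2.0 * k * traj.params.pe
    if k == 0.0 or q == 0.0:
        return DecayEstimate(
            rate=0.0, stderr=0.0, ci=(0.0, 0.0), k=k, q=q, lam_hat=0.0, n_boot=0
        )
    if lam_hat is None:
        ev = _reference_eigenvalues(q)
        lam_hat = ev[0]
        z_init = (
            np.array([ev[0], np.conj(ev[0])])
            if abs(ev[0].imag) > 1e-9
            else np.array([ev[0], ev[np.argmax(ev.real > ev[0].real + 1e-12)]])
        )
    else:
        z_init = (
            np.array([lam_hat, np.conj(lam_hat)])
            if abs(complex(lam_hat).imag) > 1e-9
            else np.array([complex(lam_hat), complex(lam_hat) * 4.0])
        )
    r = complex(lam_hat).real
    if r <= 0:
        raise ValueError("expected decay rate must be positive")
    dt_s = traj.frame_dt
    if traj.times[-1] < window[1] / r:
        raise ValueError(
            f"t_total={traj.times[-1]:g} too short for the fit window "
            f"[{window[0]/r:g}, {window[1]/r:g}]; simulate at least 10/lambda"
        )
    j_lo = max(1, int((window[0] / r) / dt_s))
    j_hi = min(len(traj.times) - 1, int((window[1] / r) / dt_s))
    lags = np.arange(j_lo, j_hi + 1)
    stride = max(1, int((0.5 / r) / dt_s))
    n = traj.x.shape[1]
    Fi = np.empty((lags.size, n), dtype=complex)
    for j, L in enumerate(lags):
        origins = np.arange(0, len(traj.times) - L, stride)
        Fi[j] = np.exp(1j * k * (traj.x[origins + L] - traj.x[origins])).mean(axis=0)
    G = Fi.mean(axis=1)
    tail_se = float(np.abs(Fi[-1]).std() / np.sqrt(n))
    if np.abs(G[-1]) < 3.0 * tail_se and np.abs(G).max() < 3.0 * tail_se:
        raise InsufficientSignalError(
            f"correlation ({np.abs(G[-1]):.2e}) below 3x noise floor ({tail_se:.2e})"
        )
    t = lags * dt_s
    rate = _fit_rates(t, G, z_init, complex(lam_hat))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[b] = _fit_rates(t, Fi[:, idx].mean(axis=1), z_init, complex(lam_hat))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return DecayEstimate(
        rate=rate,
        stderr=float(boots.std()),
        ci=(float(lo), float(hi)),
        k=k,
        q=q,
        lam_hat=complex(lam_hat),
        n_boot=n_boot,
        lags=t,
        correlation=G,
    )
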