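"""Kuramoto phase oscillators coupled through an inferred brain network.

Each channel becomes a phase oscillator; the coupling matrix is the
(thresholded) symbolic-transfer-entropy matrix, so the dynamics probe how
readily the inferred network synchronizes:

    d theta_i / dt = omega_i + (K / N) * sum_j G_ij sin(theta_j - theta_i)

with N = 23 oscillators, coupling constant K = 3.5, and intrinsic
frequencies evenly distributed over [0, 1].  Integration is fixed-step
fourth-order Runge-Kutta.  The synchronization level is quantified by the
mean-field order parameter r(t) e^{j psi(t)} = (1/N) sum e^{j theta_i(t)}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .defaults import KURAMOTO_K, N_CHANNELS


@dataclass
class KuramotoConfig:
    """Simulation settings.

    ``omega=None`` selects the deterministic even grid ``i / (N - 1)`` over
    [0, 1]; ``random_omega`` replaces it with a uniform draw.  ``theta0``
    defaults to seeded uniform initial phases on [0, 2 pi).
    """

    n: int = N_CHANNELS
    K: float = KURAMOTO_K
    omega: np.ndarray = None
    theta0: np.ndarray = None
    dt: float = 0.01
    T: float = 1000.0
    save_stride: int = 10
    seed: int = 0
    random_omega: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.T <= 0:
            raise ValueError("T must be positive")

    def resolve(self) -> tuple:
        """Concrete (omega, theta0) arrays for this configuration."""
        rng = np.random.default_rng(self.seed)
        if self.omega is not None:
            omega = np.asarray(self.omega, dtype=float)
        elif self.random_omega:
            omega = rng.uniform(0.0, 1.0, self.n)
        else:
            omega = (np.arange(self.n) / (self.n - 1) if self.n > 1
                     else np.zeros(1))
        theta0 = (np.asarray(self.theta0, dtype=float) if self.theta0 is not None
                  else rng.uniform(0.0, 2 * np.pi, self.n))
        if omega.shape != (self.n,) or theta0.shape != (self.n,):
            raise ValueError("omega/theta0 must have length n")
        return omega, theta0


@dataclass
class KuramotoTrajectory:
    """Sampled phases (radians) with their time axis."""

    times: np.ndarray          # (n_saved,)
    phases: np.ndarray         # (n_saved, n)
    config: KuramotoConfig


@dataclass
class SyncSeries:
    """Order-parameter magnitude r(t) in [0, 1] and mean phase psi(t)."""

    times: np.ndarray
    r: np.ndarray
    psi: np.ndarray


def simulate(G: np.ndarray, cfg: KuramotoConfig) -> KuramotoTrajectory:
    """Integrate the phase dynamics on coupling matrix ``G``.

    ``G[i, j]`` weights the influence of oscillator j on oscillator i, as
    in the model equation.  ``G`` must be square of dimension ``cfg.n``,
    nonnegative with a zero diagonal.  The trajectory is saved every
    ``save_stride`` steps (always including t = 0 and the final step) and
    is deterministic given the seed.
    """
    G = np.asarray(G, dtype=float)
    if G.shape != (cfg.n, cfg.n):
        raise ValueError(f"coupling matrix must be {cfg.n}x{cfg.n}, got {G.shape}")
    if np.any(G < 0):
        raise ValueError("coupling matrix must be nonnegative")
    if np.any(np.diag(G) != 0):
        raise ValueError("coupling matrix diagonal must be zero")

    omega, theta = cfg.resolve()
    theta = theta.copy()
    n_steps = int(round(cfg.T / cfg.dt))
    kn = cfg.K / cfg.n

    def deriv(th):
        z = np.exp(1j * th)
        return omega + kn * np.imag(np.conj(z) * (G @ z))

    saved_t = [0.0]
    saved_th = [theta.copy()]
    dt = cfg.dt
    for step in range(1, n_steps + 1):
        k1 = deriv(theta)
        k2 = deriv(theta + 0.5 * dt * k1)
        k3 = deriv(theta + 0.5 * dt * k2)
        k4 = deriv(theta + dt * k3)
        theta = theta + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if step % cfg.save_stride == 0 or step == n_steps:
            saved_t.append(step * dt)
            saved_th.append(theta.copy())
    return KuramotoTrajectory(times=np.array(saved_t),
                              phases=np.array(saved_th), config=cfg)


def order_parameter(traj: KuramotoTrajectory) -> SyncSeries:
    """Mean-field order parameter of the trajectory."""
    z = np.exp(1j * traj.phases).mean(axis=1)
    return SyncSeries(times=traj.times.copy(), r=np.abs(z), psi=np.angle(z))


def time_to_sync(series: SyncSeries, r_threshold: float = 0.9,
                 slack: float = 0.05):
    """First time r(t) reaches the threshold and stays near it.

    Returns the earliest time at which ``r >= r_threshold`` and ``r``
    remains at or above ``r_threshold - slack`` for the rest of the
    horizon, or ``None`` if synchronization is never sustained.
    """
    if not (0 < r_threshold <= 1):
        raise ValueError("r_threshold must be in (0, 1]")
    r = series.r
    # suffix minimum: sustained_from[t] = min r[t:]
    sustained = np.minimum.accumulate(r[::-1])[::-1]
    ok = (r >= r_threshold) & (sustained >= r_threshold - slack)
    idx = np.argmax(ok)
    if not ok[idx]:
        return None
    return float(series.times[idx])


def snapshot(traj: KuramotoTrajectory, times=(0.0, 150.0, 1000.0)) -> dict:
    """Unit-circle oscillator positions e^{j theta_i} at requested times.

    Returns ``{t: {"points": (n, 2) array of (re, im), "r": float}}``; each
    requested time snaps to the nearest saved sample and must lie within
    the simulated horizon.
    """
    out = {}
    t_max = traj.times[-1]
    for t in times:
        if t < 0 or t > t_max:
            raise ValueError(f"snapshot time {t} outside horizon [0, {t_max}]")
        idx = int(np.argmin(np.abs(traj.times - t)))
        z = np.exp(1j * traj.phases[idx])
        out[float(t)] = {
            "points": np.column_stack([z.real, z.imag]),
            "r": float(np.abs(z.mean())),
        }
    return out


def save_snapshot_png(snaps: dict, path) -> None:
    """Plot complex-plane snapshots (one panel per requested time)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    times = sorted(snaps)
    fig, axes = plt.subplots(1, len(times), figsize=(3 * len(times), 3))
    axes = np.atleast_1d(axes)
    circle = np.exp(1j * np.linspace(0, 2 * np.pi, 200))
    for ax, t in zip(axes, times):
        pts = snaps[t]["points"]
        ax.plot(circle.real, circle.imag, color="0.8", lw=1)
        ax.scatter(pts[:, 0], pts[:, 1], s=18)
        ax.set_title(f"t = {t:g}, r = {snaps[t]['r']:.2f}")
        ax.set_aspect("equal")
        ax.set_xlim(-1.2, 1.2)
        ax.set_ylim(-1.2, 1.2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def normalize_total_weight(G: np.ndarray, total: float) -> np.ndarray:
    """Rescale a nonnegative coupling matrix to a given total edge weight.

    Used to compare how quickly two networks synchronize while holding the
    overall coupling budget fixed (networks of "similar coordination"); a
    zero matrix is returned unchanged.
    """
    G = np.asarray(G, dtype=float)
    s = G.sum()
    return G * (total / s) if s > 0 else G.copy()
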