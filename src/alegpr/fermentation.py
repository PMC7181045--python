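"""Seeded fed-batch penicillin fermentation generator.

A four-state kinetic skeleton of the classic fed-batch penicillin process
(biomass X, substrate S, product P, volume V) in the Bajpai-Reuss tradition:

    mu     = mu_max * S / (K_contois * X + S)            Contois growth
    rep    = 1 / (1 + (mu / mu_crit)^h)                  growth repression
    mu_pp  = mu_p * S / (K_p + S + S^2 / K_i) * rep      specific production
    dX/dt  = mu X - k_d * K_ds/(K_ds + S) * X - (q/V) X  growth, autolysis
    dS/dt  = -mu X / Y_xs - mu_pp X / Y_ps - m_x X + q (c_f - S)/V
    dP/dt  = mu_pp X - k_h P - (q/V) P                   production, hydrolysis
    dV/dt  = q = F / rho                                 feed dilution

Penicillin synthesis is non-growth-associated: the repression factor keeps
production off while the culture grows fast (carbon catabolite repression)
and switches it on smoothly once the specific growth rate falls below
``mu_crit`` during the fed-batch phase.

The run traverses three physiological phases — batch growth until the feed
switches on, fed-batch production, and autolysis/decline after the feed
stops — which appear in the measured channels as distinct operating regimes:
pH and temperature setpoints step between phases, agitation and aeration
track biomass demand, and the feed-rate channel follows the schedule.
Controlled channels carry a small AR(1) wander plus measurement noise
(sd = 1% of each channel's noiseless range); both scale with ``noise_scale``
so the noiseless trajectory is bit-identical across seeds.

This generator stands in for an external process simulator and is not a
numerical replica of any particular plant; constants are chosen so the
penicillin trajectory spans roughly 0-1.5 g/L over a 400 h batch sampled
every 0.5 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .data import Dataset


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants, feed schedule, initial state and sampling grid.

    Rates are 1/h, concentrations g/L, yields g/g, volumes L, times h.
    ``feed_schedule`` is a list of (t_start, t_end, feed g/h) segments;
    outside all segments the feed is zero.
    """

    mu_max: float = 0.05                  # max specific growth rate
    k_contois: float = 0.50               # Contois saturation constant
    mu_p: float = 0.020                   # specific production rate constant
    k_p: float = 0.30                     # production saturation constant
    k_i: float = 1.0                      # substrate inhibition constant
    mu_crit: float = 0.010                # growth rate gating production
    rep_hill: float = 8.0                 # sharpness of the repression switch
    y_xs: float = 0.50                    # biomass/substrate yield
    y_ps: float = 0.90                    # product/substrate yield
    m_x: float = 0.025                    # maintenance coefficient
    k_d: float = 0.005                    # autolysis (death) rate
    k_ds: float = 0.08                    # substrate level halving autolysis
    k_h: float = 0.050                    # product hydrolysis rate
    feed_conc: float = 400.0              # substrate conc. in feed solution
    feed_density: float = 1150.0          # feed solution density g/L
    feed_schedule: tuple[tuple[float, float, float], ...] = ((70.0, 220.0, 120.0),)
    feed_taper: float = 0.007             # 1/h exponential feed ramp-down
    x0: float = 0.4                       # initial biomass
    s0: float = 16.0                      # initial substrate
    p0: float = 0.0                       # initial penicillin
    v0: float = 100.0                     # initial culture volume
    duration: float = 400.0
    interval: float = 0.5
    noise_scale: float = 1.0              # multiplies wander + measurement noise

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.interval <= 0:
            raise ValueError("duration and interval must be positive")
        for name in ("mu_max", "k_contois", "mu_p", "k_p", "k_i", "y_xs", "y_ps",
                     "m_x", "k_d", "k_ds", "k_h", "x0", "s0", "p0", "v0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def feed_at(self, t: float) -> float:
        for t0, t1, f in self.feed_schedule:
            if t0 <= t < t1:
                return f * np.exp(-self.feed_taper * (t - t0))
        return 0.0

    def phase_times(self) -> tuple[float, float]:
        """Batch->production and production->decline boundaries."""
        if not self.feed_schedule:
            third = self.duration / 3.0
            return third, 2.0 * third
        return self.feed_schedule[0][0], self.feed_schedule[-1][1]


@dataclass
class BatchTrajectory:
    """Simulated batch: time grid, states, phases and measured channels."""

    t: np.ndarray
    states: np.ndarray                    # (n, 4): X, S, P, V
    U: np.ndarray                         # (n, 7): measured u1..u7
    y: np.ndarray                         # penicillin concentration g/L
    phases: np.ndarray                    # 0 growth, 1 production, 2 decline
    noise_sd: np.ndarray = field(default_factory=lambda: np.zeros(7))


class IntegrationError(RuntimeError):
    """The kinetic ODE system could not be integrated."""


def _integrate_states(params: KineticParams) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic state trajectories on the sampling grid."""

    def rhs(t, z):
        X, S, P, V = z
        Xp, Sp = max(X, 0.0), max(S, 0.0)
        q = params.feed_at(t) / params.feed_density
        mu = params.mu_max * Sp / (params.k_contois * Xp + Sp + 1e-12)
        rep = 1.0 / (1.0 + (mu / params.mu_crit) ** params.rep_hill)
        mu_pp = params.mu_p * Sp / (params.k_p + Sp + Sp**2 / params.k_i) * rep
        death = params.k_d * params.k_ds / (params.k_ds + Sp)
        dX = mu * Xp - death * Xp - (q / V) * Xp
        dS = (
            -mu * Xp / params.y_xs
            - mu_pp * Xp / params.y_ps
            - params.m_x * Xp * Sp / (Sp + 1e-3)
            + q * (params.feed_conc - Sp) / V
        )
        dP = mu_pp * Xp - params.k_h * P - (q / V) * P
        dV = q
        return [dX, dS, dP, dV]

    n = int(round(params.duration / params.interval)) + 1
    t_grid = np.linspace(0.0, params.duration, n)
    # integrate piecewise so feed discontinuities fall on segment edges
    edges = sorted(
        {0.0, params.duration}
        | {t for seg in params.feed_schedule for t in seg[:2] if 0 < t < params.duration}
    )
    states = [np.array([params.x0, params.s0, params.p0, params.v0])]
    t_points = [0.0]
    z = states[0]
    for t0, t1 in zip(edges[:-1], edges[1:]):
        inside = t_grid[(t_grid > t0) & (t_grid <= t1)]
        t_eval = np.unique(np.concatenate([inside, [t1]]))
        sol = solve_ivp(
            rhs, (t0, t1), z, t_eval=t_eval, method="LSODA",
            rtol=1e-8, atol=1e-10, max_step=2.0,
        )
        if not sol.success:
            raise IntegrationError(f"ODE integration failed on [{t0}, {t1}]: {sol.message}")
        for tt, zz in zip(sol.t, sol.y.T):
            if tt in t_grid and tt > t_points[-1]:
                t_points.append(float(tt))
                states.append(zz)
        z = sol.y[:, -1]
    states = np.maximum(np.array(states), 0.0)
    return np.array(t_points), states


# phase-wise setpoints for the controlled channels (growth, production, decline)
_PH_SET = (5.0, 5.5, 5.8)
_FEED_TEMP_SET = (296.0, 297.0, 295.5)
_FERM_TEMP_SET = (297.0, 297.5, 296.5)
# stationary wander sd per channel u1..u7: level-sensor drift, broth-rheology
# load swings, controller cycling and pump variability respectively
_WANDER_SD = np.array([0.6, 0.7, 0.05, 0.20, 0.15, 1.5, 0.45])


def _ar1_wander(n: int, sd: float, rng: np.random.Generator, rho: float = 0.98) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n)
    w = np.empty(n)
    w[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        w[i] = rho * w[i - 1] + eps[i]
    return w


def simulate_batch(params: KineticParams = KineticParams(), seed: int = 0) -> BatchTrajectory:
    """Simulate one fed-batch run and derive the measured channels.

    The noiseless states depend only on ``params``; ``seed`` drives the
    controlled-channel wander and the measurement noise, both multiplied by
    ``params.noise_scale``.
    """
    t, states = _integrate_states(params)
    X, S, P, V = states.T
    n = t.shape[0]
    t1, t2 = params.phase_times()
    phases = np.where(t < t1, 0, np.where(t < t2, 1, 2)).astype(int)

    feed = np.array([params.feed_at(tt) for tt in t])
    clean = np.empty((n, 7))
    clean[:, 0] = V                                        # u1 culture volume
    clean[:, 1] = 28.0 + 0.5 * X                           # u2 agitator power
    clean[:, 2] = np.take(_PH_SET, phases)                 # u3 pH
    clean[:, 3] = np.take(_FEED_TEMP_SET, phases)          # u4 feed temperature
    clean[:, 4] = np.take(_FERM_TEMP_SET, phases)          # u5 fermenter temp
    clean[:, 5] = feed                                     # u6 substrate feed rate
    clean[:, 6] = 8.0 + 0.15 * X + np.take((0.0, 1.2, 0.3), phases)  # u7 aeration

    rng = np.random.default_rng(seed)
    scale = params.noise_scale
    U = clean.copy()
    for j in range(7):
        U[:, j] += scale * _ar1_wander(n, _WANDER_SD[j], rng)
    ranges = clean.max(axis=0) - clean.min(axis=0)
    noise_sd = scale * 0.01 * np.where(ranges > 0, ranges, 1.0)
    U += rng.normal(0.0, 1.0, size=(n, 7)) * noise_sd
    y = P.copy()
    return BatchTrajectory(t=t, states=states, U=U, y=y, phases=phases,
                           noise_sd=noise_sd)


def generate_dataset(
    params: KineticParams = KineticParams(), n_samples: int = 800, seed: int = 0
) -> Dataset:
    """Dataset of the first ``n_samples`` grid points of one simulated batch."""
    traj = simulate_batch(params, seed=seed)
    if traj.t.shape[0] < n_samples:
        raise ValueError(
            f"batch yields {traj.t.shape[0]} samples; {n_samples} requested"
        )
    return Dataset(
        ids=np.arange(n_samples, dtype=np.int64),
        X=traj.U[:n_samples],
        y=traj.y[:n_samples],
    )


def phase_labels(
    params: KineticParams = KineticParams(), n_samples: int = 800
) -> np.ndarray:
    """Ground-truth physiological phase per dataset row (0/1/2)."""
    n = int(round(params.duration / params.interval)) + 1
    t = np.linspace(0.0, params.duration, n)[:n_samples]
    t1, t2 = params.phase_times()
    return np.where(t < t1, 0, np.where(t < t2, 1, 2)).astype(int)


class LabelOracle:
    """Ground-truth annotator: returns stored quality values and counts queries."""

    def __init__(self, data: Dataset):
        self._y = {int(s): float(v) for s, v in zip(data.ids, data.y)}
        self.query_count = 0

    def __call__(self, ids) -> np.ndarray:
        ids = [int(s) for s in ids]
        if len(set(ids)) != len(ids):
            raise ValueError("repeated id in one oracle call")
        try:
            values = np.array([self._y[s] for s in ids])
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]}") from exc
        if not np.all(np.isfinite(values)):
            raise ValueError("oracle asked for a sample with no ground truth")
        self.query_count += len(ids)
        return values
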