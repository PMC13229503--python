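"""Synthetic-data generators for every pipeline input.

Generators produce µsALEX-like photon streams with two-state continuous-time
Markov chain (CTMC) FRET dynamics, mass-transport-limited SPR cycles,
binding titrations and right-censored dwell-time samples.  Every generator
embeds its ground-truth parameters and seed in the output metadata so that
downstream recovery tests read truth only from there.

Diffusion is not modeled explicitly: single-molecule transits are generated
directly as bursts with log-normal duration (median 1 ms) and constant
within-burst brightness, which carries every statistic the analyses consume
(burst photon counts, E*/S*, window proximity ratios).  Excitation
assignment is carried by the photon stream label (DD/DA/AA), not by the
timestamp phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .smfret import PhotonStream
from .spr import Sensorgram, SPRModelParams, simulate_response

__all__ = [
    "SimConfig",
    "DwellData",
    "TitrationSeries",
    "simulate_photon_stream",
    "simulate_sensorgram",
    "simulate_titration",
    "simulate_dwells",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the photon-stream generator.

    Brightnesses are detected photon rates (photons/s) of one molecule during
    a burst: ``brightness`` for donor-excitation photons (split DD/DA by the
    current FRET state) and ``a_brightness`` for acceptor-excitation (AA)
    photons.  ``E1``/``E2`` with exchange rates ``k_12``/``k_21`` (s^-1)
    define the two-state FRET model; set ``k_12 = k_21 = 0`` for a static
    molecule at ``E1``.  Optional correction factors alpha (direct acceptor
    excitation), beta (spectral crosstalk) and gamma (detection asymmetry)
    default to off so the apparent E* equals the state E.
    """

    seed: int = 0
    alternation_period: float = 50e-6
    clock: float = 100e-9
    brightness: float = 250e3
    a_brightness: float = 180e3
    background: dict = field(
        default_factory=lambda: {"DD": 1500.0, "DA": 800.0, "AA": 1200.0}
    )
    E1: float = 0.51
    E2: float = 0.68
    k_12: float = 0.0
    k_21: float = 0.0
    burst_rate: float = 5.0
    burst_duration_median: float = 1e-3
    burst_duration_sigma: float = 0.5
    donor_only_fraction: float = 0.0
    acceptor_only_fraction: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for e in (self.E1, self.E2):
            if not 0.0 <= e <= 1.0:
                raise ValueError("FRET efficiencies must lie in [0, 1]")
        if self.k_12 < 0 or self.k_21 < 0:
            raise ValueError("exchange rates must be >= 0")
        if self.donor_only_fraction + self.acceptor_only_fraction > 1:
            raise ValueError("impurity fractions must sum to <= 1")


def _ctmc_path(rng, E1, E2, k_12, k_21, duration):
    """Switch times and state E values of a two-state CTMC over [0, duration]."""
    if k_12 <= 0 or k_21 <= 0:
        return np.array([0.0]), np.array([E1])
    p1 = k_21 / (k_12 + k_21)  # stationary occupancy of state 1
    state = 0 if rng.random() < p1 else 1
    t, times, states = 0.0, [0.0], [state]
    while t < duration:
        rate = k_12 if state == 0 else k_21
        t += rng.exponential(1.0 / rate)
        state = 1 - state
        if t < duration:
            times.append(t)
            states.append(state)
    E = np.where(np.array(states) == 0, E1, E2)
    return np.array(times), E


def simulate_photon_stream(
    config: SimConfig, duration: float, rng: np.random.Generator | None = None
) -> PhotonStream:
    """Generate a photon stream of ``duration`` seconds under ``config``.

    Photons are drawn as Poisson processes per stream: a constant background
    plus molecule bursts arriving at ``config.burst_rate`` with log-normal
    durations.  During a burst each donor-excitation photon is routed to the
    acceptor channel with probability set by the molecule's current CTMC
    state (plus optional crosstalk terms); acceptor-excitation photons arrive
    at the direct-excitation brightness.  Reproducible for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if duration <= 0:
        return PhotonStream(
            timestamps=np.array([], dtype=np.int64),
            stream=np.array([], dtype=object),
            clock=config.clock,
            alternation_period=config.alternation_period,
            background=dict(config.background),
            truth={"config": asdict(config), "duration": duration},
        )
    times, labels = [], []

    for name, rate in config.background.items():
        n = rng.poisson(rate * duration)
        times.append(rng.uniform(0.0, duration, n))
        labels.append(np.full(n, name, dtype=object))

    n_bursts = rng.poisson(config.burst_rate * duration)
    starts = np.sort(rng.uniform(0.0, duration, n_bursts))
    mu_ln = math.log(config.burst_duration_median)
    for t0 in starts:
        d = rng.lognormal(mu_ln, config.burst_duration_sigma)
        d = min(d, duration - t0)
        if d <= 0:
            continue
        u = rng.random()
        donor_only = u < config.donor_only_fraction
        acceptor_only = (not donor_only) and u < (
            config.donor_only_fraction + config.acceptor_only_fraction
        )
        # donor-excitation photons
        if not acceptor_only:
            n_d = rng.poisson(config.brightness * d)
            t_d = t0 + rng.uniform(0.0, d, n_d)
            if donor_only:
                E_at = np.zeros(n_d)
            else:
                sw, sE = _ctmc_path(
                    rng, config.E1, config.E2, config.k_12, config.k_21, d
                )
                E_at = sE[np.searchsorted(sw, t_d - t0, side="right") - 1]
            g, b = config.gamma, config.beta
            p_da = (g * E_at + b * (1 - E_at)) / ((1 - E_at) * (1 + b) + g * E_at)
            is_da = rng.random(n_d) < p_da
            times.append(t_d)
            labels.append(np.where(is_da, "DA", "DD").astype(object))
        # acceptor-excitation photons, plus direct-excitation leakage into DA
        if not donor_only:
            n_a = rng.poisson(config.a_brightness * d)
            t_a = t0 + rng.uniform(0.0, d, n_a)
            times.append(t_a)
            labels.append(np.full(n_a, "AA", dtype=object))
            if config.alpha > 0:
                n_leak = rng.binomial(n_a, min(config.alpha, 1.0))
                times.append(t0 + rng.uniform(0.0, d, n_leak))
                labels.append(np.full(n_leak, "DA", dtype=object))

    t_all = np.concatenate(times) if times else np.array([])
    l_all = np.concatenate(labels) if labels else np.array([], dtype=object)
    order = np.argsort(t_all, kind="stable")
    ticks = np.round(t_all[order] / config.clock).astype(np.int64)
    return PhotonStream(
        timestamps=ticks,
        stream=l_all[order],
        clock=config.clock,
        alternation_period=config.alternation_period,
        background=dict(config.background),
        truth={"config": asdict(config), "duration": duration},
    )


def simulate_sensorgram(
    params: SPRModelParams,
    L_bulk: float,
    schedule: tuple[float, float, float] = (60.0, 110.0, 470.0),
    noise_sd: float = 0.02,
    drift: dict | None = None,
    seed: int = 0,
    sample_rate: float = 10.0,
) -> Sensorgram:
    """Simulate one SPR cycle: baseline, association at ``L_bulk``, dissociation.

    The default schedule mirrors a 60 s baseline, 50 s association and 360 s
    dissociation.  Gaussian noise of ``noise_sd`` RU and an optional
    exponential drift ``{"a": .., "b": .., "c": ..}`` (a e^-bt + c) are added;
    the truth parameters travel in the sensorgram metadata.
    """
    rng = np.random.default_rng(seed)
    b_end, a_end, d_end = schedule
    t = np.arange(0.0, d_end + 1.0 / sample_rate, 1.0 / sample_rate)
    r = np.zeros_like(t)
    assoc = (t >= b_end) & (t < a_end)
    dissoc = t >= a_end
    t_assoc = t[assoc] - b_end
    if t_assoc.size:
        t_grid = np.concatenate([t_assoc, [a_end - b_end]])
        r_assoc = simulate_response(params, L_bulk, t_grid)
        r[assoc] = r_assoc[:-1]
        r_end = r_assoc[-1]
        # carry the surface ligand concentration into the dissociation phase
        from scipy.integrate import solve_ivp
        from .spr import spr_ode_rhs

        sol = solve_ivp(
            lambda _t, y: spr_ode_rhs(params, L_bulk, y),
            (0.0, a_end - b_end),
            np.array([0.0, 0.0]),
            method="LSODA",
            rtol=1e-8,
            atol=1e-11,
        )
        L_surf_end = sol.y[0, -1]
        t_dis = t[dissoc] - a_end
        sol2 = solve_ivp(
            lambda _t, y: spr_ode_rhs(params, 0.0, y),
            (0.0, max(t_dis[-1], 1e-9)),
            np.array([L_surf_end, r_end]),
            t_eval=t_dis,
            method="LSODA",
            rtol=1e-8,
            atol=1e-11,
        )
        r[dissoc] = sol2.y[1]
    if drift:
        r = r + drift["a"] * np.exp(-drift["b"] * t) + drift["c"]
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, t.size)
    return Sensorgram(
        time=t,
        response=r,
        L_bulk=L_bulk,
        schedule=schedule,
        truth={
            "k_t": params.k_t,
            "k_on": params.k_on,
            "k_off": params.k_off,
            "r_max": params.r_max,
            "alpha": params.alpha,
            "noise_sd": noise_sd,
            "drift": drift,
            "seed": seed,
        },
    )


@dataclass(frozen=True)
class TitrationSeries:
    """Fraction-closed vs ligand concentration with generator truth attached."""

    concentrations: np.ndarray
    fraction_closed: np.ndarray
    n_bursts: int
    truth: dict = field(default_factory=dict, compare=False)


def simulate_titration(
    K_d: float,
    concentrations: np.ndarray,
    n_bursts_per_point: int = 500,
    seed: int = 0,
) -> TitrationSeries:
    """Draw fraction-closed values around the isotherm [L]/(K_d + [L]).

    Each point is a binomial fraction of ``n_bursts_per_point`` bursts
    classified closed, the shot-noise model of a burst-counting titration.
    """
    rng = np.random.default_rng(seed)
    L = np.asarray(concentrations, dtype=float)
    if np.any(L <= 0):
        raise ValueError("concentrations must be positive")
    p = L / (K_d + L)
    counts = rng.binomial(n_bursts_per_point, p)
    return TitrationSeries(
        concentrations=L,
        fraction_closed=counts / n_bursts_per_point,
        n_bursts=n_bursts_per_point,
        truth={"K_d": K_d, "seed": seed},
    )


@dataclass(frozen=True)
class DwellData:
    """Observed transition times plus right-censoring bookkeeping."""

    times: np.ndarray
    n_censored: int
    horizon: float
    truth: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(t > self.horizon + 1e-12) or np.any(t < 0):
            raise ValueError("observed times must lie in [0, horizon]")
        object.__setattr__(self, "times", t)

    @property
    def n_observed(self) -> int:
        return self.times.size


def simulate_dwells(
    mean_dwell: float, n_traj: int, horizon: float, seed: int = 0
) -> DwellData:
    """Exponential first-passage times right-censored at ``horizon``.

    Emulates a set of fixed-length trajectories of which only some exhibit
    the transition within the observation window.
    """
    if mean_dwell <= 0 or horizon <= 0 or n_traj <= 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    t = rng.exponential(mean_dwell, n_traj)
    observed = t[t <= horizon]
    return DwellData(
        times=observed,
        n_censored=int(n_traj - observed.size),
        horizon=horizon,
        truth={"mean_dwell": mean_dwell, "seed": seed, "n_traj": n_traj},
    )
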