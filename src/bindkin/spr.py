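"""Mass-transport-limited SPR sensorgram model and fitting.

The sensor response r (in RU) follows the two-step scheme: ligand is carried
from the bulk flow to the sensor surface with transport rate k_t (both
directions) and binds the immobilized protein with effective rate constants
k_on / k_off,

    d[L]_surf/dt = k_t ([L]_bulk - [L]_surf) - d[PL]/dt
    d[PL]/dt     = k_on [L]_surf ([P]_tot - [PL]) - k_off [PL]

with [PL] = alpha * r and [P]_tot = alpha * r_max.  When transport dominates
(alpha k_on r_max >> k_t) the sensorgram shape is nearly independent of k_on,
so k_on is not identifiable from a single fit; profiling the sum of squared
residuals over a fixed-k_on grid instead yields a *lower bound* on k_on: the
rescaled SSR is flat (≈1) above a knee and rises below it.

Fit results for the rate constants are insensitive to the RU-to-molar
conversion factor alpha (default 1 µM/RU).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "Sensorgram",
    "SPRModelParams",
    "SSRProfile",
    "EquilibriumSeries",
    "spr_ode_rhs",
    "simulate_response",
    "correct_drift",
    "fit_association",
    "fit_dissociation",
    "ssr_profile",
    "default_k_on_grid",
    "k_on_lower_bound",
    "fit_equilibrium_Kd",
]


@dataclass(frozen=True)
class Sensorgram:
    """A timed RU trace with its phase schedule and bulk ligand concentration.

    ``schedule`` holds (baseline_end, association_end, dissociation_end) in
    seconds on the same clock as ``time``; ligand flows at ``L_bulk`` during
    the association phase and at zero otherwise.
    """

    time: np.ndarray
    response: np.ndarray
    L_bulk: float
    schedule: tuple[float, float, float]
    truth: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if t.ndim != 1 or t.shape != r.shape:
            raise ValueError("time and response must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("response must be finite")
        b, a, d = self.schedule
        if not (b < a < d):
            raise ValueError("schedule must be ordered baseline < association < dissociation")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)

    def phase_mask(self, phase: str) -> np.ndarray:
        b, a, d = self.schedule
        if phase == "baseline":
            return self.time < b
        if phase == "association":
            return (self.time >= b) & (self.time < a)
        if phase == "dissociation":
            return (self.time >= a) & (self.time <= d)
        raise ValueError(f"unknown phase {phase!r}")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "response_RU": self.response}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, L_bulk: float, schedule: tuple[float, float, float]) -> "Sensorgram":
        df = pd.read_csv(path)
        return cls(
            time=df["time_s"].to_numpy(),
            response=df["response_RU"].to_numpy(),
            L_bulk=L_bulk,
            schedule=schedule,
        )


@dataclass(frozen=True)
class SPRModelParams:
    """Transport + binding parameters of the sensorgram model.

    alpha converts RU to molar surface concentration (M/RU); the paper-typical
    default is 1 µM/RU and the fitted rate constants are insensitive to it.
    """

    k_t: float
    k_on: float
    k_off: float
    r_max: float
    offset: float = 0.0
    alpha: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("k_t", "k_on", "k_off", "r_max", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def K_d(self) -> float:
        return self.k_off / self.k_on


@dataclass(frozen=True)
class SSRProfile:
    """Rescaled SSR vs k_on: each profile is divided by its grid minimum."""

    k_on_grid: np.ndarray
    ssr_rescaled: np.ndarray
    label: str = ""
    failed: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.k_on_grid, dtype=float)
        s = np.asarray(self.ssr_rescaled, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValueError("k_on grid must be sorted ascending")
        if np.any(s[np.isfinite(s)] < 1.0 - 1e-9):
            raise ValueError("rescaled SSR must be >= 1")
        object.__setattr__(self, "k_on_grid", g)
        object.__setattr__(self, "ssr_rescaled", s)

    def to_csv(self, path) -> None:
        pd.DataFrame({"k_on": self.k_on_grid, "ssr_rescaled": self.ssr_rescaled}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class EquilibriumSeries:
    """Maximal (plateau) responses versus ligand concentration."""

    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if np.any(c <= 0) or not np.all(np.isfinite(r)):
            raise ValueError("concentrations must be positive and responses finite")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)


def spr_ode_rhs(params: SPRModelParams, L_bulk: float, state: np.ndarray) -> np.ndarray:
    """Right-hand side of the coupled transport/binding ODE.

    ``state`` is (L_surf in M, r in RU).  Returns (dL_surf/dt, dr/dt).
    """
    L_surf, r = state
    dr = params.k_on * L_surf * (params.r_max - r) - params.k_off * r
    dL = params.k_t * (L_bulk - L_surf) - params.alpha * dr
    return np.array([dL, dr])


def simulate_response(
    params: SPRModelParams,
    L_bulk: float,
    t: np.ndarray,
    init: tuple[float, float] = (0.0, 0.0),
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> np.ndarray:
    """Integrate the model over ``t`` (starting at t[0]) and return r(t) in RU."""
    t = np.asarray(t, dtype=float)

    def jac(_t, y):
        L_surf, r = y
        d_dr_dL = params.k_on * (params.r_max - r)
        d_dr_dr = -params.k_on * L_surf - params.k_off
        return np.array(
            [
                [-params.k_t - params.alpha * d_dr_dL, -params.alpha * d_dr_dr],
                [d_dr_dL, d_dr_dr],
            ]
        )

    sol = solve_ivp(
        lambda _t, y: spr_ode_rhs(params, L_bulk, y),
        (t[0], t[-1]),
        np.asarray(init, dtype=float),
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        jac=jac,
    )
    if not sol.success:
        raise RuntimeError(f"SPR ODE integration failed: {sol.message}")
    return sol.y[1]


def _exp_drift(t, a, b, c):
    return a * np.exp(-b * t) + c


def correct_drift(
    sg: Sensorgram, window_pre: float = 60.0, window_tail: float = 100.0
) -> Sensorgram:
    """Subtract a slow exponential drift a e^(-b t) + c fitted jointly to the
    pre-injection baseline and the tail of the dissociation phase.

    Falls back to a linear drift model (with a warning) if the exponential fit
    does not converge.
    """
    b_end, _a_end, d_end = sg.schedule
    pre = sg.time < min(window_pre, b_end)
    tail = sg.time > d_end - window_tail
    if pre.sum() < 5 or tail.sum() < 5:
        raise ValueError("drift windows must each contain at least 5 points")
    mask = pre | tail
    t_fit, r_fit = sg.time[mask], sg.response[mask]
    span = max(d_end - sg.time[0], 1.0)
    try:
        popt, _ = curve_fit(
            _exp_drift,
            t_fit,
            r_fit,
            p0=(r_fit[0] - r_fit[-1], 1.0 / span, r_fit[-1]),
            maxfev=20000,
        )
        drift = _exp_drift(sg.time, *popt)
    except RuntimeError:
        logger.warning("exponential drift fit failed; falling back to linear drift")
        slope, intercept = np.polyfit(t_fit, r_fit, 1)
        drift = slope * sg.time + intercept
    return replace(sg, response=sg.response - drift)


def _assoc_residuals(theta, sg, t, r_obs, K_d, k_on_fixed, alpha):
    k_t, r_max = np.exp(theta)
    params = SPRModelParams(
        k_t=k_t, k_on=k_on_fixed, k_off=K_d * k_on_fixed, r_max=r_max, alpha=alpha
    )
    return simulate_response(params, sg.L_bulk, t, rtol=1e-7, atol=1e-10) - r_obs


# log-space fit bounds keeping the ODE well conditioned: k_t in [1e-6, 1e4] s^-1,
# r_max in [1e-4, 1e3] RU
_ASSOC_BOUNDS = (np.log([1e-6, 1e-4]), np.log([1e4, 1e3]))


def fit_association(
    sg: Sensorgram,
    K_d: float,
    k_on_fixed: float,
    alpha: float = 1e-6,
) -> dict:
    """Fit k_t and r_max to the association phase at a fixed k_on.

    k_off is tied to K_d * k_on.  Initial conditions are [L]_surf = 0, r = 0
    at the start of the injection.  Starts from two initializations (initial
    slope / trace maximum) and keeps the better optimum.  Returns a dict with
    ``k_t``, ``r_max``, ``ssr``, ``n`` and the fixed inputs.
    """
    if k_on_fixed <= 0:
        raise ValueError("k_on_fixed must be positive")
    mask = sg.phase_mask("association")
    t = sg.time[mask] - sg.time[mask][0]
    r_obs = sg.response[mask]
    if t.size < 5:
        raise ValueError("association phase must contain at least 5 points")
    r_top = max(float(np.max(r_obs)), 1e-3)
    # transport-limited initial slope: dr/dt ~ k_t L_bulk / alpha
    slope = max(float(np.polyfit(t[: max(5, t.size // 10)], r_obs[: max(5, t.size // 10)], 1)[0]), 1e-6)
    k_t0 = slope * alpha / max(sg.L_bulk, 1e-12)
    best = None
    lo, hi = _ASSOC_BOUNDS
    starts = ((k_t0, 1.2 * r_top), (10 * k_t0, 2.0 * r_top), (k_t0, 0.1 * r_top))
    for k_t_init, r_max_init in starts:
        theta0 = np.clip(
            np.log([max(k_t_init, 1e-5), r_max_init]), lo + 1e-6, hi - 1e-6
        )
        res = least_squares(
            _assoc_residuals,
            theta0,
            args=(sg, t, r_obs, K_d, k_on_fixed, alpha),
            method="trf",
            bounds=(lo, hi),
            xtol=1e-10,
            ftol=1e-10,
            max_nfev=200,
        )
        # prefer the smaller-amplitude solution when costs tie (flat-trace ridge)
        if best is None or res.cost < best.cost * 0.98 or (
            res.cost < best.cost * 1.02 and res.x[1] < best.x[1]
        ):
            best = res
    k_t, r_max = np.exp(best.x)
    ssr = float(2 * best.cost)
    if not best.success:
        logger.warning("association fit did not fully converge: %s", best.message)
    if best.x[1] > _ASSOC_BOUNDS[1][1] - 1e-3:
        logger.warning("r_max hit its upper bound; fit unreliable")
    # no-signal ridge: far from saturation the curve is independent of r_max,
    # so when the fitted amplitude is below the noise, canonicalize to the
    # minimal r_max consistent with the curve
    model = best.fun + r_obs
    amplitude = float(np.max(np.abs(model)))
    rms = math.sqrt(ssr / t.size)
    no_signal = amplitude < 0.5 * rms
    if no_signal:
        r_max = max(amplitude, 1e-6)
    return {
        "k_t": float(k_t),
        "r_max": float(r_max),
        "ssr": ssr,
        "n": int(t.size),
        "k_on": k_on_fixed,
        "K_d": K_d,
        "alpha": alpha,
        "no_signal": no_signal,
    }


def fit_dissociation(
    sg: Sensorgram,
    assoc_fit: dict,
    K_d: float,
    window: float = 50.0,
    alpha: float = 1e-6,
) -> dict:
    """Fit the single parameter k_t to the first ``window`` s of dissociation.

    Initial conditions: [L]_surf = [L]_bulk and r = r_max / (1 + K_d/[L]_bulk),
    with r_max taken from the association fit.  Flags a weakly constrained
    k_t (wide SSR valley) when k_off * window << 1.
    """
    mask = sg.phase_mask("dissociation")
    if not mask.any():
        raise ValueError("empty dissociation window")
    t_all = sg.time[mask]
    t0 = t_all[0]
    sel = t_all - t0 <= window
    t = t_all[sel] - t0
    r_obs = sg.response[mask][sel]
    if t.size < 5:
        raise ValueError("dissociation window must contain at least 5 points")
    r_max = assoc_fit["r_max"]
    k_on = assoc_fit["k_on"]
    r_init = r_max / (1.0 + K_d / sg.L_bulk)
    init = (sg.L_bulk, r_init)

    def residuals(theta):
        params = SPRModelParams(
            k_t=math.exp(theta[0]), k_on=k_on, k_off=K_d * k_on, r_max=r_max, alpha=alpha
        )
        return simulate_response(params, 0.0, t, init=init, rtol=1e-7, atol=1e-11) - r_obs

    res = least_squares(
        residuals,
        [math.log(min(max(assoc_fit["k_t"], 1e-5), 1e3))],
        method="trf",
        bounds=([math.log(1e-6)], [math.log(1e4)]),
        max_nfev=80,
    )
    k_t = math.exp(res.x[0])
    weakly_constrained = K_d * k_on * window < 0.1
    if weakly_constrained:
        logger.warning("near-flat dissociation: k_t weakly constrained")
    return {
        "k_t": float(k_t),
        "ssr": float(2 * res.cost),
        "n": int(t.size),
        "weakly_constrained": bool(weakly_constrained),
    }


def default_k_on_grid(n: int = 30, lo: float = 1e5, hi: float = 1e10) -> np.ndarray:
    """Log-spaced fixed-k_on grid (default 30 points over 1e5–1e10 M^-1 s^-1)."""
    return np.logspace(math.log10(lo), math.log10(hi), n)


def ssr_profile(
    sg: Sensorgram,
    K_d: float,
    k_on_grid: np.ndarray | None = None,
    alpha: float = 1e-6,
    dissociation_window: float = 50.0,
    label: str = "",
) -> SSRProfile:
    """Total (association + dissociation) SSR over a fixed-k_on grid,
    rescaled by the grid minimum so the plateau sits at 1.

    Grid points whose fit fails are flagged NaN; the profile is still
    returned.
    """
    grid = default_k_on_grid() if k_on_grid is None else np.asarray(k_on_grid, dtype=float)
    ssr = np.full(grid.size, np.nan)
    failed = np.zeros(grid.size, dtype=bool)
    for i, k_on in enumerate(grid):
        try:
            afit = fit_association(sg, K_d, k_on, alpha=alpha)
            dfit = fit_dissociation(sg, afit, K_d, window=dissociation_window, alpha=alpha)
            ssr[i] = afit["ssr"] + dfit["ssr"]
        except (RuntimeError, ValueError) as err:  # flag and continue
            logger.warning("SSR profile point k_on=%.3g failed: %s", k_on, err)
            failed[i] = True
    floor = np.nanmin(ssr)
    return SSRProfile(
        k_on_grid=grid, ssr_rescaled=ssr / floor, label=label, failed=failed
    )


def k_on_lower_bound(
    profile: SSRProfile, threshold_factor: float = 1.05, upper_rise: float = 2.0
) -> dict:
    """Read a lower bound on k_on off a rescaled SSR profile.

    Returns the smallest grid k_on whose rescaled SSR <= ``threshold_factor``
    plus a flag: ``"bounded"`` when the profile rises below the bound and is
    flat above, ``"unbounded-below"`` when it is flat everywhere, and
    ``"identifiable"`` when the profile has a clear interior minimum (the
    upper end rises above ``upper_rise`` times the floor), in which case k_on
    is directly estimable and the profile is a candidate outlier in a
    bound-seeking analysis.
    """
    s = profile.ssr_rescaled
    g = profile.k_on_grid
    ok = np.isfinite(s)
    below = ok & (s <= threshold_factor)
    if not below.any():
        raise ValueError("no grid point reaches the rescaling floor")
    first = int(np.argmax(below))
    monotone_violations = int(np.sum(np.diff(s[ok][: first + 1]) > 0)) if first > 0 else 0
    if first == 0 and s[ok][0] <= threshold_factor:
        flag = "unbounded-below"
    elif s[ok][-1] > upper_rise:
        flag = "identifiable"
    else:
        flag = "bounded"
    return {
        "k_on_bound": float(g[first]),
        "flag": flag,
        "monotone_violations": monotone_violations,
    }


def fit_equilibrium_Kd(series: EquilibriumSeries) -> dict:
    """Fit plateau responses with f = c / (1 + K_d/[L]) by nonlinear least squares.

    Needs >= 3 distinct concentrations; warns when the concentrations do not
    bracket the fitted K_d (ill-conditioned).  Returns estimates and standard
    errors for c and K_d.
    """
    L = series.concentrations
    r = series.responses
    if np.unique(L).size < 3:
        raise ValueError("need at least 3 distinct concentrations")

    def isotherm(conc, c, K_d):
        return c / (1.0 + K_d / conc)

    p0 = (float(np.max(r)), float(np.median(L)))
    popt, pcov = curve_fit(isotherm, L, r, p0=p0, maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    c_hat, kd_hat = popt
    if kd_hat < L.min() / 10 or kd_hat > L.max() * 10:
        logger.warning("fitted K_d outside the sampled concentration range; ill-conditioned")
    return {
        "K_d": float(kd_hat),
        "K_d_stderr": float(perr[1]),
        "c": float(c_hat),
        "c_stderr": float(perr[0]),
    }
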