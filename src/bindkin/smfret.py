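"""Burst detection and E*/S* statistics for µsALEX photon streams.

A µsALEX measurement alternates donor and acceptor excitation (50 µs period
here) so that every detected photon belongs to one of three streams: DD
(donor excitation, donor detection), DA (donor excitation, acceptor
detection) and AA (acceptor excitation, acceptor detection).  Per-molecule
bursts extracted from the stream yield

    E* = F_DA / (F_DD + F_DA)                   (proximity ratio)
    S* = (F_DD + F_DA) / (F_DD + F_DA + F_AA)   (stoichiometry)

uncorrected for background.  Species gates: S* > 0.8 donor-only, S* < 0.3
acceptor-only, 0.3–0.8 doubly-labeled FRET species.  This module implements
the all-photon and dual-channel (AND-gate) burst searches, corrected
(accurate) FRET, the lifetime-FRET relation, Gaussian population fitting,
the outside-fraction statistic used to bound undetected subpopulations,
burst variance analysis (BVA) against the binomial shot-noise semicircle
sqrt(E(1-E)/n), and the Hill (n=1) titration fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "PhotonStream",
    "Burst",
    "PopulationFit",
    "BVAResult",
    "all_photon_burst_search",
    "dual_channel_burst_search",
    "burst_proximity",
    "accurate_fret",
    "lifetime_fret",
    "lifetime_from_fret",
    "fit_population_gaussian",
    "fraction_outside",
    "bva",
    "bva_semicircle",
    "hill_titration_fit",
]

STREAMS = ("DD", "DA", "AA")
_D_EXC = ("DD", "DA")


@dataclass(frozen=True)
class PhotonStream:
    """Timestamped two-color photon records.

    ``timestamps`` are integer clock ticks (non-decreasing); ``stream`` holds
    one of "DD", "DA", "AA" per photon (excitation x detection).  ``clock``
    is the tick length in seconds.  ``background`` maps stream name to a
    background count rate in photons/s; burst searches that normalize to the
    background rate require it.
    """

    timestamps: np.ndarray
    stream: np.ndarray
    clock: float = 100e-9
    alternation_period: float = 50e-6
    background: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=np.int64)
        st = np.asarray(self.stream)
        if ts.shape != st.shape or ts.ndim != 1:
            raise ValueError("timestamps and stream must be 1-D arrays of equal length")
        if ts.size and np.any(np.diff(ts) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if self.alternation_period <= 0 or self.clock <= 0:
            raise ValueError("clock and alternation period must be positive")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "stream", st)

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def times_s(self) -> np.ndarray:
        return self.timestamps * self.clock

    def to_text(self, path) -> None:
        pd.DataFrame({"timestamp_ticks": self.timestamps, "stream": self.stream}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_text(cls, path, **kwargs) -> "PhotonStream":
        df = pd.read_csv(path, sep="\t")
        return cls(
            timestamps=df["timestamp_ticks"].to_numpy(),
            stream=df["stream"].to_numpy(),
            **kwargs,
        )


@dataclass(frozen=True)
class Burst:
    """Photon-count summary of one single-molecule transit.

    ``indices`` are the positions of the burst's photons in the parent
    stream, kept so that photon-level statistics (BVA) can be recomputed.
    """

    start: int
    stop: int
    F_DD: int
    F_DA: int
    F_AA: int
    duration: float
    indices: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def total(self) -> int:
        return self.F_DD + self.F_DA + self.F_AA

    @property
    def E_star(self) -> float:
        den = self.F_DD + self.F_DA
        return self.F_DA / den if den > 0 else math.nan

    @property
    def S_star(self) -> float:
        return (self.F_DD + self.F_DA) / self.total if self.total > 0 else math.nan


def _bursts_from_runs(stream: PhotonStream, selected: np.ndarray, min_counts) -> list[Burst]:
    """Assemble maximal runs of selected photons into Burst records."""
    bursts: list[Burst] = []
    if not selected.any():
        return bursts
    idx = np.flatnonzero(selected)
    splits = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, splits + 1):
        labels = stream.stream[run]
        counts = {s: int(np.sum(labels == s)) for s in STREAMS}
        if not min_counts(counts):
            continue
        t0, t1 = stream.timestamps[run[0]], stream.timestamps[run[-1]]
        bursts.append(
            Burst(
                start=int(t0),
                stop=int(t1),
                F_DD=counts["DD"],
                F_DA=counts["DA"],
                F_AA=counts["AA"],
                duration=float((t1 - t0) * stream.clock),
                indices=run,
            )
        )
    return bursts


def all_photon_burst_search(
    stream: PhotonStream,
    window: float = 500e-6,
    threshold: int = 15,
    min_total: int = 150,
) -> list[Burst]:
    """All-photon burst search.

    A photon is burst-like when at least ``threshold`` photons (itself
    included) fall within a centered window of ``window`` seconds around it;
    maximal runs of consecutive burst-like photons form bursts, and bursts
    with fewer than ``min_total`` photons in total are discarded.
    """
    if len(stream) == 0:
        return []
    ts = stream.timestamps
    half = int(round(window / 2 / stream.clock))
    lo = np.searchsorted(ts, ts - half, side="left")
    hi = np.searchsorted(ts, ts + half, side="right")
    selected = (hi - lo) >= threshold
    return _bursts_from_runs(
        stream, selected, lambda c: c["DD"] + c["DA"] + c["AA"] >= min_total
    )


def _rate_selected(ts: np.ndarray, clock: float, m: int, F: float, bg_rate: float) -> np.ndarray:
    """Sliding-window rate criterion on one excitation substream.

    Photon i is selected when the m-photon window centered on it spans a time
    short enough that its local rate (m-1 photons per span) is at least
    F times the background rate.
    """
    n = ts.size
    sel = np.zeros(n, dtype=bool)
    if n < m:
        return sel
    span_max = (m - 1) / (F * bg_rate) / clock  # ticks
    left = m // 2
    for i in range(n):
        j0 = max(0, min(i - left, n - m))
        if ts[j0 + m - 1] - ts[j0] <= span_max:
            sel[i] = True
    return sel


def dual_channel_burst_search(
    stream: PhotonStream,
    m: int = 10,
    F: float = 6.0,
    min_D: int = 50,
    min_A: int = 50,
) -> list[Burst]:
    """Dual-channel (AND-gate) burst search.

    The sliding-window rate criterion (m consecutive photons at >= F times
    the background rate) is evaluated separately on the donor-excitation
    photons (DD + DA against their combined background) and on the
    acceptor-excitation photons (AA); a photon belongs to a burst only while
    *both* criteria hold.  Bursts must carry at least ``min_D`` photons from
    donor excitation and ``min_A`` from acceptor excitation.
    """
    for s in STREAMS:
        if s not in stream.background:
            raise ValueError(f"background rate for stream {s!r} is required")
    if len(stream) == 0:
        return []
    ts = stream.timestamps
    d_mask = np.isin(stream.stream, _D_EXC)
    a_mask = stream.stream == "AA"
    bg_d = stream.background["DD"] + stream.background["DA"]
    bg_a = stream.background["AA"]
    sel_d_sub = _rate_selected(ts[d_mask], stream.clock, m, F, bg_d)
    sel_a_sub = _rate_selected(ts[a_mask], stream.clock, m, F, bg_a)

    # Promote per-substream selections to time intervals, AND them, and mark
    # every photon inside the intersected intervals.
    def intervals(sub_ts, sub_sel):
        out = []
        idx = np.flatnonzero(sub_sel)
        if idx.size == 0:
            return out
        for run in np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1):
            out.append((sub_ts[run[0]], sub_ts[run[-1]]))
        return out

    iv_d = intervals(ts[d_mask], sel_d_sub)
    iv_a = intervals(ts[a_mask], sel_a_sub)
    selected = np.zeros(len(stream), dtype=bool)
    i = j = 0
    while i < len(iv_d) and j < len(iv_a):
        lo = max(iv_d[i][0], iv_a[j][0])
        hi = min(iv_d[i][1], iv_a[j][1])
        if lo <= hi:
            a = np.searchsorted(ts, lo, side="left")
            b = np.searchsorted(ts, hi, side="right")
            selected[a:b] = True
        if iv_d[i][1] < iv_a[j][1]:
            i += 1
        else:
            j += 1
    return _bursts_from_runs(
        stream, selected, lambda c: (c["DD"] + c["DA"]) >= min_D and c["AA"] >= min_A
    )


def burst_proximity(burst: Burst) -> tuple[float, float]:
    """Proximity ratio and stoichiometry (E*, S*) of a burst.

    Zero denominators yield NaN sentinels (e.g. an acceptor-only burst has
    undefined E* and S* ~ 0).
    """
    if not math.isfinite(burst.E_star) or not math.isfinite(burst.S_star):
        logger.warning("burst with zero denominator flagged undefined")
    return burst.E_star, burst.S_star


def accurate_fret(
    F_GG: float, F_GR: float, F_RR: float, alpha: float, beta: float, gamma: float
) -> float:
    """Corrected FRET efficiency from background-corrected signals.

    E = (F_GR - alpha F_RR - beta F_GG) / (F_GR - alpha F_RR - beta F_GG + gamma F_GG)

    with direct acceptor excitation (alpha), spectral crosstalk (beta) and
    detection correction factor (gamma).  Reduces to the proximity ratio at
    alpha = beta = 0, gamma = 1.
    """
    num = F_GR - alpha * F_RR - beta * F_GG
    den = num + gamma * F_GG
    if den == 0:
        return math.nan
    return num / den


def lifetime_fret(tau_DA: float, tau_D0: float) -> float:
    """FRET efficiency from donor-lifetime quenching, E = 1 - tau_DA / tau_D0.

    The linear relation between E and tau_DA is the static FRET line.
    """
    if not (0 < tau_DA <= tau_D0):
        raise ValueError("requires 0 < tau_DA <= tau_D0")
    return 1.0 - tau_DA / tau_D0


def lifetime_from_fret(E: float, tau_D0: float) -> float:
    """Inverse of :func:`lifetime_fret`: tau_DA = (1 - E) tau_D0."""
    if not (0 <= E < 1):
        raise ValueError("E must be in [0, 1)")
    return (1.0 - E) * tau_D0


@dataclass(frozen=True)
class PopulationFit:
    """Gaussian mixture summary of a burst E* distribution."""

    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        mu = np.asarray(self.means, dtype=float)
        sd = np.asarray(self.sigmas, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if not (mu.shape == sd.shape == w.shape):
            raise ValueError("means, sigmas, weights must have matching shapes")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        if np.any(sd <= 0):
            raise ValueError("sigmas must be positive")
        order = np.argsort(mu)
        object.__setattr__(self, "means", mu[order])
        object.__setattr__(self, "sigmas", sd[order])
        object.__setattr__(self, "weights", w[order])


def fit_population_gaussian(
    E_values: np.ndarray,
    n_components: int = 1,
    method: str = "mle",
    bin_width: float = 0.02,
    random_state: int = 0,
) -> PopulationFit:
    """Fit the burst E* distribution with ``n_components`` Gaussians.

    ``method="mle"`` (default) fits a maximum-likelihood Gaussian mixture on
    the burst values; ``method="histogram"`` least-squares fits the binned
    histogram (bin width 0.02).  Requires >= 50 bursts.  A sample with
    (near-)zero spread is returned with sigma at the bin-width floor and the
    ``degenerate`` flag set.
    """
    E = np.asarray(E_values, dtype=float)
    E = E[np.isfinite(E)]
    if E.size < 50:
        raise ValueError("need at least 50 bursts")
    if np.std(E) < 1e-12:
        return PopulationFit(
            means=np.array([E.mean()]),
            sigmas=np.array([bin_width]),
            weights=np.array([1.0]),
            degenerate=True,
        )
    if method == "mle":
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(
            n_components=n_components,
            covariance_type="spherical",
            n_init=5,
            random_state=random_state,
        ).fit(E.reshape(-1, 1))
        if not gm.converged_:
            raise RuntimeError("Gaussian mixture fit did not converge")
        return PopulationFit(
            means=gm.means_.ravel(),
            sigmas=np.sqrt(gm.covariances_.ravel()),
            weights=gm.weights_,
        )
    if method == "histogram":
        edges = np.arange(E.min() - bin_width, E.max() + 2 * bin_width, bin_width)
        counts, edges = np.histogram(E, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def model(x, *theta):
            out = np.zeros_like(x)
            for k in range(n_components):
                a, mu, sd = theta[3 * k : 3 * k + 3]
                out += a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
            return out

        qs = np.quantile(E, np.linspace(0.2, 0.8, n_components))
        p0 = []
        for mu0 in qs:
            p0 += [counts.max(), mu0, max(np.std(E) / n_components, bin_width)]
        popt, _ = curve_fit(model, centers, counts, p0=p0, maxfev=50000)
        amps = np.abs(popt[0::3]) * np.abs(popt[2::3])  # area ∝ a·sd
        return PopulationFit(
            means=popt[1::3],
            sigmas=np.abs(popt[2::3]),
            weights=amps / amps.sum(),
        )
    raise ValueError(f"unknown method {method!r}")


def fraction_outside(
    E_values: np.ndarray, fit: PopulationFit, k_sigma: float = 1.0
) -> float:
    """Fraction of bursts outside the union of [mu_i - k sigma_i, mu_i + k sigma_i].

    Used as an upper bound on undetected subpopulations; for a single pure
    Gaussian at k = 1 the expected value is 2 Phi(-1) ~ 31.7%.
    """
    E = np.asarray(E_values, dtype=float)
    E = E[np.isfinite(E)]
    inside = np.zeros(E.size, dtype=bool)
    for mu, sd in zip(fit.means, fit.sigmas):
        inside |= np.abs(E - mu) <= k_sigma * sd
    return float(1.0 - inside.mean()) if E.size else math.nan


def bva_semicircle(E: np.ndarray, n: int) -> np.ndarray:
    """Binomial shot-noise expectation sqrt(E (1-E) / n) for window size n."""
    E = np.asarray(E, dtype=float)
    return np.sqrt(E * (1.0 - E) / n)


@dataclass(frozen=True)
class BVAResult:
    """Per-burst mean E* and within-burst SD of n-photon window proximity ratios."""

    E_star: np.ndarray
    sd_E: np.ndarray
    n_window: int
    n_skipped: int

    def semicircle(self) -> np.ndarray:
        return bva_semicircle(self.E_star, self.n_window)


def bva(stream: PhotonStream, bursts: list[Burst], n: int = 5) -> BVAResult:
    """Burst variance analysis.

    For each burst, the donor-excitation photons are partitioned in temporal
    order into consecutive windows of ``n`` photons (trailing partial windows
    dropped); each window's proximity ratio is the fraction of DA photons,
    and the burst statistic is the SD of those window ratios against the
    burst-mean E*.  Bursts with fewer than two full windows are skipped.
    Within-burst dynamics show up as SD above the shot-noise semicircle
    sqrt(E*(1-E*)/n).
    """
    if n < 2:
        raise ValueError("window size n must be >= 2")
    E_out, sd_out = [], []
    skipped = 0
    for b in bursts:
        labels = stream.stream[b.indices]
        d_exc = labels[np.isin(labels, _D_EXC)]
        n_win = d_exc.size // n
        if n_win < 2:
            skipped += 1
            continue
        wins = (d_exc[: n_win * n] == "DA").reshape(n_win, n)
        ratios = wins.mean(axis=1)
        E_out.append(b.E_star)
        sd_out.append(ratios.std(ddof=0))
    return BVAResult(
        E_star=np.asarray(E_out),
        sd_E=np.asarray(sd_out),
        n_window=n,
        n_skipped=skipped,
    )


def hill_titration_fit(
    concentrations: np.ndarray, fraction_closed: np.ndarray
) -> dict:
    """Fit the fraction of the closed (high-FRET) subpopulation with the
    Hill isotherm at fixed n = 1: f = [L] / (K_d + [L]).

    Valid when the protein concentration is far below K_d.  Returns the K_d
    estimate with its standard error.
    """
    L = np.asarray(concentrations, dtype=float)
    f = np.asarray(fraction_closed, dtype=float)
    if np.unique(L).size < 3:
        raise ValueError("need at least 3 concentrations")
    if f.max() - f.min() < 0.05:
        logger.warning("titration nearly flat (all saturated or all zero); ill-conditioned")

    def isotherm(conc, K_d):
        return conc / (K_d + conc)

    popt, pcov = curve_fit(isotherm, L, f, p0=(float(np.median(L)),), maxfev=20000)
    return {"K_d": float(popt[0]), "K_d_stderr": float(np.sqrt(pcov[0, 0]))}
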