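"""Four-state ligand-binding kinetics: induced fit (IF) and conformational selection (CS).

Both mechanisms couple a conformational equilibrium (excitation rate ``k_e``,
relaxation rate ``k_r``) to a bimolecular binding step (association rate
constant ``k_plus`` in M^-1 s^-1, dissociation rate ``k_minus`` in s^-1) of the
binding-competent conformation.  Under pseudo-first-order conditions (ligand
concentration [L] effectively constant) each pathway reduces to a linear
three-state chain

    CS:  O  --k_e-->  C   --k_+[L]--> CL        (close first, then bind)
         O <--k_r--   C  <--k_-------  CL

    IF:  O --k_+[L]-> OL  --k_r----->  CL       (bind first, then close)
         O <--k_----- OL <--k_e------  CL

with states ordered (unbound ground conformation, intermediate, final bound
state).  The dominant relaxation rate observed in a mixing or perturbation
experiment is the smallest-magnitude nonzero eigenvalue of the chain's rate
matrix and has an exact closed form for both pathways; this module provides
the closed forms, the matrix oracle, effective (lumped) two-state rate
constants, ODE integration of the chain and binding thermodynamics helpers.

Units are seconds, molar and kJ/mol throughout.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Pathway",
    "PathwayRates",
    "EffectiveRates",
    "StatePopulations",
    "exact_relaxation_rate",
    "rate_matrix",
    "stationary_distribution",
    "integrate_scheme",
    "effective_rates_cs",
    "effective_rates_if",
    "approx_relaxation_rate_cs",
    "k_minus_from_koff",
    "equilibrium_kd",
    "binding_free_energy",
    "GAS_CONSTANT",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1

# Discriminants in (-DISCRIMINANT_CLIP * S^2, 0) are treated as exact zeros;
# anything more negative signals an inconsistent rate set.
DISCRIMINANT_CLIP = 1e-12


class Pathway(enum.Enum):
    """Kinetic pathway: ligand binds before (IF) or after (CS) the conformational change."""

    IF = "IF"
    CS = "CS"


class PathwayMismatchError(ValueError):
    """Raised when an operation specific to one pathway receives the other."""


def _require_pathway(rates: "PathwayRates", pathway: Pathway) -> None:
    if rates.pathway is not pathway:
        raise PathwayMismatchError(
            f"operation requires a {pathway.value} rate set, got {rates.pathway.value}"
        )


@dataclass(frozen=True)
class PathwayRates:
    """Microscopic rate constants of one pathway.

    Parameters
    ----------
    k_e : float
        Conformational excitation rate (s^-1), ground -> higher-free-energy
        conformation of the unligated (CS) or ligated (IF) protein.
    k_r : float
        Conformational relaxation rate (s^-1), the reverse of ``k_e``.
    k_plus : float
        Association rate constant (M^-1 s^-1) of the binding-competent
        conformation.
    k_minus : float
        Dissociation rate (s^-1) of the binding-competent conformation.
    pathway : Pathway
        Which limiting mechanism these rates parameterize.
    """

    k_e: float
    k_r: float
    k_plus: float
    k_minus: float
    pathway: Pathway

    def __post_init__(self) -> None:
        for name in ("k_e", "k_r", "k_plus", "k_minus"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")
        if not isinstance(self.pathway, Pathway):
            object.__setattr__(self, "pathway", Pathway(self.pathway))


@dataclass(frozen=True)
class EffectiveRates:
    """Lumped two-state rate constants of a pathway.

    ``K_d`` always equals ``k_off / k_on``.  For IF this coincides with the
    microscopic k_- k_e / (k_+ k_r); for CS it is k_- k_r / (k_+ k_e), which
    matches the exact half-saturation constant (see :func:`equilibrium_kd`)
    only when the binding-competent conformation is weakly populated
    (k_e << k_r).
    """

    k_on: float
    k_off: float
    K_d: float

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off, self.K_d) <= 0:
            raise ValueError("effective rates must be positive")
        if not math.isclose(self.K_d, self.k_off / self.k_on, rel_tol=1e-9):
            raise ValueError("K_d must equal k_off / k_on")


@dataclass(frozen=True)
class StatePopulations:
    """Occupancy trajectory of the three pseudo-first-order states.

    ``occupancies`` has shape (len(t), 3), state order (unbound ground,
    intermediate, bound); each row sums to one.
    """

    t: np.ndarray
    occupancies: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        occ = np.asarray(self.occupancies, dtype=float)
        if occ.shape != (t.size, 3):
            raise ValueError("occupancies must have shape (len(t), 3)")
        if np.any(occ < -1e-8) or np.any(occ > 1 + 1e-8):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("occupancies must sum to 1 at every time point")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "occupancies", occ)


def _check_ligand(L: float) -> float:
    if not (math.isfinite(L) and L >= 0):
        raise ValueError(f"ligand concentration must be finite and >= 0, got {L!r}")
    return float(L)


def exact_relaxation_rate(rates: PathwayRates, L: float) -> float:
    """Exact dominant relaxation rate of a pathway at ligand concentration ``L``.

    Smallest-magnitude nonzero eigenvalue of the linear three-state chain, in
    closed form.  With S = k_e + k_r + k_+[L] + k_-,

        CS: 1/2 (S - sqrt(S^2 - 4 (k_e (k_+[L] + k_-) + k_r k_-)))
        IF: 1/2 (S - sqrt(S^2 - 4 (k_+[L] (k_e + k_r) + k_e k_-)))

    The result is real, positive and <= S/2.
    """
    L = _check_ligand(L)
    binding = rates.k_plus * L
    S = rates.k_e + rates.k_r + binding + rates.k_minus
    if rates.pathway is Pathway.CS:
        product = rates.k_e * (binding + rates.k_minus) + rates.k_r * rates.k_minus
    else:
        product = binding * (rates.k_e + rates.k_r) + rates.k_e * rates.k_minus
    disc = S * S - 4.0 * product
    if disc < 0:
        if disc > -DISCRIMINANT_CLIP * S * S:
            disc = 0.0
        else:
            raise ArithmeticError(
                f"negative discriminant {disc:g} beyond tolerance for S={S:g}"
            )
    return 0.5 * (S - math.sqrt(disc))


def rate_matrix(rates: PathwayRates, L: float) -> np.ndarray:
    """Pseudo-first-order generator of the three-state chain.

    Returns the 3x3 matrix Q with d p / dt = Q p for the column vector of
    state occupancies p ordered (unbound ground, intermediate, bound); columns
    sum to zero exactly.  The binding step is linearized as ``k_plus * L``.
    """
    L = _check_ligand(L)
    binding = rates.k_plus * L
    if rates.pathway is Pathway.CS:
        # O --k_e--> C --k_+L--> CL, reverses k_r and k_-
        up, down = (rates.k_e, binding), (rates.k_r, rates.k_minus)
    else:
        # O --k_+L--> OL --k_r--> CL, reverses k_- and k_e
        up, down = (binding, rates.k_r), (rates.k_minus, rates.k_e)
    Q = np.zeros((3, 3))
    Q[1, 0], Q[2, 1] = up
    Q[0, 1], Q[1, 2] = down
    np.fill_diagonal(Q, 0.0)
    Q[0, 0] = -(Q[1, 0] + Q[2, 0])
    Q[1, 1] = -(Q[0, 1] + Q[2, 1])
    Q[2, 2] = -(Q[0, 2] + Q[1, 2])
    return Q


def stationary_distribution(rates: PathwayRates, L: float) -> np.ndarray:
    """Stationary occupancies of the chain (detailed balance along the chain)."""
    L = _check_ligand(L)
    binding = rates.k_plus * L
    if rates.pathway is Pathway.CS:
        ratio1 = rates.k_e / rates.k_r
        ratio2 = binding / rates.k_minus if rates.k_minus > 0 else np.inf
    else:
        ratio1 = binding / rates.k_minus
        ratio2 = rates.k_r / rates.k_e
    w = np.array([1.0, ratio1, ratio1 * ratio2])
    return w / w.sum()


def integrate_scheme(
    rates: PathwayRates,
    L: float,
    init: np.ndarray,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> StatePopulations:
    """Integrate the chain ODE from ``init`` over ``t_grid``.

    Uses a stiff-capable adaptive integrator; the trajectory conserves total
    occupancy and converges to the stationary eigenvector at long times.
    """
    init = np.asarray(init, dtype=float)
    if init.shape != (3,) or abs(init.sum() - 1.0) > 1e-8:
        raise ValueError("init must be a length-3 occupancy vector summing to 1")
    t_grid = np.asarray(t_grid, dtype=float)
    Q = rate_matrix(rates, L)
    sol = solve_ivp(
        lambda t, p: Q @ p,
        (t_grid[0], t_grid[-1]),
        init,
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        jac=lambda t, p: Q,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    occ = sol.y.T
    # renormalize away integrator round-off, which stays < ~1e-9 at these tolerances
    occ = np.clip(occ, 0.0, None)
    occ /= occ.sum(axis=1, keepdims=True)
    return StatePopulations(t=sol.t, occupancies=occ)


def effective_rates_cs(rates: PathwayRates, L: float) -> EffectiveRates:
    """Effective (lumped) on/off rate constants of the CS pathway at ``L``.

    k_on = k_e k_+ / (k_r + k_+[L]),  k_off = k_r k_- / (k_r + k_+[L]).
    Valid when the binding-competent (closed) conformation is weakly populated
    and [L] > K_d.
    """
    _require_pathway(rates, Pathway.CS)
    L = _check_ligand(L)
    denom = rates.k_r + rates.k_plus * L
    k_on = rates.k_e * rates.k_plus / denom
    k_off = rates.k_r * rates.k_minus / denom
    return EffectiveRates(k_on=k_on, k_off=k_off, K_d=k_off / k_on)


def effective_rates_if(rates: PathwayRates) -> EffectiveRates:
    """Effective on/off rate constants of the IF pathway (concentration independent).

    k_on = k_+ k_r / (k_- + k_r),  k_off = k_- k_e / (k_- + k_r);
    hence K_d = k_- k_e / (k_+ k_r) and always k_off < k_e.
    """
    _require_pathway(rates, Pathway.IF)
    denom = rates.k_minus + rates.k_r
    k_on = rates.k_plus * rates.k_r / denom
    k_off = rates.k_minus * rates.k_e / denom
    return EffectiveRates(k_on=k_on, k_off=k_off, K_d=k_off / k_on)


def approx_relaxation_rate_cs(rates: PathwayRates, L: float) -> float:
    """Approximate CS relaxation rate k_e k_- (1 + [L]/K_d) / (k_e + k_- [L]/K_d).

    K_d here is the effective k_- k_r / (k_+ k_e).  The large-[L] limit is
    k_e; the rate rises with [L] when k_e > k_- and falls when k_e < k_-.
    """
    _require_pathway(rates, Pathway.CS)
    L = _check_ligand(L)
    K_d = rates.k_minus * rates.k_r / (rates.k_plus * rates.k_e)
    x = L / K_d
    return rates.k_e * rates.k_minus * (1.0 + x) / (rates.k_e + rates.k_minus * x)


def k_minus_from_koff(k_off: float, k_r: float, k_e: float) -> float:
    """Invert the IF effective off-rate: k_- = k_off k_r / (k_e - k_off).

    Only defined for k_off < k_e, which the IF scheme guarantees.
    """
    if k_off >= k_e:
        raise ValueError("IF requires k_off < k_e")
    if min(k_off, k_r, k_e) <= 0:
        raise ValueError("rates must be positive")
    return k_off * k_r / (k_e - k_off)


def equilibrium_kd(rates: PathwayRates) -> float:
    """Exact half-saturation constant of the three-state chain.

    CS: k_- (k_e + k_r) / (k_+ k_e) — the ligand concentration at which the
    bound state holds half the population.  IF: k_- k_e / (k_+ (k_e + k_r)),
    counting both liganded states as bound.
    """
    if rates.pathway is Pathway.CS:
        return rates.k_minus * (rates.k_e + rates.k_r) / (rates.k_plus * rates.k_e)
    return rates.k_minus * rates.k_e / (rates.k_plus * (rates.k_e + rates.k_r))


def binding_free_energy(K_d: float, T: float = 298.15) -> float:
    """Standard binding free energy R T ln(K_d / 1 M) in kJ/mol.

    Negative for sub-molar K_d; e.g. K_d = 35 nM at 298.15 K gives -42.6 kJ/mol.
    """
    if not (K_d > 0 and math.isfinite(K_d)):
        raise ValueError("K_d must be positive and finite")
    if not (T > 0 and math.isfinite(T)):
        raise ValueError("temperature must be positive and finite")
    return GAS_CONSTANT * T * math.log(K_d) / 1000.0
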