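"""Deterministic kinetics of the two-codon translation model.

The model tracks two isoaccepting tRNA species — a *preferred* (more
abundant) and a *non-preferred* one — each cycling between a charged
(aminoacylated) and an uncharged pool, together with a fixed pool of
ribosomes translating ``N`` identical transcripts of ``L`` codons.  A
fraction ``f_op`` of the codons on each transcript is *optimal* (read by
the preferred tRNA); the remainder is non-optimal.  Elongation from a
codon of class *i* consumes one charged tRNA of species *i* at rate
``k_speed * R_bi * T_ci``; a dedicated charging reaction restores each
uncharged pool at rate ``k_charge * T_ui``.  Ribosome initiation occurs
at rate ``k_bind_eff * N * R_f`` and termination releases the ribosome
(and one finished protein) after ``L`` elongation steps on average.

The mean-field approximation tracks only *how many* ribosomes sit on
each codon class, not where along the transcript they are: after a
non-terminal elongation step a ribosome lands on an optimal codon with
probability ``f_op``.

The central observable is the steady-state protein expression rate

    P_r = k_speed * (R_b1*T_c1 + R_b2*T_c2) / L      [molecules / s]

i.e. the ribosome off-rate.  Steady states are obtained exactly: the
stationarity conditions collapse onto a single scalar equation in the
total elongation flux E = k_speed*(R_b1*T_c1 + R_b2*T_c2), which is
strictly monotone on a known bracket, so the root (and hence the steady
state) is unique and found without starting-point sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "AVOGADRO",
    "ModelParams",
    "SystemState",
    "SteadySummary",
    "Trajectory",
    "SteadyStateError",
    "CalibrationError",
    "IntegrationError",
    "ode_rhs",
    "solve_steady_state",
    "closed_form_one_codon",
    "infinite_charging_limit",
    "protein_rate",
    "summarize",
    "calibrate",
    "molar_to_effective_bind",
    "integrate_timecourse",
    "residuals",
]

AVOGADRO = 6.02214076e23  # molecules / mol

#: order of the dynamic species in every array representation
STATE_FIELDS = ("T_c1", "T_c2", "T_u1", "T_u2", "R_f", "R_b1", "R_b2")


class SteadyStateError(RuntimeError):
    """Steady-state solve failed; carries the final residuals."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


class CalibrationError(RuntimeError):
    """Requested calibration targets are infeasible."""


class IntegrationError(RuntimeError):
    """Time-course integration failed; carries the last good time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class ModelParams:
    """Complete parameterization of the two-codon system.

    Parameters
    ----------
    T1_tot, T2_tot
        Total preferred / non-preferred tRNA molecules.
    R_tot
        Total ribosomes.
    N
        Transcript count (= ribosome binding sites).
    L
        Transcript length in codons.
    k_charge
        tRNA charging rate constant (1/s), identical for both species.
    k_speed
        Ribosome elongation constant, per charged tRNA per bound
        ribosome per second.  The biologically meaningful translation
        speed in codons/s is ``k_speed * T_c``.
    k_bind_eff
        Effective ribosome binding constant, per free ribosome per
        binding site per second (see :func:`molar_to_effective_bind`
        for the molar conversion).
    f_op
        Fraction of optimal codons, in [0, 1].
    """

    T1_tot: float
    T2_tot: float
    R_tot: float
    N: float
    L: float
    k_charge: float
    k_speed: float
    k_bind_eff: float
    f_op: float

    def __post_init__(self) -> None:
        if self.T1_tot < 0 or self.T2_tot < 0:
            raise ValueError("tRNA totals must be non-negative")
        if self.T1_tot + self.T2_tot <= 0:
            raise ValueError("T1_tot + T2_tot must be positive")
        if self.R_tot <= 0:
            raise ValueError("R_tot must be positive")
        if self.N < 1 or self.L < 1:
            raise ValueError("N and L must be at least 1")
        for name in ("k_charge", "k_speed", "k_bind_eff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.f_op <= 1.0:
            raise ValueError("f_op must lie in [0, 1]")
        if self.T2_tot == 0 and self.f_op != 1.0:
            raise ValueError("T2_tot == 0 requires f_op == 1")
        if self.T1_tot == 0 and self.f_op != 0.0:
            raise ValueError("T1_tot == 0 requires f_op == 0")

    @property
    def preferred_fraction(self) -> float:
        """Fraction of preferred tRNAs, T1_tot / (T1_tot + T2_tot)."""
        return self.T1_tot / (self.T1_tot + self.T2_tot)

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelParams fields: {sorted(unknown)}")
        missing = known - set(d)
        if missing:
            raise ValueError(f"missing ModelParams fields: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class SystemState:
    """Instantaneous molecule counts of the 7 dynamic species."""

    T_c1: float
    T_c2: float
    T_u1: float
    T_u2: float
    R_f: float
    R_b1: float
    R_b2: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "SystemState":
        return cls(*(float(v) for v in y))

    def validate(self, params: ModelParams, rtol: float = 1e-8) -> None:
        """Check non-negativity and the three conservation laws."""
        arr = self.as_array()
        if np.any(arr < -rtol * max(params.R_tot, params.T1_tot + params.T2_tot)):
            raise ValueError("negative species count")
        checks = (
            (self.T_c1 + self.T_u1, params.T1_tot),
            (self.T_c2 + self.T_u2, params.T2_tot),
            (self.R_f + self.R_b1 + self.R_b2, params.R_tot),
        )
        for got, want in checks:
            if abs(got - want) > rtol * max(want, 1.0):
                raise ValueError(
                    f"conservation violated: {got!r} != {want!r}"
                )


@dataclass(frozen=True)
class SteadySummary:
    """Derived steady-state observables (cf. bacterial translation data)."""

    P_r: float
    charged_frac_1: float
    charged_frac_2: float
    charged_frac_total: float
    active_ribosome_frac: float
    per_ribosome_speed: float
    ribosome_density: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class Trajectory:
    """Time course of the 7 species plus cumulative protein count."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 7), STATE_FIELDS order
    protein: np.ndarray  # cumulative proteins produced

    def state_at(self, i: int) -> SystemState:
        return SystemState.from_array(self.states[i])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time", self.times)
        df["protein"] = self.protein
        return df


# ---------------------------------------------------------------------------
# kinetics


def ode_rhs(state: SystemState | np.ndarray, params: ModelParams) -> np.ndarray:
    """Time derivatives of the 7 species under the mass-action network.

    Charging: ``k_charge*T_ui`` converts uncharged to charged tRNA.
    Elongation from class *i* occurs at rate ``k_speed*R_bi*T_ci`` and
    consumes one charged tRNA (charged -> uncharged).  Every elongation
    event moves the ribosome: a fraction ``1/L`` of events terminate
    (ribosome freed), the rest re-land on an optimal codon with
    probability ``f_op``.  Initiation ``k_bind_eff*N*R_f`` places the
    new ribosome on an optimal codon with probability ``f_op``.

    The ribosome derivatives sum to zero, as do the per-species tRNA
    derivatives, so the conservation laws are preserved exactly.
    """
    y = state.as_array() if isinstance(state, SystemState) else np.asarray(state, float)
    T_c1, T_c2, T_u1, T_u2, R_f, R_b1, R_b2 = y
    p = params
    e1 = p.k_speed * R_b1 * T_c1
    e2 = p.k_speed * R_b2 * T_c2
    etot = e1 + e2
    binding = p.k_bind_eff * p.N * R_f
    stay = 1.0 - 1.0 / p.L  # probability an elongation step does not terminate
    return np.array(
        [
            p.k_charge * T_u1 - e1,
            p.k_charge * T_u2 - e2,
            e1 - p.k_charge * T_u1,
            e2 - p.k_charge * T_u2,
            etot / p.L - binding,
            binding * p.f_op - e1 + stay * p.f_op * etot,
            binding * (1.0 - p.f_op) - e2 + stay * (1.0 - p.f_op) * etot,
        ]
    )


def residuals(state: SystemState, params: ModelParams) -> np.ndarray:
    """Relative residuals of the four stationarity balances.

    Order: ribosome binding/termination, charging of species 1,
    charging of species 2, codon-class exchange.  Each residual is
    |lhs - rhs| / max(|lhs|, |rhs|, 1), so a perfect steady state gives
    all zeros regardless of the magnitude of the fluxes.
    """
    p, s = params, state
    pairs = (
        (p.k_bind_eff * p.N * s.R_f,
         p.k_speed * (s.R_b1 * s.T_c1 + s.R_b2 * s.T_c2) / p.L),
        (p.k_charge * s.T_u1, p.k_speed * s.R_b1 * s.T_c1),
        (p.k_charge * s.T_u2, p.k_speed * s.R_b2 * s.T_c2),
        (s.R_b1 * s.T_c1 * (1.0 - p.f_op), s.R_b2 * s.T_c2 * p.f_op),
    )
    return np.array(
        [abs(a - b) / max(abs(a), abs(b), 1.0) for a, b in pairs]
    )


# ---------------------------------------------------------------------------
# steady states


def _state_from_flux(E: float, p: ModelParams) -> SystemState:
    """Reconstruct the full state from the total elongation flux E.

    At stationarity the class fluxes split as f_op*E and (1-f_op)*E, the
    uncharged pools carry flux/k_charge molecules, and the free-ribosome
    pool balances initiation against termination.
    """
    e1 = p.f_op * E
    e2 = (1.0 - p.f_op) * E
    T_u1 = e1 / p.k_charge
    T_u2 = e2 / p.k_charge
    T_c1 = p.T1_tot - T_u1
    T_c2 = p.T2_tot - T_u2
    R_f = E / (p.L * p.k_bind_eff * p.N)
    R_b1 = e1 / (p.k_speed * T_c1) if e1 > 0 else 0.0
    R_b2 = e2 / (p.k_speed * T_c2) if e2 > 0 else 0.0
    return SystemState(T_c1, T_c2, T_u1, T_u2, R_f, R_b1, R_b2)


def solve_steady_state(params: ModelParams, tol: float = 1e-10) -> SystemState:
    """Unique positive steady state of the two-codon system.

    The stationarity conditions determine every species from the total
    elongation flux E, leaving the single equation

        R_f(E) + R_b1(E) + R_b2(E) = R_tot.

    The left side is strictly increasing in E on (0, E_max), where
    E_max is the flux at which the busier charged pool would be fully
    drained, and runs from 0 to +inf, so a unique root exists and is
    bracketed a priori.  ``f_op`` of exactly 0 or 1 dispatches to the
    one-codon closed form.

    Raises
    ------
    SteadyStateError
        If the bracketed solve fails or the residuals of the
        stationarity balances exceed ``tol`` (relative).
    """
    p = params
    if p.f_op in (0.0, 1.0):
        return closed_form_one_codon(p)
    return _solve_flux(p, tol)


def _solve_flux(p: ModelParams, tol: float = 1e-10) -> SystemState:
    """Bracketed scalar solve in the total elongation flux E.

    Works for any f_op in [0, 1]; at the boundaries it provides an
    independent numerical route to the closed-form one-codon solution.
    """
    caps = []
    if p.f_op > 0.0:
        caps.append(p.k_charge * p.T1_tot / p.f_op)
    if p.f_op < 1.0:
        caps.append(p.k_charge * p.T2_tot / (1.0 - p.f_op))
    E_max = min(caps)

    def excess(E: float) -> float:
        e1 = p.f_op * E
        e2 = (1.0 - p.f_op) * E
        rib = E / (p.L * p.k_bind_eff * p.N)
        if e1 > 0.0:
            rib += e1 / (p.k_speed * (p.T1_tot - e1 / p.k_charge))
        if e2 > 0.0:
            rib += e2 / (p.k_speed * (p.T2_tot - e2 / p.k_charge))
        return rib - p.R_tot

    lo = E_max * 1e-300
    hi = E_max * (1.0 - 1e-12)
    while excess(hi) <= 0.0:  # pole guard; mathematically unreachable
        hi = E_max - (E_max - hi) * 0.1
    try:
        E = brentq(excess, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    except Exception as exc:  # pragma: no cover - bracket is guaranteed
        raise SteadyStateError(f"bracketed solve failed: {exc}") from exc

    state = _state_from_flux(E, p)
    res = residuals(state, p)
    if np.max(res) > tol:
        raise SteadyStateError(
            f"steady-state residuals {res} exceed tolerance {tol}", res
        )
    return state


def closed_form_one_codon(params: ModelParams) -> SystemState:
    """Analytic steady state when only one codon class is used.

    With ``f_op`` exactly 1 (resp. 0) the unused class has zero
    occupancy and a fully charged pool, and the remaining charging and
    binding balances reduce to a quadratic in the active charged-tRNA
    count, of which exactly one root is positive.
    """
    p = params
    if p.f_op not in (0.0, 1.0):
        raise ValueError("closed_form_one_codon requires f_op in {0, 1}")
    T_tot = p.T1_tot if p.f_op == 1.0 else p.T2_tot
    kc, ks = p.k_charge, p.k_speed
    kbN = p.k_bind_eff * p.N
    # kc*(T_tot - Tc) = ks*Rb*Tc with Rb = kbN*R_tot*L / (kbN*L + ks*Tc)
    A = kc * ks
    B = kc * kbN * p.L + ks * kbN * p.R_tot * p.L - kc * ks * T_tot
    C = -kc * kbN * p.L * T_tot
    Tc = (-B + math.sqrt(B * B - 4.0 * A * C)) / (2.0 * A)
    Rb = kbN * p.R_tot * p.L / (kbN * p.L + ks * Tc)
    R_f = p.R_tot - Rb
    if p.f_op == 1.0:
        return SystemState(Tc, p.T2_tot, p.T1_tot - Tc, 0.0, R_f, Rb, 0.0)
    return SystemState(p.T1_tot, Tc, 0.0, p.T2_tot - Tc, R_f, 0.0, Rb)


def infinite_charging_limit(params: ModelParams) -> float:
    """Protein expression rate when charging is instantaneous.

    With ``k_charge`` -> inf both pools stay fully charged
    (T_ci = Ti_tot); the per-ribosome speed becomes the f_op-weighted
    harmonic mean of ``k_speed*T1_tot`` and ``k_speed*T2_tot``, and the
    expression rate follows from the initiation/termination balance.
    Returns P_r in molecules/s.
    """
    p = params
    inv_speed = 0.0
    if p.f_op > 0:
        inv_speed += p.f_op / (p.k_speed * p.T1_tot)
    if p.f_op < 1:
        inv_speed += (1.0 - p.f_op) / (p.k_speed * p.T2_tot)
    # R_tot = E/(L*kb*N) + E*inv_speed  =>  E linear
    E = p.R_tot / (1.0 / (p.L * p.k_bind_eff * p.N) + inv_speed)
    return E / p.L


# ---------------------------------------------------------------------------
# observables


def protein_rate(state: SystemState, params: ModelParams) -> float:
    """Protein expression rate P_r = k_speed*(R_b1*T_c1 + R_b2*T_c2)/L."""
    return (
        params.k_speed
        * (state.R_b1 * state.T_c1 + state.R_b2 * state.T_c2)
        / params.L
    )


def summarize(state: SystemState, params: ModelParams) -> SteadySummary:
    """Derived observables of a (steady) state.

    ``per_ribosome_speed`` is the elongation flux per bound ribosome in
    codons/s (0 if no ribosome is bound); ``ribosome_density`` is bound
    ribosomes per 100 nucleotides of transcript (3 nt per codon).
    """
    p, s = params, state
    flux = p.k_speed * (s.R_b1 * s.T_c1 + s.R_b2 * s.T_c2)
    bound = s.R_b1 + s.R_b2
    t_tot = p.T1_tot + p.T2_tot
    return SteadySummary(
        P_r=flux / p.L,
        charged_frac_1=s.T_c1 / p.T1_tot if p.T1_tot > 0 else 1.0,
        charged_frac_2=s.T_c2 / p.T2_tot if p.T2_tot > 0 else 1.0,
        charged_frac_total=(s.T_c1 + s.T_c2) / t_tot,
        active_ribosome_frac=bound / p.R_tot,
        per_ribosome_speed=flux / bound if bound > 0 else 0.0,
        ribosome_density=100.0 * bound / (p.N * p.L * 3.0),
    )


# ---------------------------------------------------------------------------
# calibration


def calibrate(
    params_template: ModelParams,
    target_charged_frac: float,
    target_active_frac: float,
) -> tuple[float, float]:
    """Rate constants reproducing target charged/active fractions.

    Returns ``(k_charge, k_bind_eff)`` such that the steady state of
    the template (all other fields fixed) has total charged-tRNA
    fraction and active-ribosome fraction equal to the targets.

    The inversion is exact: the charged-fraction target alone fixes
    both charged pools (total uncharged = E/k_charge splits by codon
    class), the active-fraction target is then linear in the elongation
    flux E, and the two constants follow from the charging and binding
    balances.

    Raises
    ------
    CalibrationError
        If a target lies outside the achievable range — e.g. an active
        fraction of 1 would require infinite binding while termination
        flux is positive, or the charged fraction would drive one
        charged pool negative.
    """
    p = params_template
    c, a = target_charged_frac, target_active_frac
    if not (0.0 < c < 1.0 and 0.0 < a < 1.0):
        raise CalibrationError(
            "targets must lie strictly in (0, 1): an active fraction of 1 "
            "needs infinite binding while termination flux is positive, and "
            "a charged fraction of 1 needs infinite charging"
        )
    t_tot = p.T1_tot + p.T2_tot
    uncharged = (1.0 - c) * t_tot
    T_c1 = p.T1_tot - p.f_op * uncharged
    T_c2 = p.T2_tot - (1.0 - p.f_op) * uncharged
    if T_c1 <= 0 or T_c2 <= 0:
        c_min = 1.0 - min(
            p.T1_tot / p.f_op if p.f_op > 0 else math.inf,
            p.T2_tot / (1.0 - p.f_op) if p.f_op < 1 else math.inf,
        ) / t_tot
        raise CalibrationError(
            f"charged fraction {c} drains one tRNA pool at f_op={p.f_op}; "
            f"achievable charged fractions are ({max(c_min, 0.0):.4g}, 1)"
        )
    inv_speed = p.f_op / (p.k_speed * T_c1) + (1.0 - p.f_op) / (p.k_speed * T_c2)
    E = a * p.R_tot / inv_speed  # R_b1 + R_b2 = E * inv_speed = a*R_tot
    k_charge = E / uncharged
    R_f = (1.0 - a) * p.R_tot
    k_bind_eff = E / (p.L * p.N * R_f)
    return k_charge, k_bind_eff


def molar_to_effective_bind(k_bind_molar: float, volume: float) -> float:
    """Convert a molar binding constant to a per-molecule one.

    ``k_bind_eff = k_bind_molar / (N_A * volume)`` with the volume in
    liters, e.g. 2.5e6 M^-1 s^-1 in an E. coli-like 8e-16 L gives
    ~5.19e-3 per molecule per second.
    """
    if k_bind_molar <= 0 or volume <= 0:
        raise ValueError("k_bind_molar and volume must be positive")
    return k_bind_molar / (AVOGADRO * volume)


# ---------------------------------------------------------------------------
# time courses


def integrate_timecourse(
    params: ModelParams,
    init: SystemState,
    t_grid: Sequence[float],
    rtol: float = 1e-10,
    atol: float = 1e-9,
) -> Trajectory:
    """Deterministic time course of the mass-action network.

    Integrates :func:`ode_rhs` (plus the cumulative protein count,
    dP/dt = elongation flux / L) with a stiff solver and returns the
    state at each requested time.  ``init`` is the state at
    ``t_grid[0]``; conservation holds at every output point to the
    integrator tolerance.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0 or np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be a non-empty ordered 1-D sequence")
    init.validate(params)

    if len(t_grid) == 1 and t_grid[0] == 0.0:
        return Trajectory(t_grid, init.as_array()[None, :], np.zeros(1))

    def rhs(_t, y):
        dy = np.empty(8)
        dy[:7] = ode_rhs(y[:7], params)
        dy[7] = (
            params.k_speed
            * (y[5] * y[0] + y[6] * y[1])
            / params.L
        )
        return dy

    y0 = np.append(init.as_array(), 0.0)
    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    sol = solve_ivp(
        rhs, (t0, max(t1, t0)), y0, method="LSODA",
        t_eval=t_grid, rtol=rtol, atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if len(sol.t) else t0
        raise IntegrationError(f"integrator failed: {sol.message}", last)
    return Trajectory(sol.t, sol.y[:7].T.copy(), sol.y[7].copy())
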