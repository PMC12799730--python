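"""Exact stochastic simulation of the two-codon translation network.

Two simulators share the reaction rates of the deterministic model:

* :func:`ssa_meanfield` — the mean-field network itself (ribosomes are
  classified only by the codon class they occupy).  Termination is
  modeled per elongation event with probability ``1/L``, the geometric
  transcript-length approximation implied by the mean-field off-rate.
* :func:`ssa_codon_resolved` — every ribosome carries a transcript and
  codon position; termination happens on stepping past the last codon.
  This relaxes the mean-field assumption that only codon *composition*
  matters, and optionally enforces a ribosome footprint (exclusion).

Long-run time averages of both converge to the deterministic steady
state; the mean-field simulator is the Monte-Carlo oracle used to
cross-validate the numeric solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .core_model import ModelParams, SystemState, Trajectory, solve_steady_state

__all__ = [
    "SSAConfig",
    "CodonSequence",
    "ssa_meanfield",
    "ssa_codon_resolved",
    "generate_transcript",
    "ssa_mean_estimates",
    "default_initial_state",
]

MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SSAConfig:
    """Replicated-run settings; replicate *i* uses seed ``seed + i``."""

    seed: int = 1
    t_max: float = 5000.0
    record_interval: float = 1.0
    n_replicates: int = 10

    def __post_init__(self) -> None:
        if self.t_max <= 0 or self.record_interval <= 0:
            raise ValueError("t_max and record_interval must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if not 0 <= self.seed + self.n_replicates - 1 <= MAX_SEED:
            raise ValueError("replicate seeds must fit in [0, 2^31)")


@dataclass(frozen=True)
class CodonSequence:
    """Ordered codon classes of one transcript (1 optimal, 0 non-optimal)."""

    classes: np.ndarray  # int8, length L
    requested_f_op: float

    @property
    def L(self) -> int:
        return int(self.classes.shape[0])

    @property
    def realized_f_op(self) -> float:
        return float(np.mean(self.classes))

    def to_text(self) -> str:
        """One character per codon: 'O' optimal, 'n' non-optimal."""
        body = "".join("O" if c else "n" for c in self.classes)
        return (f"# codon-class sequence; L={self.L} "
                f"f_op={self.realized_f_op:.6f}\n{body}\n")

    @classmethod
    def from_text(cls, text: str) -> "CodonSequence":
        lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
        body = "".join(lines)
        classes = np.array([1 if ch == "O" else 0 for ch in body], dtype=np.int8)
        return cls(classes=classes, requested_f_op=float(np.mean(classes)))


def default_initial_state(params: ModelParams) -> SystemState:
    """All tRNAs charged, all ribosomes free (the natural t=0 condition)."""
    return SystemState(
        T_c1=params.T1_tot, T_c2=params.T2_tot, T_u1=0.0, T_u2=0.0,
        R_f=params.R_tot, R_b1=0.0, R_b2=0.0,
    )


def _int_state(state: SystemState, params: ModelParams) -> np.ndarray:
    arr = state.as_array()
    ints = np.rint(arr).astype(np.int64)
    if not np.allclose(arr, ints, atol=1e-9):
        raise ValueError("SSA requires integer species counts")
    state.validate(params)
    return ints


def ssa_meanfield(params: ModelParams, config: SSAConfig,
                  init: SystemState | None = None) -> list[Trajectory]:
    """Exact SSA of the mean-field network; one Trajectory per replicate.

    A newly initiated ribosome lands on an optimal codon with
    probability ``f_op``; each elongation event terminates with
    probability ``1/L`` (producing one protein and freeing the
    ribosome) or re-lands with the same ``f_op`` split.  If the total
    propensity reaches zero the run halts cleanly at the current time
    and the remaining records repeat the frozen state.
    """
    init = default_initial_state(params) if init is None else init
    ints = _int_state(init, params)
    out = []
    for i in range(config.n_replicates):
        times, states, protein = _kernels.meanfield_kernel(
            config.seed + i, config.t_max, config.record_interval,
            float(params.L), params.k_charge, params.k_speed,
            params.k_bind_eff, params.f_op, float(params.N), ints,
        )
        out.append(Trajectory(times, states.astype(float), protein.astype(float)))
    return out


def generate_transcript(L: int, f_op: float, seed: int,
                        mode: str = "exact-count") -> CodonSequence:
    """Random codon-class sequence of length L.

    ``exact-count`` places round(f_op*L) optimal codons at uniformly
    random positions; ``bernoulli`` draws each codon independently.
    Deterministic given the seed.
    """
    if L < 1 or not 0.0 <= f_op <= 1.0:
        raise ValueError("need L >= 1 and f_op in [0, 1]")
    rng = np.random.default_rng(seed)
    if mode == "exact-count":
        classes = np.zeros(L, dtype=np.int8)
        k = int(round(f_op * L))
        classes[rng.choice(L, size=k, replace=False)] = 1
    elif mode == "bernoulli":
        classes = (rng.random(L) < f_op).astype(np.int8)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'bernoulli' or 'exact-count'")
    return CodonSequence(classes=classes, requested_f_op=f_op)


def ssa_codon_resolved(params: ModelParams, sequences: list[CodonSequence],
                       config: SSAConfig, footprint: int = 0) -> list[Trajectory]:
    """Position-resolved SSA over explicit codon sequences.

    Requires exactly ``params.N`` sequences of length ``params.L``.
    All ribosomes start free and all tRNAs charged (positions of
    pre-bound ribosomes would be undefined).  ``footprint`` > 0
    enforces a minimum anchor spacing (in codons) and clear initiation
    regions; 0 disables exclusion, matching the mean-field assumption.
    """
    if len(sequences) != int(params.N):
        raise ValueError(f"need exactly N={int(params.N)} sequences")
    if any(s.L != int(params.L) for s in sequences):
        raise ValueError(f"all sequences must have length L={int(params.L)}")
    if footprint < 0:
        raise ValueError("footprint must be >= 0")
    seqs = np.stack([s.classes for s in sequences]).astype(np.int8)
    init = default_initial_state(params)
    ints = _int_state(init, params)
    out = []
    for i in range(config.n_replicates):
        times, states, protein = _kernels.codon_resolved_kernel(
            config.seed + i, config.t_max, config.record_interval,
            seqs, params.k_charge, params.k_speed, params.k_bind_eff,
            footprint, int(params.R_tot), ints,
        )
        out.append(Trajectory(times, states.astype(float), protein.astype(float)))
    return out


def ssa_mean_estimates(trajectories: list[Trajectory],
                       burn_in: float) -> pd.DataFrame:
    """Stationary means and standard errors from replicate trajectories.

    For each replicate, species are averaged over the records at times
    >= ``burn_in`` (uniform record grid, so the plain mean is the
    time-weighted mean) and the protein production rate is the protein
    increment over the window divided by its duration.  The returned
    frame has one row per species plus ``protein_rate``, with columns
    ``mean`` and ``se`` (standard error across replicates).
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 replicates for a standard error")
    from .core_model import STATE_FIELDS

    per_rep = []
    for tr in trajectories:
        if burn_in >= tr.times[-1]:
            raise ValueError("burn_in must be smaller than the trajectory span")
        mask = tr.times >= burn_in
        means = tr.states[mask].mean(axis=0)
        t0, t1 = tr.times[mask][0], tr.times[-1]
        p0, p1 = tr.protein[mask][0], tr.protein[-1]
        rate = (p1 - p0) / (t1 - t0)
        per_rep.append(np.append(means, rate))
    arr = np.array(per_rep)
    names = list(STATE_FIELDS) + ["protein_rate"]
    return pd.DataFrame(
        {
            "mean": arr.mean(axis=0),
            "se": arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]),
        },
        index=names,
    )


def meanfield_reference(params: ModelParams) -> pd.Series:
    """Deterministic steady-state values in ssa_mean_estimates layout."""
    from .core_model import STATE_FIELDS, protein_rate

    ss = solve_steady_state(params)
    vals = list(ss.as_array()) + [protein_rate(ss, params)]
    return pd.Series(vals, index=list(STATE_FIELDS) + ["protein_rate"])
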