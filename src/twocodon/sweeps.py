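"""Codon-usage sweeps and derived analyses.

Sweeping the fraction of optimal codons ``f_op`` across [0, 1] traces
how the steady-state expression rate responds to codon usage bias.  The
location of its maximum, ``f_op_max``, moves with the tRNA charging
rate: when charging limits translation the optimum sits at the fraction
of preferred tRNAs (matching codon demand to the tRNA pool), and it
drifts to 1 as charging becomes fast and both pools stay charged.

Also here: the total-tRNA scaling law (rescaling tRNA totals by alpha
while dividing ``k_charge`` and ``k_speed`` by alpha leaves the
expression rate unchanged) and the weighted-average reduction of a
mixed-transcript system to a single effective ``f_op``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    ModelParams,
    SteadyStateError,
    protein_rate,
    solve_steady_state,
)

__all__ = [
    "SweepResult",
    "FopMaxResult",
    "ScalingResult",
    "TranscriptClass",
    "sweep_fop",
    "find_fop_max",
    "sweep_kcharge_fopmax",
    "scaling_check",
    "effective_fop",
    "DEFAULT_FOP_GRID",
    "DEFAULT_KCHARGE_GRID",
]

#: f_op grid matching the published discrete sweep resolution
DEFAULT_FOP_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)
#: 20 log-spaced charging rates spanning the studied 3-300 /s range
DEFAULT_KCHARGE_GRID = np.logspace(np.log10(3.0), np.log10(300.0), 20)

#: relative P_r range below which a sweep is considered flat
FLAT_RTOL = 1e-9

_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class SweepResult:
    """Per-f_op steady states plus sweep metadata."""

    table: pd.DataFrame  # columns: f_op, P_r, T_c1, T_c2, R_b1, R_b2, ok
    metadata: dict = field(default_factory=dict)

    @property
    def n_failed(self) -> int:
        return int((~self.table["ok"]).sum())


@dataclass(frozen=True)
class FopMaxResult:
    """Expression-maximizing codon fraction.

    ``f_op_max`` is the refined argmax (grid scan + golden-section on
    the bracketing interval); ``grid_argmax`` the raw grid winner.
    ``flat`` flags curves whose relative P_r range is below
    ``FLAT_RTOL`` — there the argmax is numerically meaningless and
    ``f_op_max`` is NaN.  ``refined`` is False when solver failures
    forced a fall back to the coarse-grid argmax.
    """

    f_op_max: float
    grid_argmax: float
    P_r_max: float
    flat: bool = False
    refined: bool = True

    def __float__(self) -> float:
        return self.f_op_max


@dataclass(frozen=True)
class ScalingResult:
    """Scaling-law verification across alpha factors."""

    max_relative_deviation: float
    table: pd.DataFrame  # columns: alpha, f_op, P_r


@dataclass(frozen=True)
class TranscriptClass:
    """A transcript species: copy number, length, codon composition."""

    copies: float
    L: float
    f_op: float

    def __post_init__(self) -> None:
        if self.copies < 0 or self.L < 1 or not 0.0 <= self.f_op <= 1.0:
            raise ValueError("invalid TranscriptClass")


def _pr_at(params: ModelParams, f_op: float) -> float:
    p = params.replace(f_op=float(f_op))
    return protein_rate(solve_steady_state(p), p)


def sweep_fop(params: ModelParams, grid=None) -> SweepResult:
    """Steady states across an f_op grid; per-point failures recorded.

    The returned table is sorted by f_op; a point where the solver
    failed carries NaNs and ``ok=False``.  Raises SteadyStateError only
    if every point fails.
    """
    grid = DEFAULT_FOP_GRID if grid is None else np.asarray(grid, float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("grid must lie within [0, 1]")
    rows = []
    for f in np.sort(grid):
        try:
            p = params.replace(f_op=float(f))
            s = solve_steady_state(p)
            rows.append((f, protein_rate(s, p), s.T_c1, s.T_c2,
                         s.R_b1, s.R_b2, True))
        except (SteadyStateError, ValueError):
            rows.append((f, np.nan, np.nan, np.nan, np.nan, np.nan, False))
    table = pd.DataFrame(
        rows, columns=["f_op", "P_r", "T_c1", "T_c2", "R_b1", "R_b2", "ok"]
    )
    if not table["ok"].any():
        raise SteadyStateError("all sweep points failed")
    return SweepResult(
        table=table,
        metadata={
            "k_charge": params.k_charge,
            "preferred_fraction": params.preferred_fraction,
        },
    )


def find_fop_max(params: ModelParams, coarse_step: float = 0.01,
                 refine_tol: float = 1e-3) -> FopMaxResult:
    """Locate the codon fraction maximizing steady-state expression.

    Coarse grid scan (step <= 0.05) followed by golden-section
    refinement on the interval bracketing the grid argmax.  Ties on the
    grid break toward smaller f_op (first maximum).  A curve whose
    relative P_r range is below ``FLAT_RTOL`` (the symmetric-pool,
    fast-charging case) is reported flat with f_op_max = NaN.
    """
    if coarse_step > 0.05:
        raise ValueError("coarse_step must be <= 0.05")
    grid = np.round(np.arange(0.0, 1.0 + 1e-9, coarse_step), 12)
    if grid[-1] < 1.0:
        grid = np.append(grid, 1.0)
    res = sweep_fop(params, grid)
    tab = res.table
    pr = tab["P_r"].to_numpy()
    fvals = tab["f_op"].to_numpy()
    finite = np.isfinite(pr)
    i_max = int(np.nanargmax(pr))
    p_max = pr[i_max]
    p_min = np.nanmin(pr)
    if p_max > 0 and (p_max - p_min) / p_max < FLAT_RTOL:
        return FopMaxResult(np.nan, fvals[i_max], p_max, flat=True)
    # refine only if the neighbours solved; otherwise flag coarse result
    lo_i = max(i_max - 1, 0)
    hi_i = min(i_max + 1, len(fvals) - 1)
    if not (finite[lo_i] and finite[hi_i]):
        warnings.warn("solver failures near the bracket; returning grid argmax")
        return FopMaxResult(fvals[i_max], fvals[i_max], p_max, refined=False)
    a, b = fvals[lo_i], fvals[hi_i]
    try:
        x1 = b - _GOLD * (b - a)
        x2 = a + _GOLD * (b - a)
        f1, f2 = _pr_at(params, x1), _pr_at(params, x2)
        while b - a > refine_tol:
            if f1 < f2:
                a, x1, f1 = x1, x2, f2
                x2 = a + _GOLD * (b - a)
                f2 = _pr_at(params, x2)
            else:
                b, x2, f2 = x2, x1, f1
                x1 = b - _GOLD * (b - a)
                f1 = _pr_at(params, x1)
        x_best = 0.5 * (a + b)
        return FopMaxResult(x_best, fvals[i_max], max(p_max, f1, f2))
    except (SteadyStateError, ValueError):
        warnings.warn("refinement failed; returning grid argmax")
        return FopMaxResult(fvals[i_max], fvals[i_max], p_max, refined=False)


def sweep_kcharge_fopmax(fractions, k_charge_grid=None,
                         params_template: ModelParams | None = None,
                         coarse_step: float = 0.01,
                         refine_tol: float = 1e-3) -> pd.DataFrame:
    """f_op_max as a function of charging rate, per tRNA fraction.

    Each curve runs from the tRNA fraction (slow charging) up to 1
    (fast charging, for fractions above 0.5); monotonicity in
    ``k_charge`` is checked within the refinement tolerance and a
    violation raises, since it would indicate a solver defect.
    Returns a tidy frame (preferred_fraction, k_charge, f_op_max, flat).
    """
    from .reference import load_reference_params

    if params_template is None:
        params_template = load_reference_params("baseline")
    k_charge_grid = (DEFAULT_KCHARGE_GRID if k_charge_grid is None
                     else np.asarray(k_charge_grid, float))
    t_tot = params_template.T1_tot + params_template.T2_tot
    rows = []
    for frac in fractions:
        series = []
        for kc in k_charge_grid:
            p = params_template.replace(
                T1_tot=frac * t_tot, T2_tot=(1.0 - frac) * t_tot,
                k_charge=float(kc),
            )
            r = find_fop_max(p, coarse_step=coarse_step, refine_tol=refine_tol)
            series.append(r)
            rows.append((frac, float(kc), r.f_op_max, r.flat))
        vals = [r.f_op_max for r in series if not r.flat]
        slack = max(refine_tol, coarse_step)
        if any(b < a - slack for a, b in zip(vals, vals[1:])):
            raise SteadyStateError(
                f"f_op_max not monotone in k_charge at fraction {frac}"
            )
    return pd.DataFrame(
        rows, columns=["preferred_fraction", "k_charge", "f_op_max", "flat"]
    )


def scaling_check(params: ModelParams, alphas,
                  fop_grid=(0.0, 0.25, 0.5, 0.75, 1.0)) -> ScalingResult:
    """Verify the total-tRNA scaling law.

    For each alpha > 0: rescale both tRNA totals by alpha and divide
    ``k_charge`` and ``k_speed`` by alpha, re-solve across the f_op
    grid, and compare P_r to the alpha = 1 value.  The steady-state
    equations are invariant under this transformation, so the maximum
    relative deviation should sit at solver tolerance (< 1e-8).
    """
    alphas = np.asarray(alphas, float)
    if np.any(alphas <= 0):
        raise ValueError("alphas must be positive")
    base = {f: _pr_at(params, f) for f in fop_grid}
    rows = []
    dev = 0.0
    for a in alphas:
        scaled = params.replace(
            T1_tot=a * params.T1_tot, T2_tot=a * params.T2_tot,
            k_charge=params.k_charge / a, k_speed=params.k_speed / a,
        )
        for f in fop_grid:
            pr = _pr_at(scaled, f)
            rows.append((a, f, pr))
            if base[f] > 0:
                dev = max(dev, abs(pr - base[f]) / base[f])
    return ScalingResult(
        max_relative_deviation=dev,
        table=pd.DataFrame(rows, columns=["alpha", "f_op", "P_r"]),
    )


def effective_fop(classes: list[TranscriptClass]) -> float:
    """Codon-mass-weighted mean f_op of a mixed transcript population.

    Only the number of codons of each type being translated matters in
    the mean-field picture, so a population of transcript classes
    reduces to a single effective fraction sum(copies*L*f_op) /
    sum(copies*L); a mixed system is then represented by one solve with
    this f_op, N = total copies and L = mass-weighted mean length.
    """
    if not classes:
        raise ValueError("need at least one transcript class")
    mass = sum(c.copies * c.L for c in classes)
    if mass <= 0:
        raise ValueError("total translated codon mass must be positive")
    return sum(c.copies * c.L * c.f_op for c in classes) / mass
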