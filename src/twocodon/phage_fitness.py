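"""Burst-size to growth-rate conversion for phage fitness.

A lytic infection producing ``p`` capsid proteins yields a burst size
``b = p / virion_size`` virions per cell.  With adsorption-rate x
cell-density product kC and lysis time tau, the intrinsic growth rate r
(per minute) satisfies the implicit relation

    r = kC * (b * exp(-tau * r) - 1),

whose right-hand side is strictly decreasing in r, so the root is
unique.  Fitness is reported as doublings per hour, d = 60*r / ln 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "FitnessParams",
    "growth_rate",
    "doublings_per_hour",
    "relative_fitness",
]


@dataclass(frozen=True)
class FitnessParams:
    """Constants of the burst-size -> growth-rate conversion.

    ``lysis_time`` in minutes (note: unrelated to the transcript length
    of the translation model, despite the field's shared symbol),
    ``virion_size`` in capsid proteins per virion, ``kC`` the
    adsorption-rate x cell-density product in 1/min.
    """

    lysis_time: float = 12.0
    virion_size: float = 400.0
    kC: float = 1.0

    def __post_init__(self) -> None:
        if self.lysis_time <= 0 or self.virion_size <= 0 or self.kC <= 0:
            raise ValueError("all FitnessParams fields must be positive")


def growth_rate(p: float, fp: FitnessParams = FitnessParams()) -> float:
    """Intrinsic growth rate r (per minute) for capsid count ``p``.

    Solves r = kC*(b*exp(-tau*r) - 1) with b = p/virion_size by
    bracketed root finding.  The residual h(r) = kC*(b*exp(-tau*r) - 1)
    - r is strictly decreasing, h(-kC) >= 0 and h(max(0, kC*(b-1)) +
    eps) < 0, so [-kC, kC*(b-1) + eps] brackets the unique root; the
    bracket is expanded geometrically if floating-point rounding ever
    defeats the sign argument.
    """
    if p < 0:
        raise ValueError("capsid count must be non-negative")
    b = p / fp.virion_size
    if b == 0.0:
        return -fp.kC
    kC, tau = fp.kC, fp.lysis_time

    def h(r: float) -> float:
        return kC * (b * math.exp(-tau * r) - 1.0) - r

    lo = -kC
    hi = max(0.0, kC * (b - 1.0)) + 1e-9
    for _ in range(64):
        if h(lo) >= 0.0 and h(hi) <= 0.0:
            break
        if h(lo) < 0.0:
            lo -= (hi - lo)
        if h(hi) > 0.0:
            hi += (hi - lo)
    else:
        raise RuntimeError(
            f"could not bracket growth-rate root: h({lo})={h(lo)}, "
            f"h({hi})={h(hi)}"
        )
    if h(lo) == 0.0:
        return lo
    return brentq(h, lo, hi, xtol=1e-15, rtol=8.9e-16)


def doublings_per_hour(r: float) -> float:
    """Fitness in doublings per hour: d = log2(exp(60*r)) = 60*r/ln 2."""
    if not math.isfinite(r):
        raise ValueError("growth rate must be finite")
    return 60.0 * r / math.log(2.0)


def relative_fitness(d_values: dict, reference: str) -> dict:
    """Normalize doublings-per-hour values to a reference condition."""
    if reference not in d_values:
        raise KeyError(f"reference condition {reference!r} not present")
    ref = d_values[reference]
    if ref == 0:
        raise ZeroDivisionError("reference fitness is zero")
    return {k: v / ref for k, v in d_values.items()}
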