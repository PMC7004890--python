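"""Transit times, residence times, and plasma recycling statistics.

Two independent routes are implemented and cross-checked:

* closed forms from the embedded Markov chain of plasma exits — the return
  probability per plasma exit determines the recycling number as a geometric
  series, and residence times follow from visit counts times per-visit
  transit times;
* the mean-residence-time matrix Θ = −A⁻¹ of the {4,5,6,7} subsystem, whose
  column for entry into plasma gives the residence time of every compartment
  directly.

Both require an irreversible loss route (L(10,6) > 0 or L(8,5) > 0);
otherwise A is singular and residence times are infinite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .model import ModelSpec

__all__ = [
    "DerivedKinetics",
    "transit_times",
    "residence_times_matrix",
    "residence_and_recycling",
]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class DerivedKinetics:
    """Time-related kinetic parameters for plasma and the exchange pools.

    ``transit`` maps compartment -> mean transit time t̄(I) in days (time per
    visit); ``residence`` maps compartment -> T̄(I,5) in days (total time in I
    after first reaching plasma).  The recycling number ν(5) is the mean
    number of returns to plasma after the first arrival, and the recycling
    time is the mean time a molecule leaving plasma takes to cycle back.
    """

    transit: Mapping[int, float]
    residence: Mapping[int, float]
    system_residence: float
    recycling_number: float
    recycling_time: float

    @property
    def plasma_transit_hours(self) -> float:
        return self.transit[5] * HOURS_PER_DAY


def transit_times(model: ModelSpec) -> dict[int, float]:
    """Mean transit time t̄(I) = 1 / (total fractional exit rate), days.

    t̄(5) = 1/[L(6,5)+L(7,5)+L(8,5)], t̄(6) = 1/[L(5,6)+L(10,6)],
    t̄(7) = 1/L(5,7).
    """
    exits = {
        5: model.l(6, 5) + model.l(7, 5) + model.l(8, 5),
        6: model.l(5, 6) + model.l(10, 6),
        7: model.l(5, 7),
    }
    out = {}
    for comp, rate in exits.items():
        if rate <= 0:
            raise ValueError(f"compartment {comp} has zero exit rate; transit time undefined")
        out[comp] = 1.0 / rate
    return out


def residence_times_matrix(model: ModelSpec) -> dict[int, float]:
    """Residence times T̄(I,5) from the mean-residence-time matrix Θ = −A⁻¹.

    For a unit amount introduced into plasma, Θ's plasma column holds the
    expected total time spent in each compartment before irreversible loss.
    """
    A = model.system_matrix()
    try:
        theta = -np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("closed system: no irreversible loss, residence times diverge") from exc
    if not np.all(np.isfinite(theta)):
        raise ValueError("closed system: no irreversible loss, residence times diverge")
    col = theta[:, 1]  # entry into plasma (state order 4, 5, 6, 7)
    return {4: float(col[0]), 5: float(col[1]), 6: float(col[2]), 7: float(col[3])}


def residence_and_recycling(
    model: ModelSpec, check: bool = True, check_rtol: float = 1e-6
) -> DerivedKinetics:
    """Residence times, recycling number and recycling time (closed forms).

    The per-exit probability of eventually returning to plasma is

        p = [L(7,5) + L(6,5)·L(5,6)/(L(5,6)+L(10,6))] / [L(6,5)+L(7,5)+L(8,5)]

    (the small pool always returns; the storage pool returns with the odds of
    recycling beating irreversible loss; component 8 never returns), giving
    ν(5) = p/(1−p), T̄(5,5) = t̄(5)(1+ν(5)), and pool residence as
    visits × per-visit transit.  With ``check=True`` the values are verified
    against the matrix route to ``check_rtol``.
    """
    if model.l(10, 6) <= 0 and model.l(8, 5) <= 0:
        raise ValueError("closed system: no irreversible loss, residence times diverge")

    t = transit_times(model)
    l65, l75, l85 = model.l(6, 5), model.l(7, 5), model.l(8, 5)
    l56, l106 = model.l(5, 6), model.l(10, 6)
    plasma_exit = l65 + l75 + l85

    return_from_6 = l56 / (l56 + l106) if (l56 + l106) > 0 else 0.0
    p = (l75 + l65 * return_from_6) / plasma_exit
    if p >= 1.0:
        raise ValueError("return probability >= 1: no effective irreversible loss")
    nu = p / (1.0 - p)

    t55 = t[5] * (1.0 + nu)
    t65 = l65 * t55 * t[6]
    t75 = l75 * t55 * t[7]
    system = t55 + t65 + t75
    recycling_time = (t65 + t75) / nu if nu > 0 else float("nan")

    if check:
        theta = residence_times_matrix(model)
        for closed, via_matrix in ((t55, theta[5]), (t65, theta[6]), (t75, theta[7])):
            if not np.isclose(closed, via_matrix, rtol=check_rtol, atol=0.0):
                raise RuntimeError(
                    "closed-form and matrix residence times disagree: "
                    f"{closed!r} vs {via_matrix!r}"
                )

    return DerivedKinetics(
        transit=t,
        residence={5: t55, 6: t65, 7: t75},
        system_residence=system,
        recycling_number=nu,
        recycling_time=recycling_time,
    )
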