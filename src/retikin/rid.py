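"""Retinol isotope dilution (RID) coefficients and total-body-stores equation.

RID estimates total body vitamin A stores from a single post-dose plasma
sample via TBS = Fa · S / SAp, where Fa is the fraction of the oral tracer
dose absorbed and retained in the storage pools (compartments 6 and 7) at
time t, S is the ratio of plasma to stores specific activity at t, and SAp
is the measured plasma retinol specific activity (fraction of dose per μmol
plasma retinol).  Fa and S are population coefficients computed from a
fitted group model; SAp is the individual's measurement.

Algebraically Fa·S = F(5)(t)·[M(6)+M(7)]/M(5), so applying the equation to
the model's own plasma curve returns the model's own TBS exactly — the
self-consistency closure used in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelSpec, simulate_tracer
from .steady import TraceeSolution

__all__ = ["RIDCoefficients", "rid_coefficients", "rid_tbs", "default_rid_days"]


@dataclass(frozen=True)
class RIDCoefficients:
    """Time courses of Fa, S and their product FaS.

    ``s`` and ``fas`` are NaN-masked at times before any tracer has reached
    the stores (Fa = 0), where the specific-activity ratio is undefined.
    """

    times: np.ndarray
    fa: np.ndarray
    s: np.ndarray
    fas: np.ndarray

    def at(self, time: float) -> tuple[float, float, float]:
        """(Fa, S, FaS) at one time already on the grid."""
        idx = np.nonzero(np.isclose(self.times, time, rtol=1e-9, atol=1e-12))[0]
        if idx.size == 0:
            raise KeyError(f"time {time} not on the coefficient grid")
        i = int(idx[0])
        return float(self.fa[i]), float(self.s[i]), float(self.fas[i])


def default_rid_days() -> np.ndarray:
    """Integer days 4–28, the tabulation window used for group coefficients."""
    return np.arange(4.0, 29.0)


def rid_coefficients(
    model: ModelSpec,
    tracee: TraceeSolution,
    times: np.ndarray | None = None,
) -> RIDCoefficients:
    """Compute Fa(t), S(t) and FaS(t) from a model and its steady state.

    Fa(t) = F(6)(t) + F(7)(t); S(t) = [F(5)(t)/M(5)] / {Fa(t)/[M(6)+M(7)]}.
    """
    if times is None:
        times = default_rid_days()
    times = np.asarray(times, dtype=float)
    curve = simulate_tracer(model, times)
    f5 = curve.fdp
    fa = curve.states["F6"].to_numpy() + curve.states["F7"].to_numpy()

    m5 = tracee.mass(5)
    tbs = tracee.tbs
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(fa > 0, (f5 / m5) / (fa / tbs), np.nan)
    fas = fa * s
    return RIDCoefficients(times=times, fa=fa, s=s, fas=fas)


def rid_tbs(fas_at_t: float, sap: float) -> float:
    """Apply the RID equation: TBS = FaS / SAp (μmol).

    ``sap`` is plasma retinol specific activity at the same time, as fraction
    of dose per μmol plasma retinol.
    """
    if not np.isfinite(sap) or sap <= 0:
        raise ValueError("plasma specific activity must be finite and > 0")
    if not np.isfinite(fas_at_t) or fas_at_t < 0:
        raise ValueError("FaS must be finite and >= 0")
    return fas_at_t / sap
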