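"""Weighted nonlinear least squares on composite tracer datasets.

One or several composite (super-child) datasets are fitted simultaneously.
Each plasma observation contributes a residual (y − F5(t)) / (FSD·y); the
group's adjusted vitamin A intake enters as one additional weighted datum,
with the model's predicted intake at steady state,
[L(10,6)·M(6) + L(8,5)·M(5)] / L(4,3), as its prediction.  A sharing map
declares, per adjustable parameter, whether one value is common to all
groups, every group has its own, or only a named subset is independent
(the "partially parallel" design).

Rates span four orders of magnitude, so the optimiser works on
log-transformed parameters (positivity by construction) with a bounded
trust-region reflective algorithm.  Parameter uncertainty is reported as the
fractional standard deviation (FSD = SE/estimate), which on the log scale is
simply the standard error of the log-parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import (
    REQUIRED_PARAMETERS,
    ModelSpec,
    build_group_model,
    parse_param_name,
)
from .model import _propagate  # shared closed-form propagator

__all__ = [
    "CompositeDataset",
    "SharingMap",
    "FitResult",
    "objective",
    "fit",
    "fsd_report",
]

#: canonical ordering of adjustable parameters in theta
ADJUSTABLE_ORDER: tuple[str, ...] = (
    "DT(3)",
    "L(5,4)",
    "L(7,5)",
    "L(5,7)",
    "L(6,5)",
    "L(5,6)",
    "L(10,6)",
    "L(8,5)",
)

DEFAULT_RATE_BOUNDS = (1e-6, 1e3)
DEFAULT_DELAY_BOUNDS = (1e-3, 2.0)

#: FSD above which a parameter is reported as poorly identified
FSD_FLAG_THRESHOLD = 0.5


@dataclass
class CompositeDataset:
    """Composite super-child observations for one group.

    ``times``/``fdp`` are the geometric-mean sampling times (days) and
    fraction of dose in plasma; ``n`` the number of children per time; ``fsd``
    the fractional standard deviation used as the weight.  ``m5`` (μmol) and
    ``u3`` (μmol RAE/d) are the group constants; the intake datum is weighted
    with ``intake_fsd``.
    """

    group: str
    times: np.ndarray
    fdp: np.ndarray
    n: np.ndarray
    fsd: np.ndarray
    m5: float
    u3: float
    intake_fsd: float = 0.05

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fdp = np.asarray(self.fdp, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.fsd = np.asarray(self.fsd, dtype=float)
        if not (self.times.size == self.fdp.size == self.n.size == self.fsd.size):
            raise ValueError("observation columns must have equal length")
        if np.any(self.times <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly positive and increasing")
        if np.any(self.fdp <= 0):
            raise ValueError("FDp observations must be > 0")
        if np.any(self.fsd <= 0) or self.intake_fsd <= 0:
            raise ValueError("FSD weights must be > 0")
        if np.any(self.n < 1):
            raise ValueError("per-time sample counts must be >= 1")
        if self.m5 <= 0 or self.u3 <= 0:
            raise ValueError("group constants M(5) and U(3) must be > 0")


@dataclass
class SharingMap:
    """Which adjustable parameters are shared, independent, or fixed.

    ``independent_for`` maps a parameter to the groups in which it gets its
    own value; the remaining groups share one value.  ``fixed`` values may be
    global floats or per-group ``{group: value}`` maps.
    """

    shared: list[str] = field(default_factory=list)
    independent: list[str] = field(default_factory=list)
    independent_for: dict[str, list[str]] = field(default_factory=dict)
    fixed: dict[str, float | dict[str, float]] = field(default_factory=dict)

    def adjustable_names(self) -> list[str]:
        names = list(self.shared) + list(self.independent) + list(self.independent_for)
        order = {n: i for i, n in enumerate(ADJUSTABLE_ORDER)}
        return sorted(names, key=lambda n: (order.get(n, len(order)), n))

    def validate(self, groups: Sequence[str]) -> None:
        names = list(self.shared) + list(self.independent) + list(self.independent_for)
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"parameters declared adjustable more than once: {sorted(dup)}")
        clash = set(names) & set(self.fixed)
        if clash:
            raise ValueError(f"parameters both fixed and adjustable: {sorted(clash)}")
        for name in list(names) + list(self.fixed):
            parse_param_name(name)
        for name, subset in self.independent_for.items():
            unknown = set(subset) - set(groups)
            if unknown:
                raise ValueError(f"{name}: unknown groups in independent_for: {sorted(unknown)}")
        covered = set(names) | set(self.fixed)
        missing = [p for p in REQUIRED_PARAMETERS if p not in covered]
        if missing:
            raise ValueError(f"parameters neither fixed nor adjustable: {missing}")

    def entries(self, groups: Sequence[str]) -> list[tuple[str, tuple[str, ...]]]:
        """Theta layout: one ``(name, groups-it-applies-to)`` per element."""
        out: list[tuple[str, tuple[str, ...]]] = []
        for name in self.adjustable_names():
            if name in self.shared:
                out.append((name, tuple(groups)))
            elif name in self.independent:
                out.extend((name, (g,)) for g in groups)
            else:
                subset = self.independent_for[name]
                out.extend((name, (g,)) for g in groups if g in subset)
                rest = tuple(g for g in groups if g not in subset)
                if rest:
                    out.append((name, rest))
        return out

    def fixed_for(self, group: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for name, value in self.fixed.items():
            if isinstance(value, Mapping):
                if group not in value:
                    raise ValueError(f"fixed parameter {name} has no value for group {group!r}")
                out[name] = float(value[group])
            else:
                out[name] = float(value)
        return out


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of a multi-group fit."""

    entries: list[tuple[str, tuple[str, ...]]]
    estimates: dict[tuple[str, tuple[str, ...]], float]
    fsd: dict[tuple[str, tuple[str, ...]], float]
    models: dict[str, ModelSpec]
    wss_plasma: dict[str, float]
    wss_intake: dict[str, float]
    objective: float
    n_obs: int
    dof: int
    success: bool
    message: str
    nfev: int
    singular: set[tuple[str, tuple[str, ...]]] = field(default_factory=set)

    def estimate(self, name: str, group: str | None = None) -> float:
        for (pname, pgroups), value in self.estimates.items():
            if pname == name and (group is None or group in pgroups):
                return value
        raise KeyError(f"no estimate for {name} (group={group})")


def _group_params(
    theta: np.ndarray,
    entries: list[tuple[str, tuple[str, ...]]],
    sharing: SharingMap,
    group: str,
) -> dict[str, float]:
    params = sharing.fixed_for(group)
    for value, (name, groups) in zip(theta, entries):
        if group in groups:
            params[name] = float(value)
    return params


def _f5_curve(params: Mapping[str, float], times: np.ndarray) -> np.ndarray:
    """Plasma fraction of dose at given times (lean path for the optimiser)."""
    dt3 = params["DT(3)"]
    l54 = params["L(5,4)"]
    l65, l75, l85 = params["L(6,5)"], params["L(7,5)"], params["L(8,5)"]
    l56, l106, l57 = params["L(5,6)"], params["L(10,6)"], params["L(5,7)"]
    A = np.array(
        [
            [-l54, 0.0, 0.0, 0.0],
            [l54, -(l65 + l75 + l85), l56, l57],
            [0.0, l65, -(l56 + l106), 0.0],
            [0.0, l75, 0.0, -l57],
        ]
    )
    x0 = np.array([params["L(4,3)"], 0.0, 0.0, 0.0])
    tau = times - dt3
    post = tau >= 0
    f5 = np.zeros_like(times)
    if np.any(post):
        f5[post] = np.clip(_propagate(A, x0, tau[post])[1], 0.0, None)
    return f5


def _predicted_intake(params: Mapping[str, float], m5: float) -> float:
    l56, l106 = params["L(5,6)"], params["L(10,6)"]
    if l56 + l106 <= 0:
        raise ValueError("L(5,6) + L(10,6) must be > 0 for the intake prediction")
    m6 = params["L(6,5)"] * m5 / (l56 + l106)
    dr = l106 * m6 + params["L(8,5)"] * m5
    return dr / params["L(4,3)"]


def objective(
    theta: np.ndarray,
    datasets: Sequence[CompositeDataset],
    sharing: SharingMap,
    use_intake: bool = True,
    log_scale: bool = False,
) -> np.ndarray:
    """Weighted residual vector for a parameter vector.

    Theta elements follow ``sharing.entries([d.group for d in datasets])``;
    with ``log_scale=True`` theta holds log-parameters.  The weighted sum of
    squares is the sum of squared entries of the returned vector.
    """
    groups = [d.group for d in datasets]
    sharing.validate(groups)
    entries = sharing.entries(groups)
    theta = np.asarray(theta, dtype=float)
    if theta.size != len(entries):
        raise ValueError(f"theta has {theta.size} elements, sharing map implies {len(entries)}")
    values = np.exp(theta) if log_scale else theta

    residuals: list[np.ndarray] = []
    for ds in datasets:
        params = _group_params(values, entries, sharing, ds.group)
        f5 = _f5_curve(params, ds.times)
        residuals.append((ds.fdp - f5) / (ds.fsd * ds.fdp))
        if use_intake:
            pred = _predicted_intake(params, ds.m5)
            residuals.append(np.array([(ds.u3 - pred) / (ds.intake_fsd * ds.u3)]))
    return np.concatenate(residuals)


def _default_bounds(name: str) -> tuple[float, float]:
    kind, _, _ = parse_param_name(name)
    return DEFAULT_DELAY_BOUNDS if kind == "DT" else DEFAULT_RATE_BOUNDS


def _init_value(
    init: Mapping,
    name: str,
    groups: tuple[str, ...],
) -> float:
    for g in groups:
        if (name, g) in init:
            return float(init[(name, g)])
    if name in init:
        return float(init[name])
    raise ValueError(f"no initial value for adjustable parameter {name} (groups {groups})")


def fit(
    datasets: Sequence[CompositeDataset],
    sharing: SharingMap,
    init: Mapping,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    seed: int | None = None,
    use_intake: bool = True,
    perturb: float = 0.0,
    multistart: int = 1,
    max_nfev: int | None = None,
) -> FitResult:
    """Estimate adjustable parameters by bounded weighted least squares.

    Parameters
    ----------
    init
        Starting values: ``{name: value}`` and/or ``{(name, group): value}``.
    perturb
        Optional relative spread of random start perturbation (e.g. 0.5 for
        ±50%); requires ``seed``.
    multistart
        Number of random starts (best objective wins); 1 means a single
        start at ``init`` (perturbed if ``perturb`` > 0).
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    groups = [d.group for d in datasets]
    if len(set(groups)) != len(groups):
        raise ValueError("dataset group labels must be unique")
    sharing.validate(groups)
    entries = sharing.entries(groups)
    p = len(entries)

    x_base = np.array([_init_value(init, name, grs) for name, grs in entries])
    lo = np.array([(bounds or {}).get(name, _default_bounds(name))[0] for name, _ in entries])
    hi = np.array([(bounds or {}).get(name, _default_bounds(name))[1] for name, _ in entries])
    if np.any(x_base < lo) or np.any(x_base > hi):
        raise ValueError("initial values must lie within bounds")

    rng = np.random.default_rng(seed)
    if (perturb > 0 or multistart > 1) and seed is None:
        raise ValueError("random starts require an explicit seed")

    def resid(x_log: np.ndarray) -> np.ndarray:
        return objective(x_log, datasets, sharing, use_intake=use_intake, log_scale=True)

    best = None
    for start in range(max(multistart, 1)):
        x0 = x_base.copy()
        if perturb > 0 and (multistart > 1 or start == 0):
            factors = rng.uniform(1.0 - perturb, 1.0 + perturb, size=p)
            x0 = np.clip(x0 * factors, lo, hi)
        res = least_squares(
            resid,
            np.log(x0),
            bounds=(np.log(lo), np.log(hi)),
            method="trf",
            ftol=1e-10,
            xtol=1e-10,
            gtol=1e-10,
            max_nfev=max_nfev,
        )
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    res = best

    values = np.exp(res.x)
    estimates = {key: float(v) for key, v in zip(entries, values)}

    # covariance on the log scale: FSD(p) = SE(log p)
    m = res.fun.size
    dof = m - p
    s2 = 2.0 * res.cost / dof if dof > 0 else np.nan
    fsd: dict[tuple[str, tuple[str, ...]], float] = {}
    singular: set[tuple[str, tuple[str, ...]]] = set()
    J = res.jac
    U, s, Vt = np.linalg.svd(J, full_matrices=False)
    # J comes from forward differences, so directions below sqrt(eps) of the
    # leading singular value are numerically indistinguishable from null
    tol = s.max() * max(J.shape) * np.sqrt(np.finfo(float).eps) if s.size else 0.0
    rank = int(np.sum(s > tol))
    inv_s2 = np.where(s > tol, 1.0 / np.maximum(s, tol) ** 2, 0.0)
    cov = (Vt.T * inv_s2) @ Vt * (s2 if np.isfinite(s2) else 1.0)
    null_mass = (Vt[rank:] ** 2).sum(axis=0) if rank < p else np.zeros(p)
    for k, key in enumerate(entries):
        if null_mass[k] > 1e-10:
            fsd[key] = np.inf
            singular.add(key)
        else:
            fsd[key] = float(np.sqrt(max(cov[k, k], 0.0)))

    models: dict[str, ModelSpec] = {}
    wss_plasma: dict[str, float] = {}
    wss_intake: dict[str, float] = {}
    for ds in datasets:
        params = _group_params(values, entries, sharing, ds.group)
        models[ds.group] = build_group_model(
            {name: params[name] for name in REQUIRED_PARAMETERS},
            fixed_values={k: v for k, v in params.items() if k not in REQUIRED_PARAMETERS},
        )
        f5 = _f5_curve(params, ds.times)
        r_plasma = (ds.fdp - f5) / (ds.fsd * ds.fdp)
        wss_plasma[ds.group] = float(np.sum(r_plasma**2))
        if use_intake:
            pred = _predicted_intake(params, ds.m5)
            wss_intake[ds.group] = float(((ds.u3 - pred) / (ds.intake_fsd * ds.u3)) ** 2)
        else:
            wss_intake[ds.group] = 0.0

    return FitResult(
        entries=entries,
        estimates=estimates,
        fsd=fsd,
        models=models,
        wss_plasma=wss_plasma,
        wss_intake=wss_intake,
        objective=float(2.0 * res.cost),
        n_obs=m,
        dof=dof,
        success=bool(res.success),
        message=str(res.message),
        nfev=int(res.nfev),
        singular=singular,
    )


def fsd_report(result: FitResult) -> pd.DataFrame:
    """Per-parameter estimate/FSD table; FSD > 0.5 flags poor identifiability."""
    rows = []
    for name, grs in result.entries:
        key = (name, grs)
        value = result.fsd[key]
        rows.append(
            {
                "parameter": name,
                "groups": "+".join(grs),
                "estimate": result.estimates[key],
                "fsd": value,
                "poorly_identified": bool(not np.isfinite(value) or value > FSD_FLAG_THRESHOLD),
                "singular": key in result.singular,
            }
        )
    return pd.DataFrame(rows)
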