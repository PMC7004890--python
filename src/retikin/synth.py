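"""Synthetic super-child study generator.

Emulates the sparse-sampling tracer studies the composite fitting stage is
designed for: each child receives one oral dose of labelled retinyl acetate
and contributes one or two plasma samples; samples are pooled by nominal time
and composited as geometric means of actual times and fraction of dose; the
group geometric-mean plasma retinol pool is taken over all samples.

Between-child variability acts multiplicatively (log-normal factors of stated
geometric SD) on chosen kinetic parameters; measurement error is log-normal
on the plasma tracer concentration.  Plasma volume comes from a caller-
supplied linear-in-weight model — its coefficients are required configuration
with no default, since any literal anthropometric regression is a study
choice, not a package constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fitting import CompositeDataset
from .model import ModelSpec, simulate_tracer

__all__ = [
    "ChildRecord",
    "StudyDesign",
    "pv_model",
    "generate_children",
    "composite",
    "DEFAULT_PARAMETER_GSD",
]

#: default geometric SDs of between-child parameter variation; parameters not
#: listed do not vary between children
DEFAULT_PARAMETER_GSD: dict[str, float] = {
    "L(10,6)": 1.2,
    "L(5,6)": 1.2,
    "L(5,4)": 1.2,
}

#: geometric SD of between-child plasma retinol concentration
RETINOL_CONC_GSD = 1.15


@dataclass(frozen=True)
class ChildRecord:
    """One simulated child: dose, anthropometry and per-sample measurements."""

    child_id: int
    weight_kg: float
    dose_umol: float
    plasma_volume_l: float
    times: tuple[float, ...]
    c13_retinol_umol_l: tuple[float, ...]
    total_retinol_umol_l: tuple[float, ...]

    @property
    def fdp(self) -> tuple[float, ...]:
        """Fraction of dose in plasma per sample: conc × PV / dose."""
        return tuple(
            c * self.plasma_volume_l / self.dose_umol for c in self.c13_retinol_umol_l
        )

    @property
    def pool_umol(self) -> tuple[float, ...]:
        """Plasma retinol pool per sample: total concentration × PV."""
        return tuple(c * self.plasma_volume_l for c in self.total_retinol_umol_l)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of a super-child study.

    With ``samples_per_child=2`` every child is sampled at the anchor time
    plus one further time assigned as evenly as possible across the rest of
    the schedule.  With ``samples_per_child=1`` explicit ``per_time_counts``
    (including the anchor) partition the children across times.
    """

    n_children: int
    schedule: tuple[float, ...]
    anchor: float = 4.0
    samples_per_child: int = 2
    per_time_counts: Mapping[float, int] | None = None

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("need at least one child")
        if self.anchor not in self.schedule:
            raise ValueError("anchor time must be on the schedule")
        if len(set(self.schedule)) != len(self.schedule):
            raise ValueError("schedule times must be unique")
        if any(t <= 0 for t in self.schedule):
            raise ValueError("schedule times must be > 0")
        if self.samples_per_child not in (1, 2):
            raise ValueError("each child contributes 1 or 2 samples")
        if self.samples_per_child == 1:
            if self.per_time_counts is None:
                raise ValueError("one-sample designs need explicit per_time_counts")
            counts = dict(self.per_time_counts)
            if set(counts) - set(self.schedule):
                raise ValueError("per_time_counts contains off-schedule times")
            if sum(counts.values()) != self.n_children:
                raise ValueError(
                    f"per_time_counts sum to {sum(counts.values())}, expected {self.n_children}"
                )
            object.__setattr__(self, "per_time_counts", counts)
        elif self.per_time_counts is not None:
            raise ValueError("per_time_counts applies only to one-sample designs")

    def assignments(self, rng: np.random.Generator) -> list[tuple[float, ...]]:
        """Per-child sampling times (each child's tuple is sorted)."""
        if self.samples_per_child == 1:
            slots: list[float] = []
            for t in self.schedule:
                slots.extend([t] * self.per_time_counts.get(t, 0))  # type: ignore[union-attr]
            slots = list(rng.permutation(np.array(slots)))
            return [(float(t),) for t in slots]
        others = [t for t in self.schedule if t != self.anchor]
        n = self.n_children
        base, extra = divmod(n, len(others))
        slots = []
        for i, t in enumerate(others):
            slots.extend([t] * (base + (1 if i < extra else 0)))
        slots = list(rng.permutation(np.array(slots)))
        return [tuple(sorted((self.anchor, float(t)))) for t in slots]

    def expected_counts(self) -> dict[float, int]:
        """Number of samples per nominal time implied by the design."""
        if self.samples_per_child == 1:
            return {t: self.per_time_counts.get(t, 0) for t in self.schedule}  # type: ignore[union-attr]
        others = [t for t in self.schedule if t != self.anchor]
        base, extra = divmod(self.n_children, len(others))
        counts = {t: base + (1 if i < extra else 0) for i, t in enumerate(others)}
        counts[self.anchor] = self.n_children
        return {t: counts[t] for t in self.schedule}


def pv_model(weight_kg: float, coefficients: tuple[float, float]) -> float:
    """Plasma volume (L) from body weight via PV = a + b·weight.

    Coefficients are required configuration — there is deliberately no
    default, so the anthropometric model in use is always explicit.
    """
    if coefficients is None:
        raise ValueError("plasma-volume coefficients are required configuration")
    if weight_kg <= 0:
        raise ValueError("body weight must be > 0")
    a, b = coefficients
    pv = a + b * weight_kg
    if pv <= 0:
        raise ValueError("plasma-volume model produced a nonpositive volume")
    return pv


def generate_children(
    truth: ModelSpec,
    m5: float,
    u3: float,
    design: StudyDesign,
    pv_coefficients: tuple[float, float],
    mean_weight_kg: float,
    weight_sd_kg: float,
    retinol_conc_umol_l: float,
    seed: int,
    dose_umol: float = 1.17,
    variability: Mapping[str, float] | None = None,
    noise_cv: float = 0.10,
) -> list[ChildRecord]:
    """Simulate one super-child study from a known group truth.

    Each child's kinetic parameters are the group values multiplied by
    log-normal factors with the geometric SDs in ``variability`` (default
    :data:`DEFAULT_PARAMETER_GSD`; a GSD of 1 means no variation, so group
    values are the population medians).  Plasma tracer concentration gets
    multiplicative log-normal measurement noise of CV ``noise_cv``.
    """
    del u3  # intake enters at the composite/fitting stage, not per child
    if seed is None:
        raise ValueError("a seed is required for reproducible generation")
    gsd = dict(DEFAULT_PARAMETER_GSD if variability is None else variability)
    for name, g in gsd.items():
        if g < 1.0:
            raise ValueError(f"geometric SD for {name} must be >= 1")
    rng = np.random.default_rng(seed)
    assignments = design.assignments(rng)

    children: list[ChildRecord] = []
    for cid, times in enumerate(assignments):
        perturbed = {
            name: truth.parameter(name) * float(rng.lognormal(0.0, np.log(g)))
            for name, g in gsd.items()
            if g > 1.0
        }
        child_model = truth.replace(**perturbed) if perturbed else truth
        weight = float(rng.normal(mean_weight_kg, weight_sd_kg))
        weight = max(weight, 0.2 * mean_weight_kg)  # guard against absurd draws
        pv = pv_model(weight, pv_coefficients)
        conc_retinol = retinol_conc_umol_l * float(
            rng.lognormal(0.0, np.log(RETINOL_CONC_GSD))
        )

        f5 = simulate_tracer(child_model, np.asarray(times)).fdp
        noise = (
            rng.lognormal(0.0, np.sqrt(np.log(1.0 + noise_cv**2)), size=f5.size)
            if noise_cv > 0
            else np.ones_like(f5)
        )
        fdp = f5 * noise
        c13 = fdp * dose_umol / pv

        children.append(
            ChildRecord(
                child_id=cid,
                weight_kg=weight,
                dose_umol=dose_umol,
                plasma_volume_l=pv,
                times=tuple(float(t) for t in times),
                c13_retinol_umol_l=tuple(float(c) for c in c13),
                total_retinol_umol_l=tuple(float(conc_retinol) for _ in times),
            )
        )
    return children


def composite(
    children: Sequence[ChildRecord],
    group: str,
    u3: float,
    anchor: float = 4.0,
    fsd: float = 0.05,
    anchor_fsd: float = 0.025,
    intake_fsd: float = 0.05,
    m5: float | None = None,
) -> CompositeDataset:
    """Composite per-child samples into one super-child dataset.

    Per nominal sampling time, the geometric means of the actual times and of
    FDp are taken (with identical nominal times these are the times
    themselves); the anchor time gets the tighter FSD weight.  The group
    plasma pool is the geometric mean over all samples unless ``m5`` is
    supplied explicitly.
    """
    if not children:
        raise ValueError("no children to composite")
    by_time: dict[float, list[tuple[float, float, float]]] = {}
    for child in children:
        for t, f, pool in zip(child.times, child.fdp, child.pool_umol):
            if f <= 0:
                raise ValueError("FDp must be > 0 to take geometric means")
            by_time.setdefault(t, []).append((t, f, pool))

    slots = sorted(by_time)
    times, fdp, n, weights = [], [], [], []
    all_pools: list[float] = []
    for t in slots:
        rows = by_time[t]
        times.append(float(np.exp(np.mean(np.log([r[0] for r in rows])))))
        fdp.append(float(np.exp(np.mean(np.log([r[1] for r in rows])))))
        n.append(len(rows))
        weights.append(anchor_fsd if t == anchor else fsd)
        all_pools.extend(r[2] for r in rows)

    pool = float(np.exp(np.mean(np.log(all_pools)))) if m5 is None else m5
    return CompositeDataset(
        group=group,
        times=np.array(times),
        fdp=np.array(fdp),
        n=np.array(n),
        fsd=np.array(weights),
        m5=pool,
        u3=u3,
        intake_fsd=intake_fsd,
    )
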