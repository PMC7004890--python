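"""Packaged group fixtures: fitted kinetic parameters and study constants.

Three cohorts of young children (Bangladesh, Philippines, Guatemala) ship as
named presets carrying the group fractional transfer coefficients and delay
times, the group geometric-mean plasma retinol pool M(5) and adjusted vitamin
A intake U(3), and the sparse-sampling study design used to build the
composite ("super-child") tracer dataset.  A recommended future design
(60 children, 13 times from 5 h to 42 d, anchor at 7 d) is included as
``future-design``.

The plasma-volume slopes are a synthetic calibration: they are back-solved so
that group mean body weight × plasma retinol concentration reproduces the
group plasma pool, because the literal anthropometric regression used in the
field studies is not part of this package.
"""

from __future__ import annotations

from .fitting import SharingMap
from .model import ModelSpec, build_group_model
from .synth import StudyDesign

__all__ = [
    "GROUPS",
    "GROUP_PARAMETERS",
    "GROUP_CONSTANTS",
    "group_model",
    "group_design",
    "partially_parallel_sharing",
    "PV_COEFFICIENTS",
]

GROUPS: tuple[str, ...] = ("bangladesh", "philippines", "guatemala")

#: fitted kinetic parameters per group (1/day; delays in days)
GROUP_PARAMETERS: dict[str, dict[str, float]] = {
    "bangladesh": {
        "DT(3)": 0.206,
        "L(5,4)": 2.15,
        "L(7,5)": 13.9,
        "L(5,7)": 1.59,
        "L(6,5)": 12.3,
        "L(5,6)": 0.0217,
        "L(10,6)": 0.00246,
        "L(8,5)": 1.30,
    },
    "philippines": {
        "DT(3)": 0.206,
        "L(5,4)": 1.22,
        "L(7,5)": 3.07,
        "L(5,7)": 0.340,
        "L(6,5)": 12.3,
        "L(5,6)": 0.00884,
        "L(10,6)": 0.00194,
        "L(8,5)": 2.21,
    },
    "guatemala": {
        "DT(3)": 0.206,
        "L(5,4)": 1.22,
        "L(7,5)": 3.07,
        "L(5,7)": 0.340,
        "L(6,5)": 12.3,
        "L(5,6)": 0.00884,
        "L(10,6)": 0.00108,
        "L(8,5)": 1.34,
    },
}

#: group study constants: plasma pool (μmol), adjusted intake (μmol RAE/d),
#: plasma retinol concentration (μmol/L), mean body weight (kg) and the
#: oral tracer dose (μmol)
GROUP_CONSTANTS: dict[str, dict[str, float]] = {
    "bangladesh": {
        "m5": 0.382,
        "u3": 1.22,
        "retinol_conc": 0.785,
        "mean_weight_kg": 8.4,
        "weight_sd_kg": 1.3,
        "dose_umol": 1.17,
    },
    "philippines": {
        "m5": 0.462,
        "u3": 2.56,
        "retinol_conc": 1.02,
        "mean_weight_kg": 8.8,
        "weight_sd_kg": 1.3,
        "dose_umol": 1.17,
    },
    "guatemala": {
        "m5": 0.848,
        "u3": 2.83,
        "retinol_conc": 1.24,
        "mean_weight_kg": 15.0,
        "weight_sd_kg": 2.2,
        "dose_umol": 1.17,
    },
}

#: synthetic plasma-volume model PV = a + b·weight, back-solved per group so
#: that mean weight × retinol concentration reproduces the group plasma pool
PV_COEFFICIENTS: dict[str, tuple[float, float]] = {
    name: (0.0, c["m5"] / (c["retinol_conc"] * c["mean_weight_kg"]))
    for name, c in GROUP_CONSTANTS.items()
}

#: candidate sampling times, days (6, 9, 12 h, then 1–28 d)
STANDARD_SCHEDULE: tuple[float, ...] = (0.25, 0.375, 0.5, 1, 2, 4, 7, 11, 16, 22, 28)

#: recommended future schedule: 13 times from 5 h to 42 d, anchor at 7 d
FUTURE_SCHEDULE: tuple[float, ...] = (
    5 / 24,
    0.375,
    0.5,
    1,
    2,
    4,
    7,
    11,
    16,
    22,
    28,
    35,
    42,
)


def group_model(name: str) -> ModelSpec:
    """Validated :class:`ModelSpec` for a named group preset."""
    if name not in GROUP_PARAMETERS:
        raise KeyError(f"unknown group preset: {name!r} (choose from {GROUPS})")
    return build_group_model(GROUP_PARAMETERS[name])


def group_design(name: str) -> StudyDesign:
    """Sampling design preset for a group (or the recommended future design).

    The Philippine and Guatemalan studies sampled every child at 4 d plus one
    randomly assigned extra time.  The Bangladeshi study collected one sample
    per child: 40 at 4 d and 5–6 at each remaining time; the cohort's 87
    children (4 of whom were sampled twice late) are emulated here as 91
    single-sample children.
    """
    if name == "bangladesh":
        counts = {t: 5 for t in STANDARD_SCHEDULE}
        counts[4] = 40
        counts[22] = 6
        return StudyDesign(
            n_children=91,
            schedule=STANDARD_SCHEDULE,
            anchor=4.0,
            samples_per_child=1,
            per_time_counts=counts,
        )
    if name == "philippines":
        return StudyDesign(
            n_children=120, schedule=STANDARD_SCHEDULE, anchor=4.0, samples_per_child=2
        )
    if name == "guatemala":
        return StudyDesign(
            n_children=135, schedule=STANDARD_SCHEDULE, anchor=4.0, samples_per_child=2
        )
    if name == "future-design":
        return StudyDesign(
            n_children=60, schedule=FUTURE_SCHEDULE, anchor=7.0, samples_per_child=2
        )
    raise KeyError(f"unknown design preset: {name!r}")


def partially_parallel_sharing() -> SharingMap:
    """The multi-group sharing pattern of the final combined fit.

    DT(3) and L(6,5) are shared by all groups; L(10,6) is independent in every
    group; L(5,4), L(7,5), L(5,7) and L(5,6) are independent for the
    Bangladeshi group only; the absorption split, DT(8) and the per-group
    L(8,5) are fixed.
    """
    return SharingMap(
        shared=["DT(3)", "L(6,5)"],
        independent=["L(10,6)"],
        independent_for={
            "L(5,4)": ["bangladesh"],
            "L(7,5)": ["bangladesh"],
            "L(5,7)": ["bangladesh"],
            "L(5,6)": ["bangladesh"],
        },
        fixed={
            "L(4,3)": 0.8,
            "L(0,3)": 0.2,
            "DT(8)": 75.0 / 1440.0,
            "L(10,8)": 1.0,
            "L(8,5)": {name: GROUP_PARAMETERS[name]["L(8,5)"] for name in GROUPS},
        },
    )
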