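"""Shared fixtures: the three packaged group presets and their published values."""

from __future__ import annotations

import numpy as np
import pytest

from retikin import presets

#: published steady-state results per group (masses μmol, rates μmol/d)
PUBLISHED_STEADY = {
    "bangladesh": {
        "M(4)": 0.453,
        "M(5)": 0.382,
        "M(6)": 195.0,
        "M(7)": 3.34,
        "TBS": 198.0,
        "R(5,4)": 0.974,
        "R(7,5)": 5.31,
        "R(5,7)": 5.31,
        "R(6,5)": 4.70,
        "R(5,6)": 4.23,
        "R(10,6)": 0.480,
        "R(8,5)": 0.497,
        "absorbed_retained_pct": 76.2,
        "disposal_rate": 0.976,
        "days_of_stores": 203.0,
        "system_fcr": 0.00492,
    },
    "philippines": {
        "M(4)": 1.67,
        "M(5)": 0.462,
        "M(6)": 529.0,
        "M(7)": 4.17,
        "TBS": 533.0,
        "R(5,4)": 2.04,
        "R(7,5)": 1.42,
        "R(5,7)": 1.42,
        "R(6,5)": 5.68,
        "R(5,6)": 4.68,
        "R(10,6)": 1.03,
        "R(8,5)": 1.02,
        "absorbed_retained_pct": 69.9,
        "disposal_rate": 2.05,
        "days_of_stores": 260.0,
        "system_fcr": 0.00384,
    },
    "guatemala": {
        "M(4)": 1.85,
        "M(5)": 0.848,
        "M(6)": 1054.0,
        "M(7)": 7.65,
        "TBS": 1062.0,
        "R(5,4)": 2.26,
        "R(7,5)": 2.60,
        "R(5,7)": 2.60,
        "R(6,5)": 10.4,
        "R(5,6)": 9.32,
        "R(10,6)": 1.14,
        "R(8,5)": 1.14,
        "absorbed_retained_pct": 73.6,
        "disposal_rate": 2.27,
        "days_of_stores": 467.0,
        "system_fcr": 0.00214,
    },
}

#: published transit/residence/recycling values (times in days unless noted)
PUBLISHED_DERIVED = {
    "bangladesh": {
        "t5_h": 0.873,
        "t6_d": 41.4,
        "t7_d": 0.629,
        "T55_d": 0.392,
        "T65_d": 200.0,
        "T75_d": 3.42,
        "Tsys_d": 204.0,
        "recycling_number": 9.77,
        "recycling_time_d": 20.8,
    },
    "philippines": {
        "t5_h": 1.36,
        "t6_d": 92.8,
        "t7_d": 2.94,
        "T55_d": 0.226,
        "T65_d": 258.0,
        "T75_d": 2.04,
        "Tsys_d": 260.0,
        "recycling_number": 2.97,
        "recycling_time_d": 87.5,
    },
    "guatemala": {
        "t5_h": 1.44,
        "t6_d": 101.0,
        "t7_d": 2.94,
        "T55_d": 0.374,
        "T65_d": 465.0,
        "T75_d": 3.37,
        "Tsys_d": 469.0,
        "recycling_number": 5.25,
        "recycling_time_d": 89.2,
    },
}

#: published composite RID coefficient FaS at 4 d post-dose
PUBLISHED_FAS_4D = {"bangladesh": 1.58, "philippines": 2.44, "guatemala": 2.93}


@pytest.fixture(params=presets.GROUPS)
def group(request) -> str:
    return request.param


@pytest.fixture
def group_model(group):
    return presets.group_model(group)


@pytest.fixture
def group_constants(group):
    return presets.GROUP_CONSTANTS[group]


def make_study(group: str, seed: int, noise_cv: float = 0.05, variability=None):
    """Generate one synthetic super-child study for a preset group."""
    from retikin import composite, generate_children

    truth = presets.group_model(group)
    c = presets.GROUP_CONSTANTS[group]
    design = presets.group_design(group)
    children = generate_children(
        truth,
        m5=c["m5"],
        u3=c["u3"],
        design=design,
        pv_coefficients=presets.PV_COEFFICIENTS[group],
        mean_weight_kg=c["mean_weight_kg"],
        weight_sd_kg=c["weight_sd_kg"],
        retinol_conc_umol_l=c["retinol_conc"],
        seed=seed,
        dose_umol=c["dose_umol"],
        noise_cv=noise_cv,
        variability=variability,
    )
    return children, design, c


def single_group_sharing(group: str):
    """All group parameters adjustable (single-group fit); L(8,5) fixed."""
    from retikin import SharingMap

    return SharingMap(
        independent=["DT(3)", "L(5,4)", "L(7,5)", "L(5,7)", "L(6,5)", "L(5,6)", "L(10,6)"],
        fixed={
            "L(4,3)": 0.8,
            "L(0,3)": 0.2,
            "DT(8)": 75.0 / 1440.0,
            "L(10,8)": 1.0,
            "L(8,5)": {group: presets.GROUP_PARAMETERS[group]["L(8,5)"]},
        },
    )


def random_model(rng: np.random.Generator):
    """A random positive-rate model with irreversible loss (for property tests)."""
    from retikin import build_group_model

    params = {
        "DT(3)": rng.uniform(0.05, 0.5),
        "L(5,4)": rng.uniform(0.2, 5.0),
        "L(7,5)": rng.uniform(0.5, 20.0),
        "L(5,7)": rng.uniform(0.1, 5.0),
        "L(6,5)": rng.uniform(1.0, 20.0),
        "L(5,6)": rng.uniform(0.001, 0.1),
        "L(10,6)": rng.uniform(0.0005, 0.05),
        "L(8,5)": rng.uniform(0.2, 5.0),
    }
    return build_group_model(params)
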