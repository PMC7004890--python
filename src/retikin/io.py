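"""Readers and writers for the pipeline's delimited-text artifacts.

Conventions: comma-separated UTF-8 with a mandatory header row, '.' decimal
separator, and '#'-prefixed comment lines carrying provenance (package
version, seed, config hash).  Times are serialized in days; floats are
written with 12 significant digits so every writer/reader pair round-trips
losslessly at that precision.
"""

from __future__ import annotations

import configparser
import hashlib
import io as _io
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .derived import DerivedKinetics
from .fitting import CompositeDataset, FitResult, SharingMap, fsd_report
from .model import ModelSpec, TracerCurve, build_group_model
from .rid import RIDCoefficients
from .steady import TraceeSolution
from .synth import ChildRecord, StudyDesign

__all__ = [
    "config_hash",
    "provenance_lines",
    "write_model",
    "read_model",
    "write_curve",
    "read_curve",
    "write_datasets",
    "read_datasets",
    "write_children",
    "read_children",
    "write_sharing",
    "read_sharing",
    "write_design",
    "read_design",
    "write_steady_report",
    "write_derived_report",
    "write_rid_coefficients",
    "write_fit_report",
]

FLOAT_FMT = "%.12g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def config_hash(config: Mapping | Sequence | str | float | None) -> str:
    """Deterministic short hash of a JSON-serializable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def provenance_lines(seed: int | None = None, config: Mapping | None = None) -> list[str]:
    lines = [f"# retikin {__version__}"]
    if seed is not None:
        lines.append(f"# seed = {seed}")
    if config is not None:
        lines.append(f"# config_sha256 = {config_hash(config)}")
    return lines


def _write_frame(
    frame: pd.DataFrame, path: Path | str, seed: int | None, config: Mapping | None
) -> None:
    buf = _io.StringIO()
    for line in provenance_lines(seed, config):
        buf.write(line + "\n")
    frame.to_csv(buf, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _read_frame(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# -- model definition files ------------------------------------------------


def write_model(model: ModelSpec, path: Path | str, seed: int | None = None) -> None:
    """Write a model as key-value sections [rates] (1/day), [delays] (day), [status]."""
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keep parameter-name case
    cp["rates"] = {f"L({i},{j})": _fmt(v) for (i, j), v in sorted(model.rates.items())}
    cp["delays"] = {f"DT({i})": _fmt(v) for i, v in sorted(model.delays.items())}
    cp["status"] = dict(sorted(model.status.items()))
    buf = _io.StringIO()
    for line in provenance_lines(seed, None):
        buf.write(line + "\n")
    cp.write(buf)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_model(path: Path | str) -> ModelSpec:
    cp = configparser.ConfigParser()
    cp.optionxform = str
    text = Path(path).read_text(encoding="utf-8")
    try:
        cp.read_string(text, source=str(path))
    except configparser.Error as exc:
        raise ValueError(f"malformed model file {path}: {exc}") from exc
    if "rates" not in cp or "delays" not in cp:
        raise ValueError(f"model file {path} needs [rates] and [delays] sections")
    named = {k: float(v) for k, v in cp["rates"].items()}
    named.update({k: float(v) for k, v in cp["delays"].items()})
    group_parameters = {k: v for k, v in named.items()}
    model = build_group_model(group_parameters)
    if "status" in cp:
        model = ModelSpec(model.rates, model.delays, dict(cp["status"]))
    return model


# -- tracer curves -----------------------------------------------------------


def write_curve(
    curve: TracerCurve, path: Path | str, seed: int | None = None, config: Mapping | None = None
) -> None:
    _write_frame(curve.states, path, seed, config)


def read_curve(path: Path | str) -> pd.DataFrame:
    return _read_frame(path)


# -- composite datasets ------------------------------------------------------


def write_datasets(
    datasets: Sequence[CompositeDataset],
    data_path: Path | str,
    config_path: Path | str,
    seed: int | None = None,
) -> None:
    """Write observations to CSV and group constants to a YAML sidecar."""
    rows = []
    for ds in datasets:
        for t, f, n, w in zip(ds.times, ds.fdp, ds.n, ds.fsd):
            rows.append(
                {
                    "group": ds.group,
                    "time_d": t,
                    "fdp_geomean": f,
                    "n_children": int(n),
                    "fsd": w,
                }
            )
    _write_frame(pd.DataFrame(rows), data_path, seed, None)
    constants = {
        ds.group: {"m5": float(ds.m5), "u3": float(ds.u3), "intake_fsd": float(ds.intake_fsd)}
        for ds in datasets
    }
    Path(config_path).write_text(
        "".join(line + "\n" for line in provenance_lines(seed, constants))
        + yaml.safe_dump(constants, sort_keys=True),
        encoding="utf-8",
    )


def read_datasets(data_path: Path | str, config_path: Path | str) -> list[CompositeDataset]:
    frame = _read_frame(data_path)
    constants = yaml.safe_load(Path(config_path).read_text(encoding="utf-8"))
    datasets = []
    for group, sub in frame.groupby("group", sort=False):
        if group not in constants:
            raise ValueError(f"group {group!r} missing from dataset config {config_path}")
        c = constants[group]
        sub = sub.sort_values("time_d")
        datasets.append(
            CompositeDataset(
                group=str(group),
                times=sub["time_d"].to_numpy(),
                fdp=sub["fdp_geomean"].to_numpy(),
                n=sub["n_children"].to_numpy(),
                fsd=sub["fsd"].to_numpy(),
                m5=float(c["m5"]),
                u3=float(c["u3"]),
                intake_fsd=float(c.get("intake_fsd", 0.05)),
            )
        )
    return datasets


# -- child-level synthetic data ----------------------------------------------


def write_children(
    children: Sequence[ChildRecord],
    path: Path | str,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    rows = []
    for child in children:
        for t, c13, tot, f, pool in zip(
            child.times, child.c13_retinol_umol_l, child.total_retinol_umol_l,
            child.fdp, child.pool_umol,
        ):
            rows.append(
                {
                    "child_id": child.child_id,
                    "weight_kg": child.weight_kg,
                    "dose_umol": child.dose_umol,
                    "time_d": t,
                    "c13_retinol_umol_L": c13,
                    "total_retinol_umol_L": tot,
                    "plasma_volume_L": child.plasma_volume_l,
                    "fdp": f,
                    "pool_umol": pool,
                }
            )
    _write_frame(pd.DataFrame(rows), path, seed, config)


def read_children(path: Path | str) -> list[ChildRecord]:
    frame = _read_frame(path)
    children = []
    for cid, sub in frame.groupby("child_id", sort=True):
        sub = sub.sort_values("time_d")
        children.append(
            ChildRecord(
                child_id=int(cid),
                weight_kg=float(sub["weight_kg"].iloc[0]),
                dose_umol=float(sub["dose_umol"].iloc[0]),
                plasma_volume_l=float(sub["plasma_volume_L"].iloc[0]),
                times=tuple(sub["time_d"]),
                c13_retinol_umol_l=tuple(sub["c13_retinol_umol_L"]),
                total_retinol_umol_l=tuple(sub["total_retinol_umol_L"]),
            )
        )
    return children


# -- sharing maps and designs -------------------------------------------------


def write_sharing(sharing: SharingMap, path: Path | str) -> None:
    payload = {
        "shared": list(sharing.shared),
        "independent": list(sharing.independent),
        "independent_for": {k: list(v) for k, v in sharing.independent_for.items()},
        "fixed": sharing.fixed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")


def read_sharing(path: Path | str) -> SharingMap:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return SharingMap(
        shared=list(payload.get("shared", [])),
        independent=list(payload.get("independent", [])),
        independent_for={k: list(v) for k, v in payload.get("independent_for", {}).items()},
        fixed=payload.get("fixed", {}),
    )


def write_design(design: StudyDesign, path: Path | str) -> None:
    payload = {
        "n_children": design.n_children,
        "schedule": [float(t) for t in design.schedule],
        "anchor": float(design.anchor),
        "samples_per_child": design.samples_per_child,
        "per_time_counts": (
            {float(k): int(v) for k, v in design.per_time_counts.items()}
            if design.per_time_counts is not None
            else None
        ),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")


def read_design(path: Path | str) -> StudyDesign:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    counts = payload.get("per_time_counts")
    return StudyDesign(
        n_children=int(payload["n_children"]),
        schedule=tuple(float(t) for t in payload["schedule"]),
        anchor=float(payload.get("anchor", 4.0)),
        samples_per_child=int(payload.get("samples_per_child", 2)),
        per_time_counts={float(k): int(v) for k, v in counts.items()} if counts else None,
    )


# -- reports ------------------------------------------------------------------


def write_steady_report(
    solution: TraceeSolution,
    path: Path | str,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Steady-state report: masses, transfer rates and stores statistics."""
    rows = [("M(4)", solution.mass(4), "umol"), ("M(5)", solution.mass(5), "umol"),
            ("M(6)", solution.mass(6), "umol"), ("M(7)", solution.mass(7), "umol"),
            ("TBS", solution.tbs, "umol"), ("U(3)", solution.intake_u3, "umol/d")]
    for (i, j) in ((5, 4), (7, 5), (5, 7), (6, 5), (5, 6), (10, 6), (8, 5)):
        rows.append((f"R({i},{j})", solution.rate(i, j), "umol/d"))
    rows += [
        ("Absorbed and retained", solution.percent_absorbed_retained, "%"),
        ("Disposal rate", solution.disposal_rate, "umol/d"),
        ("Days of stores", solution.days_of_stores, "d"),
        ("System fractional catabolic rate", solution.system_fcr, "1/d"),
        ("Predicted intake", solution.predicted_intake, "umol/d"),
    ]
    frame = pd.DataFrame(rows, columns=["parameter", "value", "units"])
    _write_frame(frame, path, seed, config)


def write_derived_report(
    kinetics: DerivedKinetics,
    path: Path | str,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Transit/residence times and recycling report; plasma transit also in hours."""
    rows = [
        ("t(5)", kinetics.transit[5], "d"),
        ("t(5)", kinetics.plasma_transit_hours, "h"),
        ("t(6)", kinetics.transit[6], "d"),
        ("t(7)", kinetics.transit[7], "d"),
        ("T(5,5)", kinetics.residence[5], "d"),
        ("T(6,5)", kinetics.residence[6], "d"),
        ("T(7,5)", kinetics.residence[7], "d"),
        ("T(SYS)", kinetics.system_residence, "d"),
        ("Recycling number", kinetics.recycling_number, ""),
        ("Recycling time", kinetics.recycling_time, "d"),
    ]
    frame = pd.DataFrame(rows, columns=["parameter", "value", "units"])
    _write_frame(frame, path, seed, config)


def write_rid_coefficients(
    coefficients: RIDCoefficients,
    path: Path | str,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    frame = pd.DataFrame(
        {
            "time_d": coefficients.times,
            "Fa": coefficients.fa,
            "S": coefficients.s,
            "FaS": coefficients.fas,
        }
    )
    _write_frame(frame, path, seed, config)


def write_fit_report(
    result: FitResult,
    path: Path | str,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Fit report: estimates with FSDs, then per-group weighted sums of squares."""
    report = fsd_report(result)
    lines = provenance_lines(seed, config)
    lines.append(f"# converged = {result.success}")
    lines.append(f"# message = {result.message}")
    lines.append(f"# objective = {_fmt(result.objective)}")
    lines.append(f"# n_obs = {result.n_obs}, dof = {result.dof}, nfev = {result.nfev}")
    for group in sorted(result.wss_plasma):
        lines.append(
            f"# wss_plasma[{group}] = {_fmt(result.wss_plasma[group])}, "
            f"wss_intake[{group}] = {_fmt(result.wss_intake[group])}"
        )
    buf = _io.StringIO()
    buf.write("".join(line + "\n" for line in lines))
    report.to_csv(buf, index=False, float_format=FLOAT_FMT, lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
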