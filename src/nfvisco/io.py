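"""CSV/JSON/YAML interchange between pipeline stages.

Series go to two-column CSV with a header row; scalar metadata
(hold strain, nominal rate, label) rides along as ``# key: value``
comment lines so every stage is independently runnable from files.
JSON artifacts are written with sorted keys so identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError
from .models import (
    GroupStressSeries,
    RelaxationTrace,
    StrainSeries,
    StressStrainCurve,
)


def _write_csv(path, df: pd.DataFrame, meta: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def _read_csv(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return df, meta


def write_trace_csv(trace: RelaxationTrace, path) -> None:
    _write_csv(
        path,
        pd.DataFrame({"time_ps": trace.time, "modulus_GPa": trace.modulus}),
        {"hold_strain": trace.hold_strain},
    )


def read_trace_csv(path) -> RelaxationTrace:
    df, meta = _read_csv(path)
    for col in ("time_ps", "modulus_GPa"):
        if col not in df.columns:
            raise FormatError(f"trace CSV is missing column {col!r}")
    return RelaxationTrace(
        time=df["time_ps"].to_numpy(),
        modulus=df["modulus_GPa"].to_numpy(),
        hold_strain=float(meta.get("hold_strain", 1.0)),
    )


def write_curve_csv(curve: StressStrainCurve, path) -> None:
    _write_csv(
        path,
        pd.DataFrame({"strain": curve.strain, "stress_GPa": curve.stress}),
        {"strain_rate_per_s": curve.strain_rate, "label": curve.label},
    )


def read_curve_csv(path) -> StressStrainCurve:
    df, meta = _read_csv(path)
    for col in ("strain", "stress_GPa"):
        if col not in df.columns:
            raise FormatError(f"curve CSV is missing column {col!r}")
    return StressStrainCurve(
        strain=df["strain"].to_numpy(),
        stress=df["stress_GPa"].to_numpy(),
        strain_rate=float(meta.get("strain_rate_per_s", 0.0)),
        label=meta.get("label", "unknown"),
    )


def write_stress_series_csv(series: GroupStressSeries, path) -> None:
    df = pd.DataFrame(
        series.stress_tensor,
        columns=[f"stress_{c}_GPa" for c in ("xx", "yy", "zz", "xy", "xz", "yz")],
    )
    df.insert(0, "time_ps", series.time)
    df["axial_stress_GPa"] = series.axial_stress
    _write_csv(path, df, {})


def write_strain_series_csv(series: StrainSeries, path) -> None:
    _write_csv(path, pd.DataFrame({"time_ps": series.time, "strain": series.strain}), {})


def dump_json(obj: dict, path) -> None:
    """Deterministic JSON: sorted keys, fixed layout, trailing newline."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"config {path} must be a mapping")
    return data
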