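"""CSV/JSON round-tripping for the pipeline's tables and results.

All tables are plain RFC-4180 CSV with a "." decimal separator and UTF-8
encoding; fit results are JSON.  Column layouts:

* mass time series:  ``sample_code,medium,time_h,mass_mg``
* sorption cycle:    ``branch,rh_percent,uptake_percent`` (branch up/down)
* diameter samples:  ``sample_code,stage,diameter_nm``
* morphology field:  ``omega,tau,value`` (long format)
* generic series:    ``tau,value``
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .degradation import FiberSample, MassTimeSeries, SorptionCycle, CANONICAL_CODES
from .fitting import LogLinearFit
from .morphometry import DiameterSample, Stage
from .scale_model import ScaleField

__all__ = [
    "write_mass_series",
    "read_mass_series",
    "write_sorption_cycle",
    "read_sorption_cycle",
    "write_diameters",
    "read_diameters",
    "write_field",
    "read_field",
    "write_series",
    "read_series",
    "write_fit",
    "read_fit",
]

MASS_COLUMNS = ["sample_code", "medium", "time_h", "mass_mg"]
SORPTION_COLUMNS = ["branch", "rh_percent", "uptake_percent"]
DIAMETER_COLUMNS = ["sample_code", "stage", "diameter_nm"]
FIELD_COLUMNS = ["omega", "tau", "value"]
SERIES_COLUMNS = ["tau", "value"]


def _check_header(df: pd.DataFrame, expected: list[str], path) -> None:
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: malformed CSV header {list(df.columns)}; expected {expected}"
        )


def write_mass_series(series: MassTimeSeries | list[MassTimeSeries], path) -> None:
    if isinstance(series, MassTimeSeries):
        series = [series]
    rows = [
        (s.sample.code, s.medium, t, m)
        for s in series
        for t, m in s.points
    ]
    pd.DataFrame(rows, columns=MASS_COLUMNS).to_csv(path, index=False)


def read_mass_series(
    path, *, w0: float | None = None, w0_from_first: bool = False
) -> list[MassTimeSeries]:
    """Read one series per (sample_code, medium) group.

    ``w0`` sets the initial dry mass explicitly; ``w0_from_first`` takes it
    from each group's first mass.  Exactly one must be given.  Replicate
    rows at identical times are averaged.
    """
    if (w0 is None) == (not w0_from_first):
        raise ValueError("give exactly one of w0 / w0_from_first")
    df = pd.read_csv(path)
    _check_header(df, MASS_COLUMNS, path)
    out: list[MassTimeSeries] = []
    for (code, medium), grp in df.groupby(["sample_code", "medium"], sort=False):
        grp = grp.groupby("time_h", as_index=False)["mass_mg"].mean().sort_values("time_h")
        points = list(zip(grp["time_h"].tolist(), grp["mass_mg"].tolist()))
        if code in CANONICAL_CODES:
            sample = FiberSample.from_code(str(code))
        else:
            sample = FiberSample(code=str(code), q_fraction=0.0)
        start = points[0][1] if w0_from_first else w0
        out.append(
            MassTimeSeries(sample=sample, medium=str(medium), points=points, w0=float(start))
        )
    return out


def write_sorption_cycle(cycle: SorptionCycle, path) -> None:
    rows = [("up", rh, u) for rh, u in cycle.branch_up]
    rows += [("down", rh, u) for rh, u in cycle.branch_down]
    pd.DataFrame(rows, columns=SORPTION_COLUMNS).to_csv(path, index=False)


def read_sorption_cycle(path) -> SorptionCycle:
    df = pd.read_csv(path)
    _check_header(df, SORPTION_COLUMNS, path)
    up = df[df["branch"] == "up"]
    down = df[df["branch"] == "down"]
    return SorptionCycle(
        branch_up=list(zip(up["rh_percent"], up["uptake_percent"])),
        branch_down=list(zip(down["rh_percent"], down["uptake_percent"])),
    )


def write_diameters(samples: list[DiameterSample], path) -> None:
    rows = [
        (s.sample_code, s.stage.value, d)
        for s in samples
        for d in s.diameters_nm
    ]
    pd.DataFrame(rows, columns=DIAMETER_COLUMNS).to_csv(path, index=False)


def read_diameters(path) -> list[DiameterSample]:
    df = pd.read_csv(path)
    _check_header(df, DIAMETER_COLUMNS, path)
    out = []
    for (code, stage), grp in df.groupby(["sample_code", "stage"], sort=False):
        out.append(
            DiameterSample(str(code), Stage(stage), grp["diameter_nm"].to_numpy(float))
        )
    return out


def write_field(fld: ScaleField, path) -> None:
    om, tau = np.meshgrid(fld.omega_axis, fld.tau_axis, indexing="ij")
    pd.DataFrame(
        {"omega": om.ravel(), "tau": tau.ravel(), "value": fld.values.ravel()}
    ).to_csv(path, index=False)


def read_field(path) -> ScaleField:
    df = pd.read_csv(path)
    _check_header(df, FIELD_COLUMNS, path)
    omega_axis = np.unique(df["omega"].to_numpy(float))
    tau_axis = np.unique(df["tau"].to_numpy(float))
    piv = df.pivot(index="omega", columns="tau", values="value")
    return ScaleField(
        omega_axis=omega_axis,
        tau_axis=tau_axis,
        values=piv.to_numpy(float),
    )


def write_series(tau: np.ndarray, values: np.ndarray, path) -> None:
    pd.DataFrame({"tau": tau, "value": values}).to_csv(path, index=False)


def read_series(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    _check_header(df, SERIES_COLUMNS, path)
    return df["tau"].to_numpy(float), df["value"].to_numpy(float)


def write_fit(fit: LogLinearFit, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(fit), indent=2) + "\n")


def read_fit(path) -> LogLinearFit:
    return LogLinearFit(**json.loads(Path(path).read_text()))
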