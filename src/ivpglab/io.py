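"""Velocity-map and cohort-table containers and their on-disk formats.

A :class:`VelocityMap` holds a color-M-mode style spatiotemporal velocity
field v(s, t) along the left-ventricular long axis.  Conventions:

* ``s = 0`` at the mitral annulus, increasing toward the apex (row index);
* velocity is positive toward the apex, so trans-mitral inflow during
  diastolic filling is positive — this makes the early-filling base-to-apex
  pressure difference positive, matching the sign of reported gradients;
* time is a 0-based sample index times ``dt``; cardiac-cycle boundaries are
  stored explicitly in ``cycle_starts`` rather than re-detected downstream.

On disk a map is a dense CSV matrix (``<stem>.ivm.csv``, rows = space,
columns = time) plus a JSON sidecar (``<stem>.ivm.json``) carrying the grid
geometry and a ``format_version`` field.  A cohort is a plain CSV with the
documented column set (velocities in m/s, tissue velocities in cm/s, HR in
bpm, pressures in mmHg, gradients in mmHg/cm).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

FORMAT_VERSION = "1"

#: columns of a cohort CSV that must be present and finite for the
#: statistical stage; A-wave columns may be missing (merged inflow).
COHORT_REQUIRED_COLUMNS = (
    "animal_id",
    "group",
    "pattern",
    "pattern_code",
    "hr_bpm",
    "e_m_s",
    "eprime_ivs_cm_s",
    "eprime_lvfw_cm_s",
    "lvidd_cm",
    "ivsd_cm",
    "lvfwd_cm",
    "sap_mmhg",
)

#: optional columns (absent values allowed / appended by later stages).
COHORT_OPTIONAL_COLUMNS = (
    "a_m_s",
    "e_over_a",
    "aprime_ivs_cm_s",
    "aprime_lvfw_cm_s",
    "lvids_cm",
    "dap_mmhg",
    "map_mmhg",
    "lvm_g",
    "e_over_eprime",
    "lvedp_mmhg",
    "pre_a_lvdp_mmhg",
    "total_ivpg_mmhg_cm",
    "basal_ivpg_mmhg_cm",
    "mid_apical_ivpg_mmhg_cm",
)

VALID_GROUPS = ("Sham", "HTN-CM")


class SchemaError(ValueError):
    """A file or table violates the documented schema."""


@dataclass
class VelocityMap:
    """Spatiotemporal inflow-velocity grid with geometry/timing metadata.

    Parameters
    ----------
    values
        2-D array, shape ``(n_space, n_time)``, velocity in m/s.
    ds
        Spatial step in cm.
    dt
        Temporal step in ms.
    lv_length
        Left-ventricular long-axis length in cm spanned by the scanline.
    s_origin
        Label of the ``s = 0`` row; only ``"mitral_annulus"`` is defined.
    hr
        Heart rate in bpm, if known (metadata only).
    cycle_starts
        Time indices of cardiac-cycle onsets, strictly increasing.
    """

    values: np.ndarray
    ds: float
    dt: float
    lv_length: float
    s_origin: str = "mitral_annulus"
    hr: float | None = None
    cycle_starts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2-D (space x time) matrix")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise SchemaError(
                f"non-finite velocity at cell (row={bad[0]}, col={bad[1]})"
            )
        if self.ds <= 0 or self.dt <= 0:
            raise SchemaError("grid steps ds and dt must be positive")
        if self.lv_length <= 0:
            raise SchemaError("lv_length must be positive")
        nrows = self.values.shape[0]
        if not (self.ds * (nrows - 1) <= self.lv_length * (1 + 1e-9)
                and self.lv_length <= self.ds * nrows * (1 + 1e-9)):
            raise SchemaError(
                f"lv_length={self.lv_length} cm inconsistent with "
                f"{nrows} rows at ds={self.ds} cm"
            )
        if self.s_origin != "mitral_annulus":
            raise SchemaError(f"unknown s_origin {self.s_origin!r}")
        cs = list(self.cycle_starts)
        if any(b <= a for a, b in zip(cs, cs[1:])):
            raise SchemaError("cycle_starts must be strictly increasing")
        if cs and (cs[0] < 0 or cs[-1] >= self.values.shape[1]):
            raise SchemaError("cycle_starts out of time range")
        self.cycle_starts = [int(c) for c in cs]

    @property
    def n_space(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def s_cm(self) -> np.ndarray:
        """Positions of the rows along the scanline, in cm."""
        return np.arange(self.n_space) * self.ds

    @property
    def t_ms(self) -> np.ndarray:
        """Sample times, in ms."""
        return np.arange(self.n_time) * self.dt

    def base_trace(self) -> np.ndarray:
        """Velocity time series at the mitral annulus (s = 0)."""
        return self.values[0]


# ---------------------------------------------------------------------------
# velocity-map files

_SIDECAR_REQUIRED = ("format_version", "ds", "dt", "lv_length", "s_origin")
_SIDECAR_OPTIONAL = ("hr", "cycle_starts")


def _map_paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    name = p.name
    if name.endswith(".ivm.csv"):
        stem = name[: -len(".ivm.csv")]
    elif name.endswith(".ivm.json"):
        stem = name[: -len(".ivm.json")]
    else:
        stem = name
    return p.with_name(stem + ".ivm.csv"), p.with_name(stem + ".ivm.json")


def write_velocity_map(vmap: VelocityMap, path: str | Path) -> Path:
    """Write ``<stem>.ivm.csv`` + ``<stem>.ivm.json``; returns the CSV path.

    Values are written with 17 significant digits so the write→read round
    trip reproduces every float bit-exactly.
    """
    csv_path, json_path = _map_paths(path)
    np.savetxt(csv_path, vmap.values, delimiter=",", fmt="%.17g")
    meta = {
        "format_version": FORMAT_VERSION,
        "ds": vmap.ds,
        "dt": vmap.dt,
        "lv_length": vmap.lv_length,
        "s_origin": vmap.s_origin,
        "hr": vmap.hr,
        "cycle_starts": vmap.cycle_starts,
    }
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path


def read_velocity_map(path: str | Path) -> VelocityMap:
    """Read a velocity map written by :func:`write_velocity_map`."""
    csv_path, json_path = _map_paths(path)
    if not json_path.exists():
        raise SchemaError(f"sidecar not found: {json_path}")
    try:
        meta = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"sidecar {json_path} is not valid JSON: {exc}") from exc
    for key in _SIDECAR_REQUIRED:
        if key not in meta:
            raise SchemaError(f"sidecar missing required key {key!r}")
    extra = set(meta) - set(_SIDECAR_REQUIRED) - set(_SIDECAR_OPTIONAL)
    if extra:
        raise SchemaError(f"sidecar has unknown keys {sorted(extra)!r}")
    if str(meta["format_version"]) != FORMAT_VERSION:
        raise SchemaError(
            f"unknown format_version {meta['format_version']!r} "
            f"(supported: {FORMAT_VERSION!r})"
        )
    rows: list[list[float]] = []
    with open(csv_path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                row = [float(x) for x in line.split(",")]
            except ValueError as exc:
                raise SchemaError(f"bad numeric cell on line {lineno}: {exc}") from exc
            rows.append(row)
    if not rows:
        raise SchemaError(f"empty matrix in {csv_path}")
    width = len(rows[0])
    for lineno, row in enumerate(rows):
        if len(row) != width:
            raise SchemaError(
                f"non-rectangular matrix: line {lineno} has {len(row)} "
                f"cells, expected {width}"
            )
        for j, x in enumerate(row):
            if not math.isfinite(x):
                raise SchemaError(f"NaN/inf cell at (row={lineno}, col={j})")
    return VelocityMap(
        values=np.array(rows, dtype=float),
        ds=float(meta["ds"]),
        dt=float(meta["dt"]),
        lv_length=float(meta["lv_length"]),
        s_origin=str(meta["s_origin"]),
        hr=None if meta.get("hr") is None else float(meta["hr"]),
        cycle_starts=list(meta.get("cycle_starts") or []),
    )


# ---------------------------------------------------------------------------
# cohort tables


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table in place and return it.

    Checks the documented schema: required columns present and non-missing,
    pattern codes in {1, 2, 3}, known group labels, positive heart rates.
    """
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort missing required columns {missing!r}")
    for col in COHORT_REQUIRED_COLUMNS:
        if table[col].isna().any():
            idx = table.index[table[col].isna()][0]
            raise SchemaError(f"missing value in required column {col!r} (row {idx})")
    codes = set(int(c) for c in table["pattern_code"])
    if not codes <= {1, 2, 3}:
        raise SchemaError(
            f"unknown pattern code(s) {sorted(codes - {1, 2, 3})!r}; must be 1, 2 or 3"
        )
    groups = set(table["group"])
    if not groups <= set(VALID_GROUPS):
        raise SchemaError(f"unknown group label(s) {sorted(groups - set(VALID_GROUPS))!r}")
    if (table["hr_bpm"] <= 0).any():
        raise SchemaError("non-positive heart rate in cohort")
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated cohort table as CSV (round-trip-exact floats)."""
    validate_cohort(table)
    path = Path(path)
    table.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    table = pd.read_csv(path, float_precision="round_trip")
    return validate_cohort(table)


def cohort_from_rows(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble per-animal row dicts into a validated cohort table."""
    return validate_cohort(pd.DataFrame(list(rows)))
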