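"""Derived echocardiographic indices.

Four standard indices are computed from per-animal measurements:

* left-ventricular mass by the cube formula from M-mode dimensions,
  ``LVM = 0.8 * 1.04 * [(LVIDd + IVSd + LVFWd)^3 - LVIDd^3] + 0.6``
  (dimensions in cm, mass in g);
* E/E' — trans-mitral E velocity over the mitral-annular early diastolic
  tissue velocity, averaged over the septal (IVS) and free-wall (LVFW)
  sampling sites, with E converted m/s -> cm/s so the ratio is
  dimensionless;
* LV end-diastolic pressure estimated by the affine regression
  ``LVEDP = 17.1 + 0.19 * E/E'`` (mmHg);
* pre-A-wave LV diastolic pressure, ``Pre-A LVDP = 6.97 + 0.3 * E/E'``.

When the inflow pattern is fused the A wave cannot be measured, so A and
E/A are recorded as absent (NaN) rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LVEDP_INTERCEPT = 17.1
LVEDP_SLOPE = 0.19
PRE_A_INTERCEPT = 6.97
PRE_A_SLOPE = 0.3

HR_BOUNDS_BPM = (100.0, 600.0)  # physiologic validation bound for rats


@dataclass
class EchoRecord:
    """Per-animal measured quantities (units in field names where they vary).

    Velocities: E/A in m/s, tissue velocities in cm/s; dimensions in cm;
    pressures in mmHg.  ``a`` and the late tissue velocities may be NaN
    when the inflow is merged.
    """

    e: float
    eprime_ivs: float
    eprime_lvfw: float
    hr: float
    lvidd: float
    ivsd: float
    lvfwd: float
    group: str
    a: float = float("nan")
    aprime_ivs: float = float("nan")
    aprime_lvfw: float = float("nan")
    lvids: float = float("nan")
    sap: float = float("nan")
    dap: float = float("nan")
    map_: float = float("nan")

    def validate(self, hr_bounds: tuple[float, float] = HR_BOUNDS_BPM) -> "EchoRecord":
        for name in ("e", "eprime_ivs", "eprime_lvfw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not np.isnan(self.a) and self.a < 0:
            raise ValueError("a must be non-negative")
        for name in ("lvidd", "ivsd", "lvfwd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = hr_bounds
        if not (lo < self.hr < hi):
            raise ValueError(f"hr={self.hr} bpm outside the plausible range ({lo}, {hi})")
        return self


@dataclass
class DerivedIndices:
    lvm: float                 # g
    e_over_eprime: float       # dimensionless
    lvedp: float               # mmHg
    pre_a_lvdp: float          # mmHg
    e_over_a: float            # dimensionless, NaN when A is absent


def lv_mass(lvidd: float, ivsd: float, lvfwd: float) -> float:
    """Cube-formula LV mass in g from diastolic M-mode dimensions in cm."""
    for name, x in (("lvidd", lvidd), ("ivsd", ivsd), ("lvfwd", lvfwd)):
        if x < 0 or (name == "lvidd" and x <= 0):
            raise ValueError(f"{name} must be positive")
    return 0.8 * 1.04 * ((lvidd + ivsd + lvfwd) ** 3 - lvidd**3) + 0.6


def e_over_eprime(
    e: float, eprime_ivs: float, eprime_lvfw: float, e_in_cm_s: bool = False
) -> float:
    """Mean of E/E' at the septal and free-wall annulus sites.

    ``e`` is in m/s by default and converted to cm/s to match the tissue
    velocities; pass ``e_in_cm_s=True`` if it is already in cm/s.
    """
    if eprime_ivs <= 0 or eprime_lvfw <= 0:
        raise ValueError("tissue velocities E' must be positive")
    e_cm = e if e_in_cm_s else 100.0 * e
    return 0.5 * (e_cm / eprime_ivs + e_cm / eprime_lvfw)


def lvedp(e_over_eprime_value: float) -> float:
    """Estimated LV end-diastolic pressure (mmHg) from E/E'."""
    return LVEDP_INTERCEPT + LVEDP_SLOPE * e_over_eprime_value


def pre_a_lvdp(e_over_eprime_value: float) -> float:
    """Estimated LV diastolic pressure at A-wave onset (mmHg) from E/E'."""
    return PRE_A_INTERCEPT + PRE_A_SLOPE * e_over_eprime_value


def derive_indices(record: EchoRecord) -> DerivedIndices:
    """All derived indices for one validated animal record."""
    record.validate()
    ratio = e_over_eprime(record.e, record.eprime_ivs, record.eprime_lvfw)
    e_over_a = record.e / record.a if record.a > 0 else float("nan")
    return DerivedIndices(
        lvm=lv_mass(record.lvidd, record.ivsd, record.lvfwd),
        e_over_eprime=ratio,
        lvedp=lvedp(ratio),
        pre_a_lvdp=pre_a_lvdp(ratio),
        e_over_a=e_over_a,
    )


def append_derived_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Append lvm_g / e_over_eprime / lvedp_mmhg / pre_a_lvdp_mmhg / e_over_a
    columns to a cohort table (returns a copy)."""
    out = table.copy()
    out["lvm_g"] = [
        lv_mass(r.lvidd_cm, r.ivsd_cm, r.lvfwd_cm) for r in table.itertuples()
    ]
    ratios = [
        e_over_eprime(r.e_m_s, r.eprime_ivs_cm_s, r.eprime_lvfw_cm_s)
        for r in table.itertuples()
    ]
    out["e_over_eprime"] = ratios
    out["lvedp_mmhg"] = [lvedp(x) for x in ratios]
    out["pre_a_lvdp_mmhg"] = [pre_a_lvdp(x) for x in ratios]
    if "a_m_s" in table.columns:
        a = table["a_m_s"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out["e_over_a"] = np.where(a > 0, table["e_m_s"].to_numpy() / a, np.nan)
    return out
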