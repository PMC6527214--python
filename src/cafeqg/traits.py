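"""Trait construction from raw capillary-feeder (CAFE) readings.

A two-choice CAFE vial holds five flies and four capillaries: two with
plain sucrose medium and two with drug-supplemented medium.  Consumption
is read as the drop in liquid column length (mm; 1 mm = 0.067 ul for the
capillaries used).  Evaporation is estimated from identical fly-free
control vials run in the same chamber and subtracted per capillary.

From the corrected per-vial consumption at exposures 1 and 3 we build
twelve traits per vial: consumption of each solution at each exposure,
their changes, two preference indices at each exposure, and the changes
in preference.  Preference A is the drug-minus-sucrose difference (mm);
Preference B is the same difference scaled by total intake and is
dimensionless in [-1, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "MM_PER_UL",
    "UL_PER_MM",
    "CAPILLARY_LENGTH_MM",
    "TRAIT_COLUMNS",
    "mm_to_ul",
    "correct_evaporation",
    "compute_traits",
    "line_means",
]

UL_PER_MM = 0.067  # capillary calibration: 1 mm of column = 0.067 ul
MM_PER_UL = 1.0 / UL_PER_MM
CAPILLARY_LENGTH_MM = 127.0

RAW_COLUMNS = [
    "line_id", "sex", "exposure", "solution", "vial",
    "capillary1_mm", "capillary2_mm", "is_control",
]

TRAIT_COLUMNS = [
    "drug_E1", "sucrose_E1", "drug_E3", "sucrose_E3",
    "delta_drug", "delta_sucrose",
    "pref_A_E1", "pref_A_E3", "pref_B_E1", "pref_B_E3",
    "delta_pref_A", "delta_pref_B",
]


def mm_to_ul(x):
    """Convert a capillary column drop in mm to microlitres consumed."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative length is not a valid capillary reading")
    out = UL_PER_MM * arr
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def _validate_raw(records: pd.DataFrame) -> None:
    missing = [c for c in RAW_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"raw consumption table missing columns: {missing}")
    caps = records[["capillary1_mm", "capillary2_mm"]].to_numpy(dtype=float)
    if np.any(caps < 0):
        raise ValueError("negative raw capillary readings present")
    if np.any(caps > CAPILLARY_LENGTH_MM):
        raise ValueError(f"capillary readings exceed capillary length ({CAPILLARY_LENGTH_MM} mm)")


def correct_evaporation(records: pd.DataFrame) -> pd.DataFrame:
    """Subtract fly-free control evaporation and sum the capillary pair.

    For every (exposure, solution) stratum the mean of all control
    capillary readings (both capillaries pooled) is subtracted from each
    experimental capillary; each corrected capillary is clamped at zero
    (negative intake is physically impossible) and the two same-solution
    capillaries are summed into the vial's consumption.

    Returns a corrected consumption table with one row per
    (line_id, sex, exposure, solution, vial) and a ``consumption_mm``
    column.
    """
    _validate_raw(records)
    controls = records[records["is_control"].astype(int) == 1]
    flies = records[records["is_control"].astype(int) == 0]

    strata = flies.groupby(["exposure", "solution"], observed=True).size().index
    ctrl_caps = controls.melt(
        id_vars=["exposure", "solution"],
        value_vars=["capillary1_mm", "capillary2_mm"],
        value_name="reading",
    )
    ctrl_mean = ctrl_caps.groupby(["exposure", "solution"], observed=True)["reading"].mean()
    missing = [s for s in strata if s not in ctrl_mean.index]
    if missing:
        raise ValueError(f"no evaporation-control vials for strata: {missing}")

    out = flies.copy()
    evap = ctrl_mean.reindex(
        pd.MultiIndex.from_frame(out[["exposure", "solution"]])
    ).to_numpy()
    c1 = np.clip(out["capillary1_mm"].to_numpy(dtype=float) - evap, 0.0, None)
    c2 = np.clip(out["capillary2_mm"].to_numpy(dtype=float) - evap, 0.0, None)
    out["consumption_mm"] = c1 + c2
    out = out[["line_id", "sex", "exposure", "solution", "vial", "consumption_mm"]]
    dup = out.duplicated(["line_id", "sex", "exposure", "solution", "vial"])
    if dup.any():
        raise ValueError("duplicate vial records after correction")
    return out.reset_index(drop=True)


def compute_traits(consumption: pd.DataFrame, first: int = 1, last: int = 3) -> pd.DataFrame:
    """Build the twelve per-vial traits from corrected consumption.

    Requires both solutions at exposures ``first`` and ``last`` for every
    vial.  Preference A = drug - sucrose (mm); Preference B =
    (drug - sucrose)/(drug + sucrose), recorded as missing when total
    intake is zero.  delta_* traits are last-exposure minus
    first-exposure values, so positive deltas mean increased consumption
    (or preference) at the later exposure.
    """
    wide = consumption.pivot_table(
        index=["line_id", "sex", "vial"],
        columns=["solution", "exposure"],
        values="consumption_mm",
        aggfunc="first",
        observed=True,
    )
    needed = [(sol, e) for sol in ("drug", "sucrose") for e in (first, last)]
    missing_cols = [c for c in needed if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"consumption table lacks solution/exposure cells: {missing_cols}")
    incomplete = wide[needed].isna().any(axis=1)
    if incomplete.any():
        raise ValueError(
            f"vials missing a solution or exposure: {wide.index[incomplete].tolist()[:10]}"
        )

    out = pd.DataFrame(index=wide.index)
    out["drug_E1"] = wide[("drug", first)]
    out["sucrose_E1"] = wide[("sucrose", first)]
    out["drug_E3"] = wide[("drug", last)]
    out["sucrose_E3"] = wide[("sucrose", last)]
    out["delta_drug"] = out["drug_E3"] - out["drug_E1"]
    out["delta_sucrose"] = out["sucrose_E3"] - out["sucrose_E1"]
    for e, tag in ((first, "E1"), (last, "E3")):
        drug, suc = wide[("drug", e)], wide[("sucrose", e)]
        total = drug + suc
        out[f"pref_A_{tag}"] = drug - suc
        out[f"pref_B_{tag}"] = np.where(total > 0, (drug - suc) / total.where(total > 0), np.nan)
    out["delta_pref_A"] = out["pref_A_E3"] - out["pref_A_E1"]
    out["delta_pref_B"] = out["pref_B_E3"] - out["pref_B_E1"]
    return out.reset_index()[["line_id", "sex", "vial"] + TRAIT_COLUMNS]


def line_means(traits: pd.DataFrame) -> pd.DataFrame:
    """Average per-vial traits to one row per (line, sex).

    Missing vial-level values (e.g. undefined Preference B at zero total
    intake) are excluded from that trait's mean.  A line x sex cell with
    no vials at all is an error.
    """
    trait_cols = [c for c in TRAIT_COLUMNS if c in traits.columns]
    grouped = traits.groupby(["line_id", "sex"], observed=True)
    means = grouped[trait_cols].mean()
    means["n_vials"] = grouped.size()
    if (means["n_vials"] == 0).any():
        raise ValueError("empty line x sex cell")
    return means.reset_index()
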