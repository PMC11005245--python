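"""Vessel-level oxygen physiology: Hill saturation, arteriole/venule
classification, cortical-layer binning, and per-animal / per-cohort
summaries including depth-dependent oxygen extraction (DOE).

Conventions, fixed package-wide:

* SO2 is computed per measurement from pO2 with the Hill equation, then
  averaged (never the Hill transform of a mean).
* Cortical layers are half-open, low-inclusive depth bands:
  I = [0, 100) µm, II/III = [100, 320) µm, IV = [320, 450] µm, so the
  standard measurement depths {50, 100, 200, 300, 400} µm map to
  {I, II/III, II/III, II/III, IV}.
* Penetrating vessels are classified from their day-0 (baseline) pO2 at
  50 µm subpial depth: strictly above 66 mmHg -> arteriole, otherwise
  venule; the class is frozen and propagated to later days.
* The animal is the unit of averaging: layer means, CVs and DOEs are
  computed per animal first, then averaged (unweighted) across animals.
* DOE = mean(SaO2) - mean(SvO2) per layer, deliberately NOT normalized by
  SaO2 (that normalized variant, OEF, is out of scope).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import EmptyLayerWarning, UnclassifiedVesselWarning
from .protocol import CalibrationParams

__all__ = [
    "LAYER_BOUNDS_UM",
    "ARTERIOLE_PO2_THRESHOLD_MMHG",
    "SURFACE_DEPTH_UM",
    "po2_to_so2",
    "so2_to_po2",
    "classify_vessel",
    "classify_penetrating",
    "assign_layer",
    "layer_summary",
    "compute_doe",
    "cohort_aggregate",
    "compute_deltas",
]

#: Cortical layer depth bands (µm, half-open low-inclusive; IV closed above).
LAYER_BOUNDS_UM: dict[str, tuple[float, float]] = {
    "I": (0.0, 100.0),
    "II/III": (100.0, 320.0),
    "IV": (320.0, 450.0),
}

LAYER_ORDER = ("I", "II/III", "IV")

#: Baseline surface pO2 above which a penetrating vessel is an arteriole.
ARTERIOLE_PO2_THRESHOLD_MMHG: float = 66.0

#: Subpial depth (µm) of the surface measurement used for classification.
SURFACE_DEPTH_UM: float = 50.0


def po2_to_so2(
    po2_mmhg: Union[float, np.ndarray], calib: Optional[CalibrationParams] = None
) -> Union[float, np.ndarray]:
    """Hemoglobin saturation (%) from pO2 via the Hill equation.

    SO2 = 100 * pO2^h / (pO2^h + P50^h), with h and P50 from ``calib``
    (defaults: h = 2.59, P50 = 40.2 mmHg for C57BL/6 mice).
    """
    calib = calib or CalibrationParams()
    po2 = np.asarray(po2_mmhg, dtype=float)
    if np.any(~np.isfinite(po2)) or np.any(po2 < 0):
        raise ValueError("pO2 must be finite and >= 0")
    ratio = np.power(po2 / calib.hill_p50_mmhg, calib.hill_h)
    so2 = 100.0 * ratio / (1.0 + ratio)
    return float(so2) if np.isscalar(po2_mmhg) else so2


def so2_to_po2(
    so2_pct: Union[float, np.ndarray], calib: Optional[CalibrationParams] = None
) -> Union[float, np.ndarray]:
    """Inverse Hill: pO2 = P50 * (s / (1 - s))^(1/h) with s = SO2/100."""
    calib = calib or CalibrationParams()
    so2 = np.asarray(so2_pct, dtype=float)
    if np.any(so2 < 0) or np.any(so2 >= 100):
        raise ValueError("SO2 must lie in [0, 100)")
    s = so2 / 100.0
    po2 = calib.hill_p50_mmhg * np.power(s / (1.0 - s), 1.0 / calib.hill_h)
    return float(po2) if np.isscalar(so2_pct) else po2


def classify_vessel(surface_po2_mmhg: float) -> str:
    """Arteriole/venule call from the baseline pO2 at 50 µm depth.

    Strictly above 66 mmHg -> ``"arteriole"``; at or below (ties included)
    -> ``"venule"``.
    """
    if not np.isfinite(surface_po2_mmhg):
        raise ValueError("surface pO2 must be finite")
    return (
        "arteriole"
        if surface_po2_mmhg > ARTERIOLE_PO2_THRESHOLD_MMHG
        else "venule"
    )


def assign_layer(depth_um: float) -> str:
    """Map a subpial depth (µm) to its cortical layer label."""
    if not (0.0 <= depth_um <= 450.0):
        raise ValueError(f"depth {depth_um} um outside the 0-450 um range")
    if depth_um < 100.0:
        return "I"
    if depth_um < 320.0:
        return "II/III"
    return "IV"


def _assign_layers(depth_um: pd.Series) -> pd.Series:
    out = pd.cut(
        depth_um,
        bins=[0.0, 100.0, 320.0, 450.0],
        right=False,
        labels=["I", "II/III", "IV"],
        include_lowest=True,
    ).astype(object)
    out[depth_um == 450.0] = "IV"  # close the deep edge of layer IV
    if not depth_um.between(0, 450).all() or out.isna().any():
        raise ValueError("depth outside the 0-450 um range")
    return out


def classify_penetrating(records: pd.DataFrame) -> pd.DataFrame:
    """Attach ``vessel_class`` and ``layer`` columns to a fit table.

    ``records`` needs columns vessel_id, parent_id, animal_id, day,
    depth_um, morphology ("penetrating" or "capillary"), po2_mmhg and
    (optionally) is_primary_branch.  Each penetrating parent vessel is
    classified once, from its day-0 measurement at 50 µm, and the class is
    propagated across depths and days.  Capillary-morphology points keep
    class "capillary" except primary branches of penetrating vessels
    (pre-capillary arterioles / post-capillary venules), which are marked
    "excluded" and never enter capillary pools.
    """
    df = records.copy()
    df["layer"] = _assign_layers(df["depth_um"].astype(float))
    df["vessel_class"] = pd.Series(pd.NA, index=df.index, dtype=object)

    cap = df["morphology"] == "capillary"
    df.loc[cap, "vessel_class"] = "capillary"
    if "is_primary_branch" in df.columns:
        df.loc[cap & df["is_primary_branch"].fillna(False), "vessel_class"] = (
            "excluded"
        )

    pen = df["morphology"] == "penetrating"
    base = df[
        pen & (df["day"] == 0) & (df["depth_um"] == SURFACE_DEPTH_UM)
    ]
    calls = {
        pid: classify_vessel(po2)
        for pid, po2 in zip(base["parent_id"], base["po2_mmhg"])
        if np.isfinite(po2)
    }
    pen_parents = df.loc[pen, "parent_id"]
    missing = sorted(set(pen_parents) - set(calls))
    if missing:
        warnings.warn(
            f"no day-0 surface pO2 for penetrating vessel(s) {missing}; "
            "left unclassified",
            UnclassifiedVesselWarning,
            stacklevel=2,
        )
    df.loc[pen, "vessel_class"] = pen_parents.map(calls)
    return df


def _one_summary(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if n > 1 else np.nan
    se = sd / np.sqrt(n) if n > 1 else np.nan
    if mean <= 0:
        warnings.warn(
            "CV undefined for non-positive mean", EmptyLayerWarning, stacklevel=3
        )
        cv = np.nan
    else:
        cv = sd / mean
    return {"n": n, "mean": mean, "sd": sd, "se": se, "cv": cv}


def layer_summary(
    records: pd.DataFrame,
    value_cols: Sequence[str] = ("po2_mmhg", "so2_pct"),
    by: Sequence[str] = ("cohort", "animal_id", "day", "vessel_class", "layer"),
) -> pd.DataFrame:
    """Per-group mean, sd, SE = sd/sqrt(n) and CV = sd/mean (sample sd,
    n-1 denominator) for each value column, in tidy long format.

    Rows with a missing value or missing group key are dropped per value
    column; classes marked "excluded" never contribute.
    """
    df = records[records["vessel_class"].isin(
        ["arteriole", "venule", "capillary"]
    )] if "vessel_class" in records.columns else records
    rows = []
    for col in value_cols:
        if col not in df.columns:
            continue
        sub = df.dropna(subset=[col, *by])
        for keys, grp in sub.groupby(list(by), sort=True):
            rec = dict(zip(by, keys))
            rec["variable"] = col
            rec.update(_one_summary(grp[col].to_numpy()))
            rows.append(rec)
    return pd.DataFrame(rows)


def compute_doe(
    records: pd.DataFrame,
    by: Sequence[str] = ("cohort", "animal_id", "day", "layer"),
) -> pd.DataFrame:
    """Depth-dependent oxygen extraction per group.

    For each group: SaO2 = mean SO2 over arterioles, SvO2 = mean SO2 over
    venules, DOE = SaO2 - SvO2 (%; not normalized).  Groups missing either
    class are omitted with an :class:`EmptyLayerWarning`.
    """
    sub = records.dropna(subset=["so2_pct", *by])
    rows = []
    for keys, grp in sub.groupby(list(by), sort=True):
        art = grp.loc[grp["vessel_class"] == "arteriole", "so2_pct"]
        ven = grp.loc[grp["vessel_class"] == "venule", "so2_pct"]
        if art.empty or ven.empty:
            warnings.warn(
                f"group {dict(zip(by, keys))} lacks arterioles or venules; "
                "DOE omitted",
                EmptyLayerWarning,
                stacklevel=2,
            )
            continue
        rec = dict(zip(by, keys))
        rec.update(
            sao2_pct=float(art.mean()),
            svo2_pct=float(ven.mean()),
            doe_pct=float(art.mean() - ven.mean()),
            n_arterioles=int(art.size),
            n_venules=int(ven.size),
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def cohort_aggregate(
    animal_table: pd.DataFrame,
    value_cols: Iterable[str],
    by: Sequence[str] = ("cohort", "day", "vessel_class", "layer", "variable"),
) -> pd.DataFrame:
    """Average per-animal statistics across animals (animal = unit).

    Each animal contributes one number per group regardless of its vessel
    count; the cohort SE is the between-animal SE.  ``value_cols`` names the
    per-animal columns to aggregate (e.g. ``["mean", "cv"]`` for a
    :func:`layer_summary` table, ``["doe_pct"]`` for a DOE table).
    """
    by = [c for c in by if c in animal_table.columns]
    rows = []
    for keys, grp in animal_table.groupby(by, sort=True):
        rec = dict(zip(by, keys))
        rec["n_animals"] = int(grp["animal_id"].nunique())
        for col in value_cols:
            x = grp[col].dropna().to_numpy(dtype=float)
            if x.size == 0:
                rec[f"{col}_cohort"] = np.nan
                rec[f"{col}_se"] = np.nan
                continue
            rec[f"{col}_cohort"] = float(x.mean())
            rec[f"{col}_se"] = (
                float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def compute_deltas(
    records: pd.DataFrame,
    value_col: str = "so2_pct",
    baseline_day: int = 0,
) -> dict[str, pd.DataFrame]:
    """Longitudinal change of ``value_col`` relative to baseline day.

    Measurement points are aligned by ``vessel_id`` across days, so
    Δ = value(day d) - value(day 0) is computed within vessel; vessels
    missing the baseline are dropped.  Per-vessel deltas are averaged
    within animal (per class and layer), then across animals with a
    between-animal SE.

    Returns ``{"vessel": ..., "animal": ..., "cohort": ...}`` tables.
    """
    cols = ["cohort", "animal_id", "vessel_id", "vessel_class", "layer"]
    sub = records.dropna(subset=[value_col]).copy()
    sub = sub[sub["vessel_class"].isin(["arteriole", "venule", "capillary"])]
    wide = sub.pivot_table(
        index=cols, columns="day", values=value_col, aggfunc="mean"
    )
    if baseline_day not in wide.columns:
        raise ValueError(f"no measurements on baseline day {baseline_day}")
    deltas = wide.drop(columns=[baseline_day]).sub(wide[baseline_day], axis=0)
    vessel = (
        deltas.dropna(how="all")
        .reset_index()
        .melt(id_vars=cols, var_name="day", value_name=f"delta_{value_col}")
        .dropna(subset=[f"delta_{value_col}"])
    )
    animal = (
        vessel.groupby(
            ["cohort", "animal_id", "day", "vessel_class", "layer"], sort=True
        )[f"delta_{value_col}"]
        .mean()
        .reset_index()
    )
    cohort = cohort_aggregate(
        animal,
        value_cols=[f"delta_{value_col}"],
        by=("cohort", "day", "vessel_class", "layer"),
    )
    return {"vessel": vessel, "animal": animal, "cohort": cohort}
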