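"""Gonadal indices and histology-based maturity staging for female skipjack.

GI = Gw / FL^3 * 10^4 (gonad weight g, fork length cm) is used as the
body-size-standardised maturity index so results are comparable across the
size range; GSI = Gw / Bw * 10^2 is reported alongside when body weight is
available.  The maturity phase is assigned from the most advanced group of
oocytes (MAGO), the presence of postovulatory follicles (POF) and the
relative intensity of atresia (IA, %):

==================  ==============  =====  =======
phase               MAGO            POF    IA (%)
==================  ==============  =====  =======
immature            Pn or Ca        absent  absent
developmental       Py, Sy or Ty    absent  < 50
regression          Py or Sy        absent  >= 50
spawning_capable    Sy (or GVM/Hyd) present < 50
==================  ==============  =====  =======

POF presence (or germinal-vesicle-migration / hydrated oocytes) indicates a
recently or imminently spawning ovary and takes precedence; absent IA is
treated as < 50 for the developmental/regression split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "MAGO_CODES",
    "PHASES",
    "gonadal_index",
    "gonadosomatic_index",
    "stage_maturity",
    "stage_samples",
    "cohort_maturity_table",
]

#: perinucleolus, cortical alveolar, primary/secondary/tertiary yolked,
#: germinal vesicle migration, hydrated
MAGO_CODES = ("Pn", "Ca", "Py", "Sy", "Ty", "GVM", "Hyd")
_YOLKED = {"Py", "Sy", "Ty"}
PHASES = ("immature", "developmental", "regression", "spawning_capable")


def gonadal_index(gw_g: float, fl_cm: float) -> float:
    """GI = gonad weight / fork length cubed x 10^4."""
    if fl_cm <= 0:
        raise ValueError("fork length must be positive")
    if gw_g < 0:
        raise ValueError("gonad weight cannot be negative")
    return gw_g / fl_cm**3 * 1e4


def gonadosomatic_index(gw_g: float, bw_g: float) -> float:
    """GSI = gonad weight / body weight x 10^2."""
    if bw_g <= 0:
        raise ValueError("body weight must be positive")
    if gw_g < 0:
        raise ValueError("gonad weight cannot be negative")
    return gw_g / bw_g * 100.0


def stage_maturity(mago: str, pof_present: bool, ia_pct: float | None = None) -> str:
    """Assign a maturity phase from histology codes (see module docstring)."""
    if mago not in MAGO_CODES:
        raise ValueError(f"unknown MAGO code: {mago!r}")
    if ia_pct is not None and not 0 <= ia_pct <= 100:
        raise ValueError("IA percentage must lie in [0, 100]")
    if pof_present or mago in ("GVM", "Hyd"):
        return "spawning_capable"
    if mago in ("Pn", "Ca"):
        return "immature"
    # yolked oocytes
    if ia_pct is not None and ia_pct >= 50:
        return "regression"
    return "developmental"


def stage_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Stage a table of gonad samples and attach GI/GSI.

    Expects columns ``sample_id``, ``fl_cm``, ``gw_g``, ``mago``, ``pof``
    (bool or 'present'/'absent'); optional ``bw_g``, ``ia_pct``,
    ``capture_date``.  Adds ``gi``, ``gsi`` (NaN without body weight),
    ``phase`` and ``below_min_mature_gi`` -- a report flag marking samples
    whose GI falls below the smallest GI observed in any non-immature
    sample of the cohort (mirroring the empirical observation that fish
    below that GI are uniformly immature; a flag, not a staging rule).
    """
    df = samples.copy()
    pof = df["pof"]
    if pof.dtype == object:
        pof = pof.astype(str).str.lower().isin(("present", "true", "yes", "1"))
    ia = df["ia_pct"] if "ia_pct" in df.columns else pd.Series(np.nan, index=df.index)
    df["gi"] = [gonadal_index(g, f) for g, f in zip(df["gw_g"], df["fl_cm"])]
    if "bw_g" in df.columns:
        df["gsi"] = [
            gonadosomatic_index(g, b) if np.isfinite(b) and b > 0 else np.nan
            for g, b in zip(df["gw_g"], df["bw_g"])
        ]
    else:
        df["gsi"] = np.nan
    df["phase"] = [
        stage_maturity(m, bool(p), None if pd.isna(a) else float(a))
        for m, p, a in zip(df["mago"], pof, ia)
    ]
    mature = df.loc[df["phase"] != "immature", "gi"]
    threshold = mature.min() if len(mature) else np.nan
    df["below_min_mature_gi"] = df["gi"] < threshold if np.isfinite(threshold) else False
    return df


def cohort_maturity_table(staged: pd.DataFrame) -> pd.DataFrame:
    """Per-phase summary: n, mean +/- sd and range for GI (and GSI if present).

    The sd is the sample standard deviation (n-1 denominator); groups of a
    single sample report sd as NaN (undefined).
    """
    if "phase" not in staged.columns:
        raise ValueError("samples must be staged first (see stage_samples)")
    rows = []
    for phase in PHASES:
        sub = staged[staged["phase"] == phase]
        if sub.empty:
            continue
        row = {
            "phase": phase,
            "n": len(sub),
            "mean_gi": sub["gi"].mean(),
            "sd_gi": sub["gi"].std(ddof=1) if len(sub) > 1 else np.nan,
            "min_gi": sub["gi"].min(),
            "max_gi": sub["gi"].max(),
        }
        gsi = sub["gsi"].dropna()
        row["mean_gsi"] = gsi.mean() if len(gsi) else np.nan
        row["sd_gsi"] = gsi.std(ddof=1) if len(gsi) > 1 else np.nan
        row["min_gsi"] = gsi.min() if len(gsi) else np.nan
        row["max_gsi"] = gsi.max() if len(gsi) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
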