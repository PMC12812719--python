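"""OGTT surrogate indices of insulin sensitivity and beta-cell function.

All formulas take glucose in mg/dL and insulin in uU/mL:

* Matsuda index          10000 / sqrt(Ibar * Gbar * I0 * G0), where Ibar and
                         Gbar are trapezoidal 0/60/120-min means (AUC/120 min);
* HOMA-IS = 405/(I0*G0)  and its reciprocal HOMA-IR = I0*G0/405;
* HOMA-beta              360*I0/(G0 - 63), undefined for G0 <= 63;
* IGI60                  (I60 - I0)/(G60 - G0), the insulinogenic index;
* disposition index      product of an insulin-sensitivity and a beta-cell
                         measure (oDI = Matsuda * IGI60; mDI = mSI * mBCF).

Longitudinal change statistics follow the sign convention that a positive
value means decline: DIS/DBCF = baseline value minus year-10 value.

Undefined values (absent inputs, zero/degenerate denominators) propagate as
None in the scalar API and NaN in the vectorized cohort API — never as
numeric sentinels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_data import Cohort, OGTTRecord

logger = logging.getLogger("glycoprog")

HOMA_BETA_GLUCOSE_OFFSET = 63.0  # mg/dL; HOMA-beta denominator G0 - 63

#: selectable insulin-sensitivity / beta-cell measure pairs for DIS/DBCF
MEASURE_PAIRS = {
    "matsuda-igi": ("matsuda", "igi60"),
    "external": ("msi", "mbcf"),
}


@dataclass
class IndexSet:
    """Per-visit surrogate indices; None marks an undefined value."""

    matsuda: float | None = None
    homa_is: float | None = None
    homa_ir: float | None = None
    homa_beta: float | None = None
    igi60: float | None = None
    odi: float | None = None
    msi: float | None = None
    mbcf: float | None = None
    mdi: float | None = None


@dataclass
class DeltaMetrics:
    """Baseline-minus-year-10 changes; positive = decline."""

    dis: float | None
    dbcf: float | None
    which_measures: tuple[str, str]


def trapezoid_mean(v0: float | None, v60: float | None, v120: float | None) -> float | None:
    """Mean level over the two-hour OGTT: trapezoidal AUC divided by 120 min.

    With the 0/60/120-min grid this reduces to (v0 + 2*v60 + v120)/4.
    """
    if v0 is None or v60 is None or v120 is None:
        return None
    if v0 < 0 or v60 < 0 or v120 < 0:
        raise ValueError("trapezoid_mean requires non-negative values")
    return (v0 + 2.0 * v60 + v120) / 4.0


def matsuda_index(ogtt: OGTTRecord) -> float | None:
    vals = (ogtt.g0, ogtt.g60, ogtt.g120, ogtt.i0, ogtt.i60, ogtt.i120)
    if any(v is None or v <= 0 for v in vals):
        return None
    gbar = trapezoid_mean(ogtt.g0, ogtt.g60, ogtt.g120)
    ibar = trapezoid_mean(ogtt.i0, ogtt.i60, ogtt.i120)
    return 10000.0 / math.sqrt(ibar * gbar * ogtt.i0 * ogtt.g0)


def homa_is(g0: float | None, i0: float | None) -> float | None:
    if g0 is None or i0 is None or g0 <= 0 or i0 <= 0:
        return None
    return 405.0 / (i0 * g0)


def homa_ir(g0: float | None, i0: float | None) -> float | None:
    if g0 is None or i0 is None or g0 <= 0 or i0 <= 0:
        return None
    return i0 * g0 / 405.0


def homa_beta(g0: float | None, i0: float | None) -> float | None:
    if g0 is None or i0 is None or i0 <= 0:
        return None
    if g0 <= HOMA_BETA_GLUCOSE_OFFSET:
        logger.debug("homa_beta undefined: g0=%s <= %s", g0, HOMA_BETA_GLUCOSE_OFFSET)
        return None
    return 360.0 * i0 / (g0 - HOMA_BETA_GLUCOSE_OFFSET)


def igi60(ogtt: OGTTRecord) -> float | None:
    """Insulinogenic index: incremental insulin over incremental glucose, 0-60 min."""
    if any(v is None for v in (ogtt.g0, ogtt.g60, ogtt.i0, ogtt.i60)):
        return None
    if ogtt.g60 == ogtt.g0:
        return None
    return (ogtt.i60 - ogtt.i0) / (ogtt.g60 - ogtt.g0)


def disposition_index(is_value: float | None, bcf_value: float | None) -> float | None:
    """Product of an insulin-sensitivity and a beta-cell measure (oDI or mDI)."""
    if is_value is None or bcf_value is None:
        return None
    return is_value * bcf_value


def delta_decline(x_baseline: float | None, x_year10: float | None) -> float | None:
    """Baseline minus year-10; positive values mean decline."""
    if x_baseline is None or x_year10 is None:
        return None
    return x_baseline - x_year10


def percent_decline(x_baseline: float | None, x_year10: float | None) -> float | None:
    """Decline as a percentage of baseline; undefined for baseline <= 0."""
    if x_baseline is None or x_year10 is None or x_baseline <= 0:
        return None
    return 100.0 * (x_baseline - x_year10) / x_baseline


def indices_for_record(ogtt: OGTTRecord, msi: float | None = None,
                       mbcf: float | None = None) -> IndexSet:
    """All surrogate indices for one OGTT, plus optional model-derived values."""
    m = matsuda_index(ogtt)
    igi = igi60(ogtt)
    return IndexSet(
        matsuda=m,
        homa_is=homa_is(ogtt.g0, ogtt.i0),
        homa_ir=homa_ir(ogtt.g0, ogtt.i0),
        homa_beta=homa_beta(ogtt.g0, ogtt.i0),
        igi60=igi,
        odi=disposition_index(m, igi),
        msi=msi, mbcf=mbcf,
        mdi=disposition_index(msi, mbcf),
    )


# ---------------------------------------------------------------------------
# Vectorized cohort-level API
# ---------------------------------------------------------------------------

INDEX_COLUMNS = ("matsuda", "homa_is", "homa_ir", "homa_beta", "igi60", "odi", "mdi")


def compute_indices(df: pd.DataFrame) -> pd.DataFrame:
    """Append index columns to a participant-visit frame (NaN = undefined).

    Expects columns g0,g60,g120,i0,i60,i120 and optionally msi/mbcf (the
    plug-in slot for externally computed model-derived values).
    """
    out = df.copy()
    g0 = out["g0"].to_numpy(dtype=float)
    g60 = out["g60"].to_numpy(dtype=float)
    g120 = out["g120"].to_numpy(dtype=float)
    i0 = out["i0"].to_numpy(dtype=float)
    i60 = out["i60"].to_numpy(dtype=float)
    i120 = out["i120"].to_numpy(dtype=float)

    with np.errstate(invalid="ignore", divide="ignore"):
        gbar = (g0 + 2 * g60 + g120) / 4.0
        ibar = (i0 + 2 * i60 + i120) / 4.0
        prod = ibar * gbar * i0 * g0
        matsuda = np.where(prod > 0, 10000.0 / np.sqrt(np.where(prod > 0, prod, np.nan)), np.nan)
        pos = (g0 > 0) & (g60 > 0) & (g120 > 0) & (i0 > 0) & (i60 > 0) & (i120 > 0)
        matsuda = np.where(pos, matsuda, np.nan)

        h_ok = (g0 > 0) & (i0 > 0)
        his = np.where(h_ok, 405.0 / (i0 * g0), np.nan)
        hir = np.where(h_ok, i0 * g0 / 405.0, np.nan)
        hb = np.where(h_ok & (g0 > HOMA_BETA_GLUCOSE_OFFSET),
                      360.0 * i0 / (g0 - HOMA_BETA_GLUCOSE_OFFSET), np.nan)

        dg = g60 - g0
        igi = np.where(dg != 0, (i60 - i0) / np.where(dg != 0, dg, np.nan), np.nan)

    out["matsuda"] = matsuda
    out["homa_is"] = his
    out["homa_ir"] = hir
    out["homa_beta"] = hb
    out["igi60"] = igi
    out["odi"] = matsuda * igi
    if "msi" in out.columns and "mbcf" in out.columns:
        out["mdi"] = out["msi"].astype(float) * out["mbcf"].astype(float)
    else:
        out["mdi"] = np.nan
    return out


def merge_model_derived(df: pd.DataFrame, model_df: pd.DataFrame) -> pd.DataFrame:
    """Merge externally computed msi/mbcf by (id, visit_index), replacing any
    existing columns, and recompute mdi."""
    keep = [c for c in df.columns if c not in ("msi", "mbcf", "mdi")]
    merged = df[keep].merge(
        model_df[["id", "visit_index", "msi", "mbcf"]],
        on=["id", "visit_index"], how="left")
    merged["mdi"] = merged["msi"] * merged["mbcf"]
    return merged


def compute_deltas(df: pd.DataFrame, measures: str = "matsuda-igi") -> pd.DataFrame:
    """Per-participant DIS/DBCF from baseline (visit 0) and year-10 (visit 5).

    ``measures`` selects the insulin-sensitivity/beta-cell pair:
    ``"matsuda-igi"`` (OGTT surrogates, default) or ``"external"``
    (plugged-in model-derived msi/mbcf).  Positive values mean decline.
    """
    try:
        is_col, bcf_col = MEASURE_PAIRS[measures]
    except KeyError:
        raise ValueError(f"unknown measure pair {measures!r}; options: {sorted(MEASURE_PAIRS)}")
    for col in (is_col, bcf_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not present; run compute_indices or merge model-derived values")
    base = df[df["visit_index"] == 0].set_index("id")
    year10 = df[df["visit_index"] == 5].set_index("id")
    ids = base.index.intersection(year10.index)
    out = pd.DataFrame({
        "id": ids,
        "dis": base.loc[ids, is_col].to_numpy(dtype=float)
               - year10.loc[ids, is_col].to_numpy(dtype=float),
        "dbcf": base.loc[ids, bcf_col].to_numpy(dtype=float)
                - year10.loc[ids, bcf_col].to_numpy(dtype=float),
        "baseline_is": base.loc[ids, is_col].to_numpy(dtype=float),
        "baseline_bcf": base.loc[ids, bcf_col].to_numpy(dtype=float),
    })
    out.attrs["which_measures"] = (is_col, bcf_col)
    return out.reset_index(drop=True)
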