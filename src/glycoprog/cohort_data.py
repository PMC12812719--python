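"""Core data model for longitudinal OGTT cohorts.

A cohort is a set of participants, each observed at up to six biannual
visits (visit_index 0..5 = years 0,2,4,6,8,10).  At every visit a 75-g
two-hour OGTT gives plasma glucose and insulin at 0/60/120 min plus HbA1c;
anthropometrics (BMI, fat mass) and an antidiabetic-medication flag are
recorded alongside.  The module handles CSV ingestion/validation with
row-level diagnostics, lossless round-tripping (missing values are empty
cells, never sentinels), and Little's MCAR test for missing-data auditing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("glycoprog")

# Plausibility ranges for validation; values outside are rejected, not clamped.
GLUCOSE_RANGE = (0.0, 1000.0)   # mg/dL, exclusive bounds
INSULIN_RANGE = (0.0, 1000.0)   # uU/mL, exclusive bounds
HBA1C_RANGE = (3.0, 20.0)       # percent, inclusive bounds
MAX_VISIT_INDEX = 5
YEARS_PER_VISIT = 2

#: logical column names of the flat one-row-per-participant-visit layout
COLUMNS = (
    "id", "visit_index", "sex", "baseline_age",
    "g0", "g60", "g120", "i0", "i60", "i120", "hba1c",
    "bmi", "fat_mass", "on_medication", "msi", "mbcf",
)
_FLOAT_COLUMNS = (
    "baseline_age", "g0", "g60", "g120", "i0", "i60", "i120",
    "hba1c", "bmi", "fat_mass", "msi", "mbcf",
)


@dataclass(frozen=True)
class OGTTRecord:
    """Glucose/insulin at 0/60/120 min of one OGTT plus HbA1c; fields may be None."""

    g0: float | None = None
    g60: float | None = None
    g120: float | None = None
    i0: float | None = None
    i60: float | None = None
    i120: float | None = None
    hba1c: float | None = None

    def validate(self) -> list[str]:
        problems = []
        for name in ("g0", "g60", "g120"):
            v = getattr(self, name)
            if v is not None and not (GLUCOSE_RANGE[0] < v < GLUCOSE_RANGE[1]):
                problems.append(f"{name}={v} outside plausible glucose range")
        for name in ("i0", "i60", "i120"):
            v = getattr(self, name)
            if v is not None and not (INSULIN_RANGE[0] < v < INSULIN_RANGE[1]):
                problems.append(f"{name}={v} outside plausible insulin range")
        if self.hba1c is not None and not (HBA1C_RANGE[0] <= self.hba1c <= HBA1C_RANGE[1]):
            problems.append(f"hba1c={self.hba1c} outside plausible range")
        return problems


@dataclass(frozen=True)
class Visit:
    """One biannual observation; year = 2 * visit_index."""

    visit_index: int
    ogtt: OGTTRecord = field(default_factory=OGTTRecord)
    bmi: float | None = None
    fat_mass: float | None = None
    on_antidiabetic_medication: bool | None = None
    msi: float | None = None    # externally supplied model-derived insulin sensitivity
    mbcf: float | None = None   # externally supplied model-derived beta-cell function

    @property
    def year(self) -> int:
        return YEARS_PER_VISIT * self.visit_index


@dataclass(frozen=True)
class Participant:
    id: str
    sex: str | None = None            # "male" / "female"
    baseline_age: float | None = None
    visits: tuple[Visit, ...] = ()

    def visit(self, visit_index: int) -> Visit | None:
        for v in self.visits:
            if v.visit_index == visit_index:
                return v
        return None

    def validate(self) -> list[str]:
        problems = []
        if not self.visits:
            problems.append("no visits")
        idx = [v.visit_index for v in self.visits]
        if len(set(idx)) != len(idx):
            problems.append(f"duplicate visit_index in participant {self.id}")
        for i in idx:
            if not (0 <= i <= MAX_VISIT_INDEX):
                problems.append(f"visit_index {i} out of range 0..{MAX_VISIT_INDEX}")
        return problems


@dataclass
class Cohort:
    participants: tuple[Participant, ...]
    provenance: str = ""
    log: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate participant id: {dup!r}")

    def __len__(self) -> int:
        return len(self.participants)

    def get(self, pid: str) -> Participant | None:
        for p in self.participants:
            if p.id == pid:
                return p
        return None

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one row per participant-visit with the logical columns."""
        rows = []
        for p in self.participants:
            for v in sorted(p.visits, key=lambda x: x.visit_index):
                o = v.ogtt
                med = v.on_antidiabetic_medication
                rows.append({
                    "id": p.id, "visit_index": v.visit_index, "sex": p.sex,
                    "baseline_age": p.baseline_age,
                    "g0": o.g0, "g60": o.g60, "g120": o.g120,
                    "i0": o.i0, "i60": o.i60, "i120": o.i120, "hba1c": o.hba1c,
                    "bmi": v.bmi, "fat_mass": v.fat_mass,
                    "on_medication": None if med is None else int(med),
                    "msi": v.msi, "mbcf": v.mbcf,
                })
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        if df.empty:
            df = pd.DataFrame(columns=list(COLUMNS))
        return df

    @staticmethod
    def from_frame(df: pd.DataFrame, provenance: str = "") -> "Cohort":
        work = df.sort_values(["id", "visit_index"], kind="mergesort")

        def _col(name, as_float=True):
            if name not in work.columns:
                return [None] * len(work)
            vals = work[name].tolist()
            out = []
            for v in vals:
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    out.append(None)
                else:
                    out.append(float(v) if as_float else v)
            return out

        ids = work["id"].astype(str).tolist()
        vidx = [int(v) for v in work["visit_index"].tolist()]
        sexes = _col("sex", as_float=False)
        ages = _col("baseline_age")
        floats = {c: _col(c) for c in ("g0", "g60", "g120", "i0", "i60", "i120",
                                       "hba1c", "bmi", "fat_mass", "msi", "mbcf")}
        meds = [None if m is None else bool(int(m)) for m in _col("on_medication")]

        participants = []
        cur_id: str | None = None
        visits: list[Visit] = []
        cur_sex = cur_age = None
        for k in range(len(ids)):
            if ids[k] != cur_id:
                if cur_id is not None:
                    participants.append(Participant(id=cur_id, sex=cur_sex,
                                                    baseline_age=cur_age,
                                                    visits=tuple(visits)))
                cur_id, cur_sex, cur_age, visits = ids[k], sexes[k], ages[k], []
            visits.append(Visit(
                visit_index=vidx[k],
                ogtt=OGTTRecord(g0=floats["g0"][k], g60=floats["g60"][k],
                                g120=floats["g120"][k], i0=floats["i0"][k],
                                i60=floats["i60"][k], i120=floats["i120"][k],
                                hba1c=floats["hba1c"][k]),
                bmi=floats["bmi"][k], fat_mass=floats["fat_mass"][k],
                on_antidiabetic_medication=meds[k],
                msi=floats["msi"][k], mbcf=floats["mbcf"][k]))
        if cur_id is not None:
            participants.append(Participant(id=cur_id, sex=cur_sex,
                                            baseline_age=cur_age,
                                            visits=tuple(visits)))
        return Cohort(participants=tuple(participants), provenance=provenance)


@dataclass
class MissingnessSummary:
    """Result of Little's MCAR test on a numeric table with absences."""

    n_rows: int
    missing_counts: dict[str, int]
    patterns: pd.DataFrame           # one row per missingness pattern, with 'count'
    statistic: float | None
    df: int
    p_value: float | None
    applicable: bool
    note: str = ""


# ---------------------------------------------------------------------------
# CSV ingestion / writing
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None,
                provenance: str | None = None) -> Cohort:
    """Read a participant-visit CSV into a validated :class:`Cohort`.

    ``schema`` maps logical names (``id``, ``visit_index``, ``g0``, ...) to the
    file's column names; omitted logical columns are treated as absent.  Rows
    whose values violate the plausibility ranges, or whose numeric cells do not
    parse, are rejected with a row-level diagnostic recorded in ``cohort.log``.
    Duplicate (id, visit_index) pairs are a hard error.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema = dict(schema or {})
    colmap = {logical: schema.get(logical, logical) for logical in COLUMNS}

    for mandatory in ("id", "visit_index"):
        if colmap[mandatory] not in raw.columns:
            raise ValueError(f"mandatory column {colmap[mandatory]!r} ({mandatory}) missing from {path}")

    log: list[str] = []
    records = []
    for rownum, row in raw.iterrows():
        rec: dict = {}
        bad = None
        for logical in COLUMNS:
            col = colmap[logical]
            cell = row[col].strip() if col in raw.columns else ""
            if cell == "":
                rec[logical] = None
                continue
            if logical == "id":
                rec[logical] = cell
            elif logical == "sex":
                rec[logical] = cell
            elif logical in ("visit_index", "on_medication"):
                try:
                    rec[logical] = int(float(cell))
                except ValueError:
                    bad = f"unparseable {logical}={cell!r}"
                    break
            else:
                try:
                    rec[logical] = float(cell)
                except ValueError:
                    bad = f"unparseable {logical}={cell!r}"
                    break
        if bad is None:
            if rec["id"] is None or rec["visit_index"] is None:
                bad = "missing id or visit_index"
        if bad is None:
            ogtt = OGTTRecord(g0=rec["g0"], g60=rec["g60"], g120=rec["g120"],
                              i0=rec["i0"], i60=rec["i60"], i120=rec["i120"],
                              hba1c=rec["hba1c"])
            problems = ogtt.validate()
            if not (0 <= rec["visit_index"] <= MAX_VISIT_INDEX):
                problems.append(f"visit_index {rec['visit_index']} out of range")
            if problems:
                bad = "; ".join(problems)
        if bad is not None:
            msg = f"row {rownum + 2}: rejected ({bad})"  # +2: header + 1-based
            log.append(msg)
            logger.warning("%s: %s", path.name, msg)
            continue
        records.append(rec)

    seen = set()
    for rec in records:
        key = (rec["id"], rec["visit_index"])
        if key in seen:
            raise ValueError(f"duplicate (id, visit_index) = {key} in {path}")
        seen.add(key)

    df = pd.DataFrame(records, columns=list(COLUMNS))
    cohort = Cohort.from_frame(df, provenance=provenance or str(path)) if len(df) else \
        Cohort(participants=(), provenance=provenance or str(path))
    cohort.log = log
    for p in cohort.participants:
        problems = p.validate()
        if problems:
            raise ValueError(f"participant {p.id}: " + "; ".join(problems))
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV; absent values become empty cells.

    Round-trip property: ``read_cohort(write_cohort(c))`` reproduces ``c``
    (``repr``-based float formatting is lossless).
    """
    df = cohort.to_frame()
    out = df.copy()
    for col in _FLOAT_COLUMNS:
        out[col] = [("" if v is None or (isinstance(v, float) and math.isnan(v))
                     else repr(float(v))) for v in df[col]]
    out.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Little's MCAR test
# ---------------------------------------------------------------------------

def _em_normal(x: np.ndarray, observed: np.ndarray, max_iter: int = 500,
               tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian ML mean/covariance under ignorable missingness via EM."""
    n, k = x.shape
    mu = np.nanmean(x, axis=0)
    complete = observed.all(axis=1)
    if complete.sum() >= 2:
        sigma = np.cov(x[complete], rowvar=False, bias=True)
    else:
        sigma = np.diag(np.nanvar(x, axis=0))
    sigma += 1e-12 * np.eye(k)

    keys, inverse = np.unique(observed, axis=0, return_inverse=True)
    for _ in range(max_iter):
        sum_x = np.zeros(k)
        sum_xx = np.zeros((k, k))
        for j, key in enumerate(keys):
            rows = x[inverse == j]
            obs = np.flatnonzero(key)
            mis = np.flatnonzero(~key)
            filled = rows.copy()
            cond_cov = np.zeros((k, k))
            if len(mis):
                soo = sigma[np.ix_(obs, obs)]
                smo = sigma[np.ix_(mis, obs)]
                try:
                    w = np.linalg.solve(soo, smo.T).T
                except np.linalg.LinAlgError:
                    w = smo @ np.linalg.pinv(soo)
                filled[:, mis] = mu[mis] + (rows[:, obs] - mu[obs]) @ w.T
                cond_cov[np.ix_(mis, mis)] = sigma[np.ix_(mis, mis)] - w @ smo.T
            sum_x += filled.sum(axis=0)
            sum_xx += filled.T @ filled + len(rows) * cond_cov
        new_mu = sum_x / n
        new_sigma = sum_xx / n - np.outer(new_mu, new_mu)
        shift = max(np.abs(new_mu - mu).max(), np.abs(new_sigma - sigma).max())
        mu, sigma = new_mu, new_sigma + 1e-12 * np.eye(k)
        if shift < tol:
            break
    return mu, sigma


def mcar_test(rows: pd.DataFrame) -> MissingnessSummary:
    """Little's chi-square test that data are missing completely at random.

    Estimates the grand mean vector and covariance by Gaussian maximum
    likelihood under ignorable missingness (EM), then compares each
    missingness pattern's observed means against the ML grand means:

        d^2 = sum_j n_j (ybar_j - mu_j)' Sigma_jj^{-1} (ybar_j - mu_j)

    with degrees of freedom (sum over patterns of #observed variables) minus
    the number of variables.  Asymptotically chi-square under MCAR.
    """
    df = rows.apply(pd.to_numeric, errors="coerce") if not all(
        np.issubdtype(d, np.number) for d in rows.dtypes) else rows
    df = pd.DataFrame(df, copy=True)
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise ValueError("mcar_test needs at least 2 variables and 2 rows")
    observed = df.notna().to_numpy()
    if not observed.any(axis=1).all():
        raise ValueError("mcar_test: some rows are entirely missing")

    cols = list(df.columns)
    missing_counts = {c: int(df[c].isna().sum()) for c in cols}
    pattern_keys, pattern_inverse = np.unique(observed, axis=0, return_inverse=True)
    pat_counts = np.bincount(pattern_inverse)
    patterns = pd.DataFrame(pattern_keys, columns=cols).astype(int)
    patterns["count"] = pat_counts

    if len(pattern_keys) == 1:
        return MissingnessSummary(
            n_rows=len(df), missing_counts=missing_counts, patterns=patterns,
            statistic=0.0 if pattern_keys[0].all() else None, df=0, p_value=None,
            applicable=False, note="single missingness pattern; test not applicable")

    x = df.to_numpy(dtype=float)
    if observed.all(axis=1).sum() < 2:
        raise ValueError("mcar_test: too few complete rows to estimate a covariance")
    grand_mean, sigma = _em_normal(x, observed)

    d2 = 0.0
    dof = -len(cols)
    for k, key in enumerate(pattern_keys):
        obs_idx = np.flatnonzero(key)
        dof += len(obs_idx)
        sub = x[pattern_inverse == k][:, obs_idx]
        n_k = sub.shape[0]
        dev = sub.mean(axis=0) - grand_mean[obs_idx]
        sub_sigma = sigma[np.ix_(obs_idx, obs_idx)]
        try:
            sol = np.linalg.solve(sub_sigma, dev)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(sub_sigma, dev, rcond=None)[0]
        d2 += n_k * float(dev @ sol)

    p = float(stats.chi2.sf(d2, dof)) if dof > 0 else None
    return MissingnessSummary(
        n_rows=len(df), missing_counts=missing_counts, patterns=patterns,
        statistic=float(d2), df=int(dof), p_value=p, applicable=dof > 0)
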