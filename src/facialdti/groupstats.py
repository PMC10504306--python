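"""MPM-based scalar extraction and the cohort comparison tables.

Per subject and side, each DTI index (FA, MD, AD, RD) is averaged over the
MPM voxels carrying that side's label, using the subject's own scalar maps
on the common grid.  The comparisons mirror the study design:

* healthy cohort, left vs right nerve -- paired t-test (table 1);
* patients, affected vs healthy side  -- paired t-test (table 2);
* patients vs healthy-people nerves   -- unpaired pooled-variance t-test
  (table 3), with N1 = patients' healthy sides, N2 = affected sides,
  N3 = both sides of healthy people, N4 = N3 pooled with N1.

All tests are two-tailed; the unpaired test uses the pooled-variance
Student form with df = n1 + n2 - 2 (not Welch), which is the convention
the reference t -> p checkpoints are consistent with.  Normality is
screened with a one-sample Kolmogorov-Smirnov test against a normal with
the sample's estimated mean and SD; with estimated parameters the classic
K-S p-value is anti-conservative (a Lilliefors situation), which is
acceptable here because it is used as a permissive screen (P > 0.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dtifit import ScalarMaps
from .mpm import LABEL_CODES, MaxProbabilityMap

logger = logging.getLogger(__name__)

INDEXES = ("fa", "md", "ad", "rd")
ALPHA = 0.05
#: display scaling used by the tables: MD printed in 1e-3 mm^2/s
MD_DISPLAY_SCALE = 1e3


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    kind: str  # "paired" | "unpaired-pooled"


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p: float


def p_from_t(t: float, df: int) -> float:
    """Two-tailed p for a Student-t statistic."""
    return float(2.0 * stats.t.sf(abs(t), df))


def paired_ttest(x, y) -> TTestResult:
    """Two-tailed paired t-test on differences x - y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"paired samples must be equal-length 1-D: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    return TTestResult(t=float(t), df=df, p=p_from_t(t, df), kind="paired")


def unpaired_ttest(x, y) -> TTestResult:
    """Two-tailed pooled-variance Student t-test, df = n1 + n2 - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    return TTestResult(t=float(t), df=df, p=p_from_t(t, df), kind="unpaired-pooled")


def ks_normality(values) -> KSResult:
    """One-sample K-S test against N(mean, sd) with estimated parameters."""
    v = np.asarray(values, float)
    if v.size < 5:
        raise ValueError("K-S normality screen needs n >= 5")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return KSResult(statistic=float(stat), p=float(p))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_indices(scalars: ScalarMaps, mpm: MaxProbabilityMap,
                    subject_id: str, group: str,
                    affected_side: str = "none", mpm_name: str = "") -> pd.DataFrame:
    """Mean FA/MD/AD/RD over each MPM side label for one subject.

    Returns a long-format frame with one row per side; the ``role`` column
    maps anatomical side to affected / healthy_side for patients.  Empty
    labels yield NaN with a warning.
    """
    if scalars.fa.shape != mpm.labels.shape:
        raise ValueError(
            f"grid mismatch: scalars {scalars.fa.shape} vs MPM {mpm.labels.shape}"
        )
    rows = []
    for side, code in LABEL_CODES.items():
        sel = mpm.labels == code
        if not sel.any():
            warnings.warn(f"MPM label {side!r} is empty for {subject_id}",
                          stacklevel=2)
            vals = {k: np.nan for k in INDEXES}
        else:
            vals = {
                "fa": float(scalars.fa[sel].mean()),
                "md": float(scalars.md[sel].mean()),
                "ad": float(scalars.ad[sel].mean()),
                "rd": float(scalars.rd[sel].mean()),
            }
        if group == "patient" and affected_side in ("left", "right"):
            role = "affected" if side == affected_side else "healthy_side"
        else:
            role = side
        rows.append({"subject_id": subject_id, "group": group, "mpm": mpm_name,
                     "side": side, "role": role, **vals})
    return pd.DataFrame(rows)


def _col(values: np.ndarray, index: str) -> str:
    scale = MD_DISPLAY_SCALE if index == "md" else 1.0
    m, s = np.mean(values) * scale, np.std(values, ddof=1) * scale
    if index in ("fa",):
        return f"{m:.3f} ± {s:.3f}"
    return f"{m:.5g} ± {s:.5g}"


def _pt(res: TTestResult) -> str:
    return f"{res.p:.3f} (t = {res.t:.3f})"


def _pivot(measure: pd.DataFrame, role: str, index: str) -> np.ndarray:
    sub = measure[measure["role"] == role].sort_values("subject_id")
    return sub[index].to_numpy()


def build_table_healthy(measurements: pd.DataFrame) -> pd.DataFrame:
    """Left-vs-right paired comparisons in healthy subjects (table 1 layout)."""
    out = []
    for mpm_name in sorted(measurements["mpm"].unique()):
        m = measurements[(measurements["group"] == "healthy")
                         & (measurements["mpm"] == mpm_name)]
        if m.empty:
            continue
        for index in INDEXES:
            left = _pivot(m, "left", index)
            right = _pivot(m, "right", index)
            res = paired_ttest(left, right)
            out.append({"index": index.upper(), "mpm": mpm_name,
                        "left": _col(left, index), "right": _col(right, index),
                        "p (t)": _pt(res), "p": res.p, "t": res.t, "df": res.df})
    if not out:
        raise ValueError("no healthy-cohort measurements")
    return pd.DataFrame(out)


def build_table_patient(measurements: pd.DataFrame) -> pd.DataFrame:
    """Affected-vs-healthy-side paired comparisons in patients (table 2 layout)."""
    out = []
    for mpm_name in sorted(measurements["mpm"].unique()):
        m = measurements[(measurements["group"] == "patient")
                         & (measurements["mpm"] == mpm_name)]
        if m.empty:
            continue
        for index in INDEXES:
            healthy = _pivot(m, "healthy_side", index)
            affected = _pivot(m, "affected", index)
            res = paired_ttest(healthy, affected)
            out.append({"index": index.upper(), "mpm": mpm_name,
                        "healthy_side": _col(healthy, index),
                        "affected": _col(affected, index),
                        "p (t)": _pt(res), "p": res.p, "t": res.t, "df": res.df})
    if not out:
        raise ValueError("no patient-cohort measurements")
    return pd.DataFrame(out)


def build_table_pooled(measurements: pd.DataFrame, mpm_name: str = "all") -> pd.DataFrame:
    """Patients vs healthy-people nerves under the pooled MPM (table 3 layout).

    Row pairs per index: N1 (patients' healthy sides) vs N3 (all nerves of
    healthy people); N2 (affected sides) vs N4 (N3 plus N1).
    """
    m = measurements[measurements["mpm"] == mpm_name]
    pat = m[m["group"] == "patient"]
    hea = m[m["group"] == "healthy"]
    if pat.empty or hea.empty:
        raise ValueError("pooled table needs both cohorts under the pooled MPM")
    out = []
    for index in INDEXES:
        n1 = _pivot(pat, "healthy_side", index)
        n2 = _pivot(pat, "affected", index)
        n3 = hea[index].to_numpy()  # both sides of every healthy subject
        n4 = np.concatenate([n3, n1])
        r13 = unpaired_ttest(n1, n3)
        r24 = unpaired_ttest(n2, n4)
        out.append({"index": index.upper(), "comparison": "N1 vs N3",
                    "patients": _col(n1, index), "healthy_nerves": _col(n3, index),
                    "n_patients": n1.size, "n_healthy": n3.size,
                    "p (t)": _pt(r13), "p": r13.p, "t": r13.t, "df": r13.df})
        out.append({"index": index.upper(), "comparison": "N2 vs N4",
                    "patients": _col(n2, index), "healthy_nerves": _col(n4, index),
                    "n_patients": n2.size, "n_healthy": n4.size,
                    "p (t)": _pt(r24), "p": r24.p, "t": r24.t, "df": r24.df})
    return pd.DataFrame(out)


def build_tables(measurements: pd.DataFrame,
                 healthy_mpm: str = "healthy", patient_mpm: str = "patient",
                 pooled_mpm: str = "all") -> dict:
    """All three comparison tables from a long-format measurement frame."""
    need = {"subject_id", "group", "mpm", "side", "role", *INDEXES}
    missing = need - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements frame lacks columns {sorted(missing)}")
    t1 = build_table_healthy(
        measurements[measurements["mpm"].isin([healthy_mpm, pooled_mpm])])
    t2 = build_table_patient(
        measurements[measurements["mpm"].isin([patient_mpm, pooled_mpm])])
    t3 = build_table_pooled(measurements, mpm_name=pooled_mpm)
    return {"table1": t1, "table2": t2, "table3": t3}


def normality_screen(measurements: pd.DataFrame) -> pd.DataFrame:
    """K-S normality p per (group, mpm, role, index) sample."""
    rows = []
    for (group, mpm_name, role), sub in measurements.groupby(["group", "mpm", "role"]):
        for index in INDEXES:
            v = sub[index].dropna().to_numpy()
            if v.size < 5:
                continue
            res = ks_normality(v)
            rows.append({"group": group, "mpm": mpm_name, "role": role,
                         "index": index.upper(), "ks_stat": res.statistic,
                         "p": res.p, "normal": res.p > ALPHA})
    return pd.DataFrame(rows)
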