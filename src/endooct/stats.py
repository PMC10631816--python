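"""Longitudinal cohort statistics for vessel-density and thickness metrics.

Operations on the tidy study table (columns ``patient_id, visit,
location, bvd, vet_um, vhi, vsq``; one record per patient, visit 1-4 and
location in {da, dp, pa, pp}):

* per-(visit, location) means with standard errors, plus grand per-visit
  means pooling the four locations;
* paired comparisons of each later visit against baseline (paired t-test
  by default, Wilcoxon signed-rank as option), annotated with the usual
  star convention (*** p < 0.001, ** p < 0.01, * p < 0.05, ns otherwise);
* Pearson correlations with the strength classification |r| < 0.1
  negligible, [0.1, 0.3) weak, [0.3, 0.5) moderate, >= 0.5 strong
  (boundaries closed on the left, so 0.310 is moderate and 0.5 strong).

No multiple-testing correction is applied by default; Holm adjustment is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import LOCATIONS, VISITS

__all__ = [
    "CorrelationResult",
    "validate_study_table",
    "aggregate",
    "compare_to_baseline",
    "correlate",
    "classify_strength",
    "p_to_stars",
    "holm_adjust",
]

REQUIRED_COLUMNS = ("patient_id", "visit", "location", "bvd", "vet_um", "vhi", "vsq")
METRICS = ("bvd", "vet_um", "vhi", "vsq")


@dataclass
class CorrelationResult:
    """Pearson correlation with its strength class."""

    r: float
    abs_r: float
    strength: str
    n: int
    p_value: float


def validate_study_table(table: pd.DataFrame, metrics=("bvd", "vet_um")) -> pd.DataFrame:
    """Check study-table structure: required columns, closed visit and
    location sets, and at most one record per (patient, visit, location)."""
    missing = [c for c in metrics if c not in table.columns]
    base = [c for c in ("patient_id", "visit", "location") if c not in table.columns]
    if base or missing:
        raise ValueError(f"study table missing columns: {base + missing}")
    bad_visits = set(table["visit"]) - set(VISITS)
    if bad_visits:
        raise ValueError(f"unknown visits {sorted(bad_visits)}; expected {VISITS}")
    bad_locs = set(table["location"]) - set(LOCATIONS)
    if bad_locs:
        raise ValueError(f"unknown locations {sorted(bad_locs)}; expected {LOCATIONS}")
    dup = table.duplicated(subset=["patient_id", "visit", "location"])
    if dup.any():
        raise ValueError("duplicate (patient, visit, location) records")
    return table


def aggregate(table: pd.DataFrame, metric: str = "bvd") -> pd.DataFrame:
    """Mean, SE and n per (visit, location), plus pooled grand visit means.

    Grand rows carry ``location == "all"`` and pool the records of the
    four locations.  Cells absent from the table are simply absent from
    the output (no imputation).
    """
    validate_study_table(table, metrics=(metric,))
    per_cell = (
        table.groupby(["visit", "location"], observed=True)[metric]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    grand = (
        table.groupby("visit", observed=True)[metric]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    grand["location"] = "all"
    out = pd.concat([per_cell, grand[per_cell.columns]], ignore_index=True)
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out["metric"] = metric
    return out[["metric", "visit", "location", "mean", "se", "sd", "n"]]


def p_to_stars(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if not (0.0 <= p <= 1.0) or np.isnan(p):
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _paired_p(deltas: np.ndarray, test: str) -> float:
    if np.allclose(deltas, 0.0):
        return 1.0  # no change in any patient: maximally null
    if test == "paired-t":
        return float(sps.ttest_1samp(deltas, 0.0).pvalue)
    if test == "wilcoxon":
        return float(sps.wilcoxon(deltas).pvalue)
    raise ValueError(f"unknown test {test!r}; use 'paired-t' or 'wilcoxon'")


def compare_to_baseline(
    table: pd.DataFrame,
    metric: str = "bvd",
    test: str = "paired-t",
    mode: str = "baseline",
    holm: bool = False,
) -> pd.DataFrame:
    """Two-sided paired comparison of each later visit with its reference.

    ``mode="baseline"`` compares visits 2-4 against visit 1;
    ``mode="consecutive"`` compares each visit against the previous one.
    Patients missing either visit of a pair are excluded pairwise; fewer
    than 3 complete pairs in a cell raises an error.  Returns one row per
    (visit, location) with the mean delta, p-value and stars.
    """
    validate_study_table(table, metrics=(metric,))
    if mode not in ("baseline", "consecutive"):
        raise ValueError(f"unknown comparison mode {mode!r}")
    rows = []
    for visit in (2, 3, 4):
        ref_visit = 1 if mode == "baseline" else visit - 1
        for loc in LOCATIONS:
            ref = table[(table.visit == ref_visit) & (table.location == loc)]
            cur = table[(table.visit == visit) & (table.location == loc)]
            if ref.empty or cur.empty:
                continue
            merged = ref.merge(cur, on="patient_id", suffixes=("_ref", "_cur"))
            if len(merged) < 3:
                raise ValueError(
                    f"insufficient pairs for visit {visit} vs {ref_visit} at "
                    f"{loc}: need >= 3, got {len(merged)}"
                )
            deltas = (merged[f"{metric}_cur"] - merged[f"{metric}_ref"]).to_numpy()
            p = _paired_p(deltas, test)
            rows.append({
                "metric": metric, "visit": visit, "ref_visit": ref_visit,
                "location": loc, "mean_delta": float(deltas.mean()),
                "p_value": p, "n_pairs": len(deltas),
            })
    out = pd.DataFrame(rows)
    if holm and not out.empty:
        out["p_value"] = holm_adjust(out["p_value"].to_numpy())
    if not out.empty:
        out["stars"] = out["p_value"].map(p_to_stars)
    return out


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def classify_strength(r: float) -> str:
    """Strength class of a Pearson coefficient by |r| (closed-left bins)."""
    a = abs(float(r))
    if a > 1.0 + 1e-12:
        raise ValueError(f"|r| cannot exceed 1, got {r}")
    if a < 0.1:
        return "negligible"
    if a < 0.3:
        return "weak"
    if a < 0.5:
        return "moderate"
    return "strong"


def correlate(
    table: pd.DataFrame,
    metric_a: str,
    metric_b: str,
    group_by=None,
) -> CorrelationResult | pd.DataFrame:
    """Pearson correlation between two metrics of the study table.

    Records are pooled across visits and locations by default; pass
    ``group_by`` (e.g. ``"visit"``) to correlate within groups instead, in
    which case a DataFrame with one row per group is returned.
    """
    for col in (metric_a, metric_b):
        if col not in table.columns:
            raise ValueError(f"metric {col!r} not in table")
    if group_by is not None:
        rows = []
        for key, grp in table.groupby(group_by, observed=True):
            res = correlate(grp, metric_a, metric_b)
            rows.append({group_by: key, "r": res.r, "abs_r": res.abs_r,
                         "strength": res.strength, "n": res.n, "p_value": res.p_value})
        return pd.DataFrame(rows)

    sub = table[[metric_a, metric_b]].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 complete pairs for a correlation")
    a = sub[metric_a].to_numpy(dtype=float)
    b = sub[metric_b].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one of the metrics")
    r, p = sps.pearsonr(a, b)
    return CorrelationResult(
        r=float(r), abs_r=abs(float(r)), strength=classify_strength(r),
        n=len(sub), p_value=float(p),
    )
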