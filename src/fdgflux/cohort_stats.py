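"""Subject- and group-level summaries of the per-condition metabolic rates.

Computes hypoxia deltas and percent changes per subject, per-group means and
SDs, the univariate regressions of metabolic-rate change on oxygen-saturation
change (ordinary least squares, Pearson R, t-distribution p), and a tidy
long-format export for external mixed-effects analysis — mixed models
themselves are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import MetabolicRateResult
from .io_protocol import ValidationError

__all__ = [
    "SubjectRecord",
    "GroupSummary",
    "hypoxia_delta",
    "group_correlation",
    "summarize_groups",
    "tidy_table",
]

GROUPS = ("term", "preterm")
TISSUES = ("myocardium", "skeletal_muscle")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's fitted results plus oxygen-saturation measurements.

    ``spo2_hypoxia`` is the 55-min measurement, the protocol's designated
    hypoxia value.
    """

    subject_id: str
    group: str
    results: Sequence[MetabolicRateResult]
    spo2_normoxia: Optional[float] = None
    spo2_hypoxia: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")

    def result(self, tissue: str, condition: str) -> Optional[MetabolicRateResult]:
        for r in self.results:
            if r.tissue == tissue and r.condition == condition:
                return r
        return None


@dataclass(frozen=True)
class GroupSummary:
    group: str
    tissue: str
    n: int
    mean_rate_normoxia: float
    sd_rate_normoxia: Optional[float]
    mean_rate_hypoxia: float
    sd_rate_hypoxia: Optional[float]
    mean_percent_change: Optional[float]
    pearson_r: Optional[float] = None
    p_value: Optional[float] = None


def hypoxia_delta(record: SubjectRecord, tissue: str) -> Tuple[float, Optional[float], Optional[float]]:
    """(Δrate, percent change, ΔSpO2) for one subject and tissue.

    Δrate = rate(hypoxia) − rate(normoxia); percent = 100·Δ/rate(normoxia),
    None (undefined) if the normoxia rate is 0; ΔSpO2 = SpO2(hypoxia) −
    SpO2(normoxia), None if either saturation is missing.
    """
    rn = record.result(tissue, "normoxia")
    rh = record.result(tissue, "hypoxia")
    if rn is None or rh is None:
        missing = "normoxia" if rn is None else "hypoxia"
        raise ValidationError(
            f"subject {record.subject_id}: missing {missing} result for {tissue}")
    delta = rh.rate - rn.rate
    percent = 100.0 * delta / rn.rate if rn.rate > 0 else None
    dspo2 = None
    if record.spo2_normoxia is not None and record.spo2_hypoxia is not None:
        dspo2 = record.spo2_hypoxia - record.spo2_normoxia
    return delta, percent, dspo2


def group_correlation(
    records: Sequence[SubjectRecord], tissue: str, group: str,
) -> Tuple[float, float, float, float]:
    """OLS regression of Δrate on ΔSpO2 within one group.

    Returns (Pearson R, two-sided p from the t distribution with n−2 df,
    slope, intercept).  Requires ≥ 3 usable subjects and non-degenerate
    ΔSpO2 variance.
    """
    xs, ys = [], []
    for rec in records:
        if rec.group != group:
            continue
        try:
            delta, _, dspo2 = hypoxia_delta(rec, tissue)
        except ValidationError:
            continue
        if dspo2 is None:
            continue
        xs.append(dspo2)
        ys.append(delta)
    if len(xs) < 3:
        raise ValidationError(
            f"group {group!r}/{tissue}: need >= 3 subjects with deltas, have {len(xs)}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise ValidationError(f"group {group!r}: ΔSpO2 has zero variance")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.pvalue), float(res.slope), float(res.intercept)


def _percent_change(mean_n: float, mean_h: float,
                    subject_percents: Sequence[float],
                    of_group_means: bool) -> Optional[float]:
    if of_group_means:
        if mean_n <= 0:
            return None
        return 100.0 * (mean_h - mean_n) / mean_n
    usable = [p for p in subject_percents if p is not None]
    return float(np.mean(usable)) if usable else None


def summarize_groups(
    records: Sequence[SubjectRecord],
    percent_of_group_means: bool = True,
) -> List[GroupSummary]:
    """Per group×tissue summaries; subject-order invariant.

    The headline percent change is that of the group-mean rates by default;
    set ``percent_of_group_means=False`` for the mean of per-subject
    percent changes instead.  SDs need n ≥ 2 and are None otherwise; the
    Δrate-vs-ΔSpO2 correlation needs ≥ 3 usable subjects and is None
    otherwise.
    """
    if not records:
        raise ValidationError("no subject records to summarize")
    out: List[GroupSummary] = []
    for group in GROUPS:
        grp = sorted((r for r in records if r.group == group),
                     key=lambda r: r.subject_id)
        if not grp:
            continue
        for tissue in TISSUES:
            rn, rh, percents = [], [], []
            for rec in grp:
                res_n = rec.result(tissue, "normoxia")
                res_h = rec.result(tissue, "hypoxia")
                if res_n is None or res_h is None:
                    continue
                rn.append(res_n.rate)
                rh.append(res_h.rate)
                _, pct, _ = hypoxia_delta(rec, tissue)
                percents.append(pct)
            if not rn:
                continue
            n = len(rn)
            try:
                r, p, _, _ = group_correlation(grp, tissue, group)
            except ValidationError:
                r, p = None, None
            out.append(GroupSummary(
                group=group, tissue=tissue, n=n,
                mean_rate_normoxia=float(np.mean(rn)),
                sd_rate_normoxia=float(np.std(rn, ddof=1)) if n >= 2 else None,
                mean_rate_hypoxia=float(np.mean(rh)),
                sd_rate_hypoxia=float(np.std(rh, ddof=1)) if n >= 2 else None,
                mean_percent_change=_percent_change(
                    float(np.mean(rn)), float(np.mean(rh)), percents,
                    percent_of_group_means),
                pearson_r=r, p_value=p,
            ))
    return out


def tidy_table(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Long-format table (one row per subject×tissue×condition) for external
    statistics packages (e.g. mixed-effects models)."""
    rows = []
    for rec in sorted(records, key=lambda r: r.subject_id):
        for res in rec.results:
            rows.append({
                "subject": rec.subject_id,
                "group": rec.group,
                "tissue": res.tissue,
                "condition": res.condition,
                "Ki": res.ki,
                "rate": res.rate,
                "LC": res.lc.value,
                "glucose_umol_ml": res.glucose_umol_ml,
                "spo2_normoxia": rec.spo2_normoxia,
                "spo2_hypoxia": rec.spo2_hypoxia,
                "SSE": res.fit.sse,
                "converged": res.fit.converged,
            })
    return pd.DataFrame(rows, columns=[
        "subject", "group", "tissue", "condition", "Ki", "rate", "LC",
        "glucose_umol_ml", "spo2_normoxia", "spo2_hypoxia", "SSE", "converged"])


def summaries_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
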