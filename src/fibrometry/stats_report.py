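"""Group summaries, two-sample comparison and tabular reports.

Aggregates per-instance morphometry records (length, width, area in
microns) into group summaries, compares two groups with the two-sample
t statistic t = (X1bar - X2bar) / SED — where SED is the standard error of
the difference between the means — and reports the percent change between
group means (e.g. a transgenic line against its wildtype control).

The default is the pooled-variance Student test (``equal_var=True``), the
default of scipy's ``ttest_ind``; Welch's unequal-variance form is exposed
and preferable when group sizes or spreads differ.  Quantiles use linear
interpolation between order statistics, the common plotting convention.
P-values are two-sided by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .morphometry import MorphometryRecord, records_to_dataframe

MEASURED_FIELDS = ("length_um", "width_um", "area_um2")


@dataclass
class GroupSummary:
    """Descriptive statistics of one measured field in one group."""

    group_id: str
    field: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float


@dataclass
class ComparisonResult:
    """Two-group comparison: t statistic, p-value, df, percent change."""

    t_statistic: float
    p_value: float
    df: float
    mean_1: float
    mean_2: float
    percent_change: float
    equal_var: bool
    field: str = ""
    summary_1: GroupSummary | None = None
    summary_2: GroupSummary | None = None


def _field_values(records: Sequence[MorphometryRecord], field: str) -> np.ndarray:
    vals = [getattr(r, field) for r in records if not r.excluded]
    return np.asarray(vals, dtype=float)


def summarize(
    records: Sequence[MorphometryRecord], field: str, group_id: str
) -> GroupSummary:
    """Summary statistics over the non-excluded records of one group."""
    values = _field_values(records, field)
    if values.size == 0:
        raise ValueError("no records remain after border exclusion")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return GroupSummary(
        group_id=group_id,
        field=field,
        n=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(values.min()),
        max=float(values.max()),
    )


def t_test(
    sample_1: Sequence[float],
    sample_2: Sequence[float],
    equal_var: bool = True,
    alternative: str = "two-sided",
) -> ComparisonResult:
    """Two-independent-samples t-test, t = (X1bar - X2bar) / SED.

    Pooled-variance Student form by default; Welch with
    ``equal_var=False`` (df by Welch-Satterthwaite).
    """
    a = np.asarray(sample_1, dtype=float)
    b = np.asarray(sample_2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    n1, n2 = a.size, b.size
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        sed = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    else:
        sed = np.sqrt(v1 / n1 + v2 / n2)
        df = float(
            (v1 / n1 + v2 / n2) ** 2
            / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        ) if v1 + v2 > 0 else float(n1 + n2 - 2)
    if sed == 0:
        raise ValueError("degenerate samples")
    res = sstats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    m1, m2 = float(a.mean()), float(b.mean())
    return ComparisonResult(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=df,
        mean_1=m1,
        mean_2=m2,
        percent_change=percent_change(m1, m2) if m1 != 0 else float("nan"),
        equal_var=equal_var,
    )


def percent_change(mean_ref: float, mean_test: float) -> float:
    """Percent change of ``mean_test`` relative to ``mean_ref``."""
    if mean_ref == 0:
        raise ValueError("reference mean is zero")
    return 100.0 * (mean_test - mean_ref) / mean_ref


def compare_groups(
    records_1: Sequence[MorphometryRecord],
    records_2: Sequence[MorphometryRecord],
    field: str,
    group_ids: tuple[str, str] = ("group_1", "group_2"),
    equal_var: bool = True,
) -> ComparisonResult:
    """t-test plus percent change of means between two record groups.

    ``percent_change`` is the change of group 2 relative to group 1, so
    with the reference (e.g. wildtype) first a longer-fibered test group
    reports a positive change.
    """
    s1 = summarize(records_1, field, group_ids[0])
    s2 = summarize(records_2, field, group_ids[1])
    result = t_test(
        _field_values(records_1, field),
        _field_values(records_2, field),
        equal_var=equal_var,
    )
    result.field = field
    result.summary_1 = s1
    result.summary_2 = s2
    return result


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _comparison_payload(c: ComparisonResult) -> dict:
    return {
        "field": c.field,
        "t_statistic": round(c.t_statistic, 4),
        "p_value": float(f"{c.p_value:.4g}"),
        "df": round(c.df, 4),
        "mean_1": round(c.mean_1, 2),
        "mean_2": round(c.mean_2, 2),
        "percent_change": round(c.percent_change, 2),
        "equal_var": c.equal_var,
        "group_1": c.summary_1.group_id if c.summary_1 else None,
        "group_2": c.summary_2.group_id if c.summary_2 else None,
    }


def export_report(
    records_by_group: dict[str, Sequence[MorphometryRecord]],
    comparisons: Sequence[ComparisonResult],
    out_dir: str | Path,
    fields: Sequence[str] = MEASURED_FIELDS,
) -> dict[str, Path]:
    """Write the per-instance CSV, group-summary CSV and comparison JSON.

    Micron fields are rounded to 2 decimals in the summary table and
    statistics to 4, matching the per-instance CSV precision downstream
    tools expect.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frames = []
    for group_id, records in records_by_group.items():
        df = records_to_dataframe(list(records))
        df.insert(0, "group", group_id)
        frames.append(df)
    inst_path = out / "instances.csv"
    pd.concat(frames, ignore_index=True).to_csv(inst_path, index=False)
    paths["instances"] = inst_path

    rows = []
    for group_id, records in records_by_group.items():
        for field in fields:
            s = summarize(list(records), field, group_id)
            rows.append({
                "group": group_id, "field": field, "n": s.n,
                "mean": round(s.mean, 2), "sd": round(s.sd, 2),
                "median": round(s.median, 2), "q1": round(s.q1, 2),
                "q3": round(s.q3, 2), "min": round(s.min, 2),
                "max": round(s.max, 2),
            })
    summary_path = out / "group_summaries.csv"
    pd.DataFrame(rows).to_csv(summary_path, index=False)
    paths["summaries"] = summary_path

    if comparisons:
        cmp_path = out / "comparisons.json"
        cmp_path.write_text(json.dumps(
            [_comparison_payload(c) for c in comparisons], indent=1
        ))
        paths["comparisons"] = cmp_path
    return paths
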