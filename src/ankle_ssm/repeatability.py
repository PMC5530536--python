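"""Reader-repeatability metrics for landmark placement.

Distances between corresponding landmarks of two readings are computed in
the original image coordinates (mm), before any Procrustes scaling,
because the repeatability thresholds (1 / 1.5 / 2 mm) are physical
distances.  Agreement of derived scores (e.g. mode 1) between readings is
summarized by the two-way random-effects, absolute-agreement,
single-measure intraclass correlation ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RepeatabilityReport",
    "point_distances",
    "pct_within_thresholds",
    "icc_absolute_agreement",
    "repeatability_report",
]

DEFAULT_THRESHOLDS = (1.0, 1.5, 2.0)


@dataclass
class RepeatabilityReport:
    distances: pd.DataFrame       # columns: ankle_id, point, distance_mm
    pct_within: dict[float, float]
    mean_difference: float
    icc: float | None = None
    icc_ci: tuple[float, float] | None = None

    def frame(self) -> pd.DataFrame:
        rows = [
            {"metric": f"pct_within_{thr:g}mm", "value": val}
            for thr, val in self.pct_within.items()
        ]
        rows.append({"metric": "mean_difference_mm", "value": self.mean_difference})
        if self.icc is not None:
            rows.append({"metric": "icc", "value": self.icc})
            rows.append({"metric": "icc_ci_lower", "value": self.icc_ci[0]})
            rows.append({"metric": "icc_ci_upper", "value": self.icc_ci[1]})
        return pd.DataFrame(rows)


def point_distances(reading_a, reading_b) -> pd.DataFrame:
    """Per-landmark Euclidean distances (mm) between two paired readings.

    Readings are lists of configurations paired by ``ankle_id``; every
    ankle must appear in both.
    """
    by_id_a = {c.ankle_id: c for c in reading_a}
    by_id_b = {c.ankle_id: c for c in reading_b}
    missing = sorted(set(by_id_a) ^ set(by_id_b))
    if missing:
        raise ValueError(f"unpaired ankles between readings: {missing}")
    rows = []
    for ankle_id in (c.ankle_id for c in reading_a):
        a, b = by_id_a[ankle_id], by_id_b[ankle_id]
        if a.coords.shape != b.coords.shape:
            raise ValueError(f"{ankle_id}: point counts differ between readings")
        d = np.sqrt(((a.coords - b.coords) ** 2).sum(axis=1))
        rows.extend(
            {"ankle_id": ankle_id, "point": j + 1, "distance_mm": float(dj)}
            for j, dj in enumerate(d)
        )
    return pd.DataFrame(rows)


def pct_within_thresholds(distances, thresholds=DEFAULT_THRESHOLDS) -> dict[float, float]:
    """Percentage of pooled distances within (<=, inclusive) each threshold."""
    if isinstance(distances, pd.DataFrame):
        distances = distances["distance_mm"].to_numpy()
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("no distances supplied")
    return {float(t): float(100.0 * np.mean(d <= t)) for t in thresholds}


def icc_absolute_agreement(scores_reader1, scores_reader2, alpha: float = 0.05):
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares (subjects x raters) with
    the F-based confidence interval of McGraw & Wong.  Returns
    ``(icc, (lower, upper))``.
    """
    y1 = np.asarray(scores_reader1, dtype=float).ravel()
    y2 = np.asarray(scores_reader2, dtype=float).ravel()
    if y1.shape != y2.shape:
        raise ValueError("paired score vectors must have equal length")
    n = y1.size
    if n < 3:
        raise ValueError("ICC needs at least 3 paired observations")
    data = np.column_stack([y1, y2])  # n subjects x k=2 raters
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong F-based interval for ICC(A,1)
    r = icc
    a = k * r / (n * (1.0 - r)) if r < 1 else np.inf
    b = 1.0 + k * r * (n - 1) / (n * (1.0 - r)) if r < 1 else np.inf
    if np.isfinite(a):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        lower = upper = 1.0
    return float(icc), (float(lower), float(upper))


def repeatability_report(
    reading_a,
    reading_b,
    scores_a=None,
    scores_b=None,
    thresholds=DEFAULT_THRESHOLDS,
) -> RepeatabilityReport:
    """Full repeatability summary between two readings.

    Point-placement agreement (distance percentiles within mm thresholds,
    mean difference) always; score agreement (ICC with CI) when per-ankle
    score vectors from both readings are supplied.
    """
    dist = point_distances(reading_a, reading_b)
    pct = pct_within_thresholds(dist, thresholds)
    icc = ci = None
    if scores_a is not None and scores_b is not None:
        icc, ci = icc_absolute_agreement(scores_a, scores_b)
    return RepeatabilityReport(
        distances=dist,
        pct_within=pct,
        mean_difference=float(dist["distance_mm"].mean()),
        icc=icc,
        icc_ci=ci,
    )
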