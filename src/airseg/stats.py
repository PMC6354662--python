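"""Reliability and accuracy statistics for repeated volume measurements.

Paired t-test with 95% CI, intraclass correlation (one-way random and
two-way absolute-agreement single-measure forms), random error (SD of paired
differences divided by sqrt(2)), the voxel-count <-> mm^3 convention, and
percent-of-gold-standard accuracy reporting.  Sample SDs use the n-1
denominator throughout.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps

__all__ = [
    "MeasurementTable",
    "ReliabilityReport",
    "AccuracyReport",
    "paired_t_test",
    "random_error",
    "icc",
    "percent_of_gs",
    "voxel_mm3_convert",
    "reliability_report",
    "accuracy_report",
    "format_reliability_table",
    "format_accuracy_table",
]

ICC_MODELS = ("one_way_random", "two_way_absolute_agreement")


@dataclass
class MeasurementTable:
    """Object x session measurement grid with a unit flag."""

    object_ids: list
    session_ids: list
    values: np.ndarray  # (n_objects, n_sessions)
    unit: str = "voxel_counts"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.object_ids), len(self.session_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.object_ids)} objects x {len(self.session_ids)} sessions"
            )
        if np.any(self.values < 0):
            raise ValueError("measurements must be non-negative")

    def session(self, session_id) -> np.ndarray:
        return self.values[:, self.session_ids.index(session_id)]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["object_id", "session_id", "value", "unit"])
            for i, obj in enumerate(self.object_ids):
                for j, ses in enumerate(self.session_ids):
                    writer.writerow([obj, ses, repr(float(self.values[i, j])), self.unit])

    @classmethod
    def from_csv(cls, path) -> "MeasurementTable":
        cells: dict[tuple[str, str], float] = {}
        units = set()
        objects: list[str] = []
        sessions: list[str] = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"object_id", "session_id", "value"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(
                    f"{path}: CSV must have columns object_id, session_id, value"
                )
            for row in reader:
                obj, ses = row["object_id"], row["session_id"]
                if obj not in objects:
                    objects.append(obj)
                if ses not in sessions:
                    sessions.append(ses)
                cells[(obj, ses)] = float(row["value"])
                units.add(row.get("unit", "voxel_counts") or "voxel_counts")
        missing = [
            (o, s) for o in objects for s in sessions if (o, s) not in cells
        ]
        if missing:
            raise ValueError(f"{path}: incomplete table, missing cells {missing[:5]}")
        values = np.array([[cells[(o, s)] for s in sessions] for o in objects])
        return cls(objects, sessions, values, unit=sorted(units)[0])


@dataclass(frozen=True)
class ReliabilityReport:
    icc: float
    icc_model: str
    random_error: float
    mean_difference: float
    ci95_low: float
    ci95_high: float
    t_statistic: float
    df: int
    p_value: float
    n: int
    unit: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class AccuracyRow:
    label: str
    measured_mm3: float
    gold_standard_mm3: float
    percent_of_gs: float


@dataclass(frozen=True)
class AccuracyReport:
    rows: tuple

    def to_json(self) -> str:
        return json.dumps([asdict(r) for r in self.rows], indent=2)


def _paired(x, y, min_n: int = 2):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D arrays, got {x.shape}, {y.shape}")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(x)}")
    return x, y


def paired_t_test(x, y) -> tuple[float, int, float, tuple[float, float]]:
    """Classical paired t on d = x - y: (t, df, two-tailed p, 95% CI of mean d).

    Zero-variance differences with a nonzero mean yield t = +/-inf, p = 0.
    """
    x, y = _paired(x, y)
    d = x - y
    n = len(d)
    df = n - 1
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0, (0.0, 0.0)
        return math.copysign(math.inf, mean), df, 0.0, (mean, mean)
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(0.975, df))
    return t, df, p, (mean - tcrit * se, mean + tcrit * se)


def random_error(x, y) -> float:
    """SD (n-1 denominator) of the paired differences, divided by sqrt(2)."""
    x, y = _paired(x, y)
    return float((x - y).std(ddof=1)) / math.sqrt(2.0)


def icc(x, y, model: str = "two_way_absolute_agreement") -> float:
    """Single-measure intraclass correlation of an n x 2 table.

    ``one_way_random`` is ICC(1); ``two_way_absolute_agreement`` is ICC(A,1)
    from the standard mean-squares decomposition.
    """
    if model not in ICC_MODELS:
        raise ValueError(f"model must be one of {ICC_MODELS}, got {model!r}")
    x, y = _paired(x, y)
    table = np.column_stack([x, y])
    n, k = table.shape
    grand = table.mean()
    if np.allclose(table, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ms_rows = ss_rows / (n - 1)
    if model == "one_way_random":
        ms_within = float(((table - row_means[:, None]) ** 2).sum()) / (n * (k - 1))
        return (ms_rows - ms_within) / (ms_rows + (k - 1) * ms_within)
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((table - grand) ** 2).sum())
    ms_cols = ss_cols / (k - 1)
    ms_err = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    )


def percent_of_gs(measured_mm3: float, gs_mm3: float) -> float:
    """Accuracy as a percentage of the gold standard, to one decimal."""
    if gs_mm3 <= 0:
        raise ValueError(f"gold standard must be positive, got {gs_mm3}")
    return round(100.0 * measured_mm3 / gs_mm3, 1)


def voxel_mm3_convert(value: float, direction: str, spacing) -> float:
    """Convert between voxel counts and mm^3 for a given spacing.

    ``direction`` is ``"counts_to_mm3"`` or ``"mm3_to_counts"``; ``spacing``
    is a scalar (isotropic) or an (sx, sy, sz) triple in mm.
    """
    if np.isscalar(spacing):
        sx = sy = sz = float(spacing)
    else:
        sx, sy, sz = spacing
    if min(sx, sy, sz) <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    # sequential per-axis operations keep round decimal spacings exact
    # (1 / 0.4 / 0.4 / 0.4 == 15.625 in doubles, 1 / 0.4**3 does not)
    if direction == "counts_to_mm3":
        return value * sx * sy * sz
    if direction == "mm3_to_counts":
        return value / sx / sy / sz
    raise ValueError(
        f"direction must be 'counts_to_mm3' or 'mm3_to_counts', got {direction!r}"
    )


def reliability_report(
    x, y, icc_model: str = "two_way_absolute_agreement", unit: str = ""
) -> ReliabilityReport:
    """Bundle the statistics of one two-session comparison."""
    t, df, p, (lo, hi) = paired_t_test(x, y)
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return ReliabilityReport(
        icc=icc(x, y, model=icc_model),
        icc_model=icc_model,
        random_error=random_error(x, y),
        mean_difference=float(d.mean()),
        ci95_low=lo,
        ci95_high=hi,
        t_statistic=t,
        df=df,
        p_value=p,
        n=len(d),
        unit=unit,
    )


def accuracy_report(measured_mm3, gs_mm3, labels=None) -> AccuracyReport:
    measured_mm3 = np.asarray(measured_mm3, dtype=float)
    gs_mm3 = np.asarray(gs_mm3, dtype=float)
    if measured_mm3.shape != gs_mm3.shape:
        raise ValueError("measured and gold-standard arrays must align")
    if labels is None:
        labels = [f"object_{i + 1}" for i in range(len(measured_mm3))]
    rows = tuple(
        AccuracyRow(
            label=str(lab),
            measured_mm3=float(m),
            gold_standard_mm3=float(g),
            percent_of_gs=percent_of_gs(float(m), float(g)),
        )
        for lab, m, g in zip(labels, measured_mm3, gs_mm3)
    )
    return AccuracyReport(rows=rows)


def format_reliability_table(reports: dict) -> str:
    """Plain-text table (one row per comparison) of reliability statistics."""
    header = (
        f"{'Comparison':<16}{'ICC':>8}{'Random error':>14}{'Mean diff':>12}"
        f"{'95% CI':>24}{'p':>8}"
    )
    lines = [header, "-" * len(header)]
    for name, rep in reports.items():
        ci = f"[{rep.ci95_low:,.1f}, {rep.ci95_high:,.1f}]"
        lines.append(
            f"{name:<16}{rep.icc:>8.3f}{rep.random_error:>14,.1f}"
            f"{rep.mean_difference:>12,.1f}{ci:>24}{rep.p_value:>8.3f}"
        )
    return "\n".join(lines)


def format_accuracy_table(report: AccuracyReport) -> str:
    header = f"{'Object':<12}{'GS (mm3)':>12}{'Measured (mm3)':>16}{'% of GS':>10}"
    lines = [header, "-" * len(header)]
    for row in report.rows:
        lines.append(
            f"{row.label:<12}{row.gold_standard_mm3:>12,.0f}"
            f"{row.measured_mm3:>16,.0f}{row.percent_of_gs:>10.1f}"
        )
    return "\n".join(lines)
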