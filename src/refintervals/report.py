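"""Study-level orchestration and table/figure rendering.

``compile_report`` runs the full pipeline for every measurand — pooled
first, then per partition — and flattens the results to display-ready rows
matching the conventional reference-interval table layout (n, descriptive
stats, RI as "lower–upper", 90% CIs of both limits, Shapiro-Wilk p,
G/NG and P/NP flags, between-partition p on the pooled row).  Absent cells
render as the dash used in such tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import (
    PartitionComparison,
    ReferenceIntervalResult,
    analyze_measurand,
    compare_partitions,
)
from .errors import DegenerateDataError
from .model import (
    POOLED_PARTITION,
    MeasurandSeries,
    MethodPolicy,
    StudyTable,
    extract_series,
)

__all__ = [
    "RIReportRow",
    "DASH",
    "compile_results",
    "compile_report",
    "render_tables",
    "parse_report",
    "plot_histograms",
    "build_run_log",
]

logger = logging.getLogger("refintervals")

#: Dash rendered for absent cells (the glyph used in printed RI tables).
DASH = "–"


@dataclass(frozen=True)
class RIReportRow:
    """One display-ready report row: all optional cells pre-rendered."""

    measurand: str
    unit: str
    partition: str
    n: int
    mean: str
    sd: str
    median: str
    min: str
    max: str
    ri_text: str
    lrl_ci_text: str
    url_ci_text: str
    normality_p: str
    distribution_label: str
    method_label: str
    partition_p: str


def _fmt(x: float | None, nd: int = 2) -> str:
    return DASH if x is None else f"{x:.{nd}f}"


def _fmt_p(p: float | None) -> str:
    return DASH if p is None else f"{p:.4g}"


def _interval_text(interval: tuple[float, float] | None) -> str:
    if interval is None:
        return DASH
    return f"{interval[0]:.2f}{DASH}{interval[1]:.2f}"


def _row_from_result(
    result: ReferenceIntervalResult, partition_p: float | None
) -> RIReportRow:
    d = result.descriptive
    ri = (
        (result.lower_limit, result.upper_limit)
        if result.lower_limit is not None and result.upper_limit is not None
        else None
    )
    return RIReportRow(
        measurand=result.series.measurand,
        unit=result.series.unit,
        partition=result.series.partition,
        n=d.n if d else 0,
        mean=_fmt(d.mean if d else None),
        sd=_fmt(d.sd if d else None),
        median=_fmt(d.median if d else None),
        min=_fmt(d.min if d else None),
        max=_fmt(d.max if d else None),
        ri_text=_interval_text(ri),
        lrl_ci_text=_interval_text(result.lrl_ci),
        url_ci_text=_interval_text(result.url_ci),
        normality_p=_fmt_p(result.normality.p_value if result.normality else None),
        distribution_label=result.distribution_label or DASH,
        method_label=result.method.label,
        partition_p=_fmt_p(partition_p),
    )


def compile_results(
    table: StudyTable, policy: MethodPolicy | None = None
) -> list[tuple[ReferenceIntervalResult, PartitionComparison | None]]:
    """Full pipeline for every (measurand, partition), pooled row first.

    The between-partition comparison is computed on the pre-screening values
    of the two partition labels (when both have n >= 3) and attached to the
    pooled row, mirroring the one-p-per-measurand table convention.
    """
    policy = policy or MethodPolicy()
    labels = table.partition_labels()
    out: list[tuple[ReferenceIntervalResult, PartitionComparison | None]] = []
    for measurand in table.measurands():
        per_partition: dict[str, MeasurandSeries] = {
            POOLED_PARTITION: extract_series(table, measurand, POOLED_PARTITION)
        }
        for label in labels:
            per_partition[label] = extract_series(table, measurand, label)
        comparison: PartitionComparison | None = None
        if len(labels) == 2:
            a, b = (per_partition[label].values for label in labels)
            try:
                comparison = compare_partitions(a, b, policy)
            except DegenerateDataError:
                comparison = None
        for label, series in per_partition.items():
            result = analyze_measurand(series, policy)
            out.append((result, comparison if label == POOLED_PARTITION else None))
    return out


def compile_report(
    table: StudyTable, policy: MethodPolicy | None = None
) -> list[RIReportRow]:
    return [
        _row_from_result(result, comparison.p_value if comparison else None)
        for result, comparison in compile_results(table, policy)
    ]


def render_tables(
    rows: Sequence[RIReportRow],
    out_dir: str | Path,
    formats: Sequence[str] = ("csv", "md"),
) -> dict[str, Path]:
    """Write the report as delimited and/or markdown files; returns paths."""
    if not rows:
        raise ValueError("no rows to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    written: dict[str, Path] = {}
    if "csv" in formats:
        path = out_dir / "report.csv"
        frame.to_csv(path, index=False)
        written["csv"] = path
    if "md" in formats:
        path = out_dir / "report.md"
        cols = list(frame.columns)
        lines = [
            "| " + " | ".join(cols) + " |",
            "| " + " | ".join("---" for _ in cols) + " |",
        ]
        for _, row in frame.iterrows():
            lines.append("| " + " | ".join(str(v) for v in row) + " |")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written["md"] = path
    return written


def parse_report(path: str | Path) -> list[RIReportRow]:
    """Read back a CSV report into rows (inverse of the csv rendering)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame["n"] = frame["n"].astype(int)
    return [RIReportRow(**rec) for rec in frame.to_dict(orient="records")]


def plot_histograms(
    table: StudyTable,
    out_dir: str | Path,
    policy: MethodPolicy | None = None,
) -> list[Path]:
    """One frequency histogram per measurand (Freedman-Diaconis binning).

    Constant measurands have no spread to bin and are skipped with a log
    notice.  Returns the written image paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for measurand in table.measurands():
        series = extract_series(table, measurand, POOLED_PARTITION)
        values = series.values
        if values.size == 0 or np.ptp(values) == 0.0:
            logger.info("histogram skipped for constant/empty measurand %s", measurand)
            continue
        edges = np.histogram_bin_edges(values, bins="fd")
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(values, bins=edges, edgecolor="black", linewidth=0.5)
        unit = f" ({series.unit})" if series.unit else ""
        ax.set_xlabel(f"{measurand}{unit}")
        ax.set_ylabel("Frequency")
        fig.tight_layout()
        safe = "".join(c if c.isalnum() or c in "-." else "_" for c in measurand)
        path = out_dir / f"{safe}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def build_run_log(
    table: StudyTable, policy: MethodPolicy | None = None
) -> dict:
    """Structured audit of a full run: screening and routing per row."""
    policy = policy or MethodPolicy()
    entries = []
    for result, comparison in compile_results(table, policy):
        entries.append(
            {
                "measurand": result.series.measurand,
                "partition": result.series.partition,
                "n_before": result.series.n,
                "n_after": int(result.screen.retained.size),
                "outliers_removed": [
                    {"value": v, "iteration": i, "method": m}
                    for v, i, m in result.screen.removed
                ],
                "screen_iterations": result.screen.iterations,
                "method": result.method.name,
                "distribution": result.distribution_label,
                "partition_p": comparison.p_value if comparison else None,
            }
        )
    return {"seed": policy.rng_seed, "policy": policy.to_dict(), "rows": entries}
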