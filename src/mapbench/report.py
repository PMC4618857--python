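"""Benchmark result tables, quadrant analysis, and the HTML report.

The canonical outputs are ``report.json`` and ``report.tsv``; the HTML page
is a pure view over them. The accuracy-vs-throughput scatter places every
mapper x parameter-set result by its fraction of correctly mapped reads
(y) and correctly mapped reads per second (x), draws quadrant boundaries
through a declared baseline result, and labels each non-baseline point:

    N++  more accurate and faster than the baseline
    N+-  more accurate, slower
    N-+  less accurate (or tied), faster
    N--  outperformed by (or tied with) the baseline on both axes

"+" requires a strict improvement; ties count as "-". The points with the
highest accuracy and highest throughput carry "A" and "S" markers (ties
broken by parameter label, lexicographically). In real-data mode, where no
truth exists, percent mapped replaces accuracy on the vertical axis.
"""
from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .evaluator import EvalCounts, Metrics

log = logging.getLogger(__name__)

QUADRANTS = ("N++", "N+-", "N-+", "N--")


@dataclass(frozen=True)
class BenchmarkResult:
    """One mapper x parameter-set evaluation on one dataset and threshold."""

    mapper: str
    parameter_label: str
    counts: EvalCounts | None
    metrics: Metrics | None
    mapping_wall_time: float | None = None
    peak_memory: int | None = None
    dataset: str = "simulated"
    threshold: int = 0
    percent_mapped_real: float | None = None
    reads_per_second: float | None = None

    @property
    def key(self) -> str:
        return f"{self.mapper}/{self.parameter_label}"

    @property
    def accuracy(self) -> float:
        """Vertical axis: fraction correct (simulated) or fraction mapped (real)."""
        if self.percent_mapped_real is not None:
            return self.percent_mapped_real / 100.0
        if self.counts is None or self.counts.total == 0:
            return 0.0
        return self.counts.correct / self.counts.total

    @property
    def throughput(self) -> float:
        """Horizontal axis: correct reads per second (reads/s in real mode)."""
        if self.percent_mapped_real is not None:
            return self.reads_per_second or 0.0
        if self.metrics is None or self.metrics.correct_per_second is None:
            return 0.0
        return self.metrics.correct_per_second


def assign_quadrant(candidate: BenchmarkResult, baseline: BenchmarkResult) -> str:
    """Quadrant of ``candidate`` relative to ``baseline`` (strict-improvement '+')."""
    if candidate.dataset != baseline.dataset or candidate.threshold != baseline.threshold:
        raise ValueError(
            "quadrants are only defined between results on the same dataset and "
            f"threshold: {candidate.key} vs {baseline.key}"
        )
    acc = "+" if candidate.accuracy > baseline.accuracy else "-"
    spd = "+" if candidate.throughput > baseline.throughput else "-"
    return f"N{acc}{spd}"


def _round5(x: float | None):
    """Round to 5 significant digits; the same float feeds both TSV and JSON."""
    if x is None:
        return None
    return float(f"{x:.5g}")


def _result_row(result: BenchmarkResult, baseline: BenchmarkResult) -> dict:
    c = result.counts
    m = result.metrics
    return {
        "mapper": result.mapper,
        "parameter_label": result.parameter_label,
        "dataset": result.dataset,
        "threshold": result.threshold,
        "C": c.correct if c else None,
        "W": c.wrong if c else None,
        "N": c.not_mapped if c else None,
        "total": c.total if c else None,
        "precision": _round5(m.precision) if m else None,
        "recall": _round5(m.recall) if m else None,
        "f_measure": _round5(m.f_measure) if m else None,
        "recall_conventional": _round5(m.recall_conventional) if m else None,
        "correct_per_second": _round5(m.correct_per_second) if m else None,
        "percent_mapped": _round5(
            result.percent_mapped_real if result.percent_mapped_real is not None
            else (m.percent_mapped if m else None)
        ),
        "accuracy": _round5(result.accuracy),
        "throughput": _round5(result.throughput),
        "mapping_wall_time": _round5(result.mapping_wall_time),
        "peak_memory": result.peak_memory,
        "quadrant": (
            "baseline" if result.key == baseline.key
            else assign_quadrant(result, baseline)
        ),
    }


def _best_markers(results: Sequence[BenchmarkResult]) -> tuple[str, str]:
    """Keys of the highest-accuracy ('A') and highest-throughput ('S') results."""
    by_acc = max(results, key=lambda r: (r.accuracy, _neg_label(r)))
    by_spd = max(results, key=lambda r: (r.throughput, _neg_label(r)))
    return by_acc.key, by_spd.key


class _neg_label:
    """Order helper: among ties, prefer the lexicographically smallest label."""

    def __init__(self, result: BenchmarkResult):
        self.label = (result.parameter_label, result.mapper)

    def __lt__(self, other: "_neg_label") -> bool:
        return self.label > other.label  # inverted: max() picks the smallest label

    def __eq__(self, other) -> bool:
        return self.label == other.label


def _scatter_svg(
    results: Sequence[BenchmarkResult],
    baseline: BenchmarkResult,
    a_key: str,
    s_key: str,
) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    real_mode = baseline.percent_mapped_real is not None
    with matplotlib.rc_context({"svg.hashsalt": "mapbench"}):
        fig, ax = plt.subplots(figsize=(7, 5))
        for res in results:
            x = res.throughput
            y = 100.0 * res.accuracy
            if res.key == baseline.key:
                ax.plot(x, y, "^", color="black", markersize=9, zorder=5)
            else:
                ax.plot(x, y, "o", color="0.5", markersize=6, zorder=3)
            if res.key == a_key:
                ax.annotate("A", (x, y), textcoords="offset points",
                            xytext=(6, 8), fontweight="bold")
            if res.key == s_key:
                ax.annotate("S", (x, y), textcoords="offset points",
                            xytext=(6, -12), fontweight="bold")
        ax.axhline(100.0 * baseline.accuracy, color="black", linestyle=":", linewidth=1)
        ax.axvline(baseline.throughput, color="black", linestyle=":", linewidth=1)
        ax.set_xlabel("reads per second" if real_mode else "correctly mapped reads per second")
        ax.set_ylabel("% mapped reads" if real_mode else "% correctly mapped reads")
        ax.set_title(f"dataset: {baseline.dataset} (baseline: {baseline.key})")
        buf = io.StringIO()
        fig.savefig(buf, format="svg", metadata={"Date": None})
        plt.close(fig)
    return buf.getvalue()


_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>mapbench report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin-bottom: 2em; }}
th, td {{ border: 1px solid #999; padding: 4px 8px; text-align: right; }}
th {{ background: #eee; }}
td:first-child, td:nth-child(2) {{ text-align: left; }}
</style>
</head>
<body>
<h1>Read-mapper benchmark report</h1>
<p>Baseline: <b>{baseline}</b>. Highest accuracy (A): <b>{a_key}</b>.
Highest throughput (S): <b>{s_key}</b>.</p>
<h2>Accuracy vs throughput</h2>
{svg}
<h2>Summary</h2>
{summary_table}
</body>
</html>
"""


def render_report(
    results: Sequence[BenchmarkResult],
    baseline: BenchmarkResult,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write report.json, report.tsv, and a self-contained report.html.

    Output is deterministic for identical inputs (no timestamps; the SVG is
    rendered with a fixed hash salt).
    """
    if not results:
        raise ValueError("no results to report")
    if baseline.key not in {r.key for r in results}:
        results = list(results) + [baseline]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    a_key, s_key = _best_markers(results)
    rows = [_result_row(r, baseline) for r in results]

    json_path = out_dir / "report.json"
    payload = {
        "baseline": baseline.key,
        "highest_accuracy": a_key,
        "highest_throughput": s_key,
        "results": rows,
    }
    json_path.write_text(json.dumps(payload, indent=2) + "\n")

    tsv_path = out_dir / "report.tsv"
    df = pd.DataFrame(rows)
    df.to_csv(tsv_path, sep="\t", index=False)

    html_path = out_dir / "report.html"
    html_path.write_text(_HTML_TEMPLATE.format(
        baseline=baseline.key,
        a_key=a_key,
        s_key=s_key,
        svg=_scatter_svg(results, baseline, a_key, s_key),
        summary_table=df.to_html(index=False, na_rep=""),
    ))
    return {"json": json_path, "tsv": tsv_path, "html": html_path}


def result_to_dict(result: BenchmarkResult) -> dict:
    """Lossless serialization of a result (for runs.json round trips)."""
    return {
        "mapper": result.mapper,
        "parameter_label": result.parameter_label,
        "counts": (
            {"correct": result.counts.correct, "wrong": result.counts.wrong,
             "not_mapped": result.counts.not_mapped}
            if result.counts else None
        ),
        "metrics": (
            {"precision": result.metrics.precision,
             "recall": result.metrics.recall,
             "f_measure": result.metrics.f_measure,
             "correct_per_second": result.metrics.correct_per_second,
             "percent_mapped": result.metrics.percent_mapped,
             "recall_conventional": result.metrics.recall_conventional}
            if result.metrics else None
        ),
        "mapping_wall_time": result.mapping_wall_time,
        "peak_memory": result.peak_memory,
        "dataset": result.dataset,
        "threshold": result.threshold,
        "percent_mapped_real": result.percent_mapped_real,
        "reads_per_second": result.reads_per_second,
    }


def result_from_dict(data: dict) -> BenchmarkResult:
    counts = EvalCounts(**data["counts"]) if data.get("counts") else None
    metrics = Metrics(**data["metrics"]) if data.get("metrics") else None
    return BenchmarkResult(
        mapper=data["mapper"],
        parameter_label=data["parameter_label"],
        counts=counts,
        metrics=metrics,
        mapping_wall_time=data.get("mapping_wall_time"),
        peak_memory=data.get("peak_memory"),
        dataset=data.get("dataset", "simulated"),
        threshold=data.get("threshold", 0),
        percent_mapped_real=data.get("percent_mapped_real"),
        reads_per_second=data.get("reads_per_second"),
    )
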