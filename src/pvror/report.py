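"""Ranked result tables and forest-plot exports.

Drugs are sorted from highest to lowest reporting odds, the presentation
used for head-to-head comparisons; the forest plot draws each ROR with its
confidence interval on a log-scaled axis against a dashed reference line at
one (the no-association point).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .ror import SignalResult


@dataclass
class RankedTable:
    """Signal results in non-increasing ROR order.

    Ties break by descending case count, then label; ``rounding`` is the
    display precision in decimals (full precision is kept internally and in
    CSV exports).
    """

    rows: list[SignalResult]
    rounding: int = 1


def rank_results(results: list[SignalResult], rounding: int = 1) -> RankedTable:
    """Sort results from highest to lowest ROR (stable, deterministic)."""
    if not results:
        raise ValueError("cannot rank an empty result list")
    rows = sorted(
        results, key=lambda r: (-r.estimate.ror, -r.case_count, r.label)
    )
    return RankedTable(rows=rows, rounding=rounding)


def render_rows(table: RankedTable) -> list[tuple[str, float, float, float, bool]]:
    """Display rows with rounding applied (rounding happens only here)."""
    nd = table.rounding

    def _round(x: float) -> float:
        return round(x, nd) if math.isfinite(x) else x

    return [
        (r.label, _round(r.estimate.ror), _round(r.estimate.ci_low),
         _round(r.estimate.ci_high), r.signal)
        for r in table.rows
    ]


@dataclass(frozen=True)
class ForestDatum:
    """One forest-plot row; the reference line is fixed at 1."""

    label: str
    ror: float
    ci_low: float
    ci_high: float
    reference_line: float = field(default=1.0)

    def __post_init__(self) -> None:
        if self.reference_line != 1.0:
            raise ValueError("forest reference line is fixed at 1")


def _fmt(x: float) -> str:
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return repr(x)


def forest_export(
    table: RankedTable, stem: str | Path, fig_format: str = "svg"
) -> tuple[Path, Path]:
    """Write forest data as CSV plus a rendered figure.

    ``stem`` is the output path without extension; returns (csv_path,
    figure_path). The CSV is byte-stable for a fixed table; infinite bounds
    are encoded as ``inf`` and drawn as arrow-capped markers.
    """
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    data = [
        ForestDatum(r.label, r.estimate.ror, r.estimate.ci_low, r.estimate.ci_high)
        for r in table.rows
    ]
    csv_path = stem.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "ror", "ci_low", "ci_high", "reference_line"])
        for d in data:
            w.writerow([d.label, _fmt(d.ror), _fmt(d.ci_low), _fmt(d.ci_high), "1"])

    fig_path = stem.with_suffix(f".{fig_format}")
    finite_highs = [d.ci_high for d in data if math.isfinite(d.ci_high)] or [10.0]
    cap = max(finite_highs) * 2
    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.28 * len(data) + 1)))
    ys = range(len(data), 0, -1)
    for y, d in zip(ys, data):
        hi = d.ci_high if math.isfinite(d.ci_high) else cap
        lo = max(d.ci_low, 1e-12)
        point = d.ror if math.isfinite(d.ror) else cap
        ax.plot([lo, hi], [y, y], color="steelblue", lw=1.2)
        ax.plot([point], [y], "o", color="steelblue", ms=4)
        if not math.isfinite(d.ci_high):
            ax.plot([cap], [y], ">", color="steelblue", ms=6)
    ax.axvline(1.0, ls="--", color="gray", lw=1)
    ax.set_xscale("log")
    ax.set_yticks(list(ys))
    ax.set_yticklabels([d.label for d in data], fontsize=7)
    ax.set_xlabel("reporting odds ratio (95% CI)")
    fig.tight_layout()
    # fixed hash salt / no date metadata keep SVG output byte-deterministic
    if fig_format == "svg":
        with plt.rc_context({"svg.hashsalt": "forest"}):
            fig.savefig(fig_path, metadata={"Date": None})
    else:
        fig.savefig(fig_path)
    plt.close(fig)
    return csv_path, fig_path


def ranked_to_csv(table: RankedTable, path: str | Path) -> None:
    """Ranked table at display rounding: label, ror, ci_low, ci_high, signal."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rank", "label", "ror", "ci_low", "ci_high", "signal"])
        for rank, (label, ror, lo, hi, sig) in enumerate(render_rows(table), start=1):
            w.writerow([rank, label, _fmt(ror), _fmt(lo), _fmt(hi), sig])
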