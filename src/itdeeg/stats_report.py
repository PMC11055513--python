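"""Group-level summaries, pairwise paired t-tests and report generation.

The measure table is a long-format pandas DataFrame with one row per
(participant, condition, event, window) combination and measure columns
such as ``n1p2_uV``, ``n1_lat_ms`` and ``assr_uV``.  Inference follows the
study's reduced scheme: two-sided paired t-tests for every level pair of a
factor, Bonferroni-multiplied by the number of possible pairs — except that
a two-level factor receives no correction.  Full repeated-measures GLM
machinery is deliberately not reproduced; descriptives plus the pairwise
tests cover the reported pairwise conclusions.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "measure_table",
    "load_supplementary",
    "summarize",
    "pairwise_paired_t",
    "report",
]

MEASURE_KEYS = ("participant", "condition", "event", "window")


def measure_table(records: list[dict]) -> pd.DataFrame:
    """Build a long-format measure table from per-observation dicts."""
    df = pd.DataFrame.from_records(records)
    missing = [k for k in ("participant", "condition") if k not in df.columns]
    if missing:
        raise ValueError(f"records lack required keys: {missing}")
    return df


def load_supplementary(path, column_map: dict | None = None) -> pd.DataFrame:
    """Load a deposited per-participant measure table (CSV or Excel).

    ``column_map`` renames the file's columns onto the canonical names
    (participant, condition, event, window, n1p2_uV, n1_lat_ms, assr_uV);
    the deposited file's internal layout is configurable because it is not
    standardized.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return df


def summarize(table: pd.DataFrame, by, value: str) -> pd.DataFrame:
    """Mean / median / SD / n of ``value`` grouped by ``by``."""
    g = table.groupby(by)[value]
    return g.agg(mean="mean", median="median", sd="std", n="count")


def pairwise_paired_t(table: pd.DataFrame, value: str, factor: str,
                      within: str = "participant",
                      levels: list | None = None) -> pd.DataFrame:
    """Bonferroni-multiplied pairwise paired t-tests over a factor's levels.

    Adjusted p = min(1, p_raw * C(n_levels, 2)); no correction when the
    factor has exactly two levels.  Pairs with zero-variance differences are
    flagged ``degenerate`` and reported with p = 1.
    """
    wide = table.pivot_table(index=within, columns=factor, values=value)
    if levels is None:
        levels = list(wide.columns)
    n_levels = len(levels)
    if n_levels < 2:
        raise ValueError("need at least two levels")
    n_pairs = n_levels * (n_levels - 1) // 2
    multiplier = 1 if n_levels == 2 else n_pairs
    rows = []
    for a, b in itertools.combinations(levels, 2):
        paired = wide[[a, b]].dropna()
        if len(paired) < 2:
            raise ValueError(f"fewer than 2 complete pairs for {a} vs {b}")
        diff = paired[a] - paired[b]
        if np.allclose(diff.std(ddof=1), 0):
            t, p, degenerate = np.nan, 1.0, True
        else:
            t, p = sstats.ttest_rel(paired[a], paired[b])
            degenerate = False
        rows.append({
            "level_a": a, "level_b": b, "n": len(paired),
            "t": float(t) if np.isfinite(t) else np.nan,
            "p_raw": float(p),
            "p_adj": float(min(1.0, p * multiplier)),
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def _violin(ax, table, value, factor):
    levels = sorted(table[factor].unique())
    data = [table.loc[table[factor] == lv, value].dropna().to_numpy()
            for lv in levels]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(levels) + 1), [str(lv) for lv in levels])
    ax.set_ylabel(value)
    ax.set_xlabel(factor)


def report(results_dir, table: pd.DataFrame, evokeds: dict | None = None,
           value: str = "n1p2_uV", factor: str = "condition") -> Path:
    """Write a CSV + figure bundle: summary and pairwise tables, violin
    summaries and, when evoked responses are supplied, a condition-overlay
    waveform plot.  Returns the directory path.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(results_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "measures.csv", index=False)
    by = [c for c in ("condition", "event") if c in table.columns]
    summarize(table, by, value).to_csv(out / "summary.csv")
    try:
        pairwise_paired_t(table, value, factor).to_csv(
            out / "pairwise.csv", index=False)
    except ValueError:
        pass

    fig, ax = plt.subplots(figsize=(6, 4))
    _violin(ax, table, value, factor)
    fig.tight_layout()
    fig.savefig(out / "violin.png", dpi=120)
    plt.close(fig)

    if evokeds:
        fig, ax = plt.subplots(figsize=(8, 4))
        for name, ev in evokeds.items():
            ax.plot(ev.times, ev.trace(), label=str(name), lw=0.8)
        ax.set_xlabel("time re stimulus onset (s)")
        ax.set_ylabel("amplitude (µV)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "overlay.png", dpi=120)
        plt.close(fig)

    index = out / "index.html"
    parts = ["<html><body><h1>itdeeg report</h1>"]
    for f in sorted(out.glob("*.csv")):
        parts.append(f"<p><a href='{f.name}'>{f.name}</a></p>")
    for f in sorted(out.glob("*.png")):
        parts.append(f"<img src='{f.name}' width='600'/>")
    parts.append("</body></html>")
    index.write_text("\n".join(parts))
    return out
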