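"""Figure-style reports from scan result TSVs.

Two plot families: per-pair log first-passage counts vs separation with
the fitted exponential background overlaid, and OGT vs peak amplitude q
scatter for each retained pair.  File names are deterministic
(pair + direction [+ organism]).
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np
import pandas as pd

log = logging.getLogger("fpscan")

__all__ = ["plot_background_fit", "plot_ogt_scatter", "plot_reports"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def plot_background_fit(counts: pd.DataFrame, background: pd.DataFrame,
                        x: str, y: str, direction: str, out_path: Path) -> None:
    """Log count vs L for one pair with its fitted background line."""
    sub = counts[(counts.x == x) & (counts.y == y) & (counts.direction == direction)]
    fit = background[(background.x == x) & (background.y == y)
                     & (background.direction == direction)]
    if sub.empty or fit.empty:
        return
    fit = fit.iloc[0]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.semilogy(sub.L, sub["count"], "o", ms=4, label="observed")
    Ls = np.arange(1, sub.L.max() + 1)
    ax.semilogy(Ls, np.exp(fit["intercept"] - fit["lambda"] * Ls), "-",
                label=f"background (lambda={fit['lambda']:.3f})")
    ax.set_xlabel("separation L (residues)")
    ax.set_ylabel("number of first passages")
    ax.set_title(f"{x}->{y}, {direction}-terminal, {sub.organism_id.iloc[0]}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_ogt_scatter(amplitudes: pd.DataFrame, x: str, y: str, direction: str,
                     L: int, out_path: Path) -> None:
    """OGT vs amplitude q across organisms for one retained (pair, L)."""
    sub = amplitudes[(amplitudes.x == x) & (amplitudes.y == y)
                     & (amplitudes.direction == direction) & (amplitudes.L == L)]
    sub = sub.dropna(subset=["q"])
    if sub.empty:
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    hot = sub.ogt > 60
    ax.plot(sub.q[~hot], sub.ogt[~hot], "o", color="tab:blue", label="OGT <= 60 C")
    if hot.any():
        ax.plot(sub.q[hot], sub.ogt[hot], "o", color="tab:red", label="OGT > 60 C")
    ax.set_xlabel(f"q = ln(observed/expected), {x}{y} at L={L} ({direction})")
    ax.set_ylabel("OGT (deg C)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_reports(results_dir: str | Path, out_dir: str | Path,
                 max_organisms_per_pair: int = 4) -> list[Path]:
    """Render all report figures from a scan's result TSVs.

    For every pair in ``pair_summary.tsv``: one OGT-vs-q scatter, plus
    background-fit plots for up to ``max_organisms_per_pair`` organisms.
    An empty or absent summary is a warning no-op.
    """
    results_dir, out_dir = Path(results_dir), Path(out_dir)
    summary_path = results_dir / "pair_summary.tsv"
    written: list[Path] = []
    if not summary_path.exists():
        log.warning("no pair_summary.tsv in %s; nothing to plot", results_dir)
        return written
    summary = pd.read_csv(summary_path, sep="\t")
    if summary.empty:
        log.warning("pair summary is empty; nothing to plot")
        return written
    _require_columns(summary, ["x", "y", "direction", "L"], summary_path)
    out_dir.mkdir(parents=True, exist_ok=True)

    amp_path = results_dir / "peak_amplitudes.tsv"
    amplitudes = None
    if amp_path.exists():
        amplitudes = pd.read_csv(amp_path, sep="\t")
        _require_columns(amplitudes, ["organism_id", "ogt", "x", "y", "direction",
                                      "L", "q"], amp_path)

    for _, row in summary.iterrows():
        x, y, d, L = row.x, row.y, row.direction, int(row.L)
        if amplitudes is not None:
            p = out_dir / f"ogt_vs_q_{x}{y}_{d}_L{L}.png"
            plot_ogt_scatter(amplitudes, x, y, d, L, p)
            if p.exists():
                written.append(p)
        shown = 0
        for cpath in sorted(results_dir.glob("*_counts.tsv")):
            if shown >= max_organisms_per_pair:
                break
            org = cpath.name[:-len("_counts.tsv")]
            bpath = results_dir / f"{org}_background.tsv"
            if not bpath.exists():
                continue
            counts = pd.read_csv(cpath, sep="\t")
            background = pd.read_csv(bpath, sep="\t")
            _require_columns(counts, ["organism_id", "x", "y", "direction", "L",
                                      "count"], cpath)
            _require_columns(background, ["x", "y", "direction", "lambda",
                                          "intercept"], bpath)
            p = out_dir / f"passages_{x}{y}_{d}_{org}.png"
            plot_background_fit(counts, background, x, y, d, p)
            if p.exists():
                written.append(p)
                shown += 1
    return written
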