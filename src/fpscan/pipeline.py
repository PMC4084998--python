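"""End-to-end scan orchestration: count, fit, call, aggregate, correlate.

``analyze_organism``/``analyze_study`` run the whole method in memory;
``run_scan`` wraps them with file IO (metadata + FASTAs in, TSVs and a
run log out).  All outputs are deterministic for identical inputs,
configuration and seed.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alphabet import AMINO_ACIDS
from .background import BackgroundFitSet, fit_all_pairs, frequency_table, geometric_null
from .comparative import (CorrelationResult, PairSummary, ogt_dependence,
                          summarize_pairs)
from .config import RunConfig
from .first_passage import PassageCounts, count_all_pairs
from .peaks import DeviationScores, PeakCall, call_peaks, score_all
from .proteome_io import OrganismRecord, Proteome, load_proteome, read_metadata

__all__ = ["OrganismResult", "StudyResult", "analyze_organism", "analyze_study",
           "run_scan"]

log = logging.getLogger("fpscan")


@dataclass
class OrganismResult:
    """All per-organism artifacts of one scan."""

    record: OrganismRecord
    n_residues: int
    frequencies: dict[str, float]
    counts: dict[str, PassageCounts]          # direction -> counts
    fits: dict[str, BackgroundFitSet]
    scores: dict[str, DeviationScores]
    calls: list[PeakCall]


@dataclass
class StudyResult:
    """Cross-organism aggregation of a study set."""

    organisms: list[OrganismResult]
    summaries: list[PairSummary]
    correlations: pd.DataFrame                # one row per retained pair
    failures: list[tuple[str, str]] = field(default_factory=list)

    def q_across_organisms(self, x: str, y: str, direction: str, L: int) -> np.ndarray:
        """Per-organism amplitude q at one (pair, L); NaN where undefined."""
        xi, yi = AMINO_ACIDS.index(x), AMINO_ACIDS.index(y)
        out = np.full(len(self.organisms), np.nan)
        for k, org in enumerate(self.organisms):
            sc = org.scores.get(direction)
            if sc is not None and L <= sc.l_max:
                out[k] = sc.q[xi, yi, L]
        return out

    @property
    def ogt(self) -> np.ndarray:
        return np.array([o.record.ogt for o in self.organisms])


def analyze_organism(proteome: Proteome, config: RunConfig) -> OrganismResult:
    """Count first passages, fit backgrounds, and call peaks for one organism."""
    counts, fits, scores, calls = {}, {}, {}, []
    for d in config.directions:
        pc = count_all_pairs(proteome, d)
        fs = fit_all_pairs(pc, l_min=config.l_min, l_max=config.l_max,
                           clip_sigma=config.clip_sigma)
        counts[d], fits[d] = pc, fs
        scores[d] = score_all(pc, fs, l_max=config.scan_l_max, noise=config.noise)
        calls.extend(call_peaks(pc, fs, l_max=config.scan_l_max,
                                z_thresh=config.z_thresh, noise=config.noise))
    calls.sort(key=lambda c: (-abs(c.z), c.direction, c.x, c.y, c.L))
    return OrganismResult(
        record=proteome.organism, n_residues=proteome.n_residues,
        frequencies=frequency_table(proteome),
        counts=counts, fits=fits, scores=scores, calls=calls,
    )


def _correlation_frame(summaries, study_organisms, config) -> pd.DataFrame:
    rows = []
    ogt = np.array([o.record.ogt for o in study_organisms])
    for s in summaries:
        xi, yi = AMINO_ACIDS.index(s.x), AMINO_ACIDS.index(s.y)
        q = np.full(len(study_organisms), np.nan)
        for k, org in enumerate(study_organisms):
            sc = org.scores.get(s.direction)
            if sc is not None and s.L <= sc.l_max:
                q[k] = sc.q[xi, yi, s.L]
        res = ogt_dependence(q, ogt, n_perm=config.n_perm, seed=config.seed)
        if res is None:
            continue
        pe, sp = res
        rows.append(dict(x=s.x, y=s.y, direction=s.direction, L=s.L, sign=s.sign,
                         pearson_r=pe.value, pearson_p=pe.p_value,
                         spearman_rho=sp.value, spearman_p=sp.p_value, n=pe.n))
    cols = ["x", "y", "direction", "L", "sign", "pearson_r", "pearson_p",
            "spearman_rho", "spearman_p", "n"]
    return pd.DataFrame(rows, columns=cols)


def analyze_study(proteomes: list[Proteome], config: RunConfig) -> StudyResult:
    """Run the full method over an in-memory study set."""
    config.validate()
    organisms = [analyze_organism(p, config) for p in proteomes]
    all_calls = [c for o in organisms for c in o.calls]
    scores = {(o.record.organism_id, d): sc
              for o in organisms for d, sc in o.scores.items()}
    summaries = summarize_pairs(all_calls, min_genomes=config.min_genomes,
                                qbar_scope=config.qbar_scope, scores=scores)
    correlations = _correlation_frame(summaries, organisms, config)
    return StudyResult(organisms=organisms, summaries=summaries,
                       correlations=correlations)


# ---------------------------------------------------------------- file output

_FLOAT_FMT = "%.6g"


def _write_counts_tsv(path: Path, org: OrganismResult, l_max: int) -> None:
    rows = []
    for d, pc in org.counts.items():
        hi = min(l_max, pc.l_max)
        sub = pc.counts[:, :, 1:hi + 1]
        for xi, yi, k in zip(*np.nonzero(sub)):
            rows.append((org.record.organism_id, AMINO_ACIDS[xi], AMINO_ACIDS[yi],
                         d, int(k) + 1, int(sub[xi, yi, k]), int(pc.n_anchors[xi])))
    df = pd.DataFrame(rows, columns=["organism_id", "x", "y", "direction", "L",
                                     "count", "n_anchors"])
    df.sort_values(["direction", "x", "y", "L"], inplace=True, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def _write_background_tsv(path: Path, org: OrganismResult) -> None:
    rows = []
    for d, fs in org.fits.items():
        mean_L = fs.mean_length_matrix()
        for xi, x in enumerate(AMINO_ACIDS):
            for yi, y in enumerate(AMINO_ACIDS):
                if not fs.valid[xi, yi]:
                    continue
                f_y = org.frequencies[y]
                lam = float(fs.lam[xi, yi])
                lam_geo = -np.log1p(-f_y) if 0 < f_y < 1 else np.nan
                ratio = lam_geo / lam if lam > 0 and np.isfinite(lam_geo) else np.nan
                rows.append((org.record.organism_id, x, y, d, lam,
                             float(fs.intercept[xi, yi]), float(fs.resid_sd[xi, yi]),
                             int(fs.n_points[xi, yi]), float(fs.r[xi, yi]),
                             float(fs.p_linearity[xi, yi]), lam_geo, ratio,
                             float(mean_L[xi, yi])))
    df = pd.DataFrame(rows, columns=["organism_id", "x", "y", "direction", "lambda",
                                     "intercept", "resid_sd", "n_points", "r",
                                     "p_linearity", "lam_geo", "ratio", "mean_L"])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _write_peaks_tsv(path: Path, calls: list[PeakCall]) -> None:
    df = pd.DataFrame(
        [(c.organism_id, c.x, c.y, c.direction, c.L, c.observed, c.expected,
          c.q, c.z, c.significant, c.sign) for c in calls],
        columns=["organism_id", "x", "y", "direction", "L", "observed", "expected",
                 "q", "z", "significant", "sign"])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_scan(config: RunConfig, metadata_path: str | Path, out_dir: str | Path) -> int:
    """Scan a study set from disk and write all result TSVs.

    Per organism: ``<id>_counts.tsv`` (within the scan range),
    ``<id>_background.tsv``, ``<id>_peaks.tsv`` (significant calls).
    Study-level: ``pair_summary.tsv``, ``ogt_correlations.tsv``,
    ``peak_amplitudes.tsv`` (per-organism q at each retained pair, for
    plotting), and ``run_log.txt``.

    Returns 0 on success, 1 when any organism failed (the failure is
    logged and the rest of the study still runs).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_metadata(metadata_path)
    base_dir = Path(metadata_path).parent

    log_lines = [f"fpscan {__version__}", "config:"]
    log_lines += ["  " + ln for ln in config.to_text().splitlines()]

    organisms: list[OrganismResult] = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        try:
            proteome = load_proteome(rec, policy=config.nonstandard_policy,
                                     base_dir=base_dir)
            org = analyze_organism(proteome, config)
        except Exception as exc:  # noqa: BLE001 - per-organism isolation
            log.error("organism %s failed: %s", rec.organism_id, exc)
            failures.append((rec.organism_id, str(exc)))
            log_lines.append(f"FAILED {rec.organism_id}: {exc}")
            continue
        organisms.append(org)
        log_lines.append(f"organism {rec.organism_id}: {org.n_residues} residues, "
                         f"{len(org.calls)} significant calls")
        _write_counts_tsv(out / f"{rec.organism_id}_counts.tsv", org, config.scan_l_max)
        _write_background_tsv(out / f"{rec.organism_id}_background.tsv", org)
        _write_peaks_tsv(out / f"{rec.organism_id}_peaks.tsv", org.calls)

    all_calls = [c for o in organisms for c in o.calls]
    scores = {(o.record.organism_id, d): sc
              for o in organisms for d, sc in o.scores.items()}
    summaries = summarize_pairs(all_calls, min_genomes=config.min_genomes,
                                qbar_scope=config.qbar_scope, scores=scores)
    correlations = _correlation_frame(summaries, organisms, config)

    pd.DataFrame(
        [(s.x + s.y, s.x, s.y, s.direction, s.n_genomes, s.L, s.q_bar, s.sign)
         for s in summaries],
        columns=["pair", "x", "y", "direction", "n_genomes", "L", "q_bar", "sign"],
    ).to_csv(out / "pair_summary.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    correlations.to_csv(out / "ogt_correlations.tsv", sep="\t", index=False,
                        float_format=_FLOAT_FMT)

    amp_rows = []
    study = StudyResult(organisms=organisms, summaries=summaries,
                        correlations=correlations, failures=failures)
    for s in summaries:
        q = study.q_across_organisms(s.x, s.y, s.direction, s.L)
        for org, qv in zip(organisms, q):
            amp_rows.append((org.record.organism_id, org.record.ogt,
                             s.x, s.y, s.direction, s.L, qv))
    pd.DataFrame(amp_rows, columns=["organism_id", "ogt", "x", "y", "direction",
                                    "L", "q"]).to_csv(
        out / "peak_amplitudes.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    log_lines.append(f"retained pairs: {len(summaries)}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return 1 if failures else 0
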