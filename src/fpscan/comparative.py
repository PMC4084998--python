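"""Cross-organism aggregation and growth-temperature dependence.

Significant peaks are aggregated across a study set into per-pair
summaries (in how many organisms is the peak significant, and at which
separation), and peak amplitudes q and mean first-passage lengths are
correlated with each organism's optimal growth temperature (OGT).
Pearson correlations get a Student's-t p-value; Spearman correlations get
a permutation p-value (exact enumeration for small samples, seeded Monte
Carlo otherwise).  A Kruskal-Wallis test checks that mean first-passage
lengths group by the target amino acid and not by the anchor.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alphabet import N_AA, AMINO_ACIDS
from .peaks import DeviationScores, PeakCall

__all__ = [
    "PairSummary",
    "CorrelationResult",
    "KruskalGrouping",
    "summarize_pairs",
    "pearson_with_p",
    "spearman_with_p",
    "ogt_dependence",
    "mean_length_ogt",
    "kruskal_grouping",
    "bonferroni_cutoff",
    "study_hypothesis_count",
]

#: Number of ordered amino-acid pairs tested per organism.
N_ORDERED_PAIRS = N_AA * N_AA

DEFAULT_MIN_GENOMES = 25
DEFAULT_N_PERM = 100_000
EXACT_ENUMERATION_MAX_N = 8


@dataclass
class PairSummary:
    """Cross-organism summary of one recurrent peak."""

    x: str
    y: str
    direction: str
    L: int            # modal significant separation across organisms
    n_genomes: int    # organisms where the (pair, L) peak is significant
    q_bar: float      # mean amplitude q across organisms
    sign: str         # "over" | "under"


@dataclass
class CorrelationResult:
    """A correlation coefficient with its p-value and provenance."""

    statistic: str    # "pearson_r" | "spearman_rho"
    value: float
    p_value: float
    n: int
    method_p: str     # "t_transform" | "permutation" | "permutation_exact"


@dataclass
class KruskalGrouping:
    """Kruskal-Wallis H and p for values grouped by target and by anchor."""

    h_by_target: float
    p_by_target: float
    h_by_anchor: float
    p_by_anchor: float


def summarize_pairs(calls: list[PeakCall], min_genomes: int = DEFAULT_MIN_GENOMES,
                    qbar_scope: str = "all",
                    scores: dict[tuple[str, str], DeviationScores] | None = None,
                    ) -> list[PairSummary]:
    """Aggregate significant peak calls across a study set.

    For each (pair, direction, L, sign) the number of organisms with a
    significant call is counted; combinations reaching ``min_genomes`` are
    kept and collapsed to one summary per (pair, direction, sign) at the
    modal significant L (majority vote across organisms, ties broken
    toward smaller L).

    ``qbar_scope="all"`` averages q over every organism with a defined q
    at the retained (pair, L) — this needs ``scores``, a mapping
    ``(organism_id, direction) -> DeviationScores`` covering the study
    set.  ``qbar_scope="significant"`` averages only over the organisms
    where the call is significant.
    """
    if qbar_scope not in ("all", "significant"):
        raise ValueError(f"unknown qbar_scope {qbar_scope!r}")
    if qbar_scope == "all" and scores is None:
        raise ValueError("qbar_scope='all' requires per-organism scores")

    sig = [c for c in calls if c.significant]
    by_bin: dict[tuple, dict[str, float]] = {}
    for c in sig:
        key = (c.x, c.y, c.direction, c.sign, c.L)
        by_bin.setdefault(key, {})[c.organism_id] = c.q

    # retain bins recurring in enough organisms, then take modal L per pair
    retained: dict[tuple, list[tuple[int, int]]] = {}
    for (x, y, d, sign, L), orgs in by_bin.items():
        if len(orgs) >= min_genomes:
            retained.setdefault((x, y, d, sign), []).append((L, len(orgs)))

    summaries = []
    for (x, y, d, sign), lcounts in sorted(retained.items()):
        lcounts.sort(key=lambda t: (-t[1], t[0]))  # majority vote, ties -> smaller L
        L, n_genomes = lcounts[0]
        if qbar_scope == "significant":
            qs = list(by_bin[(x, y, d, sign, L)].values())
        else:
            xi, yi = AMINO_ACIDS.index(x), AMINO_ACIDS.index(y)
            qs = [float(sc.q[xi, yi, L])
                  for (org, dd), sc in scores.items()
                  if dd == d and L <= sc.l_max and np.isfinite(sc.q[xi, yi, L])]
        q_bar = float(np.mean(qs)) if qs else math.nan
        summaries.append(PairSummary(x=x, y=y, direction=d, L=L,
                                     n_genomes=n_genomes, q_bar=q_bar, sign=sign))
    summaries.sort(key=lambda s: (-s.n_genomes, -abs(s.q_bar) if np.isfinite(s.q_bar) else 0,
                                  s.x, s.y))
    return summaries


def pearson_with_p(a, b) -> CorrelationResult:
    """Pearson r with a two-sided Student's-t p-value.

    t = r * sqrt((n - 2) / (1 - r^2)) against t with n - 2 df.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(statistic="pearson_r", value=float(r),
                             p_value=float(p), n=n, method_p="t_transform")


def _rank_rho(ra_c: np.ndarray, rb_perm: np.ndarray, norm: float) -> np.ndarray:
    return (rb_perm @ ra_c) / norm


def spearman_with_p(a, b, n_perm: int = DEFAULT_N_PERM,
                    seed: int = 0) -> CorrelationResult:
    """Spearman rho (mid-ranks on ties) with a two-sided permutation p-value.

    For n <= 8 every permutation is enumerated and the p-value is exact;
    otherwise ``n_perm`` seeded random permutations give
    ``p = (1 + #{|rho*| >= |rho|}) / (1 + n_perm)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra_c = ra - ra.mean()
    rb_c = rb - rb.mean()
    denom = math.sqrt((ra_c ** 2).sum() * (rb_c ** 2).sum())
    if denom == 0:
        raise ValueError("zero rank variance: correlation undefined")
    rho = float(ra_c @ rb_c / denom)

    tol = 1e-12
    if n <= EXACT_ENUMERATION_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_star = _rank_rho(ra_c, rb_c[perms], denom)
        p = float(np.mean(np.abs(rho_star) >= abs(rho) - tol))
        method = "permutation_exact"
    else:
        rng = np.random.default_rng(seed)
        rb_perm = rng.permuted(np.tile(rb_c, (n_perm, 1)), axis=1)
        rho_star = _rank_rho(ra_c, rb_perm, denom)
        hits = int(np.sum(np.abs(rho_star) >= abs(rho) - tol))
        p = (1 + hits) / (1 + n_perm)
        method = "permutation"
    return CorrelationResult(statistic="spearman_rho", value=rho,
                             p_value=p, n=n, method_p=method)


def ogt_dependence(q_values, ogt, n_perm: int = DEFAULT_N_PERM, seed: int = 0
                   ) -> tuple[CorrelationResult, CorrelationResult] | None:
    """Correlate per-organism peak amplitudes q with OGT.

    Organisms with undefined (NaN) q are dropped.  Returns the Pearson and
    Spearman results, or None when fewer than 3 organisms have a defined q.
    """
    q_values = np.asarray(q_values, dtype=float)
    ogt = np.asarray(ogt, dtype=float)
    ok = np.isfinite(q_values) & np.isfinite(ogt)
    if ok.sum() < 3:
        return None
    a, b = q_values[ok], ogt[ok]
    return (pearson_with_p(a, b), spearman_with_p(a, b, n_perm=n_perm, seed=seed))


def mean_length_ogt(mean_lengths, ogt, n_perm: int = DEFAULT_N_PERM,
                    seed: int = 0) -> CorrelationResult | None:
    """Spearman correlation of mean first-passage length with OGT.

    For a fixed target amino acid, a composition that grows with OGT makes
    passages to it shorter — a negative correlation.  Returns None when
    fewer than 3 organisms have a defined mean length.
    """
    m = np.asarray(mean_lengths, dtype=float)
    ogt = np.asarray(ogt, dtype=float)
    ok = np.isfinite(m) & np.isfinite(ogt)
    if ok.sum() < 3:
        return None
    return spearman_with_p(m[ok], ogt[ok], n_perm=n_perm, seed=seed)


def kruskal_grouping(mean_length_matrix) -> KruskalGrouping:
    """Kruskal-Wallis tests of a 20x20 per-pair value matrix.

    Values (typically mean first-passage lengths, anchors on rows, targets
    on columns) are grouped by target amino acid and, separately, by
    anchor; NaN entries are dropped and groups with fewer than 2 values
    are excluded from their test.
    """
    m = np.asarray(mean_length_matrix, dtype=float)
    if m.shape != (N_AA, N_AA):
        raise ValueError(f"expected a {N_AA}x{N_AA} matrix, got {m.shape}")

    def run(groups):
        groups = [g[np.isfinite(g)] for g in groups]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            return math.nan, math.nan
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:  # all values identical: no group effect at all
            return 0.0, 1.0
        h, p = stats.kruskal(*groups)
        return float(h), float(p)

    h_y, p_y = run([m[:, j] for j in range(N_AA)])
    h_x, p_x = run([m[i, :] for i in range(N_AA)])
    return KruskalGrouping(h_by_target=h_y, p_by_target=p_y,
                           h_by_anchor=h_x, p_by_anchor=p_x)


def bonferroni_cutoff(alpha: float, n_tests: int) -> float:
    """The -ln(p) significance cutoff after Bonferroni correction."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return -math.log(alpha / n_tests)


def study_hypothesis_count(n_organisms: int) -> int:
    """Total per-organism linearity hypotheses: organisms x ordered pairs."""
    if n_organisms < 1:
        raise ValueError("need at least one organism")
    return n_organisms * N_ORDERED_PAIRS
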