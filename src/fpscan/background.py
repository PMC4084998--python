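"""Exponential background fits to first-passage distributions.

The log of a first-passage distribution is typically linear in the
separation L after the first few residues, so each (x, y, direction) gets
an exponential background ``count(L) ~ exp(intercept - lam * L)`` from
ordinary least squares of ln(count) on L over a fit window below L = 50
(larger separations are dominated by finite-gene-size noise).  One
sigma-clipping pass removes strongly deviating bins — genuine peaks —
before the final fit, so a real correlation does not bias its own
background.  Fits use raw log-counts, not normalized probabilities: the
normalization shifts only the intercept, never the decay constant or the
residuals.

Under fully independent residues the first passage to ``y`` is geometric
with per-step success probability ``f_y`` (the proteome frequency of
``y``), giving the closed-form decay constant ``lam_geo = -ln(1 - f_y)``;
the ratio ``lam_geo / lam_fitted`` is near 1 when residues are
uncorrelated.  All logarithms are natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alphabet import AMINO_ACIDS, N_AA, check_residue
from .first_passage import FirstPassageTable, PassageCounts
from .proteome_io import Proteome

__all__ = [
    "BackgroundFit",
    "GeometricNull",
    "MeanFirstPassage",
    "BackgroundFitSet",
    "fit_background",
    "fit_all_pairs",
    "geometric_null",
    "mean_first_passage",
    "frequency_table",
]

DEFAULT_L_MIN = 2
DEFAULT_L_MAX = 49
DEFAULT_CLIP_SIGMA = 3.0


@dataclass
class BackgroundFit:
    """Fitted exponential background for one (x, y, direction).

    ``lam`` is the decay constant per residue (magnitude of the slope of
    ln(count) vs L); ``resid_sd`` the residual SD of log-counts on the
    retained bins; ``r`` and ``p_linearity`` the Pearson correlation of
    ln(count) with L and its two-sided t-transform p-value.
    """

    x: str
    y: str
    direction: str
    lam: float = math.nan
    intercept: float = math.nan
    resid_sd: float = math.nan
    fit_window: tuple[int, int] = (DEFAULT_L_MIN, DEFAULT_L_MAX)
    n_points: int = 0
    r: float = math.nan
    p_linearity: float = math.nan
    valid: bool = False

    def expected_count(self, L) -> np.ndarray | float:
        """Background-expected count at separation L under the fit."""
        return np.exp(self.intercept - self.lam * np.asarray(L, dtype=float))


@dataclass
class GeometricNull:
    """Independent-residue (geometric) null for target amino acid y."""

    y: str
    f_y: float
    lam_geo: float
    decay_length_geo: float
    ratio: float  # lam_geo / fitted lam; NaN when the fit's lam <= 0
    ratio_defined: bool = True


@dataclass
class MeanFirstPassage:
    """Mean first-passage length implied by a fitted background.

    Uses the discrete (geometric) closed form ``1 / (1 - exp(-lam))`` —
    the mean of the geometric law with per-step success probability
    ``1 - exp(-lam)`` — since L is integer-valued.
    """

    x: str
    y: str
    direction: str
    mean_L: float
    defined: bool = True


def _fit_rows(W: np.ndarray, Ls: np.ndarray, clip_sigma: float):
    """Vectorized OLS of ln(count) on L for many rows, one clipping pass.

    W : (M, w) nonneg counts over the window; Ls : (w,) separations.
    Returns slope, intercept, resid_sd, n_points, r, p, valid — each (M,).
    """
    W = np.asarray(W, dtype=float)
    M = W.shape[0]
    mask = W > 0
    lny = np.where(mask, np.log(np.where(mask, W, 1.0)), 0.0)

    def ols(mask):
        n = mask.sum(axis=1)
        sx = (Ls * mask).sum(axis=1)
        sy = (lny * mask).sum(axis=1)
        sxx = (Ls ** 2 * mask).sum(axis=1)
        sxy = (Ls * lny * mask).sum(axis=1)
        syy = (lny ** 2 * mask).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = n * sxx - sx ** 2
            slope = (n * sxy - sx * sy) / denom
            intercept = (sy - slope * sx) / n
            ss_y = n * syy - sy ** 2
            r = (n * sxy - sx * sy) / np.sqrt(denom * ss_y)
        return n, slope, intercept, r

    n1, slope1, icept1, _ = ols(mask)
    resid = lny - (icept1[:, None] + slope1[:, None] * Ls)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd1 = np.sqrt((resid ** 2 * mask).sum(axis=1) / np.maximum(n1 - 2, 1))
    # one clipping pass: drop bins deviating by more than clip_sigma * sd
    keep = mask & (np.abs(resid) <= clip_sigma * sd1[:, None])
    bad1 = n1 < 3
    keep[bad1] = mask[bad1]  # clipping undefined on failed first fits

    n, slope, icept, r = ols(keep)
    resid = lny - (icept[:, None] + slope[:, None] * Ls)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = np.sqrt((resid ** 2 * keep).sum(axis=1) / np.maximum(n - 2, 1))
        t = r * np.sqrt(np.maximum(n - 2, 1) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    valid = (n >= 3) & np.isfinite(slope)
    p = np.where((1.0 - r ** 2) <= 0, 0.0, p)
    return slope, icept, sd, n.astype(int), r, p, valid


def _check_window(l_min: int, l_max: int) -> None:
    if not (1 <= l_min < l_max <= 49):
        raise ValueError(f"fit window [{l_min}, {l_max}] must lie within [1, 49]")


def fit_background(table: FirstPassageTable,
                   l_min: int = DEFAULT_L_MIN, l_max: int = DEFAULT_L_MAX,
                   clip_sigma: float = DEFAULT_CLIP_SIGMA) -> BackgroundFit:
    """Fit the exponential background to one first-passage table.

    OLS of ln(count) on L over nonzero bins in ``[l_min, l_max]``, one
    sigma-clipping pass at ``clip_sigma`` residual SDs, refit on retained
    bins.  Fewer than 3 usable bins yields an invalid fit (a flag, not an
    exception), so downstream steps can skip the pair.
    """
    _check_window(l_min, l_max)
    Ls = np.arange(l_min, l_max + 1, dtype=float)
    W = table.count_array(l_max)[l_min:l_max + 1][None, :]
    slope, icept, sd, n, r, p, valid = _fit_rows(W, Ls, clip_sigma)
    return BackgroundFit(
        x=table.x, y=table.y, direction=table.direction,
        lam=float(-slope[0]), intercept=float(icept[0]), resid_sd=float(sd[0]),
        fit_window=(l_min, l_max), n_points=int(n[0]),
        r=float(r[0]), p_linearity=float(p[0]), valid=bool(valid[0]),
    )


class BackgroundFitSet:
    """Background fits for all 400 pairs of one proteome and direction.

    Attributes are (20, 20) arrays indexed by (anchor, target) in
    alphabetical amino-acid order; ``valid`` marks pairs with enough bins.
    """

    def __init__(self, lam, intercept, resid_sd, n_points, r, p_linearity,
                 valid, fit_window, direction, organism_id=""):
        self.lam = lam
        self.intercept = intercept
        self.resid_sd = resid_sd
        self.n_points = n_points
        self.r = r
        self.p_linearity = p_linearity
        self.valid = valid
        self.fit_window = fit_window
        self.direction = direction
        self.organism_id = organism_id

    def fit(self, x: str, y: str) -> BackgroundFit:
        xi, yi = check_residue(x), check_residue(y)
        return BackgroundFit(
            x=x, y=y, direction=self.direction,
            lam=float(self.lam[xi, yi]), intercept=float(self.intercept[xi, yi]),
            resid_sd=float(self.resid_sd[xi, yi]), fit_window=self.fit_window,
            n_points=int(self.n_points[xi, yi]), r=float(self.r[xi, yi]),
            p_linearity=float(self.p_linearity[xi, yi]),
            valid=bool(self.valid[xi, yi]),
        )

    def mean_length_matrix(self) -> np.ndarray:
        """Mean first-passage length per pair; NaN where undefined."""
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            m = 1.0 / (1.0 - np.exp(-self.lam))
        m = np.where(self.valid & (self.lam > 0), m, np.nan)
        return m


def fit_all_pairs(pc: PassageCounts,
                  l_min: int = DEFAULT_L_MIN, l_max: int = DEFAULT_L_MAX,
                  clip_sigma: float = DEFAULT_CLIP_SIGMA) -> BackgroundFitSet:
    """Fit the exponential background for all 400 pairs at once."""
    _check_window(l_min, l_max)
    hi = min(l_max, pc.l_max)
    Ls = np.arange(l_min, hi + 1, dtype=float)
    W = pc.counts[:, :, l_min:hi + 1].reshape(N_AA * N_AA, -1)
    slope, icept, sd, n, r, p, valid = _fit_rows(W, Ls, clip_sigma)
    shape = (N_AA, N_AA)
    return BackgroundFitSet(
        lam=(-slope).reshape(shape), intercept=icept.reshape(shape),
        resid_sd=sd.reshape(shape), n_points=n.reshape(shape),
        r=r.reshape(shape), p_linearity=p.reshape(shape),
        valid=valid.reshape(shape), fit_window=(l_min, l_max),
        direction=pc.direction, organism_id=pc.organism_id,
    )


def geometric_null(f_y: float, fit: BackgroundFit) -> GeometricNull:
    """Independent-residue geometric null and its decay-constant ratio."""
    if not (0.0 < f_y < 1.0):
        raise ValueError(f"target frequency must be in (0, 1), got {f_y}")
    lam_geo = -math.log1p(-f_y)
    if fit.valid and fit.lam > 0:
        ratio, defined = lam_geo / fit.lam, True
    else:
        ratio, defined = math.nan, False
    return GeometricNull(y=fit.y, f_y=f_y, lam_geo=lam_geo,
                         decay_length_geo=1.0 / lam_geo,
                         ratio=ratio, ratio_defined=defined)


def mean_first_passage(fit: BackgroundFit) -> MeanFirstPassage:
    """Mean first-passage length ``1 / (1 - exp(-lam))`` from a fit."""
    if fit.valid and fit.lam > 0:
        return MeanFirstPassage(fit.x, fit.y, fit.direction,
                                mean_L=1.0 / (1.0 - math.exp(-fit.lam)))
    return MeanFirstPassage(fit.x, fit.y, fit.direction,
                            mean_L=math.nan, defined=False)


def frequency_table(proteome: Proteome) -> dict[str, float]:
    """Residue frequencies over the whole proteome (sum to 1)."""
    counts = np.zeros(N_AA, dtype=np.int64)
    from .alphabet import encode
    for c in proteome.chains:
        counts += np.bincount(encode(c), minlength=N_AA)
    total = counts.sum()
    if total == 0:
        raise ValueError("proteome has no residues")
    return {aa: counts[i] / total for i, aa in enumerate(AMINO_ACIDS)}
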