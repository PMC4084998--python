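"""Scoring deviations from the exponential background and calling peaks.

The deviation statistic at separation L is ``q = ln(observed / expected)``
with the expectation taken from the fitted background — the log amplitude
of a peak above (or dip below) the background, a signal-to-noise measure.
Its z-score divides q by the fit's residual SD of log-counts (the noise
scale of the background; a Poisson-approximate alternative ``1/sqrt(count)``
is available).  A bin is a significant peak when ``|z|`` reaches the
threshold (default 3 SDs) within a single organism's proteome.

Separations below the fit window are scored against the extrapolated
fitted line, so short-range peaks (e.g. L = 2 or 3) are still comparable
to the background fitted at larger L.  Zero-count bins have undefined q
and are never called significant; under-representation calls require an
observed count > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alphabet import AMINO_ACIDS, N_AA
from .background import BackgroundFit, BackgroundFitSet
from .first_passage import FirstPassageTable, PassageCounts

__all__ = ["PeakCall", "score_deviation", "score_all", "call_peaks", "DeviationScores"]

DEFAULT_Z_THRESH = 3.0


@dataclass
class PeakCall:
    """One scored (x, y, L) deviation from the background."""

    organism_id: str
    x: str
    y: str
    direction: str
    L: int
    observed: int
    expected: float
    q: float            # ln(observed / expected); NaN when observed == 0
    z: float
    significant: bool
    sign: str           # "over" | "under" | "undefined"


def score_deviation(table: FirstPassageTable, fit: BackgroundFit, L: int,
                    z_thresh: float = DEFAULT_Z_THRESH,
                    noise: str = "fit") -> PeakCall:
    """Score the deviation of one bin of a first-passage table.

    ``noise="fit"`` uses the background fit's residual SD as the noise
    scale; ``noise="poisson"`` uses ``1/sqrt(observed)``.
    """
    if not fit.valid:
        raise ValueError(f"cannot score against an invalid fit ({fit.x},{fit.y})")
    observed = int(table.counts.get(L, 0))
    expected = float(fit.expected_count(L))
    if observed > 0:
        q = math.log(observed / expected)
        sd = fit.resid_sd if noise == "fit" else 1.0 / math.sqrt(observed)
        z = q / sd if sd > 0 else math.inf * np.sign(q) if q else 0.0
        significant = abs(z) >= z_thresh
        sign = "over" if q > 0 else "under"
    else:
        q, z, significant, sign = math.nan, math.nan, False, "undefined"
    return PeakCall(
        organism_id="", x=table.x, y=table.y, direction=table.direction,
        L=L, observed=observed, expected=expected, q=q, z=z,
        significant=significant, sign=sign,
    )


class DeviationScores:
    """Dense q and z arrays for every (pair, L) of one organism/direction.

    ``q[x, y, L]`` and ``z[x, y, L]`` are NaN where the observed count is
    zero or the pair's background fit failed; axis 2 is indexed by L.
    """

    def __init__(self, q: np.ndarray, z: np.ndarray, observed: np.ndarray,
                 expected: np.ndarray, direction: str, organism_id: str = ""):
        self.q = q
        self.z = z
        self.observed = observed
        self.expected = expected
        self.direction = direction
        self.organism_id = organism_id

    @property
    def l_max(self) -> int:
        return self.q.shape[2] - 1


def score_all(pc: PassageCounts, fits: BackgroundFitSet,
              l_max: int = 49, noise: str = "fit") -> DeviationScores:
    """Score every (pair, L) for L in [1, l_max] against the fitted background."""
    if noise not in ("fit", "poisson"):
        raise ValueError(f"unknown noise scale {noise!r}")
    hi = min(l_max, pc.l_max)
    Ls = np.arange(hi + 1, dtype=float)
    obs = pc.counts[:, :, :hi + 1].astype(float)
    with np.errstate(over="ignore"):
        exp_ = np.exp(fits.intercept[:, :, None] - fits.lam[:, :, None] * Ls)
    ok = (obs > 0) & fits.valid[:, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(ok, np.log(np.where(obs > 0, obs, 1.0) / exp_), np.nan)
        if noise == "fit":
            sd = np.broadcast_to(fits.resid_sd[:, :, None], q.shape)
        else:
            sd = 1.0 / np.sqrt(np.where(obs > 0, obs, 1.0))
        z = np.where(ok & (sd > 0), q / np.where(sd > 0, sd, 1.0), np.nan)
    q[:, :, 0] = np.nan
    z[:, :, 0] = np.nan
    return DeviationScores(q=q, z=z, observed=pc.counts[:, :, :hi + 1],
                           expected=exp_, direction=pc.direction,
                           organism_id=pc.organism_id)


def call_peaks(pc: PassageCounts, fits: BackgroundFitSet,
               l_max: int = 49, z_thresh: float = DEFAULT_Z_THRESH,
               noise: str = "fit") -> list[PeakCall]:
    """Call significant peaks for one organism and direction.

    Every (pair, L) with L in [1, l_max] is scored; calls with
    ``|z| >= z_thresh`` are returned sorted by |z| descending (ties by
    pair then L, for determinism).  Pairs whose background fit failed are
    skipped.
    """
    scores = score_all(pc, fits, l_max=l_max, noise=noise)
    with np.errstate(invalid="ignore"):
        sig = np.abs(scores.z) >= z_thresh
    calls = []
    for xi, yi, L in zip(*np.nonzero(sig)):
        qv = float(scores.q[xi, yi, L])
        calls.append(PeakCall(
            organism_id=pc.organism_id,
            x=AMINO_ACIDS[xi], y=AMINO_ACIDS[yi], direction=pc.direction,
            L=int(L), observed=int(scores.observed[xi, yi, L]),
            expected=float(scores.expected[xi, yi, L]),
            q=qv, z=float(scores.z[xi, yi, L]), significant=True,
            sign="over" if qv > 0 else "under",
        ))
    calls.sort(key=lambda c: (-abs(c.z), c.x, c.y, c.L))
    return calls
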