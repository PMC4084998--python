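"""First-passage counting on protein chains.

For every occurrence of an *anchor* amino acid ``x`` the first passage to a
*target* amino acid ``y`` is the separation ``L`` (in residues, adjacent
residues give ``L = 1``) to the first occurrence of ``y`` in the scan
direction within the same chain — intervening residues never block, and
passages never cross protein boundaries.  Scanning toward the carboxyl end
(increasing index) is direction ``"C"``; toward the amino end is ``"N"``.
Anchors whose chain ends before any ``y`` is found are *censored* and
counted separately, so that ``sum(counts) + n_censored == n_anchors``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .alphabet import AMINO_ACIDS, N_AA, check_residue, encode
from .proteome_io import Proteome

__all__ = [
    "FirstPassageTable",
    "PassageCounts",
    "count_first_passages",
    "count_all_pairs",
]

DIRECTIONS = ("N", "C")


@dataclass
class FirstPassageTable:
    """Per-(x, y, direction) first-passage event counts.

    ``counts`` maps separation ``L >= 1`` to the number of anchor
    occurrences of ``x`` whose first passage to ``y`` is exactly ``L``.
    """

    x: str
    y: str
    direction: str
    counts: dict[int, int] = field(default_factory=dict)
    n_anchors: int = 0
    n_censored: int = 0

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        check_residue(self.x)
        check_residue(self.y)
        total = sum(self.counts.values()) + self.n_censored
        if total != self.n_anchors:
            raise ValueError(
                f"count conservation violated for ({self.x},{self.y},{self.direction}): "
                f"{total} events for {self.n_anchors} anchors"
            )
        if any(L < 1 for L in self.counts):
            raise ValueError("separations must be >= 1")

    def count_array(self, l_max: int) -> np.ndarray:
        """Counts as a dense vector indexed by L (index 0 unused, length l_max+1)."""
        out = np.zeros(l_max + 1, dtype=np.int64)
        for L, c in self.counts.items():
            if L <= l_max:
                out[L] = c
        return out

    def probabilities(self) -> dict[int, float]:
        """Per-anchor first-passage probabilities (counts / n_anchors)."""
        if self.n_anchors == 0:
            return {}
        return {L: c / self.n_anchors for L, c in sorted(self.counts.items())}


def _concat_codes(proteome: Proteome):
    """Encode chains into one array plus per-position chain start/end indices."""
    lengths = np.array([len(c) for c in proteome.chains], dtype=np.int64)
    codes = np.concatenate([encode(c) for c in proteome.chains]) if len(lengths) else np.empty(0, np.uint8)
    starts = np.repeat(np.concatenate([[0], np.cumsum(lengths)[:-1]]), lengths)
    ends = np.repeat(np.cumsum(lengths) - 1, lengths)
    return codes.astype(np.int64), starts, ends


class PassageCounts:
    """All 400 first-passage tables of one proteome in one direction.

    Built in a single pass per target letter (a sorted-occurrence scan),
    O(total residues x 20) overall, rather than 400 independent scans.
    ``counts[x, y, L]`` holds the event count at separation ``L`` (axis 2 is
    indexed directly by L; index 0 is unused).
    """

    def __init__(self, counts: np.ndarray, n_anchors: np.ndarray,
                 direction: str, organism_id: str = ""):
        self.counts = counts
        self.n_anchors = n_anchors
        self.direction = direction
        self.organism_id = organism_id

    @property
    def l_max(self) -> int:
        return self.counts.shape[2] - 1

    def n_censored(self, x: str, y: str) -> int:
        xi, yi = check_residue(x), check_residue(y)
        return int(self.n_anchors[xi] - self.counts[xi, yi].sum())

    def table(self, x: str, y: str) -> FirstPassageTable:
        xi, yi = check_residue(x), check_residue(y)
        row = self.counts[xi, yi]
        nz = np.flatnonzero(row)
        counts = {int(L): int(row[L]) for L in nz}
        return FirstPassageTable(
            x=x, y=y, direction=self.direction, counts=counts,
            n_anchors=int(self.n_anchors[xi]),
            n_censored=int(self.n_anchors[xi] - row.sum()),
        )

    def __iter__(self) -> Iterator[FirstPassageTable]:
        for x in AMINO_ACIDS:
            for y in AMINO_ACIDS:
                yield self.table(x, y)


def count_all_pairs(proteome: Proteome, direction: str,
                    l_cap: int | None = None) -> PassageCounts:
    """Count first passages for all 400 ordered pairs in one direction.

    Parameters
    ----------
    proteome:
        Chains over the standard alphabet.
    direction:
        ``"C"`` scans toward increasing index, ``"N"`` toward decreasing.
    l_cap:
        Optional cap on the stored separation; events at larger L are
        treated as censored for storage (they still consume their anchor).
        Default: the longest possible separation.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if len(proteome.chains) == 0:
        raise ValueError("proteome has no chains")

    codes, starts, ends = _concat_codes(proteome)
    n = codes.size
    max_len = max(len(c) for c in proteome.chains)
    l_max = max_len - 1 if l_cap is None else min(l_cap, max_len - 1)
    l_max = max(l_max, 1)

    counts = np.zeros((N_AA, N_AA, l_max + 1), dtype=np.int64)
    n_anchors = np.bincount(codes, minlength=N_AA).astype(np.int64)
    idx = np.arange(n, dtype=np.int64)

    for yi in range(N_AA):
        ypos = np.flatnonzero(codes == yi)
        if ypos.size == 0:
            continue
        if direction == "C":
            k = np.searchsorted(ypos, idx, side="right")
            hit = np.empty(n, dtype=np.int64)
            ok = k < ypos.size
            hit[ok] = ypos[k[ok]]
            L = hit - idx
            valid = ok & (hit <= ends)
        else:
            k = np.searchsorted(ypos, idx, side="left") - 1
            hit = np.empty(n, dtype=np.int64)
            ok = k >= 0
            hit[ok] = ypos[k[ok]]
            L = idx - hit
            valid = ok & (hit >= starts)
        valid &= L <= l_max  # events beyond the cap stay censored
        key = codes[valid] * (l_max + 1) + L[valid]
        binc = np.bincount(key, minlength=N_AA * (l_max + 1))
        counts[:, yi, :] = binc.reshape(N_AA, l_max + 1)

    return PassageCounts(counts, n_anchors, direction,
                         organism_id=proteome.organism.organism_id)


def count_first_passages(proteome: Proteome, x: str, y: str,
                         direction: str) -> FirstPassageTable:
    """First-passage table for a single ordered pair (x, y).

    Self-pairs (x == y) follow the same rule: the anchor itself never
    counts as the target.
    """
    xi, yi = check_residue(x), check_residue(y)
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if len(proteome.chains) == 0:
        raise ValueError("proteome has no chains")

    codes, starts, ends = _concat_codes(proteome)
    anchors = np.flatnonzero(codes == xi)
    ypos = np.flatnonzero(codes == yi)

    if anchors.size == 0:
        return FirstPassageTable(x=x, y=y, direction=direction)

    if ypos.size == 0:
        return FirstPassageTable(x=x, y=y, direction=direction,
                                 n_anchors=int(anchors.size),
                                 n_censored=int(anchors.size))

    if direction == "C":
        k = np.searchsorted(ypos, anchors, side="right")
        ok = k < ypos.size
        hit = np.where(ok, ypos[np.minimum(k, ypos.size - 1)], -1)
        valid = ok & (hit <= ends[anchors])
        L = hit - anchors
    else:
        k = np.searchsorted(ypos, anchors, side="left") - 1
        ok = k >= 0
        hit = np.where(ok, ypos[np.maximum(k, 0)], -1)
        valid = ok & (hit >= starts[anchors])
        L = anchors - hit

    lvals, lcounts = np.unique(L[valid], return_counts=True)
    return FirstPassageTable(
        x=x, y=y, direction=direction,
        counts={int(a): int(b) for a, b in zip(lvals, lcounts)},
        n_anchors=int(anchors.size),
        n_censored=int(anchors.size - valid.sum()),
    )
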