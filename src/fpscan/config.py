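"""Run configuration for the scan pipeline.

A flat key=value config file (``#`` comments allowed) can set any field;
CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunables of the first-passage scan.

    l_min, l_max : int
        Background fit window in residue separations, within [1, 49].
    clip_sigma : float
        Sigma-clipping threshold (residual SDs) for the one clipping pass
        of the background fit.
    z_thresh : float
        Peak-call threshold on |z| (SDs from the background).
    scan_l_max : int
        Largest separation scored for peaks.
    min_genomes : int
        Minimum number of organisms in which a peak must be significant
        to be retained in the cross-organism summary.
    directions : tuple[str, ...]
        Scan directions, subset of ("N", "C").
    nonstandard_policy : str
        "split" or "drop_chain" handling of nonstandard residues.
    noise : str
        Peak noise scale: "fit" (background residual SD) or "poisson".
    qbar_scope : str
        "all" or "significant" organisms entering the mean amplitude.
    n_perm : int
        Permutations for Spearman p-values.
    seed : int
        Seed for every stochastic step (permutation tests).
    """

    l_min: int = 2
    l_max: int = 49
    clip_sigma: float = 3.0
    z_thresh: float = 3.0
    scan_l_max: int = 49
    min_genomes: int = 25
    directions: tuple[str, ...] = ("N", "C")
    nonstandard_policy: str = "split"
    noise: str = "fit"
    qbar_scope: str = "all"
    n_perm: int = 100_000
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not (1 <= self.l_min < self.l_max <= 49):
            raise ValueError("fit window must satisfy 1 <= l_min < l_max <= 49")
        if self.clip_sigma <= 0 or self.z_thresh <= 0:
            raise ValueError("clip_sigma and z_thresh must be positive")
        if not (1 <= self.scan_l_max <= 49):
            raise ValueError("scan_l_max must be in [1, 49]")
        if self.min_genomes < 1:
            raise ValueError("min_genomes must be >= 1")
        if not self.directions or any(d not in ("N", "C") for d in self.directions):
            raise ValueError("directions must be a non-empty subset of {'N','C'}")
        if self.nonstandard_policy not in ("split", "drop_chain"):
            raise ValueError("nonstandard_policy must be 'split' or 'drop_chain'")
        if self.noise not in ("fit", "poisson"):
            raise ValueError("noise must be 'fit' or 'poisson'")
        if self.qbar_scope not in ("all", "significant"):
            raise ValueError("qbar_scope must be 'all' or 'significant'")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        return self

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "directions":
                v = ",".join(v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"


_INT_KEYS = {"l_min", "l_max", "scan_l_max", "min_genomes", "n_perm", "seed"}
_FLOAT_KEYS = {"clip_sigma", "z_thresh"}


def load_config(path: str | Path, base: RunConfig | None = None) -> RunConfig:
    """Load a flat key=value config file on top of defaults (or ``base``)."""
    cfg = base or RunConfig()
    known = {f.name for f in fields(cfg)}
    updates: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _INT_KEYS:
            updates[key] = int(val)
        elif key in _FLOAT_KEYS:
            updates[key] = float(val)
        elif key == "directions":
            updates[key] = tuple(s.strip() for s in val.split(",") if s.strip())
        else:
            updates[key] = val
    return replace(cfg, **updates).validate()
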