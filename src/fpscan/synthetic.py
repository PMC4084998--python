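"""Synthetic proteomes with controlled statistical structure.

The generator emulates the statistics the analysis pipeline is built to
detect, without any real sequence data: chains drawn iid from a chosen
amino-acid composition (an exponential/geometric first-passage background
by construction), an optional growth-temperature trend on the composition,
and optional planted lag correlations.  A planted effect (x, y, lag, eps)
is applied by scanning each chain left to right and, at each occurrence of
``x``, overwriting the residue ``lag`` positions downstream with ``y``
with probability ``eps`` — a post-hoc substitution rather than a Markov
chain, so the correlation sits at exactly the planted lag and the ground
truth is a clean single peak.  Later overwrites win; overwrites that
create new ``x`` occurrences (self-pairs) are themselves scanned.

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS, N_AA, check_residue, typical_frequency_vector
from .proteome_io import OrganismRecord, Proteome, write_fasta, write_metadata

__all__ = [
    "PlantedEffect",
    "StudyEffect",
    "SyntheticSpec",
    "generate_proteome",
    "generate_study",
]

_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)

#: Geometric chain lengths with this mean emulate the typical protein
#: scale; the floor keeps every chain long enough to exercise censoring.
DEFAULT_MEAN_LENGTH = 350
DEFAULT_MIN_LENGTH = 30
#: Reference temperature at which trend-adjusted compositions equal the base.
TREND_REFERENCE_OGT = 25.0


@dataclass(frozen=True)
class PlantedEffect:
    """A lag correlation planted into one proteome."""

    x: str
    y: str
    lag: int
    eps: float

    def __post_init__(self) -> None:
        check_residue(self.x)
        check_residue(self.y)
        if not (1 <= self.lag <= 49):
            raise ValueError(f"planted lag must be in [1, 49], got {self.lag}")
        if not (0.0 <= self.eps <= 1.0):
            raise ValueError(f"planted strength must be in [0, 1], got {self.eps}")


@dataclass(frozen=True)
class StudyEffect:
    """A planted effect whose strength varies linearly with pseudo-OGT.

    The per-organism strength is ``eps0 + eps_per_degc * ogt``, clipped to
    [0, 1]; a constant effect has ``eps_per_degc = 0``.
    """

    x: str
    y: str
    lag: int
    eps0: float
    eps_per_degc: float = 0.0

    def at(self, ogt: float) -> PlantedEffect:
        eps = min(1.0, max(0.0, self.eps0 + self.eps_per_degc * ogt))
        return PlantedEffect(self.x, self.y, self.lag, eps)


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic proteome."""

    n_proteins: int = 200
    length_mode: str = "geometric"      # "geometric" | "fixed"
    mean_length: int = DEFAULT_MEAN_LENGTH
    min_length: int = DEFAULT_MIN_LENGTH
    base_frequencies: np.ndarray | None = None   # 20-vector, sums to 1
    ogt: float = TREND_REFERENCE_OGT
    frequency_trend: dict[str, float] = field(default_factory=dict)  # slope per degC
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    seed: int = 0
    organism_id: str = "synthetic"
    name: str = "synthetic organism"

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.length_mode not in ("geometric", "fixed"):
            raise ValueError(f"unknown length_mode {self.length_mode!r}")
        if self.min_length < 1 or self.mean_length < self.min_length:
            raise ValueError("need mean_length >= min_length >= 1")
        f = self.frequencies()
        if (f <= 0).any() or not np.isclose(f.sum(), 1.0):
            raise ValueError("frequencies must be positive and sum to 1")
        for aa in self.frequency_trend:
            check_residue(aa)
        for e in self.planted_effects:
            if not isinstance(e, PlantedEffect):
                raise ValueError("planted_effects must contain PlantedEffect items")

    def frequencies(self) -> np.ndarray:
        """Trend-adjusted, renormalized composition at this spec's OGT."""
        base = (typical_frequency_vector() if self.base_frequencies is None
                else np.asarray(self.base_frequencies, dtype=float))
        if base.shape != (N_AA,):
            raise ValueError(f"base_frequencies must have length {N_AA}")
        if (base <= 0).any():
            raise ValueError("base_frequencies must be strictly positive")
        f = base / base.sum()
        if self.frequency_trend:
            f = f.copy()
            for aa, slope in self.frequency_trend.items():
                i = check_residue(aa)
                f[i] = f[i] + slope * (self.ogt - TREND_REFERENCE_OGT)
            f = np.maximum(f, 1e-5)
            f = f / f.sum()
        return f


def _plant(chain: np.ndarray, effect: PlantedEffect, rng: np.random.Generator) -> None:
    """Overwrite-plant one effect, scanning x occurrences left to right."""
    xi, yi = check_residue(effect.x), check_residue(effect.y)
    positions = np.flatnonzero(chain == xi).tolist()
    n = chain.size
    while positions:
        i = heapq.heappop(positions)
        if chain[i] != xi:     # an earlier overwrite removed this anchor
            continue
        j = i + effect.lag
        if j < n and rng.random() < effect.eps:
            was = chain[j]
            chain[j] = yi
            if yi == xi and was != xi:
                heapq.heappush(positions, j)


def generate_proteome(spec: SyntheticSpec) -> Proteome:
    """Draw one synthetic proteome; byte-identical for identical specs."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.length_mode == "fixed":
        lengths = np.full(spec.n_proteins, spec.mean_length, dtype=np.int64)
    else:
        # shifted geometric: min_length + Geom(mean - min_length + 1) - 1
        excess = spec.mean_length - spec.min_length
        if excess <= 0:
            lengths = np.full(spec.n_proteins, spec.min_length, dtype=np.int64)
        else:
            lengths = spec.min_length + rng.geometric(1.0 / (excess + 1),
                                                      size=spec.n_proteins) - 1
    freqs = spec.frequencies()
    total = int(lengths.sum())
    flat = rng.choice(N_AA, size=total, p=freqs).astype(np.uint8)
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    chains = []
    for k in range(spec.n_proteins):
        chain = flat[bounds[k]:bounds[k + 1]].copy()
        for effect in spec.planted_effects:
            if effect.eps > 0:
                _plant(chain, effect, rng)
        chains.append(_AA_BYTES[chain].tobytes().decode("ascii"))
    record = OrganismRecord(organism_id=spec.organism_id, name=spec.name,
                            ogt=spec.ogt, fasta_path="")
    return Proteome(organism=record, chains=chains)


def generate_study(n_organisms: int, ogt_range: tuple[float, float] = (5.0, 100.0),
                   effects: list[StudyEffect] | None = None,
                   frequency_trend: dict[str, float] | None = None,
                   seed: int = 0, out_dir: str | Path | None = None,
                   **spec_kwargs) -> tuple[list[OrganismRecord], list[Proteome]]:
    """Generate a whole synthetic study set.

    Pseudo-OGTs are evenly spaced over ``ogt_range``; each ``StudyEffect``
    and the optional composition trend are evaluated at the organism's
    OGT.  Per-organism seeds are spawned from ``seed``.  With ``out_dir``
    the FASTAs and a ``metadata.tsv`` consumable by the pipeline are
    written there; the study is also returned in memory either way.
    ``spec_kwargs`` pass through to :class:`SyntheticSpec` (e.g.
    ``n_proteins``, ``mean_length``).
    """
    if n_organisms < 2:
        raise ValueError("a study needs at least 2 organisms")
    lo, hi = ogt_range
    ogts = np.linspace(lo, hi, n_organisms)
    children = np.random.SeedSequence(seed).spawn(n_organisms)
    effects = effects or []
    records, proteomes = [], []
    for k in range(n_organisms):
        ogt = float(ogts[k])
        org_id = f"syn{k:03d}"
        spec = SyntheticSpec(
            ogt=ogt,
            frequency_trend=dict(frequency_trend or {}),
            planted_effects=[e.at(ogt) for e in effects],
            seed=int(children[k].generate_state(1)[0]),
            organism_id=org_id,
            name=f"synthetic organism {k}",
            **spec_kwargs,
        )
        fasta_name = f"{org_id}.fasta"
        proteome = generate_proteome(spec)
        record = replace(proteome.organism, fasta_path=fasta_name)
        proteome.organism = record
        records.append(record)
        proteomes.append(proteome)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, prot in zip(records, proteomes):
            write_fasta(out_dir / rec.fasta_path, prot.chains,
                        ids=[f"{rec.organism_id}_p{i + 1}" for i in range(len(prot.chains))])
        write_metadata(out_dir / "metadata.tsv", records)
    return records, proteomes
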