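"""Reading proteome FASTA files and the organism metadata table.

A *proteome* is an organism's set of protein chains together with its
metadata (identifier, optimal growth temperature).  Sequences are read
N-to-C as written in FASTA.  Chains are normalized onto the 20-letter
standard alphabet before analysis; the two supported policies for
nonstandard residues are

``split``
    cut each sequence at every nonstandard character, producing standard
    sub-chains (the default: an ambiguous residue never anchors nor
    terminates a passage and never contributes to a separation distance);
``drop_chain``
    discard whole sequences containing any nonstandard character.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .alphabet import AMINO_ACIDS, is_standard

__all__ = [
    "OrganismRecord",
    "Proteome",
    "read_fasta",
    "write_fasta",
    "normalize_chains",
    "read_metadata",
    "write_metadata",
]

_NONSTANDARD = re.compile(f"[^{AMINO_ACIDS}]+")

METADATA_COLUMNS = ("organism_id", "name", "ogt_celsius", "fasta_path")


@dataclass(frozen=True)
class OrganismRecord:
    """One organism of a study set.

    Parameters
    ----------
    organism_id:
        Unique token identifying the organism within the study.
    name:
        Free-text organism name.
    ogt:
        Optimal growth temperature in degrees Celsius.
    fasta_path:
        Path to the organism's proteome FASTA.
    """

    organism_id: str
    name: str = ""
    ogt: float = float("nan")
    fasta_path: str = ""


@dataclass
class Proteome:
    """An organism's protein chains over the 20-letter standard alphabet.

    Chain boundaries are preserved: first passages never cross proteins.
    """

    organism: OrganismRecord
    chains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.chains:
            if not c:
                raise ValueError("empty chain in proteome")
            if not is_standard(c):
                raise ValueError(f"nonstandard residue in chain {c[:20]!r}...")

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def __len__(self) -> int:
        return len(self.chains)


def read_fasta(path: str | Path, *, with_ids: bool = False):
    """Read protein sequences from a multi-FASTA file, in file order.

    Sequences are uppercased; headers are discarded unless ``with_ids``.

    Raises
    ------
    ValueError
        on an empty file or a record with an empty sequence (the record id
        is named in the message).
    """
    path = Path(path)
    seqs: list[str] = []
    ids: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if not s:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        seqs.append(s)
        ids.append(rec.id)
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    if with_ids:
        return seqs, ids
    return seqs


def write_fasta(path: str | Path, seqs: Sequence[str], ids: Sequence[str] | None = None,
                width: int = 60) -> None:
    """Write sequences as multi-FASTA (wrap at ``width`` columns)."""
    path = Path(path)
    if ids is None:
        ids = [f"p{i + 1}" for i in range(len(seqs))]
    with open(path, "w") as fh:
        for name, s in zip(ids, seqs):
            fh.write(f">{name}\n")
            for j in range(0, len(s), width):
                fh.write(s[j:j + width] + "\n")


def normalize_chains(raw: Iterable[str], policy: str = "split") -> list[str]:
    """Normalize raw sequences onto the standard alphabet.

    Under ``split`` each sequence is cut at every nonstandard character and
    the non-empty standard fragments are kept, in order.  Under
    ``drop_chain`` any sequence containing a nonstandard character is
    discarded whole.
    """
    if policy not in ("split", "drop_chain"):
        raise ValueError(f"unknown nonstandard-residue policy {policy!r}")
    chains: list[str] = []
    for s in raw:
        s = s.upper()
        if policy == "drop_chain":
            if is_standard(s):
                chains.append(s)
            continue
        for frag in _NONSTANDARD.split(s):
            if frag:
                chains.append(frag)
    return chains


def load_proteome(record: OrganismRecord, policy: str = "split",
                  base_dir: str | Path | None = None) -> Proteome:
    """Read and normalize one organism's proteome from its FASTA path."""
    p = Path(record.fasta_path)
    if base_dir is not None and not p.is_absolute():
        p = Path(base_dir) / p
    raw = read_fasta(p)
    return Proteome(organism=record, chains=normalize_chains(raw, policy=policy))


def read_metadata(path: str | Path) -> list[OrganismRecord]:
    """Read the organism metadata TSV.

    Expects a header with columns ``organism_id``, ``name``,
    ``ogt_celsius``, ``fasta_path``.  OGT must parse as a real number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"metadata file {path} is missing column {col!r}")
    records = []
    for i, row in df.iterrows():
        try:
            ogt = float(row["ogt_celsius"])
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric OGT {row['ogt_celsius']!r} in metadata row {i + 1}"
            ) from None
        records.append(OrganismRecord(
            organism_id=str(row["organism_id"]),
            name=str(row["name"]),
            ogt=ogt,
            fasta_path=str(row["fasta_path"]),
        ))
    ids = [r.organism_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate organism_id in metadata file {path}")
    return records


def write_metadata(path: str | Path, records: Sequence[OrganismRecord]) -> None:
    df = pd.DataFrame(
        [(r.organism_id, r.name, r.ogt, r.fasta_path) for r in records],
        columns=list(METADATA_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)
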