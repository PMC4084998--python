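"""The 20-letter standard amino-acid alphabet and integer encodings.

Chains are modelled over the 20 canonical residues only; everything else
(X, B, Z, J, U, O, ``*``, gaps) is "nonstandard" and handled by the
normalization policies in :mod:`fpscan.proteome_io`.
"""

from __future__ import annotations

import numpy as np

#: Canonical one-letter codes, alphabetical order. Index in this string is
#: the integer code used throughout the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

N_AA = len(AMINO_ACIDS)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# byte-value -> code lookup (255 marks nonstandard) for fast encoding
_LOOKUP = np.full(256, 255, dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    _LOOKUP[ord(_aa)] = _i

#: Typical proteome residue composition (fractions, renormalized from
#: large-scale protein-database averages); the synthetic generator's default.
TYPICAL_FREQUENCIES: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}


def check_residue(aa: str) -> int:
    """Return the integer code of a single residue letter, or raise ValueError."""
    code = AA_INDEX.get(aa)
    if code is None:
        raise ValueError(f"not a standard amino-acid letter: {aa!r}")
    return code


def encode(chain: str) -> np.ndarray:
    """Encode a standard-alphabet chain as a uint8 code array."""
    arr = _LOOKUP[np.frombuffer(chain.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = chain[int(np.argmax(arr == 255))]
        raise ValueError(f"nonstandard residue {bad!r} in chain")
    return arr


def is_standard(chain: str) -> bool:
    try:
        arr = _LOOKUP[np.frombuffer(chain.encode("ascii"), dtype=np.uint8)]
    except UnicodeEncodeError:
        return False
    return not bool((arr == 255).any())


def typical_frequency_vector() -> np.ndarray:
    """Typical composition as a 20-vector in AMINO_ACIDS order, summing to 1."""
    v = np.array([TYPICAL_FREQUENCIES[aa] for aa in AMINO_ACIDS], dtype=float)
    return v / v.sum()
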