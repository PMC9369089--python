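"""Per-nucleotide encodings and their concatenation into the model input.

Three encodings are applied to each base and concatenated position-wise:

* one-hot — 4-dimensional indicator, order (A, T, C, G);
* NCP (nucleotide chemical properties) — 3 binary coordinates: ring
  structure (purine=1), hydrogen-bond strength (weak=1), functional group
  (amino=1);
* EIIP (electron–ion interaction potential) — one physical scalar per base.

A 41-bp window therefore becomes a 41x8 matrix ([one-hot | NCP | EIIP]),
flattened row-major to a 328-long feature vector in which each position's
8 features stay contiguous.
"""

from __future__ import annotations

import numpy as np

from .sequence_io import DnaSequence, LabeledDataset

ONE_HOT = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "T": (0.0, 1.0, 0.0, 0.0),
    "C": (0.0, 0.0, 1.0, 0.0),
    "G": (0.0, 0.0, 0.0, 1.0),
}

NCP = {
    "A": (1.0, 1.0, 1.0),
    "T": (0.0, 1.0, 0.0),
    "C": (0.0, 0.0, 1.0),
    "G": (1.0, 0.0, 0.0),
}

# Electron–ion interaction potentials, stored exactly as tabulated to four
# decimal places; no rescaling is applied.
EIIP = {"A": 0.1260, "T": 0.1335, "C": 0.1340, "G": 0.0806}

#: Width of the concatenated per-position block.
BLOCK_WIDTH = 8

# Precomputed 8-vector per base: one-hot ++ NCP ++ EIIP.
_BLOCK = {b: np.array(ONE_HOT[b] + NCP[b] + (EIIP[b],)) for b in "ATCG"}


class EncodingError(ValueError):
    """A residue outside {A,C,G,T} was met; names the offending position."""


def _residues(seq: DnaSequence | str) -> str:
    return seq.residues if isinstance(seq, DnaSequence) else seq


def _check(residues: str) -> None:
    for i, base in enumerate(residues):
        if base not in _BLOCK:
            raise EncodingError(f"position {i + 1}: residue '{base}' is not in ACGT")


def encode_one_hot(seq: DnaSequence | str) -> np.ndarray:
    """L x 4 indicator matrix, row i = one-hot vector of residue i."""
    residues = _residues(seq)
    _check(residues)
    return np.array([ONE_HOT[b] for b in residues])


def encode_ncp(seq: DnaSequence | str) -> np.ndarray:
    """L x 3 chemical-property matrix."""
    residues = _residues(seq)
    _check(residues)
    return np.array([NCP[b] for b in residues])


def encode_eiip(seq: DnaSequence | str) -> np.ndarray:
    """L x 1 matrix of electron–ion interaction potentials."""
    residues = _residues(seq)
    _check(residues)
    return np.array([[EIIP[b]] for b in residues])


def encode_concat(seq: DnaSequence | str) -> np.ndarray:
    """L x 8 concatenation [one-hot | NCP | EIIP]; 41 x 8 at default length."""
    residues = _residues(seq)
    _check(residues)
    return np.stack([_BLOCK[b] for b in residues])


def flatten(matrix: np.ndarray) -> np.ndarray:
    """Row-major (position-major) flattening of an L x 8 matrix to length 8L."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {matrix.shape}")
    return matrix.reshape(-1)


def unflatten(vector: np.ndarray, width: int = BLOCK_WIDTH) -> np.ndarray:
    """Exact inverse of :func:`flatten`."""
    vector = np.asarray(vector)
    if vector.size % width:
        raise ValueError(f"length {vector.size} is not a multiple of {width}")
    return vector.reshape(-1, width)


def encode_dataset(dataset: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Encode every sequence; returns (n x 8L feature matrix, label vector)."""
    X = np.stack([flatten(encode_concat(s)) for s in dataset.sequences])
    y = np.asarray(dataset.labels, dtype=float)
    return X, y
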