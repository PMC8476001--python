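"""CDR3 encodings for the sequence models.

Two encodings are provided:

* aligned one-hot — a fixed-width alignment row over 21 symbols (20 residues
  plus the gap) becomes an ``(n_sites, 21)`` indicator matrix;
* Left+Right — a binary vector marking the presence of each residue at each
  distance from the left and from the right end of the unaligned CDR3, up to
  a reference length (default 19), giving 19 x 20 x 2 = 760 features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import (
    AA_INDEX,
    AMINO_ACIDS,
    ALPHABET,
    N_AA,
    N_STATES,
    SYMBOL_INDEX,
)

DEFAULT_REF_LENGTH = 19


@dataclass
class AlignedEncoding:
    matrix: np.ndarray  # (n_sites, 21) one-hot
    n_sites: int
    n_states: int = N_STATES

    def decode(self) -> str:
        idx = self.matrix.argmax(axis=1)
        return "".join(ALPHABET[i] for i in idx)


@dataclass
class LeftRightEncoding:
    """Binary Left+Right feature vector.

    Layout: the left block comes first, position-major then residue
    (feature ``pos * 20 + aa``); the right block follows at offset
    ``ref_length * 20`` with the same internal layout. ``flagged`` marks
    sequences longer than ``ref_length`` where a middle residue can carry
    both an L and an R feature.
    """

    vector: np.ndarray
    ref_length: int
    flagged: bool = False


def one_hot_aligned(aligned: str, n_sites: int | None = None) -> AlignedEncoding:
    """One-hot encode a gapped, fixed-width alignment row."""
    if n_sites is not None and len(aligned) != n_sites:
        raise ValueError(f"aligned width {len(aligned)} != expected {n_sites}")
    mat = np.zeros((len(aligned), N_STATES))
    for i, c in enumerate(aligned):
        j = SYMBOL_INDEX.get(c)
        if j is None:
            raise ValueError(f"unknown symbol {c!r} at position {i}")
        mat[i, j] = 1.0
    return AlignedEncoding(mat, n_sites=len(aligned))


def encode_indices(aligned: str) -> np.ndarray:
    """Integer state indices of an alignment row (compact one-hot)."""
    try:
        return np.fromiter((SYMBOL_INDEX[c] for c in aligned), dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"unknown symbol {e.args[0]!r} in {aligned!r}") from None


def decode_indices(idx: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in idx)


def left_right_encode(cdr3: str, ref_length: int = DEFAULT_REF_LENGTH) -> LeftRightEncoding:
    """Left+Right binary encoding of an unaligned CDR3.

    The first residue has left distance 0, the last has right distance 0.
    Distances at or beyond ``ref_length`` contribute no feature; such
    sequences (length > ref_length) are flagged.
    """
    if len(cdr3) < 1:
        raise ValueError("empty CDR3")
    vec = np.zeros(ref_length * N_AA * 2, dtype=np.int8)
    l = len(cdr3)
    for i, c in enumerate(cdr3):
        a = AA_INDEX.get(c)
        if a is None:
            raise ValueError(f"non-canonical residue {c!r} at position {i}")
        if i < ref_length:
            vec[i * N_AA + a] = 1
        d_right = l - 1 - i
        if d_right < ref_length:
            vec[ref_length * N_AA + d_right * N_AA + a] = 1
    return LeftRightEncoding(vec, ref_length=ref_length, flagged=l > ref_length)


def left_right_decode(enc: LeftRightEncoding) -> str:
    """Invert the Left+Right encoding for sequences of length <= ref_length."""
    ref = enc.ref_length
    left = enc.vector[: ref * N_AA].reshape(ref, N_AA)
    ones_per_pos = left.sum(axis=1)
    l = int(ones_per_pos.sum())
    if enc.flagged or l > ref:
        raise ValueError("decode undefined for sequences longer than ref_length")
    return "".join(AMINO_ACIDS[int(np.argmax(left[i]))] for i in range(l))


def one_hot_dataset(aligned_rows: list[str]) -> np.ndarray:
    """Stack compact index encodings of equal-width alignment rows."""
    widths = {len(r) for r in aligned_rows}
    if len(widths) != 1:
        raise ValueError("rows have unequal widths")
    return np.stack([encode_indices(r) for r in aligned_rows])
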