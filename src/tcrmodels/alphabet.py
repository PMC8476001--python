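"""Amino-acid alphabet shared across the package.

The visible alphabet has 21 states: the 20 canonical residues plus the
alignment gap ``-`` as the last state.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
ALPHABET: str = AMINO_ACIDS + GAP

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
SYMBOL_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}

N_AA: int = len(AMINO_ACIDS)
N_STATES: int = len(ALPHABET)
GAP_INDEX: int = SYMBOL_INDEX[GAP]


def is_valid_cdr3(seq: str) -> bool:
    """True if every character is one of the 20 canonical residues."""
    return len(seq) >= 1 and all(c in AA_INDEX for c in seq)


def validate_cdr3(seq: str) -> None:
    if not seq:
        raise ValueError("CDR3 sequence is empty")
    for pos, c in enumerate(seq):
        if c not in AA_INDEX:
            raise ValueError(
                f"non-canonical residue {c!r} at position {pos} in {seq!r}"
            )
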