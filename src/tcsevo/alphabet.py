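"""Amino-acid alphabet, integer encoding, and gap conventions.

Sequences are handled internally as ``int8`` arrays with values 0..19 for the
twenty canonical amino acids (alphabetical one-letter order) and ``GAP_CODE``
(20) for a gap.  Ambiguous one-letter codes (B, Z, X, U, O, J) carry no usable
frequency information for the statistics computed here and are normalized to
gaps by the readers, with a tally so the caller can log them.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_AA: int = 20
GAP: str = "-"
GAP_CODE: int = 20
AMBIGUOUS: frozenset[str] = frozenset("BZXUOJ")

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# lookup table over raw byte values; unknown/ambiguous -> GAP_CODE
_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _ENCODE_LUT[ord(_aa)] = _i
    _ENCODE_LUT[ord(_aa.lower())] = _i
for _c in AMBIGUOUS:
    _ENCODE_LUT[ord(_c)] = GAP_CODE
    _ENCODE_LUT[ord(_c.lower())] = GAP_CODE
for _g in "-.":
    _ENCODE_LUT[ord(_g)] = GAP_CODE


class AlphabetError(ValueError):
    """A character is neither a canonical residue, an ambiguity code, nor a gap."""


def encode(seq: str) -> np.ndarray:
    """Encode a residue string to int8 codes (gap/ambiguous -> GAP_CODE).

    Raises :class:`AlphabetError` on characters outside the protein alphabet.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if (codes < 0).any():
        bad = {seq[i] for i in np.nonzero(codes < 0)[0]}
        raise AlphabetError(f"unknown residue character(s): {sorted(bad)!r}")
    return codes.astype(np.int8)


def count_ambiguous(seq: str) -> int:
    """Number of ambiguity-code characters that ``encode`` will turn into gaps."""
    return sum(1 for c in seq.upper() if c in AMBIGUOUS)


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; GAP_CODE renders as '-'."""
    table = AMINO_ACIDS + GAP
    return "".join(table[int(c)] for c in codes)


def three_to_one(resname: str) -> str | None:
    """Map a PDB three-letter residue name to one-letter, or None if unknown."""
    return _THREE_TO_ONE.get(resname.upper())


_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
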