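"""Loaders for the packaged numeric tables.

Three plain-text tables ship with the package:

* the 20x20 residue contact-energy matrix (upper half + diagonal as published,
  symmetrized on load; attractive = negative),
* background amino-acid frequencies q^a,
* a binary hydrophobicity classification.

All loaders return data in the package's alphabetical residue order
(:data:`tcsevo.alphabet.AMINO_ACIDS`), whatever order the file uses.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA


def _data_path(name: str) -> Path:
    return Path(str(resources.files("tcsevo").joinpath("data", name)))


@lru_cache(maxsize=None)
def mj_matrix() -> np.ndarray:
    """Symmetric 20x20 contact-energy matrix indexed in alphabetical AA order."""
    lines = [
        ln.split()
        for ln in _data_path("mj_contact_energies.txt").read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    order = [row[0] for row in lines]
    mat = np.full((N_AA, N_AA), np.nan)
    for r, row in enumerate(lines):
        vals = [float(v) for v in row[1:]]
        if len(vals) != N_AA - r:
            raise ValueError(f"contact-energy row {row[0]}: expected {N_AA - r} values")
        for k, v in enumerate(vals):
            i = AA_INDEX[order[r]]
            j = AA_INDEX[order[r + k]]
            mat[i, j] = v
            mat[j, i] = v
    if np.isnan(mat).any():
        raise ValueError("contact-energy table incomplete")
    mat.setflags(write=False)
    return mat


def _read_keyed_tsv(name: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for ln in _data_path(name).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        aa, val = ln.split()
        out[aa] = float(val)
    missing = set(AMINO_ACIDS) - out.keys()
    if missing:
        raise ValueError(f"{name}: missing residues {sorted(missing)}")
    return out


@lru_cache(maxsize=None)
def background_frequencies() -> np.ndarray:
    """Length-20 background frequency vector, normalized to sum exactly 1."""
    d = _read_keyed_tsv("background_frequencies.tsv")
    q = np.array([d[aa] for aa in AMINO_ACIDS])
    if (q <= 0).any():
        raise ValueError("background frequencies must be strictly positive")
    q = q / q.sum()
    q.setflags(write=False)
    return q


@lru_cache(maxsize=None)
def hydrophobic_set() -> frozenset[str]:
    """Residue one-letter codes classified as hydrophobic."""
    d = _read_keyed_tsv("hydrophobicity.tsv")
    return frozenset(aa for aa, v in d.items() if v >= 0.5)
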