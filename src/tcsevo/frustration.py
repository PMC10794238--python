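"""Residue-level frustration under the contact potential.

The frustration index of position i compares the native incident contact
energy E_i^N (sum of contact energies over the contacts touching i, with the
sequence as given) against decoys that randomize ONLY the identity at i,
keeping the neighbors and the contact set fixed:

    F_i = ( <E_i^U> - E_i^N ) / sqrt( (1/N) sum_k (E_i^U(k) - <E_i^U>)^2 )

Decoy identities are drawn from the empirical amino-acid composition of the
evaluated sequence's own chain (``mode="composition"``, the default) or
uniformly over the twenty types (``mode="uniform"``). Under the
attractive-negative sign convention of the contact table, F_i > 0 means the
native identity sits below the decoy mean: minimally frustrated.

Because decoys vary only one identity over a fixed contact set, every decoy
shares the incident contact count with the native, so F_i is invariant to a
uniform shift of the whole energy table.

For binding-aware (complex) profiles the incident contacts include the
inter-chain contacts, with the partner chain's sequence held fixed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import alphabet
from .alphabet import GAP_CODE, N_AA
from .errors import (
    ConfigurationError,
    DegenerateDecoyError,
    InputError,
    NoContactError,
    UndefinedCorrelationError,
)
from .structure import ContactMap


@dataclass(frozen=True)
class FrustrationProfile:
    """Per-position frustration index over a sequence set.

    ``F`` is NaN at positions excluded from ``positions`` or with no
    contributing sequence; ``n_sequences`` counts contributors per position.
    """

    F: np.ndarray  # (n_positions_total,)
    native_energy: np.ndarray  # per-position mean E_i^N
    decoy_mean: np.ndarray
    decoy_std: np.ndarray
    n_decoys: int
    n_sequences: np.ndarray  # per-position contributor count
    label: str = ""  # NSs / FSs / FBSs / ...

    def finite_positions(self) -> np.ndarray:
        return np.nonzero(np.isfinite(self.F))[0]


@dataclass(frozen=True)
class FrustrationDelta:
    """Classified frustration change between two conditions."""

    delta: np.ndarray  # F(p2) - F(p1)
    threshold: float
    less_frustrated: tuple[int, ...]  # delta >= +threshold
    more_frustrated: tuple[int, ...]  # delta <= -threshold


def _candidate_energies(
    codes: np.ndarray, pos: int, cmap: ContactMap, em: np.ndarray
) -> np.ndarray:
    """Incident energy of every candidate identity at ``pos`` (length 20)."""
    inc = cmap.incident(pos)
    if inc.shape[0] == 0:
        raise NoContactError(f"position {pos} has no incident contacts")
    partners = np.where(inc[:, 0] == pos, inc[:, 1], inc[:, 0])
    pcodes = codes[partners].astype(int)
    if (pcodes == GAP_CODE).any() or codes[pos] == GAP_CODE:
        raise ConfigurationError(
            f"gap in the contact neighborhood of position {pos}"
        )
    return em[:, pcodes].sum(axis=1)  # (20,)


def _composition_weights(
    codes: np.ndarray, pos: int, cmap: ContactMap, mode: str
) -> np.ndarray:
    if mode == "uniform":
        return np.full(N_AA, 1.0 / N_AA)
    if mode != "composition":
        raise ConfigurationError(f"unknown decoy mode {mode!r}")
    chain = cmap.chain_of[pos]
    idx = [i for i, c in enumerate(cmap.chain_of) if c == chain]
    chain_codes = codes[idx]
    chain_codes = chain_codes[chain_codes != GAP_CODE]
    counts = np.bincount(chain_codes, minlength=N_AA)[:N_AA].astype(float)
    return counts / counts.sum()


def frustration_index(
    seq: str | np.ndarray,
    pos: int,
    cmap: ContactMap,
    em: np.ndarray,
    n_decoys: int = 1000,
    seed: int | np.random.Generator = 0,
    mode: str = "composition",
) -> float:
    """Monte-Carlo frustration index of one position (N identity draws)."""
    codes = alphabet.encode(seq) if isinstance(seq, str) else np.asarray(seq)
    e = _candidate_energies(codes, pos, cmap, em)
    w = _composition_weights(codes, pos, cmap, mode)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n_decoys, w)
    mean = float(counts @ e) / n_decoys
    var = float(counts @ (e - mean) ** 2) / n_decoys
    if var == 0.0:
        raise DegenerateDecoyError(
            f"zero decoy variance at position {pos} (all candidate energies equal "
            "or a single identity drawn)"
        )
    native = float(e[int(codes[pos])])
    return (mean - native) / np.sqrt(var)


def frustration_index_exact(
    seq: str | np.ndarray,
    pos: int,
    cmap: ContactMap,
    em: np.ndarray,
    mode: str = "composition",
) -> float:
    """Infinite-decoy limit: exact mean/variance over the identity distribution."""
    codes = alphabet.encode(seq) if isinstance(seq, str) else np.asarray(seq)
    e = _candidate_energies(codes, pos, cmap, em)
    w = _composition_weights(codes, pos, cmap, mode)
    mean = float(w @ e)
    var = float(w @ (e - mean) ** 2)
    if var == 0.0:
        raise DegenerateDecoyError(f"zero decoy variance at position {pos}")
    native = float(e[int(codes[pos])])
    return (mean - native) / np.sqrt(var)


def ensemble_frustration_profile(
    seqs: list[str] | list[np.ndarray] | np.ndarray,
    cmap: ContactMap,
    em: np.ndarray,
    n_decoys: int = 1000,
    seed: int = 0,
    positions: np.ndarray | None = None,
    mode: str = "composition",
    label: str = "",
) -> FrustrationProfile:
    """Average per-position frustration over a sequence set.

    F_i is computed per sequence then averaged per position. ``positions``
    restricts the profile (e.g. to one chain of a complex map); other
    positions are NaN. Sequences gapped in a position's neighborhood are
    skipped for that position. The decoy stream per (sequence, position) is
    derived from ``seed`` and the sequence content, so duplicated sequences
    contribute identical terms and the profile of a duplicated set equals
    the profile of the original set exactly.
    """
    if len(seqs) == 0:
        raise InputError("empty sequence set")
    n = cmap.n_residues
    if positions is None:
        positions = np.arange(n)
    acc = np.zeros(n)
    acc_native = np.zeros(n)
    acc_mean = np.zeros(n)
    acc_std = np.zeros(n)
    contrib = np.zeros(n, dtype=int)
    for seq in seqs:
        codes = alphabet.encode(seq) if isinstance(seq, str) else np.asarray(seq)
        crc = zlib.crc32(np.ascontiguousarray(codes).tobytes())
        for pos in positions:
            try:
                e = _candidate_energies(codes, int(pos), cmap, em)
            except (NoContactError, ConfigurationError):
                continue
            w = _composition_weights(codes, int(pos), cmap, mode)
            rng = np.random.default_rng([seed, int(pos), crc])
            counts = rng.multinomial(n_decoys, w)
            mean = float(counts @ e) / n_decoys
            var = float(counts @ (e - mean) ** 2) / n_decoys
            if var == 0.0:
                continue
            native = float(e[int(codes[pos])])
            acc[pos] += (mean - native) / np.sqrt(var)
            acc_native[pos] += native
            acc_mean[pos] += mean
            acc_std[pos] += np.sqrt(var)
            contrib[pos] += 1
    with np.errstate(invalid="ignore"):
        F = np.where(contrib > 0, acc / np.maximum(contrib, 1), np.nan)
        e_nat = np.where(contrib > 0, acc_native / np.maximum(contrib, 1), np.nan)
        e_mean = np.where(contrib > 0, acc_mean / np.maximum(contrib, 1), np.nan)
        e_std = np.where(contrib > 0, acc_std / np.maximum(contrib, 1), np.nan)
    return FrustrationProfile(
        F=F,
        native_energy=e_nat,
        decoy_mean=e_mean,
        decoy_std=e_std,
        n_decoys=n_decoys,
        n_sequences=contrib,
        label=label,
    )


def frustration_delta(
    p1: FrustrationProfile, p2: FrustrationProfile, threshold: float = 0.70
) -> FrustrationDelta:
    """Classify positions by frustration change dF = F(p2) - F(p1).

    dF >= +threshold: became less frustrated in p2; dF <= -threshold: became
    more frustrated. Profiles must cover identical position sets.
    """
    if p1.F.shape != p2.F.shape:
        raise ConfigurationError("profiles cover different position sets")
    f1, f2 = p1.F, p2.F
    both = np.isfinite(f1) & np.isfinite(f2)
    delta = np.where(both, f2 - f1, np.nan)
    with np.errstate(invalid="ignore"):
        less = tuple(np.nonzero(both & (delta >= threshold))[0].tolist())
        more = tuple(np.nonzero(both & (delta <= -threshold))[0].tolist())
    return FrustrationDelta(
        delta=delta, threshold=float(threshold), less_frustrated=less, more_frustrated=more
    )


def interface_enrichment_test(
    delta: np.ndarray,
    interface_positions: tuple[int, ...] | np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided label-permutation test for |dF| enrichment at the interface.

    Statistic: mean |dF| over interface positions minus mean |dF| over the
    remaining finite positions. The p-value is the fraction of random
    interface-label assignments with a statistic at least as large.
    Returns (observed statistic, p-value).
    """
    delta = np.asarray(delta, dtype=float)
    finite = np.nonzero(np.isfinite(delta))[0]
    iface = np.intersect1d(np.asarray(interface_positions, dtype=int), finite)
    rest = np.setdiff1d(finite, iface)
    if iface.size == 0 or rest.size == 0:
        raise ConfigurationError("need both interface and non-interface positions")
    absd = np.abs(delta[finite])
    k = iface.size
    iface_mask = np.isin(finite, iface)
    observed = float(absd[iface_mask].mean() - absd[~iface_mask].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(finite.size)
        stat = float(absd[perm[:k]].mean() - absd[perm[k:]].mean())
        if stat >= observed:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return observed, float(p)


def profile_correlation(
    p1: FrustrationProfile, p2: FrustrationProfile
) -> tuple[float, float]:
    """Pearson r and two-tailed p over positions finite in both profiles."""
    both = np.isfinite(p1.F) & np.isfinite(p2.F)
    if both.sum() < 3:
        raise UndefinedCorrelationError("need at least 3 shared finite positions")
    a, b = p1.F[both], p2.F[both]
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("constant profile: correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
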