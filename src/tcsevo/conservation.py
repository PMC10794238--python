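"""First- and second-order conservation statistics of a protein-family MSA.

Per-column conservation is the Kullback-Leibler divergence (relative entropy,
nats) of the observed amino-acid frequencies against database background
frequencies:

    C_i = sum_a f_i^a ln(f_i^a / q^a)

Coupling (second-order) conservation between two columns weights the joint
deviation from independence by conservation-derived log-odds coefficients:

    C_ij = sqrt( sum_{a,b} k_i^a k_j^b (f_ij^ab - f_i^a f_j^b)^2 ),
    k_i^a = ln( f_i^a (1 - q^a) / (q^a (1 - f_i^a)) ).

The coefficients k carry the sign of the deviation of f from q, so the sum
under the root is not sign-definite: on real family data it is positive for
coupled pairs, while on null (independent) data it fluctuates around zero
with both signs. We therefore keep the signed pre-root sum ("signed coupling")
for null-distribution diagnostics and clip negative sums to zero when
reporting C_ij itself.

The magnitude-frequency spectrum of C_ij over all column pairs is summarized
by a least-squares power-law fit, y = a * x^-b, performed as a line fit in
log10-log10 space over the non-empty bins of a linear histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alphabet import AMINO_ACIDS, GAP_CODE, N_AA
from .errors import ConfigurationError, FitError, NumericGuardError
from .msa import FrequencyModel, PairedAlignment, alignment_from_codes, estimate_frequencies
from .tables import background_frequencies, hydrophobic_set


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column first-order conservation and hydrophobic preference."""

    C: np.ndarray  # (L,) nats
    PH: np.ndarray | None = None  # (L,) in [0, 1]
    hydrophobic_residues: frozenset[str] | None = None


@dataclass(frozen=True)
class CouplingMatrix:
    """Symmetric column-by-column coupling conservation.

    ``C2`` holds C_ij (non-negative, diagonal zero); ``signed`` holds the
    pre-root signed sums, whose distribution is the natural null diagnostic.
    """

    C2: np.ndarray  # (L, L)
    signed: np.ndarray  # (L, L)
    k_coefficients: np.ndarray  # (L, 20)

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle (i<j) C_ij values as a flat vector."""
        iu = np.triu_indices_from(self.C2, k=1)
        return self.C2[iu]

    def offdiag_signed(self) -> np.ndarray:
        iu = np.triu_indices_from(self.signed, k=1)
        return self.signed[iu]


@dataclass(frozen=True)
class SpectrumFit:
    """Power-law fit y = a x^-b of the coupling-magnitude histogram."""

    bin_edges: np.ndarray
    frequencies: np.ndarray  # per-bin counts
    prefactor: float  # a
    exponent: float  # b (positive for a decaying spectrum)
    r_squared: float
    fit_range: tuple[float, float]
    n_bins_used: int


def position_conservation(freqs: FrequencyModel) -> np.ndarray:
    """C_i = sum_a f ln(f/q) per column, in nats, with 0 ln 0 := 0."""
    q = freqs.background
    if (q <= 0).any():
        raise ConfigurationError("background frequencies must be strictly positive")
    f = freqs.f_single
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(f / q), 0.0)
    return terms.sum(axis=1)


def hydrophobic_preference(
    aln: PairedAlignment, hydrophobic: frozenset[str] | None = None
) -> np.ndarray:
    """Fraction of observed (non-gap) residues per column that are hydrophobic."""
    if hydrophobic is None:
        hydrophobic = hydrophobic_set()
    if not hydrophobic or not hydrophobic <= set(AMINO_ACIDS):
        raise ConfigurationError("hydrophobic set must be a nonempty subset of the 20 AAs")
    mask = np.zeros(N_AA + 1, dtype=bool)
    for aa in hydrophobic:
        mask[AMINO_ACIDS.index(aa)] = True
    is_h = mask[aln.codes]
    non_gap = aln.codes != GAP_CODE
    m = non_gap.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        ph = np.where(m > 0, is_h.sum(axis=0) / m, np.nan)
    return ph


def conservation_profile(
    aln: PairedAlignment,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-4,
    hydrophobic: frozenset[str] | None = None,
) -> ConservationProfile:
    """Convenience wrapper: frequencies -> C_i and P_i^H in one call."""
    freqs = estimate_frequencies(aln, background=background, pseudocount=pseudocount)
    return ConservationProfile(
        C=position_conservation(freqs),
        PH=hydrophobic_preference(aln, hydrophobic),
        hydrophobic_residues=hydrophobic or hydrophobic_set(),
    )


def k_coefficients(freqs: FrequencyModel) -> np.ndarray:
    """Log-odds conservation coefficients k_i^a, shape (L, 20).

    Requires pseudocounted frequencies: k diverges at f in {0, 1}.
    """
    f = freqs.f_single
    if ((f <= 0) | (f >= 1)).any():
        raise NumericGuardError(
            "k coefficients need frequencies strictly inside (0, 1); "
            "use a positive pseudocount"
        )
    # background clamped away from {0, 1} so a degenerate (single-residue)
    # background yields large-but-finite coefficients instead of infinities
    q = np.clip(freqs.background, 1e-12, 1 - 1e-12)
    return np.log(f * (1 - q) / (q * (1 - f)))


def coupling_conservation(freqs: FrequencyModel) -> CouplingMatrix:
    """Compute C_ij for all column pairs.

    Joint frequencies are estimated over sequences non-gapped at both columns
    (one-hot rows are zero at gaps, so the cross-products count exactly those
    sequences); the independence reference f_i^a f_j^b uses the marginals of
    each pair's own joint table, so exactly independent columns give C_ij = 0.
    """
    if freqs.pseudocount <= 0:
        raise NumericGuardError("coupling conservation requires pseudocount > 0")
    k = k_coefficients(freqs)
    L = freqs.n_cols
    codes = freqs.codes
    M = codes.shape[0]

    # one-hot encoding; gap rows are all-zero
    X = np.zeros((M, L * N_AA), dtype=np.float32)
    rows = np.repeat(np.arange(M), L)
    flat = codes.astype(np.int64).ravel()
    ok = flat != GAP_CODE
    cols = np.arange(L * N_AA).reshape(L, N_AA)
    X[rows[ok], (np.tile(np.arange(L) * N_AA, M)[ok] + flat[ok])] = 1.0

    counts = (X.T @ X).astype(np.float64)  # (L*20, L*20) pair counts
    counts = counts.reshape(L, N_AA, L, N_AA) + freqs.pseudocount
    totals = counts.sum(axis=(1, 3))  # (L, L)
    fpair = counts / totals[:, None, :, None]
    # pairwise-restricted marginals
    mi = fpair.sum(axis=3)  # (L, 20, L): f_i^a given pair (i, j)
    mj = fpair.sum(axis=1)  # (L, L, 20): f_j^b given pair (i, j)
    diff = fpair - mi[:, :, :, None] * mj[:, None, :, :]
    signed = np.einsum("ia,jb,iajb->ij", k, k, diff**2, optimize=True)
    np.fill_diagonal(signed, 0.0)
    signed = 0.5 * (signed + signed.T)  # symmetrize away float noise
    C2 = np.sqrt(np.clip(signed, 0.0, None))
    return CouplingMatrix(C2=C2, signed=signed, k_coefficients=k)


def coupling_null(
    n_seqs: int,
    n_cols: int,
    seed: int,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-4,
) -> tuple[CouplingMatrix, dict[str, float]]:
    """Coupling conservation of independent background-drawn sequences.

    Returns the coupling matrix together with summary statistics of the
    off-diagonal values: mean/std/max of C_ij and mean/std/skew/excess
    kurtosis of the signed pre-root statistic (the Gaussian-like null
    quantity).
    """
    if n_seqs < 2:
        raise ConfigurationError("need at least 2 sequences for a null model")
    if background is None:
        background = background_frequencies()
    rng = np.random.default_rng(seed)
    background = np.asarray(background, dtype=float)
    codes = rng.choice(N_AA, size=(n_seqs, n_cols), p=background / background.sum()).astype(np.int8)
    aln = alignment_from_codes(codes)
    # a degenerate background (zeros for unused residues) is legal for the
    # null generator; clip for the frequency model's positivity contract
    bg_safe = np.clip(background, 1e-12, None)
    bg_safe = bg_safe / bg_safe.sum()
    freqs = estimate_frequencies(aln, background=bg_safe, pseudocount=pseudocount)
    cm = coupling_conservation(freqs)
    vals = cm.offdiag_values()
    sv = cm.offdiag_signed()
    spread = float(sv.std())
    summary = {
        "mean": float(vals.mean()),
        "std": float(vals.std()),
        "max": float(vals.max()),
        "signed_mean": float(sv.mean()),
        "signed_std": spread,
        # higher moments are meaningless (and numerically unstable) when the
        # signed statistic has collapsed to a point mass
        "signed_skew": float(stats.skew(sv)) if spread > 1e-12 else 0.0,
        "signed_excess_kurtosis": float(stats.kurtosis(sv)) if spread > 1e-12 else 0.0,
    }
    return cm, summary


def fit_powerlaw_spectrum(
    values: CouplingMatrix | np.ndarray,
    bin_width: float = 0.1,
    fit_range: tuple[float, float] | None = None,
) -> SpectrumFit:
    """Least-squares power-law fit of the coupling-magnitude histogram.

    Linear bins of ``bin_width`` starting at the smallest observed value;
    the fit is a straight line of log10(count) against log10(bin center)
    over the non-empty bins whose centers fall in ``fit_range`` (default:
    all non-empty bins). Returns prefactor a, positive exponent b and the
    log-log R^2.
    """
    if isinstance(values, CouplingMatrix):
        values = values.offdiag_values()
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    lo = values.min()
    n_bins = max(1, int(np.ceil((values.max() - lo) / bin_width)) + 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    usable = (counts > 0) & (centers > 0)
    if fit_range is not None:
        usable &= (centers >= fit_range[0]) & (centers <= fit_range[1])
    else:
        fit_range = (float(centers[usable].min()), float(centers[usable].max())) if usable.any() else (0.0, 0.0)
    if usable.sum() < 3:
        raise FitError(f"only {int(usable.sum())} usable bins; need at least 3")
    x = np.log10(centers[usable])
    y = np.log10(counts[usable].astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return SpectrumFit(
        bin_edges=edges,
        frequencies=counts,
        prefactor=float(10**intercept),
        exponent=float(-slope),
        r_squared=r2,
        fit_range=(float(fit_range[0]), float(fit_range[1])),
        n_bins_used=int(usable.sum()),
    )


def select_top(
    values: np.ndarray, threshold: float
) -> tuple[np.ndarray, dict[str, object]]:
    """Indices of all scores >= threshold.

    For a 1-D score vector returns column indices. For a symmetric matrix
    returns the (i, j) upper-triangle pairs, and the info dict additionally
    reports the distinct columns touched by the selected pairs.
    """
    values = np.asarray(values)
    if values.ndim == 1:
        idx = np.nonzero(values >= threshold)[0]
        return idx, {"count": int(idx.size)}
    if values.ndim == 2:
        iu = np.triu_indices_from(values, k=1)
        sel = values[iu] >= threshold
        pairs = np.stack([iu[0][sel], iu[1][sel]], axis=1)
        touched = np.unique(pairs) if pairs.size else np.array([], dtype=int)
        return pairs, {"count": int(pairs.shape[0]), "touched_columns": touched}
    raise ConfigurationError("select_top expects a vector or a square matrix")
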