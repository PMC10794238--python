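"""Paired HK/RR alignment I/O, gap filtering, and frequency estimation.

The family track operates on a paired multiple sequence alignment in which
each record concatenates the aligned histidine-kinase DHp segment and the
aligned response-regulator receiver (Rec) segment of one cognate pair.
Columns are 0-based half-open internally; ``domain_ranges`` names the column
interval of each domain.

Frequencies follow the convention of the conservation statistics: gaps are
excluded from both numerator and denominator (a column's frequencies are over
its observed residues only, summing over the twenty canonical types), and
pair frequencies are estimated from the sequences that are non-gapped at both
columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import alphabet
from .alphabet import GAP_CODE, N_AA
from .errors import (
    AlignmentFormatError,
    ConfigurationError,
    DegenerateColumnError,
    EmptyAlignmentError,
    InputError,
)

DEFAULT_DOMAIN_RANGES = {"DHp": (0, 64), "Rec": (64, 176)}
"""Column layout of the unfiltered paired profile (DHp Pfam length 64,
Rec Pfam length 112)."""


@dataclass(frozen=True)
class PairedAlignment:
    """An aligned set of paired sequences with named domain column ranges."""

    ids: tuple[str, ...]
    codes: np.ndarray  # (n_seqs, n_cols) int8, GAP_CODE for gaps
    domain_ranges: dict[str, tuple[int, int]]
    removed_columns: tuple[int, ...] = ()
    ambiguous_residue_count: int = 0

    def __post_init__(self) -> None:
        if self.codes.ndim != 2:
            raise AlignmentFormatError("codes must be a 2-D matrix")
        if len(self.ids) != self.codes.shape[0]:
            raise AlignmentFormatError("ids/codes row mismatch")
        _check_domain_ranges(self.domain_ranges, self.codes.shape[1])

    @property
    def n_seqs(self) -> int:
        return self.codes.shape[0]

    @property
    def column_count(self) -> int:
        return self.codes.shape[1]

    @property
    def gap_mask(self) -> np.ndarray:
        """Boolean (n_seqs, n_cols) matrix, True where gapped."""
        return self.codes == GAP_CODE

    def domain_of_column(self, col: int) -> str:
        for name, (lo, hi) in self.domain_ranges.items():
            if lo <= col < hi:
                return name
        raise KeyError(col)

    def sequence(self, idx: int) -> str:
        return alphabet.decode(self.codes[idx])


def _check_domain_ranges(ranges: dict[str, tuple[int, int]], n_cols: int) -> None:
    covered = np.zeros(n_cols, dtype=bool)
    for name, (lo, hi) in ranges.items():
        if not (0 <= lo < hi <= n_cols):
            raise ConfigurationError(
                f"domain {name!r} range [{lo},{hi}) out of bounds for {n_cols} columns"
            )
        if covered[lo:hi].any():
            raise ConfigurationError(f"domain {name!r} overlaps another domain")
        covered[lo:hi] = True
    if not covered.all():
        raise ConfigurationError("domain ranges do not cover all columns")


def read_paired_alignment(
    path: str | Path,
    domain_ranges: dict[str, tuple[int, int]] | None = None,
) -> PairedAlignment:
    """Read an aligned FASTA file into a :class:`PairedAlignment`.

    Unknown/ambiguous residue codes are normalized to gaps and tallied in
    ``ambiguous_residue_count``. If ``domain_ranges`` is omitted, a single
    domain ``"all"`` spanning every column is assumed.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such alignment file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    return _build_alignment(
        [(r.id, str(r.seq)) for r in records], domain_ranges, source=str(path)
    )


def read_paired_table(
    path: str | Path,
    domain_ranges: dict[str, tuple[int, int]] | None = None,
    sep: str = "\t",
) -> PairedAlignment:
    """Read the delimited variant: one line per record, ``id<sep>alignedseq``."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such alignment file: {path}")
    pairs: list[tuple[str, str]] = []
    for ln in path.read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split(sep)
        if len(parts) != 2:
            raise AlignmentFormatError(f"expected 'id{sep}sequence' rows in {path}")
        pairs.append((parts[0], parts[1]))
    return _build_alignment(pairs, domain_ranges, source=str(path))


def _build_alignment(
    pairs: list[tuple[str, str]],
    domain_ranges: dict[str, tuple[int, int]] | None,
    source: str = "<memory>",
) -> PairedAlignment:
    if not pairs:
        raise InputError(f"empty alignment: {source}")
    lengths = {len(s) for _, s in pairs}
    if len(lengths) != 1:
        raise AlignmentFormatError(
            f"ragged alignment in {source}: sequence lengths {sorted(lengths)}"
        )
    n_cols = lengths.pop()
    if domain_ranges is None:
        domain_ranges = {"all": (0, n_cols)}
    ambig = sum(alphabet.count_ambiguous(s) for _, s in pairs)
    if ambig:
        warnings.warn(f"{ambig} ambiguous residue code(s) normalized to gaps")
    codes = np.vstack([alphabet.encode(s) for _, s in pairs])
    return PairedAlignment(
        ids=tuple(i for i, _ in pairs),
        codes=codes,
        domain_ranges=dict(domain_ranges),
        ambiguous_residue_count=ambig,
    )


def alignment_from_codes(
    codes: np.ndarray,
    domain_ranges: dict[str, tuple[int, int]] | None = None,
    ids: tuple[str, ...] | None = None,
) -> PairedAlignment:
    """Wrap an integer code matrix (e.g. generator output) as an alignment."""
    codes = np.asarray(codes, dtype=np.int8)
    if ids is None:
        ids = tuple(f"seq{i}" for i in range(codes.shape[0]))
    if domain_ranges is None:
        domain_ranges = {"all": (0, codes.shape[1])}
    return PairedAlignment(ids=ids, codes=codes, domain_ranges=dict(domain_ranges))


def write_paired_alignment(aln: PairedAlignment, path: str | Path) -> None:
    """Write the alignment back to aligned FASTA (round-trip safe)."""
    records = [
        SeqRecord(Seq(aln.sequence(i)), id=aln.ids[i], description="")
        for i in range(aln.n_seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def filter_alignment(
    aln: PairedAlignment,
    max_seq_gap_frac: float = 0.2,
    max_col_gap_frac: float = 0.5,
    drop_columns: tuple[int, ...] = (),
) -> PairedAlignment:
    """Remove gappy sequences, then gappy columns.

    Sequences with gap fraction > ``max_seq_gap_frac`` are removed first;
    column gap fractions are then computed on the surviving sequences and
    columns exceeding ``max_col_gap_frac`` are dropped. ``drop_columns``
    forces removal of extra original column indices (e.g. a column that is a
    gap in the reference complex-structure sequence). Domain ranges are
    re-indexed to the retained columns; ``removed_columns`` records original
    indices (accumulated across repeated filtering).
    """
    if not (0 <= max_seq_gap_frac <= 1 and 0 <= max_col_gap_frac <= 1):
        raise ConfigurationError("gap-fraction thresholds must lie in [0, 1]")
    gaps = aln.gap_mask
    seq_frac = gaps.mean(axis=1)
    keep_seq = seq_frac <= max_seq_gap_frac
    if not keep_seq.any():
        raise EmptyAlignmentError("sequence gap filter removed every sequence")
    col_frac = gaps[keep_seq].mean(axis=0)
    keep_col = col_frac <= max_col_gap_frac
    for c in drop_columns:
        keep_col[c] = False
    removed_now = np.nonzero(~keep_col)[0]

    # re-index domain ranges onto the retained columns
    new_ranges: dict[str, tuple[int, int]] = {}
    offset = 0
    for name, (lo, hi) in aln.domain_ranges.items():
        width = int(keep_col[lo:hi].sum())
        if width:
            new_ranges[name] = (offset, offset + width)
        offset += width

    # map retained-column indices back to the original (pre-any-filter) frame
    if aln.removed_columns:
        orig_cols = np.setdiff1d(
            np.arange(aln.column_count + len(aln.removed_columns)),
            np.asarray(aln.removed_columns),
        )
    else:
        orig_cols = np.arange(aln.column_count)
    removed_orig = tuple(sorted(set(aln.removed_columns) | set(orig_cols[removed_now])))

    return PairedAlignment(
        ids=tuple(np.asarray(aln.ids, dtype=object)[keep_seq]),
        codes=aln.codes[keep_seq][:, keep_col],
        domain_ranges=new_ranges,
        removed_columns=removed_orig,
        ambiguous_residue_count=aln.ambiguous_residue_count,
    )


def filter_report(
    aln: PairedAlignment,
    max_seq_gap_frac: float = 0.2,
    max_col_gap_frac: float = 0.5,
) -> "tuple[list[tuple[str, float, bool]], list[tuple[int, float, bool]]]":
    """Per-sequence and per-column (gap fraction, kept) rows for reporting."""
    gaps = aln.gap_mask
    seq_frac = gaps.mean(axis=1)
    keep_seq = seq_frac <= max_seq_gap_frac
    col_frac = gaps[keep_seq].mean(axis=0) if keep_seq.any() else gaps.mean(axis=0)
    seq_rows = [
        (aln.ids[i], float(seq_frac[i]), bool(keep_seq[i])) for i in range(aln.n_seqs)
    ]
    col_rows = [
        (j, float(col_frac[j]), bool(col_frac[j] <= max_col_gap_frac))
        for j in range(aln.column_count)
    ]
    return seq_rows, col_rows


@dataclass(frozen=True)
class FrequencyModel:
    """Single-site and (on-demand) pairwise frequencies of an alignment.

    ``f_single[i, a]`` is the pseudocounted frequency of residue ``a`` at
    column ``i`` over non-gap residues; ``effective_counts[i]`` the number of
    observed residues at column ``i``. Pair tables are derived from the code
    matrix on demand (storing all ~L^2/2 20x20 tables densely is wasteful at
    family scale); :meth:`pair_frequencies` returns one table.
    """

    f_single: np.ndarray  # (L, 20)
    background: np.ndarray  # (20,)
    pseudocount: float
    effective_counts: np.ndarray  # (L,)
    codes: np.ndarray = field(repr=False)  # (M, L) int8

    @property
    def n_cols(self) -> int:
        return self.f_single.shape[0]

    def pair_counts(self, i: int, j: int) -> np.ndarray:
        """Raw 20x20 joint counts over sequences non-gapped at both columns."""
        ci, cj = self.codes[:, i], self.codes[:, j]
        ok = (ci != GAP_CODE) & (cj != GAP_CODE)
        combined = ci[ok].astype(np.int64) * N_AA + cj[ok]
        return np.bincount(combined, minlength=N_AA * N_AA).reshape(N_AA, N_AA)

    def pair_frequencies(self, i: int, j: int) -> np.ndarray:
        """Pseudocounted 20x20 joint frequency table f_ij^ab (sums to 1)."""
        counts = self.pair_counts(i, j) + self.pseudocount
        total = counts.sum()
        if total == 0:
            raise DegenerateColumnError(f"columns {i},{j} share no observed rows")
        return counts / total


def estimate_frequencies(
    aln: PairedAlignment,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-4,
) -> FrequencyModel:
    """Estimate per-column frequencies with gap exclusion and pseudocounts.

    A pseudocount is added to every amino-acid cell before normalization; the
    default (1e-4) is small enough not to disturb counts at family scale but
    keeps every frequency strictly inside (0, 1) for use inside logarithms.
    Raises :class:`DegenerateColumnError` if a column is entirely gaps.
    """
    from .tables import background_frequencies

    if aln.n_seqs == 0:
        raise InputError("empty alignment")
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be nonnegative")
    if background is None:
        background = background_frequencies()
    background = np.asarray(background, dtype=float)
    if background.shape != (N_AA,) or (background <= 0).any():
        raise ConfigurationError("background must be a strictly positive length-20 vector")

    counts = np.stack(
        [
            np.bincount(aln.codes[:, j][aln.codes[:, j] != GAP_CODE], minlength=N_AA)[
                :N_AA
            ]
            for j in range(aln.column_count)
        ]
    ).astype(float)
    eff = counts.sum(axis=1)
    if (eff == 0).any():
        bad = np.nonzero(eff == 0)[0]
        raise DegenerateColumnError(f"column(s) entirely gaps: {bad.tolist()}")
    f = (counts + pseudocount) / (eff + N_AA * pseudocount)[:, None]
    return FrequencyModel(
        f_single=f,
        background=background,
        pseudocount=float(pseudocount),
        effective_counts=eff,
        codes=aln.codes,
    )
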