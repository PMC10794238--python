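"""Structure parsing, heavy-atom contact maps, and contact-energy evaluation.

A residue pair is in contact when any two heavy atoms from the two residues
are closer than a cutoff (default 5.0 Angstrom, strict ``<``). Within a chain
a minimum sequence separation of 2 applies (|i-j| >= 2); inter-chain pairs
carry no separation constraint (separation is a chain-internal concept).

Sequence energies are sums of a 20x20 residue contact potential over the
contacts, E = sum over contacts (i,j) of xi(mu_i, mu_j); for a two-chain
complex the energy splits into intra terms E1, E2 and the inter term E12 by
the contact partition, and rigid-body binding comparisons use E12 only (the
intra terms are pose-invariant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser

from . import alphabet
from .alphabet import GAP_CODE
from .errors import ConfigurationError, MappingError, SelectionError
from .msa import PairedAlignment


@dataclass(frozen=True)
class Residue:
    """One residue: author numbering, type, and heavy-atom coordinates."""

    chain: str
    resnum: int
    name: str  # one-letter code, or 'X' for unknown types
    coords: np.ndarray  # (n_atoms, 3) float64, heavy atoms only


@dataclass(frozen=True)
class Structure:
    """Ordered heavy-atom residues of one or more selected chains."""

    residues: tuple[Residue, ...]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return tuple(seen)

    def chain_indices(self, chain: str) -> np.ndarray:
        """Global residue indices belonging to one chain, in order."""
        idx = np.array([i for i, r in enumerate(self.residues) if r.chain == chain])
        if idx.size == 0:
            raise SelectionError(f"no residues in chain {chain!r}")
        return idx

    def chain_sequence(self, chain: str) -> str:
        return "".join(self.residues[i].name for i in self.chain_indices(chain))

    def to_pdb(self, path: str | Path) -> None:
        """Write a minimal PDB file (CA-style pseudo-atoms named A1, A2...)."""
        lines = []
        serial = 1
        for i, res in enumerate(self.residues):
            resname = _ONE_TO_THREE.get(res.name, "UNK")
            for k, xyz in enumerate(res.coords):
                name = "CA" if k == 0 else f"C{k}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{resname:>4s} {res.chain}"
                    f"{res.resnum:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"  1.00  0.00           C"
                )
                serial += 1
        lines.append("END")
        Path(path).write_text("\n".join(lines) + "\n")


_ONE_TO_THREE = {v: k for k, v in alphabet._THREE_TO_ONE.items()}


def read_structure(path: str | Path, chain_selection: tuple[str, ...] | None = None) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Hydrogens are dropped, alternate locations resolve to the highest-occupancy
    conformer, and HETATM residues are excluded. ``chain_selection`` fixes the
    chain order of the result; a missing chain raises :class:`SelectionError`.
    """
    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", str(path))[0]
    available = {ch.id: ch for ch in model}
    if chain_selection is None:
        chain_selection = tuple(available)
    residues: list[Residue] = []
    for cid in chain_selection:
        if cid not in available:
            raise SelectionError(
                f"chain {cid!r} not in structure (has {sorted(available)})"
            )
        for res in available[cid]:
            if res.id[0] != " ":  # HETATM / water
                continue
            coords = []
            for atom in res:
                if atom.is_disordered():
                    atom = atom.selected_child  # highest occupancy
                if (atom.element or "").upper() == "H":
                    continue
                coords.append(atom.get_coord())
            if not coords:
                continue
            one = alphabet.three_to_one(res.get_resname()) or "X"
            residues.append(
                Residue(
                    chain=cid,
                    resnum=int(res.id[1]),
                    name=one,
                    coords=np.asarray(coords, dtype=float),
                )
            )
    return Structure(residues=tuple(residues))


@dataclass(frozen=True)
class ContactMap:
    """Residue-pair contacts with partition labels.

    ``pairs`` holds (i, j) with i < j in global residue indices; ``labels``
    holds ``"intra:<chain>"`` or ``"inter"`` per pair. ``chain_of`` and
    ``chain_pos`` place every global index in its chain.
    """

    n_residues: int
    pairs: np.ndarray  # (K, 2) int
    labels: tuple[str, ...]
    cutoff: float
    min_sep: int
    chain_of: tuple[str, ...]
    chain_pos: np.ndarray = field(default=None)  # (N,) position within chain

    @property
    def n_contacts(self) -> int:
        return int(self.pairs.shape[0])

    def pairs_with_label(self, label: str) -> np.ndarray:
        sel = [k for k, lb in enumerate(self.labels) if lb == label]
        return self.pairs[sel] if sel else np.empty((0, 2), dtype=int)

    def inter_pairs(self) -> np.ndarray:
        return self.pairs_with_label("inter")

    def intra_pairs(self, chain: str) -> np.ndarray:
        return self.pairs_with_label(f"intra:{chain}")

    def incident(self, pos: int) -> np.ndarray:
        """Contacts touching global residue index ``pos``, as (K', 2)."""
        sel = (self.pairs[:, 0] == pos) | (self.pairs[:, 1] == pos)
        return self.pairs[sel]

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_residues, dtype=int)
        np.add.at(d, self.pairs.ravel(), 1)
        return d

    def contact_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(map(tuple, self.pairs.tolist()))

    def replace_pairs(self, pairs: np.ndarray, labels: tuple[str, ...]) -> "ContactMap":
        return ContactMap(
            n_residues=self.n_residues,
            pairs=np.asarray(pairs, dtype=int),
            labels=labels,
            cutoff=self.cutoff,
            min_sep=self.min_sep,
            chain_of=self.chain_of,
            chain_pos=self.chain_pos,
        )


def build_contact_map(
    s: Structure, cutoff: float = 5.0, min_sep: int = 2
) -> ContactMap:
    """Heavy-atom contact map of a structure.

    Pair (i, j) is a contact iff the minimum heavy-atom distance is strictly
    below ``cutoff`` and either the residues sit on different chains or
    |pos_i - pos_j| >= ``min_sep`` within their chain.
    """
    if s.n_residues == 0:
        raise ConfigurationError("empty structure")
    chain_of = tuple(r.chain for r in s.residues)
    chain_pos = np.zeros(s.n_residues, dtype=int)
    counter: dict[str, int] = {}
    for i, c in enumerate(chain_of):
        chain_pos[i] = counter.get(c, 0)
        counter[c] = chain_pos[i] + 1

    # per-residue bounding spheres let us skip most atom-level comparisons
    centers = np.array([r.coords.mean(axis=0) for r in s.residues])
    radii = np.array(
        [np.linalg.norm(r.coords - c, axis=1).max() for r, c in zip(s.residues, centers)]
    )
    pairs: list[tuple[int, int]] = []
    labels: list[str] = []
    n = s.n_residues
    dmat = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            same_chain = chain_of[i] == chain_of[j]
            if same_chain and abs(int(chain_pos[i]) - int(chain_pos[j])) < min_sep:
                continue
            if dmat[i, j] - radii[i] - radii[j] >= cutoff:
                continue
            d = _min_atom_distance(s.residues[i].coords, s.residues[j].coords)
            if d < cutoff:
                pairs.append((i, j))
                labels.append(f"intra:{chain_of[i]}" if same_chain else "inter")
    return ContactMap(
        n_residues=n,
        pairs=np.asarray(pairs, dtype=int).reshape(-1, 2),
        labels=tuple(labels),
        cutoff=float(cutoff),
        min_sep=int(min_sep),
        chain_of=chain_of,
        chain_pos=chain_pos,
    )


def _min_atom_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def pair_min_distance(s: Structure, i: int, j: int) -> float:
    """Minimum heavy-atom distance between residues i and j (global indices)."""
    return _min_atom_distance(s.residues[i].coords, s.residues[j].coords)


def pair_ca_distance(s: Structure, i: int, j: int) -> float:
    """First-atom (CA convention) distance between two residues."""
    return float(np.linalg.norm(s.residues[i].coords[0] - s.residues[j].coords[0]))


# ---------------------------------------------------------------------------
# energies


def _as_codes(seq: str | np.ndarray) -> np.ndarray:
    if isinstance(seq, str):
        return alphabet.encode(seq)
    return np.asarray(seq, dtype=np.int8)


def sequence_energy(
    seq: str | np.ndarray,
    cmap: ContactMap,
    em: np.ndarray,
    pairs: np.ndarray | None = None,
) -> float:
    """Contact energy of a sequence on a contact map.

    ``pairs`` restricts evaluation to a subset of the map's contacts (used for
    partition sums). Gaps at a contacting position contribute zero to that
    contact, with a warning.
    """
    codes = _as_codes(seq)
    if pairs is None:
        pairs = cmap.pairs
    if pairs.size == 0:
        return 0.0
    if codes.shape[0] < int(pairs.max()) + 1:
        raise ConfigurationError("sequence shorter than the contact map requires")
    a = codes[pairs[:, 0]].astype(int)
    b = codes[pairs[:, 1]].astype(int)
    ok = (a != GAP_CODE) & (b != GAP_CODE)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} contact(s) skipped due to gaps")
    return float(em[a[ok], b[ok]].sum())


def complex_energy(
    seq_a: str | np.ndarray,
    seq_b: str | np.ndarray,
    cmap: ContactMap,
    em: np.ndarray,
    rigid: bool = False,
) -> tuple[float, float, float, float]:
    """(E1, E2, E12, E) of a two-chain complex.

    ``seq_a`` covers the first chain of the map, ``seq_b`` the second; E1/E2
    are the intra-chain sums and E12 the inter-chain sum. With ``rigid`` the
    total is E12 alone (intra terms are identical across rigid-body poses).
    """
    chains = _ordered_chains(cmap)
    if len(chains) != 2:
        raise ConfigurationError("complex_energy needs a two-chain contact map")
    ca, cb = chains
    codes_a = _as_codes(seq_a)
    codes_b = _as_codes(seq_b)
    full = np.full(cmap.n_residues, GAP_CODE, dtype=np.int8)
    idx_a = [i for i, c in enumerate(cmap.chain_of) if c == ca]
    idx_b = [i for i, c in enumerate(cmap.chain_of) if c == cb]
    if len(idx_a) != codes_a.shape[0] or len(idx_b) != codes_b.shape[0]:
        raise ConfigurationError("sequence lengths do not match chain sizes")
    full[idx_a] = codes_a
    full[idx_b] = codes_b
    e1 = sequence_energy(full, cmap, em, cmap.intra_pairs(ca))
    e2 = sequence_energy(full, cmap, em, cmap.intra_pairs(cb))
    e12 = sequence_energy(full, cmap, em, cmap.inter_pairs())
    total = e12 if rigid else e1 + e2 + e12
    return e1, e2, e12, total


def _ordered_chains(cmap: ContactMap) -> list[str]:
    seen: list[str] = []
    for c in cmap.chain_of:
        if c not in seen:
            seen.append(c)
    return seen


# ---------------------------------------------------------------------------
# alignment <-> structure mapping


@dataclass(frozen=True)
class AlignmentStructureMap:
    """Monotone mapping between retained alignment columns and residues."""

    column_to_residue: dict[int, tuple[str, int]]  # col -> (chain, resnum)
    unmapped_columns: tuple[int, ...]

    def residue_number(self, col: int) -> int | None:
        hit = self.column_to_residue.get(col)
        return hit[1] if hit else None


def map_alignment_to_structure(
    aln: PairedAlignment,
    s: Structure,
    domain_chains: dict[str, str],
) -> AlignmentStructureMap:
    """Map each domain's columns onto one structure chain.

    The per-column consensus residue of the domain is globally aligned to the
    chain sequence; columns opposite an alignment gap are reported unmapped.
    The mapping is strictly increasing in both coordinates within a domain.
    """
    from .msa import estimate_frequencies

    freqs = estimate_frequencies(aln, pseudocount=0.0)
    consensus_codes = freqs.f_single.argmax(axis=1)
    col_to_res: dict[int, tuple[str, int]] = {}
    unmapped: list[int] = []
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -0.5
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -0.5

    for domain, (lo, hi) in aln.domain_ranges.items():
        if domain not in domain_chains:
            continue
        chain = domain_chains[domain]
        chain_idx = s.chain_indices(chain)
        chain_seq = s.chain_sequence(chain).replace("X", "A")
        dom_seq = "".join(alphabet.AMINO_ACIDS[c] for c in consensus_codes[lo:hi])
        alignment = aligner.align(dom_seq, chain_seq)[0]
        prev_res = -1
        for (q0, q1), (t0, t1) in zip(*alignment.aligned):
            for off in range(q1 - q0):
                col = lo + q0 + off
                ridx = int(chain_idx[t0 + off])
                if ridx <= prev_res:
                    raise MappingError("non-monotone alignment-to-structure mapping")
                prev_res = ridx
                col_to_res[col] = (chain, s.residues[ridx].resnum)
        for col in range(lo, hi):
            if col not in col_to_res:
                unmapped.append(col)
    return AlignmentStructureMap(
        column_to_residue=col_to_res, unmapped_columns=tuple(sorted(unmapped))
    )
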