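"""Synthetic inputs: planted-signal MSAs, toy structures, decoy ensembles.

Everything the two analysis tracks consume can be generated here without
downloads:

* :func:`sample_msa` draws an aligned protein-family MSA with planted
  conserved columns and planted pairwise-covarying column pairs plus gaps
  (or, with no planting, a null MSA of independent background-drawn rows);
* :func:`make_toy_structure` builds a deterministic compact lattice fold
  (one or two chains) whose contact-count spread yields designated buried,
  surface and, for two chains, interface positions;
* :func:`folding_decoys` builds alternative intra-chain contact maps by
  degree-preserving rewiring (or by threading onto fixture maps), and
  :func:`binding_decoys` builds alternative binding poses by rigid-body
  perturbation of the ligand chain — desk-scale stand-ins for threading
  libraries and docking ensembles that preserve the one property the fitness
  formulas consume: a broad, approximately Gaussian decoy energy
  distribution.

Decoy ensembles can also be exchanged as JSON-lines files
(:func:`export_decoys` / :func:`import_decoys`) so externally produced
threading or docking outputs can be plugged in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AA_INDEX, GAP_CODE, N_AA
from .errors import (
    ConfigurationError,
    DecoyFormatError,
    GenerationError,
    SpecError,
)
from .fitness import DecoyEnsemble
from .msa import PairedAlignment, alignment_from_codes
from .structure import ContactMap, Residue, Structure, build_contact_map
from .tables import background_frequencies

LATTICE_SPACING = 3.8  # Angstrom, consecutive-residue distance
CLASH_CUTOFF = 2.0  # Angstrom, rigid-body pose rejection

DECOY_SCHEMA = "tcsevo-decoys/1"


# ---------------------------------------------------------------------------
# planted-signal MSAs


@dataclass(frozen=True)
class SyntheticMsaSpec:
    """Recipe for a synthetic family MSA.

    ``conserved`` maps column -> (dominant residue, dominance in [0, 1]);
    ``coupled`` maps (i, j) -> (((a1, b1), (a2, b2)), correlation in [0, 1]):
    the pair draws one of two residue-pair states with 50/50 marginals and
    the stated probability of drawing the states jointly rather than
    independently. Planted sets must be disjoint.

    ``gappy_columns`` (column -> gap fraction) and ``gappy_rows``
    ((row count, per-row gap fraction); the last rows are used) plant the
    gap structure the alignment filters act on, over and above the uniform
    ``gap_rate``.
    """

    n_seqs: int
    n_cols: int
    conserved: dict[int, tuple[str, float]] = field(default_factory=dict)
    coupled: dict[tuple[int, int], tuple[tuple[tuple[str, str], tuple[str, str]], float]] = field(
        default_factory=dict
    )
    gap_rate: float = 0.0
    gappy_columns: dict[int, float] = field(default_factory=dict)
    gappy_rows: tuple[int, float] = (0, 0.0)
    seed: int = 0
    background: np.ndarray | None = None
    domain_ranges: dict[str, tuple[int, int]] | None = None

    def validate(self) -> None:
        if self.n_seqs < 1 or self.n_cols < 1:
            raise SpecError("n_seqs and n_cols must be positive")
        if not 0 <= self.gap_rate < 1:
            raise SpecError("gap_rate must lie in [0, 1)")
        cons_cols = set(self.conserved)
        coup_cols: set[int] = set()
        for (i, j), (states, corr) in self.coupled.items():
            if i == j or not (0 <= i < self.n_cols and 0 <= j < self.n_cols):
                raise SpecError(f"invalid coupled pair ({i}, {j})")
            if i in coup_cols or j in coup_cols:
                raise SpecError(f"column reused across coupled pairs: ({i}, {j})")
            coup_cols |= {i, j}
            if not 0 <= corr <= 1:
                raise SpecError("correlation must lie in [0, 1]")
            (a1, b1), (a2, b2) = states
            for r in (a1, b1, a2, b2):
                if r not in AA_INDEX:
                    raise SpecError(f"unknown residue {r!r} in coupled states")
            if a1 == a2 or b1 == b2:
                raise SpecError("coupled two-state pair needs distinct residues per column")
        for col, (res, dom) in self.conserved.items():
            if not (0 <= col < self.n_cols):
                raise SpecError(f"conserved column {col} out of range")
            if res not in AA_INDEX:
                raise SpecError(f"unknown residue {res!r}")
            if not 0 <= dom <= 1:
                raise SpecError("dominance must lie in [0, 1]")
        overlap = cons_cols & coup_cols
        if overlap:
            raise SpecError(
                f"columns planted both conserved and coupled: {sorted(overlap)}"
            )
        for col, frac in self.gappy_columns.items():
            if not (0 <= col < self.n_cols) or not 0 <= frac <= 1:
                raise SpecError(f"invalid gappy column ({col}: {frac})")
        n_rows, row_frac = self.gappy_rows
        if n_rows < 0 or n_rows > self.n_seqs or not 0 <= row_frac <= 1:
            raise SpecError(f"invalid gappy_rows spec {self.gappy_rows}")


def sample_msa(spec: SyntheticMsaSpec) -> PairedAlignment:
    """Draw an alignment from a :class:`SyntheticMsaSpec` (deterministic in seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    q = spec.background if spec.background is not None else background_frequencies()
    codes = rng.choice(N_AA, size=(spec.n_seqs, spec.n_cols), p=q).astype(np.int8)

    for col, (res, dom) in spec.conserved.items():
        hit = rng.random(spec.n_seqs) < dom
        codes[hit, col] = AA_INDEX[res]

    for (i, j), (states, corr) in spec.coupled.items():
        (a1, b1), (a2, b2) = states
        ai = np.array([AA_INDEX[a1], AA_INDEX[a2]], dtype=np.int8)
        bj = np.array([AA_INDEX[b1], AA_INDEX[b2]], dtype=np.int8)
        joint = rng.random(spec.n_seqs) < corr
        s_i = rng.integers(0, 2, size=spec.n_seqs)
        s_j = np.where(joint, s_i, rng.integers(0, 2, size=spec.n_seqs))
        codes[:, i] = ai[s_i]
        codes[:, j] = bj[s_j]

    if spec.gap_rate > 0:
        codes[rng.random(codes.shape) < spec.gap_rate] = GAP_CODE
    for col, frac in spec.gappy_columns.items():
        codes[rng.random(spec.n_seqs) < frac, col] = GAP_CODE
    n_rows, row_frac = spec.gappy_rows
    if n_rows and row_frac:
        k = int(round(row_frac * spec.n_cols))
        for r in range(spec.n_seqs - n_rows, spec.n_seqs):
            cols = rng.choice(spec.n_cols, size=k, replace=False)
            codes[r, cols] = GAP_CODE
    return alignment_from_codes(codes, domain_ranges=spec.domain_ranges)


def family_study_spec(seed: int = 0) -> SyntheticMsaSpec:
    """Family-scale synthetic paired MSA emulating the TCS study conditions.

    4100 raw paired sequences of 176 columns (DHp 64 + Rec 112); 31 rows
    carry 25% gaps (removed by the 0.2 sequence filter, leaving 4069) and
    four columns carry 70% gaps (two DHp terminals, one Rec terminal, one
    mid-Rec column standing in for the column gapped in the reference
    complex sequence; removed by the 0.5 column filter, leaving 172 = 62
    DHp + 110 Rec). Sixteen Rec columns are planted strongly conserved
    (dominance 0.92, clearing the C_i >= 2.0 selection) plus two DHp
    phosphotransfer-like columns; six column pairs (three touching DHp)
    are planted covarying at correlation 0.95, clearing C_ij >= 1.10 while
    their columns stay between the 1.20 and 2.0 conservation marks.
    """
    dom = {"DHp": (0, 64), "Rec": (64, 176)}
    conserved_rec = {
        72: "D", 73: "K", 75: "T", 78: "G", 80: "E", 83: "D", 88: "N",
        92: "W", 97: "R", 103: "D", 110: "P", 118: "H", 126: "Y",
        140: "F", 150: "M", 160: "C",
    }
    conserved = {c: (aa, 0.92) for c, aa in conserved_rec.items()}
    conserved[20] = ("H", 0.95)  # phosphoacceptor-like DHp columns
    conserved[24] = ("T", 0.92)
    two_state = (("A", "L"), ("G", "S"))
    coupled = {
        (10, 100): (two_state, 0.95),  # DHp-Rec cross couplings
        (30, 120): (two_state, 0.95),
        (45, 135): (two_state, 0.95),
        (85, 145): (two_state, 0.95),  # intra-Rec couplings
        (105, 155): (two_state, 0.95),
        (115, 165): (two_state, 0.95),
    }
    # a weak-to-strong ladder of additional couplings: empirical family
    # spectra show a continuum of coupling magnitudes, not just the top tier
    used = set(conserved) | {c for pair in coupled for c in pair} | {0, 63, 130, 175}
    free = [c for c in range(64, 176) if c not in used]
    ladder = [0.25 + 0.03 * k for k in range(20)]  # 0.25 .. 0.82
    for k, corr in enumerate(ladder):
        i, j = free[2 * k], free[2 * k + 1]
        coupled[(i, j)] = (two_state, corr)
    return SyntheticMsaSpec(
        n_seqs=4100,
        n_cols=176,
        conserved=conserved,
        coupled=coupled,
        gap_rate=0.01,
        gappy_columns={0: 0.7, 63: 0.7, 130: 0.7, 175: 0.7},
        gappy_rows=(31, 0.25),
        seed=seed,
        domain_ranges=dom,
    )


# ---------------------------------------------------------------------------
# toy structures


@dataclass(frozen=True)
class ToyStructure:
    """A compact lattice fold with designated position classes.

    Buried/surface classes are derived from intra-chain contact counts of the
    first (evolving) chain; interface positions (two-chain variant) are those
    with at least one inter-chain contact. Global residue indices follow the
    chain order A then B.
    """

    structure: Structure
    contact_map: ContactMap
    buried: tuple[int, ...]
    surface: tuple[int, ...]
    interface: tuple[int, ...]
    seed: int

    @property
    def n_chain_a(self) -> int:
        return sum(1 for c in self.contact_map.chain_of if c == "A")


def _snake_coords(n: int) -> np.ndarray:
    """Boustrophedon path through a compact cubic-lattice block."""
    nx = max(2, int(round(n ** (1.0 / 3.0))))
    ny = max(2, int(np.ceil(np.sqrt(n / nx))))
    nz = int(np.ceil(n / (nx * ny)))
    sites = []
    for z in range(nz):
        ys = range(ny) if z % 2 == 0 else range(ny - 1, -1, -1)
        for yi, y in enumerate(ys):
            fwd = (z * ny + yi) % 2 == 0
            xs = range(nx) if fwd else range(nx - 1, -1, -1)
            for x in xs:
                sites.append((x, y, z))
                if len(sites) == n:
                    return np.asarray(sites, dtype=float) * LATTICE_SPACING
    return np.asarray(sites, dtype=float) * LATTICE_SPACING


def make_toy_structure(
    n_res: int, chains: int = 1, seed: int = 0, cutoff: float = 5.0, min_sep: int = 2
) -> ToyStructure:
    """Deterministic compact lattice fold with side-chain pseudo-atoms.

    A two-chain variant places a second identical block facing the first
    across a 4.2 Angstrom gap, creating a contiguous interface.
    """
    if n_res < 8:
        raise ConfigurationError("toy structures need at least 8 residues per chain")
    if chains not in (1, 2):
        raise ConfigurationError("chains must be 1 or 2")
    rng = np.random.default_rng(seed)
    ca = _snake_coords(n_res)
    residues: list[Residue] = []
    for chain_no in range(chains):
        cid = "AB"[chain_no]
        offset = np.zeros(3)
        if chain_no == 1:
            offset[0] = ca[:, 0].max() + 4.2
        for i in range(n_res):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cb = ca[i] + offset + 0.9 * direction
            residues.append(
                Residue(
                    chain=cid,
                    resnum=i + 1,
                    name="A",
                    coords=np.vstack([ca[i] + offset, cb]),
                )
            )
    s = Structure(residues=tuple(residues))
    cmap = build_contact_map(s, cutoff=cutoff, min_sep=min_sep)

    # buried/surface from intra-chain contact counts of chain A
    a_pairs = cmap.intra_pairs("A")
    deg = np.zeros(n_res, dtype=int)
    np.add.at(deg, a_pairs.ravel(), 1)
    lo_q, hi_q = np.quantile(deg, 0.25), np.quantile(deg, 0.75)
    if hi_q > lo_q:
        buried = tuple(np.nonzero(deg >= hi_q)[0].tolist())
        surface = tuple(np.nonzero(deg <= lo_q)[0].tolist())
    else:
        buried = tuple(np.nonzero(deg == deg.max())[0].tolist())
        surface = tuple(np.nonzero(deg == deg.min())[0].tolist())
    if not buried or not surface or deg[list(buried)].min() <= deg[list(surface)].max():
        raise GenerationError("degenerate contact-count spread: no buried/surface split")

    inter = cmap.inter_pairs()
    interface = tuple(sorted(set(inter.ravel().tolist()))) if inter.size else ()
    return ToyStructure(
        structure=s,
        contact_map=cmap,
        buried=buried,
        surface=surface,
        interface=interface,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# decoy ensembles


def _flat_pair_arrays(
    decoy_pairs: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ia, ib, did = [], [], []
    for d, pairs in enumerate(decoy_pairs):
        if pairs.size:
            ia.append(pairs[:, 0])
            ib.append(pairs[:, 1])
            did.append(np.full(pairs.shape[0], d))
    if not ia:
        return (np.empty(0, int), np.empty(0, int), np.empty(0, int))
    return (
        np.concatenate(ia),
        np.concatenate(ib),
        np.concatenate(did),
    )


class _DecoySetBase:
    """Shared fast energy evaluation over a native map and decoy maps."""

    kind = "folding"

    def __init__(
        self, native_pairs: np.ndarray, decoy_pairs: list[np.ndarray], n_residues: int
    ):
        if len(decoy_pairs) < 2:
            raise ConfigurationError("a decoy set needs at least 2 decoys")
        self.native_pairs = np.asarray(native_pairs, dtype=int).reshape(-1, 2)
        self.decoy_pairs = [np.asarray(p, dtype=int).reshape(-1, 2) for p in decoy_pairs]
        self.n_residues = int(n_residues)
        self._ia, self._ib, self._did = _flat_pair_arrays(self.decoy_pairs)

    @property
    def n_decoys(self) -> int:
        return len(self.decoy_pairs)

    def energies(self, codes: np.ndarray, em: np.ndarray) -> tuple[float, np.ndarray]:
        """(native energy, per-decoy energy vector) of one sequence."""
        codes = np.asarray(codes, dtype=int)
        e_native = float(em[codes[self.native_pairs[:, 0]], codes[self.native_pairs[:, 1]]].sum()) if self.native_pairs.size else 0.0
        if self._ia.size:
            vals = em[codes[self._ia], codes[self._ib]]
            e_decoys = np.bincount(self._did, weights=vals, minlength=self.n_decoys)
        else:
            e_decoys = np.zeros(self.n_decoys)
        return e_native, e_decoys

    def ensemble(self, codes: np.ndarray, em: np.ndarray, kT: float = 1.0) -> DecoyEnsemble:
        e_n, e_d = self.energies(codes, em)
        return DecoyEnsemble(native_energy=e_n, decoy_energies=e_d, kind=self.kind, kT=kT)

    def ground_state(self, codes: np.ndarray, em: np.ndarray) -> bool:
        e_n, e_d = self.energies(codes, em)
        return bool(e_n < e_d.min())


class FoldingDecoySet(_DecoySetBase):
    """Native intra-chain contact map plus alternative (decoy) maps."""

    kind = "folding"


class BindingDecoySet(_DecoySetBase):
    """Native inter-chain contacts plus alternative binding-pose contacts.

    Under the rigid-binding convention all energies are E12 only: the intra
    terms are identical across poses and cancel from every comparison.
    """

    kind = "binding"


def folding_decoys(
    native: ContactMap,
    n: int,
    mode: str = "rewire",
    seed: int = 0,
    fixture_maps: list[ContactMap] | None = None,
    max_attempts_factor: int = 200,
) -> FoldingDecoySet:
    """Build a folding-decoy set for a single-chain native contact map.

    ``rewire`` (default): each decoy is a uniformly random set of valid
    residue pairs (respecting the minimum sequence separation) with exactly
    the native's contact count — like threading onto an unrelated fold, the
    decoy's contact-degree pattern is uncorrelated with the native burial
    pattern. ``rewire-degree``: degree-preserving randomization by repeated
    edge swaps (each residue keeps its native contact count; note this makes
    decoys inherit the native burial pattern, which suppresses
    burial-dependent selection signals). ``thread``: contact maps of other
    (fixture) structures truncated to this chain's length. The native map
    itself is never a decoy.
    """
    if n < 2:
        raise ConfigurationError("need at least 2 decoys")
    pairs = native.pairs
    if mode == "thread":
        if not fixture_maps:
            raise ConfigurationError("thread mode needs fixture_maps")
        L = native.n_residues
        decoys = []
        for fm in fixture_maps:
            keep = fm.pairs[(fm.pairs < L).all(axis=1)]
            decoys.append(keep)
        if len(decoys) < n:
            raise GenerationError(f"only {len(decoys)} fixture maps for {n} decoys")
        return FoldingDecoySet(pairs, decoys[:n], native.n_residues)
    if mode not in ("rewire", "rewire-degree"):
        raise ConfigurationError(f"unknown decoy mode {mode!r}")

    rng = np.random.default_rng(seed)
    native_set = frozenset(map(tuple, pairs.tolist()))
    k = pairs.shape[0]
    min_sep = native.min_sep

    if mode == "rewire":
        L = native.n_residues
        ii, jj = np.triu_indices(L, k=min_sep)
        all_pairs = np.stack([ii, jj], axis=1)
        if all_pairs.shape[0] < k + 1:
            raise GenerationError("too few valid pairs to randomize the contact map")
        decoys = []
        attempts = 0
        budget = max_attempts_factor * n
        while len(decoys) < n:
            attempts += 1
            if attempts > budget:
                raise GenerationError(
                    f"randomization produced {len(decoys)}/{n} decoys in {budget} attempts"
                )
            pick = rng.choice(all_pairs.shape[0], size=k, replace=False)
            cand = all_pairs[np.sort(pick)]
            if frozenset(map(tuple, cand.tolist())) == native_set:
                continue
            decoys.append(cand)
        return FoldingDecoySet(pairs, decoys, native.n_residues)

    decoys: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_factor * n
    while len(decoys) < n:
        attempts += 1
        if attempts > budget:
            raise GenerationError(
                f"rewiring produced {len(decoys)}/{n} decoys in {budget} attempts"
            )
        edges = [tuple(p) for p in pairs.tolist()]
        edge_set = set(edges)
        n_swaps = 0
        for _ in range(20 * k):
            if n_swaps >= 10 * k:
                break
            e1, e2 = rng.integers(0, k, size=2)
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if rng.random() < 0.5:
                p1, p2 = (a, d), (c, b)
            else:
                p1, p2 = (a, c), (b, d)
            p1 = (min(p1), max(p1))
            p2 = (min(p2), max(p2))
            if p1[0] == p1[1] or p2[0] == p2[1]:
                continue
            if p1[1] - p1[0] < min_sep or p2[1] - p2[0] < min_sep:
                continue
            if p1 in edge_set or p2 in edge_set or p1 == p2:
                continue
            edge_set -= {edges[e1], edges[e2]}
            edge_set |= {p1, p2}
            edges[e1], edges[e2] = p1, p2
            n_swaps += 1
        if frozenset(edge_set) == native_set:
            continue
        decoys.append(np.asarray(sorted(edge_set), dtype=int))
    return FoldingDecoySet(pairs, decoys, native.n_residues)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def binding_decoys(
    toy: ToyStructure,
    n: int,
    seed: int = 0,
    max_translation: float = 12.0,
    max_contact_fraction: float = 0.75,
    max_attempts_factor: int = 50,
) -> BindingDecoySet:
    """Rigid-body binding-pose decoys for a two-chain toy complex.

    Each pose rotates the ligand chain (B) about its centroid and translates
    it by a random displacement of magnitude up to ``max_translation``
    Angstrom; poses with any heavy-atom pair closer than 2.0 Angstrom are
    rejected, as is any pose whose inter-chain contact set equals the native
    one (the identity transform included). Poses burying more than
    ``max_contact_fraction`` of the native interface's residue-pair count
    are rejected: pseudo-atom chains carry no excluded volume beyond the
    clash cutoff, so unconstrained rigid poses can interleave with the
    receptor lattice or re-create near-native interfaces with arbitrary
    residue pairing, and the complex would lose the defining premise of a
    funneled binding landscape — that the native pose buries the dominant
    interface. Poses with zero inter contacts are legal decoys (E12 = 0).
    """
    if n < 2:
        raise ConfigurationError("need at least 2 decoys")
    s = toy.structure
    cmap = toy.contact_map
    if len(set(cmap.chain_of)) != 2:
        raise ConfigurationError("binding decoys need a two-chain toy structure")
    idx_a = [i for i, c in enumerate(cmap.chain_of) if c == "A"]
    idx_b = [i for i, c in enumerate(cmap.chain_of) if c == "B"]
    atoms_a = [s.residues[i].coords for i in idx_a]
    atoms_b = [s.residues[i].coords for i in idx_b]
    flat_a = np.vstack(atoms_a)
    sizes_b = [c.shape[0] for c in atoms_b]
    flat_b0 = np.vstack(atoms_b)
    centroid_b = flat_b0.mean(axis=0)
    native_inter = cmap.inter_pairs()
    native_set = frozenset(map(tuple, native_inter.tolist()))

    rng = np.random.default_rng(seed)
    decoys: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_factor * n
    while len(decoys) < n:
        attempts += 1
        if attempts > budget:
            raise GenerationError(
                f"pose sampling produced {len(decoys)}/{n} decoys in {budget} attempts"
            )
        rot = _random_rotation(rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = rng.uniform(0.0, max_translation) * direction
        posed = (flat_b0 - centroid_b) @ rot.T + centroid_b + shift
        dists = np.linalg.norm(flat_a[:, None, :] - posed[None, :, :], axis=-1)
        if dists.min() < CLASH_CUTOFF:
            continue
        # residue-level inter contacts of the pose
        pose_pairs = []
        b_start = np.cumsum([0] + sizes_b)
        for bi, (lo, hi) in enumerate(zip(b_start[:-1], b_start[1:])):
            block = dists[:, lo:hi]
            a_off = 0
            for ai, coords in enumerate(atoms_a):
                sub = block[a_off : a_off + coords.shape[0]]
                a_off += coords.shape[0]
                if sub.min() < cmap.cutoff:
                    pose_pairs.append((idx_a[ai], idx_b[bi]))
        pose_arr = np.asarray(sorted(pose_pairs), dtype=int).reshape(-1, 2)
        if pose_arr.shape[0] > max_contact_fraction * len(native_set):
            continue
        if frozenset(map(tuple, pose_arr.tolist())) == native_set:
            continue
        decoys.append(pose_arr)
    return BindingDecoySet(native_inter, decoys, cmap.n_residues)


# ---------------------------------------------------------------------------
# decoy exchange format (JSON lines)


def export_decoys(decoy_set: _DecoySetBase, path: str | Path) -> None:
    """Write a decoy set as JSON lines (header + one line per decoy)."""
    with open(path, "w") as fh:
        header = {
            "schema": DECOY_SCHEMA,
            "kind": decoy_set.kind,
            "n_residues": decoy_set.n_residues,
            "native": decoy_set.native_pairs.tolist(),
        }
        fh.write(json.dumps(header) + "\n")
        for pairs in decoy_set.decoy_pairs:
            fh.write(json.dumps({"pairs": pairs.tolist()}) + "\n")


def import_decoys(path: str | Path) -> _DecoySetBase:
    """Read a decoy exchange file back into a decoy set.

    Raises :class:`DecoyFormatError` with the offending line number on any
    schema violation.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise DecoyFormatError(f"{path}: empty file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise DecoyFormatError(f"{path}:1: not JSON ({exc})") from exc
    if not isinstance(header, dict) or header.get("schema") != DECOY_SCHEMA:
        raise DecoyFormatError(f"{path}:1: missing/unknown schema field")
    kind = header.get("kind")
    if kind not in ("folding", "binding"):
        raise DecoyFormatError(f"{path}:1: unknown ensemble kind {kind!r}")
    try:
        native = np.asarray(header["native"], dtype=int).reshape(-1, 2)
        n_res = int(header["n_residues"])
    except (KeyError, TypeError, ValueError) as exc:
        raise DecoyFormatError(f"{path}:1: bad header ({exc})") from exc
    decoys: list[np.ndarray] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        try:
            row = json.loads(ln)
            pairs = np.asarray(row["pairs"], dtype=int).reshape(-1, 2)
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise DecoyFormatError(f"{path}:{lineno}: malformed decoy row ({exc})") from exc
        decoys.append(pairs)
    cls = FoldingDecoySet if kind == "folding" else BindingDecoySet
    return cls(native, decoys, n_res)
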