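"""Genetic-algorithm sequence evolution on a funneled contact-energy landscape.

A population of sequences evolves against a fixed target structure. At each
step one population slot is touched: a randomly chosen member is mutated at a
random position; if the mutant keeps the native conformation as its unique
ground state (strictly lowest energy against the folding — and, with a
binding partner, binding — decoy ensemble) it replaces the original,
otherwise the slot is refilled with a member drawn by rank-based wheel
selection, where the combined rank is the sum of the per-component ranks of
(dG_f, Lambda_f) and, in the folding+binding condition, (dG_b, Lambda_b).

Wheel probabilities follow the decreasing recurrence P_{n+1} = P_n (1 - P_n)
from P_1 = 0.05 over the rank order, normalized to sum 1 (a geometric
variant P_n = P_1 (1 - P_1)^(n-1) is available). The run is monitored by the
population's Shannon sequence entropy H = -sum_{i,a} P_ia ln P_ia (nats, over
the full sequence length) and stops when the window-averaged entropy stops
changing or a step cap is reached.

Two conditions are supported: ``FS`` (folding-only selection; evolved
folding sequences) and ``FBS`` (folding + binding selection with the partner
chain's native sequence fixed; evolved folding-binding sequences).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import N_AA
from .errors import ConfigurationError, InitializationError
from .fitness import accessibility, fitness_ranks, stability
from .synthetic import BindingDecoySet, FoldingDecoySet


@dataclass(frozen=True)
class SelectionConfig:
    """Tunables of one GA run."""

    population_size: int = 500
    p1: float = 0.05
    recurrence: str = "logistic"  # logistic: P_{n+1} = P_n(1-P_n); or "geometric"
    seed: int = 0
    kT: float = 1.0
    mutation_alphabet: int = N_AA
    prefilter_initial: bool = True
    max_init_attempts_factor: int = 400

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population size must be >= 2")
        if not 0 < self.p1 < 1:
            raise ConfigurationError("P_1 must lie in (0, 1)")
        if self.mutation_alphabet < 2:
            raise ConfigurationError("mutation alphabet must have >= 2 residue types")


def selection_probabilities(
    pop_size: int, p1: float = 0.05, recurrence: str = "logistic"
) -> np.ndarray:
    """Normalized, strictly decreasing selection probabilities over ranks 1..n."""
    if pop_size < 1:
        raise ConfigurationError("pop_size must be >= 1")
    p = np.empty(pop_size)
    if recurrence == "logistic":
        p[0] = p1
        for n in range(1, pop_size):
            p[n] = p[n - 1] * (1.0 - p[n - 1])
    elif recurrence == "geometric":
        p[:] = p1 * (1.0 - p1) ** np.arange(pop_size)
    else:
        raise ConfigurationError(f"unknown recurrence {recurrence!r}")
    return p / p.sum()


@dataclass
class FitnessContext:
    """Everything needed to score and admit sequences in one condition."""

    em: np.ndarray  # 20x20 contact potential
    folding: FoldingDecoySet
    condition: str = "FS"  # FS | FBS
    binding: BindingDecoySet | None = None
    hk_codes: np.ndarray | None = None  # partner chain, fixed native sequence
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.condition not in ("FS", "FBS"):
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.condition == "FBS" and (self.binding is None or self.hk_codes is None):
            raise ConfigurationError("FBS condition needs a binding ensemble and partner sequence")

    @property
    def length(self) -> int:
        return self.folding.n_residues

    @property
    def fitness_mode(self) -> str:
        return "folding" if self.condition == "FS" else "folding+binding"

    def _full_codes(self, rec_codes: np.ndarray) -> np.ndarray:
        return np.concatenate([rec_codes, self.hk_codes])

    def ground_state(self, rec_codes: np.ndarray) -> bool:
        """Unique-ground-state admission test for this condition."""
        if not self.folding.ground_state(rec_codes, self.em):
            return False
        if self.condition == "FBS":
            return self.binding.ground_state(self._full_codes(rec_codes), self.em)
        return True

    def report(self, rec_codes: np.ndarray) -> np.ndarray:
        """(dG_f, Lambda_f, dG_b, Lambda_b); binding components 0 in FS mode."""
        ens_f = self.folding.ensemble(rec_codes, self.em, kT=self.kT)
        out = np.zeros(4)
        out[0] = stability(ens_f)
        out[1] = accessibility(ens_f)
        if self.condition == "FBS":
            ens_b = self.binding.ensemble(self._full_codes(rec_codes), self.em, kT=self.kT)
            out[2] = stability(ens_b)
            out[3] = accessibility(ens_b)
        return out


@dataclass
class EvolutionTrace:
    """Bookkeeping of one GA run."""

    condition: str
    seed: int
    entropy: np.ndarray = field(default_factory=lambda: np.empty(0))
    accepted_mutations: int = 0
    wheel_replacements: int = 0
    converged: bool = False
    steps: int = 0
    initial_population: np.ndarray | None = None
    final_population: np.ndarray | None = None


def sequence_entropy(pop: np.ndarray) -> float:
    """Shannon entropy of the population's per-column residue distribution (nats)."""
    pop = np.atleast_2d(pop)
    if pop.size == 0:
        raise ConfigurationError("empty population")
    n, L = pop.shape
    h = 0.0
    for j in range(L):
        counts = np.bincount(pop[:, j], minlength=N_AA)[:N_AA]
        p = counts[counts > 0] / n
        h -= float((p * np.log(p)).sum())
    return h


def _entropy_from_counts(counts: np.ndarray, n: int) -> float:
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -float(terms.sum())


def initialize_population(
    length: int, cfg: SelectionConfig, ctx: FitnessContext, rng: np.random.Generator
) -> np.ndarray:
    """Random initial population, optionally pre-filtered by the ground state.

    Rejection sampling over uniform random sequences within a bounded attempt
    budget; remaining slots are seeded by single mutations of accepted
    members (and, as a last resort, copies). Raises
    :class:`InitializationError` if no sequence at all is admissible.
    """
    accepted: list[np.ndarray] = []
    budget = cfg.max_init_attempts_factor * cfg.population_size
    if not cfg.prefilter_initial:
        return rng.integers(
            0, cfg.mutation_alphabet, size=(cfg.population_size, length)
        ).astype(np.int8)
    for _ in range(budget):
        cand = rng.integers(0, cfg.mutation_alphabet, size=length).astype(np.int8)
        if ctx.ground_state(cand):
            accepted.append(cand)
            if len(accepted) == cfg.population_size:
                break
    if not accepted:
        raise InitializationError(
            f"no admissible sequence in {budget} random draws "
            f"(condition {ctx.condition}, length {length})"
        )
    mut_budget = budget
    while len(accepted) < cfg.population_size and mut_budget > 0:
        mut_budget -= 1
        parent = accepted[rng.integers(0, len(accepted))].copy()
        pos = rng.integers(0, length)
        parent[pos] = _mutate_identity(parent[pos], cfg.mutation_alphabet, rng)
        if ctx.ground_state(parent):
            accepted.append(parent)
    while len(accepted) < cfg.population_size:
        accepted.append(accepted[rng.integers(0, len(accepted))].copy())
    return np.vstack(accepted[: cfg.population_size])


def _mutate_identity(old: int, alphabet_size: int, rng: np.random.Generator) -> int:
    new = rng.integers(0, alphabet_size - 1)
    return int(new if new < old else new + 1)


def evolve_step(
    pop: np.ndarray,
    reports: np.ndarray,
    cfg: SelectionConfig,
    ctx: FitnessContext,
    rng: np.random.Generator,
    wheel: np.ndarray,
) -> tuple[int, bool, np.ndarray]:
    """One GA step, mutating ``pop`` and ``reports`` in place.

    Returns (slot index touched, mutation accepted?, previous slot content).
    Exactly one slot changes: to the mutant if it passes the ground-state
    test, otherwise to a wheel-selected copy of an existing member.
    """
    n, L = pop.shape
    slot = int(rng.integers(0, n))
    old_row = pop[slot].copy()
    mutant = old_row.copy()
    pos = int(rng.integers(0, L))
    mutant[pos] = _mutate_identity(int(mutant[pos]), cfg.mutation_alphabet, rng)
    if ctx.ground_state(mutant):
        pop[slot] = mutant
        reports[slot] = ctx.report(mutant)
        return slot, True, old_row
    combined, _ = fitness_ranks(reports, mode=ctx.fitness_mode)
    # member with combined rank r sits at wheel probability index r-1
    by_rank = np.argsort(combined, kind="stable")
    pick = by_rank[int(rng.choice(n, p=wheel))]
    pop[slot] = pop[pick].copy()
    reports[slot] = reports[pick].copy()
    return slot, False, old_row


def run_evolution(
    condition: str,
    cfg: SelectionConfig,
    ctx: FitnessContext,
    max_steps: int = 200_000,
    convergence_window: int = 1000,
    convergence_tol: float = 1e-3,
    entropy_stride: int = 1,
) -> tuple[EvolutionTrace, np.ndarray]:
    """Run one GA replicate until entropy convergence or the step cap.

    Convergence: the relative change between consecutive window-averaged
    entropies falls below ``convergence_tol``. Returns the trace and the
    final population (the evolved sequence set). Fully deterministic in
    ``cfg.seed``.
    """
    if condition != ctx.condition:
        raise ConfigurationError(
            f"condition {condition!r} does not match context {ctx.condition!r}"
        )
    rng = np.random.default_rng(cfg.seed)
    L = ctx.length
    pop = initialize_population(L, cfg, ctx, rng)
    reports = np.vstack([ctx.report(seq) for seq in pop])
    wheel = selection_probabilities(cfg.population_size, cfg.p1, cfg.recurrence)

    counts = np.zeros((L, N_AA), dtype=np.int64)
    for j in range(L):
        counts[j] = np.bincount(pop[:, j], minlength=N_AA)[:N_AA]

    trace = EvolutionTrace(condition=condition, seed=cfg.seed)
    trace.initial_population = pop.copy()
    entropies: list[float] = []
    window_means: list[float] = []
    converged = False
    step = 0
    cols = np.arange(L)
    while step < max_steps:
        slot, accepted, old_row = evolve_step(pop, reports, cfg, ctx, rng, wheel)
        # counts maintained incrementally by diffing the one replaced row
        counts[cols, old_row.astype(int)] -= 1
        counts[cols, pop[slot].astype(int)] += 1
        if accepted:
            trace.accepted_mutations += 1
        else:
            trace.wheel_replacements += 1
        step += 1
        if step % entropy_stride == 0:
            entropies.append(_entropy_from_counts(counts, cfg.population_size))
        if step % convergence_window == 0 and len(entropies) >= 2 * (
            convergence_window // entropy_stride
        ):
            w = convergence_window // entropy_stride
            cur = float(np.mean(entropies[-w:]))
            prev = float(np.mean(entropies[-2 * w : -w]))
            window_means.append(cur)
            if abs(cur - prev) / max(abs(prev), 1e-12) < convergence_tol:
                converged = True
                break
    trace.converged = converged
    trace.steps = step
    trace.entropy = np.asarray(entropies)
    trace.final_population = pop.copy()
    return trace, pop


def design_by_annealing(
    folding: FoldingDecoySet,
    em: np.ndarray,
    n_seqs: int,
    seed: int = 0,
    n_steps: int = 3000,
    temperature: float = 1.5,
) -> np.ndarray:
    """Structure-adapted reference sequences by native-energy annealing.

    A stand-in for a natural-sequence set on toy structures: each sequence is
    a Metropolis walk minimizing only the native contact energy (no decoy
    ensembles, no selection machinery), so it shares the structure with the
    GA-evolved sets but none of their fitness apparatus. Synthetic: these are
    not homologs of any real family.
    """
    rng = np.random.default_rng(seed)
    L = folding.n_residues
    partners: list[np.ndarray] = []
    for pos in range(L):
        p = folding.native_pairs
        sel = (p[:, 0] == pos) | (p[:, 1] == pos)
        partners.append(np.where(p[sel, 0] == pos, p[sel, 1], p[sel, 0]))
    out = np.empty((n_seqs, L), dtype=np.int8)
    for s in range(n_seqs):
        seq = rng.integers(0, N_AA, size=L).astype(np.int8)
        for _ in range(n_steps):
            pos = int(rng.integers(0, L))
            old = int(seq[pos])
            new = _mutate_identity(old, N_AA, rng)
            nb = seq[partners[pos]].astype(int)
            delta = float((em[new, nb] - em[old, nb]).sum())
            if delta <= 0 or rng.random() < np.exp(-delta / temperature):
                seq[pos] = new
        out[s] = seq
    return out
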