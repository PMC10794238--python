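"""Decoy-ensemble selection fitness: stability, accessibility, ground state.

For a sequence with native energy E_N and decoy energies {E_d} the two
selection-fitness components are

* thermodynamic stability  dG = -kT ln(P_N / P_D), with P_N = exp(-E_N/kT)
  and P_D = sum_d exp(-E_d/kT)  (more negative = more stable), and
* kinetic accessibility  Lambda = sqrt(K_B / 2S) * deltaE / DeltaE, the
  funnel Z-score, with deltaE = mean(E_d) - E_N, DeltaE = std(E_d) and the
  conformational entropy taken as S = ln(number of decoys); K_B = 1 in the
  contact-potential units and kT defaults to 1.

A sequence is admissible only if the native conformation is its unique
ground state: E_N strictly below every decoy energy.

Population fitness is rank-based: per component, rank 1 is best (most
negative dG, largest Lambda), the combined fitness is the sum of component
ranks, and ties are broken by stable input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigurationError, DegenerateEnsembleError


@dataclass(frozen=True)
class DecoyEnsemble:
    """Native energy plus decoy energies of one sequence on one ensemble."""

    native_energy: float
    decoy_energies: np.ndarray
    kind: str = "folding"  # folding | binding
    kT: float = 1.0

    def __post_init__(self) -> None:
        e = np.asarray(self.decoy_energies, dtype=float)
        object.__setattr__(self, "decoy_energies", e)
        if e.size < 2:
            raise ConfigurationError("a decoy ensemble needs at least 2 decoys")
        if not (np.isfinite(e).all() and np.isfinite(self.native_energy)):
            raise ConfigurationError("non-finite energies in ensemble")
        if self.kT <= 0:
            raise ConfigurationError("temperature factor must be positive")

    @property
    def entropy(self) -> float:
        """Conformational entropy S = ln(ensemble size)."""
        return float(np.log(self.decoy_energies.size))


def stability(ens: DecoyEnsemble) -> float:
    """dG = -kT ln(P_N/P_D), evaluated via log-sum-exp (overflow-safe)."""
    kT = ens.kT
    log_pd = logsumexp(-ens.decoy_energies / kT)
    return float(ens.native_energy + kT * log_pd)


def accessibility(ens: DecoyEnsemble) -> float:
    """Funnel Z-score Lambda = sqrt(1/(2S)) * deltaE / DeltaE."""
    e = ens.decoy_energies
    delta_e = float(e.std())  # population standard deviation
    if delta_e == 0.0:
        raise DegenerateEnsembleError("decoy energies have zero variance")
    gap = float(e.mean()) - ens.native_energy
    s = ens.entropy
    if s <= 0:
        raise DegenerateEnsembleError("conformational entropy must be positive")
    return float(np.sqrt(1.0 / (2.0 * s)) * gap / delta_e)


def ground_state_check(ens: DecoyEnsemble) -> bool:
    """True iff the native energy is strictly below every decoy energy."""
    return bool(ens.native_energy < ens.decoy_energies.min())


def _component_ranks(values: np.ndarray, best_high: bool) -> np.ndarray:
    """Rank 1 = best; ties resolved by stable input order."""
    order = np.argsort(-values if best_high else values, kind="stable")
    ranks = np.empty(values.size, dtype=int)
    ranks[order] = np.arange(1, values.size + 1)
    return ranks


def fitness_ranks(
    reports: np.ndarray, mode: str = "folding+binding"
) -> tuple[np.ndarray, np.ndarray]:
    """Combined fitness ranks of a population.

    ``reports`` is (n, 4) with columns (dG_f, Lambda_f, dG_b, Lambda_b); in
    ``"folding"`` mode only the first two columns are used. Returns
    (combined_rank, component_ranks) where combined_rank is 1 = fittest
    (smallest sum of component ranks, ties stable).
    """
    reports = np.atleast_2d(np.asarray(reports, dtype=float))
    if reports.shape[0] == 0:
        raise ConfigurationError("empty population")
    if mode == "folding":
        cols, best_high = [0, 1], [False, True]
    elif mode == "folding+binding":
        cols, best_high = [0, 1, 2, 3], [False, True, False, True]
    else:
        raise ConfigurationError(f"unknown fitness mode {mode!r}")
    comp = np.stack(
        [_component_ranks(reports[:, c], h) for c, h in zip(cols, best_high)], axis=1
    )
    combined_sum = comp.sum(axis=1)
    combined = _component_ranks(combined_sum.astype(float), best_high=False)
    return combined, comp
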