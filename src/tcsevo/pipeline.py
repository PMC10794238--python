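"""End-to-end orchestration of the two analysis tracks.

The family track chains alignment filtering, first-order conservation,
hydrophobic preference, coupling conservation, threshold selections, and the
power-law spectrum fit, writing tab-separated tables plus a JSON manifest.
The evolution track chains toy-complex construction, decoy-ensemble
generation, GA evolution under folding-only (FS) and folding+binding (FBS)
selection, frustration profiles of the evolved sets, and the frustration
change classification with interface-enrichment statistics.

Outputs are written atomically (temp file + rename) and registered in a
:class:`RunManifest`; a failed stage therefore leaves no unmarked partial
outputs.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alphabet import N_AA
from .conservation import (
    conservation_profile,
    coupling_conservation,
    fit_powerlaw_spectrum,
    select_top,
)
from .errors import ConfigurationError, FitError, InputError
from .evolution import FitnessContext, SelectionConfig, run_evolution
from .frustration import (
    ensemble_frustration_profile,
    frustration_delta,
    interface_enrichment_test,
    profile_correlation,
)
from .msa import (
    PairedAlignment,
    estimate_frequencies,
    filter_alignment,
    read_paired_alignment,
)
from .synthetic import (
    SyntheticMsaSpec,
    ToyStructure,
    binding_decoys,
    folding_decoys,
    make_toy_structure,
    sample_msa,
)
from .tables import mj_matrix


@dataclass
class RunManifest:
    """Config snapshot, seeds, timings, and registered outputs of one run."""

    track: str
    version: str = __version__
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def register(self, path: Path) -> None:
        if not path.exists():
            raise InputError(f"output missing at registration: {path}")
        self.outputs.append(str(path))

    def write(self, path: Path) -> None:
        _atomic_write_text(path, json.dumps(asdict(self), indent=2) + "\n")


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _atomic_write_df(path: Path, df: pd.DataFrame) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False, float_format="%.6g")
    os.replace(tmp, path)


def run_family_track(
    msa: str | Path | PairedAlignment | SyntheticMsaSpec,
    out_dir: str | Path,
    max_seq_gap_frac: float = 0.2,
    max_col_gap_frac: float = 0.5,
    pseudocount: float = 1e-4,
    conservation_threshold: float = 2.0,
    coupling_threshold: float = 1.10,
    bin_width: float = 0.1,
    fit_range: tuple[float, float] | None = None,
    domain_ranges: dict[str, tuple[int, int]] | None = None,
) -> dict:
    """Family-wide conservation/coupling statistics with reports.

    ``msa`` may be an aligned-FASTA path, an in-memory alignment, or a
    synthetic MSA spec. Returns a result dict (thresholded selections,
    spectrum fit, paths); tables land in ``out_dir``.
    """
    t0 = time.monotonic()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(track="family")
    manifest.config = {
        "max_seq_gap_frac": max_seq_gap_frac,
        "max_col_gap_frac": max_col_gap_frac,
        "pseudocount": pseudocount,
        "conservation_threshold": conservation_threshold,
        "coupling_threshold": coupling_threshold,
        "bin_width": bin_width,
    }

    if isinstance(msa, SyntheticMsaSpec):
        aln = sample_msa(msa)
        manifest.seeds["msa"] = msa.seed
    elif isinstance(msa, PairedAlignment):
        aln = msa
    else:
        aln = read_paired_alignment(msa, domain_ranges)
        manifest.config["input"] = str(msa)

    filtered = filter_alignment(aln, max_seq_gap_frac, max_col_gap_frac)
    freqs = estimate_frequencies(filtered, pseudocount=pseudocount)
    profile = conservation_profile(filtered, pseudocount=pseudocount)
    coupling = coupling_conservation(freqs)
    try:
        fit = fit_powerlaw_spectrum(coupling, bin_width=bin_width, fit_range=fit_range)
    except FitError as exc:  # tiny spectra may not populate 3 bins
        fit = None
        fit_note = str(exc)

    domains = [filtered.domain_of_column(j) for j in range(filtered.column_count)]
    cols_df = pd.DataFrame(
        {
            "column": np.arange(filtered.column_count),
            "domain": domains,
            "C_i": profile.C,
            "P_H": profile.PH,
        }
    )
    cols_path = out / "columns.tsv"
    _atomic_write_df(cols_path, cols_df)
    manifest.register(cols_path)

    top_cols, _ = select_top(profile.C, conservation_threshold)
    top_pairs, pair_info = select_top(coupling.C2, coupling_threshold)
    pairs_df = pd.DataFrame(
        {
            "i": top_pairs[:, 0] if top_pairs.size else [],
            "j": top_pairs[:, 1] if top_pairs.size else [],
            "C_ij": [coupling.C2[i, j] for i, j in top_pairs] if top_pairs.size else [],
        }
    )
    pairs_path = out / "top_coupling_pairs.tsv"
    _atomic_write_df(pairs_path, pairs_df)
    manifest.register(pairs_path)

    touched = pair_info.get("touched_columns", np.array([], dtype=int))
    results = {
        "n_sequences": int(filtered.n_seqs),
        "n_columns": int(filtered.column_count),
        "domain_ranges": {k: [int(v[0]), int(v[1])] for k, v in filtered.domain_ranges.items()},
        "removed_columns": [int(c) for c in filtered.removed_columns],
        "top_conserved_columns": [int(c) for c in top_cols],
        "top_conserved_by_domain": {
            d: int(sum(1 for c in top_cols if domains[c] == d))
            for d in filtered.domain_ranges
        },
        "n_top_coupling_pairs": int(pair_info["count"]),
        "touched_columns": [int(c) for c in touched],
        "touched_by_domain": {
            d: int(sum(1 for c in touched if domains[c] == d))
            for d in filtered.domain_ranges
        },
        "min_C_over_touched": float(profile.C[touched].min()) if touched.size else None,
        "powerlaw": (
            {
                "prefactor": fit.prefactor,
                "exponent": fit.exponent,
                "r_squared": fit.r_squared,
                "n_bins_used": fit.n_bins_used,
            }
            if fit is not None
            else {"error": fit_note}
        ),
    }
    summary_path = out / "family_summary.json"
    _atomic_write_text(summary_path, json.dumps(results, indent=2) + "\n")
    manifest.register(summary_path)

    manifest.timings_s["total"] = round(time.monotonic() - t0, 3)
    manifest.write(out / "manifest.json")
    results["out_dir"] = str(out)
    return results


def build_toy_contexts(
    n_res: int = 30,
    seed: int = 0,
    n_folding_decoys: int = 100,
    n_binding_decoys: int = 100,
    kT: float = 1.0,
    hk_seed: int = 1234,
) -> tuple[ToyStructure, FitnessContext, FitnessContext]:
    """Toy two-chain complex plus FS and FBS fitness contexts.

    The partner chain's "native" sequence is a fixed random draw from the
    uniform alphabet (seeded by ``hk_seed``); the evolving chain is chain A.
    """
    em = mj_matrix()
    toy = make_toy_structure(n_res, chains=2, seed=seed)
    cmap_a = _chain_a_map(toy, n_res)  # single-chain view for folding decoys
    fold = folding_decoys(cmap_a, n_folding_decoys, seed=seed + 1)
    bind = binding_decoys(toy, n_binding_decoys, seed=seed + 2)
    rng = np.random.default_rng(hk_seed)
    hk_codes = rng.integers(0, N_AA, size=toy.contact_map.n_residues - n_res).astype(np.int8)
    ctx_fs = FitnessContext(em=em, folding=fold, condition="FS", kT=kT)
    ctx_fbs = FitnessContext(
        em=em, folding=fold, condition="FBS", binding=bind, hk_codes=hk_codes, kT=kT
    )
    return toy, ctx_fs, ctx_fbs


def run_evolution_track(
    out_dir: str | Path,
    n_res: int = 30,
    population_size: int = 100,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    structure_seed: int = 0,
    conditions: tuple[str, ...] = ("FS", "FBS"),
    max_steps: int = 6000,
    n_folding_decoys: int = 100,
    n_binding_decoys: int = 100,
    n_frustration_decoys: int = 1000,
    delta_threshold: float = 0.70,
    kT: float = 1.0,
) -> dict:
    """Evolve FS/FBS populations on a toy complex and profile frustration.

    Per seed and condition one GA replicate runs to entropy convergence (or
    the step cap); frustration profiles are averaged over the final
    populations, FS profiles on the isolated chain contacts and FBS profiles
    on the complex contacts with the partner sequence fixed. Returns entropy
    trajectories, frustration deltas, and interface-enrichment statistics.
    """
    if "FBS" in conditions and "FS" not in conditions:
        pass  # FBS alone is legal; deltas just unavailable
    t0 = time.monotonic()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(track="evolution")
    manifest.config = {
        "n_res": n_res,
        "population_size": population_size,
        "max_steps": max_steps,
        "n_folding_decoys": n_folding_decoys,
        "n_binding_decoys": n_binding_decoys,
        "delta_threshold": delta_threshold,
        "kT": kT,
    }
    manifest.seeds = {"structure": structure_seed, "replicates": list(seeds)}

    toy, ctx_fs, ctx_fbs = build_toy_contexts(
        n_res=n_res,
        seed=structure_seed,
        n_folding_decoys=n_folding_decoys,
        n_binding_decoys=n_binding_decoys,
        kT=kT,
    )
    em = mj_matrix()
    contexts = {"FS": ctx_fs, "FBS": ctx_fbs}
    runs: dict[str, list] = {c: [] for c in conditions}
    traces_rows = []
    for cond in conditions:
        if cond not in contexts:
            raise ConfigurationError(f"unknown condition {cond!r}")
        for seed in seeds:
            cfg = SelectionConfig(population_size=population_size, seed=seed, kT=kT)
            trace, pop = run_evolution(cond, cfg, contexts[cond], max_steps=max_steps)
            runs[cond].append((trace, pop))
            stride = max(1, trace.entropy.size // 250)  # keep report tables lean
            for k in range(0, trace.entropy.size, stride):
                traces_rows.append((cond, seed, k + 1, trace.entropy[k]))
    trace_df = pd.DataFrame(traces_rows, columns=["condition", "seed", "step", "entropy"])
    trace_path = out / "entropy_traces.tsv"
    _atomic_write_df(trace_path, trace_df)
    manifest.register(trace_path)

    results: dict = {"conditions": list(conditions), "entropy": {}}
    for cond in conditions:
        results["entropy"][cond] = [
            {
                "seed": tr.seed,
                "initial": float(tr.entropy[0]),
                "final": float(tr.entropy[-1]),
                "converged": tr.converged,
                "steps": tr.steps,
            }
            for tr, _ in runs[cond]
        ]

    # frustration profiles of the evolved sets
    positions_a = np.arange(n_res)
    profiles = {}
    if "FS" in runs and runs["FS"]:
        fs_seqs = np.vstack([pop for _, pop in runs["FS"]])
        profiles["FS"] = ensemble_frustration_profile(
            _subsample(fs_seqs, 60, structure_seed),
            _chain_a_map(toy, n_res),
            em,
            n_decoys=n_frustration_decoys,
            seed=structure_seed + 10,
            positions=positions_a,
            label="FSs",
        )
    if "FBS" in runs and runs["FBS"]:
        fbs_seqs = np.vstack([pop for _, pop in runs["FBS"]])
        sub = _subsample(fbs_seqs, 60, structure_seed)
        full = np.hstack([sub, np.tile(ctx_fbs.hk_codes, (sub.shape[0], 1))])
        profiles["FBS"] = ensemble_frustration_profile(
            full,
            toy.contact_map,
            em,
            n_decoys=n_frustration_decoys,
            seed=structure_seed + 11,
            positions=positions_a,
            label="FBSs",
        )

    if "FS" in profiles and "FBS" in profiles:
        pf, pb = profiles["FS"], profiles["FBS"]
        # align position supports: compare over chain A only
        delta = frustration_delta(pf, _truncate_profile(pb, n_res), delta_threshold)
        iface_a = tuple(i for i in toy.interface if i < n_res)
        stat, pval = interface_enrichment_test(
            delta.delta, iface_a, seed=structure_seed + 12
        )
        r, rp = profile_correlation(pf, _truncate_profile(pb, n_res))
        results["frustration"] = {
            "delta_threshold": delta_threshold,
            "n_less_frustrated": len(delta.less_frustrated),
            "n_more_frustrated": len(delta.more_frustrated),
            "less_frustrated": list(delta.less_frustrated),
            "more_frustrated": list(delta.more_frustrated),
            "interface_positions": list(iface_a),
            "interface_enrichment_stat": stat,
            "interface_enrichment_p": pval,
            "fs_fbs_pearson_r": r,
            "fs_fbs_pearson_p": rp,
        }
        fr_df = pd.DataFrame(
            {
                "position": positions_a,
                "F_FS": pf.F[:n_res],
                "F_FBS": pb.F[:n_res],
                "delta_F": delta.delta[:n_res],
                "interface": [int(i in iface_a) for i in positions_a],
            }
        )
        fr_path = out / "frustration_delta.tsv"
        _atomic_write_df(fr_path, fr_df)
        manifest.register(fr_path)

    summary_path = out / "evolution_summary.json"
    _atomic_write_text(summary_path, json.dumps(results, indent=2) + "\n")
    manifest.register(summary_path)
    manifest.timings_s["total"] = round(time.monotonic() - t0, 3)
    manifest.write(out / "manifest.json")
    results["out_dir"] = str(out)
    results["_runs"] = runs
    results["_toy"] = toy
    results["_contexts"] = contexts
    results["_profiles"] = profiles
    return results


def _subsample(seqs: np.ndarray, n: int, seed: int) -> np.ndarray:
    if seqs.shape[0] <= n:
        return seqs
    rng = np.random.default_rng(seed)
    idx = rng.choice(seqs.shape[0], size=n, replace=False)
    return seqs[idx]


def _chain_a_map(toy: ToyStructure, n_res: int):
    from .structure import ContactMap

    intra_a = toy.contact_map.intra_pairs("A")
    return ContactMap(
        n_residues=n_res,
        pairs=intra_a,
        labels=tuple("intra:A" for _ in range(intra_a.shape[0])),
        cutoff=toy.contact_map.cutoff,
        min_sep=toy.contact_map.min_sep,
        chain_of=tuple("A" for _ in range(n_res)),
        chain_pos=np.arange(n_res),
    )


def _truncate_profile(profile, n: int):
    from .frustration import FrustrationProfile

    return FrustrationProfile(
        F=profile.F[:n],
        native_energy=profile.native_energy[:n],
        decoy_mean=profile.decoy_mean[:n],
        decoy_std=profile.decoy_std[:n],
        n_decoys=profile.n_decoys,
        n_sequences=profile.n_sequences[:n],
        label=profile.label,
    )
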