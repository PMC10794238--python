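# Methods

## Scope

`tcsevo` implements a two-track analysis of interaction patterns in
two-component signaling (TCS) proteins. The family track computes
conservation and coupling-conservation statistics over a paired DHp/Rec
multiple sequence alignment; the evolution track simulates sequence
evolution against a fixed structure under a funneled-landscape selection
fitness and compares residue-level frustration between evolved sequence
sets. Both tracks run entirely on generated inputs at desk scale; the same
code paths accept real inputs (an aligned-FASTA paired family, a PDB
complex, externally produced decoy sets).

## Family-track statistics

**Filtering.** Sequences whose gap fraction exceeds `max_seq_gap_frac`
(default 0.2) are removed first; column gap fractions are then computed on
the surviving sequences and columns above `max_col_gap_frac` (default 0.5)
are dropped. The order matters: a column's fate can flip once gappy
sequences are gone, and the tests assert this against a brute-force
recount. An optional extra filter drops named columns (for families where a
column is gapped in the reference complex structure's own sequence).

**Frequencies.** Gaps are excluded from both numerator and denominator —
a column's frequencies are over its observed residues and sum over the 20
canonical types; pair frequencies use the sequences non-gapped at both
columns. Ambiguity codes (B, Z, X, U, O, J) are normalized to gaps and
tallied. A pseudocount (default 1e-4 per cell) keeps every frequency
strictly inside (0, 1) wherever a logarithm is taken; pure counting checks
may use 0.

**Conservation.** `C_i = Σ_a f_i^a ln(f_i^a/q^a)` (nats), with 0·ln 0 := 0.
The background `q` ships as a packaged table of database-average amino-acid
frequencies (the Robinson–Robinson composition used by standard
sequence-comparison tools) and is overridable; so is the binary
hydrophobicity classification (the nine strongly hydrophobic types
C M F I L V W Y A) behind the hydrophobic preference `P_i^H`.

**Coupling conservation.** As printed above in the README:
`C_ij = sqrt(Σ_ab k_i^a k_j^b (f_ij^ab − f_i^a f_j^b)²)` with log-odds
coefficients `k`. Two numerical points deserve note:

- The summand is not sign-definite (each `k` carries the sign of `f − q`),
  so the pre-root sum can be slightly negative on data with no real
  coupling. We retain the *signed* sum as the null diagnostic — it is the
  quantity that is Gaussian around zero for independent sequences — and
  clip negative sums to zero for `C_ij` itself. On planted or real coupled
  pairs the sum is strongly positive and the clip never engages.
- The independence reference `f_i^a f_j^b` uses each pair's own
  (both-non-gap) marginals, so exactly independent columns give
  `C_ij = 0` identically.

A closed form anchors the implementation: two perfectly correlated
two-state columns at 50/50 marginals under a uniform background give
`C_ij → ln(19)/2 ≈ 1.472` as the pseudocount vanishes; the tests verify
this to 1e-4.

**Spectrum fit.** The `C_ij` histogram uses linear bins (default width 0.1)
starting at the smallest observed value; the power-law fit `y = a x^(−b)`
is an ordinary least-squares line of log10(count) on log10(bin center) over
the non-empty bins inside a configurable `fit_range`. R² is reported on the
log–log scale. Binning is exposed because published fits of such spectra
rarely state it; the family driver reports the exponent across bin widths
as a sensitivity check. Fewer than 3 usable bins is an error (degenerate
spectra do not support a fit), which the pipeline records instead of
failing the run.

**Null model.** Independent sequences drawn from the background, same
dimensions as the family. At 4069×172 the off-diagonal `C_ij` sit near 1e-4
with none approaching the 1.10 selection threshold, and the signed
statistic is symmetric (|skew| ≪ 1) — the spectrum's heavy tail on real or
planted families is a property of coevolution, not of the estimator.

## Structure and energetics

A residue pair is in contact when any two heavy atoms lie strictly below
5.0 Å apart; within a chain at least two positions must separate the pair
(|i−j| ≥ 2), while inter-chain pairs carry no separation constraint
(separation is a chain-internal concept). Hydrogens are dropped, alternate
locations resolve to the highest-occupancy conformer, and HETATM records
are excluded. The strict `<` at the cutoff is a convention choice; the
contact map is monotone in the cutoff, which the tests assert.

Sequence energy is `E = Σ_contacts ξ(μ_i, μ_j)` with the packaged 20×20
contact-energy table (the 1996 Miyazawa–Jernigan contact energies,
attractive = negative, transcribed from the published upper-triangle table
and symmetrized on load). For a two-chain complex the contact partition
gives `E = E1 + E2 + E12`; under rigid-body pose comparison only `E12`
varies, so binding decoys are compared on `E12` alone. A gap at a
contacting position contributes zero energy with a warning (configurable to
an error).

Alignment columns map onto structure residues per domain by globally
aligning the domain's column-consensus sequence to the chain sequence;
columns opposite alignment gaps are reported unmapped, and the mapping is
required to be strictly monotone. "Coupling distance" between two mapped
columns is the minimum heavy-atom distance (Cα–Cα available as an option).

## Selection fitness

For a decoy ensemble `{E_d}` and native energy `E_N`:

- `ΔG = E_N + kT·logsumexp(−E_d/kT)` (the log-ratio form evaluated
  overflow-safely); more negative = more stable. `P_D` is a plain sum over
  decoys, without a density-of-states weighting.
- `Λ = sqrt(1/(2S)) · (mean(E_d) − E_N) / sd(E_d)` with `S = ln(n_decoys)`
  and population (ddof 0) standard deviation. The gap is referenced to the
  decoy mean — the standard funnel Z-score reading.
- `kT = 1` in contact-energy units throughout (exposed in config; the
  energy scale of the contact table makes this a unit choice, not a
  physical temperature).

Both quantities are invariant to a uniform energy shift and monotone in
`E_N`; the tests assert both numerically. With Gaussian decoy energies,
`ln P_D → ln N − μ + σ²/2`, which the tests verify against sampling.

Population fitness is rank-based: per component (ΔG_f, Λ_f and, in the
binding condition, ΔG_b, Λ_b), rank 1 is best; the combined fitness is the
sum of component ranks with ties broken by stable input order.

## Genetic-algorithm evolution

Each step touches exactly one population slot: a random member is mutated
at a random position (new identity uniform over the other 19); the mutant
replaces the original iff it keeps the native conformation as its unique
ground state (strictly lowest energy against the folding ensemble, and
additionally the binding ensemble in the FBS condition); otherwise the slot
is refilled by wheel selection. Wheel probabilities follow the decreasing
recurrence `P_{n+1} = P_n(1−P_n)` from `P_1 = 0.05`, normalized (a
geometric variant `P_n = P_1(1−P_1)^(n−1)` is available by config, since
the logistic recurrence is an unusual choice).

The initial population is drawn uniformly at random and pre-filtered by the
ground-state test within a bounded attempt budget; remaining slots are
seeded by single mutations of accepted members (unfiltered initialization
is available by config). Sequence entropy is standard negative-sum Shannon
entropy over the full sequence length in nats; a published variant of this
formula omits the minus sign and fixes the summation length — both are
treated here as typographical and the standard form is used.

Convergence: the relative change between consecutive window-averaged
entropies (window 1000 steps by default) below 1e-3 stops the run; a step
cap (2×10^5 by default; 12 000 in the desk-scale drivers) otherwise ends it
with a warning flag rather than an error. One seeded generator drives each
replicate; mutation, wheel and decoy draws consume from it in a fixed
order, making runs bitwise reproducible.

Desk-scale study conditions (drivers, tests, acceptance script): 30-residue
evolving chain, population 100, 100 folding + 100 binding decoys, 5
replicate seeds, 12 000-step cap. These sizes give stable emergent
properties (below) in about a minute per condition batch on one CPU.

## Synthetic data: what it emulates, what it does not

**Planted MSAs.** Unplanted cells draw independently from the background;
conserved columns draw a dominant residue with stated probability; coupled
pairs draw one of two residue-pair states with 50/50 marginals and a
correlation parameter (probability of drawing the states jointly rather
than independently); gaps are planted uniformly, per-column, or per-row.
The family-scale preset emulates the TCS study conditions: 4100 raw pairs
× 176 columns, 31 rows at 25% gaps (removed by the sequence filter, leaving
4069), four columns at 70% gaps (two DHp terminals, one Rec terminal, one
mid-Rec column standing in for the column gapped in the complex-structure
sequence; removed by the column filter, leaving 172 = 62 + 110), sixteen
strongly conserved Rec columns (dominance 0.92) plus two DHp ones, six
strong couplings (correlation 0.95, three touching DHp) and a
weak-to-strong ladder of twenty more (correlations 0.25–0.82) so the
coupling spectrum has the continuum real families show. What this does
*not* emulate: phylogenetic correlation between sequences (rows are
exchangeable), realistic per-family residue usage, and indel structure —
so passing tests show the estimators recover planted signal at family
scale, not that real TCS families have that signal.

**Toy structures.** A deterministic boustrophedon path through a compact
cubic-lattice block (3.8 Å spacing) with one side-chain pseudo-atom per
residue (0.9 Å, seeded random direction). A compact block, rather than a
single helix, is used because it produces a genuine spread of contact
counts: buried/surface classes derive from intra-chain contact-count
quartiles (with strict separation enforced), and the two-chain variant
faces two blocks across a 4.2 Å gap, making a contiguous interface
(positions with ≥ 1 inter-chain contact). These are desk-scale stand-ins:
no secondary structure, no real packing geometry.

**Folding decoys.** The default `rewire` mode draws, per decoy, a uniformly
random set of valid pairs (respecting the 2-residue separation) with
exactly the native's contact count — statistically like threading the chain
onto unrelated folds, in that the decoy's degree pattern is uncorrelated
with the native burial pattern. A degree-preserving edge-swap mode
(`rewire-degree`) exists but is *not* the default, deliberately: decoys
that inherit the native's per-residue contact counts cancel exactly the
burial signal selection needs, and on the toy fold they suppress (even
invert) the hydrophobic-core property. A `thread` mode accepts contact maps
of other structures truncated to the chain length, and externally produced
decoys can be imported. Decoy energies of a fixed sequence are sums of ~60
weakly dependent contact energies and come out approximately Gaussian
(asserted by a normality test), which is the one property the fitness
formulas rely on.

**Binding decoys.** Rigid-body poses of the ligand chain: a uniform random
rotation about its centroid plus a random translation up to 12 Å; poses
with any heavy-atom pair under 2.0 Å are rejected as clashes, as is any
pose whose inter-chain contact set equals the native one. Poses burying
more than 75% of the native interface's pair count are also rejected:
pseudo-atom chains have no excluded volume beyond the clash cutoff, so
unconstrained poses can interleave with the receptor or re-create
near-native interfaces with arbitrary pairings, and the complex would lose
the defining premise of a funneled binding landscape — that the native pose
buries the dominant interface. Real docking decoy sets earn this property
from atomic packing; the generator must impose it. Poses that drift out of
contact range are legal decoys with `E12 = 0`.

**Reference sequence set.** For toy systems there is no natural family, so
the "natural sequences" role in frustration comparisons is played by a
synthetic structure-adapted reference set: Metropolis annealing of the
native contact energy alone (temperature 1.5, ~2000 steps), sharing the
structure but none of the decoy-ensemble selection machinery.

## Frustration

`F_i = (⟨E_i^U⟩ − E_i^N)/sd(E_i^U)` where `E_i^N` sums the contact energies
incident to position *i* and the N (default 1000) decoys resample only
position *i*'s identity — neighbors and contact set fixed — from the
empirical composition of the sequence's own chain (uniform draw available).
Positive `F_i` means the native identity is better (lower) than the decoy
mean: minimally frustrated. Because the contact set is fixed across decoys,
`F_i` is invariant to uniform energy-table shifts. Zero decoy variance and
positions without contacts raise errors rather than returning silent
zeros. The Monte-Carlo index is validated position-by-position against
exact enumeration over the 20 identities (closed-form mean/variance), with
agreement required within 3 Monte-Carlo standard errors (delta-method
`SE ≈ sqrt((1 + F²/2)/N)`).

Ensemble profiles compute `F_i` per sequence and average per position; the
per-(sequence, position) decoy stream is derived from the profile seed and
the sequence content, so duplicated sequences contribute identically and
profiles are set-level deterministic. Binding-aware (FBS) profiles include
the inter-chain contacts with the partner chain's native sequence fixed.
Frustration change `ΔF_i` between two conditions is classified at
|ΔF| ≥ 0.70 (threshold configurable) into less/more frustrated, and
enrichment of |ΔF| at designated interface positions is tested by a
one-sided label-permutation test on the mean difference.

## Emergent properties the desk-scale system reproduces

At the default desk scale, across 5 replicate seeds:

- selection compresses sequence entropy in every replicate (final H below
  initial H; convergence flag or step cap recorded);
- FS-evolved populations develop a hydrophobic core: median hydrophobic
  preference at buried positions exceeds surface positions;
- FBS-evolved sequences reach lower interface energy `E12` than FS-evolved
  sequences evaluated on the same complex, in every replicate;
- frustration change between FS and FBS concentrates at the interface
  (permutation p < 0.05);
- the FS–FBS frustration-profile correlation exceeds both correlations with
  the independent reference set.

These are properties of the model class, demonstrated on generated
structures; they are not quantitative statements about any real family.

## Known limitations

- The family track carries no phylogenetic reweighting or higher-order
  (Potts/direct-coupling) inference; `C_ij` is a second-order statistic and
  shared ancestry in real alignments will inflate it.
- The published TCS paired alignment is an external download; without it
  the family track demonstrates the machinery on the generator preset at
  identical dimensions rather than the family's own counts.
- Binding decoys are rigid-body pseudo-atom poses, not docked atomic
  models; folding decoys are randomized contact maps, not threaded real
  folds. Both preserve only the ensemble statistics the fitness consumes.
- mmCIF input, side-chain packing, and any all-atom force field are out of
  scope.
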