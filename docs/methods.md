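# Methods

## Model and search procedure

The engine treats RNA sequence design as stochastic minimization of a
multiobjective fitness over the discrete space of constraint-satisfying
sequences. The thermodynamic core of the fitness is
`S(s) = Σ_k [E_desired(s, T_k) − E_pf(s)]`, built from the nearest-neighbor
Turner model as implemented by ViennaRNA: `E_pf` is the ensemble
(partition-function) free energy and `E_desired` the energy of the sequence
folded exactly into target structure `T_k`. Because
`kT·log x_desired = E_pf − E_desired`, the core is `−kT` times the
log-probability mass of the desired conformations; it is non-negative
(the ensemble energy lower-bounds every single structure's energy) and zero
only in the perfect-design limit. For alternative-conformation targets the
core *sums* the per-structure offsets, which pushes every desired state to
high probability simultaneously; a max-aggregation would optimize only the
worst state and was not used.

The optimizer is replica-exchange (parallel-tempering) Metropolis Monte
Carlo. `R` replicas (default 10) run at Monte Carlo temperatures `T_MC`
spaced linearly over [10, 150] — control parameters, not physical
temperatures. Each global step attempts 100 mutations per replica
(counted as proposals, whether or not accepted); a worsening move `ΔS > 0`
is accepted with `exp(−L·ΔS/T_MC)` (`L = 1` by default, configurable) and
improvements (`ΔS ≤ 0`) are always accepted. After every global step one
top-down sweep of adjacent-pair exchanges is attempted, starting from the
hottest pair, with `p = min(1, exp[(L/T1 − L/T2)(S1 − S2)])`; accepted
swaps exchange chain states while temperatures stay attached to ladder
levels, so the temperature multiset is a run invariant.

### Moves

A mutation resamples one connected component of the *pooled pairing
graph* (one vertex per residue, one edge per base pair in any target
structure). For a single-structure target components are single residues
or pair partners; alternative structures couple larger sets through
overlapping pairs. Component assignments are drawn by randomized
backtracking over the six canonical pairs (AU, UA, GC, CG, GU, UG)
restricted to the per-position IUPAC sets, so every proposal is feasible
by construction and any feasible component is sampled with nonzero
probability. A per-replica fraction of proposals (linear 0.70 → 0.00 from
coldest to hottest replica) is *targeted*: the site is drawn from
residues whose currently predicted pairing disagrees with the
best-matching target structure, widened by up to three residues to each
side. When the prediction already matches the target this pool is empty
and the move falls back to a uniform site.

### Feasibility and initialization

Before any simulation the constraint system is checked exactly: each
component of the pooled pairing graph is solved by backtracking with the
canonical-pair adjacency table (a graph-coloring style constraint search).
Infeasibility — e.g. a demanded pair whose two positions are restricted to
A and G — is reported with the conflicting component before the run
starts. Initial sequences are drawn with helix positions GC-biased (80%
G/C within the allowed set) and unpaired positions A-biased (50% A),
mirroring the player heuristics long used for human-competitive RNA
design; the exact published percentages are not fixed anywhere
authoritative, so these biases are this package's documented choice. Both
biases only tilt the proposal order inside an exact backtracking search,
so constrained targets are still initialized correctly.

## Thermodynamic backend

All folding quantities come from ViennaRNA (2.7) behind a narrow
`EngineConfig`/`EnergyReport` contract, with Turner1999 or Turner2004
parameter tables at 37 °C, dangles model 2, and `kT` taken from the
engine's own gas constant (0.61632 kcal/mol at 37 °C) so exponential
identities match the backend bit for bit. The parameter table is
process-global in the backend and is compiled into its folding machinery
at first use; the engine therefore latches the parameter set at the first
evaluation and raises on a switch attempt rather than silently computing
with the wrong table. Anything needing the other parameter set runs in a
separate process (the acceptance script does this for its Turner2004
section).

Derived quantities:

- **MFE frequency** `exp((E_pf − E_MFE)/kT)`, the Boltzmann probability
  of the MFE structure.
- **Ensemble defect** relative to a target: `n − Σ_(i,j)∈T 2·p_ij −
  Σ_i unpaired q_i` with `q_i = 1 − Σ_j p_ij`, from the base-pair
  probability matrix — the expected count of incorrectly paired/unpaired
  residues. The backend's own normalized variant is not used so the value
  stays in residue units in [0, n].
- **Ensemble diversity**: mean base-pair distance within the ensemble.
- **Suboptimal gap** (negative design): lowest energy among enumerated
  structures within a window (default 5 kcal/mol, configurable) that
  differ from the MFE structure, minus `E_MFE`. When no distinct structure
  exists in the window the window width is returned as a documented
  sentinel. The gap bonus `−w·gap` is active only once the MFE structure
  equals the target, and the enumeration is costly, so negative design is
  off by default.
- **Two-strand quantities**: complex partition function and MFE over the
  *connected* two-strand ensemble; the desired-structure fraction is
  `exp((E_pf(AB) − E_desired(AB))/kT)`. For homodimers the backend's
  connected-ensemble energy includes the indistinguishable-strand symmetry
  correction that a fixed-structure evaluation lacks, so the dimer-mode
  core can dip below zero by up to `kT·ln 2`; the `core ≥ 0` bound is an
  exact theorem only for single-strand ensembles.

### Pseudoknots

The nested-only recursions cannot fold pseudoknots, so prediction is
iterative: fold; constrain every paired position to stay unpaired; refold
the remainder; repeat up to the bracket depth of the target (or until an
iteration adds no pairs). Pair sets from successive iterations are
disjoint by construction and are stacked as bracket levels `() [] {} <>`
(depths 0–3). Energy terms use the level-0 (nested) pairs only — the
backend cannot score pseudoknotted structures — while the structure
comparison (MCC) pools all levels, so "solved" still requires the full
pseudoknotted pair set.

### Oligomerization

`x_monomer` comes from the `2M ⇌ D` equilibrium with association constant
`Ka = exp(−ΔG/kT)`, `ΔG = E_pf(s·s complex) − 2·E_pf(s)` (1 M reference
state), at total strand concentration `c` (default 1 µM, configurable; a
standard in-vitro scale — the published convention for reported
monomer/dimer percentages is not stated anywhere, so values at other
concentrations can be obtained by changing one parameter). The mass
balance `[M] + 2[D] = c` is solved in the cancellation-free form
`[M] = 2c/(1 + sqrt(1 + 8·Ka·c))`, exact as `Ka → 0`; MFP/DFP are
`x_monomer·100` and `(1 − x_monomer)·100`. Heterodimer association uses
the analogous `A + B ⇌ AB` balance with `c/2` per strand. Monomer-design
and dimer-design corrections `−kT·log x_monomer` / `−kT·log(1 − x_monomer)`
are clamped at `x ∈ [1e−12, 1 − 1e−12]` with a warning so exact extremes
cannot produce infinite scores.

## Scoring structure comparison

MCC is computed over the confusion matrix of all `C(n,2)` unordered
position pairs, pooling bracket levels into one pair set; identical pair
sets return exactly 1.0 (so `1−MCC = 0` is a rounding-free solved
criterion) and the zero-denominator convention is MCC = 0. Restraint
penalties are `w_acgu · L1(composition, target)` plus one `w_motif` unit
per missing required or present forbidden IUPAC motif (motifs are matched
per strand and never across the `&` separator). The weights default to
1.0 — commensurate with kcal/mol but not prescribed by the model — and are
exposed in `ScoreConfig`. The optional length-normalized baseline term
uses `E_pf_random(n)`, the mean ensemble energy of 50 seeded uniform
random sequences of length `n`, estimated once per run.

## Reproducibility and numerics

Every run derives all randomness from one master seed via spawned
generator streams (one per replica, one for initialization, one dedicated
to exchanges), so results are byte-identical for a fixed seed and
configuration regardless of replica evaluation order. Each Metropolis and
exchange decision consumes exactly one uniform draw. Scoring is a pure
function of the sequence. Proposal dead ends (a site admitting no
alternative assignment) are resolved by bounded resampling — 8 draws per
site, 8 sites — before returning a no-op candidate, which keeps the
proposal step total and deterministic.

## What the bundled targets emulate — and what they do not

The bundled collection covers the feature surface at desk scale: 20
generated nested structures (20–50 nt, helices ≥ 3 bp, hairpin loops
≥ 3 nt), a 32-nt two-conformation switch, 19-mer monomer/dimer designs
carrying a fixed bipartite protein-binding motif, a 136-nt SRP-like
scaffold with a conserved-sequence constraint, and 2- and 4-level toy
pseudoknots. These are deliberately designable: passing the desk-scale
checks shows the search machinery and scoring are correct, not that
arbitrary natural or adversarial targets (long zigzags, lone pairs,
repetitive symmetric elements) are solvable in comparable time. External
benchmark collections can be run through the same target-file dialect but
are not redistributed here.

The acceptance script's problem sizes (25–60 s per design run, step caps
of a few hundred) are the package's chosen desk-scale defaults; they are
deliberately small, and harder targets simply need longer limits through
the same interface.

## Known limitations

- No non-canonical pairs, base triples, or more than four pseudoknot
  levels; pseudoknot *energetics* are approximated by nested-level terms.
- At most two strands; no concentration-dependent multi-species ensembles
  beyond the monomer/dimer balance.
- The Turner parameter set is fixed per process (backend constraint).
- Homodimer design searches the two strands independently; it can and
  does return heterodimeric solutions when they score better. Reported
  MFP/DFP for a designed duplex therefore refer to a chosen strand's
  self-dimerization.
- Restraint weights are heuristic defaults, not fitted quantities.
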