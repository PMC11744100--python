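# rexfold

Replica-exchange Monte Carlo design of RNA sequences for target secondary
structures (the *inverse folding* problem): given one or more dot-bracket
target structures — optionally pseudoknotted, two-strand, or alternative
conformations of one molecule — plus IUPAC sequence constraints and soft
restraints, search for sequences whose thermodynamic ensemble is dominated
by the desired structure(s). Intended for RNA engineers and structural
bioinformaticians designing aptamers, riboswitch-like bistable sequences,
dimerizing elements, or scaffold sequences for downstream 3D work.

## The objective

For a sequence `s`, a nearest-neighbor folding engine (ViennaRNA, Turner
1999 or 2004 parameters) provides the ensemble free energy
`E_pf = -kT ln Z`, the minimum free energy structure and its energy
`E_MFE`, and the fixed-structure energy `E_desired(s, T_k)` of `s` folded
into target structure `T_k`. Since the Boltzmann fraction of the ensemble
in the target structure satisfies

```
kT · log x_desired(s) = E_pf(s) − E_desired(s),
```

minimizing the core score

```
S(s) = Σ_k [ E_desired(s, T_k) − E_pf(s) ]   ≥ 0
```

is exactly maximizing the probability of each desired conformation; `S = 0`
is the perfect-design limit. Optional additive terms handle soft
restraints (ACGU composition, required/forbidden IUPAC motifs), the
monomer/dimer equilibrium (`−kT·log x_monomer` or `−kT·log(1−x_monomer)`
from the `2M ⇌ D` mass balance), negative design (a bonus proportional to
the energy gap to the best competing structure once the MFE structure
matches the target), and structure-distance/ensemble-defect terms.

The search runs `R` Metropolis chains (default 10) at Monte Carlo
temperatures `T_MC` equally spaced over [10, 150]. A worsening move
`ΔS > 0` is accepted with `p = exp(−L·ΔS / T_MC)`; improvements are always
accepted. Adjacent replicas periodically attempt state swaps with
`p = min(1, exp[(L/T_MC1 − L/T_MC2)·(S1 − S2)])`, and a per-replica
fraction of proposals (0.70 at the coldest replica down to 0.00 at the
hottest) is targeted at residues whose predicted pairing is still wrong.
Every proposal resamples one connected component of the pairing graph
pooled over all target structures, so visited sequences satisfy all
constraints by construction; infeasible constraint systems (e.g. a
required pair restricted to A/G) are detected exactly beforehand by a
graph-coloring search over the six canonical pairs.

Designs are ranked by score and reported with `1−MCC` against the target
(Matthews correlation over the base-pair confusion matrix; `1−MCC = 0`
means an exact structure match, the usual "solved" criterion).

## Worked example

A 20-nt hairpin, solved from the command line:

```
$ rexfold examples/hairpin20.txt --steps 50 --seed 4 --stop-on-perfect --quiet
best score 0.08 (E_pf -13.38 kcal/mol, 1-MCC 0.0000) after 0 steps / 1 evaluations
examples/hairpin20_results.csv
```

Here the GC-biased constraint-satisfying initialization already folds into
the target: `1-MCC 0.0000` means the predicted MFE structure matches the
target exactly, and `score 0.08` means the ensemble sits almost entirely
(`x_desired = exp(−0.08/kT) ≈ 0.88`) in the designed hairpin. The CSV
ranks the ten best distinct sequences:

```
structure,sequence,E_pf,score,one_minus_mcc
((((((((....)))))))),CCCGGAGGACACCUUCCGGG,-13.379744529724121,0.07974433898925781,0.0
```

A two-strand duplex design with a fixed bipartite sequence motif
(`-d on` enables complex mode; `mfp/dfp` columns report the
monomer/dimer partitioning of the designed complex):

```
$ rexfold examples/mom19_dimer.txt -d on -t 20 --seed 2 --quiet
best score 0.03 (E_pf -35.33 kcal/mol, 1-MCC 0.0000) after 5 steps / 4519 evaluations
```

The same engine is available as a library:

```python
from rexfold import DesignTarget, EngineConfig, run

target = DesignTarget.from_strings("N" * 32,
                                   "((((..((((((....))))))......))))",
                                   "((((....))))....((((((....))))))")
result = run(target, engine_cfg=EngineConfig("Turner1999"),
             max_seconds=60, seed=7)
print(result.best.sequence, result.best.score)
```

### Target-file dialect

Plain text: an optional `>name` line, one IUPAC constraint line (with `&`
separating the strands of a complex), then one dot-bracket line per target
structure (two or more lines define an alternative-conformation design).
Pseudoknots use the bracket families `( ) [ ] { } < >` for depths 0–3.
`#` starts a comment. Flags: `-t SECONDS` wall-clock limit, `--steps N`
step limit, `-p {1999,2004}` parameter set, `-d on` complex design,
`-nd on` negative design, `-o on` oligomerization prevention,
`-acgu on[:A,C,G,U]` composition restraint, plus `--seed`, `--replicas`,
`--out`, `--traj`.

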