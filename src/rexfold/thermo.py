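"""Nearest-neighbor thermodynamics behind a narrow engine contract.

All folding, partition-function and fixed-structure energy evaluation is
delegated to the ViennaRNA package (Turner nearest-neighbor models, 1999 or
2004 parameter sets). Everything downstream (scoring, the Monte Carlo
optimizer) depends only on :class:`EnergyReport`, so the backend can be
swapped without touching the search.

Pseudoknots: the nested-only recursions cannot fold or score pseudoknotted
structures directly, so prediction uses an iterative masking scheme — fold,
freeze the paired positions as "must stay unpaired" constraints, refold the
remainder, and stack the per-iteration pair sets as successive bracket
levels. Energy terms are taken from the first (nested) level only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import RNA

from .structures import (
    DesignTarget,
    DotBracketStructure,
    parse_dot_bracket,
    pairs_to_dot_bracket,
)

__all__ = [
    "EngineConfig",
    "EnergyReport",
    "DimerQuantities",
    "evaluate",
    "subopt_gap",
    "predict_pseudoknotted",
    "dimer_quantities",
    "ensemble_defect",
]

_PARAM_SETS = ("Turner1999", "Turner2004")
_loaded_params: str | None = None


@dataclass(frozen=True)
class EngineConfig:
    """Thermodynamic model selection.

    parameter_set : "Turner1999" or "Turner2004" nearest-neighbor tables.
    temperature_C : physical folding temperature in Celsius (default 37).
    dangles       : ViennaRNA dangling-end treatment (default 2, the
                    engine's own default).
    """

    parameter_set: str = "Turner1999"
    temperature_C: float = 37.0
    dangles: int = 2

    def __post_init__(self) -> None:
        if self.parameter_set not in _PARAM_SETS:
            raise ValueError(
                f"parameter_set must be one of {_PARAM_SETS}, "
                f"got {self.parameter_set!r}"
            )

    @property
    def kT(self) -> float:
        """Thermal energy in kcal/mol at ``temperature_C``.

        Uses the engine's own gas constant so exponential identities
        (MFE frequency, Boltzmann fractions) match the backend bit-for-bit.
        """
        return RNA.GASCONST * (RNA.K0 + self.temperature_C) / 1000.0


def _apply_params(cfg: EngineConfig) -> None:
    # The nearest-neighbor table is process-global in the backend and is
    # compiled into its folding machinery at first use, so the parameter
    # set is fixed per process: the first engine call latches it and any
    # later switch is refused rather than silently ignored.
    global _loaded_params
    if _loaded_params is None:
        if cfg.parameter_set == "Turner1999":
            RNA.params_load_RNA_Turner1999()
        else:
            RNA.params_load_RNA_Turner2004()
        _loaded_params = cfg.parameter_set
    elif _loaded_params != cfg.parameter_set:
        raise RuntimeError(
            f"thermodynamic parameter set already fixed to {_loaded_params} "
            f"in this process; run {cfg.parameter_set} work in a separate "
            "process"
        )


def _model_details(cfg: EngineConfig) -> "RNA.md":
    _apply_params(cfg)
    md = RNA.md()
    md.temperature = cfg.temperature_C
    md.dangles = cfg.dangles
    return md


def _compound(seq: str, cfg: EngineConfig) -> "RNA.fold_compound":
    seq = seq.upper().replace("T", "U")
    if not set(seq) <= set("ACGU&"):
        bad = sorted(set(seq) - set("ACGU&"))
        raise ValueError(f"illegal nucleotide(s) {bad} in sequence {seq!r}")
    return RNA.fold_compound(seq, _model_details(cfg))


@dataclass(frozen=True)
class EnergyReport:
    """Thermodynamic summary of one sequence against a design target.

    Energies in kcal/mol. ``e_desired`` has one entry per target structure
    (evaluated on its nested, level-0 pairs). ``ensemble_defect`` is the
    expected number of incorrectly paired/unpaired residues relative to the
    first target structure; ``ensemble_diversity`` the mean base-pair
    distance within the ensemble.
    """

    e_pf: float
    e_mfe: float
    mfe_structure: DotBracketStructure
    e_desired: tuple[float, ...]
    mfe_frequency: float
    ensemble_diversity: float
    ensemble_defect: float


def _level0_text(structure: DotBracketStructure) -> str:
    """Nested (level-0) projection as a flat dot-bracket string, no '&'."""
    return pairs_to_dot_bracket(
        [(i, j, 0) for i, j, lvl in structure.pairs if lvl == 0],
        structure.length,
    )


def ensemble_defect(
    fc: "RNA.fold_compound", target: DotBracketStructure
) -> float:
    """Expected count of incorrect positions in the ensemble vs ``target``.

    n - sum_{(i,j) in target} 2*p_ij - sum_{i unpaired in target} q_i with
    q_i = 1 - sum_j p_ij, from the base-pair probability matrix (partition
    function must already be filled).
    """
    n = target.length
    bpp = fc.bpp()  # 1-based upper-triangular matrix
    paired_prob = [0.0] * (n + 1)
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            p = bpp[i][j]
            if p > 0.0:
                paired_prob[i] += p
                paired_prob[j] += p
    correct = 0.0
    pm = target.pair_map
    for i0 in range(n):
        j0 = pm.get(i0)
        if j0 is None:
            correct += 1.0 - paired_prob[i0 + 1]
        elif j0 > i0:
            correct += 2.0 * bpp[i0 + 1][j0 + 1]
    return n - correct


def evaluate(seq: str, target: DesignTarget, cfg: EngineConfig) -> EnergyReport:
    """Full thermodynamic evaluation of ``seq`` against ``target``.

    For two-strand targets the partition-function and MFE quantities refer to
    the connected complex of the two strands.
    """
    if "&" not in seq and target.mode == "dimer":
        seq = target.sequence_with_breaks(seq)
    fc = _compound(seq, cfg)
    if "&" in seq:
        mfe_ss, e_mfe = fc.mfe_dimer()
        fc.exp_params_rescale(e_mfe)
        _, _, _, e_pf, _ = fc.pf_dimer()  # FcAB: connected-complex ensemble
    else:
        mfe_ss, e_mfe = fc.mfe()
        fc.exp_params_rescale(e_mfe)
        _, e_pf = fc.pf()
    kT = fc.exp_params.kT / 1000.0
    mfe_struct = parse_dot_bracket(
        target.sequence_with_breaks(mfe_ss) if target.mode == "dimer" else mfe_ss
    )
    e_desired = tuple(
        float(fc.eval_structure(_level0_text(s))) for s in target.structures
    )
    return EnergyReport(
        e_pf=float(e_pf),
        e_mfe=float(e_mfe),
        mfe_structure=mfe_struct,
        e_desired=e_desired,
        mfe_frequency=math.exp((e_pf - e_mfe) / kT),
        ensemble_diversity=float(fc.mean_bp_distance()),
        ensemble_defect=ensemble_defect(fc, target.structures[0]),
    )


def subopt_gap(seq: str, cfg: EngineConfig, window: float = 5.0) -> float:
    """Energy gap between the MFE structure and the best structure differing
    from it, from a suboptimal enumeration within ``window`` kcal/mol.

    When no distinct structure exists inside the window (e.g. a homopolymer
    whose only structure is the open chain), the window width itself is
    returned as a documented sentinel.
    """
    if "&" in seq:
        raise ValueError("subopt_gap is defined for single-strand sequences")
    fc = _compound(seq, cfg)
    mfe_ss, e_mfe = fc.mfe()
    best = None
    for s in fc.subopt(int(round(window * 100))):
        if s.structure != mfe_ss:
            if best is None or s.energy < best:
                best = s.energy
    if best is None:
        return float(window)
    return max(0.0, float(best) - float(e_mfe))


def predict_pseudoknotted(
    seq: str, depth: int, cfg: EngineConfig
) -> DotBracketStructure:
    """Iterated masked MFE prediction producing up to ``depth`` bracket levels.

    Iteration 1 is the plain MFE prediction; each later iteration re-folds
    with every previously paired position constrained to stay unpaired, so
    pair sets from distinct iterations are disjoint. Iteration k's pairs are
    emitted at bracket level k-1. Stops early when an iteration adds no
    pairs. With ``depth=1`` this is exactly the plain MFE prediction.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    has_break = "&" in seq
    breaks: list[int] = []
    if has_break:
        flat = seq.replace("&", "")
        acc = 0
        for part in seq.split("&")[:-1]:
            acc += len(part)
            breaks.append(acc)
    else:
        flat = seq
    n = len(flat)
    all_pairs: list[tuple[int, int, int]] = []
    blocked: set[int] = set()
    for level in range(min(depth, 4)):
        fc = _compound(seq, cfg)
        for i in sorted(blocked):
            fc.hc_add_up(i + 1)  # engine uses 1-based coordinates
        ss, _ = fc.mfe_dimer() if has_break else fc.mfe()
        new = parse_dot_bracket(ss).pairs
        if not new:
            break
        for i, j, _ in new:
            all_pairs.append((i, j, level))
            blocked.update((i, j))
    text = pairs_to_dot_bracket(all_pairs, n, breaks)
    return parse_dot_bracket(text)


@dataclass(frozen=True)
class DimerQuantities:
    """Connected-complex and monomer ensemble energies for a strand pair."""

    e_pf_a: float
    e_pf_b: float
    e_pf_ab: float
    kT: float

    def structure_fraction(self, e_desired_ab: float) -> float:
        """Boltzmann fraction of the complex ensemble in a given structure."""
        return math.exp((self.e_pf_ab - e_desired_ab) / self.kT)

    @property
    def delta_g_dimer(self) -> float:
        """Association free energy A + B -> AB (kcal/mol, 1 M reference)."""
        return self.e_pf_ab - self.e_pf_a - self.e_pf_b


@lru_cache(maxsize=4096)
def _single_pf(seq: str, cfg: EngineConfig) -> float:
    fc = _compound(seq, cfg)
    _, e_mfe = fc.mfe()
    fc.exp_params_rescale(e_mfe)
    _, e_pf = fc.pf()
    return float(e_pf)


def dimer_quantities(seqA: str, seqB: str, cfg: EngineConfig) -> DimerQuantities:
    """Ensemble free energies of A, B and the connected AB complex."""
    if not seqA or not seqB:
        raise ValueError("both strands must be non-empty")
    fc = _compound(seqA + "&" + seqB, cfg)
    _, e_mfe = fc.mfe_dimer()
    fc.exp_params_rescale(e_mfe)
    _, _, _, e_pf_ab, _ = fc.pf_dimer()
    return DimerQuantities(
        e_pf_a=_single_pf(seqA, cfg),
        e_pf_b=_single_pf(seqB, cfg),
        e_pf_ab=float(e_pf_ab),
        kT=cfg.kT,
    )
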