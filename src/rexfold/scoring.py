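"""Multiobjective fitness for sequence design; lower is better.

The core objective is the thermodynamic one: the free-energy difference
E_desired - E_pf summed over all target structures. Since kT*log(x_desired)
= E_pf - E_desired, minimizing the core is exactly maximizing the Boltzmann
fraction of the ensemble that adopts each desired structure. Optional terms
add structure distance (1-MCC), ensemble defect, a length-normalized E_pf
baseline, soft restraint penalties, oligomerization control (kT*log of the
monomer or dimer molar fraction from the 2M <=> D equilibrium) and a
negative-design bonus proportional to the suboptimal energy gap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .structures import (
    DesignTarget,
    DotBracketStructure,
    RestraintSpec,
    iupac_match,
)
from .thermo import DimerQuantities, EnergyReport, EngineConfig, dimer_quantities

__all__ = [
    "ScoreConfig",
    "ScoreBreakdown",
    "ComparisonReport",
    "OligomerReport",
    "mcc",
    "default_score",
    "restraint_penalty",
    "monomer_fraction",
    "dimer_fraction",
    "oligomer_term",
    "negative_design_term",
    "dimer_design_score",
    "random_epf_baseline",
]

_CLAMP = 1e-12


@dataclass(frozen=True)
class ScoreConfig:
    """Weights and switches for the fitness function.

    The restraint weights are in score units commensurate with kcal/mol and
    are not prescribed by the underlying model; defaults of 1.0 make one
    violated restraint cost about one kcal/mol of core objective.
    ``total_conc`` is the total strand concentration (mol/L) used for the
    monomer/dimer equilibrium.
    """

    w_acgu: float = 1.0
    w_motif: float = 1.0
    w_negative: float = 1.0
    use_mcc_term: bool = False
    use_defect_term: bool = False
    use_baseline_term: bool = False
    total_conc: float = 1e-6
    subopt_window: float = 5.0


@dataclass(frozen=True)
class ComparisonReport:
    """Base-pair confusion matrix over all C(n,2) position pairs."""

    tp: int
    fp: int
    fn: int
    tn: int
    mcc: float

    @property
    def one_minus_mcc(self) -> float:
        return 1.0 - self.mcc


def mcc(
    predicted: DotBracketStructure, target: DotBracketStructure
) -> ComparisonReport:
    """Matthews correlation coefficient between two structures.

    All bracket levels are pooled into one pair set, so MCC = 1 (and
    1-MCC = 0, the "solved" criterion) holds only for an exact full-structure
    match. The zero-denominator convention is MCC = 0.
    """
    if predicted.length != target.length:
        raise ValueError(
            f"structure lengths differ: {predicted.length} != {target.length}"
        )
    n = target.length
    pred = predicted.pair_set
    targ = target.pair_set
    tp = len(pred & targ)
    fp = len(pred - targ)
    fn = len(targ - pred)
    tn = n * (n - 1) // 2 - tp - fp - fn
    if fp == 0 and fn == 0:
        # identical pair sets: exactly 1 so that 1-MCC == 0 is the
        # "solved" criterion, free of square-root rounding
        value = 1.0
    else:
        denom = (
            math.sqrt(tp + fp)
            * math.sqrt(tp + fn)
            * math.sqrt(tn + fp)
            * math.sqrt(tn + fn)
        )
        value = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return ComparisonReport(tp=tp, fp=fp, fn=fn, tn=tn, mcc=value)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Additive decomposition of the minimized fitness."""

    core: float
    restraint_penalty: float = 0.0
    mcc_term: float = 0.0
    defect_term: float = 0.0
    epf_baseline_term: float = 0.0
    oligomer_term: float = 0.0
    negative_term: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.core
            + self.restraint_penalty
            + self.mcc_term
            + self.defect_term
            + self.epf_baseline_term
            + self.oligomer_term
            + self.negative_term
        )


def default_score(
    report: EnergyReport,
    target: DesignTarget,
    cfg: EngineConfig,
) -> ScoreBreakdown:
    """Core thermodynamic objective: sum_k (E_desired_k - E_pf) >= 0.

    Zero is the perfect-design limit (the whole ensemble in the desired
    structure, x_desired = 1); the bound E_pf <= E_desired makes every term
    non-negative.
    """
    core = sum(e - report.e_pf for e in report.e_desired)
    return ScoreBreakdown(core=core)


def x_desired(report: EnergyReport, k: int, cfg: EngineConfig) -> float:
    """Boltzmann fraction of the ensemble in target structure ``k``."""
    return math.exp((report.e_pf - report.e_desired[k]) / cfg.kT)


def _count_motif(strand: str, motif: str) -> int:
    m = len(motif)
    return sum(
        1 for i in range(len(strand) - m + 1) if iupac_match(strand[i : i + m], motif)
    )


def restraint_penalty(
    seq: str, spec: RestraintSpec, score_cfg: ScoreConfig = ScoreConfig()
) -> float:
    """Weighted soft-restraint violation; 0 iff all restraints satisfied.

    ACGU term: L1 distance between the sequence composition and the target
    fractions. Motif terms: IUPAC-aware substring matching per strand (motifs
    do not span the '&' separator); each missing required motif and each
    present forbidden motif costs one weight unit.
    """
    strands = seq.split("&")
    flat = seq.replace("&", "")
    penalty = 0.0
    if spec.acgu_enabled:
        n = len(flat)
        freqs = (
            flat.count("A") / n,
            flat.count("C") / n,
            flat.count("G") / n,
            flat.count("U") / n,
        )
        penalty += score_cfg.w_acgu * sum(
            abs(f - t) for f, t in zip(freqs, spec.acgu_target)
        )
    for motif in spec.motifs_required:
        if not any(_count_motif(s, motif) for s in strands):
            penalty += score_cfg.w_motif
    for motif in spec.motifs_forbidden:
        if any(_count_motif(s, motif) for s in strands):
            penalty += score_cfg.w_motif
    return penalty


@dataclass(frozen=True)
class OligomerReport:
    """Monomer/dimer partitioning of a strand at equilibrium.

    MFP/DFP are the monomer and dimer formation percentages,
    x_monomer*100 and (1-x_monomer)*100.
    """

    x_monomer: float
    delta_g_dimer: float
    total_conc: float

    @property
    def mfp(self) -> float:
        return self.x_monomer * 100.0

    @property
    def dfp(self) -> float:
        return (1.0 - self.x_monomer) * 100.0


def monomer_fraction(
    seq: str,
    cfg: EngineConfig,
    total_conc: float = 1e-6,
) -> OligomerReport:
    """Molar fraction of strands staying monomeric in the 2M <=> D equilibrium.

    The association constant comes from the ensemble free energies,
    dG = E_pf(seq.seq complex) - 2*E_pf(seq) (1 M reference state); the mass
    balance [M] + 2[D] = c has the closed form
    [M] = (sqrt(1 + 8*Ka*c) - 1) / (4*Ka), and x_monomer = [M]/c counts
    strands, not species.
    """
    q = dimer_quantities(seq, seq, cfg)
    dg = q.delta_g_dimer
    ka = math.exp(-dg / cfg.kT)
    c = total_conc
    # cancellation-free form of the quadratic root (exact as Ka -> 0)
    m = 2.0 * c / (1.0 + math.sqrt(1.0 + 8.0 * ka * c))
    x = m / c
    return OligomerReport(
        x_monomer=min(1.0, max(0.0, x)), delta_g_dimer=dg, total_conc=c
    )


def dimer_fraction(
    seqA: str,
    seqB: str,
    cfg: EngineConfig,
    total_conc: float = 1e-6,
) -> float:
    """Fraction of strands associated into the AB complex at equilibrium.

    Homodimers (seqA == seqB) use the 2M <=> D balance of
    :func:`monomer_fraction`. Heterodimers use A + B <=> AB with equal total
    concentrations c/2 per strand: with Ka = exp(-dG/kT),
    [A] = (sqrt(1 + 2*Ka*c) - 1) / (2*Ka) and x_dimer = 1 - [A]/(c/2).
    """
    if seqA == seqB:
        return 1.0 - monomer_fraction(seqA, cfg, total_conc).x_monomer
    q = dimer_quantities(seqA, seqB, cfg)
    ka = math.exp(-q.delta_g_dimer / cfg.kT)
    c = total_conc
    a = c / (1.0 + math.sqrt(1.0 + 2.0 * ka * c))  # cancellation-free root
    return min(1.0, max(0.0, 1.0 - a / (c / 2.0)))


def oligomer_term(x_monomer: float, desired: str, kT: float) -> float:
    """Additive score correction steering the oligomeric state.

    Monomer design adds -kT*log(x_monomer), dimer design -kT*log(1 -
    x_monomer): the correction is >= 0, vanishes as the desired state
    dominates, and grows as the population drifts to the wrong state.
    Exact 0/1 fractions are clamped to avoid infinite scores.
    """
    if desired not in ("monomer", "dimer"):
        raise ValueError(f"desired must be 'monomer' or 'dimer', got {desired!r}")
    if not 0.0 < x_monomer < 1.0:
        warnings.warn(
            f"x_monomer={x_monomer} clamped to the open interval", stacklevel=2
        )
        x_monomer = min(1.0 - _CLAMP, max(_CLAMP, x_monomer))
    frac = x_monomer if desired == "monomer" else 1.0 - x_monomer
    return -kT * math.log(frac)


def negative_design_term(
    gap: float, target_matched: bool, w_negative: float = 1.0
) -> float:
    """Suboptimal-gap bonus, active only once the MFE structure is the target.

    A larger gap to the best competing structure means higher specificity, so
    the minimized score receives -w*gap. Inactive (0) while the MFE structure
    still differs from the target.
    """
    if not target_matched or gap <= 0:
        return 0.0
    return -w_negative * gap


def dimer_design_score(
    quantities: DimerQuantities,
    e_desired_ab: float,
    x_monomer: float,
) -> float:
    """Two-strand design objective: -kT*log(x_structure * x_dimer).

    x_structure is the Boltzmann fraction of connected complexes in the
    desired dimer structure; x_dimer = 1 - x_monomer the fraction of strands
    associated at all. The product form makes the score additive:
    (E_desired(AB) - E_pf(AB)) - kT*log(1 - x_monomer), zero exactly when
    both fractions reach 1.
    """
    core = e_desired_ab - quantities.e_pf_ab
    return core + oligomer_term(x_monomer, "dimer", quantities.kT)


def random_epf_baseline(
    n: int,
    cfg: EngineConfig,
    seed: int = 0,
    n_samples: int = 50,
) -> float:
    """Mean ensemble free energy of uniform random sequences of length ``n``.

    Used by the optional length-normalized baseline term
    (E_pf - E_pf_random(n)) / n; estimated once per run from seeded draws.
    """
    from .thermo import _single_pf

    rng = np.random.default_rng(seed)
    nts = np.array(list("ACGU"))
    vals = []
    for _ in range(n_samples):
        seq = "".join(rng.choice(nts, size=n))
        vals.append(_single_pf(seq, cfg))
    return float(np.mean(vals))
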