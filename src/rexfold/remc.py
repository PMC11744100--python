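"""Replica-exchange Monte Carlo search over constraint-satisfying sequences.

Parallel tempering for discrete sequence space: several Metropolis chains
run at different Monte Carlo temperatures T_MC (control parameters, not
physical temperatures), and adjacent chains periodically attempt to swap
states. Low-T_MC replicas refine, high-T_MC replicas explore, and swaps let
good solutions migrate down the ladder while stuck ones are reheated.

Moves never leave the feasible set: a mutation resamples one connected
component of the pooled pairing graph (a single unpaired residue, a paired
couple, or a larger set coupled through overlapping pairs of alternative
structures), so every visited sequence satisfies all constraints by
construction. A configurable fraction of proposals is *targeted* at
residues whose current predicted pairing disagrees with the target
(or their neighbors up to three residues away).

Acceptance of a worsening move uses p = exp(-L * dS / T_MC); improvements
are always accepted. Replica swaps use
p = min(1, exp[(L/T_MC1 - L/T_MC2) * (S1 - S2)]).
"""

from __future__ import annotations

import math
import sys
import time
from dataclasses import dataclass, field
from typing import IO, Mapping

import numpy as np

from . import scoring, thermo
from .structures import (
    DesignTarget,
    DotBracketStructure,
    check_compatibility,
    pairing_graph,
    random_initial_sequence,
    sample_component,
)

__all__ = [
    "MetropolisParams",
    "ReplicaState",
    "ExchangeAttempt",
    "Evaluation",
    "Evaluator",
    "DesignRecord",
    "DesignResult",
    "metropolis_probability",
    "metropolis_accept",
    "exchange_probability",
    "attempt_exchange",
    "propose_mutation",
    "run",
]


@dataclass(frozen=True)
class MetropolisParams:
    """Schedule of the replica-exchange simulation.

    L                        : scaling constant (reciprocal Boltzmann
                               analog) in the acceptance exponents.
    t_ladder                 : strictly increasing T_MC values, one per
                               replica (default: 10 values equally spaced
                               over [10, 150]).
    targeted_fraction_ladder : per-replica fraction of proposals directed at
                               currently mispaired regions (default: linear
                               0.70 at the lowest T_MC down to 0.00 at the
                               highest).
    attempts_per_step        : mutation proposals per replica per global
                               step (default 100).
    exchange_interval        : global steps between swap sweeps (default 1).
    """

    L: float = 1.0
    t_ladder: tuple[float, ...] = tuple(np.linspace(10.0, 150.0, 10))
    targeted_fraction_ladder: tuple[float, ...] = tuple(
        np.linspace(0.70, 0.0, 10)
    )
    attempts_per_step: int = 100
    exchange_interval: int = 1

    def __post_init__(self) -> None:
        if len(self.t_ladder) != len(self.targeted_fraction_ladder):
            raise ValueError("ladder lengths differ")
        if any(b <= a for a, b in zip(self.t_ladder, self.t_ladder[1:])):
            raise ValueError("t_ladder must be strictly increasing")
        if any(not 0.0 <= f <= 1.0 for f in self.targeted_fraction_ladder):
            raise ValueError("targeted fractions must lie in [0, 1]")
        if self.attempts_per_step < 1:
            raise ValueError("attempts_per_step must be >= 1")

    @property
    def n_replicas(self) -> int:
        return len(self.t_ladder)


def metropolis_probability(delta_s: float, t_mc: float, L: float = 1.0) -> float:
    """Acceptance probability for a score change ``delta_s`` (new - old).

    Improvements (delta_s <= 0) are always accepted; worsenings with
    p = exp(-L * delta_s / T_MC).
    """
    if t_mc <= 0:
        raise ValueError("T_MC must be positive")
    if delta_s <= 0:
        return 1.0
    return math.exp(-L * delta_s / t_mc)


def metropolis_accept(
    s_old: float,
    s_new: float,
    t_mc: float,
    L: float,
    rng: np.random.Generator,
) -> bool:
    """Metropolis decision; consumes exactly one uniform draw."""
    u = rng.random()
    return u < metropolis_probability(s_new - s_old, t_mc, L)


def exchange_probability(
    s1: float, s2: float, t1: float, t2: float, L: float = 1.0
) -> float:
    """Swap probability min(1, exp[(L/T1 - L/T2) * (S1 - S2)])."""
    if t1 <= 0 or t2 <= 0:
        raise ValueError("temperatures must be positive")
    return min(1.0, math.exp((L / t1 - L / t2) * (s1 - s2)))


@dataclass(frozen=True)
class Evaluation:
    """One sequence with its full thermodynamic and fitness assessment."""

    sequence: str  # flat, no '&'
    report: thermo.EnergyReport
    predicted: DotBracketStructure
    score: scoring.ScoreBreakdown
    one_minus_mcc: float
    x_monomer: float | None = None
    subopt_gap: float | None = None

    @property
    def total(self) -> float:
        return self.score.total

    @property
    def solved(self) -> bool:
        return self.one_minus_mcc == 0.0


class Evaluator:
    """Maps a candidate sequence to its :class:`Evaluation` for one target.

    Pure given its configuration: identical sequences always produce
    bitwise-identical score breakdowns. Precomputes the pooled pairing
    graph, its connected components (the coupled mutation sets) and, when
    the baseline term is active, the random-sequence E_pf reference.
    """

    def __init__(
        self,
        target: DesignTarget,
        engine_cfg: thermo.EngineConfig | None = None,
        score_cfg: scoring.ScoreConfig | None = None,
        baseline_seed: int = 0,
    ) -> None:
        self.target = target
        self.engine_cfg = engine_cfg or thermo.EngineConfig()
        self.score_cfg = score_cfg or scoring.ScoreConfig()
        g = pairing_graph(target)
        self.adj: dict[int, list[int]] = {v: sorted(g.neighbors(v)) for v in g}
        import networkx as nx

        self.components: list[list[int]] = [
            sorted(c) for c in sorted(nx.connected_components(g), key=min)
        ]
        self.component_of: dict[int, int] = {
            v: k for k, comp in enumerate(self.components) for v in comp
        }
        self.depth = target.max_depth
        self._baseline: float | None = None
        if self.score_cfg.use_baseline_term:
            self._baseline = scoring.random_epf_baseline(
                target.length, self.engine_cfg, seed=baseline_seed
            )

    def evaluate(self, seq: str) -> Evaluation:
        target, ecfg, scfg = self.target, self.engine_cfg, self.score_cfg
        seq = seq.replace("&", "")
        seq_io = target.sequence_with_breaks(seq)
        report = thermo.evaluate(seq_io, target, ecfg)
        if self.depth > 1 and target.mode == "single":
            predicted = thermo.predict_pseudoknotted(seq, self.depth, ecfg)
        else:
            predicted = report.mfe_structure
        one_minus = min(
            scoring.mcc(predicted, s).one_minus_mcc for s in target.structures
        )
        core = sum(e - report.e_pf for e in report.e_desired)
        penalty = scoring.restraint_penalty(seq_io, target.restraints, scfg)
        mcc_term = one_minus if scfg.use_mcc_term else 0.0
        defect_term = report.ensemble_defect if scfg.use_defect_term else 0.0
        baseline_term = (
            (report.e_pf - self._baseline) / target.length
            if self._baseline is not None
            else 0.0
        )
        x_mon: float | None = None
        olig_term = 0.0
        restraints = target.restraints
        if target.mode == "dimer":
            strands = seq_io.split("&")
            x_dimer = scoring.dimer_fraction(
                strands[0], strands[1], ecfg, scfg.total_conc
            )
            x_mon = 1.0 - x_dimer
            olig_term = scoring.oligomer_term(x_mon, "dimer", ecfg.kT)
        elif restraints.oligomer_control in ("monomer", "dimer"):
            x_mon = scoring.monomer_fraction(
                seq, ecfg, scfg.total_conc
            ).x_monomer
            olig_term = scoring.oligomer_term(
                x_mon, restraints.oligomer_control, ecfg.kT
            )
        gap: float | None = None
        neg_term = 0.0
        if restraints.negative_design and target.mode == "single":
            matched = predicted.pair_set == target.structures[0].pair_set
            if matched:
                gap = thermo.subopt_gap(seq, ecfg, scfg.subopt_window)
                neg_term = scoring.negative_design_term(
                    gap, True, scfg.w_negative
                )
        score = scoring.ScoreBreakdown(
            core=core,
            restraint_penalty=penalty,
            mcc_term=mcc_term,
            defect_term=defect_term,
            epf_baseline_term=baseline_term,
            oligomer_term=olig_term,
            negative_term=neg_term,
        )
        return Evaluation(
            sequence=seq,
            report=report,
            predicted=predicted,
            score=score,
            one_minus_mcc=one_minus,
            x_monomer=x_mon,
            subopt_gap=gap,
        )


@dataclass
class ReplicaState:
    """One chain of the ladder: current sequence and its evaluation."""

    evaluation: Evaluation
    t_mc: float
    targeted_fraction: float
    rng: np.random.Generator

    @property
    def sequence(self) -> str:
        return self.evaluation.sequence

    @property
    def score(self) -> float:
        return self.evaluation.total


@dataclass(frozen=True)
class ExchangeAttempt:
    """Record of one attempted swap between adjacent ladder levels."""

    t_mc1: float
    t_mc2: float
    s1: float
    s2: float
    p: float
    accepted: bool


def _mismatch_pool(
    evaluation: Evaluation, target: DesignTarget, margin: int = 3
) -> list[int]:
    """Residues whose predicted pairing disagrees with the closest target
    structure, widened by ``margin`` residues to each side."""
    best = min(
        target.structures,
        key=lambda s: scoring.mcc(evaluation.predicted, s).one_minus_mcc,
    )
    pred_map = evaluation.predicted.pair_map
    targ_map = best.pair_map
    n = target.length
    wrong = {
        i for i in range(n) if pred_map.get(i) != targ_map.get(i)
    }
    pool: set[int] = set()
    for i in wrong:
        pool.update(range(max(0, i - margin), min(n, i + margin + 1)))
    return sorted(pool)


def propose_mutation(
    state: ReplicaState,
    target: DesignTarget,
    evaluator: Evaluator,
    rng: np.random.Generator | None = None,
    max_site_retries: int = 8,
    max_draw_retries: int = 8,
) -> str:
    """Candidate sequence differing from the current one in one coupled set.

    With probability ``targeted_fraction`` the mutation site is drawn from
    the mismatch pool (falling back to a uniform site when the pool is
    empty, i.e. the structure is already correct); the whole connected
    component of the site in the pooled pairing graph is resampled so the
    candidate stays constraint-satisfying. Returns the current sequence
    unchanged when no differing legal assignment is found within the retry
    budget (a no-op proposal).
    """
    rng = rng if rng is not None else state.rng
    seq = state.sequence
    allowed = target.constraint.allowed_sets
    pool: list[int] = []
    if state.targeted_fraction > 0 and rng.random() < state.targeted_fraction:
        pool = _mismatch_pool(state.evaluation, target)
    for _ in range(max_site_retries):
        if pool:
            site = int(pool[rng.integers(len(pool))])
        else:
            site = int(rng.integers(target.length))
        comp = evaluator.components[evaluator.component_of[site]]
        current = {v: seq[v] for v in comp}
        for _ in range(max_draw_retries):
            sol = sample_component(comp, evaluator.adj, allowed, rng)
            if sol is not None and sol != current:
                chars = list(seq)
                for v, nuc in sol.items():
                    chars[v] = nuc
                return "".join(chars)
        pool = []  # site exhausted; retry with a uniform site
    return seq


def attempt_exchange(
    r_low: ReplicaState,
    r_high: ReplicaState,
    L: float,
    rng: np.random.Generator,
) -> ExchangeAttempt:
    """Attempt a swap between two adjacent replicas (consumes one draw).

    On acceptance the *states* (sequence + evaluation) trade places while the
    T_MC and targeted-fraction assignments stay attached to the ladder
    levels, so the temperature multiset is invariant across the run.
    """
    p = exchange_probability(
        r_low.score, r_high.score, r_low.t_mc, r_high.t_mc, L
    )
    accepted = rng.random() < p
    attempt = ExchangeAttempt(
        t_mc1=r_low.t_mc,
        t_mc2=r_high.t_mc,
        s1=r_low.score,
        s2=r_high.score,
        p=p,
        accepted=accepted,
    )
    if accepted:
        r_low.evaluation, r_high.evaluation = r_high.evaluation, r_low.evaluation
    return attempt


@dataclass(frozen=True)
class DesignRecord:
    """One ranked solution in the final report."""

    sequence: str  # with '&' for two-strand designs
    structure: str  # predicted structure, dot-bracket
    e_pf: float
    score: float
    one_minus_mcc: float
    restraint_info: tuple[tuple[str, float], ...] = ()


@dataclass(frozen=True)
class DesignResult:
    """Ranked distinct sequences plus run bookkeeping."""

    records: tuple[DesignRecord, ...]
    n_steps: int
    n_evaluations: int
    elapsed_s: float
    seed: int

    @property
    def best(self) -> DesignRecord:
        return self.records[0]


def _restraint_info(
    ev: Evaluation, target: DesignTarget, scfg: scoring.ScoreConfig
) -> tuple[tuple[str, float], ...]:
    info: list[tuple[str, float]] = []
    r = target.restraints
    seq_io = target.sequence_with_breaks(ev.sequence)
    if r.acgu_enabled:
        flat = ev.sequence
        n = len(flat)
        l1 = sum(
            abs(flat.count(b) / n - t)
            for b, t in zip("ACGU", r.acgu_target)
        )
        info.append(("acgu_l1", l1))
    if r.motifs_required or r.motifs_forbidden:
        ok = scoring.restraint_penalty(
            seq_io,
            scoring.RestraintSpec(
                motifs_required=r.motifs_required,
                motifs_forbidden=r.motifs_forbidden,
            ),
            scfg,
        )
        info.append(("motif_violations", ok / max(scfg.w_motif, 1e-300)))
    if ev.x_monomer is not None:
        info.append(("mfp_percent", ev.x_monomer * 100.0))
        info.append(("dfp_percent", (1.0 - ev.x_monomer) * 100.0))
    if ev.subopt_gap is not None:
        info.append(("subopt_gap_kcal", ev.subopt_gap))
    return tuple(info)


def run(
    target: DesignTarget,
    params: MetropolisParams | None = None,
    *,
    engine_cfg: thermo.EngineConfig | None = None,
    score_cfg: scoring.ScoreConfig | None = None,
    max_steps: int | None = None,
    max_seconds: float | None = None,
    seed: int = 0,
    n_best: int = 10,
    initial_sequence: str | None = None,
    stop_on_perfect: bool = False,
    trajectory: IO[str] | None = None,
    progress: bool = False,
) -> DesignResult:
    """Run the replica-exchange design simulation.

    Each global step performs ``attempts_per_step`` propose/accept cycles in
    every replica, then one top-down sweep of adjacent-pair exchanges every
    ``exchange_interval`` steps. The run stops at ``max_steps`` global steps
    or ``max_seconds`` of wall time, whichever comes first (at least one
    must be given); with a limit of 0 the initial state is evaluated and
    returned. Fully reproducible for a fixed seed: every replica owns an
    independent RNG stream spawned from it, and exchanges use a dedicated
    stream. ``stop_on_perfect`` ends the run as soon as any replica reaches
    an exact structure match (1-MCC = 0).

    Returns the ``n_best`` best-scoring *distinct* sequences seen anywhere
    in the trajectory.
    """
    if max_steps is None and max_seconds is None:
        raise ValueError("set max_steps and/or max_seconds")
    params = params or MetropolisParams()
    check_compatibility(target).raise_if_infeasible(target.name)
    evaluator = Evaluator(target, engine_cfg, score_cfg, baseline_seed=seed)
    scfg = evaluator.score_cfg

    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(params.n_replicas + 2)
    init_rng = np.random.default_rng(streams[0])
    exch_rng = np.random.default_rng(streams[1])

    t0 = time.monotonic()
    if initial_sequence is not None:
        seq0 = initial_sequence.replace("&", "")
        if not target.constraint.allows(seq0):
            raise ValueError("initial sequence violates the constraints")
    else:
        seq0 = random_initial_sequence(target, init_rng)
    ev0 = evaluator.evaluate(seq0)
    n_evals = 1
    replicas = [
        ReplicaState(
            evaluation=ev0,
            t_mc=params.t_ladder[k],
            targeted_fraction=params.targeted_fraction_ladder[k],
            rng=np.random.default_rng(streams[k + 2]),
        )
        for k in range(params.n_replicas)
    ]
    best: dict[str, Evaluation] = {seq0: ev0}

    def out_of_time() -> bool:
        return max_seconds is not None and time.monotonic() - t0 >= max_seconds

    if trajectory is not None:
        trajectory.write("step\treplica\tt_mc\tsequence\tscore\tone_minus_mcc\n")

    step = 0
    done = stop_on_perfect and ev0.solved
    while not done:
        if max_steps is not None and step >= max_steps:
            break
        if out_of_time():
            break
        step += 1
        for k, rep in enumerate(replicas):
            for _ in range(params.attempts_per_step):
                cand = propose_mutation(rep, target, evaluator)
                if cand == rep.sequence:
                    continue
                ev = evaluator.evaluate(cand)
                n_evals += 1
                if metropolis_accept(
                    rep.evaluation.total, ev.total, rep.t_mc, params.L, rep.rng
                ):
                    rep.evaluation = ev
                    prev = best.get(cand)
                    if prev is None or ev.total < prev.total:
                        best[cand] = ev
                    if trajectory is not None:
                        trajectory.write(
                            f"{step}\t{k}\t{rep.t_mc:g}\t"
                            f"{target.sequence_with_breaks(cand)}\t"
                            f"{ev.total:.6f}\t{ev.one_minus_mcc:.6f}\n"
                        )
                    if stop_on_perfect and ev.solved:
                        done = True
                        break
                if out_of_time():
                    done = True
                    break
            if done:
                break
        if not done and step % params.exchange_interval == 0:
            for k in range(params.n_replicas - 1, 0, -1):
                attempt_exchange(
                    replicas[k - 1], replicas[k], params.L, exch_rng
                )
        if progress:
            top = min(e.total for e in best.values())
            print(
                f"step {step}: best score {top:.2f}, "
                f"{n_evals} evaluations",
                file=sys.stderr,
            )

    ranked = sorted(best.values(), key=lambda e: (e.total, e.sequence))[:n_best]
    records = tuple(
        DesignRecord(
            sequence=target.sequence_with_breaks(e.sequence),
            structure=e.predicted.text,
            e_pf=e.report.e_pf,
            score=e.total,
            one_minus_mcc=e.one_minus_mcc,
            restraint_info=_restraint_info(e, target, scfg),
        )
        for e in ranked
    )
    return DesignResult(
        records=records,
        n_steps=step,
        n_evaluations=n_evals,
        elapsed_s=time.monotonic() - t0,
        seed=seed,
    )
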