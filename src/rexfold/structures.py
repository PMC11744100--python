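"""Secondary-structure targets, sequence constraints and feasibility.

This module owns the combinatorial side of RNA inverse folding: multi-level
dot-bracket parsing (pseudoknots are encoded with extra bracket families),
IUPAC sequence constraints, the pooled base-pairing graph over one or more
alternative target structures, an exact feasibility check (a graph-coloring
style constraint search over canonical pairs), and seeded sampling of
constraint-satisfying sequences.

Coordinates are 0-based internally; the strand separator ``&`` is excluded
from residue indexing. User-facing error messages report 1-based positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "IUPAC",
    "CANONICAL_PAIRS",
    "PAIR_PARTNERS",
    "DotBracketStructure",
    "SequenceConstraint",
    "RestraintSpec",
    "DesignTarget",
    "StructureStats",
    "FeasibilityReport",
    "StructureParseError",
    "InfeasibleTargetError",
    "parse_dot_bracket",
    "pairs_to_dot_bracket",
    "check_compatibility",
    "random_initial_sequence",
    "count_compatible_sequences",
    "structure_stats",
    "pairing_graph",
    "sample_component",
    "iupac_match",
]

# IUPAC degenerate nucleotide alphabet (RNA).
IUPAC: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("GC"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

#: The six canonical (Watson-Crick + wobble) pairs.
CANONICAL_PAIRS: frozenset[tuple[str, str]] = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: For each nucleotide, the set of partners it can canonically pair with.
PAIR_PARTNERS: Mapping[str, frozenset[str]] = {
    "A": frozenset("U"),
    "C": frozenset("G"),
    "G": frozenset("CU"),
    "U": frozenset("AG"),
}

_OPEN = {"(": 0, "[": 1, "{": 2, "<": 3}
_CLOSE = {")": 0, "]": 1, "}": 2, ">": 3}
_BRACKETS = ["()", "[]", "{}", "<>"]


class StructureParseError(ValueError):
    """Raised for malformed dot-bracket or constraint strings."""


class InfeasibleTargetError(ValueError):
    """Raised when no sequence can satisfy a design target's constraints."""


def iupac_match(seq: str, motif: str) -> bool:
    """True if ``seq`` (concrete ACGU) matches the IUPAC ``motif`` exactly."""
    if len(seq) != len(motif):
        return False
    return all(s in IUPAC[m] for s, m in zip(seq, motif))


@dataclass(frozen=True)
class DotBracketStructure:
    """A (possibly pseudoknotted, possibly multi-strand) secondary structure.

    ``pairs`` holds 0-based ``(i, j, level)`` triples with ``i < j``; the
    bracket level maps ``() [] {} <>`` to pseudoknot depths 0-3. ``&`` is a
    strand separator and carries no residue index; ``strand_breaks`` lists
    the residue counts at which cuts occur (a break value ``b`` means a new
    strand starts at residue ``b``).
    """

    text: str
    pairs: tuple[tuple[int, int, int], ...]
    strand_breaks: tuple[int, ...]
    length: int

    @property
    def pair_set(self) -> frozenset[tuple[int, int]]:
        return frozenset((i, j) for i, j, _ in self.pairs)

    @property
    def pair_map(self) -> dict[int, int]:
        m: dict[int, int] = {}
        for i, j, _ in self.pairs:
            m[i] = j
            m[j] = i
        return m

    @property
    def n_levels(self) -> int:
        return 1 + max((lvl for _, _, lvl in self.pairs), default=0)

    @property
    def strands(self) -> tuple[str, ...]:
        return tuple(self.text.split("&"))

    def __len__(self) -> int:  # residues, excluding '&'
        return self.length


def parse_dot_bracket(text: str) -> DotBracketStructure:
    """Parse a dot-bracket string with up to four bracket families and ``&``.

    Each bracket family is matched with its own stack, so crossing pairs at
    different levels (pseudoknots) are legal, while pairs within one family
    must nest properly.
    """
    if not text:
        raise StructureParseError("empty structure string")
    stacks: list[list[int]] = [[], [], [], []]
    pairs: list[tuple[int, int, int]] = []
    breaks: list[int] = []
    idx = 0
    for pos, ch in enumerate(text):
        if ch == "&":
            breaks.append(idx)
            continue
        if ch == ".":
            idx += 1
            continue
        if ch in _OPEN:
            stacks[_OPEN[ch]].append(idx)
        elif ch in _CLOSE:
            lvl = _CLOSE[ch]
            if not stacks[lvl]:
                raise StructureParseError(
                    f"unmatched '{ch}' at position {pos + 1}"
                )
            i = stacks[lvl].pop()
            pairs.append((i, idx, lvl))
        else:
            raise StructureParseError(
                f"illegal character {ch!r} at position {pos + 1}"
            )
        idx += 1
    for lvl, st in enumerate(stacks):
        if st:
            raise StructureParseError(
                f"unclosed '{_BRACKETS[lvl][0]}' opened at residue {st[-1] + 1}"
            )
    if breaks and (0 in breaks or idx in breaks):
        raise StructureParseError("'&' cannot start or end a strand layout")
    return DotBracketStructure(
        text=text,
        pairs=tuple(sorted(pairs)),
        strand_breaks=tuple(breaks),
        length=idx,
    )


def pairs_to_dot_bracket(
    pairs: Iterable[tuple[int, int, int]],
    length: int,
    strand_breaks: Sequence[int] = (),
) -> str:
    """Serialize ``(i, j, level)`` pairs back to dot-bracket text."""
    chars = ["."] * length
    for i, j, lvl in pairs:
        if not (0 <= i < j < length):
            raise ValueError(f"pair ({i}, {j}) out of range for length {length}")
        if lvl not in (0, 1, 2, 3):
            raise ValueError(f"bracket level {lvl} outside 0-3")
        for k, br in ((i, _BRACKETS[lvl][0]), (j, _BRACKETS[lvl][1])):
            if chars[k] != ".":
                raise ValueError(f"residue {k} appears in two pairs")
            chars[k] = br
    for off, b in enumerate(sorted(strand_breaks)):
        chars.insert(b + off, "&")
    return "".join(chars)


@dataclass(frozen=True)
class StructureStats:
    """Paired/unpaired residue counts of a single structure."""

    p: int
    u: int
    n: int


def structure_stats(structure: DotBracketStructure) -> StructureStats:
    p = 2 * len(structure.pairs)
    return StructureStats(p=p, u=structure.length - p, n=structure.length)


def count_compatible_sequences(structure: DotBracketStructure) -> int:
    """Number of sequences compatible with an unconstrained structure.

    Each pair may be any of the 6 canonical pairs and each unpaired residue
    any of 4 nucleotides: ``6**(p/2) * 4**u``.
    """
    s = structure_stats(structure)
    return 6 ** (s.p // 2) * 4**s.u


@dataclass(frozen=True)
class SequenceConstraint:
    """Per-position IUPAC nucleotide constraint, with ``&`` strand layout."""

    code: str
    allowed_sets: tuple[frozenset[str], ...] = field(repr=False, default=())
    strand_breaks: tuple[int, ...] = ()

    @staticmethod
    def from_code(code: str) -> "SequenceConstraint":
        allowed: list[frozenset[str]] = []
        breaks: list[int] = []
        for pos, ch in enumerate(code.upper().replace("T", "U")):
            if ch == "&":
                breaks.append(len(allowed))
                continue
            if ch not in IUPAC:
                raise StructureParseError(
                    f"illegal IUPAC code {ch!r} at position {pos + 1}"
                )
            allowed.append(IUPAC[ch])
        if not allowed:
            raise StructureParseError("empty sequence constraint")
        return SequenceConstraint(
            code=code.upper().replace("T", "U"),
            allowed_sets=tuple(allowed),
            strand_breaks=tuple(breaks),
        )

    @property
    def length(self) -> int:
        return len(self.allowed_sets)

    def allows(self, seq: str) -> bool:
        seq = seq.replace("&", "")
        return len(seq) == self.length and all(
            c in s for c, s in zip(seq, self.allowed_sets)
        )


@dataclass(frozen=True)
class RestraintSpec:
    """Soft design preferences: composition, motifs, oligomeric state.

    Unlike constraints, restraints may be violated; violations are penalized
    by the scoring module. ``acgu_target`` is (A, C, G, U) fractions; the
    default reflects the composition bias typical of structured RNAs.
    """

    acgu_enabled: bool = False
    acgu_target: tuple[float, float, float, float] = (0.15, 0.35, 0.35, 0.15)
    motifs_required: tuple[str, ...] = ()
    motifs_forbidden: tuple[str, ...] = ()
    oligomer_control: str = "off"  # off | monomer | dimer
    negative_design: bool = False

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.acgu_target):
            raise ValueError("ACGU fractions must be non-negative")
        if abs(sum(self.acgu_target) - 1.0) > 1e-9:
            raise ValueError("ACGU fractions must sum to 1")
        if self.oligomer_control not in ("off", "monomer", "dimer"):
            raise ValueError(f"bad oligomer_control {self.oligomer_control!r}")


@dataclass(frozen=True)
class DesignTarget:
    """One design problem: constraint + >=1 target structures + restraints."""

    constraint: SequenceConstraint
    structures: tuple[DotBracketStructure, ...]
    restraints: RestraintSpec = RestraintSpec()
    name: str = "target"

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("at least one target structure is required")
        L = self.constraint.length
        breaks = self.constraint.strand_breaks
        for s in self.structures:
            if s.length != L:
                raise ValueError(
                    f"structure length {s.length} != constraint length {L}"
                )
            if s.strand_breaks != breaks:
                raise ValueError("structure strand layout differs from constraint")
        if len(breaks) > 1:
            raise ValueError("at most two strands are supported")

    @classmethod
    def from_strings(
        cls,
        constraint: str,
        *structures: str,
        restraints: "RestraintSpec | None" = None,
        name: str = "target",
    ) -> "DesignTarget":
        """Build a target from a constraint string and dot-bracket strings."""
        return cls(
            constraint=SequenceConstraint.from_code(constraint),
            structures=tuple(parse_dot_bracket(s) for s in structures),
            restraints=restraints or RestraintSpec(),
            name=name,
        )

    @property
    def mode(self) -> str:
        return "dimer" if self.constraint.strand_breaks else "single"

    @property
    def length(self) -> int:
        return self.constraint.length

    @property
    def max_depth(self) -> int:
        return max(s.n_levels for s in self.structures)

    def sequence_with_breaks(self, seq: str) -> str:
        """Insert '&' separators into a flat residue string."""
        out = seq
        for off, b in enumerate(sorted(self.constraint.strand_breaks)):
            out = out[: b + off] + "&" + out[b + off :]
        return out


def pairing_graph(target: DesignTarget) -> nx.Graph:
    """One vertex per residue, one edge per pair pooled over all structures."""
    g = nx.Graph()
    g.add_nodes_from(range(target.length))
    for s in target.structures:
        g.add_edges_from((i, j) for i, j, _ in s.pairs)
    return g


@dataclass(frozen=True)
class FeasibilityReport:
    """Outcome of the constraint-satisfaction check.

    ``assignment`` is one witness sequence (flat, no '&') when feasible;
    ``conflict`` lists the residues (0-based) of a connected component that
    admits no canonical-pair assignment when infeasible.
    """

    feasible: bool
    assignment: str | None = None
    conflict: tuple[int, ...] | None = None

    def raise_if_infeasible(self, name: str = "target") -> None:
        if not self.feasible:
            pos = ", ".join(str(i + 1) for i in (self.conflict or ()))
            raise InfeasibleTargetError(
                f"no sequence can satisfy the constraints of {name}: "
                f"conflicting residues at positions {pos}"
            )


def _solve_component(
    nodes: list[int],
    adj: Mapping[int, list[int]],
    allowed: Sequence[frozenset[str]],
    order_hint: Sequence[int] | None = None,
) -> dict[int, str] | None:
    """Exact backtracking search for a canonical-pair assignment.

    Components arising from k alternative structures are sparse (each vertex
    has at most one partner per structure, so degree <= k); plain backtracking
    with the 6-pair adjacency table is exact and fast at design sizes.
    """
    order = list(order_hint) if order_hint is not None else _bfs_order(nodes, adj)
    assign: dict[int, str] = {}

    def extend(k: int) -> bool:
        if k == len(order):
            return True
        v = order[k]
        opts = allowed[v]
        for u in adj[v]:
            if u in assign:
                opts = opts & PAIR_PARTNERS[assign[u]]
        for nuc in sorted(opts):
            assign[v] = nuc
            if extend(k + 1):
                return True
            del assign[v]
        return False

    return assign if extend(0) else None


def _bfs_order(nodes: list[int], adj: Mapping[int, list[int]]) -> list[int]:
    seen: set[int] = set()
    order: list[int] = []
    for start in sorted(nodes):
        if start in seen:
            continue
        queue = [start]
        seen.add(start)
        while queue:
            v = queue.pop(0)
            order.append(v)
            for u in sorted(adj[v]):
                if u not in seen:
                    seen.add(u)
                    queue.append(u)
    return order


def check_compatibility(target: DesignTarget) -> FeasibilityReport:
    """Decide whether any sequence satisfies all pairing + IUPAC constraints.

    The pooled pairing graph is solved component by component; every edge must
    carry one of the six canonical pairs and every vertex must stay within its
    IUPAC allowed set. The first component with no solution is returned as the
    conflict witness.
    """
    g = pairing_graph(target)
    allowed = target.constraint.allowed_sets
    if any(not s for s in allowed):
        empty = [i for i, s in enumerate(allowed) if not s]
        return FeasibilityReport(False, conflict=tuple(empty))
    adj = {v: list(g.neighbors(v)) for v in g.nodes}
    chars = [""] * target.length
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        sol = _solve_component(nodes, adj, allowed)
        if sol is None:
            return FeasibilityReport(False, conflict=tuple(nodes))
        for v, nuc in sol.items():
            chars[v] = nuc
    return FeasibilityReport(True, assignment="".join(chars))


# Initialization biases in the spirit of the Eterna player heuristics the
# search starts from: helix closures drawn GC-rich, loops A-rich, always
# within the IUPAC allowed set.
_PAIRED_WEIGHTS = {"G": 0.40, "C": 0.40, "A": 0.10, "U": 0.10}
_LOOP_WEIGHTS = {"A": 0.50, "C": 0.17, "G": 0.16, "U": 0.17}


def _weighted_order(
    opts: Iterable[str], weights: Mapping[str, float], rng: np.random.Generator
) -> list[str]:
    """Random order over ``opts``, biased by ``weights`` (Gumbel trick)."""
    opts = sorted(opts)
    if len(opts) <= 1:
        return list(opts)
    keys = [math.log(weights[o]) + rng.gumbel() for o in opts]
    return [o for _, o in sorted(zip(keys, opts), reverse=True)]


def sample_component(
    nodes: list[int],
    adj: Mapping[int, list[int]],
    allowed: Sequence[frozenset[str]],
    rng: np.random.Generator,
    fixed: Mapping[int, str] | None = None,
) -> dict[int, str] | None:
    """Sample one canonical-pair assignment for a component, biased but exact.

    Randomized backtracking: positions are filled in BFS order, candidate
    nucleotides tried in a weight-biased random order (GC-biased at paired
    vertices, A-biased at isolated ones), so any feasible component is always
    solved while typical draws follow the initialization biases.
    """
    order = _bfs_order(nodes, adj)
    assign: dict[int, str] = dict(fixed or {})
    order = [v for v in order if v not in assign]

    def extend(k: int) -> bool:
        if k == len(order):
            return True
        v = order[k]
        opts = allowed[v]
        for u in adj[v]:
            if u in assign:
                opts = opts & PAIR_PARTNERS[assign[u]]
        weights = _PAIRED_WEIGHTS if adj[v] else _LOOP_WEIGHTS
        for nuc in _weighted_order(opts, weights, rng):
            assign[v] = nuc
            if extend(k + 1):
                return True
            del assign[v]
        return False

    return assign if extend(0) else None


def random_initial_sequence(
    target: DesignTarget, rng_seed: int | np.random.Generator
) -> str:
    """Seeded random sequence satisfying every constraint of ``target``.

    Every IUPAC code is respected and every position paired in any target
    structure holds a canonical pair with each of its partners. Raises
    :class:`InfeasibleTargetError` when no such sequence exists.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    g = pairing_graph(target)
    allowed = target.constraint.allowed_sets
    if any(not s for s in allowed):
        check_compatibility(target).raise_if_infeasible(target.name)
    adj = {v: list(g.neighbors(v)) for v in g.nodes}
    chars = [""] * target.length
    for comp in sorted(nx.connected_components(g), key=min):
        nodes = sorted(comp)
        sol = sample_component(nodes, adj, allowed, rng)
        if sol is None:
            FeasibilityReport(False, conflict=tuple(nodes)).raise_if_infeasible(
                target.name
            )
        for v, nuc in sol.items():  # type: ignore[union-attr]
            chars[v] = nuc
    return "".join(chars)
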