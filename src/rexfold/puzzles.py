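"""Bundled design targets and deterministic structure generators.

Everything here is generated in code (pure functions of their seeds), so the
whole engine is testable without downloads. The bundled set covers the tool's
feature surface: a riboswitch-like two-conformation target, monomer/dimer
designs of a Com-protein-binding hairpin carrying a bipartite GAD(N)2HC
sequence motif, an archaeal SRP RNA scaffold for negative design, toy
pseudoknots, and a family of generated easy nested targets.

External puzzle collections (e.g. the Eterna100 set) are not redistributed;
any puzzle written in the target-file dialect of :mod:`rexfold.io` can be fed
to the engine directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import (
    DesignTarget,
    DotBracketStructure,
    RestraintSpec,
    SequenceConstraint,
    parse_dot_bracket,
)

__all__ = [
    "PuzzleSpec",
    "random_nested_structure",
    "bundled_puzzles",
    "easy_targets",
    "ALT_STRUCTURE_A",
    "ALT_STRUCTURE_B",
    "MOM19_CONSTRAINT",
    "MOM19_MONOMER_STRUCTURE",
    "MOM19_DIMER_STRUCTURE",
    "SRP_CONSTRAINT",
    "SRP_STRUCTURE",
]

# A single 32-nt sequence asked to fold into either a long stem with a double
# loop or two separate hairpins (a bistable / riboswitch-like target).
ALT_STRUCTURE_A = "((((..((((((....))))))......))))"
ALT_STRUCTURE_B = "((((....))))....((((((....))))))"

# Com-binding 19-mer design: the bipartite 5'-GAD(N)2HC-3' motif is held
# fixed while the rest of the sequence decides the oligomeric state. The
# same constraint is used for the monomeric-hairpin and duplex-dimer targets.
MOM19_CONSTRAINT = "GADNNHCNNNGAGNNNNNN&GADNNHCNNNGAGNNNNNN"
MOM19_MONOMER_STRUCTURE = "..((((......))))...&..((((......))))..."
MOM19_DIMER_STRUCTURE = "(((((((((.(((((((((&))))))))).)))))))))"

# Archaeal signal recognition particle RNA, 136 nt: conserved-sequence
# constraint and the crystal-structure-derived base-pairing pattern
# (three-way junction with several bulges).
SRP_CONSTRAINT = (
    "NNNNNGNCCNNNNNNNNNNNNNGNNNNNNNNNNNNNNNNNNNAGGNNNNNNNNNNNNNNNNNNNNNN"
    "NNNNNANNNNNNNAGGCNCGGAAGNGAGCANNNNNNNNNNNNNCNNNNNNNNNNNNNGGNNNNCNNNNN"
)
SRP_STRUCTURE = (
    "(((((((((((((((((.(((((..(((((.(((((((((....)))))))))..)))))...."
    "((((((.....(((.....(((....))).....)))..)))))).))))))).))))))))...)))))))"
)


@dataclass(frozen=True)
class PuzzleSpec:
    """A named design problem with a difficulty tag."""

    name: str
    structures: tuple[str, ...]
    constraint: str
    difficulty: str  # hairpin | multiloop | lone-pair | pseudoknot | switch | dimer
    known_sequence: str | None = None

    def to_target(self) -> DesignTarget:
        return DesignTarget(
            constraint=SequenceConstraint.from_code(self.constraint),
            structures=tuple(parse_dot_bracket(s) for s in self.structures),
            name=self.name,
        )

    def with_restraints(self, restraints: RestraintSpec) -> DesignTarget:
        t = self.to_target()
        return DesignTarget(
            constraint=t.constraint,
            structures=t.structures,
            restraints=restraints,
            name=t.name,
        )


def random_nested_structure(
    n: int,
    rng_seed: int | np.random.Generator,
    min_helix: int = 2,
    min_loop: int = 3,
) -> DotBracketStructure:
    """Seeded random pseudoknot-free structure with well-formed motifs.

    Every helix has at least ``min_helix`` stacked pairs and every hairpin
    loop at least ``min_loop`` unpaired residues, so all outputs are
    designable under the nearest-neighbor rules. Deterministic per seed.
    """
    if n < min_loop + 2 * min_helix:
        raise ValueError(
            f"n={n} too small: need at least {min_loop + 2 * min_helix}"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    def build(m: int, depth: int) -> str:
        # returns a fragment of exactly m residues
        if m < min_loop + 2 * min_helix:
            return "." * m
        choices = ["hairpin"]
        if m >= min_loop + 2 * min_helix + 1:
            choices.append("dot")
        if m >= 2 * (min_loop + 2 * min_helix):
            choices.append("split")
        kind = choices[int(rng.integers(len(choices)))]
        if kind == "dot":
            if rng.random() < 0.5:
                return "." + build(m - 1, depth)
            return build(m - 1, depth) + "."
        if kind == "split":
            a = int(
                rng.integers(
                    min_loop + 2 * min_helix, m - (min_loop + 2 * min_helix) + 1
                )
            )
            return build(a, depth) + build(m - a, depth)
        h_max = (m - min_loop) // 2
        h = int(rng.integers(min_helix, h_max + 1))
        inner = build(m - 2 * h, depth + 1)
        return "(" * h + inner + ")" * h

    return parse_dot_bracket(build(n, 0))


def easy_targets(
    count: int = 20, max_n: int = 50, seed: int = 2024
) -> list[PuzzleSpec]:
    """Generated easy unconstrained nested targets, <= ``max_n`` nt."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(count):
        n = int(rng.integers(20, max_n + 1))
        s = random_nested_structure(n, rng, min_helix=3, min_loop=3)
        out.append(
            PuzzleSpec(
                name=f"easy_{k:02d}",
                structures=(s.text,),
                constraint="N" * n,
                difficulty="hairpin",
            )
        )
    return out


def bundled_puzzles() -> list[PuzzleSpec]:
    """The full bundled collection; every entry passes the feasibility check."""
    puzzles = [
        PuzzleSpec(
            name="alt_structures",
            structures=(ALT_STRUCTURE_A, ALT_STRUCTURE_B),
            constraint="N" * len(ALT_STRUCTURE_A),
            difficulty="switch",
        ),
        PuzzleSpec(
            name="mom19_monomer",
            structures=(MOM19_MONOMER_STRUCTURE,),
            constraint=MOM19_CONSTRAINT,
            difficulty="dimer",
        ),
        PuzzleSpec(
            name="mom19_dimer",
            structures=(MOM19_DIMER_STRUCTURE,),
            constraint=MOM19_CONSTRAINT,
            difficulty="dimer",
        ),
        PuzzleSpec(
            name="srp_136",
            structures=(SRP_STRUCTURE,),
            constraint=SRP_CONSTRAINT,
            difficulty="multiloop",
        ),
        PuzzleSpec(
            name="toy_pseudoknot",
            structures=("((((..[[[[..))))....]]]]",),
            constraint="N" * 24,
            difficulty="pseudoknot",
        ),
        PuzzleSpec(
            name="toy_pseudoknot_deep",
            structures=(
                "(((..[[[..{{{..<<<.)))..]]]..}}}..>>>",
            ),
            constraint="N" * 37,
            difficulty="pseudoknot",
        ),
    ]
    puzzles.extend(easy_targets())
    return puzzles
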