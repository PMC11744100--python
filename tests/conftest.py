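"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from rexfold.structures import (
    CANONICAL_PAIRS,
    DesignTarget,
    SequenceConstraint,
    parse_dot_bracket,
)
from rexfold.thermo import EngineConfig


@pytest.fixture(scope="session")
def cfg99() -> EngineConfig:
    return EngineConfig(parameter_set="Turner1999")


def run_py(code: str, timeout: float = 300.0) -> str:
    """Run a snippet in a fresh interpreter (for Turner2004 work: the
    thermodynamic parameter set is fixed per process)."""
    import subprocess
    import sys

    out = subprocess.run(
        [sys.executable, "-c", code],
        capture_output=True,
        text=True,
        timeout=timeout,
    )
    assert out.returncode == 0, out.stderr
    return out.stdout


def make_target(constraint: str, *structures: str, **kw) -> DesignTarget:
    return DesignTarget.from_strings(constraint, *structures, **kw)


# ---------------------------------------------------------------- oracles


def brute_force_feasible(target: DesignTarget) -> bool:
    """Exhaustive check over all nucleotide assignments (n <= 8)."""
    allowed = [sorted(s) for s in target.constraint.allowed_sets]
    edges = set()
    for s in target.structures:
        edges.update((i, j) for i, j, _ in s.pairs)
    for combo in itertools.product(*allowed):
        if all((combo[i], combo[j]) in CANONICAL_PAIRS for i, j in edges):
            return True
    return False


def brute_force_compatible_count(structure_text: str) -> int:
    """Count sequences whose pairs are all canonical, via base-4 encoding."""
    s = parse_dot_bracket(structure_text)
    n = s.length
    codes = np.arange(4 ** n, dtype=np.int64)
    digits = [(codes // 4 ** k) % 4 for k in range(n)]
    canon = np.zeros((4, 4), dtype=bool)
    nts = "ACGU"
    for a, b in CANONICAL_PAIRS:
        canon[nts.index(a), nts.index(b)] = True
    ok = np.ones(len(codes), dtype=bool)
    for i, j, _ in s.pairs:
        ok &= canon[digits[i], digits[j]]
    return int(ok.sum())


def brute_force_confusion(pred_pairs, targ_pairs, n):
    """Confusion counts by iterating over every unordered position pair."""
    tp = fp = fn = tn = 0
    for i in range(n):
        for j in range(i + 1, n):
            in_p = (i, j) in pred_pairs
            in_t = (i, j) in targ_pairs
            if in_p and in_t:
                tp += 1
            elif in_p:
                fp += 1
            elif in_t:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def random_matching(n: int, rng: np.random.Generator, max_pairs: int) -> str:
    """Random (possibly crossing-free by construction) pair set as level-0
    dot-bracket text, used to build small arbitrary targets."""
    positions = list(range(n))
    rng.shuffle(positions)
    chars = ["."] * n
    pairs = []
    while len(positions) >= 2 and len(pairs) < max_pairs:
        i, j = sorted((positions.pop(), positions.pop()))
        pairs.append((i, j))
    # nested encoding is not required for feasibility tests; keep only
    # non-crossing subsets so the text stays parseable
    kept: list[tuple[int, int]] = []
    for i, j in sorted(pairs):
        if all(not (a < i < b < j or i < a < j < b) for a, b in kept):
            kept.append((i, j))
    for i, j in kept:
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


def random_constraint(n: int, rng: np.random.Generator) -> str:
    codes = "ACGUNNNNRYSWKMBDHV"
    return "".join(codes[rng.integers(len(codes))] for _ in range(n))
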