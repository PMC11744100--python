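"""Target-file parsing and result writing.

Target-file dialect
-------------------
Plain text; blank lines and ``#`` comments are ignored. An optional leading
``>name`` line names the target. The first data line is the IUPAC sequence
constraint (with ``&`` strand separators), each following data line one
dot-bracket target structure — two or more structure lines define an
alternative-conformation design. All lines must share length and strand
layout.

Results are written as an RFC 4180 CSV with columns ``structure, sequence,
E_pf, score, one_minus_mcc`` followed by one column per active restraint,
rows sorted ascending by score (best first).
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

from .remc import DesignResult
from .structures import (
    DesignTarget,
    DotBracketStructure,
    RestraintSpec,
    SequenceConstraint,
    StructureParseError,
    parse_dot_bracket,
)

__all__ = [
    "read_target_file",
    "write_target_file",
    "write_results_csv",
    "write_config_json",
]

_BASE_COLUMNS = ("structure", "sequence", "E_pf", "score", "one_minus_mcc")


def read_target_file(
    path: str | Path, restraints: RestraintSpec | None = None
) -> DesignTarget:
    """Parse a design-target file into a :class:`DesignTarget`."""
    path = Path(path)
    name = path.stem
    constraint: SequenceConstraint | None = None
    constraint_line = 0
    structures: list[DotBracketStructure] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].strip() or name
            continue
        if constraint is None:
            try:
                constraint = SequenceConstraint.from_code(line)
            except StructureParseError as exc:
                raise StructureParseError(f"{path}:{lineno}: {exc}") from exc
            constraint_line = lineno
            continue
        try:
            s = parse_dot_bracket(line)
        except StructureParseError as exc:
            raise StructureParseError(f"{path}:{lineno}: {exc}") from exc
        if s.length != constraint.length:
            raise StructureParseError(
                f"{path}:{lineno}: structure length {s.length} does not match "
                f"constraint length {constraint.length} (line {constraint_line})"
            )
        structures.append(s)
    if constraint is None:
        raise StructureParseError(f"{path}: no constraint line found")
    if not structures:
        raise StructureParseError(f"{path}: no structure lines found")
    return DesignTarget(
        constraint=constraint,
        structures=tuple(structures),
        restraints=restraints or RestraintSpec(),
        name=name,
    )


def write_target_file(target: DesignTarget, path: str | Path) -> None:
    """Serialize a target back to the dialect of :func:`read_target_file`."""
    lines = [f">{target.name}", target.constraint.code]
    lines.extend(s.text for s in target.structures)
    Path(path).write_text("\n".join(lines) + "\n")


def write_results_csv(result: DesignResult, path: str | Path) -> None:
    """Write ranked designs as CSV; floats keep full round-trip precision."""
    extra: list[str] = []
    for rec in result.records:
        for key, _ in rec.restraint_info:
            if key not in extra:
                extra.append(key)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_BASE_COLUMNS) + extra)
        for rec in sorted(result.records, key=lambda r: r.score):
            info = dict(rec.restraint_info)
            writer.writerow(
                [
                    rec.structure,
                    rec.sequence,
                    repr(rec.e_pf),
                    repr(rec.score),
                    repr(rec.one_minus_mcc),
                ]
                + [repr(info[k]) if k in info else "" for k in extra]
            )


def write_config_json(config: dict, path: str | Path) -> None:
    """Echo the effective run configuration for provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(config, indent=2, default=str) + "\n")
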