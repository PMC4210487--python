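"""Catalytic-residue and motif conservation across a multiple alignment.

Functional sites are specified relative to a named reference row: a residue
spec pins one ungapped position of the reference (e.g. the catalytic Sec/Cys
of selenophosphate synthetase, or Asn87 of the E. coli enzyme) together with
the residue letters counted as conserved; a motif spec is an ordered pattern
over consecutive ungapped residues (e.g. the active-site [CU]-X-X-K motif,
catalytic Sec/Cys followed by lysine three residues downstream). Positions
are mapped through the alignment to every other row, so conservation can be
scored per sequence family (SelD vs SelD-like).

Motifs are evaluated on ungapped residues, not alignment columns: a site
"at the same or very close position" in a homolog is a residue-space notion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .core_model import ConfigurationError, FormatError, Msa, GAP

__all__ = [
    "ResidueSpec",
    "MotifSpec",
    "ResidueStatus",
    "ResidueReport",
    "map_reference_position",
    "column_to_position",
    "check_residue",
    "check_motif",
    "load_site_specs",
]


@dataclass(frozen=True)
class ResidueSpec:
    """One functional position: reference row, 1-based ungapped position,
    and the set of letters counted as conserved."""

    name: str
    reference_id: str
    reference_pos: int
    allowed: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed", frozenset(a.upper() for a in self.allowed))
        if self.reference_pos < 1:
            raise ConfigurationError(f"residue spec {self.name!r}: position must be >= 1")


@dataclass(frozen=True)
class MotifSpec:
    """An ordered residue pattern; each element is a letter set or None (X)."""

    name: str
    pattern: tuple[frozenset[str] | None, ...]

    def __post_init__(self) -> None:
        if len(self.pattern) < 1:
            raise ConfigurationError(f"motif {self.name!r}: empty pattern")

    @classmethod
    def parse(cls, name: str, text: str) -> "MotifSpec":
        """Parse a compact pattern string: ``[CU]xx[K]`` or ``CxxK``.

        ``x``/``X`` (outside brackets) is a wildcard; ``[...]`` encloses an
        allowed-letter set.
        """
        pattern: list[frozenset[str] | None] = []
        i = 0
        while i < len(text):
            ch = text[i]
            if ch == "[":
                j = text.find("]", i)
                if j < 0:
                    raise FormatError(f"motif {name!r}: unclosed '[' in {text!r}")
                pattern.append(frozenset(text[i + 1:j].upper()))
                i = j + 1
            elif ch in "xX":
                pattern.append(None)
                i += 1
            else:
                pattern.append(frozenset(ch.upper()))
                i += 1
        return cls(name, tuple(pattern))


def map_reference_position(msa: Msa, reference_id: str, reference_pos: int) -> int:
    """The 1-based MSA column holding an ungapped reference position."""
    try:
        row = msa.rows[reference_id]
    except KeyError:
        raise KeyError(f"no alignment row {reference_id!r}") from None
    count = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            count += 1
            if count == reference_pos:
                return col
    raise IndexError(
        f"position {reference_pos} beyond ungapped length {count} of {reference_id!r}"
    )


def column_to_position(msa: Msa, row_id: str, column: int) -> int | None:
    """The 1-based ungapped position of ``row_id`` at an MSA column, or
    ``None`` if that row has a gap there."""
    row = msa.rows[row_id]
    if not (1 <= column <= msa.ncol):
        raise IndexError(f"column {column} outside 1..{msa.ncol}")
    if row[column - 1] == GAP:
        return None
    return sum(1 for ch in row[:column] if ch != GAP)


@dataclass(frozen=True)
class ResidueStatus:
    status: str            # "conserved" | "substituted" | "gap"
    letter: str | None     # the observed residue, None for a gap


@dataclass
class ResidueReport:
    spec: ResidueSpec
    column: int
    per_row: dict[str, ResidueStatus]

    @property
    def fraction_conserved(self) -> float:
        if not self.per_row:
            return 0.0
        return sum(s.status == "conserved" for s in self.per_row.values()) / len(self.per_row)


def check_residue(msa: Msa, spec: ResidueSpec,
                  rows: Iterable[str] | None = None) -> ResidueReport:
    """Status of every row at the column mapped from the reference position."""
    column = map_reference_position(msa, spec.reference_id, spec.reference_pos)
    row_ids = list(rows) if rows is not None else list(msa.rows)
    missing = [r for r in row_ids if r not in msa.rows]
    if missing:
        raise KeyError(f"rows not in alignment: {missing}")
    per_row: dict[str, ResidueStatus] = {}
    for rid in row_ids:
        ch = msa.rows[rid][column - 1].upper()
        if ch == GAP:
            per_row[rid] = ResidueStatus("gap", None)
        elif ch in spec.allowed:
            per_row[rid] = ResidueStatus("conserved", ch)
        else:
            per_row[rid] = ResidueStatus("substituted", ch)
    return ResidueReport(spec, column, per_row)


def check_motif(msa: Msa, spec: MotifSpec, anchor_column: int) -> dict[str, bool]:
    """Evaluate a motif on each row's ungapped residues from an anchor column.

    The motif starts at the residue a row carries at ``anchor_column``; rows
    with a gap at the anchor, or with fewer residues left than the pattern
    needs, evaluate to False.
    """
    if not (1 <= anchor_column <= msa.ncol):
        raise IndexError(f"anchor column {anchor_column} outside 1..{msa.ncol}")
    result: dict[str, bool] = {}
    for rid in msa.rows:
        start = column_to_position(msa, rid, anchor_column)
        if start is None:
            result[rid] = False
            continue
        residues = msa.ungapped(rid)[start - 1:]
        if len(residues) < len(spec.pattern):
            result[rid] = False
            continue
        result[rid] = all(
            allowed is None or residues[k].upper() in allowed
            for k, allowed in enumerate(spec.pattern)
        )
    return result


def load_site_specs(path: str | Path) -> tuple[list[ResidueSpec], list[MotifSpec]]:
    """Load residue/motif specs from YAML.

    Layout::

        residues:
          - {name: catalytic_cys, reference: Ec_SelD, position: 17, allowed: CU}
        motifs:
          - {name: active_site, pattern: "[CU]xx[K]"}
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    residues = [
        ResidueSpec(d["name"], d["reference"], int(d["position"]),
                    frozenset(str(d["allowed"])))
        for d in data.get("residues", [])
    ]
    motifs = [
        MotifSpec.parse(d["name"], str(d["pattern"]))
        for d in data.get("motifs", [])
    ]
    return residues, motifs
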