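"""Selenium-utilization trait classification from marker-gene presence.

Three Se utilization traits are recognised, each requiring the Se-donor
enzyme SelD (selenophosphate synthetase) plus trait-specific partners:

* ``Sec``        — selenocysteine decoding: SelD + a Sec synthase (bacterial
                   SelA or archaeal SecS) + SelB;
* ``SeU``        — 2-selenouridine tRNA modification: SelD + YbbB;
* ``SeCofactor`` — Se-containing molybdenum-hydroxylase cofactor:
                   SelD + YqeB + YqeC.

A genome carrying SelD but no complete trait is flagged as an *orphan SelD*.
The distant SelD-like family is tracked alongside but never contributes to
a Se trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

import pandas as pd

from .core_model import ConfigurationError, Genome, GenomeSet, ProteinRecord
from .homology import HomologyCriteria, ScoringScheme, SELD_SEARCH_CRITERIA, search

__all__ = [
    "MARKERS",
    "TRAIT_RULES",
    "MarkerPanel",
    "TraitCall",
    "call_markers",
    "classify_traits",
    "clade_summary",
    "round_percentage",
]

#: Marker genes of the panel, in display order.
MARKERS = ("SelD", "SelA", "SecS", "SelB", "YbbB", "YqeB", "YqeC", "SelD-like")

#: Trait name -> sets of markers, any one set sufficient (each set is a
#: conjunction). Sec accepts either Sec synthase.
TRAIT_RULES: dict[str, tuple[frozenset[str], ...]] = {
    "Sec": (frozenset({"SelD", "SelA", "SelB"}), frozenset({"SelD", "SecS", "SelB"})),
    "SeU": (frozenset({"SelD", "YbbB"}),),
    "SeCofactor": (frozenset({"SelD", "YqeB", "YqeC"}),),
}

_REQUIRED_KEYS = frozenset(m for m in MARKERS if m != "SelD-like")


@dataclass
class MarkerPanel:
    """Representative query sequences per marker plus per-marker criteria.

    ``queries`` maps a marker name to one or more representative proteins;
    a marker is present in a genome when any of its queries has a passing
    hit. ``criteria`` may assign per-marker rules; markers not listed use
    ``default_criteria`` (the E <= 0.1 occurrence-search rule).
    """

    queries: dict[str, list[ProteinRecord]]
    criteria: dict[str, HomologyCriteria] = field(default_factory=dict)
    default_criteria: HomologyCriteria = SELD_SEARCH_CRITERIA

    def __post_init__(self) -> None:
        if not self.queries:
            raise ConfigurationError("marker panel is empty")
        for marker, queries in self.queries.items():
            if not queries:
                raise ConfigurationError(f"marker {marker!r} has no query sequences")

    def criteria_for(self, marker: str) -> HomologyCriteria:
        return self.criteria.get(marker, self.default_criteria)


@dataclass(frozen=True)
class TraitCall:
    """Per-genome marker flags and derived Se-utilization traits."""

    genome_id: str
    marker_presence: Mapping[str, bool]
    traits: frozenset[str]
    orphan_seld: bool
    seld_like: bool


def call_markers(genome: Genome, panel: MarkerPanel,
                 scheme: ScoringScheme = ScoringScheme()) -> dict[str, bool]:
    """Presence of each panel marker in one genome's proteome."""
    presence: dict[str, bool] = {}
    for marker, queries in panel.queries.items():
        criteria = panel.criteria_for(marker)
        presence[marker] = any(
            search(q, genome, criteria, scheme) for q in queries
        )
    return presence


def classify_traits(marker_presence: Mapping[str, bool],
                    genome_id: str = "") -> TraitCall:
    """Derive trait labels from marker presence.

    Raises :class:`ConfigurationError` when a required panel marker is
    missing from the map (the SelD-like flag is optional and defaults to
    absent).
    """
    missing = _REQUIRED_KEYS - set(marker_presence)
    if missing:
        raise ConfigurationError(f"marker map lacks required markers: {sorted(missing)}")
    traits = frozenset(
        trait for trait, rules in TRAIT_RULES.items()
        if any(all(marker_presence[m] for m in rule) for rule in rules)
    )
    seld = bool(marker_presence["SelD"])
    return TraitCall(
        genome_id=genome_id,
        marker_presence=dict(marker_presence),
        traits=traits,
        orphan_seld=seld and not traits,
        seld_like=bool(marker_presence.get("SelD-like", False)),
    )


def round_percentage(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (26 of 215 -> 12.1)."""
    if denominator == 0:
        return 0.0
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def clade_summary(calls: Iterable[TraitCall], genomes: GenomeSet,
                  rank: int = -1) -> pd.DataFrame:
    """Per-clade counts of genomes, SelD carriers, traits and SelD-like.

    ``rank`` indexes into each genome's lineage tuple (default: narrowest
    clade). The table carries one row per clade plus a ``Total`` row, and a
    ``pct_SelD`` column with the share of SelD-positive genomes to one
    decimal, rounded half-up.
    """
    calls = list(calls)
    for call in calls:
        if call.genome_id not in genomes.genomes:
            raise ConfigurationError(f"call for unknown genome {call.genome_id!r}")

    def clade_of(gid: str) -> str:
        lineage = genomes[gid].lineage
        return lineage[rank] if lineage else "(unassigned)"

    rows: dict[str, dict[str, int]] = {}
    for call in calls:
        row = rows.setdefault(clade_of(call.genome_id), {
            "n_genomes": 0, "n_SelD": 0, "n_Sec": 0, "n_SeU": 0,
            "n_SeCofactor": 0, "n_orphan_SelD": 0, "n_SelD_like": 0,
        })
        row["n_genomes"] += 1
        row["n_SelD"] += call.marker_presence.get("SelD", False)
        row["n_Sec"] += "Sec" in call.traits
        row["n_SeU"] += "SeU" in call.traits
        row["n_SeCofactor"] += "SeCofactor" in call.traits
        row["n_orphan_SelD"] += call.orphan_seld
        row["n_SelD_like"] += call.seld_like

    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.loc["Total"] = df.sum()
    df["pct_SelD"] = [
        round_percentage(int(r["n_SelD"]), int(r["n_genomes"])) for _, r in df.iterrows()
    ]
    df.index.name = "clade"
    return df
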