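"""Synthetic genome sets with planted ground truth.

The generator emulates the shape of the comparative study the pipeline was
built for, without any downloads: clades of genomes whose protein families
diverge from common seed sequences by point substitution; trait marker genes
(SelD, SelA, SecS, SelB, YbbB, YqeB, YqeC) planted in configured genomes; a
SelD-like anchor gene with a planned gene neighborhood (e.g. SirA-like and
Prx-like partners) inside a fixed nucleotide window; fusion proteins
carrying two domains; and one gene planted exclusively in a designated
positive genome set — the target of the co-occurrence screen.

Evolution model: each family has one seed sequence; a clade ancestor is
derived from the seed and each genome's copy from its clade ancestor, with
i.i.d. substitutions at a fixed per-branch rate (uniform replacement over
the other 19 residues, no indels — alignment columns remain trivially
mappable). Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .core_model import (
    AMINO_ACIDS,
    ConfigurationError,
    GeneLocus,
    Genome,
    GenomeSet,
    ProteinRecord,
)
from .homology import HomologyCriteria
from .traits import MARKERS, MarkerPanel

__all__ = [
    "NeighborhoodPlan",
    "FusionPlan",
    "SimConfig",
    "GroundTruth",
    "simulate",
    "default_study_config",
    "marker_panel_from_truth",
    "MARKER_CALL_CRITERIA",
]

# Approximate background amino-acid frequencies (Robinson & Robinson order
# matched to AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY").
_AA_FREQS = np.array([
    0.079, 0.019, 0.054, 0.063, 0.040, 0.074, 0.022, 0.051, 0.057, 0.091,
    0.022, 0.045, 0.052, 0.042, 0.051, 0.068, 0.059, 0.066, 0.013, 0.032,
])
_AA_FREQS = _AA_FREQS / _AA_FREQS.sum()

#: Criteria used for marker calling on synthetic panels: strict enough that
#: chance hits between unrelated random proteins are effectively impossible,
#: while planted homologs at the simulated divergences pass comfortably.
MARKER_CALL_CRITERIA = HomologyCriteria(
    max_evalue=1e-5, min_query_cover=0.5, min_identity=0.30
)


@dataclass(frozen=True)
class NeighborhoodPlan:
    """Anchor gene plus neighbor genes planted within a window."""

    anchor_label: str = "SelD-like"
    member_labels: tuple[str, ...] = ("SirA-like", "Prx-like")
    genomes: frozenset[str] = frozenset()
    window_nt: int = 10_000


@dataclass(frozen=True)
class FusionPlan:
    """In the listed genomes the anchor protein carries a second domain."""

    labels: tuple[str, str] = ("SelD-like", "acylphosphatase-like")
    genomes: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic genome set.

    ``clades`` maps clade name to the genome ids it contains; every genome
    referenced anywhere else must be declared there. ``substitution_rate``
    is the per-branch fraction of sites substituted (seed -> clade ancestor
    and ancestor -> genome), so within-clade homologs differ by roughly
    twice the rate.
    """

    seed: int = 0
    clades: tuple[tuple[str, tuple[str, ...]], ...] = ()
    n_background_families: int = 50
    protein_length: tuple[int, int] = (80, 160)
    substitution_rate: float = 0.05
    trait_plantings: tuple[tuple[str, frozenset[str]], ...] = ()
    exclusive_gene: tuple[frozenset[str], frozenset[str]] | None = None
    neighborhood_plan: NeighborhoodPlan | None = None
    fusion_plan: FusionPlan | None = None
    intergenic_range: tuple[int, int] = (200, 1500)
    reference_genome: str | None = None

    def genome_ids(self) -> list[str]:
        return [gid for _, gids in self.clades for gid in gids]

    def validate(self) -> None:
        if not (0 <= self.substitution_rate < 1):
            raise ConfigurationError("substitution_rate must be in [0, 1)")
        if self.n_background_families < 1:
            raise ConfigurationError("need at least one background family")
        if self.protein_length[0] < 10 or self.protein_length[0] > self.protein_length[1]:
            raise ConfigurationError(f"bad protein length range {self.protein_length}")
        declared = set(self.genome_ids())
        if len(declared) != len(self.genome_ids()):
            raise ConfigurationError("duplicate genome ids across clades")

        def check(gids: Iterable[str], what: str) -> None:
            unknown = set(gids) - declared
            if unknown:
                raise ConfigurationError(f"{what} references undeclared genomes: {sorted(unknown)}")

        for gid, markers in self.trait_plantings:
            check([gid], "trait_plantings")
            bad = set(markers) - set(MARKERS)
            if bad:
                raise ConfigurationError(f"unknown markers {sorted(bad)} for {gid!r}")
        if self.exclusive_gene is not None:
            pos, neg = self.exclusive_gene
            check(pos, "exclusive_gene positives")
            check(neg, "exclusive_gene negatives")
            if set(pos) & set(neg):
                raise ConfigurationError("exclusive_gene positive/negative sets overlap")
        if self.neighborhood_plan is not None:
            check(self.neighborhood_plan.genomes, "neighborhood_plan")
        if self.fusion_plan is not None:
            check(self.fusion_plan.genomes, "fusion_plan")
            if self.neighborhood_plan is None:
                raise ConfigurationError("fusion_plan requires a neighborhood_plan anchor")
        if self.reference_genome is not None:
            check([self.reference_genome], "reference_genome")


@dataclass
class GroundTruth:
    """What was planted where — checkable against the emitted files."""

    config: SimConfig
    marker_seeds: dict[str, ProteinRecord]
    domain_seeds: dict[str, ProteinRecord]
    planted_markers: dict[str, frozenset[str]]
    exclusive_gene_id: str | None
    screen_expected: frozenset[str]
    ortholog_map: dict[str, dict[str, str]]
    anchor_genes: dict[str, str]
    neighborhood_members: dict[str, tuple[str, ...]]
    fusion_protein_ids: frozenset[str]
    clade_tree_newick: str


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=_AA_FREQS)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each site with probability ``rate``, uniformly over the
    other 19 residues."""
    if rate == 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = AMINO_ACIDS.replace(chars[i], "")
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


#: Functional-site constraints applied to the SelD and SelD-like families:
#: an invariant catalytic Cys at position 17 and Lys three residues
#: downstream (the active-site [CU]-X-X-K motif), exempt from substitution.
CATALYTIC_POSITION = 17
_CATALYTIC_CONSTRAINTS = ((CATALYTIC_POSITION, "C"), (CATALYTIC_POSITION + 3, "K"))


@dataclass
class _Family:
    family_id: str
    seed: str
    genomes: frozenset[str] | None   # None => all genomes
    label: str | None = None
    annotation: str = "hypothetical protein"
    constraints: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        self.seed = _apply_constraints(self.seed, self.constraints)


def _apply_constraints(seq: str, constraints: tuple[tuple[int, str], ...]) -> str:
    chars = list(seq)
    for pos, letter in constraints:
        if pos <= len(chars):
            chars[pos - 1] = letter
    return "".join(chars)


def simulate(config: SimConfig) -> tuple[GenomeSet, GroundTruth]:
    """Generate a genome set plus its ground truth, deterministically."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length
    all_genomes = config.genome_ids()
    plantings = {gid: frozenset(m) for gid, m in config.trait_plantings}

    # --- family plan ------------------------------------------------------
    families: list[_Family] = []
    for i in range(config.n_background_families):
        families.append(_Family(
            family_id=f"fam{i + 1:04d}",
            seed=_random_protein(rng, int(rng.integers(lo, hi + 1))),
            genomes=None,
        ))
    marker_seeds: dict[str, ProteinRecord] = {}
    for marker in MARKERS:
        if marker == "SelD-like":
            continue  # the SelD-like family is the neighborhood anchor
        seq = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        constraints = _CATALYTIC_CONSTRAINTS if marker == "SelD" else ()
        seq = _apply_constraints(seq, constraints)
        marker_seeds[marker] = ProteinRecord(f"ref_{marker}", f"{marker} representative", seq)
        carriers = frozenset(g for g, ms in plantings.items() if marker in ms)
        families.append(_Family(
            family_id=f"marker_{marker}", seed=seq, genomes=carriers,
            label=marker, annotation=f"{marker} protein", constraints=constraints,
        ))

    domain_seeds: dict[str, ProteinRecord] = {}
    nb = config.neighborhood_plan
    anchor_family: _Family | None = None
    member_families: list[_Family] = []
    if nb is not None:
        anchor_len = max(hi, lo + (hi - lo) // 2)
        anchor_seq = _apply_constraints(
            _random_protein(rng, anchor_len), _CATALYTIC_CONSTRAINTS
        )
        domain_seeds[nb.anchor_label] = ProteinRecord(
            f"ref_{nb.anchor_label}", f"{nb.anchor_label} representative", anchor_seq
        )
        anchor_family = _Family(
            family_id=f"anchor_{nb.anchor_label}", seed=anchor_seq,
            genomes=frozenset(nb.genomes), label=nb.anchor_label,
            annotation=f"{nb.anchor_label} protein", constraints=_CATALYTIC_CONSTRAINTS,
        )
        for label in nb.member_labels:
            seq = _random_protein(rng, int(rng.integers(lo, hi + 1)))
            domain_seeds[label] = ProteinRecord(f"ref_{label}", f"{label} representative", seq)
            member_families.append(_Family(
                family_id=f"member_{label}", seed=seq,
                genomes=frozenset(nb.genomes), label=label,
                annotation=f"{label} protein",
            ))
            if 3 * len(seq) + 20 > nb.window_nt:
                raise ConfigurationError(
                    f"neighborhood window {nb.window_nt} nt smaller than planted "
                    f"member gene {label!r} ({3 * len(seq)} nt)"
                )
    fusion_domain_seq = None
    if config.fusion_plan is not None:
        fusion_label = config.fusion_plan.labels[1]
        fusion_domain_seq = _random_protein(rng, max(lo // 2, 40))
        domain_seeds[fusion_label] = ProteinRecord(
            f"ref_{fusion_label}", f"{fusion_label} representative", fusion_domain_seq
        )

    exclusive_family: _Family | None = None
    if config.exclusive_gene is not None:
        pos, _neg = config.exclusive_gene
        exclusive_family = _Family(
            family_id="exclusive", seed=_random_protein(rng, int(rng.integers(lo, hi + 1))),
            genomes=frozenset(pos), annotation="exclusively co-occurring protein",
        )

    # --- per-clade ancestors ---------------------------------------------
    ordered_families = list(families)
    if exclusive_family is not None:
        ordered_families.append(exclusive_family)
    placeable = ordered_families + member_families + (
        [anchor_family] if anchor_family is not None else []
    )
    def evolve(fam: _Family, base: str) -> str:
        return _apply_constraints(
            _mutate(rng, base, config.substitution_rate), fam.constraints
        )

    ancestors: dict[tuple[str, str], str] = {}
    for clade, _gids in config.clades:
        for fam in placeable:
            ancestors[(clade, fam.family_id)] = evolve(fam, fam.seed)

    # --- assemble genomes -------------------------------------------------
    gs = GenomeSet()
    ortholog_map: dict[str, dict[str, str]] = {f.family_id: {} for f in placeable}
    anchor_genes: dict[str, str] = {}
    neighborhood_members: dict[str, tuple[str, ...]] = {}
    fusion_ids: set[str] = set()
    planted_markers: dict[str, frozenset[str]] = {}

    for clade, gids in config.clades:
        for gid in gids:
            # ordered gene plan: background + markers + exclusive first,
            # then the neighborhood block (members flanking the anchor)
            plan: list[tuple[_Family, str]] = []
            for fam in ordered_families:
                if fam.genomes is None or gid in fam.genomes:
                    plan.append((fam, evolve(fam, ancestors[(clade, fam.family_id)])))
            block: list[tuple[_Family, str]] = []
            if anchor_family is not None and gid in anchor_family.genomes:
                aseq = evolve(anchor_family, ancestors[(clade, anchor_family.family_id)])
                fused = (config.fusion_plan is not None
                         and gid in config.fusion_plan.genomes)
                if fused:
                    aseq = aseq + _mutate(rng, fusion_domain_seq, config.substitution_rate)
                members = [
                    (fam, evolve(fam, ancestors[(clade, fam.family_id)]))
                    for fam in member_families
                ]
                half = len(members) // 2
                block = members[:half] + [(anchor_family, aseq)] + members[half:]
            # insert the neighborhood block mid-contig
            mid = len(plan) // 2
            layout = plan[:mid] + block + plan[mid:]
            block_positions = set(range(mid, mid + len(block)))

            loci, proteome = [], {}
            gene_of_family: dict[str, str] = {}
            pos_nt = 1
            for k, (fam, seq) in enumerate(layout):
                gap_lo, gap_hi = config.intergenic_range
                if k in block_positions or k - 1 in block_positions:
                    gap_lo, gap_hi = 20, 120  # tight spacing around the planted cluster
                gap = int(rng.integers(gap_lo, gap_hi + 1))
                start = pos_nt + gap
                end = start + 3 * len(seq) - 1
                pos_nt = end
                pid = f"{gid}_p{k + 1:04d}"
                gene_id = f"{gid}_g{k + 1:04d}"
                labels: set[str] = set()
                if fam.label:
                    labels.add(fam.label)
                fused_here = (
                    anchor_family is not None and fam is anchor_family
                    and config.fusion_plan is not None
                    and gid in config.fusion_plan.genomes
                )
                if fused_here:
                    labels.add(config.fusion_plan.labels[1])
                    fusion_ids.add(pid)
                strand = "+" if rng.random() < 0.5 else "-"
                loci.append(GeneLocus(
                    gene_id, pid, "chr", start, end, strand,
                    fam.annotation, frozenset(labels),
                ))
                proteome[pid] = ProteinRecord(pid, fam.annotation, seq, genome_id=gid)
                ortholog_map[fam.family_id][gid] = pid
                gene_of_family[fam.family_id] = gene_id
                if anchor_family is not None and fam is anchor_family:
                    anchor_genes[gid] = gene_id
            gs.add(Genome(gid, (clade,), loci, proteome))
            planted_markers[gid] = plantings.get(gid, frozenset())
            if gid in anchor_genes:
                neighborhood_members[gid] = tuple(
                    gene_of_family[fam.family_id] for fam in member_families
                )
                genome = gs[gid]
                anchor = genome.locus(anchor_genes[gid])
                for m_gene in neighborhood_members[gid]:
                    m = genome.locus(m_gene)
                    if m.end < anchor.start - nb.window_nt or m.start > anchor.end + nb.window_nt:
                        raise ConfigurationError(
                            f"planted neighborhood member {m_gene} fell outside the "
                            f"{nb.window_nt} nt window in {gid}"
                        )

    # --- ground truth ----------------------------------------------------
    reference = config.reference_genome or all_genomes[0]
    exclusive_gene_id = None
    screen_expected: set[str] = set()
    if exclusive_family is not None:
        pos, neg = config.exclusive_gene
        exclusive_gene_id = ortholog_map["exclusive"].get(reference)
        for fam in placeable:
            carriers = set(all_genomes) if fam.genomes is None else set(fam.genomes)
            if (reference in carriers and set(pos) <= carriers
                    and not (set(neg) & carriers)):
                screen_expected.add(ortholog_map[fam.family_id][reference])

    clade_newick = "(" + ",".join(
        "(" + ",".join(gids) + ")" + clade for clade, gids in config.clades
    ) + ");"

    truth = GroundTruth(
        config=config,
        marker_seeds=marker_seeds,
        domain_seeds=domain_seeds,
        planted_markers=planted_markers,
        exclusive_gene_id=exclusive_gene_id,
        screen_expected=frozenset(screen_expected),
        ortholog_map=ortholog_map,
        anchor_genes=anchor_genes,
        neighborhood_members=neighborhood_members,
        fusion_protein_ids=frozenset(fusion_ids),
        clade_tree_newick=clade_newick,
    )
    return gs, truth


def marker_panel_from_truth(truth: GroundTruth) -> MarkerPanel:
    """Marker panel whose queries are the simulation's family seed sequences."""
    queries = {m: [rec] for m, rec in truth.marker_seeds.items()}
    nb = truth.config.neighborhood_plan
    if nb is not None and nb.anchor_label in truth.domain_seeds:
        queries[nb.anchor_label] = [truth.domain_seeds[nb.anchor_label]]
    elif "SelD-like" not in queries:
        queries["SelD-like"] = [ProteinRecord("ref_SelD-like", "", "M" * 40)]
    return MarkerPanel(queries=queries, default_criteria=MARKER_CALL_CRITERIA)


def default_study_config(seed: int = 0) -> SimConfig:
    """The study-shaped default: a reference thermoproteales genome among 9
    SelD-like-positive and 3 SelD-like-negative thermoproteales, a
    sulfolobales outgroup carrying SelD-like, Se-trait clades, one planted
    exclusive gene, >= 50 background families, a 10,000 nt neighborhood with
    SirA-like/Prx-like partners, and the SelD-like/acylphosphatase fusion in
    thermoproteales."""
    thermo_pos = tuple(f"TP{i:02d}" for i in range(1, 10))
    thermo_neg = tuple(f"TP{i:02d}" for i in range(10, 13))
    sulfo = tuple(f"SU{i:02d}" for i in range(1, 5))
    methano = tuple(f"MC{i:02d}" for i in range(1, 4))
    halo = tuple(f"HB{i:02d}" for i in range(1, 3))
    return SimConfig(
        seed=seed,
        clades=(
            ("Thermoproteales", thermo_pos + thermo_neg),
            ("Sulfolobales", sulfo),
            ("Methanococcales", methano),
            ("Halobacteriales", halo),
        ),
        n_background_families=50,
        protein_length=(80, 160),
        substitution_rate=0.05,
        trait_plantings=tuple(
            [(g, frozenset({"SelD", "SelA", "SelB", "YbbB"})) for g in methano]
            + [(g, frozenset({"SelD", "YqeB", "YqeC"})) for g in halo]
        ),
        exclusive_gene=(frozenset(thermo_pos), frozenset(thermo_neg)),
        neighborhood_plan=NeighborhoodPlan(
            anchor_label="SelD-like",
            member_labels=("SirA-like", "Prx-like"),
            genomes=frozenset(thermo_pos + sulfo),
            window_nt=10_000,
        ),
        fusion_plan=FusionPlan(
            labels=("SelD-like", "acylphosphatase-like"),
            genomes=frozenset(thermo_pos),
        ),
        reference_genome="TP01",
    )
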