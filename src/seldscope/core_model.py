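"""Domain types and readers/writers for every format the pipeline touches.

Coordinates are 1-based inclusive at every public boundary. Protein sequences
are uppercased on read; selenocysteine ``U`` is accepted and preserved in
storage (scoring maps it to ``C`` downstream).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SeldscopeError",
    "FormatError",
    "ValidationError",
    "ConfigurationError",
    "AMINO_ACIDS",
    "ALLOWED_ALPHABET",
    "ProteinRecord",
    "GeneLocus",
    "Genome",
    "GenomeSet",
    "Msa",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_msa",
    "write_msa",
    "read_genome_dir",
    "write_genome_dir",
    "read_genome_set",
]


class SeldscopeError(Exception):
    """Base class for all package errors."""


class FormatError(SeldscopeError):
    """A file does not conform to its declared format."""


class ValidationError(SeldscopeError):
    """A domain-type invariant is violated."""


class ConfigurationError(SeldscopeError):
    """An analysis was configured inconsistently."""


#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues accepted in stored sequences: the 20 standard letters, the
#: ambiguity code X, and selenocysteine U.
ALLOWED_ALPHABET = frozenset(AMINO_ACIDS + "XU")

GAP = "-"


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence.

    Parameters
    ----------
    protein_id:
        Unique identifier (the FASTA header token before the first whitespace).
    description:
        Remainder of the FASTA header, may be empty.
    sequence:
        Amino-acid string over :data:`ALLOWED_ALPHABET`; uppercased on
        construction.
    genome_id:
        Owning genome, or ``None`` for free-standing queries.
    """

    protein_id: str
    description: str = ""
    sequence: str = ""
    genome_id: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValidationError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(seq) - ALLOWED_ALPHABET
        if bad:
            raise ValidationError(
                f"protein {self.protein_id!r}: illegal residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


_STRANDS = frozenset("+-")


@dataclass(frozen=True)
class GeneLocus:
    """A gene with 1-based inclusive nucleotide coordinates on a contig."""

    gene_id: str
    protein_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    annotation: str = ""
    domain_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain_labels", frozenset(self.domain_labels))
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: require 1 <= start <= end, "
                f"got start={self.start} end={self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """A genome: gene loci plus the protein complement, tagged with a lineage.

    ``lineage`` is ordered from broadest to narrowest clade
    (e.g. ``("Crenarchaeota", "Thermoproteales")``).
    """

    genome_id: str
    lineage: tuple[str, ...] = ()
    loci: list[GeneLocus] = field(default_factory=list)
    proteome: dict[str, ProteinRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lineage = tuple(self.lineage)
        for locus in self.loci:
            if locus.protein_id not in self.proteome:
                raise ValidationError(
                    f"genome {self.genome_id!r}: locus {locus.gene_id!r} references "
                    f"unknown protein {locus.protein_id!r}"
                )

    def sorted_loci(self, contig_id: str | None = None) -> list[GeneLocus]:
        """Loci (optionally restricted to one contig) stably sorted by start."""
        loci = self.loci if contig_id is None else [
            l for l in self.loci if l.contig_id == contig_id
        ]
        return sorted(loci, key=lambda l: l.start)

    def locus(self, gene_id: str) -> GeneLocus:
        for l in self.loci:
            if l.gene_id == gene_id:
                return l
        raise KeyError(f"genome {self.genome_id!r}: no gene {gene_id!r}")

    def domain_labels_for(self, protein_id: str) -> frozenset[str]:
        """Union of domain labels over all loci encoding ``protein_id``."""
        labels: set[str] = set()
        for l in self.loci:
            if l.protein_id == protein_id:
                labels |= l.domain_labels
        return frozenset(labels)

    @property
    def proteins(self) -> list[ProteinRecord]:
        return list(self.proteome.values())


@dataclass
class GenomeSet:
    """A collection of genomes with an index from clade name to genome ids."""

    genomes: dict[str, Genome] = field(default_factory=dict)

    @property
    def clade_index(self) -> dict[str, set[str]]:
        index: dict[str, set[str]] = {}
        for gid, genome in self.genomes.items():
            for clade in genome.lineage:
                index.setdefault(clade, set()).add(gid)
        return index

    def __iter__(self):
        return iter(self.genomes.values())

    def __len__(self) -> int:
        return len(self.genomes)

    def __getitem__(self, genome_id: str) -> Genome:
        return self.genomes[genome_id]

    def add(self, genome: Genome) -> None:
        if genome.genome_id in self.genomes:
            raise ValidationError(f"duplicate genome id {genome.genome_id!r}")
        self.genomes[genome.genome_id] = genome

    def subset(self, genome_ids: Iterable[str]) -> "GenomeSet":
        return GenomeSet({gid: self.genomes[gid] for gid in genome_ids})


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped rows keyed by id."""

    rows: dict[str, str]
    ncol: int = 0

    def __post_init__(self) -> None:
        if self.rows:
            lengths = {len(s) for s in self.rows.values()}
            if len(lengths) > 1:
                ragged = [i for i, s in self.rows.items()
                          if len(s) != len(next(iter(self.rows.values())))]
                raise FormatError(f"ragged alignment rows: {ragged}")
            self.ncol = lengths.pop()

    def ungapped(self, row_id: str) -> str:
        return self.rows[row_id].replace(GAP, "")

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, genome_id: str | None = None) -> list[ProteinRecord]:
    """Read protein records from a FASTA file, preserving file order.

    The header token before the first whitespace becomes ``protein_id``; the
    remainder becomes ``description``. An empty file yields an empty list;
    sequence data before the first header is a :class:`FormatError` naming
    the line number.
    """
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FormatError(
                f"{path}: line {lineno}: sequence data before first FASTA header"
            )
        break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            ProteinRecord(rec.id, desc, str(rec.seq), genome_id=genome_id)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene tables

GENE_TABLE_COLUMNS = (
    "gene_id", "protein_id", "contig_id", "start", "end",
    "strand", "annotation", "domain_labels",
)


def read_gene_table(path: str | Path) -> list[GeneLocus]:
    """Read the 8-column TSV gene table (header required).

    ``domain_labels`` is a semicolon-separated list, possibly empty. Comment
    lines starting with ``#`` before the header are skipped.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        lines = [l for l in fh if not l.startswith("#")]
    reader = csv.reader(lines, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError(f"{path}: empty gene table") from None
    if tuple(header) != GENE_TABLE_COLUMNS:
        raise FormatError(
            f"{path}: bad header {header!r}, expected {list(GENE_TABLE_COLUMNS)}"
        )
    loci = []
    for row in reader:
        if not row:
            continue
        if len(row) != 8:
            raise FormatError(f"{path}: row with {len(row)} fields: {row!r}")
        gene_id, protein_id, contig_id, start, end, strand, ann, labels = row
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise FormatError(
                f"{path}: gene {gene_id!r}: non-integer coordinates {start!r}/{end!r}"
            ) from None
        loci.append(
            GeneLocus(
                gene_id, protein_id, contig_id, start_i, end_i, strand, ann,
                frozenset(x for x in labels.split(";") if x),
            )
        )
    return loci


def write_gene_table(loci: Iterable[GeneLocus], path: str | Path,
                     header_comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GENE_TABLE_COLUMNS)
        for l in loci:
            writer.writerow([
                l.gene_id, l.protein_id, l.contig_id, l.start, l.end,
                l.strand, l.annotation, ";".join(sorted(l.domain_labels)),
            ])


# ---------------------------------------------------------------------------
# Alignments

_MSA_FORMATS = {"aligned-fasta": "fasta", "clustal": "clustal"}


def read_msa(path: str | Path, format: str = "aligned-fasta") -> Msa:
    """Read an MSA from aligned FASTA or Clustal format.

    Ragged rows raise a :class:`FormatError` listing the offending ids.
    """
    if format not in _MSA_FORMATS:
        raise ConfigurationError(
            f"unknown MSA format {format!r}; choose from {sorted(_MSA_FORMATS)}"
        )
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), _MSA_FORMATS[format]):
        rows[rec.id] = str(rec.seq).upper()
    return Msa(rows)


def write_msa(msa: Msa, path: str | Path, format: str = "aligned-fasta") -> None:
    if format not in _MSA_FORMATS:
        raise ConfigurationError(f"unknown MSA format {format!r}")
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in msa.rows.items()]
    if format == "clustal":
        from Bio import AlignIO
        from Bio.Align import MultipleSeqAlignment

        AlignIO.write(MultipleSeqAlignment(recs), str(path), "clustal")
    else:
        SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Genome directories

PROTEINS_FILE = "proteins.faa"
GENES_FILE = "genes.tsv"


def read_genome_dir(path: str | Path, genome_id: str | None = None,
                    lineage: Sequence[str] = ()) -> Genome:
    """Read one genome from a directory holding ``proteins.faa`` + ``genes.tsv``."""
    path = Path(path)
    gid = genome_id or path.name
    records = read_fasta(path / PROTEINS_FILE, genome_id=gid)
    loci = read_gene_table(path / GENES_FILE)
    return Genome(gid, tuple(lineage), loci, {r.protein_id: r for r in records})


def write_genome_dir(genome: Genome, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_fasta(genome.proteins, path / PROTEINS_FILE)
    write_gene_table(genome.loci, path / GENES_FILE)


def read_genome_set(root: str | Path, taxonomy: str | Path | None = None) -> GenomeSet:
    """Read every genome subdirectory under ``root``.

    ``taxonomy`` is an optional two-column TSV (genome_id, semicolon-separated
    lineage) assigning clades; genomes absent from it get an empty lineage.
    """
    root = Path(root)
    lineages: dict[str, tuple[str, ...]] = {}
    if taxonomy is not None:
        with open(taxonomy, newline="") as fh:
            for row in csv.reader(
                (l for l in fh if not l.startswith("#")), delimiter="\t"
            ):
                if row:
                    lineages[row[0]] = tuple(x for x in row[1].split(";") if x)
    gs = GenomeSet()
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        if (sub / PROTEINS_FILE).exists():
            gs.add(read_genome_dir(sub, lineage=lineages.get(sub.name, ())))
    return gs


def write_genome_set(gs: GenomeSet, root: str | Path) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    with open(root / "taxonomy.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for gid in sorted(gs.genomes):
            writer.writerow([gid, ";".join(gs.genomes[gid].lineage)])
    for gid in sorted(gs.genomes):
        write_genome_dir(gs.genomes[gid], root / gid)
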