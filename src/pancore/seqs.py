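"""Genome/gene containers and FASTA interchange.

A :class:`GenomeSet` is the common currency of the pipeline: an ordered
collection of genomes, each holding genes with paired nucleotide and
protein sequences.  FASTA headers use the ``genomeID|geneID`` convention
so that files round-trip losslessly through :func:`write_genome_fastas`
and :func:`read_genome_fastas`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"


def translate(nt: str) -> str:
    """Conceptual frame-1 translation under the standard code."""
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    return str(Seq(nt).translate())


@dataclass(frozen=True)
class Gene:
    """A single CDS with its nucleotide and protein sequence."""

    id: str
    nt: str
    aa: str

    def __post_init__(self):
        if not self.nt or not self.aa:
            raise ValueError(f"gene {self.id}: empty sequence")

    @classmethod
    def from_nt(cls, gene_id: str, nt: str) -> "Gene":
        return cls(gene_id, nt, translate(nt))


@dataclass
class Genome:
    id: str
    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GenomeSet:
    """Ordered set of genomes with globally unique gene identifiers."""

    genomes: list[Genome] = field(default_factory=list)

    def __post_init__(self):
        self._check_unique()

    def _check_unique(self):
        seen: set[str] = set()
        for genome in self.genomes:
            for gene in genome.genes:
                if gene.id in seen:
                    raise ValueError(f"duplicate gene id {gene.id!r}")
                seen.add(gene.id)

    def __iter__(self) -> Iterator[Genome]:
        return iter(self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)

    @property
    def genome_ids(self) -> list[str]:
        return [g.id for g in self.genomes]

    def genome_of(self) -> dict[str, str]:
        """gene id -> genome id."""
        return {gene.id: genome.id for genome in self.genomes for gene in genome.genes}

    def genes_by_id(self) -> dict[str, Gene]:
        return {gene.id: gene for genome in self.genomes for gene in genome.genes}

    def gene_counts(self) -> dict[str, int]:
        return {genome.id: len(genome.genes) for genome in self.genomes}

    def subset(self, genome_ids) -> "GenomeSet":
        wanted = set(genome_ids)
        return GenomeSet([g for g in self.genomes if g.id in wanted])


def _header(genome_id: str, gene_id: str) -> str:
    if "|" in genome_id:
        raise ValueError(f"genome id {genome_id!r} contains '|'")
    return f"{genome_id}|{gene_id}"


def parse_header(header: str) -> tuple[str, str]:
    """Split a ``genomeID|geneID`` FASTA header."""
    genome_id, sep, gene_id = header.partition("|")
    if not sep or not gene_id:
        raise ValueError(f"malformed header {header!r}; expected 'genome|gene'")
    return genome_id, gene_id


def write_genome_fastas(
    genomes: GenomeSet, directory, overwrite: bool = False
) -> list[Path]:
    """Write one protein (.faa) and one nucleotide (.fna) FASTA per genome.

    Refuses to clobber existing files unless ``overwrite`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for genome in genomes:
        if not genome.genes:
            warnings.warn(f"genome {genome.id} has no genes; writing empty FASTA")
        for ext, attr in ((".fna", "nt"), (".faa", "aa")):
            path = directory / f"{genome.id}{ext}"
            if path.exists() and not overwrite:
                raise FileExistsError(f"{path} exists (pass overwrite=True)")
            records = [
                SeqRecord(Seq(getattr(gene, attr)), id=_header(genome.id, gene.id), description="")
                for gene in genome.genes
            ]
            SeqIO.write(records, path, "fasta")
            paths.append(path)
    return paths


def read_genome_fastas(directory) -> GenomeSet:
    """Read a directory of paired ``.fna``/``.faa`` files back into a GenomeSet."""
    directory = Path(directory)
    fna_paths = sorted(directory.glob("*.fna"))
    if not fna_paths:
        raise FileNotFoundError(f"no .fna files under {directory}")
    genomes = []
    for fna in fna_paths:
        faa = fna.with_suffix(".faa")
        if not faa.exists():
            raise FileNotFoundError(f"missing protein file {faa}")
        aa_by_gene: dict[str, str] = {}
        for rec in SeqIO.parse(str(faa), "fasta"):
            _, gene_id = parse_header(rec.id)
            aa_by_gene[gene_id] = str(rec.seq)
        genes = []
        genome_id = fna.stem
        for rec in SeqIO.parse(str(fna), "fasta"):
            gid, gene_id = parse_header(rec.id)
            if gid != genome_id:
                raise ValueError(f"header genome {gid!r} does not match file {fna.name}")
            genes.append(Gene(gene_id, str(rec.seq), aa_by_gene[gene_id]))
        genomes.append(Genome(genome_id, genes))
    return GenomeSet(genomes)
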