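"""Clade-structured pan-genome simulator with recoverable planted truth.

The generative model is deliberately simple so that every downstream
stage has an exact oracle:

* each gene family has a random ancestral CDS (sense codons only,
  length >= 300 nt, multiple of 3);
* each clade carrying the family gets a clade ancestor = ancestor
  mutated at ``between_clade_mut_rate``;
* each genome's copy = clade ancestor mutated at
  ``within_clade_mut_rate`` (no indels, so alignments are exact);
* clade-diagnostic positions (ecoSNPs) are planted by overwriting
  clade-ancestor columns, and the truth records *all* diagnostic
  columns of core families measured at the clade-ancestor level;
* HGT families are planted with per-clade presence fractions inside
  the 30-70% band, while every other accessory family is placed so
  that at least one clade falls outside the band;
* outlier genomes are clones of a source genome padded with duplicated
  core genes until their gene count is far outside the +/-2 sigma band.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawns, so identical configs give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqs import NUCLEOTIDES, Gene, Genome, GenomeSet, translate

_SENSE_CODONS = [
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if translate(a + b + c) != "*"
]

CLASS_CORE = "core"
CLASS_SOFTCORE = "softcore"
CLASS_SHELL = "shell"
CLASS_CLOUD = "cloud"


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    n_clades: int = 2
    genomes_per_clade: int = 10
    n_core: int = 200
    n_softcore: int = 40
    n_shell: int = 100
    n_cloud: int = 50
    n_hgt: int = 10
    gene_length_mean: float = 600.0
    gene_length_sd: float = 150.0
    within_clade_mut_rate: float = 0.0
    between_clade_mut_rate: float = 0.05
    n_ecosnp: int = 3
    n_ecosnp_families: int = 5
    n_outlier_genomes: int = 1
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_core, self.n_softcore, self.n_shell, self.n_cloud,
            self.n_hgt, self.n_ecosnp, self.n_ecosnp_families,
            self.n_outlier_genomes,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        if self.n_clades < 1 or self.genomes_per_clade < 1:
            raise ConfigurationError("need at least one clade and one genome per clade")
        for rate in (self.within_clade_mut_rate, self.between_clade_mut_rate):
            if not 0.0 <= rate < 0.75:
                raise ConfigurationError(f"mutation rate {rate} outside [0, 0.75)")
        if self.between_clade_mut_rate < self.within_clade_mut_rate:
            raise ConfigurationError("between-clade rate must be >= within-clade rate")
        n = self.n_clades * self.genomes_per_clade
        if self.n_cloud > 0 and n < 3:
            raise ConfigurationError("cloud families need >= 3 genomes")
        if self.n_shell > 0 and self._softcore_min(n) - 1 < 3:
            raise ConfigurationError("shell occupancy band empty for this genome count")
        if self.n_softcore > 0 and self._softcore_min(n) > n - 1:
            raise ConfigurationError(
                "softcore band empty: need ceil(0.95*n) <= n-1 (n >= 20)"
            )
        if self.n_ecosnp > 0 and self.n_ecosnp_families > self.n_core:
            raise ConfigurationError("more ecoSNP families requested than core families")
        if self.n_ecosnp > 0 and self.n_clades < 2:
            raise ConfigurationError("ecoSNPs need >= 2 clades")
        if self.n_hgt > 0 and self.genomes_per_clade < 2:
            raise ConfigurationError("HGT planting needs >= 2 genomes per clade")

    @staticmethod
    def _softcore_min(n: int) -> int:
        return math.ceil(0.95 * n)

    @property
    def n_genomes(self) -> int:
        return self.n_clades * self.genomes_per_clade + self.n_outlier_genomes


@dataclass(frozen=True)
class EcoSnpSite:
    """A clade-diagnostic dimorphic column of a core family."""

    family: str
    column: int  # 0-based position in the family alignment
    base_by_clade: tuple[tuple[str, str], ...]  # (clade, base), sorted by clade

    def bases(self) -> dict[str, str]:
        return dict(self.base_by_clade)


@dataclass
class TruthSet:
    clade_of: dict[str, str]
    family_class: dict[str, str]
    hgt_families: set[str]
    ecosnp_positions: list[EcoSnpSite]
    outlier_genomes: set[str]
    gene_family: dict[str, str] = field(default_factory=dict)

    def families_of_class(self, cls: str) -> set[str]:
        return {f for f, c in self.family_class.items() if c == cls}


def mutate_sequence(seq: str, rate: float, seed) -> str:
    """Independently substitute each site with probability ``rate``.

    A substituted site gets a uniformly chosen *different* base, so the
    realized mismatch fraction is binomial(len, rate).
    """
    if not 0.0 <= rate < 0.75:
        raise ValueError(f"rate {rate} outside [0, 0.75)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rate == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = np.flatnonzero(hit)
    if idx.size:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        # offset 1..3 from the current base's alphabet position = a different base
        pos = np.searchsorted(bases, arr[idx])
        arr[idx] = bases[(pos + rng.integers(1, 4, size=idx.size)) % 4]
    return arr.tobytes().decode("ascii")


def _random_cds(rng: np.random.Generator, mean: float, sd: float) -> str:
    length = max(300, int(round(rng.normal(mean, sd))))
    length -= length % 3
    codons = rng.integers(0, len(_SENSE_CODONS), size=length // 3)
    return "".join(_SENSE_CODONS[i] for i in codons)


def _in_band(count: int, size: int, low=0.30, high=0.70) -> bool:
    return low <= count / size <= high


def _accessory_placement(
    rng: np.random.Generator, occupancy: int, clade_sizes: list[int]
) -> list[int]:
    """Per-clade member counts for a non-HGT accessory family.

    Rejection-sampled so that at least one clade's presence fraction
    falls outside the 30-70% HGT band (keeps the planted HGT set the
    unique truth for the screen).  Falls back to cramming members into
    as few clades as possible, which always breaks the band.
    """
    n = sum(clade_sizes)
    for _ in range(50):
        members = rng.choice(n, size=occupancy, replace=False)
        counts = _counts_per_clade(members, clade_sizes)
        if not all(_in_band(c, s) for c, s in zip(counts, clade_sizes)):
            return counts
    counts = [0] * len(clade_sizes)
    remaining = occupancy
    for k, size in enumerate(clade_sizes):
        take = min(size, remaining)
        counts[k] = take
        remaining -= take
    return counts


def _counts_per_clade(member_idx, clade_sizes) -> list[int]:
    bounds = np.cumsum([0] + list(clade_sizes))
    return [
        int(np.sum((member_idx >= lo) & (member_idx < hi)))
        for lo, hi in zip(bounds[:-1], bounds[1:])
    ]


def _scan_diagnostic_columns(
    family: str, clade_seqs: dict[str, str]
) -> list[EcoSnpSite]:
    """All columns where the clade ancestors are dimorphic and each clade
    is monomorphic (automatic at ancestor level); the planted truth."""
    clades = sorted(clade_seqs)
    if len(clades) < 2:
        return []
    length = len(next(iter(clade_seqs.values())))
    sites = []
    for col in range(length):
        bases = {c: clade_seqs[c][col] for c in clades}
        if len(set(bases.values())) == 2:
            sites.append(EcoSnpSite(family, col, tuple(sorted(bases.items()))))
    return sites


def simulate_pangenome(config: SimulationConfig) -> tuple[GenomeSet, TruthSet]:
    """Generate a GenomeSet and the exact TruthSet describing it."""
    ss = np.random.SeedSequence(config.seed)
    (seq_ss, occ_ss, clade_ss, eco_ss, within_ss, out_ss) = ss.spawn(6)
    seq_rng = np.random.default_rng(seq_ss)
    occ_rng = np.random.default_rng(occ_ss)
    clade_rng = np.random.default_rng(clade_ss)
    eco_rng = np.random.default_rng(eco_ss)
    out_rng = np.random.default_rng(out_ss)

    n_clades = config.n_clades
    clade_names = [f"clade{k}" for k in range(n_clades)]
    clade_sizes = [config.genomes_per_clade] * n_clades
    n = sum(clade_sizes)
    softcore_min = config._softcore_min(n)

    genome_ids = [
        f"C{k}G{g:02d}" for k in range(n_clades) for g in range(config.genomes_per_clade)
    ]
    clade_of = {
        gid: clade_names[i // config.genomes_per_clade]
        for i, gid in enumerate(genome_ids)
    }

    # ---- family roster: (name, class hint, per-clade member counts) ----
    families: list[tuple[str, str, list[int]]] = []

    def _band_int(rng, lo_f, hi_f, size):
        lo, hi = math.ceil(lo_f * size), math.floor(hi_f * size)
        return int(rng.integers(lo, hi + 1))

    idx = 0
    for _ in range(config.n_core):
        families.append((f"F{idx:05d}", CLASS_CORE, list(clade_sizes)))
        idx += 1
    for _ in range(config.n_softcore):
        occ = int(occ_rng.integers(softcore_min, n))  # [softcore_min, n-1]
        families.append((f"F{idx:05d}", CLASS_SOFTCORE,
                         _accessory_placement(occ_rng, occ, clade_sizes)))
        idx += 1
    for _ in range(config.n_shell):
        occ = int(occ_rng.integers(3, softcore_min))  # [3, softcore_min-1]
        families.append((f"F{idx:05d}", CLASS_SHELL,
                         _accessory_placement(occ_rng, occ, clade_sizes)))
        idx += 1
    for _ in range(config.n_cloud):
        occ = int(occ_rng.integers(1, 3))  # 1 or 2
        families.append((f"F{idx:05d}", CLASS_CLOUD,
                         _accessory_placement(occ_rng, occ, clade_sizes)))
        idx += 1
    hgt_families: set[str] = set()
    for _ in range(config.n_hgt):
        counts = []
        for size in clade_sizes:
            frac = occ_rng.uniform(0.30, 0.70)
            c = int(np.clip(round(frac * size),
                            math.ceil(0.30 * size), math.floor(0.70 * size)))
            counts.append(max(1, c))
        families.append((f"F{idx:05d}", "hgt", counts))
        hgt_families.add(f"F{idx:05d}")
        idx += 1

    # ---- sequences: ancestor -> clade ancestors ----
    ancestors = {name: _random_cds(seq_rng, config.gene_length_mean,
                                   config.gene_length_sd)
                 for name, _, _ in families}
    clade_seq: dict[str, dict[str, str]] = {}
    for name, _, counts in families:
        per_clade = {}
        for k, cnt in enumerate(counts):
            if cnt > 0:
                per_clade[clade_names[k]] = mutate_sequence(
                    ancestors[name], config.between_clade_mut_rate, clade_rng)
        clade_seq[name] = per_clade

    # ---- plant ecoSNPs on flagged core families' clade ancestors ----
    core_names = [name for name, cls, _ in families if cls == CLASS_CORE]
    if config.n_ecosnp > 0 and config.n_ecosnp_families > 0:
        flagged = list(eco_rng.choice(core_names,
                                      size=config.n_ecosnp_families, replace=False))
        for fam in flagged:
            length = len(ancestors[fam])
            if config.n_ecosnp > length:
                raise ConfigurationError(
                    f"family {fam}: {config.n_ecosnp} ecoSNP columns requested "
                    f"but only {length} sites available")
            cols = eco_rng.choice(length, size=config.n_ecosnp, replace=False)
            for col in sorted(int(c) for c in cols):
                focal = clade_names[int(eco_rng.integers(n_clades))]
                x, y = eco_rng.choice(list(NUCLEOTIDES), size=2, replace=False)
                for cname in clade_names:
                    s = clade_seq[fam][cname]
                    base = x if cname == focal else y
                    clade_seq[fam][cname] = s[:col] + base + s[col + 1:]

    # truth = every diagnostic column of every core family
    ecosnp_positions: list[EcoSnpSite] = []
    for fam in core_names:
        ecosnp_positions.extend(_scan_diagnostic_columns(fam, clade_seq[fam]))

    # ---- realize genomes ----
    genes_per_genome: dict[str, list[Gene]] = {gid: [] for gid in genome_ids}
    gene_family: dict[str, str] = {}
    within_rng = np.random.default_rng(within_ss)
    clade_members = {
        clade_names[k]: genome_ids[k * config.genomes_per_clade:
                                   (k + 1) * config.genomes_per_clade]
        for k in range(n_clades)
    }
    for name, _, counts in families:
        for k, cnt in enumerate(counts):
            if cnt == 0:
                continue
            cname = clade_names[k]
            members = clade_members[cname]
            chosen = (members if cnt == len(members) else
                      sorted(occ_rng.choice(members, size=cnt, replace=False)))
            for gid in chosen:
                nt = mutate_sequence(clade_seq[name][cname],
                                     config.within_clade_mut_rate, within_rng)
                gene_id = f"{gid}_{name}_c0"
                genes_per_genome[gid].append(Gene.from_nt(gene_id, nt))
                gene_family[gene_id] = name

    genomes = [Genome(gid, genes_per_genome[gid]) for gid in genome_ids]

    # ---- outlier genomes: clone + duplicate core genes to ~2x mean count ----
    outlier_ids: set[str] = set()
    if config.n_outlier_genomes:
        mean_count = float(np.mean([len(g.genes) for g in genomes]))
        for j in range(config.n_outlier_genomes):
            src = genomes[int(out_rng.integers(len(genomes)))]
            oid = f"OUT{j}"
            target = int(round(2.0 * mean_count)) + 20 * j
            genes: list[Gene] = []
            copy_no: dict[str, int] = {}
            pool = [g for g in src.genes]
            core_pool = [g for g in src.genes
                         if gene_family[g.id].startswith("F") and
                         gene_family[g.id] in set(core_names)]
            i = 0
            while len(genes) < target:
                template = pool[i] if i < len(pool) else core_pool[(i - len(pool)) % len(core_pool)]
                fam = gene_family[template.id]
                c = copy_no.get(fam, 0)
                copy_no[fam] = c + 1
                gene_id = f"{oid}_{fam}_c{c}"
                genes.append(Gene(gene_id, template.nt, template.aa))
                gene_family[gene_id] = fam
                i += 1
            genomes.append(Genome(oid, genes))
            outlier_ids.add(oid)
            clade_of[oid] = clade_of[src.id]

    # family classes over non-outlier genomes, per the partition definitions
    family_class = {}
    for name, _, counts in families:
        occ = int(sum(counts))
        if occ == n:
            family_class[name] = CLASS_CORE
        elif occ >= softcore_min:
            family_class[name] = CLASS_SOFTCORE
        elif occ <= 2:
            family_class[name] = CLASS_CLOUD
        else:
            family_class[name] = CLASS_SHELL

    truth = TruthSet(
        clade_of=clade_of,
        family_class=family_class,
        hgt_families=hgt_families,
        ecosnp_positions=ecosnp_positions,
        outlier_genomes=outlier_ids,
        gene_family=gene_family,
    )
    return GenomeSet(genomes), truth


def plant_ecosnps(genomes: GenomeSet, truth: TruthSet,
                  config: SimulationConfig) -> tuple[GenomeSet, TruthSet]:
    """Overwrite planted diagnostic columns directly in realized genomes.

    :func:`simulate_pangenome` already plants ecoSNPs at the clade-ancestor
    level; this standalone operation exists for noise-free post-hoc
    planting on an existing GenomeSet (e.g. to rescue columns destroyed
    by within-clade noise).  All genomes of the focal clade receive one
    base, all others a different base, at every recorded site.
    """
    if config.n_ecosnp == 0 or not truth.ecosnp_positions:
        return genomes, truth
    if len({c for c in truth.clade_of.values()}) < 2:
        raise ValueError("ecoSNP planting needs >= 2 clades")
    sites_by_family: dict[str, list[EcoSnpSite]] = {}
    for site in truth.ecosnp_positions:
        sites_by_family.setdefault(site.family, []).append(site)
    new_genomes = []
    for genome in genomes:
        clade = truth.clade_of[genome.id]
        genes = []
        for gene in genome.genes:
            fam = truth.gene_family[gene.id]
            nt = gene.nt
            for site in sites_by_family.get(fam, ()):
                if site.column >= len(nt):
                    raise ValueError(
                        f"ecoSNP column {site.column} beyond gene {gene.id}")
                nt = nt[:site.column] + site.bases()[clade] + nt[site.column + 1:]
            genes.append(Gene.from_nt(gene.id, nt) if nt != gene.nt else gene)
        new_genomes.append(Genome(genome.id, genes))
    return GenomeSet(new_genomes), truth


def write_truth_tables(truth: TruthSet, directory) -> dict[str, Path]:
    """Emit the planted truth as plain TSV tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = directory / "clades.tsv"
    with open(p, "w") as fh:
        fh.write("genome\tclade\n")
        for gid in sorted(truth.clade_of):
            fh.write(f"{gid}\t{truth.clade_of[gid]}\n")
    paths["clades"] = p

    p = directory / "family_class.tsv"
    with open(p, "w") as fh:
        fh.write("family\tclass\n")
        for fam in sorted(truth.family_class):
            fh.write(f"{fam}\t{truth.family_class[fam]}\n")
    paths["family_class"] = p

    p = directory / "hgt.tsv"
    with open(p, "w") as fh:
        fh.write("family\n")
        for fam in sorted(truth.hgt_families):
            fh.write(f"{fam}\n")
    paths["hgt"] = p

    p = directory / "ecosnps.tsv"
    with open(p, "w") as fh:
        fh.write("family\tcolumn\tclade\tbase\n")
        for site in truth.ecosnp_positions:
            for clade, base in site.base_by_clade:
                fh.write(f"{site.family}\t{site.column}\t{clade}\t{base}\n")
    paths["ecosnps"] = p

    p = directory / "outliers.tsv"
    with open(p, "w") as fh:
        fh.write("genome\n")
        for gid in sorted(truth.outlier_genomes):
            fh.write(f"{gid}\n")
    paths["outliers"] = p
    return paths


def read_clade_table(path) -> dict[str, str]:
    """Read a two-column genome->clade TSV (with or without header)."""
    clades = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[0] == "genome":
                continue
            if len(fields) < 2:
                raise ValueError(f"malformed clade line {line!r}")
            clades[fields[0]] = fields[1]
    return clades
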