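"""End-to-end orchestration: simulate/read -> filter -> cluster -> partition
-> rarefy -> clades -> gene trees -> SNPs -> HGT -> enrichment.

Every stage communicates through flat TSV/FASTA/Newick artifacts in the
output directory, so any stage can be rerun from files.  The manifest
records the seed, parameters and a checksum per artifact; rerunning the
same config reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import enrichment as enr
from . import identity as ident
from . import orthologs, pangenome, phylo, snps, synthetic
from .seqs import GenomeSet, read_genome_fastas, write_genome_fastas

log = logging.getLogger("pancore")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    simulate: synthetic.SimulationConfig | None = None
    input_dir: Path | None = None
    clades_path: Path | None = None
    annotation_path: Path | None = None
    e_max: float = 1e-5
    cov_min: float = 0.75
    inflation: float = 1.5
    k_sigma: float = 2.0
    hgt_low: float = 0.30
    hgt_high: float = 0.70
    closed_slope: float = 5.0
    n_permutations: int | None = None  # default: number of kept genomes
    n_clades_cut: int | None = None
    bootstrap_replicates: int = 100
    n_random_trees: int = 10
    lower_pct: float = 5.0
    upper_pct: float = 95.0
    run_genetrees: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if self.simulate is None and self.input_dir is None:
            raise ValueError("config needs either a simulate block or input_dir")
        if not 0 <= self.hgt_low <= self.hgt_high <= 1:
            raise ValueError("HGT band must satisfy 0 <= low <= high <= 1")
        if self.e_max <= 0 or not 0 <= self.cov_min <= 1 or self.inflation <= 1:
            raise ValueError("threshold out of documented range")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        config = cls(
            simulate=synthetic.SimulationConfig(**sim) if sim else None,
            **{k: v for k, v in raw.items()},
        )
        return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(level: str):
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S%z"))
    log.handlers[:] = [handler]
    log.setLevel(level.upper())


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    _setup_logging(config.log_level)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                else str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }
    artifacts: dict[str, Path] = {}

    def record(stage: str, **paths: Path):
        entry = {}
        for name, p in paths.items():
            p = Path(p)
            entry[name] = {"path": str(p)}
            if p.is_file():
                entry[name]["sha256"] = _sha256(p)
        manifest["stages"][stage] = entry
        artifacts.update(paths)

    def fail(stage: str, exc: Exception):
        failed_marker.write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc

    truth = None
    clades: dict[str, str] | None = None

    # ------------------------------------------------------------ input
    stage = "input"
    try:
        if config.simulate is not None:
            log.info("simulating pan-genome (seed=%d)", config.simulate.seed)
            genomes, truth = synthetic.simulate_pangenome(config.simulate)
            fasta_dir = outdir / "genomes"
            write_genome_fastas(genomes, fasta_dir, overwrite=True)
            truth_paths = synthetic.write_truth_tables(truth, outdir / "truth")
            clades = dict(truth.clade_of)
            record(stage, fasta_dir=fasta_dir, **truth_paths)
        else:
            log.info("reading genomes from %s", config.input_dir)
            genomes = read_genome_fastas(config.input_dir)
            if config.clades_path:
                clades = synthetic.read_clade_table(config.clades_path)
            record(stage)
    except PipelineError:
        raise
    except Exception as exc:
        fail(stage, exc)

    # ----------------------------------------------------------- filter
    stage = "filter"
    try:
        kept, excluded = pangenome.quality_filter(genomes.gene_counts(),
                                                  k_sigma=config.k_sigma)
        log.info("quality filter kept %d, excluded %d genomes",
                 len(kept), len(excluded))
        p = outdir / "quality_filter.tsv"
        with open(p, "w") as fh:
            fh.write("genome\tgene_count\tstatus\n")
            counts = genomes.gene_counts()
            for g in genomes.genome_ids:
                status = "kept" if g in kept else "excluded"
                fh.write(f"{g}\t{counts[g]}\t{status}\n")
        genomes = genomes.subset(kept)
        record(stage, table=p)
    except Exception as exc:
        fail(stage, exc)

    # ---------------------------------------------------------- cluster
    stage = "cluster"
    try:
        log.info("building similarity graph (%d genes)",
                 sum(len(g.genes) for g in genomes))
        graph = orthologs.build_similarity_graph(
            genomes, e_max=config.e_max, cov_min=config.cov_min)
        clusters = orthologs.mcl_cluster(graph, inflation=config.inflation)
        log.info("MCL produced %d clusters", len(clusters))
        p = orthologs.write_clusters_tsv(clusters, outdir / "clusters.tsv")
        record(stage, clusters=p)
    except Exception as exc:
        fail(stage, exc)

    # ----------------------------------------------------------- matrix
    stage = "matrix"
    try:
        matrix = pangenome.build_presence_matrix(clusters, genomes)
        p = pangenome.write_matrix_tsv(matrix, outdir / "matrix.tsv")
        record(stage, matrix=p)
    except Exception as exc:
        fail(stage, exc)

    # -------------------------------------------------------- partition
    stage = "partition"
    try:
        report = pangenome.partition_pangenome(matrix)
        sizes = report.sizes
        log.info("partition: %s", sizes)
        p = pangenome.write_partition_tsv(report, outdir / "partition.tsv")
        manifest["partition_sizes"] = sizes
        record(stage, partition=p)
    except Exception as exc:
        fail(stage, exc)

    # ----------------------------------------------------------- rarefy
    stage = "rarefy"
    try:
        n_perm = config.n_permutations or matrix.n_genomes
        curves = pangenome.rarefaction_curves(matrix, n_perm, seed=config.seed)
        call, slope = pangenome.classify_openness(
            curves, closed_slope=config.closed_slope)
        log.info("pan-genome is %s (tail slope %.2f)", call, slope)
        p = pangenome.write_rarefaction_tsv(curves, outdir / "rarefaction.tsv")
        manifest["openness"] = {"call": call, "tail_slope": slope}
        record(stage, curves=p)
    except Exception as exc:
        fail(stage, exc)

    # ----------------------------------------------------------- clades
    stage = "clades"
    try:
        id_matrix = ident.average_identity_matrix(clusters, graph,
                                                  genomes.genome_ids)
        dist = ident.gower_distance(id_matrix)
        dendro = ident.hierarchical_cluster(dist)
        k = config.n_clades_cut
        if k is None and config.simulate is not None:
            k = config.simulate.n_clades
        inferred = ident.extract_clades(dendro, k) if k else {}
        p_id = ident.write_matrix(id_matrix, outdir / "identity.tsv")
        p_gd = ident.write_matrix(dist, outdir / "gower.tsv")
        p_nwk = outdir / "dendrogram.nwk"
        p_nwk.write_text(dendro.to_newick() + "\n")
        p_cl = outdir / "clades_inferred.tsv"
        with open(p_cl, "w") as fh:
            fh.write("genome\tclade\n")
            for g in sorted(inferred):
                fh.write(f"{g}\t{inferred[g]}\n")
        if clades is None and inferred:
            clades = inferred
        record(stage, identity=p_id, gower=p_gd, dendrogram=p_nwk,
               clades=p_cl)
    except Exception as exc:
        fail(stage, exc)

    # -------------------------------------------- core MSAs (shared below)
    stage = "msa"
    try:
        partition_classes = report.cluster_class
        core_ids = sorted(partition_classes[partition_classes == "core"].index)
        genes = genomes.genes_by_id()
        core_msas: dict[str, phylo.MSA] = {}
        msa_dir = outdir / "core_msas"
        msa_dir.mkdir(exist_ok=True)
        by_cluster = {c.id: c for c in clusters}
        for cid in core_ids:
            per_genome: dict[str, str] = {}
            for gene in sorted(by_cluster[cid].members):
                genome = clusters.genome_of[gene]
                per_genome.setdefault(genome, genes[gene].nt)  # first paralog
            msa = phylo.center_star_align(sorted(per_genome.items()),
                                          cluster_id=cid)
            core_msas[cid] = msa
            phylo.write_msa_fasta(msa, msa_dir / f"{cid}.fasta")
        log.info("aligned %d core families", len(core_msas))
        manifest["stages"][stage] = {"msa_dir": {"path": str(msa_dir)}}
    except Exception as exc:
        fail(stage, exc)

    # ------------------------------------------------------------- snps
    stage = "snps"
    try:
        snp_reports: dict[str, snps.SNPReport] = {}
        for cid, msa in core_msas.items():
            profile = snps.build_consensus(msa)
            snp_reports[cid] = snps.call_snps(msa, profile, gene=cid)
        p_snp = snps.write_snp_report_tsv(list(snp_reports.values()),
                                          outdir / "snp_report.tsv")
        paths = {"snp_report": p_snp}
        if clades:
            eco = snps.detect_ecosnps_many(core_msas, clades)
            paths["ecosnps"] = snps.write_ecosnp_tsv(eco,
                                                     outdir / "ecosnps.tsv")
            log.info("detected %d ecoSNP columns", len(eco.calls))
        record(stage, **paths)
    except Exception as exc:
        fail(stage, exc)

    # -------------------------------------------------------- gene trees
    if config.run_genetrees:
        stage = "genetrees"
        try:
            reference = phylo.Tree.from_newick(
                (outdir / "dendrogram.nwk").read_text())
            nodal = phylo.gene_tree_screen(
                core_msas, reference,
                n_random=config.n_random_trees, seed=config.seed,
                lower_pct=config.lower_pct, upper_pct=config.upper_pct,
                snp_reports=snp_reports)
            p = phylo.write_nodal_report_tsv(nodal, outdir / "nodal_report.tsv")
            tree_dir = outdir / "gene_trees"
            tree_dir.mkdir(exist_ok=True)
            if config.bootstrap_replicates > 0:
                for cid, msa in core_msas.items():
                    tree = phylo.bootstrap_support(
                        msa, n_replicates=config.bootstrap_replicates,
                        seed=config.seed)
                    (tree_dir / f"{cid}.nwk").write_text(tree.to_newick() + "\n")
            else:
                for cid, msa in core_msas.items():
                    tree = phylo.nj_tree(phylo.jc_distance_matrix(msa))
                    (tree_dir / f"{cid}.nwk").write_text(tree.to_newick() + "\n")
            manifest["nodal"] = {
                "lower_cut": nodal.lower_cut, "upper_cut": nodal.upper_cut,
                "lower_tail": nodal.lower_tail, "upper_tail": nodal.upper_tail,
            }
            record(stage, nodal_report=p)
        except Exception as exc:
            fail(stage, exc)

    # -------------------------------------------------------------- hgt
    stage = "hgt"
    try:
        if clades:
            kept_clades = {g: clades[g] for g in matrix.genome_ids}
            candidates = pangenome.hgt_screen(matrix, kept_clades,
                                              low=config.hgt_low,
                                              high=config.hgt_high)
            p = outdir / "hgt.tsv"
            candidates.to_csv(p, sep="\t", index_label="cluster")
            log.info("HGT screen: %d candidate clusters", len(candidates))
            record(stage, hgt=p)
        else:
            log.info("no clade labels; HGT screen skipped")
    except Exception as exc:
        fail(stage, exc)

    # ----------------------------------------------------------- enrich
    stage = "enrich"
    try:
        if config.annotation_path:
            annotation = enr.read_annotation_tsv(config.annotation_path)
            membership = clusters.membership()
            core_set = report.clusters_of("core")
            soft_set = report.clusters_of("softcore")
            gene_sets = {
                "core": {g for g, c in membership.items() if c in core_set},
                "softcore": {g for g, c in membership.items() if c in soft_set},
                "pan": set(membership),
            }
            counts = enr.category_counts_from_annotation(
                annotation, gene_sets["core"], gene_sets["softcore"],
                gene_sets["pan"])
            table = enr.fold_increase_table(counts)
            p = enr.write_enrichment_tsv(table, outdir / "enrichment.tsv")
            record(stage, enrichment=p)
    except Exception as exc:
        fail(stage, exc)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    log.info("run complete; manifest at %s", manifest_path)
    return manifest
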