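# pancore

Pan-/core-genome evolutionary analysis for bacterial genome sets, with a
built-in simulator that plants recoverable ground truth so every stage
is testable offline.

Stages (each a module, each re-runnable from flat text artifacts):

* **synthetic** — clade-structured pan-genome simulator: configurable
  core/softcore/shell/cloud occupancy spectrum, within/between-clade
  divergence, planted clade-diagnostic SNP columns (ecoSNPs), planted
  30–70 %-presence HGT families, and planted gene-count outlier genomes,
  all recorded in a `TruthSet`.
* **orthologs** — protein similarity graph (local alignment under
  BLOSUM62 11/1, Karlin–Altschul E-values, E < 1e-5 and ≥ 75 % coverage
  in both directions) clustered into families with Markov clustering
  (inflation 1.5).
* **pangenome** — copy-count presence matrix, ±2σ gene-count quality
  filter, core / softcore (≥ 95 %) / shell / cloud (≤ 2) partitioning,
  randomized rarefaction with an open/closed tail-slope call,
  clade-specific genes and expansions, and the 30–70 % HGT screen.
* **identity** — average per-genome-pair percent identity over shared
  clusters, Gower distances, deterministic agglomerative clustering
  (single/complete/average) with Newick export and k-clade cuts.
* **phylo** — center-star nucleotide MSA, Jukes–Cantor distances with
  pairwise deletion, neighbor joining, bootstrap supports, nodal
  (path-length RMSD) tree comparison with a random-topology baseline,
  and the 5 % / 95 % percentile gene-tree screen.
* **snps** — per-family consensus, SNP statistics (per-strain mismatch
  sum and variable/polyvariable column counts, densities per kb), and
  ecoSNP detection (dimorphic columns that perfectly partition strains
  by clade).
* **enrichment** — core-vs-pan functional category fold increases (one
  decimal, half-up) with a two-sided Fisher's exact test, from a
  user-supplied gene→category TSV.
* **pipeline / cli** — end-to-end orchestration with a YAML config, a
  seed for every stochastic stage, and a manifest with per-artifact
  checksums.

## CLI

```
pancore simulate  --outdir runs/sim --seed 42
pancore cluster   --indir runs/sim/genomes --outdir runs/work
pancore matrix    --indir runs/sim/genomes --clusters runs/work/clusters.tsv --out runs/work/matrix.tsv
pancore partition --matrix runs/work/matrix.tsv --out runs/work/partition.tsv
pancore rarefy    --matrix runs/work/matrix.tsv --seed 42 --out runs/work/rarefaction.tsv
pancore heatmap   --clusters runs/work/clusters.tsv --similarity runs/work/similarity.tsv --outdir runs/work --k 2
pancore genetrees --indir runs/sim/genomes --clusters runs/work/clusters.tsv --partition runs/work/partition.tsv --outdir runs/work
pancore nodal     --msa-dir runs/work/core_msas --reference runs/work/dendrogram.nwk --out runs/work/nodal_report.tsv
pancore snps      --msa-dir runs/work/core_msas --clades runs/sim/truth/clades.tsv --outdir runs/work
pancore hgt       --matrix runs/work/matrix.tsv --clades runs/sim/truth/clades.tsv --out runs/work/hgt.tsv
pancore enrich    --annotation annotation.tsv --clusters runs/work/clusters.tsv --partition runs/work/partition.tsv --out runs/work/enrichment.tsv
pancore run-all   --config config.yaml
```

A minimal `config.yaml` for `run-all`:

```yaml
outdir: runs/full
seed: 42
simulate:
  n_clades: 2
  genomes_per_clade: 10
  seed: 42
bootstrap_replicates: 0
```

Real data goes in via `input_dir` (a directory of paired `.fna`/`.faa`
FASTA files with `genomeID|geneID` headers) plus an optional
`clades_path` TSV and `annotation_path` TSV instead of the `simulate`
block.

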