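# spatialcite

Joint spatial mapping of high-plex protein and whole-transcriptome data
from microfluidic deterministic barcoding in tissue (DBiT). A tissue
section is stained with a cocktail of antibody-derived DNA tags (ADTs),
then two orthogonal sets of DNA barcodes — rows A1..A50, then columns
B1..B50 — are flowed over it and ligated in situ, so every tissue pixel
carries a unique spatial address code AiBj. Paired-end sequencing of the
ADT and cDNA libraries then turns both protein epitopes and mRNAs into
spatially addressed reads.

`spatialcite` implements the computational side of that assay:

- **Decoding.** Read 2 carries `UMI | barcode B | ligation linker |
  barcode A` at fixed offsets. Each barcode segment is matched against
  its whitelist exactly, or to a unique entry within Hamming distance 1
  (whitelists are built with pairwise distance ≥ 3, so single-error
  correction is unambiguous); ties are rejected. Read 1 carries the
  antibody tag (protein library) or a transcript fragment (cDNA
  library).
- **Counting.** Reads are grouped by (pixel, feature) and UMIs collapsed
  — exact identity by default, or the directional-adjacency rule
  (merge u, v when Hamming(u,v) ≤ 1 and count(u) ≥ 2·count(v) − 1) —
  yielding co-indexed sparse pixel × feature molecule-count matrices.
- **Analysis.** Protein counts get the centered log ratio transform
  across features within each pixel, CLR(x_j) = ln(x_j+1) − (1/F)Σ_f
  ln(x_f+1); RNA counts get library-size log-normalization. Pixels are
  clustered by z-scaling → PCA (30 dims) → shared-nearest-neighbor graph
  → Leiden at resolution 0.5; cluster markers come from two-sided
  Wilcoxon rank-sum tests with Benjamini–Hochberg correction. Cell types
  transfer from a labeled scRNA-seq reference by nearest type-centroid
  in a joint PC space plus a cluster-majority rule, and marker
  signatures (e.g. the peripheral helper T cell score over LAG3, PDCD1,
  CXCR6) are scored as the mean of per-feature z-scores.
- **Simulation.** A bundled generator plants contiguous spatial domains
  with distinct protein/RNA programs, emits paired FASTQ with PCR
  duplicates and sequencing errors, and keeps the ground truth, so the
  whole pipeline is testable end to end without any external data.

## Worked example

```python
import numpy as np
import spatialcite as sc
from spatialcite.demux import demux_fastq
from spatialcite.simulate import (default_gene_list, emit_fastq,
                                  make_reference_transcripts, make_tissue)
from sklearn.metrics import adjusted_rand_score

design = sc.default_chip_design(n_rows=20, n_cols=20)   # 20x20 pixel grid
panel = sc.small_panel()                                # 40-plex ADT panel
truth = make_tissue(n_domains=3, grid=(20, 20), effect_size=8.0, seed=0,
                    protein_features=panel.names, error_rate=0.005)
gene_seqs = make_reference_transcripts(default_gene_list(), seed=0)
sim = emit_fastq(truth, design, panel, gene_seqs, "simdir", seed=0)
print("reads emitted:", sim.n_reads)

matrix, summary, _ = demux_fastq(sim.protein_r1, sim.protein_r2,
                                 design, "protein", panel=panel)
print("status tallies:", summary["status_counts"])
print("molecules counted:", matrix.total_umis())

norm = sc.clr_normalize(matrix)
clusters = sc.cluster_pixels(norm, n_dims=30, resolution=0.5, seed=0)
domains = np.array([truth.domain_of(p) for p in matrix.pixel_index])
print("clusters found:", clusters.n_clusters,
      "| ARI vs planted domains:", round(adjusted_rand_score(domains, clusters.labels), 3))
```

Output:

```
reads emitted: {'protein': 89601, 'rna': 69592}
status tallies: {'OK': 89217, 'NO_FEATURE': 259, 'NO_ROW_BARCODE': 55, 'NO_COL_BARCODE': 62, 'LOW_QUALITY': 8}
molecules counted: 62197
clusters found: 3 | ARI vs planted domains: 1.0
```

The tallies account for every input read: at a 0.5% per-base error rate
a small fraction of reads carry two or more errors inside one 8-base
barcode or 15-base tag segment and are rejected rather than guessed.
The 62,197 molecules are what remains after collapsing the ~1.5× PCR
duplicate reads per UMI. Clustering the CLR-normalized protein profiles
recovers the three planted tissue domains exactly (adjusted Rand index
1.0 against the generator's domain map).

The same workflow is available from the shell:

```sh
spatialcite simulate --domains 3 --grid 20x20 --effect 8 --error 0.005 --seed 0 -o simdir
spatialcite demux --chip simdir/chip.yaml --panel simdir/panel.tsv \
    --r1 simdir/protein_R1.fastq.gz --r2 simdir/protein_R2.fastq.gz \
    --modality protein -o outdir
spatialcite cluster --matrix outdir --modality protein --dims 30 --resolution 0.5
spatialcite run --config run.yaml        # full pipeline with manifest
```

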