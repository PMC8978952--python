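# Methods notes

## The assay being modeled

DBiT-style spatial multi-omics delivers two orthogonal barcode sets over
a tissue section through microfluidic channels: row barcodes A1..An
(each with a poly-T capture region, a spatial barcode, and a ligation
linker) prime in-tissue reverse transcription, then column barcodes
B1..Bm (ligation linker, spatial barcode, UMI, PCR handle) are ligated
on in a perpendicular flow. Every grid intersection — a tissue pixel of
20–25 µm — is thereby tagged with a unique address code AiBj. Because
ADTs (antibody-derived DNA tags) carry poly-A tails just like mRNAs,
one chip run co-indexes a high-plex protein panel and the transcriptome;
the two libraries share the Read-2 structure `UMI | barcode B | linker |
barcode A` and differ only in Read 1 (antibody tag vs cDNA fragment).

## Barcode model and decoding

- **Whitelists.** The chip ships with generated stand-in barcode sets:
  random 8-mers filtered to pairwise Hamming distance ≥ 3 within each
  set (the vendor's actual sequences live in supplementary material we
  do not redistribute). Distance ≥ 3 means every sequence within one
  substitution of a barcode is nearer to it than to any other, so
  single-error correction cannot mis-assign. Panels use 15-base tags
  with the same guarantee.
- **Matching policy.** Exact match, else the unique whitelist entry
  within Hamming distance k (default 1); ties → `AMBIGUOUS_BARCODE`,
  no hit → `NO_ROW_BARCODE`/`NO_COL_BARCODE`. Bases with Phred < 10
  inside a barcode segment are untrusted and count as mismatches against
  every candidate. Reads shorter than the layout, or whose ligation
  linker differs from the expected sequence by > 2 substitutions
  (a chimeric-ligation guard), are `LOW_QUALITY`. Every read receives
  exactly one status, so status tallies always sum to the input read
  count — a conservation check asserted at run time.
- **Which UMI.** The barcode-B UMI segment on Read 2 is used for both
  modalities. ADTs carry their own internal UMI as well; we ignore it by
  default because a single consistent UMI source keeps the two libraries
  symmetric, and the tag-internal UMI would require a per-panel Read-1
  layout. The Read-1 tag offset is configurable for panels that need it.
- **Transcript assignment.** At desk scale reads are assigned by exact
  substring match: a read maps to a gene when ≥ 30 consecutive bases
  occur verbatim in that gene's transcript, with 21-mer seeding to
  prefilter candidates; multi-gene hits are discarded as ambiguous
  rather than fractionally assigned. This is an intentionally simple
  assigner adequate for synthetic references; per-read gene assignments
  produced by an external aligner can be loaded from TSV instead
  (`load_gene_assignments`).

## UMI deduplication

Within each (pixel, feature) group, molecule count = number of UMI
classes. Default is exact identity. The directional mode merges u and v
when Hamming(u,v) ≤ 1 and the more abundant UMI has count ≥ 2·count
(other) − 1 — the standard directional-adjacency rule that absorbs
sequencing-error offspring of an abundant parent without chaining
unrelated UMIs of similar abundance. The class count is the number of
connected components under that relation; the implementation finds
neighbor candidates by single-position wildcard hashing and is verified
against a quadratic all-pairs oracle in the tests.

## Normalization

- **Protein: CLR across features within each pixel.**
  CLR(x_j) = ln(x_j + 1) − (1/F)·Σ_f ln(x_f + 1). ADT counts are
  compositional (staining and capture efficiency scale all tags in a
  pixel together), and centering within the pixel makes pixels
  comparable to one another, which is what spatial clustering needs.
  The alternative margin (centering within each feature across pixels)
  is reachable by transposing the matrix but is not the default. Every
  output row sums to zero (< 1e−9), including all-zero pixels.
- **RNA: log library-size normalization,** v_ij = ln(1 + s·x_ij/Σ_j
  x_ij) with s = 10⁴. This is a deliberately transparent choice in place
  of variance-stabilizing NB-regression approaches; it is exactly scale
  invariant per pixel, and zero-total pixels are kept as zero rows and
  flagged rather than dropped. Highly-variable-gene selection ranks
  features by the variance of counts standardized by the
  Poisson-expected spread √mean (clipped at √n), so features at pure
  technical noise score ~1 and overdispersed ones rise above it.

## Clustering

z-score each feature (clipped at ±10) → PCA to 30 dims (capped at
min(features, pixels) − 1) → k-nearest-neighbor graph (k = 20,
Euclidean in PC space) → shared-nearest-neighbor Jaccard edge weights,
pruned below 1/15 → Leiden modularity (RB configuration) at resolution
0.5, seeded and deterministic. Cluster ids are relabeled by decreasing
size. UMAP is not part of any quantitative output (stochastic layout);
spatial cluster maps are drawn directly on the pixel grid.

Defaults of 30 dimensions and resolution 0.5 are the assay's standard
operating point; both are plain function arguments.

## Differential features

Per cluster: two-sided Wilcoxon rank-sum (Mann–Whitney) of in-cluster
vs all other pixels for each feature, vectorized; Benjamini–Hochberg
FDR within each cluster; effect size reported as the difference of
group means on the normalized (log-like) scale. The rank-sum choice is
an assumption — it is the conventional default for this comparison and
is calibrated on permuted-label nulls in the tests (type-I rate within
[0.03, 0.07] at α = 0.05). Clusters with fewer than 3 pixels are
skipped with a warning. Constant features (identical in both groups)
get p = 1.

## Label transfer and signatures

Seurat-style anchor integration is replaced by a fully specified
nearest-centroid procedure: intersect genes (≥ 50 required);
log-normalize both matrices; center each gene within each dataset
(a light batch correction); fit one PCA on the stacked matrices;
average reference cells per type into centroids; assign each pixel the
centroid with highest cosine similarity, confidence = softmax over
negative cosine distances. When spatial clusters are supplied, the
cluster-majority rule is applied on top: all pixels of a cluster
receive the cluster's modal predicted type (ties break alphabetically
for determinism). The majority rule is the documented annotation
contract; the centroid step merely provides the per-pixel votes.

Signature scores are the mean over signature features of per-feature
z-scores (across pixels) of normalized expression. Zero-variance
features contribute 0 (with a relative tolerance guarding float noise),
so a constant matrix scores 0 everywhere. Protein names map to gene
symbols through a small alias table (PD-1 → PDCD1, CD223 → LAG3);
a feature that is still missing raises an error naming it.

## Synthetic data: what it does and does not emulate

`make_tissue` plants D contiguous domains by Voronoi partition of the
grid around randomly chosen centers. Every feature has baseline Poisson
mean λ₀ (default 2 per protein, 1 per gene — giving per-pixel totals of
order 10²–10³ molecules on a 40-plex panel / 60-gene reference, the
right order for this assay at desk scale); each domain elevates its
disjoint marker block (5 proteins, 8 genes per domain) to λ₀ ×
effect_size (default 8). Negative-binomial overdispersion is available
through a dispersion flag. `emit_fastq` draws distinct UMIs per
molecule, 1 + Poisson(0.5) duplicate reads per UMI (mean 1.5×, so
deduplication is actually exercised), assembles Read 2 from the chip
layout, applies uniform per-base substitution errors to both mates, and
shuffles read order. Read names encode the generating pixel, so
per-read decoding accuracy is measurable. An optional per-pixel RNA
depth scale stands in for the ADT/mRNA competition for reverse
transcription observed in tissue; no mechanistic model is attempted.

What this does **not** model: ligation chimeras, optical duplicates,
realistic quality-score profiles (constant Q40), cell-density variation
within a domain, diffusion between channels, isotype-control background
levels, or splicing. Passing tests therefore demonstrate correctness of
the decoding/counting/analysis machinery under the stated generative
model, not performance on real tissue data — for real data the aligner
hook and configurable layouts are the integration points.

## Numerical and scale choices

- Default validation scale: 20×20 pixel grid, 3 domains, 40-plex panel,
  60 genes, ~90k protein and ~70k RNA read pairs; each simulated
  experiment runs in seconds and the whole validation suite in well
  under five minutes on one core.
- Matrices are CSR sparse with int64 counts; MatrixMarket + TSV on
  disk (pixels.tsv carries grid indices and micron coordinates from the
  affine map x = (col−1)·pitch, y = (row−1)·pitch, origin at the center
  of pixel (1,1); pitch defaults to 25 µm and is per-experiment
  configuration, since published experiments used 20 µm and 25 µm
  chips).
- Determinism: one global seed propagates to every stochastic stage;
  deduplication and counting are order-independent (groups are sorted),
  so rerunning a config reproduces byte-identical matrices — asserted
  via manifest checksums.

## Known limitations

- The exact-substring transcript assigner cannot handle splicing,
  sequencing errors inside the matched window (a read whose every
  30-base window carries an error is dropped as `NO_FEATURE`), or
  paralog-aware assignment; it is a desk-scale stand-in with an
  explicit hook for external aligner output.
- The nearest-centroid transfer assumes reference and spatial data
  differ by a per-gene shift only; strong batch nonlinearity would
  need proper anchor-based integration.
- Bundled barcode/tag sequences are generated stand-ins, not the
  published oligo sets; decoding real libraries requires loading the
  real whitelists via the chip-design YAML / panel TSV.
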