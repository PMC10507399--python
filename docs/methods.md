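# Methods

## Scope and data model

cytosweep clusters per-event cytometry tables and evaluates the result. The
central container, `CellTable`, pairs an events × channels raw matrix and
its arcsinh-transformed counterpart with per-event metadata (source file,
donor, batch/pool, control flag, and, as stages complete, embedding
coordinates and cluster ids). Events carry barcodes of the form
`<sample_id>_<index>`, where the sample id is the FCS basename without
extension and the index is 1-based within the file — 1-based to match the
event-index convention of FCS files. Barcodes make events traceable through
control removal, subsampling and external label tables.

A run is defined by three files: `file_metadata.csv` (file name, donor,
pool/batch, control flag), `marker_metadata.csv` (channel name, marker
name, and independent boolean flags `used_for_UMAP`, `used_for_clustering`,
`used_for_scaffold`), and `config.yml`. Boolean columns accept
`true/false`, `TRUE/FALSE` and `1/0`, since metadata prepared in R
spreadsheets commonly mixes these. Unknown extra columns are ignored with a
warning rather than rejected — metadata files are often hand-extended.

FCS reading and writing is implemented directly (FCS 3.0/3.1 list mode,
float32/float64/unsigned-integer data, both byte orders); the writer emits
float32 FCS 3.1. Matrix intake accepts a cells × markers CSV either as raw
counts or as already-transformed values (the imaging `trans_exp` route), in
which case no raw matrix exists and no further transform is applied.

## Transformation

`asinh(x / c)` with one global cofactor per run. Default `c = 5`, the
standard choice for mass-cytometry ion counts; fluorescence data needs much
larger cofactors (a few hundred to several thousand — a typical spectral
flow setting is 6000). The transform is applied to all channels uniformly;
per-channel cofactors were deliberately not added, keeping one knob with a
clear meaning. Negative inputs (possible after spillover compensation) pass
through — asinh is defined on all reals — and are never truncated.

## Clustering

**SOM.** Online training of an `xdim × ydim` prototype grid: prototypes are
initialised from a seeded uniform sample of data rows, drawn from the
distinct rows when at least `xdim·ydim` exist (duplicate-heavy fixtures
otherwise collapse several prototypes onto one value); then `rlen` passes
(default 10) present events in seeded random order, and each event pulls
its best-matching unit plus all grid neighbours within the current radius
toward itself. Learning rate decays linearly 0.05 → 0.01; the bubble
(threshold) neighbourhood radius decays linearly from the 0.67 quantile of
node-to-node grid distances to zero. These are the hyperparameter
conventions commonly used for cytometry SOMs; all are exposed. The inner
loop is a numba kernel, which keeps 50,000-event training below a second.
Ties in BMU search resolve to the lowest node index. No scaling or
standardisation is applied before training — clustering operates on
arcsinh-transformed, unscaled values, matching the unscaled median-expression
heatmaps used for annotation — though callers can standardise the matrix
themselves if desired.

The grid size fixes the cluster count; nodes that own no events remain
valid (empty) cluster ids so summary matrices stay comparable across runs.

**Metaclustering.** Node prototypes are merged into `k` groups by
average-linkage hierarchical clustering with Euclidean distance, cut at
`k` — chosen over consensus metaclustering because it is deterministic and
therefore testable. When an occupancy mask is available (the pipeline always
passes one), only prototypes that own events are clustered: a stranded,
empty prototype carries no population signal, and letting it claim a
metacluster slot can force two real populations to merge. Empty nodes are
then mapped to the group of their nearest occupied prototype, so every node
stays mapped.

**CLARA.** Classic CLARA: `samples` (default 50) seeded subsamples of size
`min(n, 40 + 2k)`, PAM (BUILD, then best-improvement SWAP) on each, and the
medoid set with the lowest mean dissimilarity over *all* events wins. The
SWAP phase asserts its defining invariant — cost never increases. PAM
guarantees a 1-swap local optimum, not a global one; the tests check
exactly that. Metrics: Euclidean (default) and Manhattan.

## Embedding

UMAP (via umap-learn) on the `used_for_UMAP` markers, defaults
`n_neighbors = 15`, `min_dist = 0.1`, `spread = 0.1`,
`learning_rate = 0.5`, random initialisation, fixed seed. When
`min_dist > spread` (which the backend rejects), spread is raised to
`min_dist` with a warning. The embedding is visualisation only: clustering
consumes marker space, never the coordinates. With a seed set, umap-learn
runs single-threaded and the coordinates are reproducible.

## Resolution selection

The Davies–Bouldin index is computed from its definition: for the K
non-empty clusters, `DBI = (1/K) Σ_i max_{j≠i} (S_i + S_j) / M_ij`, with
`S_i` the mean Euclidean distance of cluster-i events to the cluster
centroid and `M_ij` the centroid distance. Empty ids are dropped (a
zero-member centroid is undefined); fewer than two non-empty clusters is an
error. The index is computed on the same feature space as clustering and on
all clustered events — full-data computation keeps the sweep deterministic.

The sweep trains one SOM per grid in a shipped default series ((2,2) …
(8,8), editable via `grid_sizes.csv`), each with a deterministic per-grid
seed derived from the configured seed, and records total/non-empty cluster
counts and DBI; a failing grid is flagged and the sweep continues. Grid
selection defaults to manual — the pipeline exits after the sweep so the
analyst can read the cluster-count-vs-DBI plot — with `global_min`
(ties: fewest clusters, then lowest xdim) and `local_min` (first interior
dip in ascending cluster-count order; monotone sequences fall back to the
global minimum with a warning) available for scripted runs.

## Summaries

Per-file cluster counts and within-file proportions (rows sum to 1),
batch × cluster counts, and median transformed expression per cluster over
*all* markers, unscaled. "Normalized" means within-file proportions, the
form that per-sample frequency plots need. A row-scaled variant
(`(x − row mean)/row sd`, constant rows mapping to 0) is provided for
shape-focused heatmaps. Empty clusters appear with zero frequency and
all-NaN median rows rather than disappearing.

## Landmark assignment

Landmarks are gated FCS files, one population each, named by file stem;
profiles are median transformed expression over the `used_for_scaffold`
markers. Each non-empty cluster is assigned to the landmark with the
highest cosine similarity of profiles — scale-invariant by construction, so
global staining-intensity differences do not drive the match. Ties resolve
to the lexicographically first landmark name; zero-norm or empty cluster
profiles come back "unassigned" with a warning. Cosine is computed on
median profiles (not concatenated events), matching the cluster-level
profile on the other side of the comparison.

## Evaluation

Truth and prediction are `{cell_id, label}` tables; all metrics operate on
the intersection of barcodes. The protocol subsamples 10,000 shared
barcodes without replacement, computes accuracy (exact string match — both
sides are expert cell-type vocabularies, so no Hungarian matching is
applied), adjusted Rand index, Fowlkes–Mallows, and mutual information (in
nats; natural log), and repeats 10 times with per-repeat seeds spawned from
one master seed, reporting per-repeat values and means. ARI, FM and MI are
delegated to scikit-learn and cross-checked in the tests against
independent brute-force pair/contingency enumeration to 1e-9.

The pipeline's evaluation stage needs per-cell predicted labels in the
truth vocabulary; absent an expert annotation map it annotates each cluster
with the majority ground-truth label of its members — a stand-in for the
human annotation step that makes synthetic end-to-end runs self-contained.

The tetramer gate marks an event positive when its raw intensity is at
least `mean + 3·sd` of the supplied intensities; sd is the sample standard
deviation (ddof = 1, configurable). A zero-variance vector yields no
positives.

## Spatial enrichment

Imaging cluster labels are joined to `{cell_id, x, y, region}` tables.
`region_frequencies` normalises within region (each region column is a
probability vector over clusters); enrichment is
`log2(freq[stroma] / freq[tumor])` per cluster. The log-ratio is identical
up to one additive constant whether frequencies are normalised per region
or per cluster (verified in tests), so the choice does not affect cluster
rankings. Clusters absent from either compartment are flagged undefined —
no pseudocounts, since imputing a floor would manufacture finite
enrichment for unobserved combinations. Pixel coordinates pass through
unchanged.

## Pipeline and checkpoints

Eight stages, each gated on its predecessor's checkpoint: 1 ingest +
transform, 2 embedding, 3 sweep, 4 clustering (needs a chosen grid or the
CLARA backend), 5 summaries, 6 landmark (skipped cleanly when no landmark
directory is configured), 7 evaluation (skipped without truth labels),
8 export. A checkpoint is a directory holding the expression matrices as
`.npy`, metadata as CSV, and a JSON descriptor; `manifest.json` records
completed stages, SHA-256 hashes of outputs, and the seeds used. Rerunning
a completed stage requires `force`. `run_all` (CLI: `run --grid X,Y`)
bypasses the interactive pause for scripted and test use. Two runs with the
same config and seeds produce hash-identical labels and summary CSVs.

## Synthetic data generator

Populations are Gaussian on the arcsinh scale — each has a per-marker
signature mean, spread, and mixture proportion — so that after the
pipeline's forward transform the planted structure is exactly Gaussian and
separability is analytically controllable. Raw counts are
`c · sinh(value)` truncated at zero (ion counts are non-negative). The
default design plants five immune-like populations (CD4 T, CD8 T, B,
monocyte, NK signatures over ten metal-tagged channels) with high/low
levels 3.5/0.5 and spread 0.3 — a 10-sd signature separation, squarely in
the well-separated regime where recovery guarantees are meaningful — at
proportions (0.30, 0.25, 0.15, 0.20, 0.10), across a configurable number
of files split into batches (default 6 files, 2 batches) with an additive
per-batch arcsinh-scale shift (default 0.15, a mild residual batch effect)
and one control file per batch. The generator can emit the complete
on-disk input set of a real run, including a gated landmark directory (one
FCS per population) and the per-cell truth table. The imaging variant
places cells uniformly in a rectangle whose left half is stroma, with a
per-population stroma affinity to plant known enrichment.

What the generator does *not* emulate: spillover, doublets, acquisition
drift, rare populations on expression continua, or non-Gaussian marker
distributions. Tests passing on this data therefore demonstrate
correctness of the machinery and recoverability under clean separation,
not clustering performance on hard real-world mixtures.

## Problem sizes and numerical choices

The test suite runs at desk scale (hundreds to thousands of events per
fixture; the planted-recovery protocol at 50,000 events × 10 seeds, which
the numba SOM kernel completes in seconds). DBI agreement with brute force
is asserted to 1e-9; the scikit-learn cross-check uses 1e-7 because its
centroid distances go through the quadratic expansion and lose a few
digits. Subsample and repeat seeds are spawned from master seeds via
`SeedSequence` and kept below 2^31. Degenerate inputs have defined
behavior throughout: empty FCS files warn and contribute nothing, removing
all controls leaves an empty table with a warning, a 1×1 SOM grid yields a
single cluster near the data mean, and constant rows scale to zero.

## Known limitations

- The online SOM can strand prototypes on pathological duplicate-heavy
  data; occupancy-aware metaclustering absorbs the consequence, but node
  counts above the number of genuine populations will always leave empty
  nodes.
- Accuracy requires a shared label vocabulary; it is intentionally not
  permutation-invariant (use ARI/FM/MI for vocabulary-free comparison).
- One global arcsinh cofactor per run; mixed-modality panels needing
  per-channel cofactors must be transformed upstream and ingested via the
  already-transformed matrix route.
- No batch correction is performed — only assessment (split-by-batch
  visualisation, batch × cluster composition); corrected inputs are
  expected upstream.
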