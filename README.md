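# cytosweep

Unsupervised clustering and cluster-quality evaluation for high-dimensional
cytometry: mass cytometry (CyTOF), spectral flow, and multiplexed-imaging
cell tables. The package is a checkpointed pipeline — ingest and arcsinh
transformation, UMAP embedding, self-organizing-map (SOM) or CLARA
(k-medoids) clustering, a Davies–Bouldin sweep over SOM grid sizes to pick
the cluster resolution, cluster summary matrices for annotation, cosine
assignment of clusters to expert-gated landmark populations, a
repeated-subsample concordance protocol against manually gated ground
truth, and stroma/tumor spatial enrichment for imaging data — usable both
as a Python library and as a thin `cytosweep` command-line tool.

It is aimed at immunologists and cytometry analysts who have pre-gated,
batch-corrected FCS files (or an expression matrix) and want reproducible,
inspectable clustering with an explicit, data-driven resolution choice.

## Method

Raw intensities are variance-stabilised as `asinh(x / c)` with a global
cofactor `c` (default 5 for mass cytometry; thousands for fluorescence). A
SOM on an `xdim × ydim` node grid is trained online in the space of the
markers flagged for clustering; every event is assigned to its best-matching
unit, so the grid fixes the number of clusters (a 6 × 6 grid defines 36,
a 2 × 4 grid defines 8). Optionally the node prototypes are merged into
`k` metaclusters by average-linkage hierarchical clustering.

Resolution is chosen by sweeping a series of grids and scoring each
clustering with the Davies–Bouldin index

    DBI = (1/K) Σ_i  max_{j≠i} (S_i + S_j) / M_ij ,

where `S_i` is the mean Euclidean distance of cluster *i*'s events to their
centroid and `M_ij` the distance between centroids — lower is better. The
pipeline pauses after the sweep so the analyst can pick a grid from the
cluster-count-vs-DBI plot (automatic global-minimum / local-minimum
selection is available for scripted runs).

Cluster annotations are evaluated against gated ground truth by repeatedly
subsampling 10,000 shared barcodes (10 repeats, seeded) and averaging
accuracy, the adjusted Rand index, the Fowlkes–Mallows index and mutual
information. Clusters can also be anchored to gated landmark populations by
cosine similarity of median expression profiles, and — for imaging data —
scored for compartment preference as `log2(stromal frequency / tumor
frequency)`.

A seeded synthetic-data generator plants Gaussian populations on the
arcsinh scale across multiple files and batches, with known per-cell
labels, and writes the exact file set a real run needs; every test runs on
its output.

## Worked example

`examples/02_resolution_sweep.py` generates a 1,000-event synthetic run
with five planted immune-like populations and sweeps eight grids:

```
 xdim  ydim  n_clusters_total  n_clusters_nonempty      dbi
    2     2                 4                    4 0.584326
    2     3                 6                    5 0.386698
    2     4                 8                    5 0.386698
    3     3                 9                    5 0.386698
    3     4                12                    8 1.665187
    4     4                16                    9 1.763127
    4     5                20                   15 2.020719
    5     5                25                   17 2.431020

global-minimum DBI grid: 2x3 (6 clusters)
```

The DBI bottoms out once the grid offers enough nodes to isolate the five
planted populations (the 2 × 3, 2 × 4 and 3 × 3 grids all converge to the
same five non-empty clusters, hence the identical index) and grows at
higher resolutions as clusters fragment. `examples/01_full_pipeline.py` then runs all eight
stages end-to-end and reports concordance against the planted labels
(accuracy and ARI of 1.000 on this widely separated synthetic mixture);
the other examples demonstrate CLARA, landmark assignment, the concordance
protocol on deliberately corrupted labels (mean accuracy 0.9002 for a 10%
corruption), and spatial enrichment.

From the shell, the same run is:

```sh
cytosweep sweep   --config config.yml     # then inspect cluster_vs_dbi.png
cytosweep cluster --config config.yml --xdim 6 --ydim 6
cytosweep run     --config config.yml --grid 6,6   # all stages, no pause
```

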