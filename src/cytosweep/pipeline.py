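"""The checkpointed eight-stage pipeline.

Stages: 1 ingest+transform, 2 embedding, 3 resolution sweep, 4 clustering,
5 summaries, 6 landmark assignment, 7 evaluation, 8 final export. Each stage
reads its predecessor's checkpoint directory under ``output_dir`` and writes
its own, so a run can pause — deliberately so after the sweep, which is
where the analyst inspects the cluster-count-vs-DBI plot and picks a grid —
and resume later. A ``manifest.json`` records completed stages, output
hashes and the seeds used.

Stage 4 needs either a selected SOM grid (from the sweep or given
explicitly) or the CLARA backend, which skips the sweep entirely.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .celltable import CellTable
from .clara import clara_cluster
from .config import PipelineConfig, marker_channels, read_file_metadata, read_marker_metadata
from .embedding import compute_embedding
from .evaluation import concordance_report
from .ingest import load_fcs_directory, load_matrix, remove_controls, subsample_per_file
from .landmark import assign_landmarks, load_landmarks
from .resolution import SweepResult, default_grid_sizes, grid_sweep, read_grid_sizes, select_grid
from .som import ClusterAssignment, SOMModel, apply_metaclustering, assign_bmu, metacluster_codes, train_som
from .summaries import summarize
from .transform import apply_transform

__all__ = ["Pipeline", "STAGE_NAMES"]

STAGE_NAMES = {
    1: "ingest",
    2: "embed",
    3: "sweep",
    4: "cluster",
    5: "summarize",
    6: "landmark",
    7: "evaluate",
    8: "export",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {
                "version": __version__,
                "config": config.to_dict(),
                "stages": {},
            }

    # --- plumbing -------------------------------------------------------

    def checkpoint_dir(self, stage: int) -> Path:
        return self.out / f"checkpoint{stage}"

    def stage_completed(self, stage: int) -> bool:
        return self.manifest["stages"].get(str(stage), {}).get("completed", False)

    def _require(self, stage: int) -> None:
        if stage > 1 and not self.stage_completed(stage - 1):
            raise RuntimeError(
                f"stage {stage} ({STAGE_NAMES[stage]}) requires "
                f"checkpoint{stage - 1} — run stage {stage - 1} "
                f"({STAGE_NAMES[stage - 1]}) first"
            )

    def _finish(self, stage: int, outputs: list[Path], info: dict | None = None) -> None:
        entry = {
            "completed": True,
            "name": STAGE_NAMES[stage],
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {
                str(p.relative_to(self.out)): _sha256(p) for p in outputs if p.is_file()
            },
        }
        if info:
            entry.update(info)
        self.manifest["stages"][str(stage)] = entry
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def _load_table(self, stage: int) -> CellTable:
        return CellTable.load(self.checkpoint_dir(stage))

    def _markers(self) -> pd.DataFrame:
        return read_marker_metadata(self.config.marker_metadata_path)

    # --- stages ---------------------------------------------------------

    def run_stage(self, stage: int, force: bool = False, **extra):
        if stage not in STAGE_NAMES:
            raise ValueError(f"stage must be in 1..8, got {stage}")
        if self.stage_completed(stage) and not force:
            raise RuntimeError(
                f"stage {stage} already completed; pass force=True to rerun"
            )
        self._require(stage)
        return getattr(self, f"stage{stage}_{STAGE_NAMES[stage]}")(**extra)

    def stage1_ingest(self) -> CellTable:
        cfg = self.config
        markers = self._markers()
        if cfg.matrix_path is not None:
            table = load_matrix(
                cfg.matrix_path, cfg.cell_meta_path, markers,
                already_transformed=cfg.already_transformed,
            )
        else:
            files = read_file_metadata(cfg.file_metadata_path)
            table = load_fcs_directory(cfg.fcs_dir, files, markers)
        if cfg.remove_controls:
            table = remove_controls(table)
        if cfg.subsample_per_file is not None:
            table = subsample_per_file(table, cfg.subsample_per_file, seed=cfg.som_params.seed)
        if table.trans_expr is None:
            table = apply_transform(table, cfg.arcsinh_cofactor)
        ck = table.save(self.checkpoint_dir(1))
        self._finish(1, list(ck.iterdir()), {"n_events": table.n_events})
        return table

    def stage2_embed(self) -> CellTable:
        table = self._load_table(1)
        compute_embedding(table, self._markers(), self.config.umap_params)
        ck = table.save(self.checkpoint_dir(2))
        self._finish(2, list(ck.iterdir()), {"seed": self.config.umap_params.seed})
        return table

    def stage3_sweep(self) -> SweepResult | None:
        ck = self.checkpoint_dir(3)
        ck.mkdir(parents=True, exist_ok=True)
        if self.config.backend == "clara":
            (ck / "sweep_skipped.txt").write_text(
                "CLARA backend: resolution is set by k, no DBI sweep\n"
            )
            self._finish(3, [ck / "sweep_skipped.txt"], {"skipped": True})
            return None
        table = self._load_table(2)
        if self.config.grid_sizes_path is not None:
            grids = read_grid_sizes(self.config.grid_sizes_path)
        else:
            grids = default_grid_sizes()
        sweep = grid_sweep(table, self._markers(), grids, self.config.som_params)
        sweep.to_csv(ck / "sweep.csv")
        from .plots import plot_sweep

        plot_sweep(sweep.table, ck / "cluster_vs_dbi.png")
        self._finish(3, list(ck.iterdir()), {"n_grids": len(grids)})
        return sweep

    def stage4_cluster(
        self,
        xdim: int | None = None,
        ydim: int | None = None,
        selection_mode: str | None = None,
    ) -> ClusterAssignment:
        cfg = self.config
        table = self._load_table(2)
        markers = self._markers()
        X = table.expression(marker_channels(markers, "clustering"))
        ck = self.checkpoint_dir(4)
        ck.mkdir(parents=True, exist_ok=True)
        info: dict = {"backend": cfg.backend}
        if cfg.backend == "clara":
            p = cfg.clara_params
            assignment = clara_cluster(X, p.k, p.metric, p.samples, p.seed)
            info.update({"k": p.k, "seed": p.seed})
        else:
            if xdim is None or ydim is None:
                if selection_mode is None:
                    raise RuntimeError(
                        "stage 4 needs a selected grid: pass xdim/ydim after "
                        "inspecting the sweep table (checkpoint3/sweep.csv), or a "
                        "selection_mode for automatic choice"
                    )
                sweep = SweepResult.from_csv(self.checkpoint_dir(3) / "sweep.csv")
                xdim, ydim = select_grid(sweep, mode=selection_mode)
            p = cfg.som_params
            model = train_som(
                X, xdim, ydim,
                rlen=p.rlen, alpha_start=p.alpha_start, alpha_end=p.alpha_end,
                seed=p.seed, channels=marker_channels(markers, "clustering"),
            )
            assignment = assign_bmu(model, X)
            if p.meta_clustering:
                occupied = np.bincount(assignment.labels - 1, minlength=model.n_nodes) > 0
                meta_map = metacluster_codes(model, p.k, occupied=occupied)
                assignment = apply_metaclustering(assignment, meta_map)
            pd.DataFrame(
                model.codebook, columns=model.channels,
                index=[f"node_{i + 1}" for i in range(model.n_nodes)],
            ).to_csv(ck / "codebook.csv")
            info.update({"xdim": xdim, "ydim": ydim, "seed": p.seed,
                         "meta_clustering": p.meta_clustering})
        table.cell_meta["cluster"] = assignment.labels
        table.extras["cluster_backend"] = assignment.backend
        table.extras["n_clusters"] = assignment.C
        table.save(ck)
        np.save(ck / "labels.npy", assignment.labels)
        self._finish(4, list(ck.iterdir()), info)
        return assignment

    def _assignment(self, table: CellTable) -> ClusterAssignment:
        return ClusterAssignment(
            labels=table.cell_meta["cluster"].to_numpy(),
            C=int(table.extras["n_clusters"]),
            backend=table.extras.get("cluster_backend", "som"),
        )

    def stage5_summarize(self) -> dict[str, pd.DataFrame]:
        table = self._load_table(4)
        mats = summarize(table, self._assignment(table))
        ck = self.checkpoint_dir(5)
        ck.mkdir(parents=True, exist_ok=True)
        for name, df in mats.items():
            df.to_csv(ck / f"{name}.csv")
        from .plots import plot_heatmap
        from .summaries import row_scale

        plot_heatmap(mats["freq_norm"], ck / "file_by_cluster.png", "file x cluster frequency")
        plot_heatmap(mats["batch_comp"], ck / "batch_by_cluster.png", "batch x cluster counts")
        valid = mats["median_expr"].dropna(how="all")
        plot_heatmap(valid, ck / "median_expression.png", "median arcsinh expression (unscaled)")
        plot_heatmap(row_scale(valid), ck / "median_expression_rowscaled.png",
                     "median expression (row-scaled)", cmap="RdBu_r")
        self._finish(5, list(ck.iterdir()))
        return mats

    def stage6_landmark(self) -> pd.DataFrame | None:
        ck = self.checkpoint_dir(6)
        ck.mkdir(parents=True, exist_ok=True)
        if self.config.landmark_dir is None:
            (ck / "landmark_skipped.txt").write_text("no landmark directory configured\n")
            self._finish(6, [ck / "landmark_skipped.txt"], {"skipped": True})
            return None
        table = self._load_table(4)
        markers = self._markers()
        median_expr = pd.read_csv(self.checkpoint_dir(5) / "median_expr.csv", index_col=0)
        landmarks = load_landmarks(self.config.landmark_dir, markers, self.config.arcsinh_cofactor)
        assignment = assign_landmarks(median_expr, landmarks, markers)
        assignment.to_csv(ck / "landmark_assignment.csv", index=False)
        edges = assignment.dropna(subset=["cosine"])[["cluster", "landmark", "cosine"]]
        edges.to_csv(ck / "cluster_landmark_edges.csv", index=False)
        self._finish(6, list(ck.iterdir()), {"n_landmarks": len(landmarks.names)})
        return assignment

    def stage7_evaluate(self, seed: int | None = None) -> pd.DataFrame | None:
        ck = self.checkpoint_dir(7)
        ck.mkdir(parents=True, exist_ok=True)
        if self.config.truth_labels_path is None:
            (ck / "evaluation_skipped.txt").write_text("no ground-truth labels configured\n")
            self._finish(7, [ck / "evaluation_skipped.txt"], {"skipped": True})
            return None
        table = self._load_table(4)
        truth = pd.read_csv(self.config.truth_labels_path)
        # Stand-in for expert cluster annotation: each cluster takes the
        # majority ground-truth label of its members, so accuracy is
        # interpretable on synthetic runs without a human in the loop.
        pred = table.cell_meta[["cell_id", "cluster"]].merge(truth, on="cell_id")
        majority = pred.groupby("cluster")["label"].agg(lambda s: s.value_counts().idxmax())
        pred = pd.DataFrame(
            {"cell_id": pred["cell_id"], "label": pred["cluster"].map(majority)}
        )
        n_shared = len(pred)
        report = concordance_report(
            truth, pred,
            n_per_repeat=min(10_000, n_shared),
            n_repeats=10,
            seed=self.config.som_params.seed if seed is None else seed,
        )
        report.to_csv(ck / "concordance.csv")
        self._finish(7, list(ck.iterdir()), {"means": report.means.to_dict()})
        return report.per_repeat

    def stage8_export(self, with_plots: bool = True) -> Path:
        table = self._load_table(4)
        ck = self.checkpoint_dir(8)
        ck.mkdir(parents=True, exist_ok=True)
        table.cell_meta.to_csv(ck / "cell_metadata.csv", index=False)
        table.save(ck)
        if with_plots and "umap1" in table.cell_meta.columns:
            from .plots import plot_cluster_dispersion, plot_feature_umaps, plot_umap_by_batch, plot_umap_clusters

            plot_umap_clusters(table.cell_meta, ck / "umap_clusters.png")
            plot_umap_by_batch(table.cell_meta, ck / "umap_by_batch.png")
            plot_feature_umaps(table.cell_meta, table.expression(), table.channels,
                               ck / "feature_umaps.png")
            plot_cluster_dispersion(table.cell_meta, ck / "dispersion")
        self._finish(8, [p for p in ck.iterdir() if p.is_file()])
        return ck

    # --- convenience ----------------------------------------------------

    def run_all(
        self,
        grid: tuple[int, int] | None = None,
        selection_mode: str | None = None,
        force: bool = False,
        with_plots: bool = True,
    ) -> Path:
        """Run stages 1..8, bypassing the interactive pause.

        A grid (or automatic selection mode) must be supplied for the SOM
        backend since there is no user in the loop.
        """
        if self.config.backend == "som" and grid is None and selection_mode is None:
            raise ValueError("run_all needs grid=(xdim, ydim) or a selection_mode")
        self.run_stage(1, force=force)
        self.run_stage(2, force=force)
        self.run_stage(3, force=force)
        kwargs = {}
        if grid is not None:
            kwargs = {"xdim": grid[0], "ydim": grid[1]}
        elif selection_mode is not None:
            kwargs = {"selection_mode": selection_mode}
        self.run_stage(4, force=force, **kwargs)
        self.run_stage(5, force=force)
        self.run_stage(6, force=force)
        self.run_stage(7, force=force)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.run_stage(8, force=force, with_plots=with_plots)
        return self.checkpoint_dir(8)
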