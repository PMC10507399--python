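"""Metadata parsing, FCS/matrix intake, barcodes, control removal, subsampling."""

import numpy as np
import pandas as pd
import pytest
import yaml
from scipy.stats import hypergeom

import cytosweep as cs
from cytosweep import synth
from cytosweep.config import ConfigError, SchemaError


def _write_metadata_files(tmp_path, config_extra=None, marker_drop=None):
    files = pd.DataFrame(
        {
            "file_name": ["a.fcs", "b.fcs"],
            "donor_id": ["d1", "d2"],
            "pool_id": ["p1", "p1"],
            "control_sample": ["TRUE", "false"],
        }
    )
    markers = pd.DataFrame(
        {
            "channel_name": ["c1", "c2"],
            "marker_name": ["CD3", "CD4"],
            "used_for_UMAP": [1, 0],
            "used_for_clustering": ["true", "TRUE"],
            "used_for_scaffold": [0, 1],
        }
    )
    if marker_drop:
        markers = markers.drop(columns=[marker_drop])
    files.to_csv(tmp_path / "file_metadata.csv", index=False)
    markers.to_csv(tmp_path / "marker_metadata.csv", index=False)
    config = {"fcs_dir": str(tmp_path), "output_dir": str(tmp_path / "out")}
    config.update(config_extra or {})
    with open(tmp_path / "config.yml", "w") as fh:
        yaml.safe_dump(config, fh)
    return tmp_path


class TestReadMetadata:
    def test_defaults_filled_for_absent_config_keys(self, tmp_path):
        _write_metadata_files(tmp_path)
        files, markers, cfg = cs.read_metadata(
            tmp_path / "file_metadata.csv", tmp_path / "marker_metadata.csv",
            tmp_path / "config.yml",
        )
        assert cfg.arcsinh_cofactor == 5
        assert cfg.umap_params.n_neighbors == 15
        assert cfg.umap_params.min_dist == 0.1
        assert cfg.som_params.xdim == 6 and cfg.som_params.ydim == 6
        assert cfg.clara_params.k == 20 and cfg.clara_params.samples == 50
        assert cfg.clara_params.metric == "euclidean"
        assert files["control_sample"].tolist() == [True, False]

    def test_mixed_boolean_vocabulary_parsed(self, tmp_path):
        _write_metadata_files(tmp_path)
        _, markers, _ = cs.read_metadata(
            tmp_path / "file_metadata.csv", tmp_path / "marker_metadata.csv",
            tmp_path / "config.yml",
        )
        assert markers["used_for_UMAP"].tolist() == [True, False]
        assert markers["used_for_scaffold"].tolist() == [False, True]

    def test_missing_required_marker_column_is_schema_error(self, tmp_path):
        _write_metadata_files(tmp_path, marker_drop="used_for_clustering")
        with pytest.raises(SchemaError, match="used_for_clustering"):
            cs.read_marker_metadata(tmp_path / "marker_metadata.csv")

    def test_non_boolean_flag_names_row(self, tmp_path):
        tmp_path = _write_metadata_files(tmp_path)
        df = pd.read_csv(tmp_path / "file_metadata.csv")
        df.loc[1, "control_sample"] = "maybe"
        df.to_csv(tmp_path / "file_metadata.csv", index=False)
        with pytest.raises(SchemaError, match="row 1"):
            cs.read_file_metadata(tmp_path / "file_metadata.csv")

    def test_unknown_backend_rejected(self, tmp_path):
        _write_metadata_files(tmp_path, config_extra={"backend": "phenograph"})
        with pytest.raises(ConfigError, match="backend"):
            cs.read_config(tmp_path / "config.yml")

    def test_small_rectangular_grid_accepted(self, tmp_path):
        _write_metadata_files(
            tmp_path, config_extra={"som_params": {"xdim": 2, "ydim": 4}}
        )
        cfg = cs.read_config(tmp_path / "config.yml")
        assert cfg.som_params.xdim * cfg.som_params.ydim == 8

    def test_duplicate_file_name_rejected(self, tmp_path):
        _write_metadata_files(tmp_path)
        df = pd.read_csv(tmp_path / "file_metadata.csv")
        df.loc[1, "file_name"] = df.loc[0, "file_name"]
        df.to_csv(tmp_path / "file_metadata.csv", index=False)
        with pytest.raises(SchemaError, match="duplicat"):
            cs.read_file_metadata(tmp_path / "file_metadata.csv")

    def test_extra_columns_ignored_with_warning(self, tmp_path):
        _write_metadata_files(tmp_path)
        df = pd.read_csv(tmp_path / "file_metadata.csv")
        df["scratch_note"] = "x"
        df.to_csv(tmp_path / "file_metadata.csv", index=False)
        with pytest.warns(UserWarning, match="scratch_note"):
            out = cs.read_file_metadata(tmp_path / "file_metadata.csv")
        assert "scratch_note" not in out.columns

    def test_nonpositive_cofactor_rejected(self, tmp_path):
        _write_metadata_files(tmp_path, config_extra={"arcsinh_cofactor": 0})
        with pytest.raises(ConfigError, match="cofactor"):
            cs.read_config(tmp_path / "config.yml")


class TestLoadFcsDirectory:
    def test_events_concatenated_in_metadata_order(self, tmp_path):
        design = synth.default_design(n_files=3, events_per_file=100, seed=2)
        table, files, markers = synth.generate_dataset(design)
        synth.write_fcs(table, tmp_path)
        loaded = cs.load_fcs_directory(tmp_path, files, markers)
        assert len(loaded) == 300
        assert loaded.cell_meta["file_name"].tolist() == table.cell_meta["file_name"].tolist()

    def test_roundtrip_values_match(self, tmp_path):
        design = synth.default_design(n_files=2, events_per_file=80, seed=3)
        table, files, markers = synth.generate_dataset(design)
        synth.write_fcs(table, tmp_path)
        loaded = cs.load_fcs_directory(tmp_path, files, markers)
        np.testing.assert_allclose(loaded.raw_expr, table.raw_expr, rtol=1e-5, atol=1e-4)

    def test_per_event_metadata_copied_from_owning_file(self, tmp_path):
        design = synth.default_design(n_files=2, events_per_file=50, seed=4)
        table, files, markers = synth.generate_dataset(design)
        synth.write_fcs(table, tmp_path)
        loaded = cs.load_fcs_directory(tmp_path, files, markers)
        second = loaded.cell_meta[loaded.cell_meta["file_name"] == files.loc[1, "file_name"]]
        assert (second["donor_id"] == files.loc[1, "donor_id"]).all()
        assert (second["pool_id"] == files.loc[1, "pool_id"]).all()

    def test_missing_channel_error_names_file_and_channel(self, tmp_path):
        design = synth.default_design(n_files=1, events_per_file=30, seed=5)
        table, files, markers = synth.generate_dataset(design)
        synth.write_fcs(table, tmp_path)
        markers = pd.concat(
            [markers, pd.DataFrame([{
                "channel_name": "Er168Di", "marker_name": "missing",
                "used_for_UMAP": True, "used_for_clustering": True,
                "used_for_scaffold": True,
            }])],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="Er168Di"):
            cs.load_fcs_directory(tmp_path, files, markers)


class TestLoadMatrix:
    def test_already_transformed_stored_verbatim(self, tmp_path, rng):
        channels = [f"m{i}" for i in range(7)]
        markers = pd.DataFrame({
            "channel_name": channels, "marker_name": channels,
            "used_for_UMAP": True, "used_for_clustering": True,
            "used_for_scaffold": False,
        })
        mat = pd.DataFrame(rng.normal(size=(40, 7)), columns=channels)
        mat.to_csv(tmp_path / "trans_exp.csv", index=False)
        table = cs.load_matrix(tmp_path / "trans_exp.csv", None, markers, already_transformed=True)
        np.testing.assert_allclose(table.trans_expr, mat.to_numpy(), rtol=1e-12)
        assert table.raw_expr is None

    def test_extra_column_ignored_with_warning(self, tmp_path, rng):
        channels = ["m0", "m1"]
        markers = pd.DataFrame({
            "channel_name": channels, "marker_name": channels,
            "used_for_UMAP": True, "used_for_clustering": True,
            "used_for_scaffold": False,
        })
        mat = pd.DataFrame(rng.normal(size=(10, 2)), columns=channels)
        mat["unlisted"] = 1.0
        mat.to_csv(tmp_path / "m.csv", index=False)
        with pytest.warns(UserWarning, match="unlisted"):
            table = cs.load_matrix(tmp_path / "m.csv", None, markers)
        assert table.channels == channels

    def test_empty_matrix_rejected(self, tmp_path):
        channels = ["m0"]
        markers = pd.DataFrame({
            "channel_name": channels, "marker_name": channels,
            "used_for_UMAP": True, "used_for_clustering": True,
            "used_for_scaffold": False,
        })
        pd.DataFrame(columns=channels).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ValueError, match="empty input"):
            cs.load_matrix(tmp_path / "m.csv", None, markers)

    def test_row_count_mismatch_rejected(self, tmp_path, rng):
        channels = ["m0"]
        markers = pd.DataFrame({
            "channel_name": channels, "marker_name": channels,
            "used_for_UMAP": True, "used_for_clustering": True,
            "used_for_scaffold": False,
        })
        pd.DataFrame(rng.normal(size=(5, 1)), columns=channels).to_csv(
            tmp_path / "m.csv", index=False
        )
        pd.DataFrame({"cell_id": ["a", "b"]}).to_csv(tmp_path / "meta.csv", index=False)
        with pytest.raises(ValueError, match="alignment"):
            cs.load_matrix(tmp_path / "m.csv", tmp_path / "meta.csv", markers)


class TestBarcodes:
    def test_sample_underscore_index_format(self, dataset):
        table, _, _ = dataset
        first_file = table.cell_meta["file_name"].iloc[0].replace(".fcs", "")
        ids = table.cell_meta.loc[
            table.cell_meta["file_name"].str.startswith(first_file), "cell_id"
        ]
        assert ids.iloc[0] == f"{first_file}_1"
        assert ids.iloc[2] == f"{first_file}_3"

    def test_ids_globally_unique(self, dataset):
        table, _, _ = dataset
        assert table.cell_meta["cell_id"].is_unique

    def test_uniqueness_survives_filter_and_subsample(self, dataset):
        table, _, _ = dataset
        out = cs.subsample_per_file(cs.remove_controls(table), 100, seed=0)
        assert out.cell_meta["cell_id"].is_unique


class TestRemoveControls:
    def test_controls_dropped_order_preserved(self, dataset):
        table, files, _ = dataset
        out = cs.remove_controls(table)
        n_control = table.cell_meta["control_sample"].sum()
        assert len(out) == len(table) - n_control
        assert not out.cell_meta["control_sample"].any()
        kept = table.cell_meta.loc[~table.cell_meta["control_sample"], "cell_id"]
        assert out.cell_meta["cell_id"].tolist() == kept.tolist()

    def test_no_controls_is_identity(self, dataset):
        table, _, _ = dataset
        once = cs.remove_controls(table)
        twice = cs.remove_controls(once)
        assert len(once) == len(twice)

    def test_all_controls_yields_empty_with_warning(self, dataset):
        table, _, _ = dataset
        all_ctrl = table.take(np.arange(len(table)))
        all_ctrl.cell_meta["control_sample"] = True
        with pytest.warns(UserWarning, match="empty"):
            out = cs.remove_controls(all_ctrl)
        assert len(out) == 0


class TestSubsample:
    def test_capped_at_available(self, dataset):
        table, _, _ = dataset
        out = cs.subsample_per_file(table, 50_000, seed=1)
        assert len(out) == len(table)

    def test_exact_count_per_file(self, dataset):
        table, _, _ = dataset
        out = cs.subsample_per_file(table, 100, seed=1)
        counts = out.cell_meta["file_name"].value_counts()
        assert (counts == 100).all()
        assert len(out) == 100 * table.cell_meta["file_name"].nunique()

    def test_fixed_seed_bitwise_reproducible(self, dataset):
        table, _, _ = dataset
        a = cs.subsample_per_file(table, 120, seed=9)
        b = cs.subsample_per_file(table, 120, seed=9)
        assert a.cell_meta["cell_id"].tolist() == b.cell_meta["cell_id"].tolist()
        np.testing.assert_array_equal(a.raw_expr, b.raw_expr)

    def test_differing_seeds_overlap_near_hypergeometric(self):
        design = synth.default_design(n_files=1, events_per_file=10_000, seed=20)
        table, _, _ = synth.generate_dataset(design)
        k = 2_000
        a = set(cs.subsample_per_file(table, k, seed=1).cell_meta["cell_id"])
        b = set(cs.subsample_per_file(table, k, seed=2).cell_meta["cell_id"])
        overlap = len(a & b)
        dist = hypergeom(10_000, k, k)
        assert abs(overlap - dist.mean()) <= 3 * dist.std()

    def test_invalid_count_rejected(self, dataset):
        table, _, _ = dataset
        with pytest.raises(ValueError):
            cs.subsample_per_file(table, 0, seed=1)
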