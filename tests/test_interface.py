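"""I/O schemas, config loading, the pipeline driver and the CLI surface."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from dentalcascade.cli import main as cli_main
from dentalcascade.config import config_from_dict, load_config, \
    shipped_config_names
from dentalcascade.errors import PipelineStageError, SchemaError
from dentalcascade.io import (
    read_embryo_series, read_measurements, read_species_metadata,
    write_measurements, write_species_metadata,
)
from dentalcascade.pipeline import run_pipeline


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadMeasurements:
    def test_replicates_averaged_with_count(self, tmp_path):
        rows = ["species_id,individual_id,side,tooth,length_mm,width_mm"]
        for rep_val in (1.0, 2.0, 3.0):
            rows.append(f"spA,i1,L,M1,{rep_val},1.0")
        path = _write(tmp_path, "m.csv", "\n".join(rows) + "\n")
        out = read_measurements(path)
        assert len(out) == 1
        assert out.loc[0, "length_mm"] == pytest.approx(2.0)
        assert out.loc[0, "replicate_n"] == 3

    def test_empty_file_raises(self, tmp_path):
        path = _write(tmp_path, "m.csv", "")
        with pytest.raises(SchemaError, match="empty"):
            read_measurements(path)

    def test_unknown_tooth_label_names_row(self, tmp_path):
        path = _write(tmp_path, "m.csv",
                      "species_id,individual_id,side,tooth,length_mm,width_mm\n"
                      "spA,i1,L,M1,1.0,1.0\n"
                      "spA,i1,L,M4,1.0,1.0\n")
        with pytest.raises(SchemaError, match="M4.*row 2"):
            read_measurements(path)

    def test_nonpositive_measurement_names_row(self, tmp_path):
        path = _write(tmp_path, "m.csv",
                      "species_id,individual_id,side,tooth,length_mm,width_mm\n"
                      "spA,i1,R,M1,-1.0,1.0\n")
        with pytest.raises(SchemaError, match="length_mm.*row 1"):
            read_measurements(path)

    def test_missing_column_raises(self, tmp_path):
        path = _write(tmp_path, "m.csv", "species_id,tooth\nspA,M1\n")
        with pytest.raises(SchemaError, match="missing columns"):
            read_measurements(path)

    def test_roundtrip_identity_on_validated_representation(self, tmp_path):
        raw = _write(tmp_path, "m.csv",
                     "species_id,individual_id,side,tooth,length_mm,width_mm\n"
                     "spA,i1,L,M1,1.25,0.5\n"
                     "spA,i1,L,M1,1.75,0.5\n"
                     "spA,i1,R,M2,2.0,1.0\n")
        validated = read_measurements(raw)
        back = read_measurements(write_measurements(validated, tmp_path / "v.csv"))
        pd.testing.assert_frame_equal(validated, back)


class TestMetadataAndEmbryoReaders:
    def test_count_validation(self, tmp_path):
        path = _write(tmp_path, "meta.csv",
                      "species_id,jaw_length_mm,body_mass_g,diet,"
                      "premolar_count,molar_count\n"
                      "spA,20,15,fruit,5,3\n")
        with pytest.raises(SchemaError, match="0..3"):
            read_species_metadata(path)

    def test_duplicate_species_rejected(self, tmp_path):
        path = _write(tmp_path, "meta.csv",
                      "species_id,jaw_length_mm,body_mass_g,diet,"
                      "premolar_count,molar_count\n"
                      "spA,20,15,fruit,3,3\nspA,21,15,fruit,3,3\n")
        with pytest.raises(SchemaError, match="duplicate"):
            read_species_metadata(path)

    def test_embryo_stage_labels_validated(self, tmp_path):
        path = _write(tmp_path, "e.csv",
                      "species_id,stage,canine_to_P4_um\nsp,stage20,100\n")
        with pytest.raises(SchemaError, match="stage20"):
            read_embryo_series(path)


class TestConfig:
    @pytest.mark.parametrize("name", shipped_config_names())
    def test_shipped_configs_load(self, name):
        cfg = load_config(name)
        assert cfg.premolar.cascade == "premolar"
        assert cfg.molar.growth.direction == "posterior"
        assert cfg.t_end > 0

    def test_with_seed_reseeds_both_cascades(self):
        cfg = load_config("regular_jaw").with_seed(100)
        assert cfg.premolar.seed == 100 and cfg.molar.seed == 101

    def test_missing_cascade_block_rejected(self):
        with pytest.raises(ValueError, match="molar"):
            config_from_dict({"premolar": {}})

    def test_unknown_name_raises(self):
        with pytest.raises(FileNotFoundError, match="shipped"):
            load_config("nonexistent_jaw")

    def test_custom_yaml_file(self, tmp_path):
        cfg0 = load_config("regular_jaw")
        path = tmp_path / "custom.yaml"
        import yaml

        raw = dict(cfg0.raw)
        raw["t_end"] = 33.0
        path.write_text(yaml.safe_dump(raw))
        cfg = load_config(path)
        assert cfg.t_end == 33.0
        assert cfg.premolar.D_v == cfg0.premolar.D_v


@pytest.fixture(scope="module")
def pipeline_once(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe")
    overrides = {"n_species": {"3P3MR": 12, "3P3ML": 8, "2P3MR": 8, "2P2MS": 6},
                 "individuals_per_species": 1, "replicates": 1}
    report = run_pipeline(out, seed=5, generator_overrides=overrides,
                          simulations=("regular_jaw", "intermediate_jaw"))
    return out, report


class TestPipeline:
    def test_artifacts_and_manifest(self, pipeline_once):
        out, report = pipeline_once
        for name in ("measurements.csv", "species_metadata.csv",
                     "embryo_series.csv", "morphogroups.csv", "ic_molar.csv",
                     "locus_variability.csv", "growth_profiles.csv",
                     "events_regular_jaw.csv", "report.json", "report.md",
                     "manifest.json"):
            assert (out / name).exists(), name
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 5
        assert set(manifest["input_digests"]) == {
            "measurements.csv", "species_metadata.csv", "embryo_series.csv"}
        assert report["simulations"]["regular_jaw"]["premolar_count"] == 3
        assert report["simulations"]["intermediate_jaw"]["premolar_count"] == 2

    def test_rerun_reproduces_report(self, pipeline_once, tmp_path):
        out, _ = pipeline_once
        overrides = {"n_species": {"3P3MR": 12, "3P3ML": 8, "2P3MR": 8,
                                   "2P2MS": 6},
                     "individuals_per_species": 1, "replicates": 1}
        run_pipeline(tmp_path, seed=5, generator_overrides=overrides,
                     simulations=("regular_jaw", "intermediate_jaw"))
        assert (out / "report.json").read_bytes() == \
            (tmp_path / "report.json").read_bytes()
        assert (out / "events_regular_jaw.csv").read_bytes() == \
            (tmp_path / "events_regular_jaw.csv").read_bytes()

    def test_stage_failure_names_stage(self, tmp_path):
        with pytest.raises(PipelineStageError, match="synthesize"):
            run_pipeline(tmp_path, seed=0,
                         generator_overrides={"noise_cv": -1.0})


class TestCLI:
    def test_synth_and_ic_test_roundtrip(self, tmp_path):
        runner = CliRunner()
        spec = tmp_path / "spec.yaml"
        spec.write_text("n_species: {3P3MR: 15}\nnoise_cv: 0.0\n"
                        "individuals_per_species: 1\nreplicates: 1\n"
                        "ic_conformity_rate: {molar: 1.0, premolar: 0.0}\n")
        r = runner.invoke(cli_main, ["synth", "species", "--spec", str(spec),
                                     "--seed", "2", "--out", str(tmp_path)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["ic-test", "--input",
                                     str(tmp_path / "measurements.csv"),
                                     "--triplet", "molar",
                                     "--out", str(tmp_path)])
        assert r.exit_code == 0, r.output
        occ = json.loads((tmp_path / "ic_molar_occupancy.json").read_text())
        assert occ["percent_inside"] == 100.0
        assert "100.0%" in r.output

    def test_morpho_classify(self, tmp_path):
        runner = CliRunner()
        runner.invoke(cli_main, ["synth", "species", "--seed", "2",
                                 "--out", str(tmp_path)])
        r = runner.invoke(cli_main, ["morpho", "classify", "--metadata",
                                     str(tmp_path / "species_metadata.csv"),
                                     "--out", str(tmp_path)])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "morphogroups.csv").exists()

    def test_simulate_subcommand(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["simulate", "--config", "intermediate_jaw",
                                     "--out", str(tmp_path)])
        assert r.exit_code == 0, r.output
        events = pd.read_csv(tmp_path / "events.csv")
        assert set(events["cascade"]) == {"premolar", "molar"}
        assert (tmp_path / "manifest.json").exists()
        assert "premolar: 2 insertions" in r.output
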