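"""Model/Results surface, full pipeline orchestration and CLI plumbing."""

import json
import os

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from netgof import (
    NetworkCorrespondenceModel,
    SyntheticCohortSpec,
    Volume3D,
    generate_cohort,
    generate_parcellation,
    load_config,
    run_pipeline,
    simulate_zmaps,
    write_volume,
)
from netgof.atlas import write_lookup
from netgof.cli import main as cli_main
from netgof.pipeline import StageError
from netgof.volume import write_mask


SPEC = SyntheticCohortSpec(shape=(20, 20, 20), n_controls=6, n_patients=6, seed=9)


@pytest.fixture(scope="module")
def cohort_dir(tmp_path_factory):
    """Materialize a small simulated cohort on disk, as real data would be."""
    root = tmp_path_factory.mktemp("cohort")
    atlas, reference, cortex = generate_parcellation(SPEC)
    controls, patients = generate_cohort(SPEC, atlas, reference)
    write_volume(Volume3D(atlas.labels.astype(float), SPEC.voxel_size_mm),
                 root / "atlas.nii.gz")
    write_lookup({7: atlas.names}, root / "lookup.tsv")
    write_mask(reference, root / "reference.nii.gz", SPEC.voxel_size_mm)
    for group, vols in (("control", controls), ("patient", patients)):
        for i, v in enumerate(vols):
            write_volume(v, root / f"{group}-{i:02d}.nii.gz")
    return root


def write_config(cohort_dir, out_dir, **overrides):
    cfg = {
        "controls": str(cohort_dir / "control-*.nii.gz"),
        "patients": str(cohort_dir / "patient-*.nii.gz"),
        "reference_mask": str(cohort_dir / "reference.nii.gz"),
        "levels": [{"level": 7, "atlas": str(cohort_dir / "atlas.nii.gz"),
                    "lookup": str(cohort_dir / "lookup.tsv")}],
        "out_dir": str(out_dir),
        "fwhm_mm": 0.0,
        "alpha_fw": 0.05,
    }
    cfg.update(overrides)
    path = out_dir / "config.yaml"
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)
    return path


class TestModel:
    def test_fit_results_surface(self):
        zmaps, _, atlas, _ = simulate_zmaps(SPEC)
        res = NetworkCorrespondenceModel(zmaps, atlas).fit(alpha_fw=0.05)
        assert res.n_subjects == 6
        assert res.level == 7
        assert len(res.summary_frame) == 14
        assert res.alpha_corrected == pytest.approx(0.05 / 7)
        assert sorted(res.ranking) == list(range(1, 8))
        text = res.summary()
        assert "Bonferroni-corrected alpha = 0.007" in text
        assert "Ranking by mean Z" in text

    def test_from_scores_round_trip(self):
        zmaps, _, atlas, _ = simulate_zmaps(SPEC)
        direct = NetworkCorrespondenceModel(zmaps, atlas).fit()
        rebuilt = NetworkCorrespondenceModel.from_scores(direct.scores, atlas).fit()
        pd.testing.assert_frame_equal(direct.summary_frame, rebuilt.summary_frame)

    def test_empty_model_rejected(self):
        atlas, _, _ = generate_parcellation(SPEC)
        with pytest.raises(ValueError, match="neither"):
            NetworkCorrespondenceModel(None, atlas).fit()


class TestPipeline:
    def test_end_to_end_outputs(self, cohort_dir, tmp_path):
        cfg_path = write_config(cohort_dir, tmp_path / "run1")
        report = run_pipeline(load_config(cfg_path))
        assert 7 in report.summaries
        assert len(report.summaries[7]) == 14
        for path in report.table_paths.values():
            assert os.path.exists(path)
        assert os.path.exists(report.mean_zmap_paths[7])
        with open(tmp_path / "run1" / "run_report.json") as fh:
            payload = json.load(fh)
        assert payload["alpha_corrected_displayed"]["7"] == "0.007"
        assert payload["provenance"]["config_hash"]

    def test_rendered_tables_have_seven_rows_and_3dp(self, cohort_dir, tmp_path):
        cfg_path = write_config(cohort_dir, tmp_path / "run2")
        report = run_pipeline(load_config(cfg_path))
        for metric in ("mean_z", "gof"):
            table = pd.read_csv(report.table_paths[f"cohort_a/level7/{metric}"], sep="\t",
                                dtype=str)
            assert len(table) == 7
            assert list(table.columns) == ["Network", "Mean", "SD", "t",
                                           "p(2-tailed)", "Significant"]
            assert all(len(v.split(".")[-1]) == 3 for v in table["Mean"])

    def test_idempotent_byte_identical_tsvs(self, cohort_dir, tmp_path):
        cfg1 = write_config(cohort_dir, tmp_path / "runA")
        cfg2 = write_config(cohort_dir, tmp_path / "runB")
        r1 = run_pipeline(load_config(cfg1))
        r2 = run_pipeline(load_config(cfg2))
        for key in r1.table_paths:
            with open(r1.table_paths[key], "rb") as f1, open(r2.table_paths[key], "rb") as f2:
                assert f1.read() == f2.read()

    def test_summary_rows_recompute_from_scores_file(self, cohort_dir, tmp_path):
        from netgof import summary_t

        cfg_path = write_config(cohort_dir, tmp_path / "run3")
        report = run_pipeline(load_config(cfg_path))
        scores = pd.read_csv(report.table_paths["cohort_a/level7/scores"], sep="\t")
        summary = report.summaries[7]
        for _, row in summary[summary["metric"] == "mean_z"].iterrows():
            vals = scores.loc[scores["network_id"] == row["network_id"], "mean_z"]
            res = summary_t(vals.mean(), vals.std(ddof=1), len(vals))
            assert row["t"] == pytest.approx(res.t, abs=5e-5)  # scores stored at 6 d.p.

    def test_missing_atlas_aborts_naming_stage(self, cohort_dir, tmp_path):
        cfg_path = write_config(
            cohort_dir, tmp_path / "run4",
            levels=[{"level": 7, "atlas": str(tmp_path / "absent.nii.gz"),
                     "lookup": str(cohort_dir / "lookup.tsv")}],
        )
        with pytest.raises(StageError, match=r"\[stage: load-atlas\].*absent"):
            run_pipeline(load_config(cfg_path))

    def test_second_cohort_produces_cross_correlation(self, cohort_dir, tmp_path):
        cfg_path = write_config(
            cohort_dir, tmp_path / "run5",
            cohort_b={"controls": str(cohort_dir / "control-*.nii.gz"),
                      "patients": str(cohort_dir / "patient-*.nii.gz"),
                      "name": "replica"},
        )
        report = run_pipeline(load_config(cfg_path))
        assert report.cross_cohort is not None
        # identical cohorts: r is exactly 1
        assert report.cross_cohort["r"] == pytest.approx(1.0)


class TestCLI:
    def test_simulate_and_group_stats_commands(self, tmp_path):
        runner = CliRunner()
        spec_file = tmp_path / "spec.yaml"
        with open(spec_file, "w") as fh:
            yaml.safe_dump({"shape": [16, 16, 16], "n_controls": 3, "n_patients": 3,
                            "seed": 4}, fh)
        out_dir = tmp_path / "sim"
        result = runner.invoke(cli_main, ["simulate", "--spec", str(spec_file),
                                          "--out-dir", str(out_dir)])
        assert result.exit_code == 0, result.output
        manifest = pd.read_csv(out_dir / "manifest.tsv", sep="\t")
        assert len(manifest) == 6
        assert set(manifest["group"]) == {"control", "patient"}
        assert (out_dir / "atlas.nii.gz").exists()
        assert (out_dir / "lookup.tsv").exists()

    def test_preprocess_command(self, tmp_path, rng):
        runner = CliRunner()
        vol = Volume3D(rng.uniform(1, 2, (8, 8, 8)), (2, 2, 2))
        write_volume(vol, tmp_path / "suv.nii.gz")
        mask = np.zeros((8, 8, 8)); mask[:2] = 1
        write_volume(Volume3D(mask, (2, 2, 2)), tmp_path / "ref.nii.gz")
        result = runner.invoke(cli_main, [
            "preprocess", "--suv", str(tmp_path / "suv.nii.gz"),
            "--reference-mask", str(tmp_path / "ref.nii.gz"),
            "--fwhm", "0", "--out", str(tmp_path / "suvr.nii.gz")])
        assert result.exit_code == 0, result.output
        from netgof import read_volume
        out = read_volume(tmp_path / "suvr.nii.gz")
        assert out.data[mask.astype(bool)].mean() == pytest.approx(1.0, abs=1e-12)
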