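import dataclasses

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from mviradiomics import CohortSpec, MDTFusion, RunConfig, generate_cohort, run_study
from mviradiomics.cli import main as cli_main
from mviradiomics.features.extract import PhaseCombo
from mviradiomics.io import read_case, read_cohort, write_case, write_cohort
from mviradiomics.voi import build_region_set

from oracles import brute_expand_region


@pytest.fixture(scope="module")
def tiny_cohort(small_spec):
    spec = dataclasses.replace(small_spec, n_patients=12, prevalence=0.5,
                               effect_intensity=20.0)
    return generate_cohort(spec)


@pytest.fixture(scope="module")
def fitted(tiny_cohort):
    cases, _ = tiny_cohort
    mdl = MDTFusion.from_cohort(
        cases, distances_mm=(4.0, 12.0), phases=("EAP", "PVP"),
        region_ids=["core", "combined:4", "combined:12"],
    )
    res = mdl.fit(
        selectors=("t_score", "f_score", "trace_ratio"),
        classifiers=("logistic",),
        n_train=10,
        n_splits=5,
        seed=0,
    )
    return mdl, res


class TestMDTFusion:
    def test_benchmark_covers_requested_grid(self, fitted):
        _, res = fitted
        # 3 phase combos (EAP, PVP, EAP+PVP) x 3 regions x 3 selectors
        assert len(res.results) == 3 * 3 * 3
        assert set(res.table["phase_combo"]) == {"Fpha1", "Fpha3", "Fpha1;3"}

    def test_matrix_is_phase_prefixed(self, fitted):
        mdl, _ = fitted
        m = mdl.matrix(PhaseCombo(("EAP", "PVP")), "core")
        assert m.shape[1] == 188
        assert all(c.startswith(("EAP_", "PVP_")) for c in m.columns)

    def test_top3_and_fusion_outputs(self, fitted):
        _, res = fitted
        assert len(res.top_models) == 3
        perf = res.performance_table()
        assert set(perf.index[-2:]) == {"PV", "WF"}
        assert res.nri_matrix.shape == (5, 5)
        assert np.allclose(res.nri_matrix.values, -res.nri_matrix.values.T)

    def test_summary_renders(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "top models" in text
        assert "WF" in text and "PV" in text

    def test_fit_deterministic(self, fitted, tiny_cohort):
        mdl, res = fitted
        res2 = mdl.fit(
            selectors=("t_score", "f_score", "trace_ratio"),
            classifiers=("logistic",),
            n_train=10,
            n_splits=5,
            seed=0,
        )
        pd.testing.assert_frame_equal(res.table, res2.table)

    def test_no_leakage_from_test_labels(self, fitted, tiny_cohort):
        """Scrambling the held-out labels leaves every CV metric unchanged."""
        mdl, res = fitted
        flipped = mdl.labels.copy()
        flipped.iloc[10:] = 1 - flipped.iloc[10:]
        mdl2 = MDTFusion(mdl.feature_store, flipped, mdl.chronological_index)
        res2 = mdl2.fit(
            selectors=("t_score", "f_score", "trace_ratio"),
            classifiers=("logistic",),
            n_train=10,
            n_splits=5,
            seed=0,
        )
        pd.testing.assert_frame_equal(res.table, res2.table)

    def test_plots_return_axes(self, fitted):
        import matplotlib

        matplotlib.use("Agg")
        _, res = fitted
        assert res.plot_distance_trend() is not None
        assert res.plot_nri_matrix() is not None


class TestIO:
    def test_case_round_trip(self, tiny_cohort, tmp_path):
        cases, _ = tiny_cohort
        case = cases[0]
        write_case(case, tmp_path)
        back = read_case(tmp_path / case.case_id, case.mvi_label,
                         case.chronological_index)
        assert np.array_equal(back.tumor_mask, case.tumor_mask)
        assert np.array_equal(back.liver_mask, case.liver_mask)
        for p, vol in case.phase_volumes.items():
            assert np.array_equal(back.phase_volumes[p], vol)
        assert back.spacing_mm == pytest.approx(case.spacing_mm)

    def test_cohort_round_trip(self, tiny_cohort, tmp_path):
        cases, table = tiny_cohort
        write_cohort(cases[:3], table.iloc[:3], tmp_path / "cohort")
        back_cases, back_table = read_cohort(tmp_path / "cohort")
        assert len(back_cases) == 3
        assert back_table["mvi_label"].tolist() == table["mvi_label"][:3].tolist()

    def test_shape_mismatch_reported(self, tiny_cohort, tmp_path):
        import nibabel as nib

        cases, _ = tiny_cohort
        out = write_case(cases[0], tmp_path)
        bad = np.zeros((4, 4, 4), dtype=np.uint8)
        nib.save(nib.Nifti1Image(bad, np.eye(4)), out / "mask_liver.nii.gz")
        with pytest.raises(ValueError, match="mismatch"):
            read_case(out)

    def test_anisotropic_spacing_preserved_through_regions(self, tmp_path):
        """Ring volumes built after a NIfTI round trip match the brute-force
        oracle at (1, 1, 3) mm spacing."""
        from mviradiomics.synthetic import PhantomCase

        shape = (12, 12, 6)
        tumor = np.zeros(shape, bool)
        tumor[5:7, 5:7, 2:4] = True
        liver = np.ones(shape, bool)
        case = PhantomCase(
            case_id="aniso",
            phase_volumes={p: np.zeros(shape, np.int16)
                           for p in ("EAP", "LAP", "PVP", "EP")},
            liver_mask=liver,
            tumor_mask=tumor,
            vessel_mask=np.zeros(shape, bool),
            bileduct_mask=np.zeros(shape, bool),
            spacing_mm=(1.0, 1.0, 3.0),
            mvi_label=0,
        )
        write_case(case, tmp_path)
        back = read_case(tmp_path / "aniso")
        assert back.spacing_mm == pytest.approx((1.0, 1.0, 3.0))
        rs = build_region_set(back.tumor_mask, back.liver_mask, None,
                              back.spacing_mm, (2.0, 4.0))
        for d in (2.0, 4.0):
            want = brute_expand_region(tumor, liver, None, (1, 1, 3), d)
            assert np.array_equal(rs.rings[d], want)


class TestRunStudy:
    def _config(self, tmp_path, name):
        cohort = CohortSpec(
            n_patients=10, prevalence=0.5, volume_shape=(32, 32, 32),
            spacing_mm=(2.0, 2.0, 2.0), tumor_radius_mm=(7.0, 9.0),
            effect_intensity=20.0,
        )
        return RunConfig(
            cohort=cohort,
            distances_mm=(4.0, 12.0),
            selectors=("t_score", "f_score", "trace_ratio"),
            classifiers=("logistic",),
            n_train=8,
            n_cv_splits=4,
            master_seed=5,
            out_dir=str(tmp_path / name),
        )

    def test_end_to_end_bundle(self, tmp_path):
        bundle = run_study(self._config(tmp_path, "run1"))
        out = bundle["out_dir"]
        for f in ("cohort.csv", "benchmark.csv", "phase_region_auc.csv",
                  "distance_trend.csv", "top3_fusion_metrics.csv",
                  "nri_matrix.csv", "feature_census.csv", "run_log.json"):
            assert (out / f).exists(), f
        # 15 phase combos x (core + 2 rings + 2 combined) x 3 selectors
        assert len(bundle["results"].results) == 15 * 5 * 3

    def test_rerun_reproduces_results(self, tmp_path):
        b1 = run_study(self._config(tmp_path, "a"))
        b2 = run_study(self._config(tmp_path, "b"))
        t1 = pd.read_csv(b1["out_dir"] / "benchmark.csv")
        t2 = pd.read_csv(b2["out_dir"] / "benchmark.csv")
        pd.testing.assert_frame_equal(t1, t2)


class TestCLI:
    def test_synth_voi_features_chain(self, tmp_path):
        runner = CliRunner()
        spec_yaml = tmp_path / "spec.yaml"
        spec_yaml.write_text(yaml.safe_dump({
            "n_patients": 2, "prevalence": 0.5,
            "volume_shape": [32, 32, 32], "spacing_mm": [2.0, 2.0, 2.0],
            "tumor_radius_mm": [7.0, 9.0],
        }))
        out = tmp_path / "cohort"
        r = runner.invoke(cli_main, ["synth", "--spec", str(spec_yaml),
                                     "--out", str(out), "--seed", "3"])
        assert r.exit_code == 0, r.output
        case_dir = out / "case0000"
        assert (case_dir / "PVP.nii.gz").exists()

        vdir = tmp_path / "voi"
        r = runner.invoke(cli_main, ["voi", "--case", str(case_dir),
                                     "--distances", "4,12", "--out", str(vdir)])
        assert r.exit_code == 0, r.output
        assert (vdir / "combined_12.nii.gz").exists()

        feat = tmp_path / "features.csv"
        r = runner.invoke(cli_main, [
            "features", "--image", str(case_dir / "PVP.nii.gz"),
            "--mask", str(vdir / "combined_12.nii.gz"), "--out", str(feat),
        ])
        assert r.exit_code == 0, r.output
        df = pd.read_csv(feat, index_col=0)
        assert len(df) == 94
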