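"""Canonical file formats, the screening pipeline and the CLI verbs."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from simstitch import io as sio
from simstitch.chem import PanelConfig, builtin_molecule
from simstitch.cli import main as cli_main
from simstitch.errors import ConsistencyError, FormatError
from simstitch.metrics import ccs_from_reduced_mobility
from simstitch.screen import percent_detected, run_screen
from simstitch.simulate import SimConfig, SimPeakSpec, make_enantiomer_fixture, \
    simulate_segments
from simstitch.stitching import Segment


class TestSegmentRoundTrip:
    def test_write_then_read_preserves_values(self, paper_plan, tmp_path):
        cfg = SimConfig(plan=paper_plan, seed=4)
        peak = SimPeakSpec(mz=292.048, apex_inv_k0=0.9, sigma_inv_k0=0.0025,
                           height=1000.0)
        segments = simulate_segments([peak], cfg)
        path = tmp_path / "segments.tsv"
        sio.write_segments(segments, path)
        back = sio.read_segments(path)
        assert len(back) == len(segments)
        for a, b in zip(segments, back):
            assert np.allclose(a.inv_k0, b.inv_k0, rtol=1e-9)
            assert np.allclose(a.intensity, b.intensity, rtol=1e-9)
            assert a.window == b.window

    def test_negative_intensity_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "segment_id\twindow_start\twindow_end\tinv_k0\tmz\tintensity\n"
            "seg0\t0.70\t0.85\t0.72\t100.0\t5.0\n"
            "seg0\t0.70\t0.85\t0.73\t100.0\t-1.0\n")
        with pytest.raises(FormatError, match="line 3"):
            sio.read_segments(path)

    def test_missing_header_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("segment_id\tinv_k0\tintensity\nseg0\t0.72\t5.0\n")
        with pytest.raises(FormatError, match="window_start"):
            sio.read_segments(path)

    def test_out_of_window_record_names_segment(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "segment_id\twindow_start\twindow_end\tinv_k0\tmz\tintensity\n"
            "segA\t0.70\t0.85\t0.72\t100.0\t5.0\n"
            "segA\t0.70\t0.85\t0.90\t100.0\t5.0\n")
        with pytest.raises(ConsistencyError, match="segA"):
            sio.read_segments(path)


def test_plan_json_round_trip(paper_plan, tmp_path):
    path = tmp_path / "plan.json"
    sio.write_plan(paper_plan, path, metadata={"note": "x"})
    back = sio.read_plan(path)
    assert back == paper_plan


def test_calibration_table_reader(tmp_path):
    path = tmp_path / "cal.csv"
    path.write_text("measured_coordinate,reference_inv_k0\n1.0,0.6\n2.0,1.1\n")
    pairs = sio.read_calibration_table(path)
    assert pairs == [(1.0, 0.6), (2.0, 1.1)]
    bad = tmp_path / "bad.csv"
    bad.write_text("x,y\n1,2\n")
    with pytest.raises(FormatError):
        sio.read_calibration_table(bad)


def test_percent_detected_rounds_to_nearest_integer():
    assert percent_detected(91, 153) == 59
    assert percent_detected(0, 153) == 0
    assert percent_detected(153, 153) == 100


def _panel(analyte_names):
    analytes = tuple(builtin_molecule(n, role="analyte") for n in analyte_names)
    selectors = (builtin_molecule("Phe", role="selector"),
                 builtin_molecule("Pro", role="selector"))
    return PanelConfig(analytes=analytes, selectors=selectors)


class TestRunScreen:
    def test_empty_runs_report_all_nd(self, paper_plan, identity_model):
        panel = _panel(["Ile", "Glu"])
        empty = [Segment(w, np.array([]), np.array([]), np.array([]))
                 for w in paper_plan.windows]
        report = run_screen(panel, {"L": empty, "D": empty, "mix": empty},
                            paper_plan, identity_model)
        assert report.possible == 18
        assert report.detected == 0
        assert report.percent_detected == 0
        df = report.to_dataframe()
        assert (df == "nd").all().all()
        assert df.shape == (2, 9)

    def test_one_analyte_panel_has_nine_columns(self, paper_plan, identity_model):
        panel = _panel(["Ile"])
        report = run_screen(panel, {}, paper_plan, identity_model)
        assert len(report.columns) == 9
        assert report.possible == 9

    def test_detected_channel_classified(self, paper_plan, identity_model):
        panel = _panel(["Ile"])
        # give every one of the 9 channels a separable enantiomer pair
        from simstitch.chem import enumerate_complexes
        specs = enumerate_complexes(panel.analytes, panel.selectors)
        cfg = SimConfig(plan=paper_plan, seed=6)
        coeff = ccs_from_reduced_mobility(1.0, specs[0].mz, 1,
                                          model=identity_model)
        runs = {"L": [], "D": [], "mix": []}
        merged = {r: None for r in runs}
        for i, spec in enumerate(specs):
            ccs_L = (0.80 + 0.03 * i) * ccs_from_reduced_mobility(
                1.0, spec.mz, 1, model=identity_model)
            fix, _ = make_enantiomer_fixture(spec, ccs_L, 1.3, 150,
                                             identity_model,
                                             SimConfig(plan=paper_plan, seed=6 + i))
            for r in runs:
                if merged[r] is None:
                    merged[r] = fix[r]
                else:
                    merged[r] = [
                        Segment(a.window,
                                np.concatenate([a.inv_k0, b.inv_k0]),
                                np.concatenate([a.mz, b.mz]),
                                np.concatenate([a.intensity, b.intensity]),
                                segment_id=a.segment_id)
                        for a, b in zip(merged[r], fix[r])]
        report = run_screen(panel, merged, paper_plan, identity_model)
        assert report.possible == 9
        assert report.detected == 9
        assert report.percent_detected == 100
        assert report.separated_baseline >= 8
        summary = report.summary()
        assert summary["possible"] == summary["detected"] + sum(
            1 for oc in report.outcomes if not oc.detected)

    def test_report_cells_render_delta_to_one_decimal(self, paper_plan,
                                                      identity_model):
        from simstitch.metrics import SeparationResult, delta_ccs_percent
        from simstitch.screen import ScreenReport
        res = SeparationResult(complex_label="x", ccs_A=200.0, ccs_B=202.6,
                               delta_ccs_pct=delta_ccs_percent(200.0, 202.6),
                               classification="baseline")
        assert ScreenReport.render_cell(res) == "1.3"
        res_nd = SeparationResult(complex_label="x")
        assert ScreenReport.render_cell(res_nd) == "nd"
        res_none = SeparationResult(complex_label="x", classification="none")
        assert ScreenReport.render_cell(res_none) == "-"


class TestCli:
    def test_plan_verb_prints_reference_windows(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["plan", "--start", "0.70",
                                          "--end", "1.15"])
        assert result.exit_code == 0
        doc = json.loads(result.output)
        assert doc["windows"] == [[0.70, 0.85], [0.80, 0.95],
                                  [0.90, 1.05], [1.00, 1.15]]
        assert doc["interior_boundaries"] == [0.85, 0.95, 1.05]

    def test_enumerate_verb_counts_channels(self, tmp_path):
        panel = tmp_path / "panel.yaml"
        panel.write_text("analytes: [Ile, Glu]\nselectors: [Phe, Pro]\n")
        runner = CliRunner()
        result = runner.invoke(cli_main, ["enumerate", "--panel", str(panel)])
        assert result.exit_code == 0
        lines = [l for l in result.output.strip().splitlines() if l]
        assert len(lines) == 1 + 18   # header + 9 per analyte

    def test_screen_verb_end_to_end(self, tmp_path, paper_plan, identity_model,
                                    pro_dimer):
        panel = tmp_path / "panel.yaml"
        panel.write_text("analytes: [Ile]\nselectors: [Phe, Pro]\n")
        plan_path = tmp_path / "plan.json"
        sio.write_plan(paper_plan, plan_path)
        from simstitch.chem import enumerate_complexes
        spec = enumerate_complexes((builtin_molecule("Ile"),),
                                   (builtin_molecule("Phe"),
                                    builtin_molecule("Pro")))[0]
        coeff = ccs_from_reduced_mobility(1.0, spec.mz, 1, model=identity_model)
        fix, _ = make_enantiomer_fixture(spec, 0.9 * coeff, 1.3, 150,
                                         identity_model,
                                         SimConfig(plan=paper_plan, seed=2))
        run_args = []
        for r, segs in fix.items():
            p = tmp_path / f"{r}.tsv"
            sio.write_segments(segs, p)
            run_args += ["--run", f"{r}={p}"]
        runner = CliRunner()
        with runner.isolated_filesystem(temp_dir=tmp_path):
            result = runner.invoke(cli_main, ["screen", "--panel", str(panel),
                                              "--plan", str(plan_path)]
                                   + run_args + ["-o", "out"])
            assert result.exit_code == 0, result.output
            assert "complexes possible: 9" in result.output
            assert "complexes detected: 1" in result.output
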