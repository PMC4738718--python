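import numpy as np
import pytest
from click.testing import CliRunner

from lisawave.cli import main as cli_main
from lisawave.errors import ConfigError, InsufficientExtentError, LisaWaveError
from lisawave.io import (
    load_config,
    load_profile_csv,
    save_profile_csv,
    write_vtk_snapshot,
)
from lisawave.measurement import estimate_wavelength_peaks
from lisawave.scenarios import phantom_presets, run_preset
from lisawave.synthetic import SyntheticWaveSpec, make_synthetic_profile


class TestSyntheticGenerator:
    def test_pure_sinusoid_when_no_decay_no_noise(self):
        spec = SyntheticWaveSpec(wavelength=10e-3, extent=0.05, sampling=0.5e-3)
        prof = make_synthetic_profile(spec)
        expected = spec.amplitude * np.sin(2 * np.pi * prof.positions / 10e-3)
        assert np.allclose(prof.displacements, expected, atol=1e-20)

    def test_seeded_regeneration_is_byte_identical(self):
        spec = SyntheticWaveSpec(
            wavelength=10e-3, extent=0.05, sampling=0.5e-3,
            noise_sd=1e-8, seed=42,
        )
        a = make_synthetic_profile(spec)
        b = make_synthetic_profile(spec)
        assert a.displacements.tobytes() == b.displacements.tobytes()

    def test_noisy_profile_estimator_recovers_wavelength(self):
        spec = SyntheticWaveSpec(
            wavelength=21e-3, extent=0.1, sampling=0.5e-3,
            decay_length=40e-3, noise_sd=1e-6 / 50.0, seed=7,
        )
        est = estimate_wavelength_peaks(make_synthetic_profile(spec))
        assert abs(est.mean - 21e-3) <= 0.5e-3

    def test_insufficient_extent_rejected(self):
        with pytest.raises(InsufficientExtentError):
            SyntheticWaveSpec(wavelength=30e-3, extent=0.1, sampling=0.5e-3)


class TestProfileCsv:
    def test_round_trip_lossless(self, tmp_path):
        prof = make_synthetic_profile(
            SyntheticWaveSpec(
                wavelength=5e-3, extent=0.5, sampling=0.5e-3,
                noise_sd=1e-7, seed=3,
            )
        )
        path = tmp_path / "profile.csv"
        save_profile_csv(prof, path)
        back = load_profile_csv(path)
        assert np.array_equal(back.positions, prof.positions)
        assert np.array_equal(back.displacements, prof.displacements)

    def test_malformed_rows_name_the_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("position_m,displacement_m\n0.0,1.0\nnot,a,row\n")
        with pytest.raises(LisaWaveError, match="line 3"):
            load_profile_csv(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x,y\n0,1\n")
        with pytest.raises(LisaWaveError, match="line 1"):
            load_profile_csv(path)


class TestVtkWriter:
    def test_structured_points_layout(self, tmp_path):
        snap = np.zeros((3, 10, 10, 5))
        path = tmp_path / "snap.vtk"
        write_vtk_snapshot(path, snap, (1e-3, 1e-3, 1e-3))
        lines = path.read_text().splitlines()
        assert lines[0].startswith("# vtk DataFile")
        assert "DATASET STRUCTURED_POINTS" in lines
        assert "DIMENSIONS 10 10 5" in lines
        assert "POINT_DATA 500" in lines
        assert sum(1 for l in lines if l.startswith("SCALARS")) == 3
        # 3 fields x 500 points of data values
        n_values = sum(
            1 for l in lines if l and not l[0].isalpha() and not l.startswith("#")
        )
        assert n_values == 3 * 500


class TestConfig:
    def _write(self, tmp_path, text):
        p = tmp_path / "cfg.yaml"
        p.write_text(text)
        return p

    def test_valid_config_loads(self, tmp_path):
        cfg = load_config(
            self._write(
                tmp_path,
                """
material: {E: 90000.0, nu: 0.495, rho: 1000.0}
grid: {kind: strip, length: 0.2, thickness: 0.02, spacing: 1.0e-3}
excitation: {frequency: 150.0}
bc: [{region: bottom, fix: y}]
run: {n_cycles: 3}
scaling: {S: 1}
""",
            )
        )
        assert cfg["material"]["E"] == 90000.0

    def test_unknown_key_named(self, tmp_path):
        with pytest.raises(ConfigError, match="material.youngs"):
            load_config(
                self._write(
                    tmp_path,
                    """
material: {youngs: 1, E: 1, nu: 0.3, rho: 1}
grid: {kind: strip, length: 0.1, thickness: 0.02, spacing: 1.0e-3}
""",
                )
            )

    def test_missing_required_key_named(self, tmp_path):
        with pytest.raises(ConfigError, match="material.E"):
            load_config(
                self._write(
                    tmp_path,
                    """
material: {nu: 0.3, rho: 1}
grid: {kind: strip, length: 0.1, thickness: 0.02, spacing: 1.0e-3}
""",
                )
            )


class TestPresets:
    def test_study_matrix_is_complete(self):
        presets = phantom_presets()
        names = {p.name for p in presets}
        assert len(presets) == 15
        assert {"phantom_E90k", "bc_20mm_yfixed", "bc_40mm_free"} <= names
        bulk = [p for p in presets if p.name.startswith("bulk_")]
        assert len(bulk) == 9
        assert all(p.expected_wavelength is not None for p in bulk)

    @pytest.mark.parametrize("preset", phantom_presets(), ids=lambda p: p.name)
    def test_every_preset_runs_end_to_end_at_reduced_scale(self, preset):
        grid, records = run_preset(preset)
        assert int(np.prod(grid.node_shape)) <= 5e5
        snap = next(iter(records.snapshots.values()))
        assert np.isfinite(snap).all()
        assert np.abs(snap).max() > 0


class TestCli:
    def test_table1_and_stability_exit_zero(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["table1"])
        assert res.exit_code == 0
        assert "rho,S,V_L" in res.output
        res = runner.invoke(
            cli_main,
            ["stability", "--E", "90e3", "--nu", "0.495", "--rho", "1000",
             "--dx", "1e-3", "--dt", "5e-8"],
        )
        assert res.exit_code == 0
        assert "stable" in res.output

    def test_measure_and_rescale_pipeline(self, tmp_path):
        prof = make_synthetic_profile(
            SyntheticWaveSpec(wavelength=12e-3, extent=0.06, sampling=0.5e-3)
        )
        src = tmp_path / "p.csv"
        save_profile_csv(prof, src)
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["measure", "--in", str(src), "--frequency", "150",
             "--density", "1000"],
        )
        assert res.exit_code == 0
        assert "wavelength" in res.output and "shear modulus" in res.output
        out = tmp_path / "r.csv"
        res = runner.invoke(
            cli_main, ["rescale", "--factor", "3", "--in", str(src), "--out", str(out)]
        )
        assert res.exit_code == 0
        rescaled = load_profile_csv(out)
        assert rescaled.positions[-1] == pytest.approx(
            prof.positions[-1] * np.sqrt(3.0)
        )

    def test_dispersion_curve_csv(self, tmp_path):
        out = tmp_path / "curve.csv"
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["dispersion", "--E", "90e3", "--nu", "0.495", "--rho", "1000",
             "--thickness", "0.02", "--freq", "150", "--bc-bottom", "yfixed",
             "--out", str(out)],
        )
        assert res.exit_code == 0
        lines = out.read_text().splitlines()
        assert lines[0] == "frequency_hz,wavenumber_rad_per_m,wavelength_m,mode"
        assert len(lines) >= 2

    def test_simulate_from_config(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "material: {E: 90.0e3, nu: 0.495, rho: 1000.0}\n"
            "grid: {kind: strip, length: 0.06, thickness: 0.02, spacing: 2.0e-3}\n"
            "excitation: {frequency: 150.0}\n"
            "bc: [{region: bottom, fix: y}]\n"
            "run: {n_steps: 60}\n"
        )
        out = tmp_path / "out"
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["simulate", "--config", str(cfg), "--out", str(out),
             "--snapshot-every", "30"],
        )
        assert res.exit_code == 0, res.output
        assert list(out.glob("profile_step*.csv"))
        assert list(out.glob("snapshot_step*.vtk"))
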