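import hashlib
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from thzcryst.optics import extract_optical_constants
from thzcryst.spectral_fit import quadratic
from thzcryst.synthetic_study import (
    DEFAULT_AMORPHOUS_BACKGROUND,
    KineticsParams,
    PhaseFractions,
    PulseParams,
    StudyRefs,
    compose_absorption,
    default_reference_model,
    generate_study,
    simulate_kinetics,
    synthesize_waveform_pair,
)
from thzcryst.waveform_io import read_manifest


class TestKinetics:
    def test_initial_condition(self):
        (f0,) = simulate_kinetics(KineticsParams(), 24.0, [0.0])
        assert (f0.x_amorphous, f0.x_beta, f0.x_alpha) == (1.0, 0.0, 0.0)

    def test_absorbing_state_at_long_times(self):
        (f_inf,) = simulate_kinetics(KineticsParams(), 24.0, [1e6])
        assert f_inf.x_alpha == pytest.approx(1.0, abs=1e-9)
        assert f_inf.x_amorphous == pytest.approx(0.0, abs=1e-9)
        assert f_inf.x_beta == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_rates_match_analytic_and_integrator(self):
        # closed form for k1 = k2 = k: x_beta = k t e^{-kt}; cross-check the
        # whole trajectory against an independent fine-step ODE integration
        k = 0.05
        params = KineticsParams(k1_per_hour=k, k2_per_hour=k)
        t = np.linspace(0.0, 60.0, 121)
        fracs = simulate_kinetics(params, 24.0, t)
        xb = np.array([f.x_beta for f in fracs])
        np.testing.assert_allclose(xb, k * t * np.exp(-k * t), atol=1e-12)
        assert t[np.argmax(xb)] == pytest.approx(1.0 / k, abs=0.5)

        def rhs(_, y):
            return [-k * y[0], k * y[0] - k * y[1], k * y[1]]

        sol = solve_ivp(rhs, (0, 60.0), [1.0, 0.0, 0.0], t_eval=t, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(xb, sol.y[1], atol=1e-7)

    @settings(derandomize=True, max_examples=50)
    @given(
        k1=st.floats(1e-4, 1.0),
        k2=st.floats(1e-4, 1.0),
        temp=st.floats(20.0, 40.0),
        t=st.floats(0.0, 500.0),
    )
    def test_fractions_conserved_and_bounded(self, k1, k2, temp, t):
        params = KineticsParams(k1_per_hour=k1, k2_per_hour=k2)
        (f,) = simulate_kinetics(params, temp, [t])
        total = f.x_amorphous + f.x_beta + f.x_alpha
        assert total == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= min(f.x_amorphous, f.x_beta, f.x_alpha)

    def test_beta_peak_time_decreases_with_temperature(self):
        params = KineticsParams()
        t = np.linspace(0.0, 200.0, 2001)
        peaks = []
        for temp in params.temperatures_C:
            xb = np.array([f.x_beta for f in simulate_kinetics(params, temp, t)])
            peaks.append(t[np.argmax(xb)])
        assert peaks[0] > peaks[1] > peaks[2]

    def test_default_peak_time_near_100h_at_ambient(self):
        params = KineticsParams()
        t = np.linspace(0.0, 300.0, 6001)
        xb = np.array([f.x_beta for f in simulate_kinetics(params, 24.0, t)])
        assert t[np.argmax(xb)] == pytest.approx(100.0, abs=0.5)


class TestComposeAbsorption:
    def test_fully_amorphous_is_the_amorphous_quadratic(self, fit_grid):
        out = compose_absorption(
            PhaseFractions(1.0, 0.0, 0.0),
            default_reference_model("alpha"), default_reference_model("beta"),
            DEFAULT_AMORPHOUS_BACKGROUND, fit_grid,
        )
        np.testing.assert_array_equal(out, quadratic(DEFAULT_AMORPHOUS_BACKGROUND, fit_grid))

    def test_fully_alpha_is_the_alpha_model(self, fit_grid):
        ra = default_reference_model("alpha")
        out = compose_absorption(
            PhaseFractions(0.0, 0.0, 1.0), ra, default_reference_model("beta"),
            DEFAULT_AMORPHOUS_BACKGROUND, fit_grid,
        )
        np.testing.assert_allclose(out, ra.evaluate(fit_grid), atol=1e-14)

    def test_mixture_is_convex_combination(self):
        # independent arithmetic at 10 frequencies
        ra, rb = default_reference_model("alpha"), default_reference_model("beta")
        nu = np.linspace(0.6, 1.7, 10)
        frac = PhaseFractions(0.5, 0.25, 0.25)
        out = compose_absorption(frac, ra, rb, DEFAULT_AMORPHOUS_BACKGROUND, nu)
        for i, v in enumerate(nu):
            amorph = sum(c * v**j for j, c in enumerate(DEFAULT_AMORPHOUS_BACKGROUND))
            beta = sum(p.G * np.exp(-(((v - p.nu0_THz) / p.dnu_THz) ** 2)) for p in rb.peaks)
            beta += sum(c * v**j for j, c in enumerate(rb.background))
            alpha = sum(p.G * np.exp(-(((v - p.nu0_THz) / p.dnu_THz) ** 2)) for p in ra.peaks)
            alpha += sum(c * v**j for j, c in enumerate(ra.background))
            assert out[i] == pytest.approx(0.5 * amorph + 0.25 * beta + 0.25 * alpha, rel=1e-12)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            PhaseFractions(0.5, 0.5, 0.5)


class TestSynthesizePair:
    def test_vacuum_slab_is_identity(self, noiseless_pulse):
        ref, smp = synthesize_waveform_pair(1.0, 0.0, 2.0, noiseless_pulse)
        np.testing.assert_allclose(smp.amplitude_au, ref.amplitude_au, atol=1e-12)

    def test_dispersionless_slab_group_delay(self, noiseless_pulse):
        # (n-1)d/c = 0.5 mm / c = 1.668 ps for n = 1.5, d = 1 mm
        ref, smp = synthesize_waveform_pair(1.5, 0.0, 1.0, noiseless_pulse)
        shift = (np.argmax(smp.amplitude_au) - np.argmax(ref.amplitude_au)) * noiseless_pulse.dt_ps
        assert shift == pytest.approx(1.668, abs=noiseless_pulse.dt_ps)

    def test_seed_contract(self):
        pulse = PulseParams()
        a1 = synthesize_waveform_pair(1.5, 5.0, 1.3, pulse, seed=11)
        a2 = synthesize_waveform_pair(1.5, 5.0, 1.3, pulse, seed=11)
        b = synthesize_waveform_pair(1.5, 5.0, 1.3, pulse, seed=12)
        np.testing.assert_array_equal(a1[1].amplitude_au, a2[1].amplitude_au)
        assert not np.array_equal(a1[1].amplitude_au, b[1].amplitude_au)

    def test_delayed_pulse_outside_record_names_required_window(self, noiseless_pulse):
        with pytest.raises(ValueError, match="time_window_ps >="):
            synthesize_waveform_pair(5.0, 0.0, 50.0, noiseless_pulse)


class TestGenerateStudy:
    def _tiny(self, **kw):
        defaults = dict(
            temperatures_C=(30.0,), n_replicates=1, duration_h=1.0, cadence_min=30.0
        )
        defaults.update(kw)
        return KineticsParams(**defaults)

    def test_timepoint_count_inclusive(self, tmp_path):
        manifest = generate_study(self._tiny(), out_dir=tmp_path / "s", seed=0)
        samples = manifest[manifest.role == "sample"]
        np.testing.assert_allclose(sorted(samples.time_h), [0.0, 0.5, 1.0])

    def test_manifest_row_count_matches_protocol(self, tmp_path):
        kin = self._tiny(temperatures_C=(24.0, 30.0, 35.0), n_replicates=5)
        manifest = generate_study(kin, out_dir=tmp_path / "s", seed=0)
        n_t = 3
        assert (manifest.role == "sample").sum() == 15 * n_t
        assert (manifest.role == "reference").sum() == 3 * n_t
        assert all((Path(tmp_path / "s") / f).exists() for f in manifest.file)

    def test_initial_samples_fully_amorphous(self, tmp_path):
        manifest = generate_study(self._tiny(n_replicates=2), out_dir=tmp_path / "s", seed=0)
        t0 = manifest[(manifest.role == "sample") & (manifest.time_h == 0.0)]
        assert (t0.x_amorphous == 1.0).all()
        assert (t0.x_beta == 0.0).all() and (t0.x_alpha == 0.0).all()

    def test_thickness_fixed_per_sample_within_range(self, tmp_path):
        manifest = generate_study(self._tiny(n_replicates=3), out_dir=tmp_path / "s", seed=1)
        samples = manifest[manifest.role == "sample"]
        for _, grp in samples.groupby("replicate"):
            assert grp.thickness_mm.nunique() == 1
            assert 1.1 <= grp.thickness_mm.iloc[0] <= 1.6

    def test_seed_determinism_byte_identical_tree(self, tmp_path):
        def tree_hash(root):
            h = hashlib.sha256()
            for p in sorted(Path(root).rglob("*")):
                if p.is_file():
                    h.update(p.relative_to(root).as_posix().encode())
                    h.update(p.read_bytes())
            return h.hexdigest()

        kin = self._tiny(n_replicates=2)
        generate_study(kin, out_dir=tmp_path / "a", seed=5)
        generate_study(kin, out_dir=tmp_path / "b", seed=5)
        generate_study(kin, out_dir=tmp_path / "c", seed=6)
        assert tree_hash(tmp_path / "a") == tree_hash(tmp_path / "b")
        assert tree_hash(tmp_path / "a") != tree_hash(tmp_path / "c")

    def test_nonempty_out_dir_requires_overwrite(self, tmp_path):
        out = tmp_path / "s"
        generate_study(self._tiny(), out_dir=out, seed=0)
        with pytest.raises(FileExistsError, match="overwrite"):
            generate_study(self._tiny(), out_dir=out, seed=0)
        generate_study(self._tiny(), out_dir=out, seed=0, overwrite=True)

    def test_noiseless_round_trip_recovers_optical_constants(self, tmp_path, noiseless_pulse):
        out = tmp_path / "s"
        manifest = generate_study(
            self._tiny(), pulse=noiseless_pulse, out_dir=out, seed=0
        )
        manifest = read_manifest(out / "manifest.tsv")
        refs = StudyRefs()
        from thzcryst.waveform_io import read_waveform

        ref_rows = manifest[manifest.role == "reference"].set_index("time_h")
        for row in manifest[manifest.role == "sample"].itertuples():
            smp = read_waveform(out / row.file)
            ref = read_waveform(out / ref_rows.loc[row.time_h].file)
            oc = extract_optical_constants(smp, ref, band_THz=(0.3, 2.0))
            frac = PhaseFractions(row.x_amorphous, row.x_beta, row.x_alpha)
            n_true = frac.mixture_index()
            a_true = compose_absorption(
                frac, refs.ref_alpha, refs.ref_beta, refs.amorphous_background, oc.freq_THz
            )
            assert np.max(np.abs(oc.n - n_true) / n_true) < 0.005
            assert np.max(np.abs(oc.alpha_cm1 - a_true)) < 0.5
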