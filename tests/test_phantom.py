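import numpy as np
import pandas as pd
import pytest

from myoquant.ephys import ensemble_average
from myoquant.phantom import (FRAPSimSpec, INaSimSpec, PhantomSpec,
                              make_band_table, make_frap_dataset,
                              make_ina_dataset, make_myocyte_stack)

SMALL = dict(cell_length_um=20.0, cell_width_um=8.0, frame_margin_um=1.0)


class TestMyocyteStack:
    def test_determinism(self):
        spec = PhantomSpec(**SMALL, cluster_density_pct=3.0, seed=7)
        s1, t1 = make_myocyte_stack(spec)
        s2, t2 = make_myocyte_stack(PhantomSpec(**SMALL, cluster_density_pct=3.0,
                                                seed=7))
        assert np.array_equal(s1.voxels, s2.voxels)
        assert t1.cluster_table == t2.cluster_table

    def test_no_clusters_degenerate_case(self):
        spec = PhantomSpec(**SMALL, cluster_density_pct=0.0,
                           apply_psf=False, apply_noise=False, seed=1)
        stack, truth = make_myocyte_stack(spec)
        assert truth.cluster_table == []
        # deterministic geometry: regenerating gives the identical image
        stack2, _ = make_myocyte_stack(spec)
        assert np.array_equal(stack.voxels, stack2.voxels)

    def test_unit_enrichment_means_uniform_rim(self):
        spec = PhantomSpec(**SMALL, lateral_enrichment=1.0, icd_enrichment=1.0,
                           apply_psf=False, apply_noise=False, seed=2)
        stack, truth = make_myocyte_stack(spec)
        plane = stack.channel("target")[truth.central_z] - spec.background
        rim = truth.rim_mask.mask
        interior = truth.cell_mask.mask & ~rim & ~truth.icd_mask.mask
        assert plane[rim & ~truth.icd_mask.mask].mean() == pytest.approx(
            plane[interior].mean(), rel=1e-9)

    def test_truth_masks_consistent(self, clean_phantom):
        _, truth = clean_phantom
        cell = truth.cell_mask.mask
        assert np.all(cell[truth.rim_mask.mask])
        assert np.all(cell[truth.icd_mask.mask])
        pitch = truth.cell_mask.pixel_xy_um
        for (cy, cx), _r, _i in truth.cluster_table:
            assert cell[int(cy / pitch - 0.5), int(cx / pitch - 0.5)]

    def test_cell_must_fit_frame(self):
        with pytest.raises(ValueError, match="fit"):
            make_myocyte_stack(PhantomSpec(cell_length_um=50, cell_width_um=10,
                                           frame_yx_um=(12.0, 30.0)))

    def test_nonpositive_photon_scale_rejected(self):
        with pytest.raises(ValueError, match="photon_scale"):
            make_myocyte_stack(PhantomSpec(**SMALL, photon_scale=0.0))

    def test_poisson_gaussian_variance_calibration(self):
        # uniform region: var ~= mean/photon_scale + read_noise_sd^2
        spec = PhantomSpec(**SMALL, background=50.0, photon_scale=2.0,
                           read_noise_sd=3.0, apply_psf=False, seed=3)
        stack, _ = make_myocyte_stack(spec)
        vals = stack.channel("target")[0].ravel()  # empty plane, bg only
        assert vals.size >= 10_000
        expected = 50.0 / 2.0 + 3.0**2
        assert vals.var() == pytest.approx(expected, rel=0.10)


class TestFrapDataset:
    def test_noiseless_construction(self):
        spec = FRAPSimSpec(noise_sd=0.0, background_bleach_rate_per_s=0.0)
        table = make_frap_dataset(spec)
        roi3 = table[table.roi == 3]["value"].to_numpy()
        assert np.ptp(roi3) == 0.0  # reference constant without bleach decay
        roi1 = table[table.roi == 1].sort_values("scan")["value"].to_numpy()
        norm = (roi1 - spec.background_offset) / spec.prebleach_intensity
        assert norm[spec.n_prebleach] == pytest.approx(spec.bleach_depth)

    def test_immobile_case_flat_after_bleach(self):
        spec = FRAPSimSpec(A1=0.0, A2=0.0, noise_sd=0.0,
                           background_bleach_rate_per_s=0.0)
        table = make_frap_dataset(spec)
        roi1 = table[table.roi == 1].sort_values("scan")["value"].to_numpy()
        post = roi1[spec.n_prebleach:]
        assert np.ptp(post) == 0.0

    def test_amplitude_budget_enforced(self):
        with pytest.raises(ValueError):
            make_frap_dataset(FRAPSimSpec(A1=0.7, A2=0.5))

    def test_trace_length_and_determinism(self):
        spec = FRAPSimSpec(noise_sd=0.02, seed=9)
        t1 = make_frap_dataset(spec)
        t2 = make_frap_dataset(FRAPSimSpec(noise_sd=0.02, seed=9))
        assert len(t1) == 4 * (spec.n_prebleach + spec.n_postbleach)
        pd.testing.assert_frame_equal(t1, t2)


class TestInaDataset:
    def test_single_voltage_noiseless_ensemble_identity(self):
        spec = INaSimSpec(sweep_noise_sd=0.0, n_repeats=3, v_start=-30.0,
                          v_stop=-30.0, v_step=5.0, pulse_ms=20.0)
        fam = make_ina_dataset(spec)
        ens = ensemble_average(fam)
        np.testing.assert_allclose(ens[0], fam.current[0, 0], rtol=1e-12,
                                   atol=1e-15)

    def test_no_inward_current_at_or_above_reversal(self):
        spec = INaSimSpec(sweep_noise_sd=0.0, v_start=70.0, v_stop=100.0,
                          v_step=5.0, pulse_ms=20.0)
        fam = make_ina_dataset(spec)
        assert fam.current.min() >= 0.0

    def test_designed_peak_found_by_bruteforce_scan(self):
        spec = INaSimSpec(sweep_noise_sd=0.0, pulse_ms=25.0)
        t = np.arange(0.0, spec.pulse_ms, spec.dt_ms)
        peaks = {v: abs(spec.noiseless_sweep(v, t).min())
                 for v in spec.voltages}
        best = max(peaks, key=peaks.get)
        assert spec.designed_peak_voltage() == best
        # inward between threshold and reversal
        assert spec.v_start < best < spec.e_rev

    def test_repeat_count_validated(self):
        with pytest.raises(ValueError):
            make_ina_dataset(INaSimSpec(n_repeats=0))


class TestBandTable:
    def test_noiseless_ratio_exact(self):
        table = make_band_table({"EB1": 1.5}, 0.0, seed=0)
        con = table[(table.condition == "CON")]["band_intensity"].iloc[0]
        pka = table[(table.condition == "PKA")]["band_intensity"].iloc[0]
        assert pka / con == pytest.approx(1.5)

    def test_identity_ratios(self):
        table = make_band_table({"a": 1.0, "b": 1.0}, 0.0, seed=0,
                                scheme="coip", n_experiments=3)
        ip = table[table.lane_kind == "IP_pos"].set_index(
            ["experiment_id", "condition"])["band_intensity"]
        wcl = table[table.lane_kind == "WCL"].set_index(
            ["experiment_id", "condition"])["band_intensity"]
        degrees = ip / wcl
        assert np.allclose(degrees, degrees.iloc[0])

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            make_band_table({"a": 1.0}, -0.1, seed=0)

    def test_monte_carlo_mean_close_to_truth(self):
        table = make_band_table({"t": 2.0}, 0.1, seed=4, n_experiments=1000)
        piv = table.pivot_table(index="experiment_id", columns="condition",
                                values="band_intensity")
        ratios = piv["PKA"] / piv["CON"]
        assert ratios.mean() == pytest.approx(2.0, rel=0.02)
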