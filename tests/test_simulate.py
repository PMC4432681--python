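import numpy as np
import pandas as pd
import pytest

import seqmvpa as sm
from seqmvpa.design import make_localizer_run, make_scan_run
from seqmvpa.simulate import (
    ParticipantState,
    learning_accuracy,
    make_voxel_population,
    simulate_run,
)


class TestVoxelPopulation:
    def test_selectivity_assignment(self):
        pop = make_voxel_population(400, 0.5, 1.0, 1.0, np.random.default_rng(0))
        n_sel = int(np.sum(pop.preference > 0))
        # binomial(400, 0.5) stays within 5 sigma of its mean
        assert abs(n_sel - 200) < 50
        n_left = int(np.sum(pop.preference == 1))
        assert abs(n_left - n_sel / 2) < 40
        assert np.all(pop.selectivity_amplitude[pop.preference == 0] == 0)

    def test_zero_fraction_gives_no_selectivity(self):
        pop = make_voxel_population(10, 0.0, 1.0, 1.0, np.random.default_rng(0))
        assert np.all(pop.preference == 0)

    def test_determinism(self):
        a = make_voxel_population(50, 0.5, 1.0, 1.0, np.random.default_rng(7), frac_edge=0.2)
        b = make_voxel_population(50, 0.5, 1.0, 1.0, np.random.default_rng(7), frac_edge=0.2)
        assert np.array_equal(a.preference, b.preference)
        assert np.array_equal(a.edge_flag, b.edge_flag)

    def test_edge_voxels_untuned(self):
        pop = make_voxel_population(200, 1.0, 1.0, 1.0, np.random.default_rng(1), frac_edge=0.5)
        assert np.all(pop.preference[pop.edge_flag] == 0)

    @pytest.mark.parametrize("kwargs", [
        {"n_voxels": 0}, {"frac_selective": 1.5}, {"noise_sd": 0.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        defaults = dict(n_voxels=10, frac_selective=0.5, noise_sd=1.0)
        defaults.update(kwargs)
        with pytest.raises(ValueError):
            make_voxel_population(defaults["n_voxels"], defaults["frac_selective"],
                                  1.0, defaults["noise_sd"], np.random.default_rng(0))


def _noiseless_population(n=6):
    """Three left-tuned, three right-tuned voxels, amplitude 1, negligible noise."""
    pref = np.array([1, 1, 1, 2, 2, 2])[:n]
    return sm.VoxelPopulation(
        preference=pref,
        selectivity_amplitude=np.ones(n),
        activation_gain=np.ones(n),
        noise_sd=np.full(n, 1e-9),
        edge_flag=np.zeros(n, dtype=bool),
    )


class TestSimulateRun:
    def test_noiseless_blank_closed_form(self):
        """Under the lag model, a tuned voxel's blank-window BOLD equals
        baseline + reactivation_gain * amplitude when the trial's prediction
        matches its preference, and baseline otherwise."""
        cfg = sm.SimulationConfig(motion_spike_prob=0.0)
        pop = _noiseless_population()
        rng = np.random.default_rng(0)
        schedule = make_scan_run("prediction", rng)
        gain = 0.3
        run = simulate_run(schedule, pop, cfg, ParticipantState(1.0, gain), rng)
        for i, row in run.trial_table.iterrows():
            v0 = int(round(row["onset"] / cfg.tr))
            window = run.data[:, v0 + 7: v0 + 13]  # trial volumes 8..13
            match_voxels = pop.preference == row["predicted"]
            assert np.allclose(window[match_voxels], gain, atol=1e-6)
            assert np.allclose(window[~match_voxels], 0.0, atol=1e-6)

    def test_zero_gain_blank_difference_is_zero(self):
        cfg = sm.SimulationConfig(motion_spike_prob=0.0)
        pop = _noiseless_population()
        rng = np.random.default_rng(1)
        schedule = make_scan_run("prediction", rng)
        run = simulate_run(schedule, pop, cfg, ParticipantState(1.0, 0.0), rng)
        windows = []
        for _, row in run.trial_table.iterrows():
            v0 = int(round(row["onset"] / cfg.tr))
            windows.append(run.data[:, v0 + 7: v0 + 13].mean(axis=1))
        windows = np.array(windows)
        left = run.trial_table["predicted"] == 1
        diff = windows[left.to_numpy()].mean(axis=0) - windows[(~left).to_numpy()].mean(axis=0)
        assert np.allclose(diff, 0.0, atol=1e-6)

    def test_localizer_block_preference(self):
        """Block-averaged response is higher for a voxel's preferred
        orientation: gratings occupy half of each volume, so the noiseless
        drive is 0.5*(gain + amplitude) vs 0.5*gain."""
        cfg = sm.SimulationConfig(motion_spike_prob=0.0)
        pop = _noiseless_population()
        rng = np.random.default_rng(2)
        run = simulate_run(make_localizer_run(rng), pop, cfg, None, rng)
        for _, row in run.trial_table.iterrows():
            v0 = int(round(row["onset"] / cfg.tr)) + 3
            block = run.data[:, v0: v0 + 10].mean(axis=1)
            preferred = pop.preference == row["orientation"]
            assert np.allclose(block[preferred], 0.5 * (1 + 1), atol=1e-6)
            assert np.allclose(block[~preferred], 0.5 * 1, atol=1e-6)

    def test_determinism(self):
        cfg = sm.SimulationConfig(n_voxels=30)
        pop = make_voxel_population(30, 0.5, 1.0, 1.0, np.random.default_rng(3))
        a = simulate_run(make_scan_run("prediction", np.random.default_rng(4)), pop, cfg,
                         ParticipantState(0.8, 0.1), np.random.default_rng(5))
        b = simulate_run(make_scan_run("prediction", np.random.default_rng(4)), pop, cfg,
                         ParticipantState(0.8, 0.1), np.random.default_rng(5))
        assert np.array_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.trial_table, b.trial_table)

    def test_volume_count_and_motion(self):
        cfg = sm.SimulationConfig(n_voxels=10)
        pop = make_voxel_population(10, 0.5, 1.0, 1.0, np.random.default_rng(0))
        rng = np.random.default_rng(0)
        run = simulate_run(make_scan_run("prediction", rng), pop, cfg, None, rng)
        assert run.n_volumes == int(np.ceil((15 + 12 * 28.5 + 15) / 1.5))
        assert run.motion.shape == (run.n_volumes, 6)

    def test_hrf_model_smoke(self):
        cfg = sm.SimulationConfig(n_voxels=10, hemodynamic="hrf")
        pop = make_voxel_population(10, 0.5, 1.0, 1.0, np.random.default_rng(0))
        rng = np.random.default_rng(0)
        run = simulate_run(make_scan_run("prediction", rng), pop, cfg, None, rng)
        assert np.all(np.isfinite(run.data))


class TestBehaviour:
    def test_learning_curve_values(self):
        cfg = sm.SimulationConfig(k=0.0, c=0.7)
        assert all(learning_accuracy(r, cfg) == 0.7 for r in (1, 5, 20))
        cfg = sm.SimulationConfig(k=0.1, c=0.55)
        assert learning_accuracy(1, cfg) == pytest.approx(0.55)
        # clamped into [0.5, 1]
        cfg_low = sm.SimulationConfig(k=0.0, c=0.3)
        assert learning_accuracy(1, cfg_low) == 0.5

    def test_response_implies_prediction(self):
        """Match response to test orientation o implies prediction o;
        nonmatch implies the other orientation."""
        cfg = sm.SimulationConfig()
        trials = sm.make_training_run(sm.builtin_sequences(), 40, np.random.default_rng(0))
        table = sm.simulate_responses(trials, 3, cfg, np.random.default_rng(1))
        match = table["response"] == "match"
        assert np.array_equal(table.loc[match, "predicted"], table.loc[match, "test"])
        assert np.array_equal(table.loc[~match, "predicted"], 3 - table.loc[~match, "test"])
        # correctness == predicted the expected orientation
        assert np.array_equal(table["correct"], table["predicted"] == table["expected"])

    def test_learning_parameters_recovered_from_noiseless_curve(self):
        cfg = sm.SimulationConfig(k=0.08, c=0.6)
        p = [learning_accuracy(r, cfg) for r in range(1, 17)]
        fit = sm.fit_learning_curve(p)
        assert fit.k == pytest.approx(0.08, abs=1e-9)
        assert fit.c == pytest.approx(0.6, abs=1e-9)


class TestExperiment:
    def test_structure(self, experiment_data):
        data = experiment_data
        for task in ("prediction", "control"):
            for phase in ("pre", "post"):
                session = data.session(task, phase)
                assert session.n_runs == data.config.n_runs_per_session
                assert all(len(r.trial_table) == 12 for r in session.runs)
        assert len(data.localizer_runs) == 2
        n_runs = data.config.n_training_sessions * data.config.runs_per_training_session
        assert len(data.training) == n_runs

    def test_gain_ordering_enforced(self):
        with pytest.raises(ValueError):
            sm.SimulationConfig(reactivation_gain_pre=0.5, reactivation_gain_post=0.1)

    def test_run_serialization_roundtrip(self, experiment_data, tmp_path):
        run = experiment_data.localizer_runs[0]
        run.save(tmp_path / "run.npz")
        loaded = sm.Run.load(tmp_path / "run.npz")
        assert np.array_equal(loaded.data, run.data)
        assert loaded.task == run.task
        pd.testing.assert_frame_equal(loaded.trial_table, run.trial_table)

    def test_nifti_export(self, experiment_data, tmp_path):
        import nibabel as nib

        run = experiment_data.pre_prediction.runs[0]
        run.to_nifti(tmp_path / "run.nii.gz")
        img = nib.load(tmp_path / "run.nii.gz")
        assert img.shape == (run.n_voxels, 1, 1, run.n_volumes)
        assert img.header.get_zooms()[3] == pytest.approx(1.5)
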