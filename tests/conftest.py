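import numpy as np
import pytest

import seqmvpa as sm
from seqmvpa.simulate import ParticipantState, make_voxel_population, simulate_session


def small_config(**overrides) -> sm.SimulationConfig:
    """Reduced-scale simulation settings for fast tests."""
    base = dict(
        n_voxels=80,
        n_runs_per_session=4,
        motion_spike_prob=0.0,
        frac_edge=0.0,
        amplitude_jitter=0.0,
    )
    base.update(overrides)
    return sm.SimulationConfig(**base)


@pytest.fixture(scope="session")
def make_session():
    """Factory for a simulated prediction/control session with known truth."""

    def _make(
        gain: float = 0.0,
        p_correct: float = 0.55,
        seed: int = 0,
        task: str = "prediction",
        pop: sm.VoxelPopulation | None = None,
        cued_gain: float = 0.0,
        **cfg_overrides,
    ):
        cfg = small_config(**cfg_overrides)
        rng = np.random.default_rng(seed)
        if pop is None:
            pop = make_voxel_population(
                cfg.n_voxels, cfg.frac_selective, cfg.amplitude, cfg.noise_sd, rng,
                activation_gain=cfg.activation_gain, frac_edge=cfg.frac_edge,
            )
        state = ParticipantState(p_correct, gain, cued_gain)
        return simulate_session(task, "pre", pop, cfg, state, rng), pop, cfg

    return _make


@pytest.fixture(scope="session")
def null_patterns(make_session):
    """Blank-interval patterns with zero reactivation signal (pure noise)."""
    session, _, _ = make_session(gain=0.0, seed=11)
    return sm.prepare_patterns(session)


@pytest.fixture(scope="session")
def signal_patterns(make_session):
    """Blank-interval patterns with a strong reactivation signal."""
    session, pop, _ = make_session(gain=0.5, p_correct=0.85, seed=12)
    return sm.prepare_patterns(session), pop


@pytest.fixture(scope="session")
def experiment_data():
    """One full simulated participant at reduced scale, shared across tests."""
    cfg = small_config(n_voxels=120, frac_edge=0.1)
    return sm.simulate_experiment(cfg, seed=5)
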