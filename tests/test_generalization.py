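import numpy as np
import pytest

import seqmvpa as sm
from seqmvpa.design import make_localizer_run
from seqmvpa.generalization import (
    common_informative,
    cross_decode,
    loro_with_rfe_selection,
    rfe_rank,
)
from seqmvpa.simulate import ParticipantState, make_voxel_population, simulate_run, simulate_session


def _toy_problem(n_informative=2, n_noise=20, n_samples=60, seed=0, scale=3.0):
    rng = np.random.default_rng(seed)
    y = rng.permutation(np.r_[np.ones(n_samples // 2), 2 * np.ones(n_samples // 2)]).astype(int)
    X = rng.normal(size=(n_samples, n_informative + n_noise))
    X[:, :n_informative] += scale * np.where(y == 1, -1, 1)[:, None]
    return X, y


class TestRFE:
    def test_informative_voxels_ranked_first(self):
        X, y = _toy_problem()
        ranking = rfe_rank(X, y, step_fraction=0.2)
        assert set(ranking.top(2)) == {0, 1}

    def test_one_at_a_time_elimination(self):
        X, y = _toy_problem(n_noise=10)
        n = X.shape[1]
        ranking = rfe_rank(X, y, step_fraction=1.0 / n)
        assert len(ranking.elimination_order) == n
        assert sorted(ranking.elimination_order) == list(range(n))
        assert sorted(ranking.ranks) == list(range(1, n + 1))
        # deterministic
        again = rfe_rank(X, y, step_fraction=1.0 / n)
        assert np.array_equal(ranking.elimination_order, again.elimination_order)

    def test_survivor_sets_nested(self):
        X, y = _toy_problem()
        ranking = rfe_rank(X, y, step_fraction=0.3)
        for earlier, later in zip(ranking.survivor_sets, ranking.survivor_sets[1:]):
            assert set(later) <= set(earlier)
        assert len(ranking.survivor_sets[-1]) == 0

    def test_all_noise_has_no_systematic_favorite(self):
        tops = set()
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(48, 12))
            y = rng.permutation(np.r_[np.ones(24), 2 * np.ones(24)]).astype(int)
            tops.add(int(rfe_rank(X, y, step_fraction=0.25).top(1)[0]))
        assert len(tops) > 2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            rfe_rank(np.zeros((10, 1)), np.r_[np.ones(5), 2 * np.ones(5)])
        with pytest.raises(ValueError):
            rfe_rank(np.zeros((10, 4)), np.ones(10))


class TestCommonInformative:
    def _ranking(self, ranks):
        ranks = np.asarray(ranks)
        order = np.argsort(-ranks)  # eliminated in ascending informativeness
        return sm.RFERanking(elimination_order=order, survivor_sets=[], ranks=ranks)

    def test_identical_rankings_give_top_n(self):
        r = self._ranking(np.arange(1, 11))
        assert list(common_informative(r, r, 4)) == [0, 1, 2, 3]

    def test_reversed_rankings_match_brute_force(self):
        """Combined rank = max of the two ranks; expectation computed by an
        explicit enumeration oracle over a 10-voxel toy pair."""
        r1 = self._ranking(np.arange(1, 11))
        r2 = self._ranking(np.arange(10, 0, -1))
        got = list(common_informative(r1, r2, 4))
        # oracle: sort voxels by (max rank, rank sum, index)
        keys = sorted(range(10), key=lambda i: (max(r1.ranks[i], r2.ranks[i]),
                                                r1.ranks[i] + r2.ranks[i], i))
        assert got == keys[:4]
        # a balanced set: drawn from the middle of both orderings
        assert all(3 <= r1.ranks[i] <= 8 for i in got)

    def test_oversized_request_returns_universe_with_warning(self):
        r = self._ranking(np.arange(1, 11))
        with pytest.warns(UserWarning):
            got = common_informative(r, r, 15)
        assert len(got) == 10

    def test_mismatched_universes_rejected(self):
        r1 = self._ranking(np.arange(1, 11))
        r2 = self._ranking(np.arange(1, 6))
        with pytest.raises(ValueError):
            common_informative(r1, r2, 3)


@pytest.fixture(scope="module")
def shared_code_setup():
    """Localizer + prediction-task patterns from one population, with the
    blank-interval reactivation using the same tuning as stimulus drive."""
    cfg = sm.SimulationConfig(n_voxels=80, n_runs_per_session=4, motion_spike_prob=0.0,
                              frac_edge=0.0, amplitude_jitter=0.0)
    rng = np.random.default_rng(71)
    pop = make_voxel_population(cfg.n_voxels, cfg.frac_selective, cfg.amplitude,
                                cfg.noise_sd, rng, activation_gain=cfg.activation_gain)
    loc_runs = [simulate_run(make_localizer_run(rng), pop, cfg, None, rng, run_id=r)
                for r in range(2)]
    loc_patterns = sm.localizer_block_patterns(loc_runs)
    return cfg, pop, rng, loc_patterns


def _prediction_patterns(cfg, pop, gain, seed):
    rng = np.random.default_rng(seed)
    session = simulate_session("prediction", "pre", pop, cfg,
                               ParticipantState(0.85, gain), rng)
    return sm.prepare_patterns(session)


class TestCrossDecode:
    def test_shared_code_generalizes(self, shared_code_setup):
        cfg, pop, _, loc_patterns = shared_code_setup
        test = _prediction_patterns(cfg, pop, gain=0.5, seed=72)
        result = cross_decode(loc_patterns, test)
        assert result.mean_accuracy > 0.75

    def test_independent_code_does_not_generalize(self, shared_code_setup):
        """When the prediction signal uses a tuning with no net overlap with
        the stimulus tuning, a stimulus-trained classifier cannot read it:
        cross-decoding sits at chance, far below the shared-code level."""
        cfg, pop, _, loc_patterns = shared_code_setup
        shared = cross_decode(loc_patterns, _prediction_patterns(cfg, pop, 0.5, 72))
        ortho = pop.with_orthogonal_reactivation(np.random.default_rng(300))
        accs = [cross_decode(loc_patterns,
                             _prediction_patterns(cfg, ortho, 0.5, 310 + i)).mean_accuracy
                for i in range(3)]
        assert abs(np.mean(accs) - 0.5) < 0.12
        assert np.mean(accs) < shared.mean_accuracy - 0.2

    def test_zero_gain_at_chance(self, shared_code_setup):
        """With no reactivation signal, cross-decoding is at chance in
        expectation (averaged over sessions; a single 48-trial session has
        dispersion well beyond binomial because all folds share one
        stimulus-trained decision rule)."""
        cfg, pop, _, loc_patterns = shared_code_setup
        accs = [cross_decode(loc_patterns,
                             _prediction_patterns(cfg, pop, 0.0, 74 + i)).mean_accuracy
                for i in range(4)]
        assert abs(np.mean(accs) - 0.5) < 0.12

    def test_monotone_in_gain(self, shared_code_setup):
        cfg, pop, _, loc_patterns = shared_code_setup
        accs = [cross_decode(loc_patterns, _prediction_patterns(cfg, pop, g, 75)).mean_accuracy
                for g in (0.0, 0.2, 0.8)]
        assert accs[1] >= accs[0] - 0.05
        assert accs[2] >= accs[1] - 0.02
        assert accs[2] > 0.85

    def test_selection_modes_run(self, shared_code_setup):
        cfg, pop, _, loc_patterns = shared_code_setup
        test = _prediction_patterns(cfg, pop, gain=0.5, seed=76)
        for mode in ("physical", "common"):
            result = cross_decode(loc_patterns, test, selection=mode,
                                  n_voxels=20, step_fraction=0.25)
            assert result.mean_accuracy > 0.7
        with pytest.raises(ValueError):
            cross_decode(loc_patterns, test, selection="bogus")


class TestCircularity:
    def test_fold_respecting_selection_shows_no_leakage(self):
        """RFE-based voxel selection that includes the held-out run inflates
        null-data accuracy (double dipping); the fold-respecting procedure
        stays at chance."""
        circ, fold = [], []
        for seed in range(6):
            cfg = sm.SimulationConfig(n_voxels=60, n_runs_per_session=4,
                                      motion_spike_prob=0.0, frac_edge=0.0,
                                      amplitude_jitter=0.0)
            rng = np.random.default_rng(200 + seed)
            pop = make_voxel_population(cfg.n_voxels, cfg.frac_selective, cfg.amplitude,
                                        cfg.noise_sd, rng, activation_gain=cfg.activation_gain)
            session = simulate_session("prediction", "pre", pop, cfg,
                                       ParticipantState(0.55, 0.0), rng)
            patterns = sm.prepare_patterns(session)
            circ.append(loro_with_rfe_selection(
                patterns, n_voxels=8, step_fraction=0.25,
                include_test_in_selection=True).mean_accuracy)
            fold.append(loro_with_rfe_selection(
                patterns, n_voxels=8, step_fraction=0.25,
                include_test_in_selection=False).mean_accuracy)
        bound = 0.5 + 1.96 * np.sqrt(0.25 / 48)
        # circular selection inflates accuracy above the null bound far more
        # often than the fold-respecting procedure
        assert np.mean(np.asarray(circ) > bound) > np.mean(np.asarray(fold) > bound)
        assert np.mean(circ) > np.mean(fold) + 0.1
        assert abs(np.mean(fold) - 0.5) < 0.1
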