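import numpy as np
import pytest

from ignite_grn import (
    CandidateGRN,
    Hyperparameters,
    IsingModel,
    KnownInteractionSet,
    NullEnsemble,
    RunConfig,
    ValidationError,
    cmd_from_replicates,
    corr_distance,
    correlation_matrix,
    fci,
    fit_null_ensemble,
    interaction_permutation_test,
    select_best,
    shuffle_dataset,
)


class TestCorrDistance:
    def test_identical_matrices(self):
        A = np.eye(3)
        assert corr_distance(A, A) == 0.0

    def test_unit_difference_everywhere(self):
        A = np.zeros((2, 2))
        B = np.ones((2, 2))
        assert corr_distance(A, B) == pytest.approx(1.0)  # sqrt(4)/2

    def test_symmetry(self, rng):
        A, B = rng.normal(size=(2, 4, 4))
        assert corr_distance(A, B) == pytest.approx(corr_distance(B, A))

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            corr_distance(np.eye(2), np.eye(3))

    def test_no_sqrt_variant(self):
        A = np.zeros((2, 2))
        B = np.ones((2, 2))
        assert corr_distance(A, B, sqrt=False) == pytest.approx(2.0)


class TestCorrelationMatrix:
    def test_matches_numpy_on_nondegenerate_data(self, rng):
        X = rng.normal(size=(4, 50))
        np.testing.assert_allclose(correlation_matrix(X), np.corrcoef(X), atol=1e-12)

    def test_constant_gene_zeroed_with_warning(self, rng):
        X = rng.normal(size=(3, 30))
        X[1] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            corr = correlation_matrix(X)
        assert (corr[1] == 0).all() and (corr[:, 1] == 0).all()
        assert corr[0, 0] == pytest.approx(1.0)


class TestShuffle:
    def test_entry_multiset_preserved(self, rng):
        X = rng.integers(0, 10, size=(5, 8))
        Y = shuffle_dataset(X, rng)
        assert sorted(X.ravel()) == sorted(Y.ravel())

    def test_index_mode_permutes_row_sums(self, rng):
        X = rng.integers(0, 10, size=(5, 8)).astype(float)
        Y = shuffle_dataset(X, rng, mode="index")
        assert sorted(X.sum(axis=1)) == pytest.approx(sorted(Y.sum(axis=1)))

    def test_value_mode_keeps_rows_in_place(self, rng):
        X = rng.normal(size=(4, 10))
        Y = shuffle_dataset(X, rng, mode="values")
        for i in range(4):
            assert sorted(X[i]) == pytest.approx(sorted(Y[i]))

    def test_seed_reproducible(self):
        X = np.arange(20).reshape(4, 5)
        a = shuffle_dataset(X, np.random.default_rng(1))
        b = shuffle_dataset(X, np.random.default_rng(1))
        np.testing.assert_array_equal(a, b)


class TestCMD:
    def test_zero_when_replicates_equal_input(self, planted_trajectory, rng):
        spins = planted_trajectory.spins[:, :2000]
        reps = np.stack([spins, spins])
        report = cmd_from_replicates(spins, reps, n_shuffle=10, rng=rng)
        assert report.value == 0.0

    def test_shuffled_input_as_model_scores_near_one(self, planted_trajectory):
        """A 'model' that emits shuffles of the input is exactly chance:
        its expected distance equals the null mean, so CMD ~ 1."""
        spins = planted_trajectory.spins[:, :3000]
        rng = np.random.default_rng(31)
        values = []
        for _ in range(30):
            fake = shuffle_dataset(spins, rng)[None]
            report = cmd_from_replicates(spins, fake, n_shuffle=20, rng=rng)
            values.append(report.value)
        mean = np.mean(values)
        se = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(mean - 1.0) < 3 * se + 0.05

    def test_doubling_shuffles_stable_denominator(self, planted_trajectory):
        spins = planted_trajectory.spins[:, :3000]
        reps = np.stack([spins])
        r1 = cmd_from_replicates(spins, reps, 40, np.random.default_rng(0))
        r2 = cmd_from_replicates(spins, reps, 80, np.random.default_rng(1))
        sd = r2.null_distances.std(ddof=1)
        se = sd * np.sqrt(1 / 40 + 1 / 80)
        assert abs(r1.denominator - r2.denominator) < 4 * se


class TestFCI:
    def _model(self, J):
        n = J.shape[0]
        return IsingModel(J, np.zeros(n), [f"g{i}" for i in range(n)])

    def test_all_signs_match(self):
        J = np.array([[0.0, 2.0], [-1.0, 0.0]])
        known = KnownInteractionSet([("g1", "g0", 1), ("g0", "g1", -1)])
        assert fci(self._model(J), known) == 1.0

    def test_partial_match_fraction(self):
        # 12 of 18 edges correct in a 6-gene model
        n = 6
        rng = np.random.default_rng(3)
        J = np.zeros((n, n))
        edges = []
        pairs = [(i, j) for i in range(n) for j in range(n) if i != j][:18]
        for k, (i, j) in enumerate(pairs):
            true_sign = 1 if rng.random() < 0.5 else -1
            inferred = true_sign if k < 12 else -true_sign
            J[i, j] = inferred * rng.uniform(0.5, 2.0)
            edges.append((f"g{j}", f"g{i}", true_sign))
        value = fci(self._model(J), KnownInteractionSet(edges))
        assert value == pytest.approx(12 / 18)

    def test_zero_weight_counts_incorrect(self):
        J = np.zeros((2, 2))
        known = KnownInteractionSet([("g0", "g1", 1)])
        assert fci(self._model(J), known) == 0.0

    def test_undirected_mode_accepts_either_orientation(self):
        J = np.array([[0.0, 0.0], [3.0, 0.0]])  # only g0 -> g1 present
        known = KnownInteractionSet([("g1", "g0", 1)])  # curated reverse
        assert fci(self._model(J), known, directed=True) == 0.0
        assert fci(self._model(J), known, directed=False) == 1.0

    def test_invariant_under_positive_rescaling(self, planted):
        m = planted.model
        scaled = IsingModel(m.J * 7.3, m.h.copy(), m.gene_ids.copy())
        assert fci(m, planted.planted_edges) == fci(scaled, planted.planted_edges)

    def test_unknown_gene_raises(self):
        known = KnownInteractionSet([("gX", "g0", 1)])
        with pytest.raises(ValidationError):
            fci(self._model(np.zeros((2, 2))), known)


def _candidate(idx, cmd=None, fci_value=None, success=True):
    model = IsingModel(np.zeros((2, 2)), np.zeros(2), ["a", "b"]) if success else None
    hp = Hyperparameters("NADAM", n_epochs=10)
    return CandidateGRN(model, hp, cmd, fci_value, idx, success=success)


class TestSelectBest:
    def test_single_candidate(self):
        c = _candidate(0, cmd=0.7)
        assert select_best([c], "cmd") is c

    def test_minimum_cmd_wins(self):
        cands = [_candidate(0, 0.5), _candidate(1, 0.43), _candidate(2, 0.9)]
        assert select_best(cands, "cmd").trial_index == 1

    def test_maximum_fci_wins(self):
        cands = [_candidate(0, fci_value=0.4), _candidate(1, fci_value=0.8)]
        assert select_best(cands, "fci").trial_index == 1

    def test_failed_fits_never_selected(self):
        cands = [_candidate(0, 0.5), _candidate(1, None, success=False)]
        assert select_best(cands, "cmd").trial_index == 0

    def test_tie_break_is_seeded(self):
        cands = [_candidate(0, 0.5), _candidate(1, 0.5), _candidate(2, 0.5)]
        picks = {select_best(cands, "cmd", np.random.default_rng(s)).trial_index
                 for s in range(30)}
        assert len(picks) > 1  # different seeds can pick different ties
        a = select_best(cands, "cmd", np.random.default_rng(7)).trial_index
        b = select_best(cands, "cmd", np.random.default_rng(7)).trial_index
        assert a == b

    def test_empty_list_raises(self):
        with pytest.raises(ValidationError):
            select_best([], "cmd")


class TestNullEnsembleAndPermutationTest:
    def test_stub_fitter_enumerates_all_combinations(self, planted_trajectory):
        calls = []

        def stub(spins, hp):
            calls.append(hp)
            return IsingModel(np.zeros((10, 10)), np.zeros(10),
                              [f"g{i}" for i in range(10)])

        config = RunConfig(seed=0, n_test=4, n_sets=3)
        ens = fit_null_ensemble(planted_trajectory, config, fitter=stub)
        assert len(ens) == 12 and len(calls) == 12
        assert ens.n_test == 4 and ens.n_sets == 3

    def _nulls_from_values(self, values, gene_ids=("gR", "gT")):
        models = []
        for v in values:
            J = np.zeros((2, 2))
            J[1, 0] = v  # regulator gR (col 0) -> target gT (row 1)
            models.append(IsingModel(J, np.zeros(2), list(gene_ids)))
        return NullEnsemble(models, n_test=len(values), n_sets=1)

    def test_observed_above_all_nulls_is_significant(self):
        nulls = self._nulls_from_values(np.linspace(-1, 1, 50))
        J = np.zeros((2, 2))
        J[1, 0] = 5.0
        obs = IsingModel(J, np.zeros(2), ["gR", "gT"])
        edges = KnownInteractionSet([("gR", "gT", 1)])
        out = interaction_permutation_test(obs, nulls, edges)
        assert bool(out.significant.iloc[0]) is True

    def test_observed_at_null_median_not_significant(self):
        nulls = self._nulls_from_values(np.linspace(-1, 1, 51))
        obs = IsingModel(np.zeros((2, 2)), np.zeros(2), ["gR", "gT"])
        edges = KnownInteractionSet([("gR", "gT", 1)])
        out = interaction_permutation_test(obs, nulls, edges)
        assert bool(out.significant.iloc[0]) is False

    def test_standard_normal_null_flags_three_sigma(self):
        rng = np.random.default_rng(6)
        nulls = self._nulls_from_values(rng.standard_normal(2500))
        J = np.zeros((2, 2))
        J[1, 0] = 3.0
        obs = IsingModel(J, np.zeros(2), ["gR", "gT"])
        edges = KnownInteractionSet([("gR", "gT", 1)])
        out = interaction_permutation_test(obs, nulls, edges)
        assert bool(out.significant.iloc[0]) is True
        assert out.null_p_hi.iloc[0] == pytest.approx(1.645, abs=0.12)

    def test_small_ensemble_warns(self):
        nulls = self._nulls_from_values(np.linspace(-1, 1, 5))
        obs = IsingModel(np.zeros((2, 2)), np.zeros(2), ["gR", "gT"])
        edges = KnownInteractionSet([("gR", "gT", 1)])
        with pytest.warns(UserWarning, match="percentiles"):
            interaction_permutation_test(obs, nulls, edges)
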