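import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dosefm.data import Dataset, Measurement
from dosefm.evaluation import (audit_folds, auc, make_folds,
                               make_folds_combinations, make_folds_entries,
                               make_folds_matrices, metrics, nested_cv)
from dosefm.hofm import TrainingConfig


class TestMakeFoldsEntries:
    def test_balanced_partition(self, small_sim):
        ds, _ = small_sim
        fa = make_folds_entries(ds, 4, seed=0)
        sizes = [len(fa.test_indices(ds, f)) for f in range(4)]
        assert sum(sizes) == len(ds.combination_indices)
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_under_seed(self, small_sim):
        ds, _ = small_sim
        assert make_folds_entries(ds, 5, 3).fold_of == make_folds_entries(ds, 5, 3).fold_of

    def test_monotherapies_always_in_training(self, small_sim):
        ds, _ = small_sim
        fa = make_folds_entries(ds, 3, seed=1)
        monos = set(ds.monotherapy_indices.tolist())
        for f in range(3):
            assert monos <= set(fa.train_indices(ds, f).tolist())
            assert not monos & set(fa.test_indices(ds, f).tolist())

    def test_too_few_entries_rejected(self, toy_dataset):
        with pytest.raises(ValueError):
            make_folds_entries(toy_dataset, 10, seed=0)


class TestMakeFoldsMatrices:
    def test_groups_stay_together(self, small_sim):
        ds, _ = small_sim
        fa = make_folds_matrices(ds, 3, seed=2)
        for i, m in enumerate(ds.measurements):
            if m.is_combination:
                key = (m.drug_a, m.drug_b, m.cell_line)
                assert fa.fold_of[key] == fa._fold_of_measurement(i, m)
        audit_folds(ds, fa)

    def test_pair_still_seen_in_other_cell_lines(self, small_sim):
        """A held-out (pair, cell line) matrix leaves the pair trainable."""
        ds, _ = small_sim
        fa = make_folds_matrices(ds, 3, seed=2)
        for f in range(3):
            train_pairs = {ds.measurements[i].pair_key()
                           for i in fa.train_indices(ds, f)
                           if ds.measurements[i].is_combination}
            test_pairs = {ds.measurements[i].pair_key()
                          for i in fa.test_indices(ds, f)}
            # with 3 cell lines and 3 folds, most pairs survive in training
            assert len(test_pairs & train_pairs) > 0


class TestMakeFoldsCombinations:
    def test_every_test_drug_occurs_in_training(self, small_sim):
        ds, _ = small_sim
        fa = make_folds_combinations(ds, 3, seed=4)
        audit_folds(ds, fa)

    def test_coverage_checker_rejects_isolated_drug(self):
        """A drug appearing in exactly one pair can never satisfy the
        coverage constraint: whenever its pair is the test fold, the drug
        is unseen in training, so construction must fail."""
        pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "E")]
        ms = [Measurement(a, 1.0, b, 1.0, "c", 50.0) for a, b in pairs]
        ds = Dataset.from_measurements(ms)
        with pytest.raises(RuntimeError, match="coverage"):
            make_folds_combinations(ds, 2, seed=0, max_retries=20)

    def test_coverage_satisfiable_with_connected_pairs(self):
        """With every drug in >= 2 pairs a valid 2-fold split exists and
        the retry loop finds it."""
        pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"),
                 ("B", "E"), ("C", "E"), ("D", "E")]
        ms = [Measurement(a, 1.0, b, 1.0, "c", 50.0) for a, b in pairs]
        ds = Dataset.from_measurements(ms)
        fa = make_folds_combinations(ds, 2, seed=0)
        audit_folds(ds, fa)

    def test_determinism(self, small_sim):
        ds, _ = small_sim
        a = make_folds_combinations(ds, 3, seed=9)
        b = make_folds_combinations(ds, 3, seed=9)
        assert a.fold_of == b.fold_of


class TestLeakageProperties:
    @pytest.mark.parametrize("scenario", ["new_entries", "new_matrices",
                                          "new_combinations"])
    def test_audits_pass_over_many_seeds(self, small_sim, scenario):
        ds, _ = small_sim
        for seed in range(50):
            fa = make_folds(ds, scenario, 3, seed)
            audit_folds(ds, fa)

    def test_permutation_equivariance(self, small_sim):
        """Relabeling drugs consistently permutes the assignment."""
        ds, _ = small_sim
        relabel = {d: f"X{d}" for d in ds.drugs}
        ms2 = [Measurement(relabel[m.drug_a], m.conc_a,
                           None if m.drug_b is None else relabel[m.drug_b],
                           m.conc_b, m.cell_line, m.response)
               for m in ds.measurements]
        ds2 = Dataset.from_measurements(ms2)
        fa = make_folds_combinations(ds, 3, seed=5)
        fa2 = make_folds_combinations(ds2, 3, seed=5)
        for pair, fold in fa.fold_of.items():
            mapped = tuple(sorted(relabel[d] for d in pair))
            assert fa2.fold_of[mapped] == fold


class TestMetrics:
    def test_identity_predictions(self):
        obs = np.array([1.0, 2.0, 3.0])
        rep = metrics(obs, obs)
        assert rep.rmse == 0.0
        assert rep.pearson == pytest.approx(1.0)
        assert rep.spearman == pytest.approx(1.0)

    def test_anti_identity(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert metrics(-obs, obs).pearson == pytest.approx(-1.0)

    def test_constant_observations_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            metrics(np.array([1.0, 2.0]), np.array([3.0, 3.0]))

    def test_auc_two_point_cases(self):
        assert auc([1, 0], [0.9, 0.1]) == 1.0
        assert auc([1, 0], [0.5, 0.5]) == 0.5

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.2, 0.4])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.r_[np.ones(5), np.zeros(5)].astype(int)
        scores = rng.normal(size=10)
        assert auc(labels, scores) == pytest.approx(auc(labels, np.exp(scores)))


class TestNestedCV:
    CFG = TrainingConfig(beta=1e-3, learning_rate=0.05, epochs=60,
                         batch_size=128, seed=0)

    def test_degenerate_grid_equals_plain_cv(self, small_sim):
        from dosefm.encoding import fit_layout
        from dosefm.evaluation import evaluate_fold
        ds, _ = small_sim
        layout = fit_layout(ds)
        report = nested_cv(ds, "new_entries", grid_k=(2,), grid_beta=(1e-3,),
                           m=2, config=self.CFG, n_outer=3, n_inner=2, seed=0)
        fa = make_folds(ds, "new_entries", 3, 0)
        direct, _, _ = evaluate_fold(ds, fa, 0, layout, 2, 2, self.CFG)
        assert report.per_fold[0]["rmse"] == pytest.approx(direct.rmse)
        assert all(s == {"fold": s["fold"], "k": 2, "beta": 1e-3}
                   for s in report.selected)

    def test_selection_prefers_adequate_rank(self, small_sim):
        """With a planted rank-2 interaction, inner CV should not pick a
        rank-1 model over an adequate one in most folds."""
        ds, _ = small_sim
        report = nested_cv(ds, "new_entries", grid_k=(1, 4), grid_beta=(1e-3,),
                           m=2, config=self.CFG, n_outer=2, n_inner=2, seed=1)
        ks = [s["k"] for s in report.selected]
        assert all(k in (1, 4) for k in ks)
        assert report.rmse > 0

    def test_empty_grid_rejected(self, small_sim):
        ds, _ = small_sim
        with pytest.raises(ValueError):
            nested_cv(ds, "new_entries", grid_k=(), grid_beta=(1.0,), m=2)
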