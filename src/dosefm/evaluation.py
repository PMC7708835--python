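"""Leakage-controlled cross-validation for three prediction scenarios.

The generalization difficulty of dose-response prediction depends on
what the training set shares with the test set, so folds are built at
three levels:

* ``new_entries`` -- individual tensor entries held out at random;
* ``new_matrices`` -- whole (drug pair, cell line) dose-response
  matrices held out; no entry of a test triplet appears in training,
  while the same pair is still seen in other cell lines;
* ``new_combinations`` -- whole drug pairs held out across all cell
  lines; each drug of a held-out pair must still occur in some training
  pair, so the model can learn how the individual drugs behave.

Monotherapy measurements are always part of the training set: the
single-agent responses of the drugs in a combination are assumed known.
Nested cross-validation selects (rank k, regularization beta) by inner
RMSE under the same scenario's grouping, then reports outer-fold RMSE,
Pearson and Spearman.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .data import Dataset
from .encoding import duplicate_symmetric, encode_measurements, fit_layout, swap_blocks
from .hofm import TrainingConfig, fit, predict

SCENARIOS = ("new_entries", "new_matrices", "new_combinations")


@dataclass
class FoldAssignment:
    """Partition of the combination measurements into folds.

    ``fold_of`` maps a key to a fold index: the measurement index for
    ``new_entries``, a (drug_a, drug_b, cell_line) triplet for
    ``new_matrices``, a (drug_a, drug_b) pair for ``new_combinations``.
    """

    scenario: str
    n_folds: int
    fold_of: dict
    seed: int

    def _fold_of_measurement(self, i: int, m) -> int:
        if self.scenario == "new_entries":
            return self.fold_of.get(i, -1)
        if self.scenario == "new_matrices":
            return self.fold_of.get((m.drug_a, m.drug_b, m.cell_line), -1)
        return self.fold_of.get(m.pair_key(), -1)

    def test_indices(self, dataset: Dataset, fold: int) -> np.ndarray:
        out = [i for i, m in enumerate(dataset.measurements)
               if m.is_combination and self._fold_of_measurement(i, m) == fold]
        return np.array(out, dtype=int)

    def train_indices(self, dataset: Dataset, fold: int) -> np.ndarray:
        """Everything outside the test fold, monotherapies included."""
        out = [i for i, m in enumerate(dataset.measurements)
               if not m.is_combination or self._fold_of_measurement(i, m) != fold]
        return np.array(out, dtype=int)


def _round_robin(items: list, n_folds: int, rng: np.random.Generator) -> dict:
    """Shuffled round-robin assignment: near-equal group counts per fold."""
    order = rng.permutation(len(items))
    return {items[j]: i % n_folds for i, j in enumerate(order)}


def make_folds_entries(dataset: Dataset, n_folds: int, seed: int) -> FoldAssignment:
    """Uniform random partition of the combination measurements."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    combo = [int(i) for i in dataset.combination_indices]
    if len(combo) < n_folds:
        raise ValueError(f"{len(combo)} combination entries < {n_folds} folds")
    rng = np.random.default_rng(seed)
    return FoldAssignment("new_entries", n_folds, _round_robin(combo, n_folds, rng), seed)


def make_folds_matrices(dataset: Dataset, n_folds: int, seed: int) -> FoldAssignment:
    """Partition at the level of (drug pair, cell line) dose-response matrices."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    groups, seen = [], set()
    for m in dataset.measurements:
        if not m.is_combination:
            continue
        key = (m.drug_a, m.drug_b, m.cell_line)
        if key not in seen:
            seen.add(key)
            groups.append(key)
    if len(groups) < n_folds:
        raise ValueError(f"{len(groups)} (pair, cell line) groups < {n_folds} folds")
    rng = np.random.default_rng(seed)
    return FoldAssignment("new_matrices", n_folds, _round_robin(groups, n_folds, rng), seed)


def make_folds_combinations(dataset: Dataset, n_folds: int, seed: int,
                            max_retries: int = 100) -> FoldAssignment:
    """Partition at the level of canonical drug pairs.

    All cell lines and doses of a test pair are held out; additionally
    every drug of every test pair must occur in at least one training
    pair.  Draws violating the coverage constraint are re-drawn with an
    incremented sub-seed, up to ``max_retries``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    pairs, seen = [], set()
    for m in dataset.measurements:
        if m.is_combination and m.pair_key() not in seen:
            seen.add(m.pair_key())
            pairs.append(m.pair_key())
    if len(pairs) < n_folds:
        raise ValueError(f"{len(pairs)} drug pairs < {n_folds} folds")
    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        fold_of = _round_robin(pairs, n_folds, rng)
        if _pair_coverage_ok(fold_of, n_folds):
            return FoldAssignment("new_combinations", n_folds, fold_of, seed)
    raise RuntimeError(f"could not satisfy drug-coverage constraint after "
                       f"{max_retries} draws; try fewer folds")


def _pair_coverage_ok(fold_of: dict, n_folds: int) -> bool:
    """Every drug of every test pair appears in >= 1 training pair."""
    for fold in range(n_folds):
        train_drugs = {d for p, f in fold_of.items() if f != fold for d in p}
        for p, f in fold_of.items():
            if f == fold and any(d not in train_drugs for d in p):
                return False
    return True


def audit_folds(dataset: Dataset, fa: FoldAssignment) -> bool:
    """Verify the scenario's leakage constraints; raises on violation.

    Checks that folds partition the combination measurements and that no
    test group key (triplet / pair) leaks into its training set; for
    ``new_combinations`` additionally checks drug coverage.
    """
    combo = set(int(i) for i in dataset.combination_indices)
    covered = set()
    for fold in range(fa.n_folds):
        test = fa.test_indices(dataset, fold)
        train = fa.train_indices(dataset, fold)
        if covered & set(test.tolist()):
            raise AssertionError("folds overlap")
        covered.update(test.tolist())
        if set(test.tolist()) & set(train.tolist()):
            raise AssertionError("test entries present in training")
        if fa.scenario == "new_matrices":
            test_keys = {(dataset.measurements[i].drug_a, dataset.measurements[i].drug_b,
                          dataset.measurements[i].cell_line) for i in test}
            for i in train:
                m = dataset.measurements[i]
                if m.is_combination and (m.drug_a, m.drug_b, m.cell_line) in test_keys:
                    raise AssertionError("test triplet found in training set")
        elif fa.scenario == "new_combinations":
            test_pairs = {dataset.measurements[i].pair_key() for i in test}
            train_drugs = set()
            for i in train:
                m = dataset.measurements[i]
                if m.is_combination:
                    if m.pair_key() in test_pairs:
                        raise AssertionError("test pair found in training set")
                    train_drugs.update(m.pair_key())
            for p in test_pairs:
                if any(d not in train_drugs for d in p):
                    raise AssertionError(f"test pair {p} has a drug unseen in training")
    if covered != combo:
        raise AssertionError("folds do not cover all combination measurements")
    return True


def make_folds(dataset: Dataset, scenario: str, n_folds: int, seed: int) -> FoldAssignment:
    if scenario == "new_entries":
        return make_folds_entries(dataset, n_folds, seed)
    if scenario == "new_matrices":
        return make_folds_matrices(dataset, n_folds, seed)
    if scenario == "new_combinations":
        return make_folds_combinations(dataset, n_folds, seed)
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


@dataclass
class MetricReport:
    rmse: float
    pearson: float
    spearman: float
    auc: Optional[float] = None
    per_fold: list[dict] = field(default_factory=list)
    selected: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "pearson": self.pearson, "spearman": self.spearman,
                "auc": self.auc, "per_fold": self.per_fold, "selected": self.selected}


def metrics(predictions: np.ndarray, observations: np.ndarray) -> MetricReport:
    """RMSE, Pearson and Spearman correlation of predictions vs observations."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predictions and observations must have equal length")
    if len(np.unique(o)) < 2:
        raise ValueError("correlation undefined: observations are constant")
    if len(np.unique(p)) < 2:
        raise ValueError("correlation undefined: predictions are constant")
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    pearson = float(stats.pearsonr(p, o).statistic)
    spearman = float(stats.spearmanr(p, o).statistic)
    return MetricReport(rmse=rmse, pearson=pearson, spearman=spearman)


def auc(labels: Sequence[bool], scores: Sequence[float]) -> float:
    """Probability a random positive outranks a random negative (ties: 0.5)."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("auc needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def evaluate_fold(dataset: Dataset, fa: FoldAssignment, fold: int,
                  layout, m: int, k: int, config: TrainingConfig,
                  tables=None) -> tuple[MetricReport, np.ndarray, np.ndarray]:
    """Fit on a fold's training set and score its test set.

    Training measurements are symmetrically duplicated before fitting;
    test predictions average both orientations.  Returns the report plus
    (test indices, predictions).
    """
    train_idx = fa.train_indices(dataset, fold)
    test_idx = fa.test_indices(dataset, fold)
    train_ms = duplicate_symmetric([dataset.measurements[i] for i in train_idx])
    X = encode_measurements(train_ms, layout, tables)
    y = np.array([mm.response for mm in train_ms])
    model = fit(X, y, m, k, config, layout=layout)
    test_ms = [dataset.measurements[i] for i in test_idx]
    Xt = encode_measurements(test_ms, layout, tables)
    pred = 0.5 * (predict(model, Xt) + predict(model, swap_blocks(Xt, layout)))
    obs = np.array([mm.response for mm in test_ms])
    return metrics(pred, obs), test_idx, pred


def nested_cv(dataset: Dataset, scenario: str,
              grid_k: Sequence[int] = (25, 50, 75, 100),
              grid_beta: Sequence[float] = (1e2, 1e3, 1e4, 1e5),
              m: int = 5,
              config: Optional[TrainingConfig] = None,
              n_outer: int = 10, n_inner: int = 5,
              seed: int = 0, tables=None, layout=None) -> MetricReport:
    """Nested cross-validation with hyperparameter selection.

    Outer folds estimate generalization; for each outer fold an inner
    CV (same scenario, restricted to the outer-training measurements)
    selects (k, beta) by mean inner RMSE; the model is refit on the
    outer-training set and scored on the outer test set.  Per-fold
    metrics are aggregated as unweighted means.  A leakage audit runs on
    every fold construction.
    """
    if not grid_k or not grid_beta:
        raise ValueError("hyperparameter grids must be nonempty")
    config = config or TrainingConfig()
    if layout is None:
        layout = fit_layout(dataset, tables)
    outer = make_folds(dataset, scenario, n_outer, seed)
    audit_folds(dataset, outer)
    per_fold, selected = [], []
    for fold in range(n_outer):
        train_idx = outer.train_indices(dataset, fold)
        test_idx = outer.test_indices(dataset, fold)
        inner_ds = dataset.subset(train_idx)
        # degenerate grid: no selection needed, skip the inner loop
        if len(grid_k) * len(grid_beta) == 1:
            best_k, best_beta = grid_k[0], grid_beta[0]
        else:
            inner = make_folds(inner_ds, scenario, n_inner, seed + 1000 + fold)
            audit_folds(inner_ds, inner)
            best_k, best_beta, best_rmse = None, None, np.inf
            for kk in grid_k:
                for bb in grid_beta:
                    cfg = TrainingConfig(beta=bb, learning_rate=config.learning_rate,
                                         epochs=config.epochs,
                                         batch_size=config.batch_size,
                                         seed=config.seed,
                                         init_scale=config.init_scale)
                    rmses = []
                    for ifold in range(n_inner):
                        rep, _, _ = evaluate_fold(inner_ds, inner, ifold, layout,
                                                  m, kk, cfg, tables)
                        rmses.append(rep.rmse)
                    mean_rmse = float(np.mean(rmses))
                    if mean_rmse < best_rmse:
                        best_k, best_beta, best_rmse = kk, bb, mean_rmse
        cfg = TrainingConfig(beta=best_beta, learning_rate=config.learning_rate,
                             epochs=config.epochs, batch_size=config.batch_size,
                             seed=config.seed, init_scale=config.init_scale)
        rep, t_idx, pred = evaluate_fold(dataset, outer, fold, layout, m, best_k,
                                         cfg, tables)
        # outer test entries were never part of inner CV or the refit
        assert not set(t_idx.tolist()) & set(train_idx.tolist())
        per_fold.append({"fold": fold, "rmse": rep.rmse, "pearson": rep.pearson,
                         "spearman": rep.spearman})
        selected.append({"fold": fold, "k": int(best_k), "beta": float(best_beta)})
    report = MetricReport(
        rmse=float(np.mean([f["rmse"] for f in per_fold])),
        pearson=float(np.mean([f["pearson"] for f in per_fold])),
        spearman=float(np.mean([f["spearman"] for f in per_fold])),
        per_fold=per_fold, selected=selected)
    return report


def export_folds(fa: FoldAssignment, path) -> None:
    """Write (group key, fold) pairs as delimited text for auditability."""
    import pandas as pd

    rows = [{"key": "|".join(str(x) for x in (k if isinstance(k, tuple) else (k,))),
             "fold": f} for k, f in fa.fold_of.items()]
    pd.DataFrame(rows).to_csv(path, index=False)
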