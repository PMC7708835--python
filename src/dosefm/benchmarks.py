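"""Self-contained benchmark computations on synthetic screens.

Each function generates its own inputs from a seed, runs the package's
actual code paths, and returns the measured quantities.  They back both
the reproducibility script and the top-level test suite.  Problem sizes
are desk-scale: the generator's default screen (10 drugs, 20 pairs,
5 cell lines, 4 x 4 grids) trains an order-3 model in seconds to
minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from .data import DoseResponseMatrix
from .encoding import fit_layout
from .evaluation import (audit_folds, evaluate_fold, make_folds,
                         make_folds_combinations, make_folds_entries)
from .hofm import HOFMModel, TrainingConfig, gradient, objective, predict, \
    predict_brute_force
from .simulate import SimulationConfig, generate_dataset
from .synergy import combo_score, expected_response, label_top_synergistic

#: Training settings for the small synthetic benchmark screens; chosen
#: for the small-sample regime (see docs/methods.md), not the library's
#: full-scale defaults.
BENCH_CONFIG = dict(beta=1e-3, learning_rate=0.05, epochs=400, batch_size=256)


def _sub_seed(seed: int, salt: int) -> int:
    return int(np.random.default_rng((seed, salt)).integers(0, 2 ** 31 - 1))


def oracle_equivalence(seed: int, n_draws: int = 100) -> dict:
    """Worst relative deviation between the dynamic-programming predictor
    and exhaustive enumeration over random small models (d <= 12,
    m <= 5, k <= 3)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        d = int(rng.integers(3, 13))
        m = int(rng.integers(1, 6))
        k = int(rng.integers(1, 4))
        model = HOFMModel(m=m, k=k, w=rng.normal(size=d),
                          P={t: rng.normal(size=(d, k)) for t in range(2, m + 1)})
        x = rng.normal(size=d) * (rng.random(d) < 0.6)
        fast = predict(model, x)
        slow = predict_brute_force(model, x)
        worst = max(worst, abs(fast - slow) / (1.0 + abs(slow)))
    return {"max_rel_dev": worst, "n": n_draws}


def gradient_check(seed: int, n_models: int = 5) -> dict:
    """Worst relative deviation of the analytic gradient from central
    finite differences (h = 1e-5) over random small models."""
    rng = np.random.default_rng(seed)
    h = 1e-5
    worst = 0.0
    checked = 0
    for _ in range(n_models):
        d = int(rng.integers(4, 8))
        m = int(rng.integers(2, 5))
        k = int(rng.integers(1, 3))
        model = HOFMModel(m=m, k=k, w=rng.normal(size=d),
                          P={t: rng.normal(size=(d, k)) for t in range(2, m + 1)})
        X = rng.normal(size=(4, d))
        y = rng.normal(size=4)
        cfg = TrainingConfig(beta=float(rng.random()))
        gw, gP = gradient(model, X, y, cfg)

        def central(bump):
            bump(h)
            up = objective(model, X, y, cfg)
            bump(-2 * h)
            down = objective(model, X, y, cfg)
            bump(h)
            return (up - down) / (2 * h)

        for i in range(d):
            num = central(lambda e, i=i: model.w.__setitem__(i, model.w[i] + e))
            worst = max(worst, abs(num - gw[i]) / (1.0 + abs(gw[i])))
            checked += 1
        for t in range(2, m + 1):
            for i in range(d):
                for s in range(k):
                    num = central(lambda e, t=t, i=i, s=s: model.P[t].__setitem__(
                        (i, s), model.P[t][i, s] + e))
                    worst = max(worst, abs(num - gP[t][i, s]) / (1.0 + abs(gP[t][i, s])))
                    checked += 1
    return {"max_rel_dev": worst, "n": checked}


def comboscore_examples() -> dict:
    """The worked ComboScore example and the truncation case."""
    mat = DoseResponseMatrix("A", "B", "cell", [1.0, 2.0], [1.0, 2.0],
                             [[50.0, -40.0], [30.0, -50.0]],
                             [100.0, 60.0], [90.0, -30.0],
                             np.ones((2, 2), dtype=bool))
    return {
        "as_printed": combo_score(mat, "as_printed").value,
        "alm_positive_synergy": combo_score(mat, "alm_positive_synergy").value,
        "truncated_expected": float(expected_response([200.0], [150.0])[0, 0]),
    }


def parameter_recovery(seed: int) -> dict:
    """Held-out accuracy on the generator's default screen.

    Trains an order-3 rank-4 model and an order-1 model on the same
    random 90/10 entry split and reports test RMSE / Pearson plus the
    order-1 : order-3 RMSE ratio.
    """
    sim = SimulationConfig(seed=_sub_seed(seed, 1))
    dataset, truth = generate_dataset(sim)
    layout = fit_layout(dataset)
    fa = make_folds_entries(dataset, 10, seed=_sub_seed(seed, 2))
    cfg = TrainingConfig(seed=_sub_seed(seed, 3), **BENCH_CONFIG)
    rep3, _, _ = evaluate_fold(dataset, fa, 0, layout, m=3, k=4, config=cfg)
    rep1, _, _ = evaluate_fold(dataset, fa, 0, layout, m=1, k=1, config=cfg)
    return {
        "noise_sd": sim.noise_sd,
        "rmse_order3": rep3.rmse,
        "pearson_order3": rep3.pearson,
        "rmse_order1": rep1.rmse,
        "rmse_ratio_order1_vs_order3": rep1.rmse / rep3.rmse,
        "n": len(fa.test_indices(dataset, 0)),
    }


def scenario_c_generalization(seed: int, n_folds: int = 5) -> dict:
    """New-drug-combination prediction on the default screen: whole drug
    pairs held out, order-3 rank-4 model, mean metrics over folds."""
    sim = SimulationConfig(seed=_sub_seed(seed, 1))
    dataset, _ = generate_dataset(sim)
    layout = fit_layout(dataset)
    fa = make_folds_combinations(dataset, n_folds, seed=_sub_seed(seed, 4))
    audit_folds(dataset, fa)
    cfg = TrainingConfig(seed=_sub_seed(seed, 3), **BENCH_CONFIG)
    rmses, pearsons, n_test = [], [], 0
    for fold in range(n_folds):
        rep, idx, _ = evaluate_fold(dataset, fa, fold, layout, m=3, k=4, config=cfg)
        rmses.append(rep.rmse)
        pearsons.append(rep.pearson)
        n_test += len(idx)
    return {"pearson": float(np.mean(pearsons)), "rmse": float(np.mean(rmses)),
            "per_fold_pearson": pearsons, "n": n_test}


def leakage_suite(seed: int, n_seeds: int = 1000) -> dict:
    """Audit fold constraints over many random draws per scenario."""
    sim = SimulationConfig(n_drugs=8, n_cell_lines=3, grid_size=2,
                           pair_fraction=12 / 28, noise_sd=0.0,
                           seed=_sub_seed(seed, 5))
    dataset, _ = generate_dataset(sim)
    passed = 0
    total = 0
    for scenario in ("new_entries", "new_matrices", "new_combinations"):
        for draw in range(n_seeds):
            fa = make_folds(dataset, scenario, 3, _sub_seed(seed, 10_000 + draw))
            audit_folds(dataset, fa)
            passed += 1
            total += 1
    return {"pass_fraction": passed / total, "n": total}


def top_fraction_labeling(seed: int, sizes=(10, 100, 1000)) -> dict:
    """Positive counts from top-10% labeling at several score-set sizes."""
    rng = np.random.default_rng(seed)
    counts = {}
    for n in sizes:
        scores = [combo_score_stub(i, float(v))
                  for i, v in enumerate(rng.normal(size=n))]
        labels = label_top_synergistic(scores, 0.1)
        counts[n] = int(sum(labels))
    return {"counts": counts, "n": max(sizes)}


def combo_score_stub(i: int, value: float):
    from .synergy import SynergyScore
    return SynergyScore(f"a{i}", f"b{i}", "c", "comboscore", value)
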