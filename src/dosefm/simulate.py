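"""Synthetic drug-combination screens with known ground truth.

Monotherapies follow Hill dose-response curves in percentage growth,

    g(c) = 100 * (1 - Emax * c^h / (c^h + EC50^h)) + noise,

with per-(drug, cell line) parameters.  Combination responses start
from the Bliss-multiplicative baseline g_AB = g_A * g_B / 100 (growth
fractions multiply under independence) and subtract a planted low-rank
drug-drug-cell interaction weighted by a smooth dose "bump" peaking
mid-grid:

    response = g_A g_B / 100 - I(A, B, cell) * bump(p, q) + noise,
    I(A, B, cell) = scale * sum_r u_Ar u_Br v_cr / sqrt(rank).

A positive I reduces growth below independence (synergy); negative I
produces antagonism.  The trilinear form is symmetric in the two drugs
and gives the response tensor genuine higher-order structure for a
factorization machine to recover.  Each drug has its own log-spaced
concentration grid centered on its reference EC50, mirroring the
4 x 4 factorial matrix design of large combination screens.

Note the baseline is Bliss independence, not the truncated-product
expectation used by the NCI ComboScore, so the ComboScore of noise-free
independent data is near but not exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.special import expit

from .data import Dataset, Measurement, round_conc


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults emulate a small screen: 10 drugs, 20 of the 45 possible
    pairs, 5 cell lines, complete 4 x 4 dose grids, a planted rank-2
    interaction of magnitude 10 %-growth units, and Gaussian noise of
    5 %-growth units.
    """

    n_drugs: int = 10
    n_cell_lines: int = 5
    grid_size: int = 4
    pair_fraction: float = 20 / 45
    ec50_log10_range: tuple = (-8.0, -5.0)
    slope_range: tuple = (0.5, 3.0)
    emax_range: tuple = (0.0, 1.0)
    interaction_rank: int = 2
    interaction_scale: float = 10.0
    noise_sd: float = 5.0
    n_tissues: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if not (0 < self.pair_fraction <= 1):
            raise ValueError("pair_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to reproduce the noiseless surface."""

    config: SimulationConfig
    drugs: list[str]
    cell_lines: list[str]
    conc_grids: dict  # drug -> list of concentrations (increasing)
    ec50: np.ndarray   # (n_drugs, n_cells)
    slope: np.ndarray
    emax: np.ndarray
    drug_factors: np.ndarray  # (n_drugs, rank)
    cell_factors: np.ndarray  # (n_cells, rank)
    tissue_of: dict = field(default_factory=dict)

    def drug_index(self, drug: str) -> int:
        return self.drugs.index(drug)

    def cell_index(self, cell: str) -> int:
        return self.cell_lines.index(cell)

    def interaction(self, drug_a: str, drug_b: str, cell: str) -> float:
        """Planted synergy magnitude I(A, B, cell); symmetric in the drugs."""
        ua = self.drug_factors[self.drug_index(drug_a)]
        ub = self.drug_factors[self.drug_index(drug_b)]
        vc = self.cell_factors[self.cell_index(cell)]
        r = self.config.interaction_rank
        return float(self.config.interaction_scale * np.sum(ua * ub * vc) / np.sqrt(r))

    def bump(self, drug_a: str, conc_a: float, drug_b: str, conc_b: float) -> float:
        """Smooth dose weight peaking at the grid center."""
        g = self.config.grid_size
        ia = self.conc_grids[drug_a].index(conc_a)
        ib = self.conc_grids[drug_b].index(conc_b)
        center = (g - 1) / 2.0
        sigma = g / 4.0
        return float(np.exp(-((ia - center) ** 2 + (ib - center) ** 2) / (2 * sigma ** 2)))

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "drugs": self.drugs, "cell_lines": self.cell_lines,
            "conc_grids": self.conc_grids,
            "ec50": self.ec50.tolist(), "slope": self.slope.tolist(),
            "emax": self.emax.tolist(),
            "drug_factors": self.drug_factors.tolist(),
            "cell_factors": self.cell_factors.tolist(),
            "tissue_of": self.tissue_of,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _hill_growth(conc: float, ec50: float, slope: float, emax: float) -> float:
    # c^h / (c^h + e^h) = sigmoid(h * (ln c - ln e)), stable in log space
    effect = expit(slope * (np.log(conc) - np.log(ec50)))
    return 100.0 * (1.0 - emax * effect)


def simulate_monotherapy(drug: str, cell: str, conc: float, truth: GroundTruth,
                         rng: Optional[np.random.Generator] = None) -> float:
    """Hill-curve percentage growth, strictly decreasing in dose when Emax > 0."""
    if conc <= 0:
        raise ValueError("concentration must be positive")
    i, j = truth.drug_index(drug), truth.cell_index(cell)
    g = _hill_growth(conc, truth.ec50[i, j], truth.slope[i, j], truth.emax[i, j])
    if rng is not None and truth.config.noise_sd > 0:
        g += rng.normal(0.0, truth.config.noise_sd)
    return float(g)


def simulate_combination(drug_a: str, conc_a: float, drug_b: str, conc_b: float,
                         cell: str, truth: GroundTruth,
                         rng: Optional[np.random.Generator] = None) -> float:
    """Bliss-multiplicative baseline minus the planted interaction term."""
    ga = simulate_monotherapy(drug_a, cell, conc_a, truth)
    gb = simulate_monotherapy(drug_b, cell, conc_b, truth)
    resp = ga * gb / 100.0
    resp -= truth.interaction(drug_a, drug_b, cell) * truth.bump(drug_a, conc_a,
                                                                 drug_b, conc_b)
    if rng is not None and truth.config.noise_sd > 0:
        resp += rng.normal(0.0, truth.config.noise_sd)
    return float(resp)


def generate_dataset(config: Optional[SimulationConfig] = None) -> tuple[Dataset, GroundTruth]:
    """Generate a complete synthetic screen.

    Emits, in deterministic order, a full grid_size x grid_size
    combination block for every screened (pair, cell line) plus every
    monotherapy row (all drugs x all cell lines x their grids):
    pairs * cells * grid^2 combination rows and drugs * cells * grid
    monotherapy rows.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    nd, nc, g = config.n_drugs, config.n_cell_lines, config.grid_size
    drugs = [f"D{i:02d}" for i in range(nd)]
    cells = [f"CL{j}" for j in range(nc)]
    lo, hi = config.ec50_log10_range
    ref_log_ec50 = rng.uniform(lo, hi, size=nd)
    ec50 = 10 ** (ref_log_ec50[:, None] + rng.normal(0.0, 0.3, size=(nd, nc)))
    slope = rng.uniform(*config.slope_range, size=(nd, nc))
    emax = rng.uniform(*config.emax_range, size=(nd, nc))
    r = config.interaction_rank
    drug_factors = rng.normal(0.0, 1.0, size=(nd, r))
    cell_factors = rng.normal(0.0, 1.0, size=(nc, r))
    conc_grids = {}
    for i, d in enumerate(drugs):
        grid = np.logspace(ref_log_ec50[i] - 1.5, ref_log_ec50[i] + 1.5, g)
        conc_grids[d] = [round_conc(c) for c in grid]
    tissue_of = {c: f"T{j % config.n_tissues}" for j, c in enumerate(cells)}
    truth = GroundTruth(config=config, drugs=drugs, cell_lines=cells,
                        conc_grids=conc_grids, ec50=ec50, slope=slope, emax=emax,
                        drug_factors=drug_factors, cell_factors=cell_factors,
                        tissue_of=tissue_of)

    all_pairs = [(drugs[i], drugs[j]) for i in range(nd) for j in range(i + 1, nd)]
    n_pairs = int(round(config.pair_fraction * len(all_pairs)))
    # re-draw until every screened drug sits in >= 2 pairs (screens pair
    # each drug with many partners; also keeps pair-level hold-out feasible)
    for _ in range(1000):
        chosen = [all_pairs[i] for i in sorted(rng.choice(len(all_pairs), size=n_pairs,
                                                          replace=False))]
        degree: dict[str, int] = {}
        for a, b in chosen:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        if all(v >= 2 for v in degree.values()):
            break

    noise = rng if config.noise_sd > 0 else None
    measurements: list[Measurement] = []
    for da, db in chosen:
        for cell in cells:
            for ca in conc_grids[da]:
                for cb in conc_grids[db]:
                    resp = simulate_combination(da, ca, db, cb, cell, truth, noise)
                    measurements.append(Measurement(da, ca, db, cb, cell, resp))
    for d in drugs:
        for cell in cells:
            for c in conc_grids[d]:
                resp = simulate_monotherapy(d, cell, c, truth, noise)
                measurements.append(Measurement(d, c, None, None, cell, resp))
    return Dataset.from_measurements(measurements), truth
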