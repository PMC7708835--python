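"""Synergy quantification from dose-response matrices.

Two scores are provided.  The NCI ComboScore sums, over all grid cells,
the deviation between the observed combination growth and an expected
growth built from truncated monotherapy growth fractions:

    y(A, B) = sum_{p,q} (y_c(A_p, B_q) - y_e(A_p, B_q))
    y_e     = min(y_m(A_p), y_m(B_q))            if either margin <= 0
              (1/150) min(y_m(A_p), 150) * min(y_m(B_q), 150)  otherwise

As printed, lower-than-expected growth (more kill, i.e. synergy for
growth data) makes the sum negative; the opposite convention -- positive
values synergistic, as synergy scores are usually read -- is exposed as
``alm_positive_synergy``.  The Bliss most-synergistic-area score is the
maximal windowed mean of excess inhibition over the Bliss independence
surface e_a + e_b - e_a*e_b, scaled by 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .data import DoseResponseMatrix

TRUNCATION = 150.0


@dataclass(frozen=True)
class SynergyScore:
    drug_a: str
    drug_b: str
    cell_line: str
    method: str  # "comboscore" or "bliss_msa"
    value: float


def expected_response(mono_a: np.ndarray, mono_b: np.ndarray) -> np.ndarray:
    """Expected combination growth from monotherapy margins.

    Cell (p, q) is min(y_m(A_p), y_m(B_q)) when either margin is <= 0,
    otherwise the product of the margins truncated at 150, divided by
    150.  Shape: (len(mono_a), len(mono_b)).
    """
    a = np.asarray(mono_a, dtype=float)
    b = np.asarray(mono_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("monotherapy vectors must be nonempty")
    A = a[:, None]
    B = b[None, :]
    product = (np.minimum(A, TRUNCATION) * np.minimum(B, TRUNCATION)) / TRUNCATION
    return np.where((A <= 0) | (B <= 0), np.minimum(A, B), product)


def combo_score(matrix: DoseResponseMatrix,
                sign_convention: str = "as_printed",
                combo: Optional[np.ndarray] = None) -> SynergyScore:
    """NCI ComboScore of one dose-response matrix.

    Requires fully observed monotherapy margins; masked combination
    cells are excluded from the sum with a warning.  ``combo`` overrides
    the observed grid (e.g. to score a model-predicted grid against the
    measured monotherapies).  ``sign_convention``: ``as_printed`` sums
    observed-minus-expected (synergistic growth reduction is negative);
    ``alm_positive_synergy`` negates it.
    """
    if sign_convention not in ("as_printed", "alm_positive_synergy"):
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    if not (matrix.mono_a_mask.all() and matrix.mono_b_mask.all()):
        raise ValueError(f"monotherapy margins incomplete for "
                         f"({matrix.drug_a}, {matrix.drug_b}, {matrix.cell_line})")
    observed = matrix.combo if combo is None else np.asarray(combo, dtype=float)
    mask = matrix.mask if combo is None else np.ones_like(observed, dtype=bool)
    if not mask.any():
        raise ValueError("no observed combination cell to score")
    if not mask.all():
        warnings.warn(f"{(~mask).sum()} masked cell(s) excluded from ComboScore",
                      stacklevel=2)
    expected = expected_response(matrix.mono_a, matrix.mono_b)
    value = float(np.sum((observed - expected)[mask]))
    if sign_convention == "alm_positive_synergy":
        value = -value
    return SynergyScore(matrix.drug_a, matrix.drug_b, matrix.cell_line,
                        "comboscore", value)


def label_top_synergistic(scores: Sequence[SynergyScore],
                          fraction: float = 0.1,
                          grouping: str = "global",
                          tissue_of: Optional[Mapping[str, str]] = None) -> list[bool]:
    """Binary labels marking the most synergistic fraction of scores.

    Exactly floor(fraction * N) positives per group (globally, or per
    tissue when ``grouping='per_tissue'``), taking the largest values;
    ties at the cutoff are broken deterministically by descending score
    then ascending (drug_a, drug_b, cell_line).
    """
    if not scores:
        raise ValueError("no scores to label")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if grouping == "global":
        groups = {"<all>": list(range(len(scores)))}
    elif grouping == "per_tissue":
        if tissue_of is None:
            raise ValueError("per_tissue labeling requires a tissue mapping")
        groups = {}
        for i, s in enumerate(scores):
            groups.setdefault(tissue_of[s.cell_line], []).append(i)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    labels = [False] * len(scores)
    for name, idx in groups.items():
        if not idx:
            raise ValueError(f"empty group {name!r}")
        n_pos = int(np.floor(fraction * len(idx)))
        ranked = sorted(idx, key=lambda i: (-scores[i].value, scores[i].drug_a,
                                            scores[i].drug_b, scores[i].cell_line))
        for i in ranked[:n_pos]:
            labels[i] = True
    return labels


def bliss_msa(inhibition: np.ndarray,
              inh_a: np.ndarray,
              inh_b: np.ndarray,
              window: int = 3,
              *,
              drug_a: str = "", drug_b: str = "", cell_line: str = "") -> SynergyScore:
    """Bliss most-synergistic-area score of a fraction-inhibition grid.

    excess(p, q) = obs(p, q) - (e_a(p) + e_b(q) - e_a(p) e_b(q)); the
    score is 100 times the maximal mean excess over all contiguous
    window x window sub-grids.  Inputs are clamped to [0, 1]; a window
    larger than the grid is shrunk with a warning.
    """
    obs = np.clip(np.asarray(inhibition, dtype=float), 0.0, 1.0)
    ea = np.clip(np.asarray(inh_a, dtype=float), 0.0, 1.0)
    eb = np.clip(np.asarray(inh_b, dtype=float), 0.0, 1.0)
    if obs.shape != (len(ea), len(eb)):
        raise ValueError("inhibition grid does not match its margins")
    if window < 1:
        raise ValueError("window must be >= 1")
    wmax = min(obs.shape)
    if window > wmax:
        warnings.warn(f"window {window} larger than grid {obs.shape}; using {wmax}",
                      stacklevel=2)
        window = wmax
    bliss = ea[:, None] + eb[None, :] - ea[:, None] * eb[None, :]
    excess = obs - bliss
    windows = np.lib.stride_tricks.sliding_window_view(excess, (window, window))
    value = 100.0 * float(windows.mean(axis=(2, 3)).max())
    return SynergyScore(drug_a, drug_b, cell_line, "bliss_msa", value)


def matrix_bliss_msa(matrix: DoseResponseMatrix, window: int = 3,
                     combo: Optional[np.ndarray] = None) -> SynergyScore:
    """Bliss MSA of a percentage-growth matrix (inhibition = 1 - growth/100)."""
    observed = matrix.combo if combo is None else np.asarray(combo, dtype=float)
    return bliss_msa(1.0 - observed / 100.0,
                     1.0 - matrix.mono_a / 100.0,
                     1.0 - matrix.mono_b / 100.0,
                     window,
                     drug_a=matrix.drug_a, drug_b=matrix.drug_b,
                     cell_line=matrix.cell_line)


def write_scores(scores: Sequence[SynergyScore], labels: Optional[Sequence[bool]],
                 path) -> None:
    """Delimited score table: drug_a, drug_b, cell_line, method, value, label."""
    import pandas as pd

    rows = []
    for i, s in enumerate(scores):
        rows.append({"drug_a": s.drug_a, "drug_b": s.drug_b, "cell_line": s.cell_line,
                     "method": s.method, "value": s.value,
                     "label": int(labels[i]) if labels is not None else ""})
    pd.DataFrame(rows, columns=["drug_a", "drug_b", "cell_line",
                                "method", "value", "label"]).to_csv(path, index=False)
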