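"""Data model and I/O for drug-combination dose-response screens.

A screen is a long-format table of wells: (drug A, concentration A,
drug B, concentration B, cell line, percentage growth).  Monotherapy
wells leave the drug-B fields empty.  Percentage growth follows the
NCI-60 convention: 100 = untreated growth, 0 = complete growth
inhibition, negative = net cell kill.  Measurements are assembled into
per-(drug pair, cell line) dose-response matrices with monotherapy
margins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Sentinel drug identifier used for the absent partner of a monotherapy well.
NONE_DRUG = "<none>"

#: Default column mapping, matching NCI-ALMANAC export names.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "drug_a": "NSC1",
    "conc_a": "CONC1",
    "drug_b": "NSC2",
    "conc_b": "CONC2",
    "cell_line": "CELLNAME",
    "response": "PERCENTGROWTH",
}

#: Column names written by :func:`write_predictions`.
OUTPUT_COLUMNS = ("drug_a", "conc_a", "drug_b", "conc_b", "cell_line", "response", "predicted")


def round_conc(value: float) -> float:
    """Round a concentration to 10 significant digits.

    Concentrations coming from delimited text may carry formatting jitter
    (e.g. ``1e-7`` vs ``1.0000000001e-7``); all comparisons go through
    this canonical rounding.
    """
    return float(f"{float(value):.10g}")


@dataclass(frozen=True)
class Measurement:
    """One screened well.

    ``drug_b``/``conc_b`` are ``None`` for monotherapy wells.  After the
    symmetric duplication used for training, the sentinel may also occupy
    the A slot; at least one real drug is always present.
    """

    drug_a: Optional[str]
    conc_a: Optional[float]
    drug_b: Optional[str]
    conc_b: Optional[float]
    cell_line: str
    response: float

    def __post_init__(self):
        if (self.drug_a is None) != (self.conc_a is None):
            raise ValueError(f"drug_a and conc_a must be jointly present or absent: {self}")
        if (self.drug_b is None) != (self.conc_b is None):
            raise ValueError(f"drug_b and conc_b must be jointly present or absent: {self}")
        if self.drug_a is None and self.drug_b is None:
            raise ValueError("a measurement needs at least one drug")
        if self.conc_a is not None and self.conc_a <= 0:
            raise ValueError(f"conc_a must be positive, got {self.conc_a}")
        if self.conc_b is not None and self.conc_b <= 0:
            raise ValueError(f"conc_b must be positive, got {self.conc_b}")
        if self.drug_a is not None and self.drug_a == self.drug_b:
            raise ValueError(f"combination of a drug with itself: {self.drug_a}")

    @property
    def is_combination(self) -> bool:
        return self.drug_a is not None and self.drug_b is not None

    def key(self):
        """Unique well key (drug_a, conc_a, drug_b, conc_b, cell_line)."""
        return (self.drug_a, self.conc_a, self.drug_b, self.conc_b, self.cell_line)

    def pair_key(self):
        """Canonical unordered drug pair (lexicographic)."""
        a, b = self.drug_a, self.drug_b
        if a is None or b is None:
            return (a if a is not None else b,)
        return (a, b) if a <= b else (b, a)

    def swapped(self) -> "Measurement":
        """The same well with the drug slots exchanged."""
        return Measurement(self.drug_b, self.conc_b, self.drug_a, self.conc_a,
                           self.cell_line, self.response)


@dataclass
class Dataset:
    """An ordered collection of measurements plus its vocabularies.

    Vocabularies are built in first-appearance order and contain exactly
    the values occurring in the measurements (the monotherapy sentinel is
    added later, by the encoding layer).
    """

    measurements: list[Measurement]
    drugs: list[str]
    concentrations: list[float]
    cell_lines: list[str]

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def combination_indices(self) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.measurements) if m.is_combination],
                        dtype=int)

    @property
    def monotherapy_indices(self) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.measurements) if not m.is_combination],
                        dtype=int)

    def subset(self, indices: Iterable[int]) -> "Dataset":
        """A new Dataset sharing this one's vocabularies (structural metadata)."""
        ms = [self.measurements[i] for i in indices]
        return Dataset(ms, list(self.drugs), list(self.concentrations), list(self.cell_lines))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"drug_a": m.drug_a, "conc_a": m.conc_a, "drug_b": m.drug_b,
                 "conc_b": m.conc_b, "cell_line": m.cell_line, "response": m.response}
                for m in self.measurements]
        return pd.DataFrame(rows)

    @classmethod
    def from_measurements(cls, measurements: Sequence[Measurement]) -> "Dataset":
        """Build a Dataset with vocabularies in first-appearance order."""
        drugs: list[str] = []
        concs: list[float] = []
        cells: list[str] = []
        seen_d, seen_c, seen_l = set(), set(), set()
        for m in measurements:
            for d in (m.drug_a, m.drug_b):
                if d is not None and d not in seen_d:
                    seen_d.add(d)
                    drugs.append(d)
            for c in (m.conc_a, m.conc_b):
                if c is not None and c not in seen_c:
                    seen_c.add(c)
                    concs.append(c)
            if m.cell_line not in seen_l:
                seen_l.add(m.cell_line)
                cells.append(m.cell_line)
        return cls(list(measurements), drugs, concs, cells)


@dataclass
class DoseResponseMatrix:
    """A (drug pair, cell line) grid of combination responses plus margins.

    ``combo[p, q]`` is the percentage growth at ``conc_a_grid[p]`` of
    ``drug_a`` combined with ``conc_b_grid[q]`` of ``drug_b``; ``mask``
    flags observed cells.  ``mono_a``/``mono_b`` are the monotherapy
    margins at the grid concentrations (NaN where unobserved, flagged in
    ``mono_a_mask``/``mono_b_mask``).  ``predicted`` optionally holds a
    model-filled grid of the same shape.
    """

    drug_a: str
    drug_b: str
    cell_line: str
    conc_a_grid: np.ndarray
    conc_b_grid: np.ndarray
    combo: np.ndarray
    mono_a: np.ndarray
    mono_b: np.ndarray
    mask: np.ndarray
    mono_a_mask: np.ndarray = None
    mono_b_mask: np.ndarray = None
    predicted: Optional[np.ndarray] = None

    def __post_init__(self):
        self.conc_a_grid = np.asarray(self.conc_a_grid, dtype=float)
        self.conc_b_grid = np.asarray(self.conc_b_grid, dtype=float)
        if np.any(np.diff(self.conc_a_grid) <= 0) or np.any(np.diff(self.conc_b_grid) <= 0):
            raise ValueError("concentration grids must be strictly increasing")
        shape = (len(self.conc_a_grid), len(self.conc_b_grid))
        self.combo = np.asarray(self.combo, dtype=float)
        if self.combo.shape != shape:
            raise ValueError(f"combo shape {self.combo.shape} != grid shape {shape}")
        self.mono_a = np.asarray(self.mono_a, dtype=float)
        self.mono_b = np.asarray(self.mono_b, dtype=float)
        if len(self.mono_a) != shape[0] or len(self.mono_b) != shape[1]:
            raise ValueError("monotherapy margins must match grid lengths")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != shape:
            raise ValueError("mask must match combo shape")
        if self.mono_a_mask is None:
            self.mono_a_mask = ~np.isnan(self.mono_a)
        if self.mono_b_mask is None:
            self.mono_b_mask = ~np.isnan(self.mono_b)
        self.mono_a_mask = np.asarray(self.mono_a_mask, dtype=bool)
        self.mono_b_mask = np.asarray(self.mono_b_mask, dtype=bool)


class ConfigurationError(ValueError):
    """A problem with the column mapping or file layout."""


def _parse_conc(raw, lineno: int) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
        return None
    try:
        v = float(raw)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: unparsable concentration {raw!r}") from exc
    if v <= 0:
        raise ValueError(f"line {lineno}: concentration must be positive, got {v}")
    return round_conc(v)


def read_measurements(path, column_map: Optional[Mapping[str, str]] = None) -> Dataset:
    """Read a long-format screen table into a :class:`Dataset`.

    The delimiter (comma or tab) is auto-detected.  ``column_map`` maps
    the logical names ``drug_a, conc_a, drug_b, conc_b, cell_line,
    response`` to the file's column headers; the default matches
    NCI-ALMANAC export names.  Combination rows are canonicalized so
    that ``drug_a <= drug_b`` lexicographically; replicate wells (same
    key) are averaged with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    frame = pd.read_csv(path, sep=None, engine="python",
                        dtype={cols["drug_a"]: str, cols["drug_b"]: str,
                               cols["cell_line"]: str})
    for logical, name in cols.items():
        if logical in ("drug_a", "conc_a", "drug_b", "conc_b", "cell_line", "response") \
                and name not in frame.columns:
            raise ConfigurationError(f"missing column {name!r} (mapped from {logical!r})")

    measurements: list[Measurement] = []
    for pos, row in enumerate(frame.itertuples(index=False)):
        lineno = pos + 2  # header is line 1
        rec = dict(zip(frame.columns, row))
        drug_a = rec[cols["drug_a"]]
        drug_b = rec[cols["drug_b"]]
        drug_a = None if (drug_a is None or (isinstance(drug_a, float) and np.isnan(drug_a))
                          or str(drug_a).strip() == "") else str(drug_a).strip()
        drug_b = None if (drug_b is None or (isinstance(drug_b, float) and np.isnan(drug_b))
                          or str(drug_b).strip() == "") else str(drug_b).strip()
        if drug_a == NONE_DRUG:
            drug_a = None
        if drug_b == NONE_DRUG:
            drug_b = None
        conc_a = _parse_conc(rec[cols["conc_a"]], lineno)
        conc_b = _parse_conc(rec[cols["conc_b"]], lineno)
        try:
            response = float(rec[cols["response"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"line {lineno}: unparsable response "
                             f"{rec[cols['response']]!r}") from exc
        try:
            m = Measurement(drug_a, conc_a, drug_b, conc_b,
                            str(rec[cols["cell_line"]]).strip(), response)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        # canonical pair ordering: drug_a lexicographically first
        if m.is_combination and m.drug_a > m.drug_b:
            m = m.swapped()
        elif m.drug_a is None:  # monotherapy written with the drug in slot B
            m = m.swapped()
        measurements.append(m)

    # average replicates (same key, multiple responses)
    by_key: dict[tuple, list[Measurement]] = {}
    order: list[tuple] = []
    for m in measurements:
        k = m.key()
        if k not in by_key:
            by_key[k] = []
            order.append(k)
        by_key[k].append(m)
    deduped: list[Measurement] = []
    n_replicated = 0
    for k in order:
        group = by_key[k]
        if len(group) == 1:
            deduped.append(group[0])
        else:
            n_replicated += 1
            mean = float(np.mean([g.response for g in group]))
            deduped.append(replace(group[0], response=mean))
    if n_replicated:
        warnings.warn(f"{n_replicated} well key(s) had replicate rows; responses averaged",
                      stacklevel=2)
    return Dataset.from_measurements(deduped)


def assemble_matrices(dataset: Dataset) -> list[DoseResponseMatrix]:
    """Group combination measurements into dose-response matrices.

    One matrix per (canonical drug pair, cell line) with at least one
    combination measurement.  Grids are the sorted distinct
    concentrations observed for that matrix; unobserved combination
    cells are masked, and monotherapy margins are filled from matching
    monotherapy wells (NaN + mask where absent).
    """
    if not dataset.measurements:
        raise ValueError("empty dataset")
    mono: dict[tuple, float] = {}
    for m in dataset.measurements:
        if not m.is_combination:
            mono[(m.drug_a, m.conc_a, m.cell_line)] = m.response

    groups: dict[tuple, list[Measurement]] = {}
    for m in dataset.measurements:
        if m.is_combination:
            groups.setdefault((m.drug_a, m.drug_b, m.cell_line), []).append(m)

    matrices = []
    for (da, db, cell), ms in groups.items():
        grid_a = sorted({m.conc_a for m in ms})
        grid_b = sorted({m.conc_b for m in ms})
        ia = {c: i for i, c in enumerate(grid_a)}
        ib = {c: i for i, c in enumerate(grid_b)}
        combo = np.full((len(grid_a), len(grid_b)), np.nan)
        mask = np.zeros_like(combo, dtype=bool)
        for m in ms:
            combo[ia[m.conc_a], ib[m.conc_b]] = m.response
            mask[ia[m.conc_a], ib[m.conc_b]] = True
        mono_a = np.array([mono.get((da, c, cell), np.nan) for c in grid_a])
        mono_b = np.array([mono.get((db, c, cell), np.nan) for c in grid_b])
        matrices.append(DoseResponseMatrix(da, db, cell, np.array(grid_a), np.array(grid_b),
                                           combo, mono_a, mono_b, mask))
    return matrices


def write_predictions(matrices: Sequence[DoseResponseMatrix], path) -> None:
    """Write matrices as a long-format delimited file (one row per cell).

    Emits combination rows for every observed (unmasked) grid cell plus
    monotherapy margin rows, with columns ``drug_a, conc_a, drug_b,
    conc_b, cell_line, response, predicted``.  Round-trips through
    :func:`read_measurements` up to row ordering.
    """
    rows = []
    for mat in matrices:
        for p, ca in enumerate(mat.conc_a_grid):
            for q, cb in enumerate(mat.conc_b_grid):
                if not mat.mask[p, q]:
                    continue
                pred = mat.predicted[p, q] if mat.predicted is not None else ""
                rows.append((mat.drug_a, ca, mat.drug_b, cb, mat.cell_line,
                             mat.combo[p, q], pred))
        for p, ca in enumerate(mat.conc_a_grid):
            if mat.mono_a_mask[p]:
                rows.append((mat.drug_a, ca, "", "", mat.cell_line, mat.mono_a[p], ""))
        for q, cb in enumerate(mat.conc_b_grid):
            if mat.mono_b_mask[q]:
                rows.append((mat.drug_b, cb, "", "", mat.cell_line, mat.mono_b[q], ""))
    frame = pd.DataFrame(rows, columns=OUTPUT_COLUMNS)
    # a monotherapy margin shared by two matrices must appear once
    frame = frame.drop_duplicates(subset=list(OUTPUT_COLUMNS[:5]))
    frame.to_csv(path, index=False)


#: column_map for re-reading files produced by :func:`write_predictions`.
PREDICTION_COLUMNS: Mapping[str, str] = {
    "drug_a": "drug_a", "conc_a": "conc_a", "drug_b": "drug_b",
    "conc_b": "conc_b", "cell_line": "cell_line", "response": "response",
}
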