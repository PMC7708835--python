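"""One-hot + descriptor feature encoding for factorization machines.

Each well becomes a sparse real vector whose first five blocks one-hot
encode the tensor modes (drug A, drug B, concentration A, concentration
B, cell line); optional auxiliary blocks carry molecular fingerprints
for each drug slot, a gene-expression profile for the cell line, and
scalar log10 concentrations.  A monotherapy well places a sentinel
category in the absent drug/concentration slots, so every measurement
remains an entry of the same fifth-order tensor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import NONE_DRUG, Dataset, Measurement

#: Sentinel concentration category label (the sentinel has no numeric value).
NONE_CONC = "<none>"


@dataclass
class DescriptorTables:
    """Auxiliary descriptors: drug fingerprints and cell-line expression.

    ``fingerprints``: drugs x bits binary DataFrame (e.g. 79 raw E-state
    bits).  ``expression``: cell lines x genes real DataFrame (z-score
    scale).  Row indices are drug / cell-line identifiers.
    """

    fingerprints: Optional[pd.DataFrame] = None
    expression: Optional[pd.DataFrame] = None


@dataclass(frozen=True)
class Block:
    name: str
    offset: int
    width: int


@dataclass
class EncodingLayout:
    """Block structure of the feature vector.

    Blocks appear in the fixed order drugA/drugB/concA/concB/cell
    one-hots, then drugA/drugB fingerprint, cell expression and scalar
    concentration blocks where enabled.  ``d`` is the total dimension.
    """

    blocks: list[Block]
    d: int
    drugs: list[str]
    concentrations: list[float]
    cell_lines: list[str]
    fingerprint_mask: Optional[np.ndarray] = None
    gene_selection: Optional[list[str]] = None
    sentinel: bool = True
    drug_index: dict = field(default_factory=dict)
    conc_index: dict = field(default_factory=dict)
    cell_index: dict = field(default_factory=dict)

    def block(self, name: str) -> Block:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def has_block(self, name: str) -> bool:
        return any(b.name == name for b in self.blocks)

    def decode(self, x: np.ndarray):
        """Invert the one-hot part of an encoded vector.

        Returns the (drug_a, conc_a, drug_b, conc_b, cell_line) tuple,
        with ``None`` for sentinel categories.
        """
        def _argone(bname, vocab, sentinel_label):
            b = self.block(bname)
            idx = int(np.argmax(x[b.offset:b.offset + b.width]))
            if self.sentinel and idx == b.width - 1:
                return None
            return vocab[idx]

        da = _argone("drug_a_onehot", self.drugs, NONE_DRUG)
        db = _argone("drug_b_onehot", self.drugs, NONE_DRUG)
        ca = _argone("conc_a_onehot", self.concentrations, NONE_CONC)
        cb = _argone("conc_b_onehot", self.concentrations, NONE_CONC)
        cell_b = self.block("cell_onehot")
        cell = self.cell_lines[int(np.argmax(x[cell_b.offset:cell_b.offset + cell_b.width]))]
        return (da, ca, db, cb, cell)

    def to_manifest(self) -> dict:
        return {
            "d": self.d,
            "blocks": [{"name": b.name, "offset": b.offset, "width": b.width}
                       for b in self.blocks],
            "drugs": self.drugs,
            "concentrations": self.concentrations,
            "cell_lines": self.cell_lines,
            "sentinel": self.sentinel,
            "fingerprint_mask": (None if self.fingerprint_mask is None
                                 else [int(i) for i in self.fingerprint_mask]),
            "gene_selection": self.gene_selection,
        }


def zero_variance_filter(fingerprints: pd.DataFrame) -> np.ndarray:
    """Indices of fingerprint bits taking >= 2 distinct values across drugs.

    Constant bits carry no information and are removed (ascending index
    order).  Requires at least two drugs.
    """
    if fingerprints.shape[0] < 2:
        raise ValueError("zero-variance filtering needs at least 2 drugs")
    values = fingerprints.to_numpy()
    keep = [j for j in range(values.shape[1]) if len(np.unique(values[:, j])) >= 2]
    return np.array(keep, dtype=int)


def top_variance_genes(expression: pd.DataFrame, fraction: float) -> list[str]:
    """The ceil(fraction * n_genes) genes with largest sample variance.

    Variance is taken across cell lines (ddof=1); ties are broken by
    gene-identifier lexicographic order for determinism.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if expression.shape[0] < 2:
        raise ValueError("gene selection needs at least 2 cell lines")
    n = math.ceil(fraction * expression.shape[1])
    var = expression.var(axis=0, ddof=1)
    order = sorted(expression.columns, key=lambda g: (-var[g], str(g)))
    return list(order[:n])


def fit_layout(dataset: Dataset,
               tables: Optional[DescriptorTables] = None,
               *,
               use_fingerprints: Optional[bool] = None,
               use_expression: Optional[bool] = None,
               use_conc_values: bool = False,
               gene_fraction: float = 0.005,
               monotherapy_sentinel: bool = True) -> EncodingLayout:
    """Derive the encoding layout from a dataset's vocabularies.

    One-hot widths are |drugs|, |drugs|, |concentrations|,
    |concentrations|, |cell lines| (each drug/concentration block gains
    one sentinel category when ``monotherapy_sentinel``).  Fingerprint
    bits pass a zero-variance filter; expression genes are reduced to
    the top ``gene_fraction`` by variance.  ``use_fingerprints`` /
    ``use_expression`` default to "on iff the table is provided".
    """
    tables = tables or DescriptorTables()
    if use_fingerprints is None:
        use_fingerprints = tables.fingerprints is not None
    if use_expression is None:
        use_expression = tables.expression is not None
    if use_fingerprints and tables.fingerprints is None:
        raise ValueError("use_fingerprints requires a fingerprint table")
    if use_expression and tables.expression is None:
        raise ValueError("use_expression requires an expression table")

    if use_fingerprints:
        missing = [d for d in dataset.drugs if d not in tables.fingerprints.index]
        if missing:
            raise KeyError(f"no fingerprint row for drug(s): {missing}")
    if use_expression:
        missing = [c for c in dataset.cell_lines if c not in tables.expression.index]
        if missing:
            raise KeyError(f"no expression row for cell line(s): {missing}")

    fp_mask = zero_variance_filter(tables.fingerprints) if use_fingerprints else None
    genes = top_variance_genes(tables.expression, gene_fraction) if use_expression else None

    extra = 1 if monotherapy_sentinel else 0
    nd = len(dataset.drugs) + extra
    nc = len(dataset.concentrations) + extra
    nl = len(dataset.cell_lines)
    widths = [("drug_a_onehot", nd), ("drug_b_onehot", nd),
              ("conc_a_onehot", nc), ("conc_b_onehot", nc),
              ("cell_onehot", nl)]
    if fp_mask is not None:
        widths += [("drug_a_fingerprint", len(fp_mask)), ("drug_b_fingerprint", len(fp_mask))]
    if genes is not None:
        widths += [("cell_expression", len(genes))]
    if use_conc_values:
        widths += [("conc_a_value", 1), ("conc_b_value", 1)]

    blocks, offset = [], 0
    for name, w in widths:
        blocks.append(Block(name, offset, w))
        offset += w
    layout = EncodingLayout(
        blocks=blocks, d=offset,
        drugs=list(dataset.drugs),
        concentrations=list(dataset.concentrations),
        cell_lines=list(dataset.cell_lines),
        fingerprint_mask=fp_mask, gene_selection=genes,
        sentinel=monotherapy_sentinel,
    )
    layout.drug_index = {d: i for i, d in enumerate(layout.drugs)}
    layout.conc_index = {c: i for i, c in enumerate(layout.concentrations)}
    layout.cell_index = {c: i for i, c in enumerate(layout.cell_lines)}
    return layout


def _slot_index(value, index: Mapping, width: int, sentinel: bool, what: str) -> int:
    if value is None:
        if not sentinel:
            raise KeyError(f"monotherapy {what} encountered but sentinel disabled")
        return width - 1
    try:
        return index[value]
    except KeyError as exc:
        raise KeyError(f"unknown {what}: {value!r}") from exc


def encode(measurement: Measurement,
           layout: EncodingLayout,
           tables: Optional[DescriptorTables] = None) -> np.ndarray:
    """Encode one measurement as a length-d feature vector."""
    return encode_measurements([measurement], layout, tables)[0]


def encode_measurements(measurements: Sequence[Measurement],
                        layout: EncodingLayout,
                        tables: Optional[DescriptorTables] = None) -> np.ndarray:
    """Encode measurements into a dense (n, d) design matrix.

    One-hot blocks receive exactly one 1 each (sentinel categories for
    monotherapy slots); fingerprint and expression blocks carry the
    drug/cell descriptors (all-zero for the sentinel drug); scalar
    concentration features are log10 of molar concentration, 0 for the
    sentinel.  Unknown categories raise (vocabularies are never silently
    extended).
    """
    tables = tables or DescriptorTables()
    n = len(measurements)
    X = np.zeros((n, layout.d))
    bda = layout.block("drug_a_onehot")
    bdb = layout.block("drug_b_onehot")
    bca = layout.block("conc_a_onehot")
    bcb = layout.block("conc_b_onehot")
    bcell = layout.block("cell_onehot")
    fp = layout.fingerprint_mask
    if fp is not None:
        fpa = layout.block("drug_a_fingerprint")
        fpb = layout.block("drug_b_fingerprint")
        fp_rows = tables.fingerprints.iloc[:, fp]
    if layout.gene_selection is not None:
        bexp = layout.block("cell_expression")
        expr = tables.expression[layout.gene_selection]
    has_vals = layout.has_block("conc_a_value")
    if has_vals:
        bva = layout.block("conc_a_value")
        bvb = layout.block("conc_b_value")

    for i, m in enumerate(measurements):
        ia = _slot_index(m.drug_a, layout.drug_index, bda.width, layout.sentinel, "drug")
        ib = _slot_index(m.drug_b, layout.drug_index, bdb.width, layout.sentinel, "drug")
        ica = _slot_index(m.conc_a, layout.conc_index, bca.width, layout.sentinel, "concentration")
        icb = _slot_index(m.conc_b, layout.conc_index, bcb.width, layout.sentinel, "concentration")
        if m.cell_line not in layout.cell_index:
            raise KeyError(f"unknown cell line: {m.cell_line!r}")
        X[i, bda.offset + ia] = 1.0
        X[i, bdb.offset + ib] = 1.0
        X[i, bca.offset + ica] = 1.0
        X[i, bcb.offset + icb] = 1.0
        X[i, bcell.offset + layout.cell_index[m.cell_line]] = 1.0
        if fp is not None:
            if m.drug_a is not None:
                X[i, fpa.offset:fpa.offset + fpa.width] = fp_rows.loc[m.drug_a].to_numpy()
            if m.drug_b is not None:
                X[i, fpb.offset:fpb.offset + fpb.width] = fp_rows.loc[m.drug_b].to_numpy()
        if layout.gene_selection is not None:
            X[i, bexp.offset:bexp.offset + bexp.width] = expr.loc[m.cell_line].to_numpy()
        if has_vals:
            X[i, bva.offset] = 0.0 if m.conc_a is None else np.log10(m.conc_a)
            X[i, bvb.offset] = 0.0 if m.conc_b is None else np.log10(m.conc_b)
    return X


def swap_blocks(X: np.ndarray, layout: EncodingLayout) -> np.ndarray:
    """Exchange the drug-A and drug-B halves of encoded vectors.

    Swaps the drugA/drugB one-hots, concA/concB one-hots, fingerprint
    blocks and scalar concentration features; the cell blocks are
    untouched.  ``encode(m.swapped())`` equals ``swap_blocks(encode(m))``
    exactly.
    """
    out = np.array(X, copy=True)
    pairs = [("drug_a_onehot", "drug_b_onehot"), ("conc_a_onehot", "conc_b_onehot")]
    if layout.has_block("drug_a_fingerprint"):
        pairs.append(("drug_a_fingerprint", "drug_b_fingerprint"))
    if layout.has_block("conc_a_value"):
        pairs.append(("conc_a_value", "conc_b_value"))
    for na, nb in pairs:
        a, b = layout.block(na), layout.block(nb)
        out[..., a.offset:a.offset + a.width] = X[..., b.offset:b.offset + b.width]
        out[..., b.offset:b.offset + b.width] = X[..., a.offset:a.offset + a.width]
    return out


def duplicate_symmetric(measurements: Sequence[Measurement]) -> list[Measurement]:
    """Duplicate each well with the drug slots exchanged.

    A combination appears in both orientations (A,p,B,q) and (B,q,A,p)
    with equal response, telling the model that drug order is
    immaterial; monotherapies are duplicated with the sentinel on either
    side.  Output size is exactly twice the input.
    """
    out: list[Measurement] = []
    for m in measurements:
        out.append(m)
        out.append(m.swapped())
    return out


def dedupe_measurements(measurements: Sequence[Measurement]) -> list[Measurement]:
    """Drop repeated (key, response) rows, keeping first-appearance order."""
    seen = set()
    out = []
    for m in measurements:
        k = (m.key(), m.response)
        if k not in seen:
            seen.add(k)
            out.append(m)
    return out
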