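"""Count-to-FPKM conversion and the expression filter.

FPKM(g, s) = count(g, s) * 1e9 / (length(g) * total(s)), with total(s)
taken as the column sum of the supplied count matrix. Genes are retained
for downstream analysis when FPKM exceeds a threshold (default 1.0) in
at least one sample.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import TrioCountMatrix


def _as_length_series(lengths) -> pd.Series:
    if isinstance(lengths, pd.DataFrame):
        if "gene_id" in lengths.columns:
            lengths = lengths.set_index("gene_id")["length_bp"]
        else:
            lengths = lengths.iloc[:, 0]
    s = pd.Series(lengths, dtype=float)
    return s


def compute_fpkm(trio: TrioCountMatrix, lengths) -> pd.DataFrame:
    """Convert a trio count matrix to FPKM.

    Parameters
    ----------
    trio
        The count matrix.
    lengths
        Gene lengths in bp: a Series indexed by gene id, or a DataFrame
        with ``gene_id`` and ``length_bp`` columns. Every gene in the
        matrix must have a length >= 1.

    Returns
    -------
    DataFrame of FPKM values, same shape/index/columns as the counts.
    """
    lengths = _as_length_series(lengths)
    missing = trio.gene_ids.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene length for: {missing[:10].tolist()}")
    lens = lengths.reindex(trio.gene_ids)
    if (lens < 1).any() or lens.isna().any():
        bad = lens.index[(lens < 1) | lens.isna()].tolist()
        raise ValueError(f"gene length must be >= 1 bp; offending genes: {bad[:10]}")
    totals = trio.counts.sum(axis=0).astype(float)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total count: {zero}")
    fpkm = trio.counts.astype(float).div(lens, axis=0).div(totals, axis=1) * 1e9
    return fpkm


def filter_expressed(fpkm: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Genes with FPKM strictly above ``threshold`` in at least one sample.

    Gene order of the input is preserved. ``threshold`` must be >= 0.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = (fpkm > threshold).any(axis=1)
    return fpkm.index[keep.to_numpy(dtype=bool)]
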