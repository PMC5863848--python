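"""TSV readers and writers for every pipeline format.

All files are UTF-8 tab-delimited with '.' decimals. Count matrices use
a ``gene_id`` first column and ``sample:genotype:replicate`` headers so
the genotype-role metadata travels with the data.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ROLES, TrioCountMatrix


def write_counts_tsv(trio: TrioCountMatrix, path) -> None:
    df = trio.counts.copy()
    df.columns = [
        f"{s}:{trio.sample_meta.loc[s, 'role']}:{trio.sample_meta.loc[s, 'replicate']}"
        for s in trio.counts.columns
    ]
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path) -> TrioCountMatrix:
    """Read a counts TSV with ``sample:genotype:replicate`` headers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no genes")
    samples, roles, reps = [], [], []
    for col in df.columns:
        parts = str(col).split(":")
        if len(parts) != 3:
            raise ValueError(
                f"{path}: header {col!r} is not of the form sample:genotype:replicate"
            )
        sample, role, rep = parts
        if role not in ROLES:
            raise ValueError(f"{path}: unknown genotype token {role!r} in header {col!r}")
        try:
            rep = int(rep)
        except ValueError:
            raise ValueError(f"{path}: non-integer replicate index in header {col!r}") from None
        samples.append(sample)
        roles.append(role)
        reps.append(rep)
    vals = df.to_numpy()
    flt = vals.astype(float)
    if not np.allclose(flt, np.round(flt)):
        bad = np.argwhere(~np.isclose(flt, np.round(flt)))[0]
        raise ValueError(
            f"{path}: non-integer count {vals[bad[0], bad[1]]!r} at gene "
            f"{df.index[bad[0]]!r}, column {df.columns[bad[1]]!r}"
        )
    counts = pd.DataFrame(np.round(flt).astype(np.int64), index=df.index, columns=samples)
    counts.index.name = "gene_id"
    meta = pd.DataFrame(
        {"role": roles, "replicate": reps}, index=pd.Index(samples, name="sample")
    )
    return TrioCountMatrix(counts=counts, sample_meta=meta)


def write_lengths_tsv(lengths: pd.DataFrame, path) -> None:
    lengths.to_csv(path, sep="\t", index=False)


def read_lengths_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "length_bp"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns gene_id, length_bp")
    return df


def write_phenotype_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"genotype", "year", "stage", "replicate", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing column(s) {sorted(missing)}")
    return df


def write_ct_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_ct_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "genotype", "gene_id", "tech_rep", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: Ct table missing column(s) {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path, *, index: bool = True) -> None:
    """Generic TSV writer for result tables."""
    df.to_csv(path, sep="\t", index=index)
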