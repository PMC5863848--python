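"""Core in-memory containers for trio expression data.

A *trio* is the unit of analysis throughout: a female parent, a male
parent, and their F1 hybrid, each sequenced in one or more replicate
libraries. Counts are gene-level non-negative integers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ROLE_FEMALE = "parent_female"
ROLE_MALE = "parent_male"
ROLE_F1 = "f1"
ROLES = (ROLE_FEMALE, ROLE_MALE, ROLE_F1)


@dataclass
class TrioCountMatrix:
    """Gene x sample integer count matrix with genotype-role metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample. Values must
        be non-negative integers.
    sample_meta
        DataFrame indexed by sample id with columns ``role`` (one of
        ``parent_female``, ``parent_male``, ``f1``) and ``replicate``
        (1-based integer index). Index must match ``counts.columns``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.counts.index) == 0:
            raise ValueError("no genes: count matrix has an empty gene list")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:10]}")
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise ValueError(
                "sample_meta index must match count matrix columns "
                f"(got columns {list(self.counts.columns)} vs meta {list(self.sample_meta.index)})"
            )
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(~np.isfinite(vals.astype(float))):
            raise ValueError("counts contain non-finite values")
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals.astype(float))):
            bad = np.argwhere(~np.isclose(vals.astype(float), np.round(vals.astype(float))))
            g, s = bad[0]
            raise ValueError(
                f"non-integer count at gene {self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
            )
        unknown = set(self.sample_meta["role"]) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown genotype role token(s): {sorted(unknown)}; expected one of {ROLES}")
        for role in ROLES:
            if not (self.sample_meta["role"] == role).any():
                raise ValueError(f"genotype role {role!r} has no samples")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return len(self.counts.index)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_for_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown genotype role {role!r}; expected one of {ROLES}")
        return list(self.sample_meta.index[self.sample_meta["role"] == role])
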