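"""Heterosis indices for traits and per-gene expression.

For an F1 with parents of trait values p1, p2 (HP = max, LP = min,
MP = (p1+p2)/2):

    OPH (%) = (F1 - HP) / HP * 100      over-high-parent heterosis
    MPH (%) = (F1 - MP) / MP * 100      mid-parent heterosis
    BPH (%) = (F1 - LP) / LP * 100      low-parent index

Eliminating F1, HP and LP from the three definitions gives the exact
harmonic-mean identity

    1 + MPH/100 = 2 / ( 1/(1+OPH/100) + 1/(1+BPH/100) ),

which lets a published (MPH, OPH, BPH) triple be checked for internal
consistency without access to the underlying trait means.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ROLE_F1, ROLE_FEMALE, ROLE_MALE, TrioCountMatrix

STAGES = ("BT", "AT")  # before / after topping


@dataclass(frozen=True)
class HeterosisIndices:
    f1: float
    hp: float
    lp: float
    mp: float
    oph_pct: float
    mph_pct: float
    bph_pct: float


def heterosis_indices(f1: float, parent1: float, parent2: float) -> HeterosisIndices:
    """OPH/MPH/BPH (percent) for one trait measurement.

    HP and LP are assigned per measurement: whichever parent has the
    larger value is the high parent for this cell. Parent values must be
    positive for the percent formulas to be defined.
    """
    if parent1 <= 0 or parent2 <= 0:
        raise ValueError("parent trait values must be > 0")
    hp = max(parent1, parent2)
    lp = min(parent1, parent2)
    mp = (parent1 + parent2) / 2.0
    return HeterosisIndices(
        f1=f1, hp=hp, lp=lp, mp=mp,
        oph_pct=(f1 - hp) / hp * 100.0,
        mph_pct=(f1 - mp) / mp * 100.0,
        bph_pct=(f1 - lp) / lp * 100.0,
    )


def mph_from_oph_bph(oph_pct: float, bph_pct: float) -> float:
    """Mid-parent heterosis implied by OPH and BPH (harmonic-mean identity).

    Valid for OPH, BPH > -100 (positive F1/parent ratios).
    """
    a = 1.0 + np.asarray(oph_pct, dtype=float) / 100.0
    b = 1.0 + np.asarray(bph_pct, dtype=float) / 100.0
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("OPH and BPH must each be > -100")
    mph = (2.0 / (1.0 / a + 1.0 / b) - 1.0) * 100.0
    return float(mph) if np.ndim(oph_pct) == 0 else mph


def phenotype_heterosis(table: pd.DataFrame) -> pd.DataFrame:
    """Per (year, stage) heterosis from a long phenotype table.

    ``table`` columns: genotype (parent_female/parent_male/f1), year,
    stage, replicate, value. Replicates are averaged per genotype within
    each (year, stage) cell before computing indices.
    """
    required = {"genotype", "year", "stage", "replicate", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table missing column(s): {sorted(missing)}")
    rows = []
    for (year, stage), cell in table.groupby(["year", "stage"], sort=True):
        means = cell.groupby("genotype")["value"].mean()
        for role in (ROLE_FEMALE, ROLE_MALE, ROLE_F1):
            if role not in means.index:
                raise ValueError(f"genotype {role!r} missing in cell (year={year}, stage={stage})")
        h = heterosis_indices(means[ROLE_F1], means[ROLE_FEMALE], means[ROLE_MALE])
        rows.append(
            {"year": year, "stage": stage, "mph_pct": h.mph_pct,
             "oph_pct": h.oph_pct, "bph_pct": h.bph_pct,
             "f1": h.f1, "hp": h.hp, "lp": h.lp, "mp": h.mp}
        )
    return pd.DataFrame(rows)


def gene_expression_heterosis(
    fpkm: pd.DataFrame, sample_meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene OPH/MPH/BPH on genotype-mean FPKM.

    Genes where either parental mean is zero cannot be expressed as
    percent deviations; they are kept in the output with NaN indices and
    ``ok=False`` rather than dropped.
    """
    means = {}
    for role in (ROLE_FEMALE, ROLE_MALE, ROLE_F1):
        cols = sample_meta.index[sample_meta["role"] == role]
        means[role] = fpkm[cols].mean(axis=1)
    pf, pm, f1 = means[ROLE_FEMALE], means[ROLE_MALE], means[ROLE_F1]
    hp = np.maximum(pf, pm)
    lp = np.minimum(pf, pm)
    mp = (pf + pm) / 2.0
    ok = (pf > 0) & (pm > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = pd.DataFrame(
            {
                "oph_pct": np.where(ok, (f1 - hp) / hp * 100.0, np.nan),
                "mph_pct": np.where(ok, (f1 - mp) / mp * 100.0, np.nan),
                "bph_pct": np.where(ok, (f1 - lp) / lp * 100.0, np.nan),
                "ok": ok,
            },
            index=fpkm.index,
        )
    return out
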