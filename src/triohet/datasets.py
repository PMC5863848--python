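"""Small built-in reference datasets.

``nicotine_heterosis_table`` holds published field-trial heterosis
indices of leaf nicotine content for the flue-cured x Oriental tobacco
cross VA116 x Basma over three seasons (2013-2015), measured before
(BT) and after (AT) topping. Values are percent; MPH/OPH/BPH as defined
in :mod:`triohet.heterosis`. The table serves two purposes: an
internal-consistency check of the three indices via the harmonic-mean
identity, and realistic planted effect sizes for the phenotype
simulator.
"""
from __future__ import annotations

import pandas as pd

from .containers import ROLE_F1, ROLE_FEMALE, ROLE_MALE

_NICOTINE_ROWS = [
    # year, stage, mph_pct, oph_pct, bph_pct
    (2013, "BT", 11.48, 3.92, 20.24),
    (2013, "AT", 34.56, 24.65, 46.18),
    (2014, "BT", 10.39, 2.13, 20.11),
    (2014, "AT", 40.84, 28.38, 55.99),
    (2015, "BT", 2.83, 2.36, 3.31),
    (2015, "AT", 44.82, 33.48, 58.26),
]


def nicotine_heterosis_table() -> pd.DataFrame:
    """Nicotine-content heterosis (%) per (year, stage) for VA116 x Basma."""
    return pd.DataFrame(
        _NICOTINE_ROWS, columns=["year", "stage", "mph_pct", "oph_pct", "bph_pct"]
    )


def nicotine_trial_means(lp_value: float = 2.0) -> pd.DataFrame:
    """Genotype trait means consistent with the heterosis table.

    Reconstructs per-cell (female, male, F1) nicotine means from the
    published OPH/BPH pairs, anchoring the low parent at ``lp_value``
    (% dry weight; the high parent is taken as the flue-cured female
    VA116, the low parent as the Oriental male Basma). Feeding the
    result through a noiseless phenotype simulation and
    ``phenotype_heterosis`` recovers OPH and BPH exactly and MPH up to
    the rounding of the published inputs.
    """
    rows = []
    for year, stage, _mph, oph, bph in _NICOTINE_ROWS:
        f1 = lp_value * (1.0 + bph / 100.0)
        hp = f1 / (1.0 + oph / 100.0)
        rows.extend(
            [
                {"genotype": ROLE_FEMALE, "year": year, "stage": stage, "mean": hp},
                {"genotype": ROLE_MALE, "year": year, "stage": stage, "mean": lp_value},
                {"genotype": ROLE_F1, "year": year, "stage": stage, "mean": f1},
            ]
        )
    return pd.DataFrame(rows)
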