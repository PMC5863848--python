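"""Classification of trio genes into the 12 inheritance patterns.

Given three pairwise calls per gene — parents compared to each other,
and the F1 compared to each parent — each gene maps to exactly one of
P1..P12 or NC (not classifiable):

=========  =====================  ==========================================
pattern    rollup                 meaning
=========  =====================  ==========================================
P1, P2     additive               F1 strictly between significantly
                                  different parents (P1: female higher)
P3, P4     higher-parent dom.     F1 level with the higher parent
                                  (P3: male higher, P4: female higher)
P5, P6     lower-parent dom.      F1 level with the lower parent
                                  (P5: male lower, P6: female lower)
P7-P9      up overdominance       F1 significantly above both parents
                                  (P7 female>male, P8 male>female, P9 ns)
P10-P12    down overdominance     mirror of P7-P9
NC         none                   no signal, or logically inconsistent
                                  call combinations
=========  =====================  ==========================================

Call vocabularies: parents f_higher/m_higher/ns; F1-vs-parent up/down/ns
(up = F1 higher than that parent).
"""
from __future__ import annotations

import pandas as pd

from .containers import ROLE_F1, ROLE_FEMALE, ROLE_MALE

PP_CALLS = ("f_higher", "m_higher", "ns")
F1_CALLS = ("up", "down", "ns")
PATTERNS = tuple(f"P{i}" for i in range(1, 13)) + ("NC",)

#: (parents, F1-vs-female, F1-vs-male) -> pattern
DECISION_TABLE: dict[tuple[str, str, str], str] = {
    ("f_higher", "down", "up"): "P1",
    ("m_higher", "up", "down"): "P2",
    ("m_higher", "up", "ns"): "P3",
    ("f_higher", "ns", "up"): "P4",
    ("f_higher", "down", "ns"): "P5",
    ("m_higher", "ns", "down"): "P6",
    ("f_higher", "up", "up"): "P7",
    ("m_higher", "up", "up"): "P8",
    ("ns", "up", "up"): "P9",
    ("f_higher", "down", "down"): "P10",
    ("m_higher", "down", "down"): "P11",
    ("ns", "down", "down"): "P12",
}

ROLLUP: dict[str, str] = {
    "P1": "additive", "P2": "additive",
    "P3": "HPD", "P4": "HPD",
    "P5": "LPD", "P6": "LPD",
    "P7": "UOD", "P8": "UOD", "P9": "UOD",
    "P10": "DOD", "P11": "DOD", "P12": "DOD",
    "NC": "none",
}

ROLLUP_SET_NAMES = {"HPD": "HPDG", "LPD": "LPDG", "UOD": "UODG", "DOD": "DODG"}


def classify_pattern(call_pp: str, call_f1f: str, call_f1m: str) -> tuple[str, str]:
    """Map one gene's three calls to (pattern, rollup).

    Any call combination not in the decision table — no signal, or a
    logically inconsistent combination such as F1 above one parent and
    below the other while the parents do not differ — returns NC/none.
    """
    if call_pp not in PP_CALLS:
        raise ValueError(f"unknown parent-vs-parent call {call_pp!r}; expected {PP_CALLS}")
    if call_f1f not in F1_CALLS or call_f1m not in F1_CALLS:
        raise ValueError(f"unknown F1-vs-parent call; expected {F1_CALLS}")
    pattern = DECISION_TABLE.get((call_pp, call_f1f, call_f1m), "NC")
    return pattern, ROLLUP[pattern]


def classify_patterns(calls: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification of a TrioCalls table.

    ``calls`` must have columns ``call_pp``, ``call_f1f``, ``call_f1m``
    and be indexed by gene id. Returns a DataFrame with ``pattern`` and
    ``rollup`` columns.
    """
    pats = [
        classify_pattern(pp, ff, fm)[0]
        for pp, ff, fm in zip(calls["call_pp"], calls["call_f1f"], calls["call_f1m"])
    ]
    out = pd.DataFrame(
        {"pattern": pats, "rollup": [ROLLUP[p] for p in pats]}, index=calls.index
    )
    return out


def derive_trio_calls(
    de_pp: pd.DataFrame, de_f1f: pd.DataFrame, de_f1m: pd.DataFrame
) -> pd.DataFrame:
    """Build a TrioCalls table from three called DE tables.

    ``de_pp`` must be the male-over-female contrast (its up/down calls
    are translated to m_higher/f_higher); ``de_f1f`` and ``de_f1m`` the
    F1-over-parent contrasts. All three must share a gene index.
    """
    for tbl, expected in (
        (de_pp, (ROLE_FEMALE, ROLE_MALE)),
        (de_f1f, (ROLE_FEMALE, ROLE_F1)),
        (de_f1m, (ROLE_MALE, ROLE_F1)),
    ):
        got = tbl.attrs.get("contrast")
        if got is not None and tuple(got) != expected:
            raise ValueError(f"contrast mismatch: expected {expected}, table has {got}")
    idx = de_pp.index
    if not (idx.equals(de_f1f.index) and idx.equals(de_f1m.index)):
        raise ValueError("the three DE tables must share the same gene index")
    pp = de_pp["call"].map({"up": "m_higher", "down": "f_higher", "ns": "ns"})
    return pd.DataFrame(
        {"call_pp": pp, "call_f1f": de_f1f["call"], "call_f1m": de_f1m["call"]},
        index=idx,
    )


def build_rollup_sets(assignments: pd.DataFrame) -> dict[str, set]:
    """The four non-additive gene sets HPDG/LPDG/UODG/DODG.

    Additive and NC genes belong to none of them; the sets are pairwise
    disjoint by construction.
    """
    sets: dict[str, set] = {name: set() for name in ROLLUP_SET_NAMES.values()}
    for gene, rollup in assignments["rollup"].items():
        name = ROLLUP_SET_NAMES.get(rollup)
        if name is not None:
            sets[name].add(gene)
    return sets


def pattern_summary(assignments: pd.DataFrame) -> pd.Series:
    """Gene counts per pattern P1..P12 and NC (always all 13 rows)."""
    counts = assignments["pattern"].value_counts()
    return counts.reindex(PATTERNS, fill_value=0).astype(int)
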