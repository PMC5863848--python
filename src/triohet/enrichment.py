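"""Hypergeometric over-representation of annotation terms in gene sets.

For a study set of size n drawn from a population of size N, a term
with K members in the population and k members in the study set has
upper-tail p-value P(X >= k) under Hypergeometric(N, K, n). P-values
are BH-adjusted across the tested terms.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust


@dataclass
class TermMap:
    """term id -> (name, member gene-id set)."""

    names: dict[str, str]
    members: dict[str, set]

    def __len__(self) -> int:
        return len(self.members)

    def restrict(self, population: set) -> "TermMap":
        """Intersect every term with the population; drop emptied terms."""
        members = {
            tid: mem & population
            for tid, mem in self.members.items()
            if mem & population
        }
        return TermMap({t: self.names[t] for t in members}, members)


def read_gmt(path) -> TermMap:
    """Parse a GMT file (term, description, tab-separated member genes).

    Duplicate members within a term collapse to one; a duplicated term
    id is an error.
    """
    names: dict[str, str] = {}
    members: dict[str, set] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: malformed GMT line {lineno}: expected "
                    f"term<TAB>description<TAB>member..., got {len(fields)} field(s)"
                )
            tid, desc, *genes = fields
            if tid in members:
                raise ValueError(f"{path}: duplicate term id {tid!r} at line {lineno}")
            genes = {g for g in genes if g}
            names[tid] = desc
            members[tid] = genes
    return TermMap(names, members)


def hypergeom_enrich(
    study,
    population,
    terms: TermMap,
    *,
    min_term_size: int = 2,
    auto_restrict: bool = False,
) -> pd.DataFrame:
    """Over-representation of every term in the study set.

    Parameters
    ----------
    study, population
        Gene-id collections; study must be a subset of population
        (or pass ``auto_restrict=True`` to intersect it first).
    min_term_size
        Terms with fewer members in the population are not tested
        (singletons are untestable and only inflate the BH denominator).

    Returns
    -------
    DataFrame with columns term_id, term, count (study overlap), size
    (population overlap), p_raw, p_adjust; sorted by p_adjust then
    term_id.
    """
    study = set(study)
    population = set(population)
    if not population:
        raise ValueError("population is empty")
    stray = study - population
    if stray:
        if auto_restrict:
            study &= population
        else:
            raise ValueError(
                f"study gene(s) absent from population: {sorted(stray)[:10]}; "
                "pass auto_restrict=True to intersect"
            )
    restricted = terms.restrict(population)
    rows = []
    N, n = len(population), len(study)
    for tid in sorted(restricted.members):
        mem = restricted.members[tid]
        K = len(mem)
        if K < min_term_size:
            continue
        k = len(mem & study)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": tid, "term": restricted.names[tid],
             "count": k, "size": K, "p_raw": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["term_id", "term", "count", "size", "p_raw"])
    if len(out):
        out["p_adjust"] = bh_adjust(out["p_raw"].to_numpy())
        out = out.sort_values(["p_adjust", "term_id"], kind="stable").reset_index(drop=True)
    else:
        out["p_adjust"] = []
    return out
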