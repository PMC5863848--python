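"""Livak 2^-ddCt relative quantification and RNA-seq concordance.

Per genotype, dCt = mean Ct(target) - mean Ct(reference); relative to a
calibrator genotype, ddCt = dCt(genotype) - dCt(calibrator) and the
fold change is 2^-ddCt (amplification efficiency fixed at 2). Technical
replicates are averaged on the Ct scale (arithmetic mean of cycles);
the geometric-mean-of-folds alternative averages per-replicate folds
instead.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ("sample", "genotype", "gene_id", "tech_rep", "ct")


def _check_ct(ct: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    if not np.isfinite(ct["ct"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite Ct values present")


def ddct_relative_expression(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str,
    *,
    average: str = "ct",
) -> pd.Series:
    """Per-genotype fold change of ``target`` relative to ``calibrator``.

    Parameters
    ----------
    ct
        Long Ct table with columns sample, genotype, gene_id, tech_rep, ct.
    target, reference
        Gene ids; reference is the endogenous control (e.g. Actin-2).
    calibrator
        Genotype whose fold change is 1 by construction.
    average
        "ct" (default): technical replicates averaged on the cycle scale
        before dCt. "fold": per-replicate 2^-dCt values averaged
        geometrically (identical result when replicates are balanced).
    """
    if target == reference:
        raise ValueError("target and reference genes must differ")
    if average not in ("ct", "fold"):
        raise ValueError("average must be 'ct' or 'fold'")
    _check_ct(ct)
    genotypes = list(dict.fromkeys(ct["genotype"]))
    if calibrator not in genotypes:
        raise ValueError(f"calibrator genotype {calibrator!r} not in Ct table")
    dct = {}
    for geno in genotypes:
        sub = ct[ct["genotype"] == geno]
        t = sub.loc[sub["gene_id"] == target, "ct"].to_numpy(dtype=float)
        r = sub.loc[sub["gene_id"] == reference, "ct"].to_numpy(dtype=float)
        if r.size == 0:
            raise ValueError(f"no reference-gene ({reference!r}) Ct for genotype {geno!r}")
        if t.size == 0:
            raise ValueError(f"no target-gene ({target!r}) Ct for genotype {geno!r}")
        if average == "ct":
            dct[geno] = t.mean() - r.mean()
        else:
            # geometric mean of per-replicate folds == arithmetic mean of dCt
            # computed pairwise; pair replicates positionally when balanced
            m = min(t.size, r.size)
            dct[geno] = float(np.mean(t[:m] - r[:m]))
    folds = {g: 2.0 ** -(d - dct[calibrator]) for g, d in dct.items()}
    return pd.Series(folds, name=f"fold_{target}_vs_{calibrator}")


def concordance(rnaseq_log2fc, qpcr_log2fc) -> dict:
    """OLS fit of qPCR log2 fold changes on RNA-seq log2 fold changes.

    Inputs are aligned on their shared index when Series, else
    positionally. Returns {slope, intercept, r2, n}; r2 is the squared
    Pearson correlation. Requires >= 3 shared finite pairs and non-zero
    variance in the predictor.
    """
    x = pd.Series(rnaseq_log2fc, dtype=float)
    y = pd.Series(qpcr_log2fc, dtype=float)
    if isinstance(rnaseq_log2fc, pd.Series) and isinstance(qpcr_log2fc, pd.Series):
        shared = x.index.intersection(y.index)
        x, y = x.loc[shared], y.loc[shared]
    else:
        if len(x) != len(y):
            raise ValueError("fold-change vectors differ in length")
    keep = np.isfinite(x.to_numpy()) & np.isfinite(y.to_numpy())
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 shared genes with finite values, got {len(x)}")
    if np.ptp(x.to_numpy()) == 0:
        raise ValueError("zero variance in RNA-seq fold changes")
    fit = stats.linregress(x.to_numpy(), y.to_numpy())
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "n": int(len(x)),
    }
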