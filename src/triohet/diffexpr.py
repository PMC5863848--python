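"""Negative-binomial differential expression for trio contrasts.

The model is NB with variance mu + alpha*mu^2 (alpha = 0 degenerates to
Poisson). Libraries are normalized by median-of-ratios size factors.
Per-gene dispersion is estimated by method of moments on normalized
counts and shrunk toward the across-gene median; a Wald statistic on the
difference of log group means gives a two-sided p-value. This supports
the no-replicate design (one library per genotype) via a "blind" pooled
dispersion over all samples, at the cost of an over-dispersed null
(conservative when genotypes truly differ).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import TrioCountMatrix

DISPERSION_MODES = ("blind_pooled", "per_group", "fixed")


def estimate_size_factors(
    counts, *, allow_pseudo_reference: bool = False
) -> pd.Series:
    """Median-of-ratios library size factors.

    For each sample s, factor(s) is the median over genes (restricted to
    genes with positive counts in every sample) of
    count(g, s) / geometric_mean_g(count(g, .)).

    Parameters
    ----------
    counts
        TrioCountMatrix or a genes x samples DataFrame.
    allow_pseudo_reference
        When no gene is positive in all samples, fall back to geometric
        means computed over positive entries only (instead of raising).
    """
    if isinstance(counts, TrioCountMatrix):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(mat)
    all_pos = np.all(mat > 0, axis=1)
    if not all_pos.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no gene has positive counts in every sample; "
                "pass allow_pseudo_reference=True to use a positive-entries "
                "pseudo-reference instead"
            )
        pos = mat > 0
        loggeo = np.where(
            pos.any(axis=1),
            np.where(pos, logc, 0.0).sum(axis=1) / np.maximum(pos.sum(axis=1), 1),
            np.nan,
        )
        ratios = logc - loggeo[:, None]
        ratios[~pos] = np.nan
        sf = np.exp(np.nanmedian(ratios, axis=0))
    else:
        loggeo = logc[all_pos].mean(axis=1)
        sf = np.exp(np.median(logc[all_pos] - loggeo[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    nan_idx = np.flatnonzero(np.isnan(p))
    if nan_idx.size:
        raise ValueError(f"NaN p-values at indices {nan_idx.tolist()[:20]}")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _parse_dispersion_mode(mode, fixed_dispersion):
    if isinstance(mode, str) and mode.startswith("fixed:"):
        fixed_dispersion = float(mode.split(":", 1)[1])
        mode = "fixed"
    if mode not in DISPERSION_MODES:
        raise ValueError(f"unknown dispersion_mode {mode!r}; expected one of {DISPERSION_MODES}")
    if mode == "fixed":
        if fixed_dispersion is None:
            raise ValueError("dispersion_mode='fixed' requires fixed_dispersion")
        if fixed_dispersion < 0:
            raise ValueError("fixed dispersion must be >= 0")
    return mode, fixed_dispersion


def _moments_dispersion(norm: np.ndarray, inv_sf: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersion from normalized counts.

    Var(K/s) = mu/s + alpha*mu^2, so alpha = (v - mu*mean(1/s)) / mu^2.
    Negative estimates are clipped at zero. Rows with zero mean get NaN.
    """
    m = norm.mean(axis=1)
    v = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m * inv_sf.mean()) / m**2
    alpha = np.where(m > 0, np.clip(alpha, 0.0, None), np.nan)
    return alpha


def nb_test(
    trio: TrioCountMatrix,
    contrast: tuple[str, str],
    dispersion_mode: str = "blind_pooled",
    *,
    fixed_dispersion: float | None = None,
    shrink_weight: float = 0.5,
    size_factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Wald test of the ``contrast[1]``-over-``contrast[0]`` log fold change.

    Returns a DataFrame indexed by gene id with columns ``log2fc``,
    ``p_raw`` and ``q_bh``; ``table.attrs["contrast"]`` records the role
    pair. ``log2fc`` is log2((mean_alt + eps) / (mean_ref + eps)) on
    normalized counts with eps = ``pseudocount``.
    """
    mode, fixed_dispersion = _parse_dispersion_mode(dispersion_mode, fixed_dispersion)
    ref_role, alt_role = contrast
    ref = trio.samples_for_role(ref_role)
    alt = trio.samples_for_role(alt_role)
    if (len(ref) < 2 or len(alt) < 2) and mode == "per_group":
        raise ValueError(
            "per_group dispersion needs >= 2 replicates in both groups; "
            "use blind_pooled or fixed for single-library designs"
        )
    if size_factors is None:
        size_factors = estimate_size_factors(trio)
    sf = size_factors.to_numpy(dtype=float)
    norm_all = trio.counts.to_numpy(dtype=float) / sf[None, :]
    cols = list(trio.counts.columns)
    i_ref = [cols.index(c) for c in ref]
    i_alt = [cols.index(c) for c in alt]

    if mode == "fixed":
        alpha = np.full(trio.n_genes, float(fixed_dispersion))
    else:
        if mode == "blind_pooled":
            raw = _moments_dispersion(norm_all, 1.0 / sf)
        else:  # per_group: pooled within-contrast-group moments
            ests, weights = [], []
            for idx in (i_ref, i_alt):
                sub = norm_all[:, idx]
                ests.append(_moments_dispersion(sub, 1.0 / sf[idx]))
                weights.append(len(idx) - 1)
            raw = (
                np.nansum([w * e for w, e in zip(weights, ests)], axis=0)
                / sum(weights)
            )
        finite = raw[np.isfinite(raw)]
        global_alpha = float(np.median(finite)) if finite.size else 0.0
        raw = np.where(np.isfinite(raw), raw, global_alpha)
        alpha = (1.0 - shrink_weight) * raw + shrink_weight * global_alpha

    eps = float(pseudocount)
    out = {}
    mus, ses2 = [], []
    for idx in (i_ref, i_alt):
        sub = norm_all[:, idx]
        mu = sub.mean(axis=1)
        mut = mu + eps
        # delta method: Var(log mean) ~= (1/n^2) sum_j (1/(mu*s_j) + alpha)
        inv_terms = (1.0 / sf[idx]).sum()
        var_log = (inv_terms / mut + len(idx) * alpha) / len(idx) ** 2
        mus.append(mut)
        ses2.append(var_log)
    se = np.sqrt(ses2[0] + ses2[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(mus[1]) - np.log(mus[0])) / se
    z = np.where(np.isfinite(z), z, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    log2fc = np.log2(mus[1] / mus[0])

    out = pd.DataFrame(
        {"log2fc": log2fc, "p_raw": p, "q_bh": bh_adjust(p)},
        index=trio.gene_ids,
    )
    out.attrs["contrast"] = (ref_role, alt_role)
    return out


def call_deg(
    table: pd.DataFrame,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Three-level up/down/ns call from significance and fold change.

    up: significance <= alpha and log2fc >= log2(min_fold);
    down: significance <= alpha and log2fc <= -log2(min_fold); else ns.
    ``use_adjusted`` selects q_bh (default) versus raw p.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    sig = (table["q_bh"] if use_adjusted else table["p_raw"]) <= alpha
    thr = np.log2(min_fold)
    call = np.where(
        sig & (table["log2fc"] >= thr),
        "up",
        np.where(sig & (table["log2fc"] <= -thr), "down", "ns"),
    )
    out = table.copy()
    out["call"] = call
    return out
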