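"""Synthetic trio data with planted inheritance modes.

Generates (i) NB-distributed gene-level count libraries for a female
parent, a male parent and their F1, with each gene's genotype means set
by a planted inheritance class; (ii) phenotype trait trajectories with
configurable per-(genotype, year, stage) means; (iii) qPCR Ct tables
whose 2^-ddCt quantification recovers configured fold changes. One
global seed is split into per-operation substreams so a full pipeline
run is reproducible from a single integer.

Planted classes and the pattern they induce (e = effect_size_log2,
f = 2**e, b = baseline mean):

==============  =================================  ========
class           (female, male, F1) means           pattern
==============  =================================  ========
null            (b, b, b)                          NC
additive_f      (b*f, b, (b*f+b)/2)                P1
additive_m      (b, b*f, (b+b*f)/2)                P2
hpd_m           (b, b*f, b*f)                      P3
hpd_f           (b*f, b, b*f)                      P4
lpd_m           (b*f, b, b)                        P5
lpd_f           (b, b*f, b)                        P6
uod_3sub        cycles P7 (b*f, b, b*f*f),         P7-P9
                P8 (b, b*f, b*f*f), P9 (b, b, b*f)
dod_3sub        cycles P10 (b*f, b, b/f),          P10-P12
                P11 (b, b*f, b/f), P12 (b, b, b/f)
==============  =================================  ========

Counts are NB(mean mu, variance mu + dispersion*mu^2); dispersion 0
degenerates to Poisson.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ROLE_F1, ROLE_FEMALE, ROLE_MALE, ROLES, TrioCountMatrix

#: Dominance-heavy mixture with a paternal excess and rare additivity,
#: emulating the qualitative class structure seen in parent/hybrid
#: transcriptome comparisons of tobacco.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "additive_f": 0.02,
    "additive_m": 0.02,
    "hpd_f": 0.05,
    "hpd_m": 0.09,
    "lpd_f": 0.05,
    "lpd_m": 0.08,
    "uod_3sub": 0.09,
    "dod_3sub": 0.06,
    "null": 0.54,
}

CLASS_NAMES = tuple(DEFAULT_CLASS_PROPORTIONS)

_CLASS_PATTERN = {
    "additive_f": ["P1"], "additive_m": ["P2"],
    "hpd_m": ["P3"], "hpd_f": ["P4"],
    "lpd_m": ["P5"], "lpd_f": ["P6"],
    "uod_3sub": ["P7", "P8", "P9"],
    "dod_3sub": ["P10", "P11", "P12"],
    "null": ["NC"],
}


@dataclass
class SimulationConfig:
    """Parameters of the trio count simulation.

    ``baseline_mean_log`` is the (meanlog, sdlog) of the natural-log
    normal distribution of per-gene baseline mean counts; the default
    gives a median of ~245 counts, i.e. well-expressed genes in a deep
    bulk library. ``n_replicates=1`` emulates a one-library-per-genotype
    design; the NB test then needs blind pooled or fixed dispersion.
    """

    n_genes: int = 2000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    n_replicates: int = 1
    baseline_mean_log: tuple[float, float] = (5.5, 0.8)
    dispersion: float = 0.05
    effect_size_log2: float = 2.0
    library_size_factors: list[float] | None = None
    gene_length_range: tuple[int, int] = (200, 5000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        unknown = set(self.class_proportions) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"class_proportions: unknown class(es) {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1 (got {total!r})")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class_proportions must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not all(np.isfinite(v) for v in self.baseline_mean_log):
            raise ValueError("baseline_mean_log must be finite")
        if self.baseline_mean_log[1] < 0:
            raise ValueError("baseline_mean_log sdlog must be >= 0")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("gene_length_range must satisfy 1 <= lo <= hi")
        n_samples = 3 * self.n_replicates
        if self.library_size_factors is not None:
            if len(self.library_size_factors) != n_samples:
                raise ValueError(
                    f"library_size_factors needs {n_samples} entries "
                    f"(3 genotypes x {self.n_replicates} replicates)"
                )
            if any(f <= 0 for f in self.library_size_factors):
                raise ValueError("library_size_factors must be > 0")


def _allocate_classes(n_genes: int, proportions: dict[str, float]) -> list[str]:
    """Deterministic largest-remainder allocation of genes to classes."""
    keys = [k for k in CLASS_NAMES if proportions.get(k, 0.0) > 0]
    exact = {k: proportions[k] * n_genes for k in keys}
    base = {k: int(np.floor(v)) for k, v in exact.items()}
    left = n_genes - sum(base.values())
    order = sorted(keys, key=lambda k: exact[k] - base[k], reverse=True)
    for k in order[:left]:
        base[k] += 1
    out: list[str] = []
    for k in keys:
        out.extend([k] * base[k])
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_trio_counts(
    config: SimulationConfig,
) -> tuple[TrioCountMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw a trio count matrix with planted inheritance modes.

    Returns (matrix, truth, lengths): ``truth`` has one row per gene
    with the planted class, the induced pattern label, and the true
    log2 fold changes of the three contrasts (male/female, F1/female,
    F1/male); ``lengths`` has gene_id and length_bp columns.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(3)
    rng_mean, rng_counts, rng_len = (np.random.default_rng(s) for s in ss)

    n = config.n_genes
    classes = _allocate_classes(n, config.class_proportions)
    meanlog, sdlog = config.baseline_mean_log
    baseline = np.exp(rng_mean.normal(meanlog, sdlog, size=n))
    f = 2.0 ** config.effect_size_log2

    mu = np.empty((n, 3))  # columns: female, male, f1
    patterns = []
    sub_counter = {"uod_3sub": 0, "dod_3sub": 0}
    for i, (cls, b) in enumerate(zip(classes, baseline)):
        if cls in sub_counter:
            subs = _CLASS_PATTERN[cls]
            pat = subs[sub_counter[cls] % len(subs)]
            sub_counter[cls] += 1
        else:
            pat = _CLASS_PATTERN[cls][0]
        patterns.append(pat)
        mu[i] = {
            "NC": (b, b, b),
            "P1": (b * f, b, (b * f + b) / 2),
            "P2": (b, b * f, (b + b * f) / 2),
            "P3": (b, b * f, b * f),
            "P4": (b * f, b, b * f),
            "P5": (b * f, b, b),
            "P6": (b, b * f, b),
            "P7": (b * f, b, b * f * f),
            "P8": (b, b * f, b * f * f),
            "P9": (b, b, b * f),
            "P10": (b * f, b, b / f),
            "P11": (b, b * f, b / f),
            "P12": (b, b, b / f),
        }[pat]
    if not np.isfinite(mu).all() or (mu <= 0).any():
        raise ValueError("non-finite or non-positive simulated means; check baseline_mean_log/effect_size_log2")

    n_rep = config.n_replicates
    sample_ids, roles, reps = [], [], []
    short = {ROLE_FEMALE: "Pf", ROLE_MALE: "Pm", ROLE_F1: "F1"}
    for role in ROLES:
        for r in range(1, n_rep + 1):
            sample_ids.append(f"{short[role]}_{r}")
            roles.append(role)
            reps.append(r)
    lib = (
        np.asarray(config.library_size_factors, dtype=float)
        if config.library_size_factors is not None
        else np.ones(3 * n_rep)
    )
    role_col = {ROLE_FEMALE: 0, ROLE_MALE: 1, ROLE_F1: 2}
    mean_matrix = np.stack(
        [mu[:, role_col[role]] * lf for role, lf in zip(roles, lib)], axis=1
    )
    counts = _nb_draw(rng_counts, mean_matrix, config.dispersion)

    matrix = TrioCountMatrix(
        counts=pd.DataFrame(
            counts,
            index=pd.Index([f"gene{i+1:05d}" for i in range(n)], name="gene_id"),
            columns=sample_ids,
        ),
        sample_meta=pd.DataFrame(
            {"role": roles, "replicate": reps},
            index=pd.Index(sample_ids, name="sample"),
        ),
    )
    truth = pd.DataFrame(
        {
            "true_class": classes,
            "true_pattern": patterns,
            "lfc_pp": np.log2(mu[:, 1] / mu[:, 0]),
            "lfc_f1f": np.log2(mu[:, 2] / mu[:, 0]),
            "lfc_f1m": np.log2(mu[:, 2] / mu[:, 1]),
        },
        index=matrix.gene_ids,
    )
    lengths = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "length_bp": rng_len.integers(
                config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
            ),
        }
    )
    return matrix, truth, lengths


def simulate_phenotype(
    genotype_means: dict[tuple[str, object, str], float] | pd.DataFrame,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Long phenotype table with Gaussian noise around configured means.

    ``genotype_means`` maps (genotype, year, stage) -> mean trait value,
    or is a DataFrame with columns genotype, year, stage, mean. The
    default three replicates mirror a randomized field design.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(genotype_means, pd.DataFrame):
        genotype_means = {
            (row["genotype"], row["year"], row["stage"]): row["mean"]
            for _, row in genotype_means.iterrows()
        }
    if any(v <= 0 for v in genotype_means.values()):
        raise ValueError("phenotype means must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []
    for (genotype, year, stage), mean in genotype_means.items():
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "genotype": genotype,
                    "year": year,
                    "stage": stage,
                    "replicate": rep,
                    "value": mean + rng.normal(0.0, noise_sd) if noise_sd > 0 else mean,
                }
            )
    return pd.DataFrame(rows)


def simulate_ct(
    expression_fold_changes: dict[str, float] | pd.Series,
    *,
    calibrator: str = ROLE_FEMALE,
    test_genotype: str = ROLE_F1,
    reference_gene: str = "Actin-2",
    reference_ct: float = 15.0,
    target_base_ct: float = 25.0,
    noise_sd: float = 0.0,
    n_technical: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table whose ddCt quantification recovers the given fold changes.

    ``expression_fold_changes`` maps target gene id -> fold change of
    ``test_genotype`` relative to ``calibrator``. With ``noise_sd=0``
    the recovery is exact: the test genotype's target Ct is shifted by
    -log2(fold) cycles from the calibrator's.
    """
    folds = pd.Series(expression_fold_changes, dtype=float)
    if (folds <= 0).any():
        raise ValueError("fold changes must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []

    def emit(genotype: str, gene: str, ct_value: float) -> None:
        for t in range(1, n_technical + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample": f"{genotype}_s1",
                    "genotype": genotype,
                    "gene_id": gene,
                    "tech_rep": t,
                    "ct": ct_value + noise,
                }
            )

    for genotype in (calibrator, test_genotype):
        emit(genotype, reference_gene, reference_ct)
        for gene, fold in folds.items():
            ct_value = target_base_ct
            if genotype == test_genotype:
                ct_value = target_base_ct - np.log2(fold)
            emit(genotype, gene, ct_value)
    return pd.DataFrame(rows)
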