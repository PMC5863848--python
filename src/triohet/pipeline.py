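"""End-to-end orchestration of the trio heterosis analysis.

Stages: counts -> FPKM + expression filter -> three NB contrasts ->
DEG calls -> 12-pattern classification -> rollup gene sets ->
per-gene and phenotype heterosis -> term over-representation ->
qPCR concordance. Every intermediate is written as TSV/JSON together
with a manifest recording input hashes and parameters.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .containers import ROLE_F1, ROLE_FEMALE, ROLE_MALE, TrioCountMatrix
from .diffexpr import call_deg, estimate_size_factors, nb_test
from .enrichment import hypergeom_enrich, read_gmt
from .heterosis import gene_expression_heterosis, phenotype_heterosis
from .patterns import (
    build_rollup_sets,
    classify_patterns,
    derive_trio_calls,
    pattern_summary,
)
from .qpcr import concordance, ddct_relative_expression
from .quantify import compute_fpkm, filter_expressed

log = logging.getLogger("triohet")

CONTRASTS = {
    "pp": (ROLE_FEMALE, ROLE_MALE),
    "f1f": (ROLE_FEMALE, ROLE_F1),
    "f1m": (ROLE_MALE, ROLE_F1),
}


@dataclass
class PipelineConfig:
    counts: str | Path = "counts.tsv"
    lengths: str | Path = "lengths.tsv"
    gmt: str | Path | None = None
    phenotype: str | Path | None = None
    ct: str | Path | None = None
    outdir: str | Path = "triohet_out"
    fpkm_min: float = 1.0
    alpha: float = 0.05
    min_fold: float = 2.0
    use_adjusted: bool = True
    # pattern classification uses significance-only calls (no fold filter);
    # see docs/methods.md
    pattern_alpha: float = 0.05
    pattern_use_adjusted: bool = True
    dispersion_mode: str = "blind_pooled"
    fixed_dispersion: float | None = None
    qpcr_reference: str = "Actin-2"
    qpcr_calibrator: str = ROLE_FEMALE
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.pattern_alpha < 1:
            raise ValueError("alpha thresholds must be in (0, 1)")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if self.fpkm_min < 0:
            raise ValueError("fpkm_min must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def trio_de_tables(
    trio: TrioCountMatrix,
    *,
    alpha: float = 0.05,
    min_fold: float = 1.0,
    use_adjusted: bool = False,
    dispersion_mode: str = "blind_pooled",
    fixed_dispersion: float | None = None,
) -> dict[str, pd.DataFrame]:
    """The three called DE tables (pp, f1f, f1m) for one trio."""
    sf = estimate_size_factors(trio)
    out = {}
    for key, contrast in CONTRASTS.items():
        tbl = nb_test(
            trio,
            contrast,
            dispersion_mode,
            fixed_dispersion=fixed_dispersion,
            size_factors=sf,
        )
        out[key] = call_deg(tbl, alpha=alpha, min_fold=min_fold, use_adjusted=use_adjusted)
    return out


def classify_trio(
    trio: TrioCountMatrix,
    *,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    min_fold: float = 1.0,
    dispersion_mode: str = "blind_pooled",
    fixed_dispersion: float | None = None,
) -> pd.DataFrame:
    """Counts -> pattern/rollup assignment in one call (used by tests)."""
    de = trio_de_tables(
        trio,
        alpha=alpha,
        min_fold=min_fold,
        use_adjusted=use_adjusted,
        dispersion_mode=dispersion_mode,
        fixed_dispersion=fixed_dispersion,
    )
    calls = derive_trio_calls(de["pp"], de["f1f"], de["f1m"])
    return classify_patterns(calls)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage the configured inputs allow; return a result bundle."""
    config.validate()
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {
        k: Path(v)
        for k, v in (
            ("counts", config.counts),
            ("lengths", config.lengths),
            ("gmt", config.gmt),
            ("phenotype", config.phenotype),
            ("ct", config.ct),
        )
        if v is not None
    }
    for name, p in inputs.items():
        if not p.exists():
            raise FileNotFoundError(f"[{name}] input not found: {p}")

    def stage(name):
        log.info("stage %-12s %.2fs elapsed", name, time.time() - t0)

    results: dict = {}
    stage("read")
    trio = io.read_counts_tsv(inputs["counts"])
    lengths = io.read_lengths_tsv(inputs["lengths"])

    stage("quantify")
    fpkm = compute_fpkm(trio, lengths)
    expressed = filter_expressed(fpkm, config.fpkm_min)
    io.write_table(fpkm, outdir / "fpkm.tsv")
    trio_f = TrioCountMatrix(trio.counts.loc[expressed], trio.sample_meta)
    results["fpkm"] = fpkm
    results["expressed"] = expressed

    stage("diffexpr")
    deg = trio_de_tables(
        trio_f,
        alpha=config.alpha,
        min_fold=config.min_fold,
        use_adjusted=config.use_adjusted,
        dispersion_mode=config.dispersion_mode,
        fixed_dispersion=config.fixed_dispersion,
    )
    pattern_de = trio_de_tables(
        trio_f,
        alpha=config.pattern_alpha,
        min_fold=1.0,
        use_adjusted=config.pattern_use_adjusted,
        dispersion_mode=config.dispersion_mode,
        fixed_dispersion=config.fixed_dispersion,
    )
    for key, tbl in deg.items():
        io.write_table(tbl, outdir / f"de_{key}.tsv")
    results["deg"] = deg

    stage("patterns")
    calls = derive_trio_calls(pattern_de["pp"], pattern_de["f1f"], pattern_de["f1m"])
    assignments = classify_patterns(calls)
    summary = pattern_summary(assignments)
    rollups = build_rollup_sets(assignments)
    io.write_table(assignments, outdir / "patterns.tsv")
    io.write_table(summary.rename("n_genes").to_frame(), outdir / "pattern_summary.tsv")
    for name, genes in rollups.items():
        (outdir / f"{name}.txt").write_text("\n".join(sorted(genes)) + "\n")
    results["assignments"] = assignments
    results["summary"] = summary
    results["rollups"] = rollups

    stage("heterosis")
    gene_het = gene_expression_heterosis(fpkm.loc[expressed], trio.sample_meta)
    io.write_table(gene_het, outdir / "gene_heterosis.tsv")
    results["gene_heterosis"] = gene_het
    if "phenotype" in inputs:
        pheno = io.read_phenotype_tsv(inputs["phenotype"])
        het = phenotype_heterosis(pheno)
        io.write_table(het, outdir / "phenotype_heterosis.tsv", index=False)
        results["phenotype_heterosis"] = het

    if "gmt" in inputs:
        stage("enrichment")
        terms = read_gmt(inputs["gmt"])
        population = set(expressed)
        results["enrichment"] = {}
        for name, genes in rollups.items():
            enr = hypergeom_enrich(genes, population, terms, auto_restrict=True)
            io.write_table(enr, outdir / f"enrichment_{name}.tsv", index=False)
            results["enrichment"][name] = enr

    if "ct" in inputs:
        stage("qpcr")
        ct = io.read_ct_tsv(inputs["ct"])
        targets = sorted(set(ct["gene_id"]) - {config.qpcr_reference})
        folds = {}
        for gene in targets:
            f = ddct_relative_expression(
                ct, gene, config.qpcr_reference, config.qpcr_calibrator
            )
            folds[gene] = f.drop(config.qpcr_calibrator).iloc[0]
        import numpy as np

        qpcr_lfc = pd.Series(folds, dtype=float)
        qpcr_lfc = np.log2(qpcr_lfc.where(qpcr_lfc > 0))
        shared = [g for g in targets if g in pattern_de["f1f"].index]
        if len(shared) >= 3:
            conc = concordance(
                pattern_de["f1f"].loc[shared, "log2fc"], qpcr_lfc.loc[shared]
            )
            (outdir / "qpcr_concordance.json").write_text(json.dumps(conc, indent=2))
            results["qpcr_concordance"] = conc
        results["qpcr_log2fc"] = qpcr_lfc

    manifest = {
        "version": __version__,
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("counts", "lengths", "gmt", "phenotype", "ct", "outdir")
        },
        "n_genes": int(trio.n_genes),
        "n_expressed": int(len(expressed)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    stage("done")
    return results
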