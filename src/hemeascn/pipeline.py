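"""End-to-end per-case orchestration and cohort summaries.

``analyze_case`` wires the stages together: reference-normal selection and
logR -> het-SNP mask (host/donor intersection for post-transplant cases)
and logOR -> two-pass segmentation (coarse pass anchors the diploid logR,
sensitive pass defines segments) -> purity/ploidy fit -> WGD/CN-LOH ->
gene- and arm-level calls -> variant filter cascade -> TMB.  Every
threshold applied is logged.  Identical inputs and config yield identical
output.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ascn import (DEFAULT_MIN_HET_DEPTH, compute_logr, compute_logor,
                   select_het_snps, select_unmatched_normal)
from .cnfit import (PurityPloidyFit, call_arm_level, call_cnloh,
                    call_gene_level, detect_wgd, fit_purity_ploidy)
from .filters import AnnotatedVariant, FilterConfig, run_cascade
from .germline import intersect_het_snps
from .io import (IntervalSet, Role, SnpMatrix, VariantRecord, read_arm_table,
                 read_bed, read_hotspots, read_roles, read_snp_pileup,
                 read_variants, write_seg, write_variants_maf)
from .segment import (BALANCE_THRESHOLD, DEFAULT_CVAL_COARSE,
                      DEFAULT_CVAL_FINE, MIN_SEG_MARKS, _robust_sd,
                      estimate_diplogr, segment_bivariate)
from .tmb import compute_tmb, tmb_high_threshold

logger = logging.getLogger("hemeascn")


class ConfigError(ValueError):
    """Invalid analysis configuration."""


@dataclass
class PipelineConfig:
    """All tunable thresholds in one place; defaults are the printed values."""

    cval_coarse: float = DEFAULT_CVAL_COARSE
    cval_fine: float = DEFAULT_CVAL_FINE
    min_seg_marks: int = MIN_SEG_MARKS
    balance_threshold: float = BALANCE_THRESHOLD
    min_het_depth: int = DEFAULT_MIN_HET_DEPTH
    include_sex_chroms: bool = False
    panel_mb: float = 1.0837
    filters: FilterConfig = field(default_factory=FilterConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        try:
            if "filters" in d:
                d["filters"] = FilterConfig.from_dict(d["filters"])
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class CaseResult:
    fit: PurityPloidyFit
    gene_calls: list
    arm_calls: list
    variants: list[AnnotatedVariant]
    tmb: float
    mutation_count: int
    mode: str
    chosen_normal: str | None
    config_hash: str
    version: str = __version__

    def somatic_variants(self) -> list[VariantRecord]:
        return [a.variant for a in self.variants if a.result.verdict == "PASS"]

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "mode": self.mode,
            "chosen_normal": self.chosen_normal,
            "fit": self.fit.to_dict(),
            "gene_calls": [asdict(c) for c in self.gene_calls],
            "arm_calls": [asdict(c) for c in self.arm_calls],
            "tmb": self.tmb,
            "mutation_count": self.mutation_count,
            "variants": [
                {
                    "chrom": a.variant.chrom, "pos": a.variant.pos,
                    "ref": a.variant.ref, "alt": a.variant.alt,
                    "verdict": a.result.verdict,
                    "failed_rules": a.result.failed_rules,
                    "tier": a.result.tier,
                    "provenance": a.provenance.verdict.value if a.provenance else None,
                }
                for a in self.variants
            ],
        }

    def output_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def analyze_case(sm: SnpMatrix, variants: list[VariantRecord],
                 config: PipelineConfig | None = None,
                 genes: IntervalSet | None = None,
                 arms=None,
                 hotspots: set[tuple[str, int]] | None = None) -> CaseResult:
    """Run the full per-case analysis on in-memory objects."""
    cfg = config or PipelineConfig()
    if not sm.matched_normals:
        raise ValueError(
            "no MATCHED_NORMAL sample: matched-mode analysis requires a host "
            "baseline normal (supply one in the role map)"
        )
    host = sm.matched_normals[0]
    donors = sm.donor_normals
    mode = "post_transplant" if donors else "matched"
    logger.info("mode=%s host=%s donors=%s", mode, host, donors)

    if hotspots:
        for v in variants:
            if (v.chrom, v.pos) in hotspots:
                v.hotspot = True

    gc = sm.loci["gc"].to_numpy()
    tumor_depth = sm.depth(sm.tumor_sample)
    auto = sm.autosomal_mask()
    if cfg.include_sex_chroms:
        auto = np.ones(sm.n_loci, dtype=bool)

    if sm.unmatched_normals:
        chosen, logr_track = select_unmatched_normal(
            tumor_depth, {s: sm.depth(s) for s in sm.unmatched_normals}, gc,
            autosomal_mask=auto)
        logger.info("reference normal %s (sum-squared logR %s)", chosen,
                    {k: round(v, 2) for k, v in logr_track.ss_logr.items()})
    else:
        chosen = host
        logr_track = compute_logr(tumor_depth, sm.depth(host), gc)
        logger.info("no unmatched pool; normalizing against matched normal")

    if donors:
        het = intersect_het_snps(
            sm.ref(host), sm.alt(host),
            [(sm.ref(d), sm.alt(d)) for d in donors],
            min_depth=cfg.min_het_depth)
        logger.info("host/donor het-SNP intersection: %d loci", int(het.sum()))
    else:
        het = select_het_snps(sm.ref(host), sm.alt(host), min_depth=cfg.min_het_depth)
    het = het & auto
    logor_track = compute_logor(sm.ref(sm.tumor_sample), sm.alt(sm.tumor_sample),
                                sm.ref(host), sm.alt(host), het)

    chrom = sm.loci["chrom"].to_numpy()[auto]
    pos = sm.loci["pos"].to_numpy()[auto]
    args = (chrom, pos, logr_track.logr[auto], logor_track.logor[auto],
            logor_track.variance[auto], het[auto])
    coarse = segment_bivariate(*args, cval=cfg.cval_coarse,
                               min_seg_marks=cfg.min_seg_marks)
    diplogr, fallback = estimate_diplogr(coarse, balance_threshold=cfg.balance_threshold)
    logger.info("two-pass segmentation: cval %s -> dipLogR %.4f%s; re-segmenting at cval %s",
                cfg.cval_coarse, diplogr, " (fallback)" if fallback else "",
                cfg.cval_fine)
    segments = segment_bivariate(*args, cval=cfg.cval_fine,
                                 min_seg_marks=cfg.min_seg_marks)

    logr_sd = _robust_sd(logr_track.logr[auto])
    het_var = logor_track.variance[auto][het[auto]]
    logor_sd = float(np.sqrt(np.nanmedian(het_var))) if len(het_var) else 0.5
    fit = fit_purity_ploidy(segments, diplogr, logr_sd=logr_sd, logor_sd=logor_sd)
    fit.wgd = detect_wgd(fit)
    call_cnloh(fit)
    logger.info("fit: purity=%.2f ploidy=%.2f wgd=%s quiet=%s below_sensitivity=%s",
                fit.purity, fit.ploidy, fit.wgd, fit.quiet, fit.below_sensitivity)

    annotated = run_cascade(variants, sm.roles, mode=mode, cfg=cfg.filters)
    somatic = [a.variant for a in annotated if a.result.verdict == "PASS"]

    gene_calls = call_gene_level(fit, genes, somatic) if genes is not None else []
    arm_calls = call_arm_level(fit, arms) if arms is not None else []

    tmb_res = compute_tmb(somatic, panel_mb=cfg.panel_mb)
    logger.info("somatic calls: %d / %d candidates; TMB %.2f mut/Mb",
                len(somatic), len(variants), tmb_res.tmb)

    return CaseResult(
        fit=fit, gene_calls=gene_calls, arm_calls=arm_calls,
        variants=annotated, tmb=tmb_res.tmb,
        mutation_count=tmb_res.mutation_count, mode=mode,
        chosen_normal=chosen, config_hash=cfg.config_hash(),
    )


def run_case(case_dir: str | Path, config: PipelineConfig | None = None,
             out_dir: str | Path | None = None) -> CaseResult:
    """Analyze a case directory and write SEG/MAF/JSON outputs.

    Expects ``pileup.tsv``, ``roles.tsv``, ``variants.maf``; optional
    ``genes.bed``, ``arms.tsv``, ``hotspots.tsv``.
    """
    case_dir = Path(case_dir)
    roles = read_roles(case_dir / "roles.tsv")
    sm = read_snp_pileup(case_dir / "pileup.tsv", roles)
    variants = read_variants(case_dir / "variants.maf", "MAF")
    genes = read_bed(case_dir / "genes.bed") if (case_dir / "genes.bed").exists() else None
    arms = read_arm_table(case_dir / "arms.tsv") if (case_dir / "arms.tsv").exists() else None
    hotspots = (read_hotspots(case_dir / "hotspots.tsv")
                if (case_dir / "hotspots.tsv").exists() else None)

    result = analyze_case(sm, variants, config, genes=genes, arms=arms,
                          hotspots=hotspots)

    out = Path(out_dir) if out_dir is not None else case_dir
    out.mkdir(parents=True, exist_ok=True)
    write_seg(result.fit.segments, out / "segments.seg", sample_id=sm.tumor_sample)
    import pandas as pd
    extra = pd.DataFrame({
        "verdict": [a.result.verdict for a in result.variants],
        "failed_rules": [",".join(a.result.failed_rules) for a in result.variants],
        "tier": [a.result.tier for a in result.variants],
    })
    write_variants_maf([a.variant for a in result.variants],
                       out / "variants.annotated.maf", extra=extra)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
    return result


def cohort_summary(results: list[CaseResult]) -> dict:
    """Cohort counting conventions: per-patient event prevalence and TMB.

    The TMB-high threshold needs >= 4 cases; below that it is reported as
    missing and no case is classified.
    """
    if not results:
        raise ValueError("at least one case required")
    tmbs = [r.tmb for r in results]
    summary = {
        "n_cases": len(results),
        "n_with_snv_indel": sum(1 for r in results if r.somatic_variants()),
        "n_with_arm_event": sum(1 for r in results if r.arm_calls),
        "n_with_cnloh": sum(
            1 for r in results if any(s.cnloh for s in r.fit.segments)
        ),
        "median_mutations_per_sample": float(np.median([r.mutation_count for r in results])),
        "tmb_median": float(np.median(tmbs)),
    }
    if len(results) >= 4:
        thr = tmb_high_threshold(tmbs)
        summary["tmb_high_threshold"] = thr
        summary["n_tmb_high"] = sum(1 for t in tmbs if t > thr)
    else:
        summary["tmb_high_threshold"] = None
        summary["n_tmb_high"] = None
    return summary
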