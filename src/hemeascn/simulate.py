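"""Synthetic case generator with full ground truth.

Emulates the data model of a targeted hematologic panel: genome-wide SNPs
with Beta(2, 2) population allele frequencies, host and donor genotypes
drawn under Hardy-Weinberg equilibrium, negative-binomial sequencing depth
with a GC-dependent multiplicative bias, segmental integer allele-specific
copy states (including CN-LOH), a tumor cell fraction (purity), an optional
donor chimerism fraction, injected somatic variants at set VAFs, and
tumor-contaminated nail/saliva normals.  Every draw flows from one
``numpy`` Generator seeded from the config, so a seed fully determines the
case.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (IntervalSet, Role, SnpMatrix, VariantRecord, write_bed,
                 write_arm_table, write_roles, write_snp_pileup,
                 write_variants_maf)
from .resources import GENOME_GRCH37, default_arm_table

AUTOSOMES = [str(i) for i in range(1, 23)]
# acrocentric chromosomes: no unique target sequence on the p arm, so the
# simulator places SNPs on the q arm only (as real capture panels do)
ACROCENTRIC = {"13", "14", "15", "21", "22"}


@dataclass
class SegmentSpec:
    """A simulated allele-specific copy state over a genomic interval."""

    chrom: str
    start: int
    end: int
    tcn: int
    lcn: int

    def __post_init__(self) -> None:
        if self.lcn > self.tcn - self.lcn:
            raise ValueError(f"lcn {self.lcn} exceeds major copy for tcn {self.tcn}")


@dataclass
class SomaticSpec:
    chrom: str
    pos: int
    vaf: float
    gene: str | None = None
    hotspot: bool = False
    coding_effect: str = "nonsynonymous"
    variant_class: str = "SNV"
    ref: str = "C"
    alt: str = "T"
    context: str = "ACA"


@dataclass
class SimConfig:
    n_snps: int = 6000
    chroms: list[str] = field(default_factory=lambda: list(AUTOSOMES))
    depth_mean: float = 500.0
    depth_dispersion: float = 50.0   # NB size parameter; larger = less overdispersed
    locus_efficiency_sd: float = 0.4  # log2 sd of per-target capture efficiency,
                                      # shared by all samples (cancels in logR)
    gc_amplitude: float = 0.25       # log2-scale slope of depth on GC
    maf_alpha: float = 2.0
    maf_beta: float = 2.0
    purity: float = 0.6              # tumor cell fraction
    donor_fraction: float = 0.0      # chimerism fraction in the tumor sample
    n_donors: int = 0
    n_unmatched: int = 3
    segments: list[SegmentSpec] = field(default_factory=list)
    somatic: list[SomaticSpec] = field(default_factory=list)
    n_germline_tracer_variants: int = 0
    contamination: float = 0.0       # tumor-cell fraction in the matched normal
    normal_tissue: str = "nail"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.purity + self.donor_fraction > 1 + 1e-12:
            raise ValueError("purity + donor_fraction must not exceed 1")
        if self.donor_fraction > 0 and self.n_donors == 0:
            self.n_donors = 1
        for s in self.somatic:
            if not 0 <= s.vaf <= 1:
                raise ValueError("somatic VAF outside [0, 1]")


@dataclass
class TruthSet:
    host_genotypes: np.ndarray            # alt-allele copies of 2, per locus
    donor_genotypes: list[np.ndarray]
    locus_tcn: np.ndarray
    locus_lcn: np.ndarray
    segments: list[SegmentSpec]
    purity: float
    donor_fraction: float
    ploidy: float
    somatic: list[SomaticSpec]
    variant_labels: dict[tuple, str]      # variant key -> SOMATIC/HOST_GERMLINE/DONOR_GERMLINE


@dataclass
class SimCase:
    snp_matrix: SnpMatrix
    variants: list[VariantRecord]
    truth: TruthSet
    config: SimConfig


def _nb_depth(rng: np.random.Generator, mu: np.ndarray, size_param: float) -> np.ndarray:
    mu = np.maximum(mu, 1e-6)
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def _locus_states(loci: pd.DataFrame, segments: list[SegmentSpec]) -> tuple[np.ndarray, np.ndarray]:
    tcn = np.full(len(loci), 2, dtype=int)
    lcn = np.ones(len(loci), dtype=int)
    chrom = loci["chrom"].to_numpy()
    pos = loci["pos"].to_numpy()
    for seg in segments:
        m = (chrom == seg.chrom) & (pos >= seg.start) & (pos <= seg.end)
        tcn[m] = seg.tcn
        lcn[m] = seg.lcn
    return tcn, lcn


def simulate_case(cfg: SimConfig) -> SimCase:
    """Generate one case: SNP count matrix, variant table, and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    rho, delta = cfg.purity, cfg.donor_fraction
    host_frac = 1.0 - rho - delta
    rank = {c: i for i, c in enumerate([str(k) for k in range(1, 23)] + ["X", "Y"])}
    cfg.chroms = sorted(cfg.chroms, key=rank.__getitem__)

    # --- loci ------------------------------------------------------------
    starts = {c: (GENOME_GRCH37[c][1] if c in ACROCENTRIC else 0)
              for c in cfg.chroms}
    lengths = np.array([GENOME_GRCH37[c][0] - starts[c] for c in cfg.chroms],
                       dtype=float)
    alloc = np.maximum(1, np.round(cfg.n_snps * lengths / lengths.sum()).astype(int))
    rows = []
    bases = np.array(list("ACGT"))
    for chrom, n, span in zip(cfg.chroms, alloc, lengths):
        pos = (np.sort(rng.choice(int(span) // 50, size=n, replace=False)) * 50
               + 25 + starts[chrom])
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    loci = pd.concat(rows, ignore_index=True)
    n = len(loci)
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
    loci["ref"] = bases[ref_idx]
    loci["alt"] = bases[alt_idx]
    loci["gc"] = np.clip(rng.normal(0.5, 0.08, n), 0.25, 0.75)

    p_alt = rng.beta(cfg.maf_alpha, cfg.maf_beta, n)
    g_host = rng.binomial(2, p_alt)
    g_donors = [rng.binomial(2, p_alt) for _ in range(cfg.n_donors)]
    g_unmatched = [rng.binomial(2, p_alt) for _ in range(cfg.n_unmatched)]

    tcn, lcn = _locus_states(loci, cfg.segments)
    major = tcn - lcn
    # which parental haplotype carries the alt allele at host-het loci
    alt_on_major = rng.random(n) < 0.5
    a_tumor = np.where(g_host == 2, tcn,
                       np.where(g_host == 0, 0,
                                np.where(alt_on_major, major, lcn)))

    # gc_amplitude = log2 depth swing across the observed GC span (+-0.25)
    gc_factor = 2.0 ** (cfg.gc_amplitude * (loci["gc"].to_numpy() - 0.5) / 0.25)
    # target-to-target capture efficiency, shared across samples so that it
    # cancels in coverage ratios (normalized to mean 1)
    eff = 2.0 ** (cfg.locus_efficiency_sd * rng.standard_normal(n))
    eff /= np.exp(0.5 * (cfg.locus_efficiency_sd * np.log(2.0)) ** 2)
    gc_factor = gc_factor * eff

    # --- tumor sample ----------------------------------------------------
    cn_mult = (rho * tcn + (1 - rho) * 2.0) / 2.0
    t_depth = _nb_depth(rng, cfg.depth_mean * gc_factor * cn_mult, cfg.depth_dispersion)
    denom = rho * tcn + host_frac * 2.0 + delta * 2.0
    f_tumor = np.where(denom > 0,
                       (rho * a_tumor + host_frac * g_host
                        + delta * (g_donors[0] if g_donors else 0)) / np.maximum(denom, 1e-12),
                       0.0)
    t_alt = rng.binomial(t_depth, np.clip(f_tumor, 0, 1))

    samples: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    roles: dict[str, Role] = {}
    samples["TUMOR"] = (t_depth - t_alt, t_alt)
    roles["TUMOR"] = Role.TUMOR

    # --- matched (host baseline) normal, optionally tumor-contaminated ---
    eps = cfg.contamination
    n_depth_mu = cfg.depth_mean * gc_factor
    m_depth = _nb_depth(rng, n_depth_mu, cfg.depth_dispersion)
    f_norm = ((1 - eps) * g_host + eps * a_tumor) / ((1 - eps) * 2.0 + eps * np.maximum(tcn, 1e-12))
    m_alt = rng.binomial(m_depth, np.clip(f_norm, 0, 1))
    samples["NORMAL"] = (m_depth - m_alt, m_alt)
    roles["NORMAL"] = Role.MATCHED_NORMAL

    for i, g_d in enumerate(g_donors, start=1):
        d_depth = _nb_depth(rng, n_depth_mu, cfg.depth_dispersion)
        d_alt = rng.binomial(d_depth, g_d / 2.0)
        samples[f"DONOR{i}"] = (d_depth - d_alt, d_alt)
        roles[f"DONOR{i}"] = Role.DONOR_NORMAL

    for i, g_u in enumerate(g_unmatched, start=1):
        # pool normals carry their own GC response so reference selection matters
        amp = cfg.gc_amplitude * rng.uniform(0.6, 1.4)
        gfac = eff * 2.0 ** (amp * (loci["gc"].to_numpy() - 0.5) / 0.25)
        u_depth = _nb_depth(rng, cfg.depth_mean * gfac, cfg.depth_dispersion)
        u_alt = rng.binomial(u_depth, g_u / 2.0)
        samples[f"UNMATCHED{i}"] = (u_depth - u_alt, u_alt)
        roles[f"UNMATCHED{i}"] = Role.UNMATCHED_NORMAL

    ref_counts = pd.DataFrame({s: pair[0] for s, pair in samples.items()})
    alt_counts = pd.DataFrame({s: pair[1] for s, pair in samples.items()})
    sm = SnpMatrix(loci, ref_counts, alt_counts, roles)

    # --- variant records -------------------------------------------------
    variants: list[VariantRecord] = []
    labels: dict[tuple, str] = {}
    normal_samples = [s for s, r in roles.items() if r is not Role.TUMOR]
    for spec in cfg.somatic:
        depth = int(_nb_depth(rng, np.array([cfg.depth_mean]), cfg.depth_dispersion)[0])
        alt = int(rng.binomial(depth, spec.vaf))
        ev: dict[str, tuple[int, int]] = {}
        for s in normal_samples:
            nd = int(_nb_depth(rng, np.array([cfg.depth_mean]), cfg.depth_dispersion)[0])
            f = eps * spec.vaf if roles[s] is Role.MATCHED_NORMAL else 0.0
            ev[s] = (nd, int(rng.binomial(nd, f)))
        v = VariantRecord(
            chrom=spec.chrom, pos=spec.pos, ref=spec.ref, alt=spec.alt,
            variant_class=spec.variant_class, coding_effect=spec.coding_effect,
            tumor_depth=depth, tumor_alt=alt, normal_evidence=ev,
            hotspot=spec.hotspot, gene=spec.gene,
            trinucleotide_context=spec.context,
        )
        variants.append(v)
        labels[v.key()] = "SOMATIC"

    # germline tracer variants: emitted from SNP loci so provenance can be
    # audited against genotype truth
    if cfg.n_germline_tracer_variants:
        host_carrier = np.flatnonzero(g_host >= 1)
        donor_only = (np.flatnonzero((g_host == 0) & (g_donors[0] >= 1))
                      if g_donors else np.array([], dtype=int))
        n_half = cfg.n_germline_tracer_variants // 2
        picks = [(i, "HOST_GERMLINE") for i in
                 rng.choice(host_carrier, size=min(n_half, len(host_carrier)), replace=False)]
        if len(donor_only):
            picks += [(i, "DONOR_GERMLINE") for i in
                      rng.choice(donor_only, size=min(n_half, len(donor_only)), replace=False)]
        for i, label in picks:
            ev = {s: (int(samples[s][0][i] + samples[s][1][i]), int(samples[s][1][i]))
                  for s in normal_samples}
            v = VariantRecord(
                chrom=str(loci["chrom"].iloc[i]), pos=int(loci["pos"].iloc[i]),
                ref=str(loci["ref"].iloc[i]), alt=str(loci["alt"].iloc[i]),
                variant_class="SNV", coding_effect="other",
                tumor_depth=int(t_depth[i]), tumor_alt=int(t_alt[i]),
                normal_evidence=ev,
            )
            variants.append(v)
            labels[v.key()] = label

    ploidy = float(np.mean(tcn))
    truth = TruthSet(
        host_genotypes=g_host, donor_genotypes=g_donors, locus_tcn=tcn,
        locus_lcn=lcn, segments=list(cfg.segments), purity=rho,
        donor_fraction=delta, ploidy=ploidy, somatic=list(cfg.somatic),
        variant_labels=labels,
    )
    return SimCase(snp_matrix=sm, variants=variants, truth=truth, config=cfg)


def simulate_dilution_series(cfg: SimConfig, fractions: list[float]) -> list[tuple[float, SimCase]]:
    """Dilute a base profile: case i has purity ``cfg.purity * fractions[i]``.

    Seeds derive as ``cfg.seed + i`` so the series is reproducible from the
    base seed.  The base profile must contain at least one copy-number
    event.
    """
    if not any(s.tcn != 2 or s.lcn != 1 for s in cfg.segments):
        raise ValueError("dilution series requires a base profile with >=1 SCNA")
    cases = []
    for i, f in enumerate(fractions):
        sub = replace(cfg, purity=cfg.purity * f, seed=cfg.seed + i,
                      segments=list(cfg.segments), somatic=list(cfg.somatic))
        cases.append((f, simulate_case(sub)))
    return cases


def write_case(case: SimCase, out_dir: str | Path) -> None:
    """Emit a case directory in the same formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_snp_pileup(case.snp_matrix, out / "pileup.tsv")
    write_roles(case.snp_matrix.roles, out / "roles.tsv")
    write_variants_maf(case.variants, out / "variants.maf")
    write_arm_table(default_arm_table(case.config.chroms), out / "arms.tsv")
    genes = IntervalSet(pd.DataFrame(
        [{"chrom": s.chrom, "start": s.pos, "end": s.pos + 1, "name": s.gene}
         for s in case.config.somatic if s.gene]
        or [{"chrom": "1", "start": 1, "end": 2, "name": "placeholder"}]
    ))
    write_bed(genes, out / "genes.bed")
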