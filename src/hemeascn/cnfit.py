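"""Purity/ploidy fitting, integer allele-specific copy number, and SCNA calls.

Model: a tumor cell fraction (purity) rho mixes tumor cells carrying
integer allele-specific copy number (tcn, lcn) with diploid normal cells.
Expected tracks for a segment with total copy c and allele copies
(m_major, m_minor):

    logR   = log2( (2(1-rho) + rho*c) / (2(1-rho) + rho*psi) )
    logOR  = log2( ((1-rho) + rho*m_major) / ((1-rho) + rho*m_minor) )

where psi is the average ploidy.  The fit anchors observed logR at the
diploid level (dipLogR from the coarse segmentation pass), grid-searches
rho in [0.05, 0.95] (step 0.01), and per segment picks the integer state
minimizing a weighted squared-error loss on (logR, |logOR|).  Whole-genome
doubling (major copy >= 2 over more than half the fitted autosome) switches
the integer thresholds used for gene- and arm-level calls, and copy-neutral
LOH is lcn = 0 at the copy-neutral total (tcn 2, or 4 with WGD).

Fits with estimated purity below the assay's validated sensitivity floor
(tumor fraction 20%) are flagged ``below_sensitivity`` and emit no SCNA
calls.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import IntervalSet, VariantRecord
from .segment import Segment

PURITY_GRID = np.round(np.arange(0.05, 0.95 + 1e-9, 0.01), 2)
MAX_TCN = 10
MIN_HET_FIT = 10
LOGR_WEIGHT = 0.25       # down-weighting of the logR residual in the loss
LOGOR_CAP = 10.0
SENSITIVITY_FLOOR = 0.20   # validated tumor-fraction detection floor
SENSITIVITY_MARGIN = 0.02  # two purity-grid steps: estimates this close to the
                           # floor are not suppressed by estimation noise alone
QUIET_LOGR = 0.10


@dataclass
class PurityPloidyFit:
    purity: float
    ploidy: float
    diplogr: float
    segments: list[Segment]
    loss: float
    wgd: bool | None = None
    quiet: bool = False
    low_confidence: bool = False

    @property
    def below_sensitivity(self) -> bool:
        """True when the fitted tumor fraction is below the validated
        detection floor (20%), with a two-grid-step margin so samples at
        the floor are not suppressed by estimation noise."""
        return (not self.quiet) and np.isfinite(self.purity) \
            and self.purity < SENSITIVITY_FLOOR - SENSITIVITY_MARGIN - 1e-9

    def to_dict(self) -> dict:
        return {
            "purity": None if not np.isfinite(self.purity) else self.purity,
            "ploidy": self.ploidy,
            "diplogr": self.diplogr,
            "loss": self.loss,
            "wgd": self.wgd,
            "quiet": self.quiet,
            "low_confidence": self.low_confidence,
            "segments": [
                {
                    "chrom": s.chrom, "start": s.start_pos, "end": s.end_pos,
                    "num_mark": s.num_mark, "mean_logr": s.mean_logr,
                    "mean_logor2": s.mean_logor2, "n_het": s.n_het,
                    "tcn": s.tcn, "lcn": s.lcn, "cnloh": s.cnloh,
                }
                for s in self.segments
            ],
        }


@dataclass
class GeneCall:
    gene: str
    call: str  # AMP | HOMDEL | HETLOSS | CNLOH
    tcn: int
    lcn: int | None = None


@dataclass
class ArmCall:
    chrom: str
    arm: str
    call: str  # GAIN | LOSS | CNLOH
    fraction_of_arm: float
    tcn: int | None = None
    lcn: int | None = None


def expected_logr(c: float, rho: float, psi: float) -> float:
    """Expected log2 coverage ratio of total copy c at purity rho, ploidy psi."""
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0, 1]")
    if psi <= 0:
        raise ValueError("psi must be positive")
    num = 2 * (1 - rho) + rho * c
    den = 2 * (1 - rho) + rho * psi
    if num <= 0:
        return -LOGOR_CAP
    return float(np.log2(num / den))


def expected_logor(m_major: float, m_minor: float, rho: float) -> float:
    """Expected |logOR| for allele copies (m_major, m_minor) at purity rho.

    Divergent values (rho = 1 with m_minor = 0) are capped at 10.
    """
    num = (1 - rho) + rho * m_major
    den = (1 - rho) + rho * m_minor
    if den <= 0:
        return LOGOR_CAP
    return float(min(np.log2(num / den), LOGOR_CAP))


def _states(max_tcn: int = MAX_TCN) -> list[tuple[int, int]]:
    return [(t, l) for t in range(max_tcn + 1) for l in range(t // 2 + 1)]


def fit_purity_ploidy(segments: list[Segment], diplogr: float,
                      purity_grid: np.ndarray = PURITY_GRID,
                      max_tcn: int = MAX_TCN,
                      min_het: int = MIN_HET_FIT,
                      logr_weight: float = LOGR_WEIGHT,
                      logr_sd: float = 0.10,
                      logor_sd: float = 0.50,
                      tau_logr: float = 0.01,
                      tau_logor2: float = 0.01,
                      max_iter: int = 20) -> PurityPloidyFit:
    """Grid-search purity and assign integer (tcn, lcn) per segment.

    For each candidate purity the per-segment state minimizes a
    noise-standardized squared-error loss with an allelic term on the
    logOR**2 scale (where the noise-corrected segment mean is an unbiased
    estimate of the true squared logOR) and a coverage term on the logR
    scale:

        (y - e_or^2)^2 / ((4 e_or^2 s^2 + 2 s^4)/n_het + tau_logor2^2)
          + logr_weight * (r - e_r)^2 / (s_r^2/num_mark + tau_logr^2)

    with s = ``logor_sd`` and s_r = ``logr_sd`` the per-locus noise scales
    of the tracks (measured upstream and passed in by the pipeline), and
    the tau terms small systematic-error floors so that huge segments do
    not claim unbounded precision.  Standardizing keeps both terms on a
    common z**2 scale, which is what separates a genuine low-tumor-fraction
    solution from a high-copy state mimicking its allelic imbalance: the
    mimic always pays on the coverage term.  Observed logR is re-anchored
    at dipLogR.  Ploidy is iterated to its fixed point (the marker-weighted
    mean tcn).  Segments with fewer than ``min_het`` het SNPs get tcn from
    logR alone and missing lcn.
    """
    informative = [s for s in segments if s.n_het >= min_het]
    if not informative:
        raise ValueError("insufficient heterozygous SNPs: no informative segment")

    r_obs = np.array([s.mean_logr - diplogr for s in informative])
    y_obs = np.array([s.mean_logor2 for s in informative])
    w_het = np.array([s.n_het for s in informative], dtype=float)
    w_mark = np.array([s.num_mark for s in informative], dtype=float)

    # degenerate copy-number-quiet genome: purity unidentifiable
    balanced = np.array([s.mean_logor2 <= 0.05 for s in informative])
    if balanced.all() and np.all(np.abs(r_obs) <= QUIET_LOGR):
        fitted = [_copy_with_state(s, 2, 1) if s.n_het >= min_het
                  else _copy_with_state(s, 2, None) for s in segments]
        return PurityPloidyFit(purity=float("nan"), ploidy=2.0, diplogr=diplogr,
                               segments=fitted, loss=0.0, quiet=True,
                               low_confidence=True)

    states = _states(max_tcn)
    tcn_arr = np.array([t for t, _ in states], dtype=float)
    maj_arr = np.array([t - l for t, l in states], dtype=float)
    min_arr = np.array([l for _, l in states], dtype=float)

    best = None
    for rho in purity_grid:
        # relative-to-diploid expectations; independent of psi
        with np.errstate(divide="ignore"):
            e_r = np.log2(np.maximum(2 * (1 - rho) + rho * tcn_arr, 1e-12) / 2.0)
        e_or = np.minimum(
            np.log2(((1 - rho) + rho * maj_arr) / np.maximum((1 - rho) + rho * min_arr, 1e-12)),
            LOGOR_CAP,
        )
        # states x segments losses, residuals standardized by track noise
        e_or2 = e_or**2
        var_y = ((4 * e_or2[:, None] * logor_sd**2 + 2 * logor_sd**4) / w_het[None, :]
                 + tau_logor2**2)
        var_r = logr_sd**2 / w_mark[None, :] + tau_logr**2
        loss_mat = ((y_obs[None, :] - e_or2[:, None]) ** 2 / var_y
                    + logr_weight * (r_obs[None, :] - e_r[:, None]) ** 2 / var_r)
        assign = np.argmin(loss_mat, axis=0)
        total = float(loss_mat[assign, np.arange(len(informative))].sum())
        if best is None or total < best[0] - 1e-12:
            best = (total, float(rho), assign.copy())

    total_loss, rho_hat, assign = best
    # psi fixed point: assignments do not feed back, so one pass converges
    psi = 2.0
    for _ in range(max_iter):
        tcn_assigned = tcn_arr[assign]
        psi_new = float(np.average(tcn_assigned, weights=w_mark))
        if abs(psi_new - psi) < 1e-9:
            break
        psi = psi_new
    psi = float(np.average(tcn_arr[assign], weights=w_mark))

    state_of = {id(s): states[a] for s, a in zip(informative, assign)}
    fitted: list[Segment] = []
    for s in segments:
        if id(s) in state_of:
            t, l = state_of[id(s)]
            fitted.append(_copy_with_state(s, t, l))
        else:
            t = _tcn_from_logr(s.mean_logr - diplogr, rho_hat, max_tcn)
            fitted.append(_copy_with_state(s, t, None))

    return PurityPloidyFit(purity=rho_hat, ploidy=psi, diplogr=diplogr,
                           segments=fitted, loss=total_loss)


def _copy_with_state(s: Segment, tcn: int | None, lcn: int | None) -> Segment:
    return Segment(chrom=s.chrom, start_pos=s.start_pos, end_pos=s.end_pos,
                   num_mark=s.num_mark, mean_logr=s.mean_logr,
                   mean_logor2=s.mean_logor2, n_het=s.n_het, tcn=tcn, lcn=lcn)


def _tcn_from_logr(r: float, rho: float, max_tcn: int) -> int:
    cands = np.arange(max_tcn + 1, dtype=float)
    with np.errstate(divide="ignore"):
        e_r = np.log2(np.maximum(2 * (1 - rho) + rho * cands, 1e-12) / 2.0)
    return int(np.argmin((r - e_r) ** 2))


def detect_wgd(fit: PurityPloidyFit, min_coverage: float = 0.5) -> bool | None:
    """Whole-genome doubling: major copy >= 2 over more than half the autosome.

    Requires lcn on at least ``min_coverage`` of the fitted autosomal
    length; otherwise returns None and callers fall back to non-WGD
    thresholds (with a warning).
    """
    auto = [s for s in fit.segments if s.chrom not in ("X", "Y")]
    total = sum(s.length for s in auto)
    known = [s for s in auto if s.lcn is not None and s.tcn is not None]
    covered = sum(s.length for s in known)
    if total == 0 or covered / total < min_coverage:
        warnings.warn("lcn unavailable on >=50% of the genome; WGD status unknown, "
                      "using non-WGD thresholds", stacklevel=2)
        return None
    major2 = sum(s.length for s in known if s.major_cn >= 2)
    return major2 / covered > 0.5


def call_cnloh(fit: PurityPloidyFit) -> list[Segment]:
    """Flag copy-neutral LOH: lcn = 0 at tcn 2 (or tcn 4 under WGD)."""
    wgd = bool(fit.wgd)
    neutral_tcn = 4 if wgd else 2
    flagged = []
    for s in fit.segments:
        if s.tcn is None or s.lcn is None:
            s.cnloh = None
            continue
        s.cnloh = s.lcn == 0 and s.tcn == neutral_tcn
        if s.cnloh:
            flagged.append(s)
    return flagged


def _overlaps(seg: Segment, chrom: str, start: int, end: int) -> bool:
    return seg.chrom == chrom and seg.start_pos <= end and seg.end_pos >= start


def call_gene_level(fit: PurityPloidyFit, genes: IntervalSet,
                    somatic_variants: list[VariantRecord] | None = None) -> list[GeneCall]:
    """Gene-level SCNA calls with WGD-adjusted thresholds.

    AMP: tcn >= 5 without WGD, > 6 with WGD (maximal overlapping segment);
    HOMDEL: tcn = 0; HETLOSS (tcn = 1) only when a somatic SNV/indel
    co-occurs in the gene; CN-LOH annotated per gene.  Genes not covered by
    any fitted segment are skipped with a warning.  No calls are emitted
    from a below-sensitivity fit.
    """
    if fit.below_sensitivity:
        warnings.warn("fit below the tumor-fraction sensitivity floor; "
                      "no gene-level SCNA emitted", stacklevel=2)
        return []
    somatic_variants = somatic_variants or []
    mutated_genes = {v.gene for v in somatic_variants if v.gene}
    wgd = bool(fit.wgd)
    amp_min = 7 if wgd else 5  # tcn > 6 with WGD == tcn >= 7
    calls: list[GeneCall] = []
    for _, g in genes.records.iterrows():
        overlapping = [s for s in fit.segments
                       if s.tcn is not None and _overlaps(s, g["chrom"], g["start"], g["end"])]
        if not overlapping:
            warnings.warn(f"gene {g['name']} not covered by any segment; skipped",
                          stacklevel=2)
            continue
        top = max(overlapping, key=lambda s: s.tcn)
        low = min(overlapping, key=lambda s: s.tcn)
        if top.tcn >= amp_min:
            calls.append(GeneCall(g["name"], "AMP", top.tcn, top.lcn))
        if low.tcn == 0:
            calls.append(GeneCall(g["name"], "HOMDEL", 0, 0))
        elif low.tcn == 1 and g["name"] in mutated_genes:
            calls.append(GeneCall(g["name"], "HETLOSS", 1, 0))
        if any(s.cnloh for s in overlapping):
            c = next(s for s in overlapping if s.cnloh)
            calls.append(GeneCall(g["name"], "CNLOH", c.tcn, c.lcn))
    return calls


def call_arm_level(fit: PurityPloidyFit, arms, min_fraction: float = 0.5) -> list[ArmCall]:
    """Arm-level gains/losses/CN-LOH covering at least half the arm.

    Gains: tcn >= 3 without WGD, tcn > 5 with WGD.  Losses: tcn < 2 without
    WGD, tcn < 4 with WGD (symmetric rule under doubling).  ``arms`` is an
    arm-definition DataFrame (chrom, arm, start, end, arm_length).
    """
    if fit.below_sensitivity:
        warnings.warn("fit below the tumor-fraction sensitivity floor; "
                      "no arm-level SCNA emitted", stacklevel=2)
        return []
    wgd = bool(fit.wgd)
    gain_min = 6 if wgd else 3   # tcn > 5 with WGD == tcn >= 6
    loss_below = 4 if wgd else 2
    calls: list[ArmCall] = []
    for _, a in arms.iterrows():
        arm_len = int(a["arm_length"])
        gain_len = loss_len = cnloh_len = 0
        gain_state = loss_state = cnloh_state = None
        for s in fit.segments:
            if s.tcn is None or not _overlaps(s, a["chrom"], a["start"], a["end"]):
                continue
            ov = min(s.end_pos, a["end"]) - max(s.start_pos, a["start"]) + 1
            if s.tcn >= gain_min:
                gain_len += ov
                gain_state = s
            if s.tcn < loss_below:
                loss_len += ov
                loss_state = s
            if s.cnloh:
                cnloh_len += ov
                cnloh_state = s
        for name, ln, st in (("GAIN", gain_len, gain_state),
                             ("LOSS", loss_len, loss_state),
                             ("CNLOH", cnloh_len, cnloh_state)):
            frac = ln / arm_len
            if frac >= min_fraction:
                calls.append(ArmCall(a["chrom"], a["arm"], name, frac,
                                     st.tcn if st else None, st.lcn if st else None))
    return calls
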