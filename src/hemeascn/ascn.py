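"""Copy-number log-ratios and allelic log-odds-ratios.

The tumor coverage track is normalized against a single reference normal.
Because library chemistry differs between tumor tissues and the nail or
saliva normals used in hematologic panels, the reference is chosen from a
pool of unmatched normals: each candidate yields a GC-corrected,
median-centered logR track and the candidate with the lowest sum of squared
logR is kept.  Allelic imbalance is measured by the log odds ratio of
alt:ref counts in tumor versus the patient-matched normal at SNPs that are
heterozygous in that normal (alt allele fraction within [0.25, 0.75]).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

LN2_SQ = np.log(2.0) ** 2
DEFAULT_MIN_HET_DEPTH = 20
HET_LOW, HET_HIGH = 0.25, 0.75  # inclusive bounds
GC_SPAN = 0.3


@dataclass
class LogRTrack:
    """Per-locus log2 coverage ratio, GC-corrected and median-centered."""

    logr: np.ndarray
    chosen_normal: str | None = None
    ss_logr: dict[str, float] = field(default_factory=dict)


@dataclass
class LogOrTrack:
    """Per-het-locus log2 odds ratio (sign arbitrary) with its variance."""

    logor: np.ndarray       # NaN outside het_mask
    variance: np.ndarray    # NaN outside het_mask
    het_mask: np.ndarray


def gc_correct(raw_logr: np.ndarray, gc: np.ndarray, span: float = GC_SPAN) -> np.ndarray:
    """Subtract a loess-style local-regression trend of logR on GC."""
    gc = np.asarray(gc, dtype=float)
    if np.ptp(gc) < 1e-9 or len(gc) < 10:
        return raw_logr.copy()
    fitted = lowess(raw_logr, gc, frac=span, return_sorted=False,
                    delta=0.01 * np.ptp(gc))
    return raw_logr - fitted


def compute_logr(tumor_depth: np.ndarray, normal_depth: np.ndarray,
                 gc: np.ndarray, span: float = GC_SPAN) -> LogRTrack:
    """logR_i = log2((t_i + 1) / (n_i + 1)) - GC trend - median.

    A +1 pseudocount keeps zero-depth loci finite; the median is removed
    exactly, so ``median(logr) == 0``.
    """
    tumor_depth = np.asarray(tumor_depth, dtype=float)
    normal_depth = np.asarray(normal_depth, dtype=float)
    if tumor_depth.shape != normal_depth.shape:
        raise ValueError("tumor and normal depth vectors differ in length")
    raw = np.log2(tumor_depth + 1.0) - np.log2(normal_depth + 1.0)
    corrected = gc_correct(raw, gc, span=span)
    corrected = corrected - np.median(corrected)
    return LogRTrack(logr=corrected)


def select_unmatched_normal(tumor_depth: np.ndarray,
                            candidate_depths: dict[str, np.ndarray],
                            gc: np.ndarray,
                            autosomal_mask: np.ndarray | None = None,
                            span: float = GC_SPAN) -> tuple[str, LogRTrack]:
    """Pick the pool normal minimizing the sum-squared centered logR.

    The sum of squares is evaluated on autosomal loci only (sex-chromosome
    dosage differences between tumor and pool samples would otherwise
    dominate).  Ties break to the earliest candidate in iteration order.
    Returns the chosen sample id and its full-length logR track.
    """
    if not candidate_depths:
        raise ValueError("at least one candidate normal is required")
    if all(np.sum(d) == 0 for d in candidate_depths.values()):
        raise ValueError("all candidate normals have zero depth")
    if autosomal_mask is None:
        autosomal_mask = np.ones(len(tumor_depth), dtype=bool)

    ss: dict[str, float] = {}
    tracks: dict[str, LogRTrack] = {}
    for sample, depth in candidate_depths.items():
        track = compute_logr(tumor_depth, depth, gc, span=span)
        tracks[sample] = track
        ss[sample] = float(np.sum(track.logr[autosomal_mask] ** 2))
    chosen = min(ss, key=lambda s: (ss[s], list(candidate_depths).index(s)))
    best = tracks[chosen]
    best.chosen_normal = chosen
    best.ss_logr = ss
    return chosen, best


def select_het_snps(normal_ref: np.ndarray, normal_alt: np.ndarray,
                    min_depth: int = DEFAULT_MIN_HET_DEPTH) -> np.ndarray:
    """Heterozygous-SNP mask from matched-normal counts.

    het iff depth >= min_depth and alt fraction in [0.25, 0.75], bounds
    inclusive; the fraction comparison is exact integer arithmetic.
    """
    normal_ref = np.asarray(normal_ref, dtype=np.int64)
    normal_alt = np.asarray(normal_alt, dtype=np.int64)
    depth = normal_ref + normal_alt
    return (depth >= min_depth) & (4 * normal_alt >= depth) & (4 * normal_alt <= 3 * depth)


def compute_logor(tumor_ref: np.ndarray, tumor_alt: np.ndarray,
                  normal_ref: np.ndarray, normal_alt: np.ndarray,
                  het_mask: np.ndarray) -> LogOrTrack:
    """Log odds ratio of alt:ref counts, tumor vs normal, at het SNPs.

    Haldane-Anscombe 0.5 pseudocounts give finite values and the matching
    asymptotic variance (1/(ta+.5) + 1/(tr+.5) + 1/(na+.5) + 1/(nr+.5)) on
    the log2 scale.
    """
    het_mask = np.asarray(het_mask, dtype=bool)
    if not het_mask.any():
        raise ValueError(
            "no heterozygous SNPs available; insufficient heterozygous coverage"
        )
    ta = np.asarray(tumor_alt, dtype=float) + 0.5
    tr = np.asarray(tumor_ref, dtype=float) + 0.5
    na = np.asarray(normal_alt, dtype=float) + 0.5
    nr = np.asarray(normal_ref, dtype=float) + 0.5
    logor = np.full(len(het_mask), np.nan)
    variance = np.full(len(het_mask), np.nan)
    m = het_mask
    logor[m] = np.log2((ta[m] / tr[m]) / (na[m] / nr[m]))
    variance[m] = (1 / ta[m] + 1 / tr[m] + 1 / na[m] + 1 / nr[m]) / LN2_SQ
    return LogOrTrack(logor=logor, variance=variance, het_mask=het_mask)
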