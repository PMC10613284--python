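"""Joint segmentation of copy-number logR and allelic logOR tracks.

The changepoint scan is a bivariate CUSUM-style recursive binary
segmentation run per chromosome.  At each candidate split the statistic

    T = z_logR**2 + z_logOR**2

combines scaled mean differences of the logR track and of the
noise-corrected squared logOR track (allelic imbalance is sign-free, so the
folded value logOR**2 is segmented).  A split is accepted iff max T exceeds
the sensitivity parameter ``cval``; accepted splits are recursed into, so
boundaries found at a high cval are a subset of those found at a lower one.
A two-pass scheme runs a coarse pass (default cval 150) to anchor the
diploid logR level and a sensitive pass (default cval 75) for focal events.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_CVAL_COARSE = 150.0
DEFAULT_CVAL_FINE = 75.0
MIN_SEG_MARKS = 10
BALANCE_THRESHOLD = 0.05  # on noise-corrected mean logOR^2
_MIN_HET_SIDE = 5  # het SNPs required on each flank for the logOR term


@dataclass
class Segment:
    """A run of loci with homogeneous logR and allelic imbalance."""

    chrom: str
    start_pos: int
    end_pos: int
    num_mark: int
    mean_logr: float
    mean_logor2: float = 0.0
    n_het: int = 0
    # filled in by the purity/ploidy fit
    tcn: int | None = None
    lcn: int | None = None
    cnloh: bool | None = None

    @property
    def length(self) -> int:
        return self.end_pos - self.start_pos + 1

    @property
    def major_cn(self) -> int | None:
        if self.tcn is None or self.lcn is None:
            return None
        return self.tcn - self.lcn


def _robust_sd(x: np.ndarray) -> float:
    """Noise scale from median absolute first differences (trend-immune)."""
    x = x[np.isfinite(x)]
    if len(x) < 3:
        return 1.0
    d = np.abs(np.diff(x))
    sd = 1.4826 * np.median(d) / np.sqrt(2.0)
    if not np.isfinite(sd) or sd <= 0:
        sd = float(np.std(x)) or 1.0
    return float(sd)


def _scan_t(logr: np.ndarray, y_or: np.ndarray, het: np.ndarray,
            min_marks: int) -> tuple[int, float]:
    """Return (best split index k, max T) for one segment; k splits [0:k), [k:n).

    Noise scales are estimated locally (median absolute first differences
    within the scanned stretch), so heteroscedasticity between balanced and
    imbalanced regions does not inflate the statistic.
    """
    n = len(logr)
    if n < 2 * min_marks:
        return -1, -np.inf
    sd_r = _robust_sd(logr)
    sd_y = _robust_sd(y_or[het]) if het.sum() >= 3 else 1.0
    ks = np.arange(min_marks, n - min_marks + 1)
    cr = np.concatenate(([0.0], np.cumsum(logr)))
    nl = ks.astype(float)
    nr = n - nl
    mean_l = cr[ks] / nl
    mean_r = (cr[n] - cr[ks]) / nr
    z_r = (mean_l - mean_r) / (sd_r * np.sqrt(1.0 / nl + 1.0 / nr))
    t = z_r**2

    hc = np.concatenate(([0], np.cumsum(het.astype(np.int64))))
    y_filled = np.where(het, y_or, 0.0)
    cy = np.concatenate(([0.0], np.cumsum(y_filled)))
    hl = hc[ks].astype(float)
    hr = hc[n] - hl
    ok = (hl >= _MIN_HET_SIDE) & (hr >= _MIN_HET_SIDE)
    with np.errstate(divide="ignore", invalid="ignore"):
        my_l = cy[ks] / hl
        my_r = (cy[n] - cy[ks]) / hr
        z_y = (my_l - my_r) / (sd_y * np.sqrt(1.0 / hl + 1.0 / hr))
    t = t + np.where(ok, z_y**2, 0.0)

    i = int(np.argmax(t))
    return int(ks[i]), float(t[i])


def _binary_segment(logr: np.ndarray, y_or: np.ndarray, het: np.ndarray,
                    cval: float, min_marks: int) -> list[int]:
    """Breakpoint indices (split positions) within one chromosome."""
    n = len(logr)
    breaks: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        k, t = _scan_t(logr[lo:hi], y_or[lo:hi], het[lo:hi], min_marks)
        if k >= 0 and t > cval:
            breaks.append(lo + k)
            stack.append((lo, lo + k))
            stack.append((lo + k, hi))
    return sorted(breaks)


def segment_bivariate(chrom: np.ndarray, pos: np.ndarray, logr: np.ndarray,
                      logor: np.ndarray, logor_var: np.ndarray, het_mask: np.ndarray,
                      cval: float = DEFAULT_CVAL_FINE,
                      min_seg_marks: int = MIN_SEG_MARKS) -> list[Segment]:
    """Segment aligned logR / logOR tracks chromosome by chromosome.

    ``logor`` and ``logor_var`` are read only where ``het_mask`` is true.
    Chromosomes with fewer than ``2 * min_seg_marks`` loci yield a single
    segment.  Segment summaries report the mean logR, the het count, and
    the noise-corrected mean squared logOR floored at zero.
    """
    if cval <= 0:
        raise ValueError("cval must be positive")
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    logr = np.asarray(logr, dtype=float)
    het_mask = np.asarray(het_mask, dtype=bool)
    y = np.zeros_like(logr)
    y[het_mask] = np.asarray(logor, dtype=float)[het_mask] ** 2 - np.asarray(
        logor_var, dtype=float)[het_mask]

    segments: list[Segment] = []
    # preserve genomic order: iterate chromosomes in order of appearance
    _, first_idx = np.unique(chrom, return_index=True)
    for c in chrom[np.sort(first_idx)]:
        idx = np.flatnonzero(chrom == c)
        breaks = _binary_segment(logr[idx], y[idx], het_mask[idx],
                                 cval, min_seg_marks)
        bounds = [0, *breaks, len(idx)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            sl = idx[lo:hi]
            het_sl = sl[het_mask[sl]]
            n_het = len(het_sl)
            mean_or2 = max(0.0, float(np.mean(y[het_sl]))) if n_het else 0.0
            segments.append(
                Segment(
                    chrom=str(c),
                    start_pos=int(pos[sl[0]]),
                    end_pos=int(pos[sl[-1]]),
                    num_mark=len(sl),
                    mean_logr=float(np.mean(logr[sl])),
                    mean_logor2=mean_or2,
                    n_het=n_het,
                )
            )
    return segments


def estimate_diplogr(segments: list[Segment],
                     balance_threshold: float = BALANCE_THRESHOLD,
                     min_het: int = 10,
                     cluster_gap: float = 0.10) -> tuple[float, bool]:
    """Estimate the logR level corresponding to the diploid genome.

    Allelically balanced segments (noise-corrected mean logOR^2 below
    ``balance_threshold``, at least ``min_het`` het SNPs) are clustered on
    mean logR by single-linkage with gap ``cluster_gap``; the marker-weighted
    mean of the heaviest cluster is returned.  Falls back to the weighted
    median over all segments (with a warning) when no balanced segment
    exists.  Returns ``(dipLogR, used_fallback)``.
    """
    balanced = [s for s in segments if s.n_het >= min_het
                and s.mean_logor2 <= balance_threshold]
    if not balanced:
        warnings.warn("no allelically balanced segments; dipLogR falls back to "
                      "the weighted median logR", stacklevel=2)
        means = np.array([s.mean_logr for s in segments])
        weights = np.array([s.num_mark for s in segments], dtype=float)
        order = np.argsort(means)
        cum = np.cumsum(weights[order])
        med_idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
        return float(means[order][min(med_idx, len(means) - 1)]), True

    means = np.array([s.mean_logr for s in balanced])
    weights = np.array([s.num_mark for s in balanced], dtype=float)
    order = np.argsort(means)
    means, weights = means[order], weights[order]
    # single-linkage 1-d clustering: break where consecutive means gap
    cluster_ids = np.concatenate(([0], np.cumsum(np.diff(means) > cluster_gap)))
    best_id = max(set(cluster_ids.tolist()),
                  key=lambda cid: (weights[cluster_ids == cid].sum(), -means[cluster_ids == cid].min()))
    sel = cluster_ids == best_id
    return float(np.average(means[sel], weights=weights[sel])), False
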