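"""Tumor mutation burden, cohort thresholding, and SBS96 signature refitting.

TMB counts synonymous and nonsynonymous SNVs and indels per megabase of
the panel's targeted footprint (1.0837 Mb).  The cohort TMB-high cutoff is
median + 2*IQR with linear-interpolation (type-7) quantiles, and
classification is strictly greater-than.  High-TMB samples are decomposed
into SBS96 spectra (pyrimidine-strand convention) and refit against a
signature catalog by nonnegative least squares, with one pruning pass
removing signatures contributing under 5%.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import SBS96_CHANNELS, VariantRecord, revcomp

PANEL_MB = 1.0837
TMB_HIGH_CUTOFF = 12.9  # cohort-derived published cutoff, strict >
PRUNE_BELOW = 0.05

_COUNTED_EFFECTS = {"synonymous", "nonsynonymous"}


@dataclass
class TmbResult:
    mutation_count: int
    panel_mb: float
    tmb: float
    tmb_high: bool | None = None  # None until a cohort threshold is applied


def compute_tmb(variants: list[VariantRecord], panel_mb: float = PANEL_MB) -> TmbResult:
    """Mutations per megabase for one sample (coding SNVs + indels)."""
    count = sum(1 for v in variants if v.coding_effect in _COUNTED_EFFECTS)
    return TmbResult(mutation_count=count, panel_mb=panel_mb, tmb=count / panel_mb)


def tmb_high_threshold(cohort_tmbs) -> float:
    """Cohort TMB-high cutoff: median + 2*IQR (type-7 quantiles)."""
    tmbs = np.asarray(list(cohort_tmbs), dtype=float)
    if len(tmbs) < 4:
        raise ValueError("cohort of at least 4 samples required for a TMB threshold")
    q25, q50, q75 = np.quantile(tmbs, [0.25, 0.5, 0.75])  # linear interpolation
    return float(q50 + 2 * (q75 - q25))


def classify_tmb_high(tmb: float, threshold: float) -> bool:
    """TMB-high iff strictly above the threshold."""
    return tmb > threshold


@dataclass
class Sbs96Vector:
    counts: pd.Series  # indexed by SBS96_CHANNELS
    n_skipped: int = 0  # non-SNV or context-less records

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def count_sbs96(variants: list[VariantRecord]) -> Sbs96Vector:
    """Build the 96-channel substitution spectrum of a sample.

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand.  Non-SNV records and SNVs lacking a trinucleotide
    context are skipped and counted.
    """
    counts = pd.Series(0, index=SBS96_CHANNELS, dtype=int)
    skipped = 0
    for v in variants:
        ctx = v.trinucleotide_context
        if v.variant_class != "SNV" or ctx is None or len(ctx) != 3:
            skipped += 1
            continue
        ref, alt = v.ref, v.alt
        if ctx[1] != ref:
            skipped += 1
            continue
        if ref in "GA":
            ctx = revcomp(ctx)
            ref, alt = ctx[1], revcomp(alt)
        channel = f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"
        if channel not in counts.index:
            skipped += 1
            continue
        counts[channel] += 1
    return Sbs96Vector(counts=counts, n_skipped=skipped)


@dataclass
class SignatureFit:
    weights: pd.Series    # nonnegative, indexed by signature id
    fractions: pd.Series
    dominant: str
    residual: float

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.to_dict(),
            "fractions": self.fractions.to_dict(),
            "dominant": self.dominant,
            "residual": self.residual,
        }


def refit_signatures(spectrum: Sbs96Vector | pd.Series | np.ndarray,
                     catalog: pd.DataFrame,
                     prune_below: float = PRUNE_BELOW,
                     allow: list[str] | None = None) -> SignatureFit:
    """Nonnegative least-squares refit of a spectrum onto a catalog.

    ``w = argmin ||v - P w||_2  s.t.  w >= 0``; signatures whose fraction
    falls below ``prune_below`` are dropped and the fit re-solved once to
    limit inter-signature bleeding.  ``allow`` restricts the catalog to a
    signature subset (e.g. those extracted de novo for the tumor type).
    """
    if isinstance(spectrum, Sbs96Vector):
        v = spectrum.counts.reindex(catalog.index).to_numpy(dtype=float)
    elif isinstance(spectrum, pd.Series):
        v = spectrum.reindex(catalog.index).to_numpy(dtype=float)
    else:
        v = np.asarray(spectrum, dtype=float)
    if v.sum() <= 0:
        raise ValueError("empty spectrum: no counted substitutions to decompose")
    if allow is not None:
        catalog = catalog[list(allow)]
    cols = list(catalog.columns)
    P = catalog.to_numpy(dtype=float)

    w, _ = nnls(P, v)
    if w.sum() > 0:
        frac = w / w.sum()
        keep = frac >= prune_below
        if keep.any() and not keep.all():
            w2 = np.zeros_like(w)
            sub, _ = nnls(P[:, keep], v)
            w2[keep] = sub
            w = w2
    weights = pd.Series(w, index=cols)
    total = weights.sum()
    fractions = weights / total if total > 0 else weights * 0.0
    residual = float(np.linalg.norm(v - P @ w))
    return SignatureFit(weights=weights, fractions=fractions,
                        dominant=str(fractions.idxmax()), residual=residual)
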