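"""Variant provenance against host and donor normals, and contamination QC.

After allogeneic stem-cell transplant a marrow sample is a chimera of host
tumor, residual host normal, and donor-derived hematopoiesis, so a variant
seen in the tumor may be somatic, a host polymorphism, or a donor
polymorphism.  Provenance is resolved by genotyping every call in the host
baseline and all donor samples: somatic calls must reach a tumor VAF floor
(0.02) and be undetected in every normal; carriers at germline-like VAF
(>= 0.25, the het lower bound) assign the variant to host or donor.

Nail and saliva normals can carry contaminating tumor DNA.  Variants whose
matched-normal VAF exceeds 2% are flagged; those with a tumor:normal VAF
ratio of at least 5 are still treated as somatic (the same ratio the filter
cascade applies to unmatched normals), the rest as germline.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .ascn import select_het_snps
from .io import VariantRecord

VAF_FLOOR = 0.02
DETECT_ALT = 2          # alt reads below which a normal counts as "not detected"
DETECT_VAF = 0.01
CARRIER_VAF = 0.25      # germline-carrier threshold, reusing the het lower bound
CONTAMINATION_VAF = 0.02
RESCUE_RATIO = 5.0


class Provenance(str, Enum):
    SOMATIC = "SOMATIC"
    HOST_GERMLINE = "HOST_GERMLINE"
    DONOR_GERMLINE = "DONOR_GERMLINE"
    AMBIGUOUS = "AMBIGUOUS"
    BELOW_FLOOR = "BELOW_FLOOR"


@dataclass
class ProvenanceCall:
    verdict: Provenance
    tumor_vaf: float
    normal_vafs: dict[str, float] = field(default_factory=dict)
    tumor_to_normal_ratio: float = float("inf")


@dataclass
class ContaminationReport:
    """Per-variant contamination assessment of a matched normal tissue."""

    table: pd.DataFrame  # columns: tumor_vaf, normal_vaf, ratio, flagged, still_somatic
    normal_tissue: str
    n_flagged: int
    max_normal_vaf: float
    median_ratio: float | None


def intersect_het_snps(host_ref: np.ndarray, host_alt: np.ndarray,
                       donors: list[tuple[np.ndarray, np.ndarray]],
                       min_depth: int = 20) -> np.ndarray:
    """Het-SNP mask restricted to sites het in host AND every donor.

    With zero donors this degenerates to the host het mask.  Raises if the
    intersection is empty, since no allelic-imbalance signal would remain.
    """
    mask = select_het_snps(host_ref, host_alt, min_depth=min_depth)
    for d_ref, d_alt in donors:
        mask = mask & select_het_snps(d_ref, d_alt, min_depth=min_depth)
    if not mask.any():
        raise ValueError(
            "host/donor heterozygous-SNP intersection is empty; "
            "more loci or deeper normal coverage is needed"
        )
    return mask


def _detected(depth: int, alt: int, detect_alt: int, detect_vaf: float) -> bool:
    vaf = alt / depth if depth else 0.0
    return not (alt < detect_alt and vaf < detect_vaf)


def classify_posttransplant(v: VariantRecord,
                            host_samples: list[str],
                            donor_samples: list[str],
                            floor: float = VAF_FLOOR,
                            detect_alt: int = DETECT_ALT,
                            detect_vaf: float = DETECT_VAF,
                            carrier_vaf: float = CARRIER_VAF) -> ProvenanceCall:
    """Assign somatic / host-germline / donor-germline provenance.

    Order of evaluation: tumor VAF below ``floor`` -> BELOW_FLOOR; variant
    undetected (alt < detect_alt and VAF < detect_vaf) in host and every
    donor -> SOMATIC; otherwise the normal carrying it at VAF >=
    ``carrier_vaf`` names the germline source (host takes precedence when
    both carry it); detected but carried by no one -> AMBIGUOUS.
    """
    if not donor_samples:
        raise ValueError("post-transplant classification requires >=1 donor sample")
    for s in host_samples + donor_samples:
        if s not in v.normal_evidence:
            raise ValueError(f"missing genotyping evidence for normal sample {s!r}")

    vafs = {s: v.normal_vaf(s) for s in host_samples + donor_samples}
    max_normal = max(vafs.values(), default=0.0)
    ratio = v.vaf / max_normal if max_normal > 0 else float("inf")
    call = lambda verdict: ProvenanceCall(verdict, v.vaf, vafs, ratio)  # noqa: E731

    if v.vaf < floor:
        return call(Provenance.BELOW_FLOOR)
    undetected = all(
        not _detected(*v.normal_evidence[s], detect_alt, detect_vaf)
        for s in host_samples + donor_samples
    )
    if undetected:
        return call(Provenance.SOMATIC)
    if any(vafs[s] >= carrier_vaf for s in host_samples):
        return call(Provenance.HOST_GERMLINE)
    if any(vafs[s] >= carrier_vaf for s in donor_samples):
        return call(Provenance.DONOR_GERMLINE)
    return call(Provenance.AMBIGUOUS)


def assess_normal_contamination(tumor_vafs: np.ndarray, normal_vafs: np.ndarray,
                                tissue: str = "nail",
                                flag_threshold: float = CONTAMINATION_VAF,
                                rescue_ratio: float = RESCUE_RATIO) -> ContaminationReport:
    """Flag tumor-in-normal contamination and rescue high-ratio somatic calls.

    A variant is flagged when its normal VAF exceeds ``flag_threshold``
    (2%).  A flagged variant is still considered somatic when the tumor VAF
    is at least ``rescue_ratio`` (5x) the normal VAF, mirroring the cascade's
    unmatched-normal rule; otherwise it is treated as germline.
    """
    tumor_vafs = np.asarray(tumor_vafs, dtype=float)
    normal_vafs = np.asarray(normal_vafs, dtype=float)
    if tumor_vafs.shape != normal_vafs.shape:
        raise ValueError("tumor and normal VAF vectors differ in length")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(normal_vafs > 0, tumor_vafs / normal_vafs, np.inf)
    flagged = normal_vafs > flag_threshold
    still_somatic = flagged & (tumor_vafs >= rescue_ratio * normal_vafs)
    table = pd.DataFrame(
        {
            "tumor_vaf": tumor_vafs,
            "normal_vaf": normal_vafs,
            "ratio": ratio,
            "flagged": flagged,
            "still_somatic": still_somatic,
        }
    )
    finite = ratio[flagged & np.isfinite(ratio)]
    return ContaminationReport(
        table=table,
        normal_tissue=tissue,
        n_flagged=int(flagged.sum()),
        max_normal_vaf=float(normal_vafs.max()) if len(normal_vafs) else 0.0,
        median_ratio=float(np.median(finite)) if len(finite) else None,
    )
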