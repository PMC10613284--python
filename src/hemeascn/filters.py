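"""The matched somatic SNV/indel filter cascade and tumor-only triage.

Every candidate call must clear the common filters: tumor VAF at least 5x
the unmatched-normal VAF, >= 20 total reads, >= 5 alt reads, VAF >= 1%, and
presence in fewer than 20% of the standard panel of normals.  Tiered
filters then apply: hotspot sites need >= 8 alt reads and VAF >= 2%;
non-hotspot sites need >= 10 alt reads, VAF >= 5%, and a matched-normal to
tumor VAF ratio <= 0.35 (a literal both-samples-<=-35% reading is available
behind a config switch).  Tumor-only triage labels variants with any
population frequency > 0.01 as likely germline; it never runs in matched
mode.

VAFs are compared as exact rationals (alt/depth against decimal
thresholds), so printed boundary values behave deterministically.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from fractions import Fraction

from .germline import Provenance, ProvenanceCall, classify_posttransplant
from .io import Role, VariantRecord


@dataclass
class FilterConfig:
    """Cascade thresholds; defaults are the assay's printed values."""

    ratio_unmatched: float = 5.0
    min_depth: int = 20
    min_alt_common: int = 5
    min_vaf_common: float = 0.01
    pon_max: float = 0.20
    hotspot_min_alt: int = 8
    hotspot_min_vaf: float = 0.02
    nonhotspot_min_alt: int = 10
    nonhotspot_min_vaf: float = 0.05
    matched_ratio_max: float = 0.35
    population_af_max: float = 0.01
    literal_matched_rule: bool = False  # both tumor and normal VAF <= 0.35

    def __post_init__(self) -> None:
        for name in ("min_vaf_common", "pon_max", "hotspot_min_vaf",
                     "nonhotspot_min_vaf", "matched_ratio_max", "population_af_max"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} outside [0, 1]")
        if self.ratio_unmatched < 1:
            raise ValueError("ratio_unmatched must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        return cls(**d)


@dataclass
class FilterResult:
    verdict: str  # PASS | FAIL
    failed_rules: list[str] = field(default_factory=list)
    tier: str = "non-hotspot"

    def __post_init__(self) -> None:
        assert (self.verdict == "PASS") == (not self.failed_rules)


def _frac(x: float) -> Fraction:
    """Decimal threshold as an exact rational."""
    return Fraction(str(x))


def apply_common_filters(v: VariantRecord, unmatched_normal_vaf: float | Fraction | None,
                         cfg: FilterConfig = FilterConfig()) -> FilterResult:
    """Common filters every candidate must clear, failures enumerated.

    ``unmatched_normal_vaf`` of None skips the 5x ratio rule (no unmatched
    control was genotyped).
    """
    failed: list[str] = []
    vaf = v.exact_vaf()
    if unmatched_normal_vaf is not None:
        u = unmatched_normal_vaf if isinstance(unmatched_normal_vaf, Fraction) \
            else Fraction(str(unmatched_normal_vaf))
        if vaf < _frac(cfg.ratio_unmatched) * u:
            failed.append("unmatched_ratio")
    if v.tumor_depth < cfg.min_depth:
        failed.append("min_depth")
    if v.tumor_alt < cfg.min_alt_common:
        failed.append("min_alt")
    if vaf < _frac(cfg.min_vaf_common):
        failed.append("min_vaf")
    if not Fraction(str(v.pon_fraction)) < _frac(cfg.pon_max):  # strict <
        failed.append("panel_of_normals")
    tier = "hotspot" if v.hotspot else "non-hotspot"
    return FilterResult("PASS" if not failed else "FAIL", failed, tier)


def apply_tier_filters(v: VariantRecord, cfg: FilterConfig = FilterConfig(),
                       matched_normal_vaf: float | Fraction | None = None,
                       require_matched: bool = True) -> FilterResult:
    """Hotspot / non-hotspot tier filters (common filters assumed passed)."""
    failed: list[str] = []
    vaf = v.exact_vaf()
    if v.hotspot:
        if v.tumor_alt < cfg.hotspot_min_alt:
            failed.append("min_alt_hotspot")
        if vaf < _frac(cfg.hotspot_min_vaf):
            failed.append("min_vaf_hotspot")
        return FilterResult("PASS" if not failed else "FAIL", failed, "hotspot")

    if v.tumor_alt < cfg.nonhotspot_min_alt:
        failed.append("min_alt_nonhotspot")
    if vaf < _frac(cfg.nonhotspot_min_vaf):
        failed.append("min_vaf_nonhotspot")
    if matched_normal_vaf is None:
        if require_matched:
            failed.append("no_matched_normal")
    else:
        n = matched_normal_vaf if isinstance(matched_normal_vaf, Fraction) \
            else Fraction(str(matched_normal_vaf))
        if cfg.literal_matched_rule:
            if n > _frac(cfg.matched_ratio_max) or vaf > _frac(cfg.matched_ratio_max):
                failed.append("germline_ratio")
        elif vaf == 0 or n / vaf > _frac(cfg.matched_ratio_max):
            failed.append("germline_ratio")
    return FilterResult("PASS" if not failed else "FAIL", failed, "non-hotspot")


def population_triage(v: VariantRecord, af_threshold: float = 0.01) -> str:
    """Tumor-only triage: GERMLINE_LIKELY iff population AF > threshold.

    Missing population frequency retains the variant.  Never applied in
    matched mode.
    """
    if v.population_af is not None and v.population_af > af_threshold:
        return "GERMLINE_LIKELY"
    return "RETAINED"


@dataclass
class AnnotatedVariant:
    variant: VariantRecord
    result: FilterResult
    provenance: ProvenanceCall | None = None
    population_label: str | None = None


def _pooled_vaf(v: VariantRecord, samples: list[str]) -> Fraction | None:
    depth = alt = 0
    for s in samples:
        ev = v.normal_evidence.get(s)
        if ev is not None:
            depth += ev[0]
            alt += ev[1]
    if depth == 0:
        return None
    return Fraction(alt, depth)


def run_cascade(variants: list[VariantRecord], roles: dict[str, Role],
                mode: str = "matched",
                cfg: FilterConfig = FilterConfig()) -> list[AnnotatedVariant]:
    """Compose common, tier, and provenance filtering per analysis mode.

    Modes: ``matched`` (matched normal drives the germline-ratio rule),
    ``unmatched`` (no matched normal; the ratio rule is skipped and
    population triage annotates the output), ``post_transplant`` (host +
    donor provenance classification must return SOMATIC).  Input order is
    preserved; every variant carries the full reason trail.
    """
    roles = {s: Role(r) for s, r in roles.items()}
    matched = [s for s, r in roles.items() if r is Role.MATCHED_NORMAL]
    donors = [s for s, r in roles.items() if r is Role.DONOR_NORMAL]
    unmatched = [s for s, r in roles.items() if r is Role.UNMATCHED_NORMAL]
    if mode == "matched" and not matched:
        raise ValueError("matched mode requires a MATCHED_NORMAL sample")
    if mode == "post_transplant" and (not matched or not donors):
        raise ValueError("post_transplant mode requires host and donor samples")
    if mode not in ("matched", "unmatched", "post_transplant"):
        raise ValueError(f"unknown mode {mode!r}")

    out: list[AnnotatedVariant] = []
    for v in variants:
        unmatched_vaf = _pooled_vaf(v, unmatched)
        common = apply_common_filters(v, unmatched_vaf, cfg)
        failed = list(common.failed_rules)
        matched_vaf = _pooled_vaf(v, matched) if matched else None
        tier = apply_tier_filters(
            v, cfg, matched_normal_vaf=matched_vaf,
            require_matched=(mode != "unmatched"),
        )
        failed += tier.failed_rules

        provenance = None
        pop_label = None
        if mode == "post_transplant":
            provenance = classify_posttransplant(v, matched, donors)
            if provenance.verdict is not Provenance.SOMATIC:
                failed.append(f"provenance_{provenance.verdict.value.lower()}")
        elif mode == "unmatched":
            pop_label = population_triage(v, cfg.population_af_max)

        result = FilterResult("PASS" if not failed else "FAIL", failed, tier.tier)
        out.append(AnnotatedVariant(v, result, provenance, pop_label))
    return out
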