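"""Readers and writers for every external format the toolkit touches.

Coordinate conventions
----------------------
All genomic positions are 1-based inclusive internally (the VCF/MAF
convention, which dominates the data model).  BED inputs are converted on
read (``start + 1``).  Chromosomes are ordered 1..22, X, Y; mitochondrial
and alternate contigs are rejected — the panel is nuclear.

Formats: SNP pileup count tables (TSV/CSV), MAF-style variant tables,
VCF 4.x, BED gene panels, chromosome-arm TSVs, SEG output, hotspot TSVs and
COSMIC-style 96-channel signature catalogs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .segment import Segment


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class EmptyInputError(ValueError):
    """A file parsed cleanly but contains no usable records."""


AUTOSOMES = [str(i) for i in range(1, 23)]
CHROMS = AUTOSOMES + ["X", "Y"]
_CHROM_RANK = {c: i for i, c in enumerate(CHROMS)}

_SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
#: COSMIC channel order: substitution class major, 5' then 3' context minor.
SBS96_CHANNELS = [
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def normalize_chrom(chrom: str) -> str:
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c not in _CHROM_RANK:
        raise FormatError(
            f"unsupported contig {chrom!r}: only nuclear chromosomes 1-22, X, Y are accepted"
        )
    return c


def chrom_rank(chrom: str) -> int:
    return _CHROM_RANK[normalize_chrom(chrom)]


class Role(str, Enum):
    TUMOR = "TUMOR"
    MATCHED_NORMAL = "MATCHED_NORMAL"
    DONOR_NORMAL = "DONOR_NORMAL"
    UNMATCHED_NORMAL = "UNMATCHED_NORMAL"


NORMAL_ROLES = {Role.MATCHED_NORMAL, Role.DONOR_NORMAL, Role.UNMATCHED_NORMAL}


@dataclass
class SnpMatrix:
    """Per-locus ref/alt read counts across all samples of a case.

    ``loci`` has columns chrom, pos, ref, alt, gc; ``ref_counts`` and
    ``alt_counts`` are loci x samples integer frames sharing the loci index.
    """

    loci: pd.DataFrame
    ref_counts: pd.DataFrame
    alt_counts: pd.DataFrame
    roles: dict[str, Role]

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ref", "alt", "gc"}
        missing = required - set(self.loci.columns)
        if missing:
            raise FormatError(f"loci table missing columns: {sorted(missing)}")
        if len(self.loci) == 0:
            raise EmptyInputError("SNP matrix contains zero loci")
        self.roles = {s: Role(r) for s, r in self.roles.items()}
        samples = list(self.roles)
        for frame, name in ((self.ref_counts, "ref_counts"), (self.alt_counts, "alt_counts")):
            if list(frame.columns) != samples:
                frame_cols = set(frame.columns)
                if frame_cols != set(samples):
                    raise FormatError(f"{name} columns do not match role map samples")
            if len(frame) != len(self.loci):
                raise FormatError(f"{name} length does not match loci")
            if (frame.to_numpy() < 0).any():
                raise FormatError(f"{name} contains negative counts")
        n_tumor = sum(r is Role.TUMOR for r in self.roles.values())
        if n_tumor != 1:
            raise FormatError(f"exactly one TUMOR sample required, got {n_tumor}")
        if not any(r in NORMAL_ROLES for r in self.roles.values()):
            raise FormatError("at least one normal-role sample required")
        self.loci = self.loci.copy()
        self.loci["chrom"] = [normalize_chrom(c) for c in self.loci["chrom"]]
        rank = self.loci["chrom"].map(_CHROM_RANK).to_numpy()
        order = np.lexsort((self.loci["pos"].to_numpy(), rank))
        self.loci = self.loci.iloc[order].reset_index(drop=True)
        self.ref_counts = self.ref_counts[samples].iloc[order].reset_index(drop=True)
        self.alt_counts = self.alt_counts[samples].iloc[order].reset_index(drop=True)
        if not (self.loci["gc"].between(0, 1)).all():
            raise FormatError("gc fractions must lie in [0, 1]")

    # -- convenience accessors -------------------------------------------
    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def samples(self) -> list[str]:
        return list(self.roles)

    def samples_with_role(self, role: Role) -> list[str]:
        return [s for s, r in self.roles.items() if r is role]

    @property
    def tumor_sample(self) -> str:
        return self.samples_with_role(Role.TUMOR)[0]

    @property
    def matched_normals(self) -> list[str]:
        return self.samples_with_role(Role.MATCHED_NORMAL)

    @property
    def donor_normals(self) -> list[str]:
        return self.samples_with_role(Role.DONOR_NORMAL)

    @property
    def unmatched_normals(self) -> list[str]:
        return self.samples_with_role(Role.UNMATCHED_NORMAL)

    def ref(self, sample: str) -> np.ndarray:
        return self.ref_counts[sample].to_numpy(dtype=np.int64)

    def alt(self, sample: str) -> np.ndarray:
        return self.alt_counts[sample].to_numpy(dtype=np.int64)

    def depth(self, sample: str) -> np.ndarray:
        return self.ref(sample) + self.alt(sample)

    def autosomal_mask(self) -> np.ndarray:
        return self.loci["chrom"].isin(AUTOSOMES).to_numpy()


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_snp_pileup(path: str | Path, role_map: dict[str, Role | str]) -> SnpMatrix:
    """Read a SNP pileup count table.

    Expects columns chrom, pos, ref, alt, optionally gc, and per-sample
    pairs ``<sample>_ref`` / ``<sample>_alt`` for every sample in
    ``role_map``.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    base = {"chrom", "pos", "ref", "alt"}
    missing = base - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: zero loci")
    for sample in role_map:
        for suffix in ("_ref", "_alt"):
            if f"{sample}{suffix}" not in df.columns:
                raise FormatError(f"{path}: missing column {sample}{suffix}")
    loci = df[["chrom", "pos", "ref", "alt"]].copy()
    loci["gc"] = df["gc"] if "gc" in df.columns else 0.5
    ref_counts = pd.DataFrame({s: df[f"{s}_ref"] for s in role_map})
    alt_counts = pd.DataFrame({s: df[f"{s}_alt"] for s in role_map})
    return SnpMatrix(loci, ref_counts, alt_counts, dict(role_map))


def write_snp_pileup(sm: SnpMatrix, path: str | Path) -> None:
    df = sm.loci.copy()
    for s in sm.samples:
        df[f"{s}_ref"] = sm.ref_counts[s]
        df[f"{s}_alt"] = sm.alt_counts[s]
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_roles(path: str | Path) -> dict[str, Role]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "role"} <= set(df.columns):
        raise FormatError(f"{path}: role table needs columns sample, role")
    try:
        return {str(r["sample"]): Role(r["role"]) for _, r in df.iterrows()}
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_roles(roles: dict[str, Role], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(roles), "role": [Role(r).value for r in roles.values()]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant records
# ---------------------------------------------------------------------------

VARIANT_CLASSES = {"SNV", "INS", "DEL", "ITD"}
CODING_EFFECTS = {"synonymous", "nonsynonymous", "other"}

_CLASSIFICATION_TO_EFFECT = {
    "Silent": "synonymous",
    "Missense_Mutation": "nonsynonymous",
    "Nonsense_Mutation": "nonsynonymous",
    "Nonstop_Mutation": "nonsynonymous",
    "Splice_Site": "nonsynonymous",
    "Translation_Start_Site": "nonsynonymous",
    "Frame_Shift_Ins": "nonsynonymous",
    "Frame_Shift_Del": "nonsynonymous",
    "In_Frame_Ins": "nonsynonymous",
    "In_Frame_Del": "nonsynonymous",
}
_EFFECT_TO_CLASSIFICATION = {
    "synonymous": "Silent",
    "nonsynonymous": "Missense_Mutation",
    "other": "Other",
}
_MAF_TYPE = {"SNV": "SNP", "INS": "INS", "DEL": "DEL", "ITD": "ITD"}
_MAF_TYPE_BACK = {"SNP": "SNV", "SNV": "SNV", "INS": "INS", "DEL": "DEL", "ITD": "ITD", "DNP": "SNV"}


@dataclass
class VariantRecord:
    """A candidate somatic mutation with per-sample genotyping evidence."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str = "SNV"
    coding_effect: str = "nonsynonymous"
    tumor_depth: int = 0
    tumor_alt: int = 0
    normal_evidence: dict[str, tuple[int, int]] = field(default_factory=dict)
    hotspot: bool = False
    population_af: float | None = None
    pon_fraction: float = 0.0
    gene: str | None = None
    trinucleotide_context: str | None = None

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.variant_class not in VARIANT_CLASSES:
            raise FormatError(f"unknown variant_class {self.variant_class!r}")
        if self.coding_effect not in CODING_EFFECTS:
            raise FormatError(f"unknown coding_effect {self.coding_effect!r}")
        if self.tumor_alt > self.tumor_depth:
            raise FormatError("tumor_alt exceeds tumor_depth")
        if not 0.0 <= self.pon_fraction <= 1.0:
            raise FormatError("pon_fraction outside [0, 1]")

    @property
    def vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    def exact_vaf(self) -> Fraction:
        """Tumor VAF as an exact rational, for boundary-safe threshold tests."""
        if self.tumor_depth == 0:
            return Fraction(0)
        return Fraction(self.tumor_alt, self.tumor_depth)

    def normal_vaf(self, sample: str) -> float | None:
        ev = self.normal_evidence.get(sample)
        if ev is None:
            return None
        depth, alt = ev
        return alt / depth if depth else 0.0

    @property
    def is_indel(self) -> bool:
        return self.variant_class in {"INS", "DEL", "ITD"}

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _encode_normals(ev: dict[str, tuple[int, int]]) -> str:
    return ";".join(f"{s}:{d}:{a}" for s, (d, a) in ev.items())


def _decode_normals(text) -> dict[str, tuple[int, int]]:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return {}
    out: dict[str, tuple[int, int]] = {}
    for part in str(text).split(";"):
        sample, depth, alt = part.rsplit(":", 2)
        out[sample] = (int(depth), int(alt))
    return out


_MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Type",
    "Variant_Classification",
    "t_depth",
    "t_alt_count",
    "Hotspot",
    "Population_AF",
    "PoN_Fraction",
    "Trinucleotide_Context",
    "Normal_Genotypes",
]


def read_variants(path: str | Path, dialect: str = "MAF") -> list[VariantRecord]:
    """Read candidate variants from a MAF-style TSV or a VCF.

    One record per row (MAF) or per ALT allele (VCF, multi-allelic sites
    decomposed).  VCF indels are left-normalized by allele trimming on read.
    """
    dialect = dialect.upper()
    if dialect == "MAF":
        return _read_maf(path)
    if dialect == "VCF":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_maf(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chromosome": str})
    needed = {"Chromosome", "Start_Position", "Reference_Allele", "Tumor_Seq_Allele2"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"{path}: MAF missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            classification = str(row.get("Variant_Classification", "Other"))
            effect = _CLASSIFICATION_TO_EFFECT.get(classification, "other")
            af = row.get("Population_AF")
            af = None if af is None or pd.isna(af) else float(af)
            gene = row.get("Hugo_Symbol")
            gene = None if gene is None or pd.isna(gene) else str(gene)
            ctx = row.get("Trinucleotide_Context")
            ctx = None if ctx is None or pd.isna(ctx) else str(ctx)
            records.append(
                VariantRecord(
                    chrom=str(row["Chromosome"]),
                    pos=int(row["Start_Position"]),
                    ref=str(row["Reference_Allele"]),
                    alt=str(row["Tumor_Seq_Allele2"]),
                    variant_class=_MAF_TYPE_BACK.get(str(row.get("Variant_Type", "SNP")), "SNV"),
                    coding_effect=effect,
                    tumor_depth=int(row.get("t_depth", 0)),
                    tumor_alt=int(row.get("t_alt_count", 0)),
                    normal_evidence=_decode_normals(row.get("Normal_Genotypes")),
                    hotspot=bool(row.get("Hotspot", False)),
                    population_af=af,
                    pon_fraction=float(row.get("PoN_Fraction", 0.0) or 0.0),
                    gene=gene,
                    trinucleotide_context=ctx,
                )
            )
        except (ValueError, KeyError, FormatError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    return records


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-normalize a REF/ALT pair by trimming shared suffix then prefix."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _read_vcf(path: str | Path) -> list[VariantRecord]:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            for alt_i, alt in enumerate(rec.alts or ()):
                pos, ref, alt_t = trim_alleles(rec.pos, rec.ref, alt)
                if len(ref) == len(alt_t) == 1:
                    vclass = "SNV"
                elif len(alt_t) > len(ref):
                    vclass = "INS"
                else:
                    vclass = "DEL"
                depth = alt_count = 0
                if sample_names:
                    sample = rec.samples[sample_names[0]]
                    ad = sample.get("AD")
                    if ad is not None and ad[0] is not None:
                        depth = int(sum(x for x in ad if x is not None))
                        alt_count = int(ad[alt_i + 1] or 0)
                records.append(
                    VariantRecord(
                        chrom=str(rec.chrom),
                        pos=pos,
                        ref=ref,
                        alt=alt_t,
                        variant_class=vclass,
                        coding_effect="other",
                        tumor_depth=depth,
                        tumor_alt=alt_count,
                    )
                )
    return records


def write_variants_maf(records: list[VariantRecord], path: str | Path,
                       extra: pd.DataFrame | None = None) -> None:
    """Write variants as a MAF-style TSV (lossless for all typed fields).

    ``extra`` may carry additional aligned columns (e.g. filter verdicts).
    """
    rows = []
    for v in records:
        rows.append(
            {
                "Hugo_Symbol": v.gene or "",
                "Chromosome": v.chrom,
                "Start_Position": v.pos,
                "Reference_Allele": v.ref,
                "Tumor_Seq_Allele2": v.alt,
                "Variant_Type": _MAF_TYPE[v.variant_class],
                "Variant_Classification": _EFFECT_TO_CLASSIFICATION[v.coding_effect],
                "t_depth": v.tumor_depth,
                "t_alt_count": v.tumor_alt,
                "Hotspot": v.hotspot,
                "Population_AF": "" if v.population_af is None else v.population_af,
                "PoN_Fraction": v.pon_fraction,
                "Trinucleotide_Context": v.trinucleotide_context or "",
                "Normal_Genotypes": _encode_normals(v.normal_evidence),
            }
        )
    df = pd.DataFrame(rows, columns=_MAF_COLUMNS)
    if extra is not None:
        df = pd.concat([df, extra.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------


@dataclass
class IntervalSet:
    """Named genomic intervals, internally 1-based inclusive."""

    records: pd.DataFrame  # columns chrom, start, end, name

    def __post_init__(self) -> None:
        needed = {"chrom", "start", "end", "name"}
        if not needed <= set(self.records.columns):
            raise FormatError(f"interval table needs columns {sorted(needed)}")
        self.records = self.records.copy()
        self.records["chrom"] = [normalize_chrom(c) for c in self.records["chrom"]]
        if not (self.records["end"] >= self.records["start"]).all():
            raise FormatError("interval end < start")

    def __len__(self) -> int:
        return len(self.records)

    def by_chrom(self, chrom: str) -> pd.DataFrame:
        return self.records[self.records["chrom"] == normalize_chrom(chrom)]


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED gene panel (0-based half-open) into 1-based intervals."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
        dtype={0: str},
    )
    if len(df) == 0:
        raise EmptyInputError(f"{path}: empty BED")
    df["start"] = df["start"].astype(int) + 1  # BED -> 1-based inclusive
    df["end"] = df["end"].astype(int)
    return IntervalSet(df)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    df = intervals.records.copy()
    df["start"] = df["start"] - 1
    df[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", header=False, index=False)


def read_arm_table(path: str | Path) -> pd.DataFrame:
    """Read chromosome-arm definitions (TSV, 1-based inclusive).

    Columns chrom, arm, start, end; arm_length recomputed.  Arms must
    partition each chromosome into at most two disjoint intervals.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = {"chrom", "arm", "start", "end"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: arm table needs columns {sorted(needed)}")
    df["chrom"] = [normalize_chrom(c) for c in df["chrom"]]
    if not df["arm"].isin(["p", "q"]).all():
        raise FormatError(f"{path}: arm must be 'p' or 'q'")
    df["arm_length"] = df["end"] - df["start"] + 1
    for chrom, grp in df.groupby("chrom"):
        if len(grp) > 2:
            raise FormatError(f"{path}: chromosome {chrom} has more than two arms")
        if len(grp) == 2:
            g = grp.sort_values("start")
            if g.iloc[0]["end"] >= g.iloc[1]["start"]:
                raise FormatError(f"{path}: overlapping arms on chromosome {chrom}")
    return df


def write_arm_table(arms: pd.DataFrame, path: str | Path) -> None:
    arms[["chrom", "arm", "start", "end"]].to_csv(path, sep="\t", index=False)


def read_hotspots(path: str | Path) -> set[tuple[str, int]]:
    """Read a hotspot site list (TSV with columns chrom, pos[, gene])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos"} <= set(df.columns):
        raise FormatError(f"{path}: hotspot table needs columns chrom, pos")
    return {(normalize_chrom(c), int(p)) for c, p in zip(df["chrom"], df["pos"])}


# ---------------------------------------------------------------------------
# Segments (SEG format)
# ---------------------------------------------------------------------------

_SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean",
                "tcn", "lcn", "cnloh"]


def write_seg(segments: list[Segment], path: str | Path, sample_id: str = "TUMOR") -> None:
    """Write segments as SEG-format TSV with extended tcn/lcn/cnloh columns."""
    rows = []
    for s in segments:
        rows.append(
            {
                "ID": sample_id,
                "chrom": s.chrom,
                "loc.start": s.start_pos,
                "loc.end": s.end_pos,
                "num.mark": s.num_mark,
                "seg.mean": repr(float(s.mean_logr)),
                "tcn": "" if s.tcn is None else s.tcn,
                "lcn": "" if s.lcn is None else s.lcn,
                "cnloh": "" if s.cnloh is None else s.cnloh,
            }
        )
    pd.DataFrame(rows, columns=_SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_SEG_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: SEG missing columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        seg = Segment(
            chrom=normalize_chrom(r["chrom"]),
            start_pos=int(r["loc.start"]),
            end_pos=int(r["loc.end"]),
            num_mark=int(r["num.mark"]),
            mean_logr=float(r["seg.mean"]),
        )
        if "tcn" in df.columns and not pd.isna(r.get("tcn")) and r.get("tcn") != "":
            seg.tcn = int(r["tcn"])
        if "lcn" in df.columns and not pd.isna(r.get("lcn")) and r.get("lcn") != "":
            seg.lcn = int(r["lcn"])
        if "cnloh" in df.columns and not pd.isna(r.get("cnloh")) and r.get("cnloh") != "":
            seg.cnloh = bool(r["cnloh"])
        out.append(seg)
    return out


# ---------------------------------------------------------------------------
# Signature catalogs
# ---------------------------------------------------------------------------


def read_signature_catalog(path: str | Path) -> pd.DataFrame:
    """Read a 96-channel signature catalog (channels x signatures TSV).

    Rows are reordered to canonical COSMIC channel order and columns are
    renormalized to sum to one.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if set(df.index) != set(SBS96_CHANNELS):
        raise FormatError(f"{path}: catalog channels do not match the 96 canonical channels")
    df = df.loc[SBS96_CHANNELS]
    sums = df.sum(axis=0)
    if (sums <= 0).any():
        raise FormatError(f"{path}: catalog contains an all-zero signature column")
    return df / sums


def write_signature_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index_label="Type")


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))
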