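import warnings

import numpy as np
import pandas as pd
import pytest

import hemeascn as h
from hemeascn.io import SBS96_CHANNELS
from hemeascn.resources import GENOME_GRCH37

warnings.filterwarnings("ignore", message="fit below the tumor-fraction")
warnings.filterwarnings("ignore", message="no allelically balanced")

ABERRANT_STATES = [(1, 0), (2, 0), (3, 1), (4, 2), (3, 0), (4, 1)]


def random_profile(rng: np.random.Generator, n_segments: int) -> list[h.SegmentSpec]:
    """Random aberrant segments on distinct chromosomes, diploid elsewhere."""
    chroms = rng.choice([str(i) for i in range(1, 23)], size=n_segments, replace=False)
    segs = []
    for c in chroms:
        length = GENOME_GRCH37[c][0]
        frac = rng.uniform(0.4, 0.9)
        start = int(rng.uniform(0, 1 - frac) * length) + 1
        tcn, lcn = ABERRANT_STATES[rng.integers(len(ABERRANT_STATES))]
        segs.append(h.SegmentSpec(c, start, start + int(frac * length), tcn, lcn))
    return segs


def fitted_state_per_locus(case: h.SimCase, fit: h.PurityPloidyFit):
    """Map fitted segment states back onto the simulated loci."""
    loci = case.snp_matrix.loci
    chrom = loci["chrom"].to_numpy()
    pos = loci["pos"].to_numpy()
    fit_t = np.full(len(loci), -1)
    fit_l = np.full(len(loci), -2)
    for s in fit.segments:
        m = (chrom == s.chrom) & (pos >= s.start_pos) & (pos <= s.end_pos)
        fit_t[m] = s.tcn if s.tcn is not None else -1
        fit_l[m] = s.lcn if s.lcn is not None else -2
    return fit_t, fit_l


def exact_state_fraction(case: h.SimCase, fit: h.PurityPloidyFit) -> float:
    """Fraction of true segments (aberrant + the diploid bulk) whose
    majority fitted (tcn, lcn) equals the truth."""
    fit_t, fit_l = fitted_state_per_locus(case, fit)
    loci = case.snp_matrix.loci
    chrom = loci["chrom"].to_numpy()
    pos = loci["pos"].to_numpy()

    def mode_state(mask):
        vals, counts = np.unique(np.stack([fit_t[mask], fit_l[mask]]), axis=1,
                                 return_counts=True)
        return tuple(vals[:, counts.argmax()])

    total = correct = 0
    for ts in case.truth.segments:
        m = (chrom == ts.chrom) & (pos >= ts.start) & (pos <= ts.end)
        if m.sum() == 0:
            continue
        total += 1
        correct += mode_state(m) == (ts.tcn, ts.lcn)
    bulk = (case.truth.locus_tcn == 2) & (case.truth.locus_lcn == 1)
    if bulk.any():
        total += 1
        correct += mode_state(bulk) == (2, 1)
    return correct / total


def make_catalog(rng: np.random.Generator, k: int = 6) -> pd.DataFrame:
    """Synthetic peaked signature catalog (96 channels x k signatures)."""
    cols = {}
    for j in range(k):
        alpha = np.full(96, 0.08)
        alpha[rng.choice(96, 8, replace=False)] = 4.0
        cols[f"SBS_sim{j + 1}"] = rng.dirichlet(alpha)
    return pd.DataFrame(cols, index=SBS96_CHANNELS)


@pytest.fixture(scope="session")
def catalog() -> pd.DataFrame:
    return make_catalog(np.random.default_rng(123))


@pytest.fixture(scope="session")
def standard_case() -> h.SimCase:
    """A mid-purity tumor with an arm deletion and a CN-LOH segment."""
    cfg = h.SimConfig(
        seed=42, purity=0.6, n_snps=6000,
        segments=[h.SegmentSpec("13", 17_900_001, 115_169_878, 1, 0),
                  h.SegmentSpec("9", 1, 40_000_000, 2, 0)],
        somatic=[h.SomaticSpec("13", 28_600_000, 0.4, gene="FLT3"),
                 h.SomaticSpec("17", 7_570_000, 0.3, gene="TP53")],
    )
    return h.simulate_case(cfg)


@pytest.fixture(scope="session")
def standard_result(standard_case) -> h.CaseResult:
    from hemeascn.resources import default_arm_table
    return h.analyze_case(standard_case.snp_matrix, standard_case.variants,
                          arms=default_arm_table(standard_case.config.chroms))


def make_variant(depth=100, alt=10, hotspot=False, pon=0.0, chrom="1", pos=1000,
                 ref="C", alt_allele="T", normal_evidence=None, **kw) -> h.VariantRecord:
    return h.VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=kw.pop("alt2", alt_allele),
                           tumor_depth=depth, tumor_alt=alt, hotspot=hotspot,
                           pon_fraction=pon,
                           normal_evidence=normal_evidence or {}, **kw)
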