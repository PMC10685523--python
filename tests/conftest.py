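"""Shared builders for summary statistics, harmonized pairs and LD fixtures."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mr2s.harmonize import HarmonizedPair
from mr2s.instrument_selection import LDTable
from mr2s.sumstats_io import SummaryTable, VariantAssociation
from mr2s.synthetic_gwas import SyntheticStudy


def make_assoc(variant_id="rs1", effect_allele="A", other_allele="G",
               beta=0.1, se=0.01, **kw) -> VariantAssociation:
    return VariantAssociation(variant_id=variant_id,
                              effect_allele=effect_allele,
                              other_allele=other_allele,
                              beta=beta, se=se, **kw)


def make_pairs(bx, by, sy, sx=None) -> list[HarmonizedPair]:
    sx = sx if sx is not None else [1e-4] * len(bx)
    return [HarmonizedPair(f"rs{i + 1}", float(b), float(s_x), float(b_y),
                           float(s_y))
            for i, (b, b_y, s_x, s_y) in enumerate(zip(bx, by, sx, sy))]


def pairs_from_study(study: SyntheticStudy) -> list[HarmonizedPair]:
    """Zip a synthetic study's tables into harmonized pairs directly
    (generated tables share alleles, so no flipping is needed)."""
    out = []
    for e in study.exposure_table.rows:
        o = study.outcome_table.get(e.variant_id)
        out.append(HarmonizedPair(e.variant_id, e.beta, e.se, o.beta, o.se,
                                  e.eaf))
    return out


def clump_oracle(rows, ld: LDTable, r2_max: float, window_bp: int) -> list[str]:
    """Brute-force reference for greedy p-ordered clumping.

    Enumerates every pairwise-compatible subset and returns the one whose
    inclusion vector over the p-sorted candidate order is lexicographically
    greatest (include-first beats exclude), which is the defining property
    of the greedy acceptance rule. Independent of the production code path.
    """
    import math

    def key(v):
        pv = v.pval if math.isfinite(v.pval) else math.inf
        return (pv, v.chrom, v.pos, v.variant_id)

    cand = sorted(rows, key=key)
    n = len(cand)

    def compatible(a, b):
        pa, pb = ld.positions.get(a.variant_id), ld.positions.get(b.variant_id)
        if pa is not None and pb is not None:
            if pa[0] != pb[0] or abs(pa[1] - pb[1]) > window_bp:
                return True
        return ld.r2(a.variant_id, b.variant_id) < r2_max

    best_vec, best_ids = None, []
    for mask in itertools.product([1, 0], repeat=n):
        chosen = [cand[i] for i in range(n) if mask[i]]
        if all(compatible(a, b) for a, b in itertools.combinations(chosen, 2)):
            if best_vec is None or mask > best_vec:
                best_vec, best_ids = mask, [v.variant_id for v in chosen]
    return best_ids


@pytest.fixture
def two_pair_dataset() -> list[HarmonizedPair]:
    """The worked IVW example: w = (bx/sy)^2 gives beta 0.34, se 1/sqrt(500)."""
    return make_pairs(bx=[1.0, 2.0], by=[0.5, 0.6], sy=[0.1, 0.1])


def random_summary_table(rng: np.random.Generator, n: int = 6,
                         trait_name: str = "trait") -> SummaryTable:
    rows = []
    for j in range(n):
        rows.append(make_assoc(
            variant_id=f"rs{j + 1}", chrom=str(1 + j % 2),
            pos=int(rng.integers(1, 5_000_000)),
            beta=float(rng.normal(0.1, 0.02)),
            se=float(rng.uniform(0.005, 0.02)),
            eaf=float(rng.uniform(0.1, 0.9)),
            pval=float(rng.uniform(1e-15, 1e-9))))
    return SummaryTable(trait_name, "continuous", rows)
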