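"""Genetic instrument selection: significance filtering, LD clumping, proxies.

Candidate instruments pass a multiplicity-corrected genome-wide threshold
(e.g. 5e-8 / 102 traits for a metabolome-wide scan). Correlated candidates
are pruned by greedy p-value-ordered clumping (the PLINK convention): sort
by ascending p-value and accept a variant only if its r-squared with every
already-accepted variant on the same chromosome within the window is below
the cutoff. Instruments absent from an outcome GWAS may be replaced by the
best high-LD proxy within a positional window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateVariantError, DomainError, VariantLookupError
from .sumstats_io import SummaryTable, VariantAssociation

logger = logging.getLogger("mr2s")


def significance_threshold(alpha_gw: float, n_tests: int) -> float:
    """Bonferroni-corrected significance threshold alpha_gw / n_tests."""
    if not 0.0 < alpha_gw < 1.0:
        raise DomainError(f"alpha_gw must lie in (0,1), got {alpha_gw!r}")
    if n_tests < 1:
        raise DomainError(f"n_tests must be >= 1, got {n_tests!r}")
    return alpha_gw / n_tests


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class LDTable:
    """Pairwise r-squared between variants, with positional window semantics.

    ``entries`` maps an unordered id pair to r-squared in [0, 1];
    ``positions`` maps a variant id to its (chrom, pos). r-squared of a
    variant with itself is 1; pairs on different chromosomes are 0; pairs
    absent from the table are treated as 0 (real LD tables are sparse) and
    the miss is logged by callers that required coverage. ``signs`` may
    carry the sign of the underlying dosage correlation, used to orient
    proxy alleles.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)
    signs: dict[tuple[str, str], int] = field(default_factory=dict)

    def set_r2(self, a: str, b: str, r2: float, sign: int = 0) -> None:
        if not 0.0 <= r2 <= 1.0 + 1e-12:
            raise DomainError(f"r2 must lie in [0,1], got {r2!r} for ({a},{b})")
        key = _pair_key(a, b)
        self.entries[key] = min(float(r2), 1.0)
        if sign:
            self.signs[key] = 1 if sign > 0 else -1

    def r2(self, a: str, b: str, log_missing: bool = False) -> float:
        if a == b:
            return 1.0
        pa, pb = self.positions.get(a), self.positions.get(b)
        if pa is not None and pb is not None and pa[0] != pb[0]:
            return 0.0
        val = self.entries.get(_pair_key(a, b))
        if val is None:
            if log_missing:
                logger.warning("LD pair (%s, %s) missing; treating r2 as 0", a, b)
            return 0.0
        return val

    def sign(self, a: str, b: str) -> int:
        """Sign of the dosage correlation (+1/-1), or 0 if unknown."""
        if a == b:
            return 1
        return self.signs.get(_pair_key(a, b), 0)

    def within_window(self, a: str, b: str, window_bp: int) -> bool:
        pa, pb = self.positions.get(a), self.positions.get(b)
        if pa is None or pb is None:
            return True  # unknown positions: assume in-window (conservative)
        return pa[0] == pb[0] and abs(pa[1] - pb[1]) <= window_bp

    @classmethod
    def from_file(cls, path) -> "LDTable":
        """Read a delimited LD table with columns id_a, id_b, r2 and optional
        chrom_a/pos_a/chrom_b/pos_b (or a separate positions file merged in)."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        need = {"id_a", "id_b", "r2"}
        if not need.issubset(df.columns):
            raise DomainError(f"{path}: LD table needs columns {sorted(need)}")
        tab = cls()
        for rec in df.to_dict("records"):
            tab.set_r2(str(rec["id_a"]), str(rec["id_b"]), float(rec["r2"]),
                       int(rec.get("sign", 0) or 0))
            for suffix in ("a", "b"):
                cid = str(rec[f"id_{suffix}"])
                if f"chrom_{suffix}" in rec and pd.notna(rec.get(f"pos_{suffix}")):
                    tab.positions[cid] = (str(rec[f"chrom_{suffix}"]),
                                          int(rec[f"pos_{suffix}"]))
        return tab

    def add_positions(self, table: SummaryTable) -> None:
        for r in table.rows:
            if r.chrom:
                self.positions[r.variant_id] = (r.chrom, r.pos)


@dataclass
class InstrumentSet:
    """Clumped instruments for one exposure with per-variant provenance.

    ``provenance[variant_id]`` is "direct" or "proxy(<original_id>)".
    """

    exposure_name: str
    variants: list[VariantAssociation]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.variants:
            self.provenance.setdefault(v.variant_id, "direct")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def without(self, excluded_ids: Iterable[str]) -> "InstrumentSet":
        drop = set(excluded_ids)
        keep = [v for v in self.variants if v.variant_id not in drop]
        return InstrumentSet(self.exposure_name, keep,
                             {v.variant_id: self.provenance[v.variant_id]
                              for v in keep})


def _p_order_key(v: VariantAssociation) -> tuple[float, str, int, str]:
    pv = v.pval if math.isfinite(v.pval) else math.inf
    return (pv, v.chrom, v.pos, v.variant_id)


def ld_clump(candidates: SummaryTable | Sequence[VariantAssociation],
             ld: LDTable, r2_max: float, window_bp: int) -> list[str]:
    """Greedy p-value-ordered LD clumping; returns retained ids in
    acceptance order.

    Ties in p-value break by (chrom, pos, id) so the output is independent
    of input row order. A variant is accepted iff r2 with every previously
    accepted same-chromosome variant within ``window_bp`` is < ``r2_max``.
    Missing LD pairs count as r2 = 0 (logged).
    """
    rows = candidates.rows if isinstance(candidates, SummaryTable) else list(candidates)
    accepted: list[VariantAssociation] = []
    for cand in sorted(rows, key=_p_order_key):
        ok = True
        for kept in accepted:
            if not ld.within_window(cand.variant_id, kept.variant_id, window_bp):
                continue
            if ld.r2(cand.variant_id, kept.variant_id, log_missing=True) >= r2_max:
                ok = False
                break
        if ok:
            accepted.append(cand)
    return [v.variant_id for v in accepted]


def find_proxy(missing_id: str, outcome: SummaryTable, ld: LDTable,
               r2_min: float, window_bp: int) -> str | None:
    """Best high-LD proxy for an instrument absent from the outcome table.

    Among outcome variants within ``window_bp`` of ``missing_id`` with
    r2 > ``r2_min``, returns the one with highest r2; ties break by smaller
    positional distance, then lexicographic id. Returns ``None`` when no
    candidate qualifies — the instrument is then dropped for that outcome.
    """
    if missing_id not in ld.positions:
        raise VariantLookupError(f"variant {missing_id} has no known position "
                                 "in the LD table")
    chrom, pos = ld.positions[missing_id]
    best: tuple[float, int, str] | None = None  # (-r2, |dist|, id)
    for cand in outcome.rows:
        cid = cand.variant_id
        if cid == missing_id:
            continue
        cpos = ld.positions.get(cid)
        if cpos is None or cpos[0] != chrom or abs(cpos[1] - pos) > window_bp:
            continue
        r2 = ld.r2(missing_id, cid)
        if r2 <= r2_min:
            continue
        key = (-r2, abs(cpos[1] - pos), cid)
        if best is None or key < best:
            best = key
    if best is None:
        logger.warning("no proxy with r2 > %.2f within %d bp for %s; "
                       "instrument dropped", r2_min, window_bp, missing_id)
        return None
    return best[2]


def r2_from_dosages(dosage_matrix: np.ndarray,
                    variant_ids: Sequence[str] | None = None,
                    positions: dict[str, tuple[str, int]] | None = None,
                    ) -> LDTable:
    """Build an :class:`LDTable` from an individuals x variants dosage matrix.

    r2(i, j) is the squared Pearson correlation of dosage columns; the
    correlation sign is stored for proxy-allele orientation.
    """
    X = np.asarray(dosage_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DomainError("dosage matrix must be 2-D with >= 2 individuals")
    n_ind, n_var = X.shape
    ids = list(variant_ids) if variant_ids is not None else [
        f"snp{i}" for i in range(n_var)]
    if len(ids) != n_var:
        raise DomainError(f"{len(ids)} ids for {n_var} dosage columns")
    sd = X.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise DegenerateVariantError(
                f"dosage column {ids[j]} is constant; correlation undefined")
    corr = np.corrcoef(X, rowvar=False)
    tab = LDTable(positions=dict(positions or {}))
    for i in range(n_var):
        for j in range(i + 1, n_var):
            c = float(corr[i, j])
            tab.set_r2(ids[i], ids[j], min(c * c, 1.0),
                       sign=1 if c >= 0 else -1)
    return tab


def select_candidates(exposure: SummaryTable, p_threshold: float) -> SummaryTable:
    """Variants passing the significance threshold, as a new table."""
    keep = [r for r in exposure.rows
            if math.isfinite(r.pval) and r.pval < p_threshold]
    return SummaryTable(exposure.trait_name, exposure.trait_type, keep)


def select_instruments(exposure: SummaryTable, ld: LDTable,
                       alpha_gw: float = 5e-8, n_tests: int = 1,
                       clump_r2: float = 0.01,
                       clump_window_bp: int = 10_000_000) -> InstrumentSet:
    """Significance filter followed by LD clumping, yielding an InstrumentSet."""
    thr = significance_threshold(alpha_gw, n_tests)
    cands = select_candidates(exposure, thr)
    kept = ld_clump(cands, ld, clump_r2, clump_window_bp)
    return InstrumentSet(exposure.trait_name,
                         [cands.get(v) for v in kept])
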