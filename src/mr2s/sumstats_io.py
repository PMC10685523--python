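"""GWAS summary-statistics data model, file I/O and per-variant derived quantities.

A summary-statistics table carries one row per variant: identifier,
coordinates, effect/other allele, effect-allele frequency, the per-allele
association ``beta`` with its standard error and p-value, and the sample
size. For standardized continuous traits whose source GWAS reports only a
z-score, the association and its standard error are recovered from the
z-score, allele frequency and sample size via

    beta = z / sqrt(2 p (1 - p) (n + z^2))
    se   = 1 / sqrt(2 p (1 - p) (n + z^2))

so that beta / se reproduces z exactly. Binary-trait effects are carried
internally on the log odds-ratio scale; odds ratios appear only at
reporting boundaries.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

logger = logging.getLogger("mr2s")

VALID_ALLELES = frozenset("ACGT")

#: canonical column order for summary-statistics files
CANONICAL_COLUMNS = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "z",
)


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` in SD units of a
    standardized trait, or a log odds ratio for a binary trait. ``eaf`` and
    ``n`` may be absent (``None``); outcome GWASs frequently omit them.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str = ""
    pos: int = 0
    eaf: float | None = None
    pval: float = float("nan")
    n: int | None = None

    def __post_init__(self) -> None:
        if self.se <= 0 or not math.isfinite(self.se):
            raise DomainError(f"se must be a positive finite real, got {self.se!r} "
                              f"for variant {self.variant_id}")
        ea, oa = self.effect_allele, self.other_allele
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            raise FormatError(f"alleles must be single uppercase A/C/G/T, got "
                              f"({ea!r}, {oa!r}) for variant {self.variant_id}")
        if ea == oa:
            raise FormatError(f"effect and other allele identical ({ea}) for "
                              f"variant {self.variant_id}")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise DomainError(f"eaf must lie in (0,1), got {self.eaf!r} for "
                              f"variant {self.variant_id}")

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    def flipped(self) -> "VariantAssociation":
        """The same association expressed per copy of the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class SummaryTable:
    """A named collection of variant associations, unique by variant id."""

    trait_name: str
    trait_type: str  # "continuous" or "binary"
    rows: list[VariantAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise DomainError(f"trait_type must be 'continuous' or 'binary', "
                              f"got {self.trait_type!r}")
        ids = [r.variant_id for r in self.rows]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate variant ids in {self.trait_name}: {dupes}")
        self._index = {r.variant_id: r for r in self.rows}

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, variant_id: str) -> VariantAssociation | None:
        return self._index.get(variant_id)

    def subset(self, variant_ids: Iterable[str]) -> "SummaryTable":
        keep = [self._index[v] for v in variant_ids if v in self._index]
        return SummaryTable(self.trait_name, self.trait_type, keep)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({
                "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta, "se": r.se, "pval": r.pval,
                "n": np.nan if r.n is None else r.n,
            })
        return pd.DataFrame.from_records(
            recs, columns=list(CANONICAL_COLUMNS[:-1]))


def zscore_to_beta(z: float, maf: float, n: int) -> tuple[float, float]:
    """Convert a z-score to (beta, se) for a standardized continuous trait.

    Uses beta = z / sqrt(2 p (1-p) (n + z^2)), se = 1 / sqrt(2 p (1-p) (n + z^2)),
    where p is the (minor or effect) allele frequency and n the sample size.
    The identity beta / se == z holds exactly.
    """
    if not 0.0 < maf < 1.0:
        raise DomainError(f"maf must lie in (0,1), got {maf!r}")
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n!r}")
    se = 1.0 / math.sqrt(2.0 * maf * (1.0 - maf) * (n + z * z))
    return z * se, se


def variance_explained(assoc: VariantAssociation) -> float:
    """Proportion of variance of a standardized trait explained by one variant.

    Returns 2 p (1-p) beta^2 clipped to [0, 1]; summing over an instrument
    set gives the set-level proportion (instruments assumed independent).
    """
    if assoc.eaf is None:
        raise DomainError(f"eaf unavailable for variant {assoc.variant_id}; "
                          "variance explained requires an allele frequency")
    r2 = 2.0 * assoc.eaf * (1.0 - assoc.eaf) * assoc.beta ** 2
    return min(max(r2, 0.0), 1.0)


def f_statistic(assoc: VariantAssociation) -> float:
    """Single-instrument strength F ~ (beta/se)^2; >10 is conventionally strong."""
    return (assoc.beta / assoc.se) ** 2


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_MANDATORY = ("variant_id", "effect_allele", "other_allele")


def _sniff_table(path) -> pd.DataFrame:
    """Read a delimited text file with '#' metadata lines; auto-detect the
    delimiter among tab / comma / whitespace. A header row is mandatory."""
    with open(path, "rt") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: no content lines")
    header = lines[0]
    if "\t" in header:
        sep: str = "\t"
    elif "," in header:
        sep = ","
    else:
        # whitespace-delimited: normalize runs of blanks to tabs
        sep = "\t"
        lines = ["\t".join(ln.split()) + "\n" for ln in lines]
    text = "".join(lines)
    # round_trip parsing keeps finite decimals bit-exact across write/read
    return pd.read_csv(io.StringIO(text), sep=sep,
                       float_precision="round_trip")


def read_summary_table(
    path,
    column_mapping: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str | None = None,
) -> SummaryTable:
    """Read a delimited summary-statistics file into a :class:`SummaryTable`.

    ``column_mapping`` maps canonical field names to file column names
    (identity for canonical columns already present). Rows carrying ``z``
    but no ``beta``/``se`` are converted through :func:`zscore_to_beta`
    (this requires ``eaf`` and ``n``). Duplicate variant ids keep the row
    with the smallest p-value; the drop is logged. Alleles are uppercased.
    """
    df = _sniff_table(path)
    meta = read_table_metadata(path)
    if trait_name is None:
        trait_name = meta.get("trait_name")
    if trait_type is None:
        trait_type = meta.get("trait_type", "continuous")
    if column_mapping:
        rename = {src: dst for dst, src in column_mapping.items() if src in df.columns}
        df = df.rename(columns=rename)

    missing = [c for c in _MANDATORY if c not in df.columns]
    has_beta = "beta" in df.columns and "se" in df.columns
    has_z = all(c in df.columns for c in ("z", "eaf", "n"))
    if not (has_beta or has_z):
        missing.append("beta+se or z+eaf+n")
    if missing:
        raise FormatError(f"{path}: missing mandatory columns: {missing}")

    rows: list[VariantAssociation] = []
    for rec in df.to_dict("records"):
        if has_beta and pd.notna(rec.get("beta")) and pd.notna(rec.get("se")):
            beta, se = float(rec["beta"]), float(rec["se"])
        else:
            beta, se = zscore_to_beta(
                float(rec["z"]), float(rec["eaf"]), int(rec["n"]))
        eaf = rec.get("eaf")
        n = rec.get("n")
        pval = rec.get("pval", np.nan)
        rows.append(VariantAssociation(
            variant_id=str(rec["variant_id"]),
            chrom=str(rec.get("chrom", "")),
            pos=int(rec.get("pos", 0) or 0),
            effect_allele=str(rec["effect_allele"]).upper(),
            other_allele=str(rec["other_allele"]).upper(),
            eaf=None if pd.isna(eaf) else float(eaf),
            beta=beta, se=se,
            pval=float(pval) if pd.notna(pval) else float("nan"),
            n=None if pd.isna(n) else int(n),
        ))

    # duplicate policy: keep smallest p-value, log the drop
    best: dict[str, VariantAssociation] = {}
    order: list[str] = []
    for r in rows:
        prev = best.get(r.variant_id)
        if prev is None:
            best[r.variant_id] = r
            order.append(r.variant_id)
        else:
            pv_new = r.pval if math.isfinite(r.pval) else math.inf
            pv_old = prev.pval if math.isfinite(prev.pval) else math.inf
            keep = r if pv_new < pv_old else prev
            best[r.variant_id] = keep
            logger.warning("duplicate variant %s in %s: kept row with p=%.3g",
                           r.variant_id, path, keep.pval)

    return SummaryTable(
        trait_name=trait_name or str(path),
        trait_type=trait_type,
        rows=[best[v] for v in order],
    )


def write_summary_table(table: SummaryTable, path,
                        metadata: Mapping[str, object] | None = None,
                        sep: str = "\t") -> None:
    """Write a summary table as delimited text with a '#' metadata header.

    Floats are written with ``repr`` precision so a read-back round trip
    reproduces finite decimal inputs bit-for-bit.
    """
    with open(path, "wt") as fh:
        fh.write(f"# trait_name={table.trait_name}\n")
        fh.write(f"# trait_type={table.trait_type}\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        table.to_frame().to_csv(fh, sep=sep, index=False)


def read_table_metadata(path) -> dict[str, str]:
    """Parse the '#' key=value header block of a written table."""
    meta: dict[str, str] = {}
    with open(path, "rt") as fh:
        for ln in fh:
            if not ln.startswith("#"):
                break
            body = ln.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta
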