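"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the standardized-trait summary-statistics model:
per variant j with allele frequency p_j, a true per-allele exposure effect
b_j, an optional direct (pleiotropic) outcome effect alpha_j, and a causal
effect theta, the true outcome effect is theta * b_j + alpha_j. Observed
effects add independent Gaussian noise with

    se = 1 / sqrt(2 p_j (1 - p_j) n)

for the respective sample size (exposure and outcome samples do not
overlap, so the two noise draws are independent). z-scores and p-values
are emitted so the instrument-selection stage is exercised end to end.
Binary outcomes are simulated directly on the log odds-ratio scale with
the same noise model.

Pleiotropy configurations: ``none``; ``balanced(sd)`` (alpha ~ N(0, sd),
mean zero, InSIDE holds); ``directional(mean, sd, fraction)`` (a random
fraction of variants receives alpha ~ N(mean, sd)). Setting
``inside_violation`` scales each alpha by the variant's relative
instrument strength, correlating pleiotropy with |b_j|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DomainError
from .instrument_selection import LDTable, r2_from_dosages
from .sumstats_io import SummaryTable, VariantAssociation

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class PleiotropyConfig:
    """Per-variant direct-effect distribution.

    ``kind``: "none" | "balanced" | "directional". ``fraction`` is the
    proportion of variants that receive a direct effect (1.0 = all).
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional"):
            raise DomainError(f"unknown pleiotropy kind {self.kind!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise DomainError(f"fraction must lie in [0,1], got {self.fraction!r}")
        if self.kind == "balanced" and self.mean != 0.0:
            raise DomainError("balanced pleiotropy has mean 0 by definition")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic exposure/outcome pair.

    Defaults echo a metabolite-GWAS-scale exposure sample (n ~ 8.5e4) with
    an outcome sample small enough that causal-effect uncertainty is
    visible at desk scale; instrument effect magnitudes give per-variant
    variance explained of roughly 0.1-1%, matching the span seen for
    amino-acid instruments. The default causal effect 0.35 is an
    alanine-like log-OR per SD.
    """

    n_snps: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_range: tuple[float, float] = (0.05, 0.15)  # |b_j| magnitude bounds
    causal_theta: float = 0.35
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    inside_violation: bool = False
    n_exposure: int = 85_000
    n_outcome: int = 20_000
    outcome_type: str = "binary"  # log-OR scale; or "continuous"
    ld_blocks: tuple[int, float] | None = None  # (block_size, within-block r2)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi < 1.0:
            raise DomainError(f"maf_range must satisfy 0 < lo <= hi < 1, "
                              f"got {self.maf_range!r}")
        lo, hi = self.effect_range
        if not 0.0 < lo <= hi:
            raise DomainError(f"effect_range must satisfy 0 < lo <= hi, "
                              f"got {self.effect_range!r}")
        if self.outcome_type not in ("continuous", "binary"):
            raise DomainError(f"outcome_type must be continuous/binary, "
                              f"got {self.outcome_type!r}")
        if self.n_snps < 1 or self.n_exposure < 2 or self.n_outcome < 2:
            raise DomainError("n_snps >= 1 and sample sizes >= 2 required")


@dataclass
class SyntheticStudy:
    """Generated exposure/outcome tables plus the generating truth."""

    exposure_table: SummaryTable
    outcome_table: SummaryTable
    causal_theta: float
    true_exposure_effects: np.ndarray
    #: direct outcome effects per copy of the exposure-increasing allele
    pleiotropy_effects: np.ndarray
    valid_instrument: np.ndarray  # boolean: no direct effect on the outcome
    ld: LDTable | None = None


def _draw_pleiotropy(cfg: SimulationConfig, b: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    m = cfg.n_snps
    pl = cfg.pleiotropy
    alpha = np.zeros(m)
    if pl.kind != "none":
        affected = rng.random(m) < pl.fraction
        mean = 0.0 if pl.kind == "balanced" else pl.mean
        alpha[affected] = rng.normal(mean, pl.sd, affected.sum())
    if cfg.inside_violation and np.any(alpha != 0):
        # couple direct effects to instrument strength, breaking InSIDE
        alpha *= np.abs(b) / np.mean(np.abs(b))
    return alpha


def simulate_two_sample(config: SimulationConfig) -> SyntheticStudy:
    """Generate one exposure and one outcome summary table with known truth.

    Reproducible: the same config (including seed) yields identical tables.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    maf = rng.uniform(*config.maf_range, m)
    sign = rng.choice([-1.0, 1.0], m)
    b = sign * rng.uniform(*config.effect_range, m)
    alpha = _draw_pleiotropy(config, b, rng)
    theta = config.causal_theta
    # alpha is defined per copy of the exposure-increasing allele, so
    # "directional" keeps one sign after orienting instruments; translate it
    # to the arbitrary allele coding by the sign of the exposure effect
    gamma = theta * b + sign * alpha  # true outcome effect

    se_exp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome)
    beta_exp = b + rng.normal(0.0, se_exp)
    beta_out = gamma + rng.normal(0.0, se_out)

    alleles = [_ALLELE_PAIRS[int(i)] for i in rng.integers(0, len(_ALLELE_PAIRS), m)]

    if config.ld_blocks is not None:
        block_size = config.ld_blocks[0]
        chrom = [str(1 + (j // block_size) % 22) for j in range(m)]
        pos = [100_000 + 1_000 * j for j in range(m)]
    else:
        chrom = [str(1 + j % 22) for j in range(m)]
        pos = [1_000_000 * (1 + j // 22) for j in range(m)]

    def rows(betas, ses, n):
        out = []
        for j in range(m):
            z = betas[j] / ses[j]
            out.append(VariantAssociation(
                variant_id=f"rs{j + 1:06d}", chrom=chrom[j], pos=pos[j],
                effect_allele=alleles[j][0], other_allele=alleles[j][1],
                eaf=float(maf[j]), beta=float(betas[j]), se=float(ses[j]),
                pval=float(2.0 * stats.norm.sf(abs(z))), n=n))
        return out

    exposure = SummaryTable("synthetic_exposure", "continuous",
                            rows(beta_exp, se_exp, config.n_exposure))
    outcome = SummaryTable("synthetic_outcome", config.outcome_type,
                           rows(beta_out, se_out, config.n_outcome))

    ld = None
    if config.ld_blocks is not None:
        block_size, target_r2 = config.ld_blocks
        _, ld = simulate_ld_blocks(
            n_snps=m, block_size=block_size, within_r2=target_r2,
            n_individuals=2_000,
            rng=np.random.default_rng(rng.integers(0, 2**31 - 1)))
        for r in exposure.rows:
            ld.positions[r.variant_id] = (r.chrom, r.pos)

    return SyntheticStudy(exposure, outcome, theta, b, alpha,
                          valid_instrument=(alpha == 0.0), ld=ld)


def simulate_ld_blocks(n_snps: int, block_size: int, within_r2: float,
                       n_individuals: int = 2_000,
                       rng: np.random.Generator | int | None = None,
                       variant_ids: list[str] | None = None,
                       ) -> tuple[np.ndarray, LDTable]:
    """Block-structured dosages and the corresponding empirical LD table.

    Within a block every pair of variants has dosage correlation
    sqrt(within_r2) (so pairwise r2 ~ within_r2); blocks are independent.
    Dosages are linear rescalings of Gaussian latent scores into [0, 2],
    which preserves the correlation structure exactly.
    """
    if block_size < 1:
        raise DomainError(f"block_size must be >= 1, got {block_size}")
    if not 0.0 <= within_r2 <= 1.0:
        raise DomainError(f"within_r2 must lie in [0,1], got {within_r2}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # each column loads rho on the block factor, so pairwise correlation is
    # rho^2 and pairwise r2 is rho^4
    rho = within_r2 ** 0.25
    X = np.empty((n_individuals, n_snps))
    for j in range(n_snps):
        if j % block_size == 0:
            shared = rng.normal(size=n_individuals)
        noise = rng.normal(size=n_individuals)
        X[:, j] = rho * shared + np.sqrt(1.0 - rho**2) * noise
    # rescale each column into the dosage range [0, 2]
    mn, mx = X.min(axis=0), X.max(axis=0)
    X = 2.0 * (X - mn) / (mx - mn)
    ids = variant_ids or [f"rs{j + 1:06d}" for j in range(n_snps)]
    return X, r2_from_dosages(X, ids)
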