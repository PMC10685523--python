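"""Fixed-effect inverse-variance meta-analysis on the log odds-ratio scale.

Discovery and replication causal estimates are combined with weights
1/se^2. Printed odds ratios with 95% confidence intervals are converted
back to (log-OR, se) using the reporting convention that the interval is
beta +/- 1.96 se, so se = (ln CI_high - ln CI_low) / (2 * 1.96).
Between-group heterogeneity uses Cochran's Q against the pooled estimate.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError
from .mr_core import MREstimate, Z_CI


def se_from_ci(or_point: float, ci_low: float, ci_high: float,
               ) -> tuple[float, float]:
    """Recover (log-OR, se) from a printed odds ratio and 95% CI."""
    if not 0 < ci_low <= or_point <= ci_high:
        raise DomainError(
            f"CI ordering violated: need 0 < {ci_low} <= {or_point} <= {ci_high}")
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_CI)
    if se <= 0:
        raise DomainError("degenerate CI: se must be > 0")
    return math.log(or_point), se


def fixed_effect_meta(estimates: Sequence[tuple[float, float]],
                      method_label: str = "ivw_fe") -> MREstimate:
    """Fixed-effect meta-analysis of (beta, se) estimates.

    beta_meta = sum(w b) / sum(w) with w = 1/se^2; se_meta = 1/sqrt(sum w);
    two-sided normal p. A single estimate is returned unchanged.
    """
    if len(estimates) == 0:
        raise InsufficientDataError("meta-analysis needs >= 1 estimate")
    b = np.array([e[0] for e in estimates], dtype=float)
    s = np.array([e[1] for e in estimates], dtype=float)
    if np.any(s <= 0):
        raise DomainError("all standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    p = 2.0 * float(stats.norm.sf(abs(beta / se)))
    return MREstimate(method_label, beta, se, p, len(estimates))


def between_group_q(estimates: Sequence[tuple[float, float]],
                    ) -> tuple[float, int, float]:
    """Cochran's Q for heterogeneity between cohort-level estimates.

    Q = sum w_i (b_i - b_meta)^2 with w = 1/se^2, df = k-1, chi-square
    upper-tail p.
    """
    if len(estimates) < 2:
        raise InsufficientDataError(
            f"between-group heterogeneity needs >= 2 estimates, "
            f"got {len(estimates)}")
    meta = fixed_effect_meta(estimates)
    b = np.array([e[0] for e in estimates], dtype=float)
    w = 1.0 / np.array([e[1] for e in estimates], dtype=float) ** 2
    q = float(np.sum(w * (b - meta.beta) ** 2))
    df = len(estimates) - 1
    return q, df, float(stats.chi2.sf(q, df))
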