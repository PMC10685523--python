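"""Exposure/outcome harmonization: align both associations to one effect allele.

Outcome effects are re-expressed per copy of the exposure's effect allele:
swapped alleles negate the outcome beta and complement its frequency;
strand-complemented records (A<->T, C<->G) are complemented before the
comparison. Palindromic variants (A/T or C/G), whose strand cannot be
resolved from alleles alone, are dropped by default; an alternative policy
infers orientation from allele frequency and drops only frequency-ambiguous
records (min(eaf, 1-eaf) > 0.42 on either side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

from .errors import FormatError
from .instrument_selection import InstrumentSet, LDTable, find_proxy
from .sumstats_io import SummaryTable, VariantAssociation

logger = logging.getLogger("mr2s")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: frequency band within which a palindromic variant cannot be oriented
PALINDROME_AMBIGUITY_BAND = 0.42


@dataclass(frozen=True)
class HarmonizedPair:
    """Per-variant exposure and outcome effects on a common effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    action_log: str = ""


@dataclass(frozen=True)
class Drop:
    """A variant excluded from harmonization, with the reason."""

    variant_id: str
    reason: str


@dataclass
class HarmonizedDataset:
    """Harmonized exposure/outcome pairs plus the dropped remainder."""

    exposure_name: str
    outcome_name: str
    pairs: list[HarmonizedPair] = field(default_factory=list)
    dropped: list[Drop] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


def is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize_pair(exp: VariantAssociation, out: VariantAssociation,
                   palindrome_policy: str = "drop_all",
                   ) -> Union[HarmonizedPair, Drop]:
    """Align one outcome association to the exposure's effect allele.

    ``palindrome_policy`` is ``"drop_all"`` (drop every A/T or C/G variant)
    or ``"frequency_inference"`` (orient by allele frequency; drop when
    either frequency is inside the ambiguity band or the outcome frequency
    is unavailable).
    """
    if exp.variant_id != out.variant_id:
        raise FormatError(f"variant id mismatch: {exp.variant_id} vs "
                          f"{out.variant_id}")
    if palindrome_policy not in ("drop_all", "frequency_inference"):
        raise FormatError(f"unknown palindrome policy {palindrome_policy!r}")
    vid = exp.variant_id
    actions: list[str] = []

    if is_palindromic(exp.effect_allele, exp.other_allele):
        if palindrome_policy == "drop_all":
            return Drop(vid, "palindromic")
        # frequency inference: orient by comparing minor-allele identity
        if exp.eaf is None or out.eaf is None:
            return Drop(vid, "palindromic_no_frequency")
        if (min(exp.eaf, 1 - exp.eaf) > PALINDROME_AMBIGUITY_BAND
                or min(out.eaf, 1 - out.eaf) > PALINDROME_AMBIGUITY_BAND):
            return Drop(vid, "palindromic_ambiguous_frequency")
        # same-side frequencies -> same allele; opposite -> flipped outcome
        if (exp.eaf < 0.5) == (out.eaf < 0.5):
            actions.append("palindrome_oriented_by_frequency")
            beta_out, eaf_note = out.beta, out.eaf
        else:
            actions.append("palindrome_flipped_by_frequency")
            beta_out, eaf_note = -out.beta, 1 - out.eaf
        return HarmonizedPair(vid, exp.beta, exp.se, beta_out, out.se,
                              exp.eaf, ";".join(actions))

    out_aligned = out
    ea, oa = out.effect_allele, out.other_allele
    if (ea, oa) == (exp.effect_allele, exp.other_allele):
        actions.append("aligned")
    elif (oa, ea) == (exp.effect_allele, exp.other_allele):
        out_aligned = out.flipped()
        actions.append("flipped_alleles")
    else:
        cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        if (cea, coa) == (exp.effect_allele, exp.other_allele):
            actions.append("strand_complemented")
        elif (coa, cea) == (exp.effect_allele, exp.other_allele):
            out_aligned = out.flipped()
            actions.append("strand_complemented;flipped_alleles")
        else:
            return Drop(vid, "allele_mismatch")

    return HarmonizedPair(vid, exp.beta, exp.se,
                          out_aligned.beta, out_aligned.se,
                          exp.eaf, ";".join(actions))


def harmonize_dataset(instrs: InstrumentSet, outcome: SummaryTable,
                      ld: LDTable | None = None,
                      palindrome_policy: str = "drop_all",
                      proxy_r2: float = 0.8,
                      proxy_window_bp: int = 500_000,
                      ) -> HarmonizedDataset:
    """Harmonize every instrument against the outcome, with proxy fallback.

    Instruments absent from the outcome table are replaced by the best
    high-LD proxy when an LD table is supplied (outcome beta re-oriented by
    the dosage correlation sign when known, else flagged in the action log);
    otherwise they are dropped with reason ``no_proxy``. ``pairs`` and
    ``dropped`` partition the instrument set.
    """
    ds = HarmonizedDataset(instrs.exposure_name, outcome.trait_name)
    for instr in instrs.variants:
        vid = instr.variant_id
        out = outcome.get(vid)
        if out is not None:
            res = harmonize_pair(instr, out, palindrome_policy)
            if isinstance(res, Drop):
                ds.dropped.append(res)
            else:
                ds.pairs.append(res)
            continue
        # proxy substitution
        proxy_id = None
        if ld is not None and vid in ld.positions:
            proxy_id = find_proxy(vid, outcome, ld, proxy_r2, proxy_window_bp)
        if proxy_id is None:
            ds.dropped.append(Drop(vid, "no_proxy"))
            continue
        prox = outcome.get(proxy_id)
        sign = ld.sign(vid, proxy_id)
        note = f"proxy({proxy_id})"
        beta_out = prox.beta
        if sign < 0:
            beta_out = -beta_out
            note += ";proxy_negatively_correlated_flipped"
        elif sign == 0:
            note += ";proxy_orientation_unknown_review"
            logger.warning("proxy %s for %s has unknown correlation sign; "
                           "orientation flagged for review", proxy_id, vid)
        ds.pairs.append(HarmonizedPair(vid, instr.beta, instr.se,
                                       beta_out, prox.se, instr.eaf, note))
    return ds
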