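"""End-to-end orchestration of the two-sample MR analysis stages.

For each exposure: select instruments (significance filter + LD clumping),
harmonize against each outcome (with proxy fallback), estimate the causal
effect with the instrument-count-keyed method plan, attach sensitivity
analyses where four or more instruments are available, and combine the
discovery and replication estimates by fixed-effect meta-analysis. Further
stages rerun the same machinery under restricted instrument sets
(confounder exclusion, conservative biologically/genetically prioritized
instruments), in the reverse direction (disease as exposure), and against
a continuous outcome reported on the SD scale.

Evidence labels follow a Bonferroni convention over the number of
exposures analysed: p < 0.05/n_exposures is "strong", 0.05/n_exposures <=
p < 0.05 is "suggestive", otherwise "little_evidence". Stage failures
never abort a run; they become structured records in the output.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mr_core
from .errors import InsufficientDataError
from .harmonize import HarmonizedDataset, harmonize_dataset
from .instrument_selection import (InstrumentSet, LDTable, select_instruments,
                                   significance_threshold)
from .meta_combine import between_group_q, fixed_effect_meta
from .mr_core import MREstimate, select_main_method
from .sumstats_io import (SummaryTable, f_statistic, read_summary_table,
                          variance_explained)

logger = logging.getLogger("mr2s")


@dataclass
class AnalysisConfig:
    """Everything a run needs, as in-memory objects.

    Use :func:`load_config` to build one from a YAML file referencing
    summary-statistics tables on disk.
    """

    exposures: list[SummaryTable]
    discovery: SummaryTable | None = None
    replication: SummaryTable | None = None
    continuous: SummaryTable | None = None
    ld: LDTable | None = None
    alpha_gw: float = 5e-8
    n_tests: int = 102
    clump_r2: float = 0.01
    clump_window_bp: int = 10_000_000
    proxy_r2: float = 0.8
    proxy_window_bp: int = 500_000
    palindrome_policy: str = "drop_all"
    confounder_exclusion: list[str] = field(default_factory=list)
    conservative_ids: dict[str, list[str]] = field(default_factory=dict)
    reverse_exposure: SummaryTable | None = None
    reverse_instrument_ids: list[str] = field(default_factory=list)
    reverse_outcomes: list[SummaryTable] = field(default_factory=list)
    n_exposures_tested: int | None = None  # Bonferroni denominator; None = len(exposures)
    seed: int = 0
    n_boot: int = 5000

    @property
    def bonferroni_n(self) -> int:
        return self.n_exposures_tested or max(len(self.exposures), 1)

    def stage_seed(self, *labels: str) -> int:
        """Deterministic per-stage bootstrap seed derived from the run seed."""
        tag = "|".join(labels)
        return (self.seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


def load_config(path) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML file.

    File-valued keys (exposure/outcome tables, LD table, id lists) are
    resolved relative to the config file's directory.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def _table(entry, trait_type=None):
        if entry is None:
            return None
        return read_summary_table(
            base / entry["file"], entry.get("columns"),
            trait_name=entry.get("name"), trait_type=entry.get("trait_type",
                                                               trait_type))

    def _id_list(entry):
        if entry is None:
            return []
        if isinstance(entry, list):
            return [str(x) for x in entry]
        return [ln.strip() for ln in open(base / entry)
                if ln.strip() and not ln.startswith("#")]

    thresholds = raw.get("thresholds", {})
    ld = LDTable.from_file(base / raw["ld_file"]) if raw.get("ld_file") else None
    cfg = AnalysisConfig(
        exposures=[_table(e, "continuous") for e in raw.get("exposures", [])],
        discovery=_table(raw.get("discovery"), "binary"),
        replication=_table(raw.get("replication"), "binary"),
        continuous=_table(raw.get("continuous"), "continuous"),
        ld=ld,
        confounder_exclusion=_id_list(raw.get("confounder_exclusion")),
        conservative_ids={k: _id_list(v) for k, v in
                          (raw.get("conservative") or {}).items()},
        reverse_exposure=_table(raw.get("reverse_exposure"), "binary"),
        reverse_instrument_ids=_id_list(raw.get("reverse_instruments")),
        reverse_outcomes=[_table(e, "continuous")
                          for e in raw.get("reverse_outcomes", [])],
        n_exposures_tested=raw.get("n_exposures_tested"),
        seed=int(raw.get("seed", 0)),
        n_boot=int(raw.get("n_boot", 5000)),
        palindrome_policy=raw.get("palindrome_policy", "drop_all"),
        **{k: thresholds[k] for k in
           ("alpha_gw", "n_tests", "clump_r2", "clump_window_bp",
            "proxy_r2", "proxy_window_bp") if k in thresholds},
    )
    if ld is not None:
        for t in cfg.exposures + [x for x in (cfg.discovery, cfg.replication,
                                              cfg.continuous) if x]:
            ld.add_positions(t)
    return cfg


# ---------------------------------------------------------------------------
# row assembly
# ---------------------------------------------------------------------------

_ROW_COLUMNS = ["exposure", "outcome", "stage", "method", "n_snps", "beta",
                "se", "ci_low", "ci_high", "pval", "q_stat", "q_pval",
                "evidence", "note"]
_OR_COLUMNS = ["odds_ratio", "or_ci_low", "or_ci_high"]


def evidence_label(pval: float, n_exposures: int) -> str:
    if pval < 0.05 / n_exposures:
        return "strong"
    if pval < 0.05:
        return "suggestive"
    return "little_evidence"


def _row(exposure: str, outcome: str, stage: str, est: MREstimate | None,
         binary: bool, n_exposures: int, note: str = "",
         labelled: bool = True) -> dict:
    row = dict.fromkeys(_ROW_COLUMNS + (_OR_COLUMNS if binary else []))
    row.update(exposure=exposure, outcome=outcome, stage=stage, note=note)
    if est is None:
        row["method"] = "none"
        row["evidence"] = "not_assessable"
        return row
    row.update(method=est.method, n_snps=est.n_snps, beta=est.beta, se=est.se,
               ci_low=est.ci_low, ci_high=est.ci_high, pval=est.pval,
               q_stat=est.q_stat, q_pval=est.q_pval)
    if binary:
        lo, hi = est.or_ci
        row.update(odds_ratio=est.odds_ratio, or_ci_low=lo, or_ci_high=hi)
    row["evidence"] = (evidence_label(est.pval, n_exposures)
                       if labelled else "")
    return row


def _estimate_stage(ds: HarmonizedDataset, plan_mode: str,
                    config: AnalysisConfig, stage: str, binary: bool,
                    sensitivity: bool = True,
                    force_fixed: bool = False) -> tuple[list[dict], MREstimate | None]:
    """Estimate one (exposure, outcome) stage; returns (rows, main estimate)."""
    name, out_name = ds.exposure_name, ds.outcome_name
    k = len(ds.pairs)
    note_bits = []
    if ds.dropped:
        note_bits.append("dropped:" + ",".join(
            f"{d.variant_id}({d.reason})" for d in ds.dropped))
    proxied = [p.variant_id for p in ds.pairs if "proxy(" in p.action_log]
    if proxied:
        note_bits.append("proxied:" + ",".join(proxied))
    note = ";".join(note_bits)
    if k == 0:
        logger.warning("%s vs %s: no instruments survived harmonization", name,
                       out_name)
        return [_row(name, out_name, stage, None, binary, config.bonferroni_n,
                     note="no_instruments;" + note)], None

    plan = select_main_method(k, plan_mode)
    main_label = plan.main
    if force_fixed and main_label == "ivw_mre":
        main_label = "ivw_fe"
    if main_label == "wald_ratio":
        main = mr_core.wald_ratio(ds.pairs[0])
    else:
        main = mr_core.ivw(ds, "multiplicative_random"
                           if main_label == "ivw_mre" else "fixed")
    rows = [_row(name, out_name, stage, main, binary, config.bonferroni_n,
                 note=note)]

    if sensitivity and not force_fixed and plan.sensitivity:
        wm = mr_core.weighted_median(
            ds, n_boot=config.n_boot,
            seed=config.stage_seed(name, out_name, stage, "wm"))
        rows.append(_row(name, out_name, stage, wm, binary,
                         config.bonferroni_n, labelled=False))
        slope, intercept = mr_core.mr_egger(ds)
        rows.append(_row(name, out_name, stage, slope, binary,
                         config.bonferroni_n, labelled=False))
        rows.append(_row(name, out_name, stage, intercept, binary,
                         config.bonferroni_n, labelled=False,
                         note="pleiotropy_test"))
    return rows, main


def _select_all_instruments(config: AnalysisConfig) -> dict[str, InstrumentSet]:
    ld = config.ld or LDTable()
    out: dict[str, InstrumentSet] = {}
    for exp in config.exposures:
        if config.ld is None:
            ld = LDTable()
            ld.add_positions(exp)
        out[exp.trait_name] = select_instruments(
            exp, ld, config.alpha_gw, config.n_tests,
            config.clump_r2, config.clump_window_bp)
    return out


def instrument_report(config: AnalysisConfig,
                      instruments: dict[str, InstrumentSet] | None = None,
                      ) -> pd.DataFrame:
    """Per-instrument strength diagnostics: F statistic, variance explained."""
    instruments = instruments or _select_all_instruments(config)
    rows = []
    for name, iset in instruments.items():
        for v in iset.variants:
            rows.append({
                "exposure": name, "variant_id": v.variant_id,
                "chrom": v.chrom, "pos": v.pos, "pval": v.pval,
                "provenance": iset.provenance[v.variant_id],
                "f_stat": f_statistic(v),
                "variance_explained": (variance_explained(v)
                                       if v.eaf is not None else np.nan),
            })
    cols = ["exposure", "variant_id", "chrom", "pos", "pval", "provenance",
            "f_stat", "variance_explained"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class ForwardResult:
    estimates: pd.DataFrame     # discovery + replication + meta rows
    instruments: pd.DataFrame   # per-instrument diagnostics
    instrument_sets: dict[str, InstrumentSet]


def _forward_with_instruments(config: AnalysisConfig,
                              instruments: dict[str, InstrumentSet],
                              stage_tag: str = "") -> pd.DataFrame:
    binary = True
    rows: list[dict] = []
    stages = [(s, t) for s, t in (("discovery", config.discovery),
                                  ("replication", config.replication)) if t]
    for exp in config.exposures:
        name = exp.trait_name
        iset = instruments[name]
        if len(iset) == 0:
            rows.append(_row(name, "", stage_tag + "all", None, binary,
                             config.bonferroni_n, note="no_instruments"))
            continue
        mains: list[MREstimate] = []
        for stage, table in stages:
            ds = harmonize_dataset(iset, table, config.ld,
                                   config.palindrome_policy,
                                   config.proxy_r2, config.proxy_window_bp)
            srows, main = _estimate_stage(ds, "binary_primary", config,
                                          stage_tag + stage, binary)
            rows.extend(srows)
            if main is not None:
                mains.append(main)
        if len(mains) >= 2:
            meta = fixed_effect_meta([(m.beta, m.se) for m in mains],
                                     method_label=mains[0].method)
            q, df, qp = between_group_q([(m.beta, m.se) for m in mains])
            meta_row = _row(name, "combined", stage_tag + "meta",
                            meta, binary, config.bonferroni_n)
            meta_row.update(q_stat=q, q_pval=qp,
                            n_snps=max(m.n_snps for m in mains),
                            method="meta_" + mains[0].method)
            rows.append(meta_row)
    df = pd.DataFrame(rows, columns=_ROW_COLUMNS + _OR_COLUMNS)
    return df


def run_forward_mr(config: AnalysisConfig) -> ForwardResult:
    """The main analysis: discovery + replication MR and their meta-analysis."""
    instruments = _select_all_instruments(config)
    estimates = _forward_with_instruments(config, instruments)
    return ForwardResult(estimates, instrument_report(config, instruments),
                         instruments)


def run_confounder_exclusion(config: AnalysisConfig,
                             exclusion_ids: list[str] | None = None,
                             ) -> pd.DataFrame:
    """Forward MR after removing confounder-associated instruments.

    Exposures whose instrument count drops below the main-method threshold
    are flagged in the note column; exposures left without instruments are
    recorded and skipped.
    """
    if exclusion_ids is None:
        exclusion_ids = config.confounder_exclusion
    full = _select_all_instruments(config)
    reduced = {name: iset.without(exclusion_ids)
               for name, iset in full.items()}
    df = _forward_with_instruments(config, reduced, stage_tag="confexcl_")
    notes = []
    for _, row in df.iterrows():
        name = row["exposure"]
        k_full, k_red = len(full[name]), len(reduced[name])
        extra = ""
        if k_red < k_full:
            extra = f"k_reduced_{k_full}_to_{k_red}"
            if k_red < 4 <= k_full:
                extra += ";sensitivity_no_longer_available"
        notes.append(";".join(x for x in (row["note"], extra) if x))
    df = df.assign(note=notes)
    return df


def run_conservative(config: AnalysisConfig) -> pd.DataFrame:
    """Forward MR restricted to biologically/genetically prioritized instruments.

    Only Wald ratios (one instrument) or fixed-effects IVW are used.
    Exposures with no prioritized instruments are reported not-assessable.
    """
    full = _select_all_instruments(config)
    rows: list[dict] = []
    stages = [(s, t) for s, t in (("discovery", config.discovery),
                                  ("replication", config.replication)) if t]
    for exp in config.exposures:
        name = exp.trait_name
        prioritized = set(config.conservative_ids.get(name, []))
        iset = full[name]
        keep = [v for v in iset.variants if v.variant_id in prioritized]
        if not keep:
            rows.append(_row(name, "", "conservative", None, True,
                             config.bonferroni_n,
                             note="no_prioritized_instruments"))
            continue
        sub = InstrumentSet(name, keep,
                            {v.variant_id: iset.provenance[v.variant_id]
                             for v in keep})
        mains: list[MREstimate] = []
        for stage, table in stages:
            ds = harmonize_dataset(sub, table, config.ld,
                                   config.palindrome_policy,
                                   config.proxy_r2, config.proxy_window_bp)
            srows, main = _estimate_stage(ds, "binary_primary", config,
                                          "conservative_" + stage, True,
                                          sensitivity=False, force_fixed=True)
            rows.extend(srows)
            if main is not None:
                mains.append(main)
        if len(mains) >= 2:
            meta = fixed_effect_meta([(m.beta, m.se) for m in mains],
                                     method_label=mains[0].method)
            meta_row = _row(name, "combined", "conservative_meta", meta, True,
                            config.bonferroni_n)
            meta_row["method"] = "meta_" + mains[0].method
            rows.append(meta_row)
    return pd.DataFrame(rows, columns=_ROW_COLUMNS + _OR_COLUMNS)


def run_reverse_mr(config: AnalysisConfig) -> pd.DataFrame:
    """Reverse-direction MR: disease liability as exposure, traits as outcomes.

    Uses the configured instrument ids (missing ones are dropped with a
    log), estimating with fixed-effects IVW plus weighted-median and
    weighted-mode sensitivity analyses.
    """
    if config.reverse_exposure is None:
        raise InsufficientDataError("no reverse-direction exposure table")
    exp_tab = config.reverse_exposure
    missing = [v for v in config.reverse_instrument_ids if v not in exp_tab]
    for v in missing:
        logger.warning("reverse-MR instrument %s absent from %s; dropped",
                       v, exp_tab.trait_name)
    keep = [v for v in config.reverse_instrument_ids if v in exp_tab]
    iset = InstrumentSet(exp_tab.trait_name,
                         [exp_tab.get(v) for v in keep])
    rows: list[dict] = []
    note = "dropped:" + ",".join(missing) if missing else ""
    for outcome in config.reverse_outcomes:
        ds = harmonize_dataset(iset, outcome, config.ld,
                               config.palindrome_policy,
                               config.proxy_r2, config.proxy_window_bp)
        k = len(ds.pairs)
        if k == 0:
            rows.append(_row(exp_tab.trait_name, outcome.trait_name, "reverse",
                             None, False, config.bonferroni_n,
                             note="no_instruments"))
            continue
        est = (mr_core.wald_ratio(ds.pairs[0]) if k == 1
               else mr_core.ivw(ds, "fixed"))
        rows.append(_row(exp_tab.trait_name, outcome.trait_name, "reverse",
                         est, False, config.bonferroni_n, note=note))
        if k >= 3:
            wm = mr_core.weighted_median(
                ds, n_boot=config.n_boot,
                seed=config.stage_seed(outcome.trait_name, "reverse", "wm"))
            mode = mr_core.weighted_mode(
                ds, n_boot=config.n_boot,
                seed=config.stage_seed(outcome.trait_name, "reverse", "mode"))
            rows.append(_row(exp_tab.trait_name, outcome.trait_name, "reverse",
                             wm, False, config.bonferroni_n, labelled=False))
            rows.append(_row(exp_tab.trait_name, outcome.trait_name, "reverse",
                             mode, False, config.bonferroni_n, labelled=False))
    return pd.DataFrame(rows, columns=_ROW_COLUMNS)


def run_continuous_outcome(config: AnalysisConfig) -> pd.DataFrame:
    """Forward MR against a continuous outcome, reported on the SD scale.

    The method-selection rules are unchanged; outputs are SD difference per
    SD of exposure and carry no odds-ratio columns.
    """
    if config.continuous is None:
        raise InsufficientDataError("no continuous outcome table")
    instruments = _select_all_instruments(config)
    rows: list[dict] = []
    for exp in config.exposures:
        name = exp.trait_name
        iset = instruments[name]
        if len(iset) == 0:
            rows.append(_row(name, config.continuous.trait_name, "continuous",
                             None, False, config.bonferroni_n,
                             note="no_instruments"))
            continue
        ds = harmonize_dataset(iset, config.continuous, config.ld,
                               config.palindrome_policy,
                               config.proxy_r2, config.proxy_window_bp)
        srows, _ = _estimate_stage(ds, "continuous_pdff", config, "continuous",
                                   binary=False, sensitivity=False)
        rows.extend(srows)
    return pd.DataFrame(rows, columns=_ROW_COLUMNS)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_estimates(df: pd.DataFrame, path, config: AnalysisConfig,
                    stage: str) -> None:
    """Write an estimates table as tab-delimited text with a '#' header
    recording the analysis settings (provenance of every number)."""
    with open(path, "wt") as fh:
        fh.write(f"# stage={stage}\n")
        fh.write(f"# p_threshold={significance_threshold(config.alpha_gw, config.n_tests)!r}\n")
        fh.write(f"# clump_r2={config.clump_r2} clump_window_bp={config.clump_window_bp}\n")
        fh.write(f"# proxy_r2={config.proxy_r2} proxy_window_bp={config.proxy_window_bp}\n")
        fh.write(f"# palindrome_policy={config.palindrome_policy}\n")
        fh.write(f"# bonferroni_n={config.bonferroni_n} seed={config.seed} "
                 f"n_boot={config.n_boot}\n")
        fh.write("# random_effects=multiplicative (assumption); "
                 "egger_overdispersion=max(1,sqrt(RSS/(k-2))) (assumption); "
                 "mode_bandwidth_factor=1\n")
        df.to_csv(fh, sep="\t", index=False)


def run_all(config: AnalysisConfig, outdir) -> dict[str, pd.DataFrame]:
    """Run every configured stage and write one table per stage to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}
    fwd = run_forward_mr(config)
    results["forward"] = fwd.estimates
    results["instruments"] = fwd.instruments
    if config.confounder_exclusion:
        results["confounder_excluded"] = run_confounder_exclusion(config)
    if config.conservative_ids:
        results["conservative"] = run_conservative(config)
    if config.reverse_exposure is not None and config.reverse_outcomes:
        results["reverse"] = run_reverse_mr(config)
    if config.continuous is not None:
        results["continuous"] = run_continuous_outcome(config)
    for stage, df in results.items():
        write_estimates(df, outdir / f"{stage}.tsv", config, stage)
    return results
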