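"""End-to-end analysis orchestration.

One :class:`AnalysisConfig` describes an exposure–outcome pair; the stages
run read → genome-wide filter → LD clump → strength screen → harmonize →
MR-PRESSO outlier removal → estimator suite → sensitivity suite, with every
instrument's fate logged so attrition counts always reconcile.  Method
routing follows the instrument count: a single instrument reports only the
Wald ratio; two or more add IVW fixed- and random-effects (IVW-RE is the
headline row); three or more add MR-Egger, the weighted median,
leave-one-out and the Q diagnostics; a heterogeneity signal (Cochran p <
0.05) additionally triggers the penalized-IVW row.  Identical configuration
and seed give byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .estimators import (
    MRResult,
    egger,
    ivw,
    ivw_penalized,
    ratio_estimates,
    wald_result,
    weighted_median,
    with_or_scale,
)
from .harmonize import DEFAULT_PALINDROME_BAND, HarmonizedSet, harmonize, orient_positive
from .instruments import (
    DEFAULT_CLUMP_KB,
    DEFAULT_CLUMP_R2,
    GENOME_WIDE_P,
    InstrumentSet,
    LDMatrix,
    clump,
    filter_significant,
    screen_weak,
)
from .sensitivity import (
    HETEROGENEITY_ALPHA,
    HeterogeneityResult,
    LOOResult,
    PressoResult,
    cochran_q,
    egger_intercept_test,
    funnel_data,
    leave_one_out,
    mr_presso,
    rucker_q,
)
from .sumstats import SummaryStatSet, read_sumstats

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "run_batch", "write_report"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of one exposure–outcome analysis.

    Defaults are the conventional thresholds: genome-wide significance
    p < 5e-8, clumping at r² < 0.001 within ±10,000 kb, no F exclusion
    (report-only), 1000 bootstrap and MR-PRESSO replicates.  ``seed`` is
    mandatory because the weighted median and MR-PRESSO are stochastic.
    """

    exposure_path: str
    outcome_path: str
    seed: int
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    exposure_type: str = "continuous"
    outcome_type: str = "continuous"
    p_threshold: float = GENOME_WIDE_P
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_kb: float = DEFAULT_CLUMP_KB
    f_min: float = 0.0
    ld_path: str | None = None
    palindrome_eaf_band: float = DEFAULT_PALINDROME_BAND
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_alpha: float = 0.05
    exposure_column_map: dict | None = None
    outcome_column_map: dict | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")
        if not 0 <= self.clump_r2 <= 1:
            raise ValueError("clump_r2 must lie in [0, 1]")
        if self.clump_kb <= 0:
            raise ValueError("clump_kb must be > 0")
        if self.seed is None:
            raise ValueError("seed is required")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class AnalysisReport:
    """Everything one analysis produced, recomputable from inputs + header."""

    exposure: str
    outcome: str
    outcome_type: str
    header: dict
    results: list[MRResult] = field(default_factory=list)
    heterogeneity: list[HeterogeneityResult] = field(default_factory=list)
    egger_intercept: object | None = None
    presso: PressoResult | None = None
    loo: LOOResult | None = None
    funnel: pd.DataFrame | None = None
    provenance: list[tuple[str, str, str]] = field(default_factory=list)  # (stage, rsid, decision)
    not_estimable: dict[str, str] = field(default_factory=dict)
    f_range: tuple[float, float] | None = None
    harmonized: HarmonizedSet | None = None
    failure: str | None = None

    @property
    def headline(self) -> MRResult | None:
        for method in ("ivw_re", "wald"):
            for r in self.results:
                if r.method == method:
                    return r
        return self.results[0] if self.results else None

    def results_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            or_est, or_lo, or_hi = r.or_scale if r.or_scale else (None, None, None)
            rows.append(
                {
                    "exposure": self.exposure, "outcome": self.outcome,
                    "method": r.method, "n_snp": r.n_snp, "estimate": r.estimate,
                    "se": r.se, "ci_low": r.ci_low, "ci_high": r.ci_high,
                    "pval": r.pval, "or": or_est, "or_ci_low": or_lo, "or_ci_high": or_hi,
                }
            )
        cols = ["exposure", "outcome", "method", "n_snp", "estimate", "se",
                "ci_low", "ci_high", "pval", "or", "or_ci_low", "or_ci_high"]
        return pd.DataFrame(rows, columns=cols)


def _log_stage(provenance, stage: str, before: set[str], after: set[str], reason: str) -> None:
    for rsid in sorted(before - after):
        provenance.append((stage, rsid, reason))


def run_analysis(
    config: AnalysisConfig,
    exposure: SummaryStatSet | None = None,
    outcome: SummaryStatSet | None = None,
    ld: LDMatrix | None = None,
) -> AnalysisReport:
    """Run the full analysis for one exposure–outcome pair.

    ``exposure``/``outcome``/``ld`` may be passed in-memory; otherwise they
    are read from the paths in ``config``.  Zero surviving instruments at
    any stage produce a structured failure naming the stage rather than an
    exception; an estimator whose precondition is unmet is marked
    not-estimable and the run continues.
    """
    header = {k: v for k, v in asdict(config).items()}
    header["version"] = __version__
    report = AnalysisReport(
        exposure=config.exposure_name, outcome=config.outcome_name,
        outcome_type=config.outcome_type, header=header,
    )
    provenance = report.provenance

    if exposure is None:
        exposure = read_sumstats(config.exposure_path, config.exposure_column_map,
                                 config.exposure_name, config.exposure_type)
    if outcome is None:
        outcome = read_sumstats(config.outcome_path, config.outcome_column_map,
                                config.outcome_name, config.outcome_type)

    candidates = {r.rsid for r in exposure}
    significant = filter_significant(exposure, config.p_threshold)
    _log_stage(provenance, "significance", candidates, {r.rsid for r in significant},
               "dropped:p-threshold")
    if not len(significant):
        report.failure = "no instruments after significance filtering"
        return report

    permissive = ld is None and config.ld_path is None
    if ld is None:
        ld = LDMatrix.read(config.ld_path) if config.ld_path else LDMatrix.identity([])
    clumped = clump(significant, ld, config.clump_r2, config.clump_kb, permissive=permissive)
    for rsid, decision in clumped.provenance:
        if decision != "kept":
            provenance.append(("clumping", rsid, decision))

    screened = screen_weak(clumped, config.f_min)
    _log_stage(provenance, "strength", {r.rsid for r in clumped},
               {r.rsid for r in screened}, "dropped:weak-instrument")
    if not len(screened):
        report.failure = "no instruments after strength screening"
        return report
    report.f_range = screened.f_range()

    harmonized = harmonize(screened, outcome, config.palindrome_eaf_band)
    for rec in harmonized:
        if rec.action == "dropped":
            provenance.append(("harmonization", rec.rsid, f"dropped:{rec.drop_reason}"))
    harmonized = orient_positive(harmonized)
    if harmonized.n_kept == 0:
        report.failure = "no instruments after harmonization"
        return report

    # MR-PRESSO outlier removal, applied once before the estimator suite
    if harmonized.n_kept >= 4 and config.presso_n_sim > 0:
        report.presso = mr_presso(harmonized, n_sim=config.presso_n_sim,
                                  outlier_alpha=config.presso_alpha, seed=config.seed)
        if report.presso.outlier_indices:
            for rsid in report.presso.outlier_indices:
                provenance.append(("presso", rsid, "dropped:presso-outlier"))
            harmonized = harmonized.drop_rsids(report.presso.outlier_indices, "presso_outlier")
    else:
        report.not_estimable["mr_presso"] = f"requires >= 4 instruments, have {harmonized.n_kept}"

    kept = harmonized.kept
    j = len(kept)
    if j == 0:
        report.failure = "no instruments after outlier removal"
        return report

    binary = config.outcome_type == "binary"

    def emit(res: MRResult) -> None:
        report.results.append(with_or_scale(res) if binary else res)

    ratios = ratio_estimates(harmonized)
    if j == 1:
        emit(wald_result(kept[0]))
        for m in ("ivw_fe", "ivw_re", "egger", "weighted_median",
                  "leave_one_out", "cochran_q", "rucker_q"):
            report.not_estimable[m] = "requires >= 2 instruments"
    else:
        emit(ivw(ratios, mode="fixed"))
        emit(ivw(ratios, mode="random"))
        cq = cochran_q(ratios)
        report.heterogeneity.append(cq)
        if j >= 3:
            slope, icpt = egger(harmonized)
            emit(slope)
            report.egger_intercept = icpt
            emit(weighted_median(ratios, n_boot=config.n_boot, seed=config.seed))
            report.heterogeneity.append(rucker_q(harmonized))
            report.loo = leave_one_out(harmonized)
        else:
            for m in ("egger", "weighted_median", "leave_one_out", "rucker_q"):
                report.not_estimable[m] = "requires >= 3 instruments"
        if cq.heterogeneous:
            emit(ivw_penalized(ratios))

    if report.headline is not None and ratios:
        report.funnel = funnel_data(ratios, report.headline)
    report.harmonized = harmonized
    return report


def run_batch(configs: list[AnalysisConfig]) -> tuple[list[AnalysisReport], pd.DataFrame]:
    """Run independent analyses; one failing pair does not abort the batch.

    Returns the per-pair reports and a combined summary table keyed by
    (exposure, outcome, method).
    """
    reports: list[AnalysisReport] = []
    for config in configs:
        try:
            reports.append(run_analysis(config))
        except Exception as exc:  # structured failures are already reports
            failed = AnalysisReport(
                exposure=config.exposure_name, outcome=config.outcome_name,
                outcome_type=config.outcome_type,
                header={"seed": config.seed, "version": __version__},
                failure=f"error: {exc}",
            )
            reports.append(failed)
    frames = [f for f in (r.results_frame() for r in reports) if not f.empty]
    if frames:
        combined = pd.concat(frames, ignore_index=True)
    else:
        combined = reports[0].results_frame() if reports else pd.DataFrame()
    return reports, combined


def _round_trip_float(x):
    return None if x is None else float(x)


def report_to_dict(report: AnalysisReport) -> dict:
    """Machine-readable form of a report (deterministic key order)."""
    d = {
        "exposure": report.exposure,
        "outcome": report.outcome,
        "outcome_type": report.outcome_type,
        "header": report.header,
        "failure": report.failure,
        "f_range": list(report.f_range) if report.f_range else None,
        "results": [
            {
                "method": r.method, "n_snp": r.n_snp, "estimate": r.estimate,
                "se": r.se, "ci_low": r.ci_low, "ci_high": r.ci_high, "pval": r.pval,
                "or_scale": list(r.or_scale) if r.or_scale else None,
            }
            for r in report.results
        ],
        "heterogeneity": [
            {"statistic": h.statistic, "q": h.q, "df": h.df, "pval": h.pval}
            for h in report.heterogeneity
        ],
        "egger_intercept": None
        if report.egger_intercept is None
        else {
            "intercept": report.egger_intercept.intercept,
            "se": report.egger_intercept.se,
            "pval": report.egger_intercept.pval,
        },
        "presso": None
        if report.presso is None
        else {
            "rss_obs": report.presso.rss_obs,
            "global_pval": report.presso.global_pval,
            "outlier_indices": report.presso.outlier_indices,
            "outlier_pvals": report.presso.outlier_pvals,
            "distortion_pval": _round_trip_float(report.presso.distortion_pval),
            "estimate_before": report.presso.estimate_before,
            "estimate_after": _round_trip_float(report.presso.estimate_after),
            "n_sim": report.presso.n_sim,
            "seed": report.presso.seed,
        },
        "loo": None
        if report.loo is None
        else {
            "influential": report.loo.influential,
            "entries": [
                {"excluded": rsid, "estimate": res.estimate, "se": res.se,
                 "ci_low": res.ci_low, "ci_high": res.ci_high, "pval": res.pval}
                for rsid, res in report.loo.entries
            ],
        },
        "not_estimable": report.not_estimable,
        "provenance": [list(p) for p in report.provenance],
    }
    return d


def write_report(report: AnalysisReport, outdir) -> Path:
    """Write the delimited tables and the structured JSON for one analysis."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.results_frame().to_csv(outdir / "results.tsv", sep="\t", index=False)
    diag_rows = [
        {"diagnostic": h.statistic, "value": h.q, "df": h.df, "pval": h.pval}
        for h in report.heterogeneity
    ]
    if report.egger_intercept is not None:
        diag_rows.append({"diagnostic": "egger_intercept",
                          "value": report.egger_intercept.intercept,
                          "df": None, "pval": report.egger_intercept.pval})
    if report.presso is not None:
        diag_rows.append({"diagnostic": "presso_global", "value": report.presso.rss_obs,
                          "df": None, "pval": report.presso.global_pval})
        if report.presso.distortion_pval is not None:
            diag_rows.append({"diagnostic": "presso_distortion", "value": None,
                              "df": None, "pval": report.presso.distortion_pval})
    pd.DataFrame(diag_rows, columns=["diagnostic", "value", "df", "pval"]).to_csv(
        outdir / "diagnostics.tsv", sep="\t", index=False)
    if report.loo is not None:
        pd.DataFrame(
            [
                {"excluded": rsid, "estimate": res.estimate, "se": res.se,
                 "ci_low": res.ci_low, "ci_high": res.ci_high, "pval": res.pval,
                 "influential": rsid in report.loo.influential}
                for rsid, res in report.loo.entries
            ]
        ).to_csv(outdir / "leave_one_out.tsv", sep="\t", index=False)
    if report.funnel is not None:
        report.funnel.to_csv(outdir / "funnel.tsv", sep="\t", index=False)
    pd.DataFrame(report.provenance, columns=["stage", "SNP", "decision"]).to_csv(
        outdir / "provenance.tsv", sep="\t", index=False)
    if report.harmonized is not None:
        report.harmonized.write_audit(outdir / "harmonization_audit.tsv")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
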