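"""Per-cancer screening loop: sample-size gate, core homogeneity gate, survival.

Every cohort is processed independently (gene-wise location/scale within the
cohort is the only batch handling): consensus clustering at k=4 over the two
gene sets, core-cluster selection with the >=50% composition rule, rejection
when either core's homogeneity falls below the threshold, quadrant subtype
assignment, and a 4-group log-rank test on samples surviving the follow-up
filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from metabosub.consensus import ConsensusConfig
from metabosub.data_io import ClinicalTable, ExpressionMatrix, GeneSet
from metabosub.errors import CoreSelectionError, MetabosubError
from metabosub.pipeline import run_subtyping_pipeline
from metabosub.subtyping import SUBTYPES
from metabosub.survival import filter_min_followup, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class CohortScreenReport:
    cancer_code: str
    n_samples: int
    passed_min_samples: bool
    core_found: dict[str, bool] = field(default_factory=dict)
    homogeneity: dict[str, float] = field(default_factory=dict)
    passed_homogeneity: bool = False
    subtype_counts: dict[str, int] = field(default_factory=dict)
    logrank_statistic: float | None = None
    logrank_p: float | None = None
    failure_reason: str | None = None

    @property
    def passed(self) -> bool:
        return self.passed_min_samples and self.passed_homogeneity


def screen_cohorts(
    cohorts: Mapping[str, tuple[ExpressionMatrix, ClinicalTable]],
    gly_set: GeneSet,
    chol_set: GeneSet,
    min_samples: int = 100,
    homogeneity_min: float = 0.75,
    consensus_config: ConsensusConfig | None = None,
    min_followup_months: float = 1.0,
) -> list[CohortScreenReport]:
    """Apply the pan-cancer gates to each cohort; failures become report rows.

    The sample-size gate keeps cohorts with >= ``min_samples`` samples
    (inclusive at the boundary); the homogeneity gate requires both selected
    cores to reach ``homogeneity_min``.
    """
    if not cohorts:
        raise MetabosubError("no cohorts supplied")
    reports = []
    for code in cohorts:
        expr, clinical = cohorts[code]
        report = CohortScreenReport(code, expr.n_samples,
                                    passed_min_samples=expr.n_samples >= min_samples)
        reports.append(report)
        if not report.passed_min_samples:
            report.failure_reason = f"fewer than {min_samples} samples"
            continue
        try:
            result = run_subtyping_pipeline(expr, clinical, gly_set, chol_set,
                                            consensus_config=consensus_config)
        except CoreSelectionError as exc:
            report.core_found = {"gly": False, "chol": False}
            report.failure_reason = str(exc)
            continue
        report.core_found = {"gly": bool(result.cores.gly_core),
                             "chol": bool(result.cores.chol_core)}
        report.homogeneity = dict(result.cores.homogeneity)
        report.passed_homogeneity = all(
            h >= homogeneity_min for h in report.homogeneity.values())
        if not report.passed_homogeneity:
            report.failure_reason = (
                f"core homogeneity below {homogeneity_min}: {report.homogeneity}")
            continue
        counts = {s: 0 for s in SUBTYPES}
        for call in result.calls:
            counts[call.subtype] += 1
        report.subtype_counts = counts
        surv = filter_min_followup(result.clinical, min_followup_months)
        subtype_of = {c.sample_id: c.subtype for c in result.calls}
        groups = []
        for s in SUBTYPES:
            mask = surv.df["sample_id"].map(subtype_of) == s
            sub = surv.df[mask]
            if len(sub):
                groups.append((sub["os_months"].to_numpy(),
                               sub["os_event"].to_numpy()))
        try:
            lr = logrank_test(groups)
            report.logrank_statistic = lr.statistic
            report.logrank_p = lr.p_value
        except MetabosubError as exc:
            logger.warning("%s: survival test skipped (%s)", code, exc)
    return reports


def rank_survival_separation(reports: list[CohortScreenReport]) -> pd.DataFrame:
    """Passing cohorts sorted by log-rank statistic, descending."""
    rows = [
        {"cancer_code": r.cancer_code, "logrank_statistic": r.logrank_statistic,
         "logrank_p": r.logrank_p}
        for r in reports if r.passed and r.logrank_statistic is not None
    ]
    if not rows:
        logger.warning("no passing cohorts with a survival test")
        return pd.DataFrame(columns=["cancer_code", "logrank_statistic", "logrank_p"])
    return (pd.DataFrame(rows)
            .sort_values("logrank_statistic", ascending=False)
            .reset_index(drop=True))


def reports_to_frame(reports: list[CohortScreenReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "cancer_code": r.cancer_code,
            "n_samples": r.n_samples,
            "passed_min_samples": r.passed_min_samples,
            "gly_core_found": r.core_found.get("gly", False),
            "chol_core_found": r.core_found.get("chol", False),
            "gly_homogeneity": r.homogeneity.get("gly", float("nan")),
            "chol_homogeneity": r.homogeneity.get("chol", float("nan")),
            "passed_homogeneity": r.passed_homogeneity,
            "logrank_statistic": r.logrank_statistic,
            "logrank_p": r.logrank_p,
            "failure_reason": r.failure_reason or "",
        }
        for s in SUBTYPES:
            row[f"n_{s}"] = r.subtype_counts.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)
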