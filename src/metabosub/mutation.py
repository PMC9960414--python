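"""CNV event calling, mutation matrices, and subtype contingency tests.

Two CNV sources are supported — integer copy status (amplified when >= 3,
deleted when <= 1) and SEG segments (>= 10 probes and |seg mean| strictly
above 0.2) — and their calls are unioned when both are supplied. A gene is
hit by a segment event when their 1-based inclusive intervals overlap by at
least one base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from metabosub.data_io import GeneCoordinates, MutationTable, SegmentTable
from metabosub.errors import ValidationError
from metabosub.subtyping import SUBTYPES, SubtypeCall

logger = logging.getLogger(__name__)

#: frequently mutated genes tested by default
DEFAULT_GENE_PANEL = ("TP53", "CDKN2A", "PIK3CA", "LRP1B", "FLG")


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    gene: str
    direction: str  # amplified | deleted
    source: str     # ploidy | segment

    def __post_init__(self) -> None:
        if self.direction not in ("amplified", "deleted"):
            raise ValidationError(f"unknown CNV direction {self.direction!r}")
        if self.source not in ("ploidy", "segment"):
            raise ValidationError(f"unknown CNV source {self.source!r}")


@dataclass
class GeneMutationMatrix:
    """Samples x genes binary indicators per event class plus the OR."""

    snv_indel: pd.DataFrame
    amplified: pd.DataFrame
    deleted: pd.DataFrame
    altered: pd.DataFrame


@dataclass
class ContingencyResult:
    gene: str
    table: pd.DataFrame  # 2 x k (altered/wild x subtype)
    statistic: float
    p_value: float
    test_used: str  # chi2 | fisher
    q_value: float = float("nan")


def call_cnv_from_ploidy(copy_status: pd.DataFrame) -> list[CnvCall]:
    """Integer copy status (samples x genes): >=3 amplified, <=1 deleted, 2 neutral."""
    values = copy_status.to_numpy()
    if (values < 0).any():
        raise ValidationError("negative copy status")
    calls = []
    for i, sample in enumerate(copy_status.index):
        for j, gene in enumerate(copy_status.columns):
            status = values[i, j]
            if status >= 3:
                calls.append(CnvCall(str(sample), str(gene), "amplified", "ploidy"))
            elif status <= 1:
                calls.append(CnvCall(str(sample), str(gene), "deleted", "ploidy"))
    return calls


def call_cnv_from_segments(segments: SegmentTable, coords: GeneCoordinates,
                           min_probes: int = 10,
                           mean_thresh: float = 0.2) -> list[CnvCall]:
    """Map segment-level events onto genes by any-overlap.

    A segment is an event when num_probes >= min_probes (inclusive) AND
    seg_mean is strictly greater than +mean_thresh (amplified) or strictly
    less than -mean_thresh (deleted). Conflicting amplified+deleted calls for
    one (sample, gene) are both kept and flagged in the log.
    """
    seg = segments.df
    genes = coords.df
    unknown = sorted(set(seg["chrom"].astype(str)) - set(genes["chrom"].astype(str)))
    if unknown:
        raise ValidationError(f"segment chromosomes absent from gene coordinates: {unknown}")
    passing = seg[(seg["num_probes"] >= min_probes)
                  & (seg["seg_mean"].abs() > mean_thresh)]
    calls: list[CnvCall] = []
    seen: set[tuple[str, str, str]] = set()
    for row in passing.itertuples(index=False):
        direction = "amplified" if row.seg_mean > mean_thresh else "deleted"
        hits = genes[(genes["chrom"].astype(str) == str(row.chrom))
                     & (genes["start"] <= row.end) & (genes["end"] >= row.start)]
        for gene in hits["gene"]:
            key = (str(row.sample_id), str(gene), direction)
            if key in seen:
                continue
            seen.add(key)
            calls.append(CnvCall(str(row.sample_id), str(gene), direction, "segment"))
    conflicted = {(s, g) for s, g, d in seen if (s, g, "amplified") in seen
                  and (s, g, "deleted") in seen}
    if conflicted:
        logger.warning("conflicting amplified+deleted calls for %d (sample, gene) "
                       "pairs: %s", len(conflicted), sorted(conflicted)[:5])
    return calls


def build_mutation_matrix(mutations: MutationTable, cnv: Sequence[CnvCall],
                          samples: Sequence[str],
                          genes: Sequence[str] = DEFAULT_GENE_PANEL) -> GeneMutationMatrix:
    """Binary alteration indicators; altered = SNV/INDEL OR amplification OR deletion.

    Samples absent from the mutation data are treated as wild-type (logged).
    """
    if not genes:
        raise ValidationError("gene panel must be non-empty")
    samples = list(samples)
    genes = list(genes)
    zero = lambda: pd.DataFrame(False, index=samples, columns=genes)
    snv, amp, dele = zero(), zero(), zero()
    mut_samples = set(mutations.df["sample_id"])
    missing = [s for s in samples if s not in mut_samples]
    if missing:
        logger.info("%d samples absent from mutation data assumed wild-type",
                    len(missing))
    for row in mutations.df.itertuples(index=False):
        if row.sample_id in snv.index and row.gene in snv.columns:
            snv.loc[row.sample_id, row.gene] = True
    for call in cnv:
        if call.sample_id in amp.index and call.gene in amp.columns:
            target = amp if call.direction == "amplified" else dele
            target.loc[call.sample_id, call.gene] = True
    altered = snv | amp | dele
    return GeneMutationMatrix(snv, amp, dele, altered)


def chi2_on_table(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a contingency table."""
    statistic, p_value, _, _ = stats.chi2_contingency(table, correction=False)
    return float(statistic), float(p_value)


def _monte_carlo_p(table: np.ndarray, reps: int, seed: int) -> tuple[float, float]:
    """Permutation p-value for a 2 x k table with fixed margins.

    Column totals and the altered-row total are held fixed; tableaux are
    generated by permuting sample group labels. Deterministic under seed.
    """
    observed_stat = _pearson_stat(table)
    col_totals = table.sum(axis=0)
    n_altered = int(table[0].sum())
    n = int(table.sum())
    group_labels = np.repeat(np.arange(table.shape[1]), col_totals.astype(int))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(reps):
        perm = rng.permutation(n)
        altered_groups = group_labels[perm[:n_altered]]
        top = np.bincount(altered_groups, minlength=table.shape[1])
        sim = np.vstack([top, col_totals - top])
        if _pearson_stat(sim) >= observed_stat - 1e-12:
            exceed += 1
    return observed_stat, (exceed + 1) / (reps + 1)


def _pearson_stat(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def test_gene_by_subtype(matrix: GeneMutationMatrix, calls: Sequence[SubtypeCall],
                         mc_reps: int = 10_000, seed: int = 0) -> list[ContingencyResult]:
    """Per-gene 2 x k (altered/wild x subtype) association tests with BH q-values.

    Pearson chi-square when all expected counts are >= 5, otherwise a seeded
    Monte-Carlo permutation test (reported as 'fisher' fallback).
    """
    subtype_of = {c.sample_id: c.subtype for c in calls}
    present = [s for s in matrix.altered.index if s in subtype_of]
    levels = [s for s in SUBTYPES if any(subtype_of[x] == s for x in present)]
    if len(levels) < 2:
        raise ValidationError("all samples fall in a single subtype")
    results: list[ContingencyResult] = []
    for gene in matrix.altered.columns:
        altered = matrix.altered.loc[present, gene].to_numpy()
        groups = np.array([subtype_of[s] for s in present])
        table = pd.DataFrame(
            [[int(((groups == lv) & altered).sum()) for lv in levels],
             [int(((groups == lv) & ~altered).sum()) for lv in levels]],
            index=["altered", "wild"], columns=levels)
        arr = table.to_numpy(dtype=float)
        expected = arr.sum(axis=1, keepdims=True) @ arr.sum(axis=0, keepdims=True) / arr.sum()
        if arr.sum(axis=1).min() == 0:
            # no altered (or no wild) samples at all: association undefined
            statistic, p_value, test_used = 0.0, 1.0, "chi2"
        elif (expected < 5).any():
            statistic, p_value = _monte_carlo_p(arr, mc_reps, seed)
            test_used = "fisher"
        else:
            statistic, p_value = chi2_on_table(arr)
            test_used = "chi2"
        results.append(ContingencyResult(str(gene), table, statistic, p_value, test_used))
    q_values = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, q in zip(results, q_values):
        r.q_value = float(q)
    return results


def subtype_frequencies(matrix: GeneMutationMatrix,
                        calls: Sequence[SubtypeCall]) -> pd.DataFrame:
    """Fraction of altered samples per (gene, subtype)."""
    subtype_of = {c.sample_id: c.subtype for c in calls}
    present = [s for s in matrix.altered.index if s in subtype_of]
    groups = pd.Series([subtype_of[s] for s in present], index=present)
    return matrix.altered.loc[present].groupby(groups).mean().T
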