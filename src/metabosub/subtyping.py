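"""Core co-expressed cluster selection, pathway scores, quadrant subtypes.

A sample's subtype is read off the signs of its median centered expression
over the core glycolytic and cholesterogenic genes:

==============  ===========  ============
subtype         gly score    chol score
==============  ===========  ============
quiescent       <= 0         <= 0
glycolytic      > 0          <= 0
cholesterogenic <= 0         > 0
mixed           > 0          > 0
==============  ===========  ============
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from metabosub.data_io import ExpressionMatrix, GeneSet
from metabosub.errors import CoreSelectionError, ValidationError

logger = logging.getLogger(__name__)

SUBTYPES = ("quiescent", "glycolytic", "cholesterogenic", "mixed")


@dataclass
class CoreClusters:
    """Selected co-expressed gene subsets and their cluster statistics."""

    gly_core: list[str]
    chol_core: list[str]
    composition: dict[int, dict[str, float]]
    homogeneity: dict[str, float]
    winning_cluster: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.gly_core) & set(self.chol_core):
            raise ValidationError("core gene lists overlap")


@dataclass
class PathwayScores:
    sample_ids: list[str]
    gly: np.ndarray
    chol: np.ndarray

    def __post_init__(self) -> None:
        self.gly = np.asarray(self.gly, dtype=float)
        self.chol = np.asarray(self.chol, dtype=float)
        if not (len(self.sample_ids) == self.gly.size == self.chol.size):
            raise ValidationError("score arrays do not match sample ids")


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    subtype: str
    gly_score: float
    chol_score: float


def _composition_table(labels: Mapping[str, int], gly: GeneSet,
                       chol: GeneSet) -> dict[int, dict[str, float]]:
    table: dict[int, dict[str, float]] = {}
    for cluster in sorted(set(labels.values())):
        members = [g for g, c in labels.items() if c == cluster]
        n = len(members)
        table[cluster] = {
            "size": float(n),
            "gly": sum(g in gly for g in members) / n,
            "chol": sum(g in chol for g in members) / n,
        }
    return table


def select_core_clusters(
    labels: Mapping[str, int],
    gly_set: GeneSet,
    chol_set: GeneSet,
    min_composition: float = 0.5,
    composition_of_set: bool = False,
) -> CoreClusters:
    """Pick, per gene set, the cluster dominated by that set's genes.

    A candidate cluster has at least ``min_composition`` of its members in
    the set; the most homogeneous candidate wins (ties: larger cluster, then
    lowest cluster id). The core gene list is the winning cluster's members
    that belong to the set.

    With ``composition_of_set=True`` the candidate criterion is instead the
    fraction of the SET captured by the cluster (the alternative reading of
    the 50% rule); homogeneity is always the within-cluster fraction.
    """
    unknown = [g for g in labels if g not in gly_set and g not in chol_set]
    if unknown:
        raise ValidationError(f"clustered genes outside both gene sets: {unknown}")
    table = _composition_table(labels, gly_set, chol_set)

    def candidates(set_key: str, gene_set: GeneSet) -> list[int]:
        out = []
        for cluster, stats in table.items():
            if composition_of_set:
                captured = stats[set_key] * stats["size"] / len(gene_set)
                ok = captured >= min_composition
            else:
                ok = stats[set_key] >= min_composition
            if ok:
                out.append(cluster)
        return out

    def best(cands: list[int], set_key: str) -> int:
        return min(cands, key=lambda c: (-table[c][set_key], -table[c]["size"], c))

    cand = {"gly": candidates("gly", gly_set), "chol": candidates("chol", chol_set)}
    for key in ("gly", "chol"):
        if not cand[key]:
            raise CoreSelectionError(f"no candidate core cluster for the "
                                     f"{'glycolytic' if key == 'gly' else 'cholesterogenic'} set")
    winner = {key: best(cand[key], key) for key in ("gly", "chol")}

    if winner["gly"] == winner["chol"]:
        contested = winner["gly"]
        alt = {key: [c for c in cand[key] if c != contested] for key in ("gly", "chol")}
        if not alt["gly"] and not alt["chol"]:
            raise CoreSelectionError(
                f"cluster {contested} is the only candidate for both gene sets")
        if alt["gly"] and not alt["chol"]:
            winner["gly"] = best(alt["gly"], "gly")
        elif alt["chol"] and not alt["gly"]:
            winner["chol"] = best(alt["chol"], "chol")
        else:
            # both sets have fallbacks: the contested cluster goes to the set
            # it represents better, the other set takes its next-best
            if table[contested]["gly"] >= table[contested]["chol"]:
                winner["chol"] = best(alt["chol"], "chol")
            else:
                winner["gly"] = best(alt["gly"], "gly")

    gly_core = [g for g, c in labels.items() if c == winner["gly"] and g in gly_set]
    chol_core = [g for g, c in labels.items() if c == winner["chol"] and g in chol_set]
    homogeneity = {"gly": table[winner["gly"]]["gly"],
                   "chol": table[winner["chol"]]["chol"]}
    return CoreClusters(gly_core, chol_core, table, homogeneity,
                        {"gly": winner["gly"], "chol": winner["chol"]})


def compute_pathway_scores(expr_centered: ExpressionMatrix,
                           core: CoreClusters) -> PathwayScores:
    """Per-sample median centered expression over each core gene list."""
    missing = [g for g in (*core.gly_core, *core.chol_core)
               if g not in expr_centered.gene_ids]
    if missing:
        raise ValidationError(f"core genes missing from matrix: {missing}")
    gly = np.median(expr_centered.subset_genes(core.gly_core).values, axis=0)
    chol = np.median(expr_centered.subset_genes(core.chol_core).values, axis=0)
    return PathwayScores(list(expr_centered.sample_ids), gly, chol)


def assign_subtype(scores: PathwayScores) -> list[SubtypeCall]:
    """Quadrant rule on the two pathway scores; 0 belongs to the '<= 0' side."""
    calls = []
    for sample, g, c in zip(scores.sample_ids, scores.gly, scores.chol):
        if math.isnan(g) or math.isnan(c):
            raise ValidationError(f"NaN pathway score for sample {sample!r}")
        if g > 0 and c > 0:
            subtype = "mixed"
        elif g > 0:
            subtype = "glycolytic"
        elif c > 0:
            subtype = "cholesterogenic"
        else:
            subtype = "quiescent"
        calls.append(SubtypeCall(sample, subtype, float(g), float(c)))
    return calls


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": [c.sample_id for c in calls],
        "gly_score": [c.gly_score for c in calls],
        "chol_score": [c.chol_score for c in calls],
        "subtype": [c.subtype for c in calls],
    })


def cross_tabulate(calls: list[SubtypeCall],
                   external_labels: Mapping[str, str]) -> dict:
    """Contingency table of subtype vs an external labeling plus a chi-square test.

    Returns counts, row proportions, and the test result (None, with a
    warning, when the table is degenerate in either dimension).
    """
    from metabosub.mutation import chi2_on_table  # local import: no cycle at module load

    overlap = [c for c in calls if c.sample_id in external_labels]
    if not overlap:
        raise ValidationError("no overlapping samples between labelings")
    rows = sorted({c.subtype for c in overlap}, key=SUBTYPES.index)
    cols = sorted({external_labels[c.sample_id] for c in overlap})
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for c in overlap:
        counts.loc[c.subtype, external_labels[c.sample_id]] += 1
    proportions = counts.div(counts.sum(axis=1), axis=0)
    if len(rows) < 2 or len(cols) < 2:
        logger.warning("degenerate contingency table (%dx%d); test skipped",
                       len(rows), len(cols))
        test = None
    else:
        statistic, p_value = chi2_on_table(counts.to_numpy())
        test = {"statistic": statistic, "p_value": p_value,
                "df": (len(rows) - 1) * (len(cols) - 1)}
    return {"counts": counts, "proportions": proportions, "test": test}
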