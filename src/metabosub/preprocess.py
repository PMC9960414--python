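"""Normalization, purity filtering, fold-change gene selection, centering.

The working expression scale downstream of :func:`tpm_log_transform` is
log10(TPM + 1); the quadrant subtype rule requires gene-wise centering so
that a score of 0 is cohort-relative (see :mod:`metabosub.subtyping`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from metabosub.data_io import ClinicalTable, ExpressionMatrix
from metabosub.errors import ValidationError

logger = logging.getLogger(__name__)

LOG2_PER_LOG10 = np.log2(10.0)


@dataclass
class PreprocessConfig:
    purity_min: float = 0.30
    de_log2fc_min: float = 1.0
    centering: str = "median"
    scaling: str = "sd"

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity_min <= 1.0:
            raise ValidationError("purity_min must lie in [0, 1]")
        if self.centering not in ("median", "mean"):
            raise ValidationError(f"unknown centering {self.centering!r}")
        if self.scaling not in ("none", "sd", "mad"):
            raise ValidationError(f"unknown scaling {self.scaling!r}")


def tpm_log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Map expression v -> log10(v + 1) after per-sample TPM rescaling of counts.

    Counts input is column-rescaled to sum to 1e6 (gene lengths are assumed
    pre-normalized; no length file is used). TPM input is transformed as-is.
    """
    if expr.scale_tag not in ("counts", "tpm"):
        raise ValidationError(f"expected counts or tpm input, got {expr.scale_tag!r}")
    values = np.asarray(expr.values, dtype=float)
    if np.any(values < 0):
        raise ValidationError("negative expression values cannot be log-transformed")
    if expr.scale_tag == "counts":
        totals = values.sum(axis=0)
        totals[totals == 0] = 1.0
        values = values / totals * 1e6
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids),
                            np.log10(values + 1.0), "log_tpm")


def filter_low_purity(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    purity_min: float = 0.30,
) -> tuple[ExpressionMatrix, ClinicalTable, dict]:
    """Drop samples whose tumor purity is strictly below ``purity_min``.

    Samples with missing purity are retained and counted in the report.
    """
    cdf = clinical.df.set_index("sample_id")
    missing_rows = [s for s in expr.sample_ids if s not in cdf.index]
    if missing_rows:
        raise ValidationError(f"expression samples without clinical rows: {missing_rows}")
    purity = cdf.loc[expr.sample_ids, "purity"]
    known_low = purity.notna() & (purity < purity_min)
    keep = [s for s, low in zip(expr.sample_ids, known_low) if not low]
    report = {
        "n_input": expr.n_samples,
        "n_kept": len(keep),
        "n_removed": int(known_low.sum()),
        "n_missing_purity": int(purity.isna().sum()),
        "purity_min": purity_min,
    }
    if not keep:
        logger.warning("purity filter removed every sample")
    return expr.subset_samples(keep), clinical.subset(keep), report


def select_de_genes(
    expr_log: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    de_log2fc_min: float = 1.0,
) -> list[str]:
    """Genes with |mean log2 difference| >= threshold between two sample groups.

    The matrix is on the log10 scale; differences are converted to log2 units
    before thresholding. The threshold is inclusive.
    """
    set_a, set_b = set(group_a), set(group_b)
    if not set_a or not set_b:
        raise ValidationError("both groups must be non-empty")
    if set_a & set_b:
        raise ValidationError(f"groups overlap: {sorted(set_a & set_b)}")
    df = expr_log.to_frame()
    mean_a = df[list(group_a)].mean(axis=1)
    mean_b = df[list(group_b)].mean(axis=1)
    log2fc = (mean_a - mean_b).abs() * LOG2_PER_LOG10
    return [g for g, fc in zip(df.index, log2fc) if fc >= de_log2fc_min]


def center_scale_genes(
    expr_log: ExpressionMatrix,
    centering: str = "median",
    scaling: str = "sd",
) -> ExpressionMatrix:
    """Gene-wise location (and optionally scale) normalization.

    Constant gene rows are centered to 0 and left unscaled (scale treated as
    1), with a warning.
    """
    if expr_log.n_samples < 2:
        raise ValidationError("center_scale_genes requires >= 2 samples")
    values = np.asarray(expr_log.values, dtype=float)
    if centering == "median":
        center = np.median(values, axis=1, keepdims=True)
    elif centering == "mean":
        center = values.mean(axis=1, keepdims=True)
    else:
        raise ValidationError(f"unknown centering {centering!r}")
    centered = values - center

    if scaling == "none":
        scale = np.ones((expr_log.n_genes, 1))
    elif scaling == "sd":
        scale = values.std(axis=1, ddof=1, keepdims=True)
    elif scaling == "mad":
        scale = np.median(np.abs(centered), axis=1, keepdims=True)
    else:
        raise ValidationError(f"unknown scaling {scaling!r}")
    constant = scale[:, 0] == 0
    if constant.any():
        names = [g for g, c in zip(expr_log.gene_ids, constant) if c]
        logger.warning("constant gene rows left unscaled: %s", names)
        scale[constant] = 1.0
    return ExpressionMatrix(list(expr_log.gene_ids), list(expr_log.sample_ids),
                            centered / scale, "centered")
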