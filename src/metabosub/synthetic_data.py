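"""Synthetic cohort generator with planted metabolic-subtype structure.

Expression is drawn as Gaussian on the log10(TPM+1) scale and back-transformed
to TPM so the preprocessing log transform is exercised. Core glycolytic genes
are mean-shifted up in glycolytic and mixed samples and down otherwise;
core cholesterogenic genes analogously for cholesterogenic and mixed samples;
non-core genes are pure noise. Survival is exponential per subtype with
uniform censoring; mutations are per-(gene, subtype) Bernoulli; copy-number
segments are drawn per sample over the panel genes so the SEG-to-gene mapping
path is testable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from metabosub.data_io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneCoordinates,
    GeneSet,
    MutationTable,
    SegmentTable,
)
from metabosub.errors import ValidationError
from metabosub.subtyping import SUBTYPES

#: default per-subtype mutation probabilities, order (quiescent, glycolytic,
#: cholesterogenic, mixed); TP53 highest overall, CDKN2A most differential
DEFAULT_MUTATION_FREQS: dict[str, tuple[float, float, float, float]] = {
    "TP53": (0.65, 0.80, 0.75, 0.80),
    "CDKN2A": (0.05, 0.45, 0.10, 0.40),
    "PIK3CA": (0.15, 0.25, 0.20, 0.25),
    "LRP1B": (0.15, 0.20, 0.15, 0.25),
    "FLG": (0.10, 0.15, 0.20, 0.15),
}

#: proportions follow the observed HNSCC split (quiescent largest)
DEFAULT_PROPORTIONS = (0.36, 0.23, 0.21, 0.20)


@dataclass
class SyntheticCohortConfig:
    n_samples: int = 480
    subtype_proportions: tuple[float, float, float, float] = DEFAULT_PROPORTIONS
    n_gly_genes: int = 29
    n_chol_genes: int = 24
    n_core_gly: int = 12
    n_core_chol: int = 16
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_log_tpm: float = 3.0
    baseline_hazards: tuple[float, float, float, float] = (0.005, 0.02, 0.015, 0.02)
    censor_rate: float = 0.3
    mutation_freqs: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_FREQS))
    cnv_amp_rate: float = 0.10
    cnv_del_rate: float = 0.10
    n_neutral_segments: int = 2
    purity_range: tuple[float, float] = (0.2, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValidationError("subtype proportions must sum to 1")
        if any(p < 0 for p in self.subtype_proportions):
            raise ValidationError("subtype proportions must be non-negative")
        if min(self.n_samples, self.n_gly_genes, self.n_chol_genes,
               self.n_core_gly, self.n_core_chol) <= 0:
            raise ValidationError("all counts must be positive")
        if self.n_core_gly > self.n_gly_genes or self.n_core_chol > self.n_chol_genes:
            raise ValidationError("core sizes exceed gene-set sizes")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValidationError("effect_size must be >= 0 and noise_sd > 0")
        if not all(np.isfinite(self.baseline_hazards)) or min(self.baseline_hazards) <= 0:
            raise ValidationError("hazards must be finite and positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValidationError("censor_rate must lie in [0, 1)")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    mutations: MutationTable
    segments: SegmentTable
    gene_coords: GeneCoordinates
    gene_sets: tuple[GeneSet, GeneSet]
    truth_subtypes: pd.Series       # sample_id -> planted subtype
    truth_core_genes: pd.Series     # gene -> core membership flag

    def __post_init__(self) -> None:
        ids = set(self.expression.sample_ids)
        if set(self.clinical.sample_ids) != ids:
            raise ValidationError("clinical sample ids differ from expression")
        if set(self.truth_subtypes.index) != ids:
            raise ValidationError("truth does not cover every sample")


def _subtype_assignment(config: SyntheticCohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic counts per subtype (largest-remainder), shuffled order."""
    n = config.n_samples
    raw = np.array(config.subtype_proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    assignment = np.repeat(np.arange(4), counts)
    return assignment[rng.permutation(n)]


def generate_cohort(config: SyntheticCohortConfig,
                    sample_prefix: str = "S") -> SyntheticCohort:
    """Generate a full synthetic cohort; identical seed gives identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(1, n + 1)]
    subtype_idx = _subtype_assignment(config, rng)
    subtypes = np.array(SUBTYPES)[subtype_idx]

    gly_genes = [f"GLY{i:03d}" for i in range(1, config.n_gly_genes + 1)]
    chol_genes = [f"CHOL{i:03d}" for i in range(1, config.n_chol_genes + 1)]
    gly_core = set(gly_genes[:config.n_core_gly])
    chol_core = set(chol_genes[:config.n_core_chol])
    genes = gly_genes + chol_genes

    gly_up = np.isin(subtypes, ("glycolytic", "mixed"))
    chol_up = np.isin(subtypes, ("cholesterogenic", "mixed"))
    shift = config.effect_size * config.noise_sd
    log_tpm = np.empty((len(genes), n))
    for i, gene in enumerate(genes):
        row = config.baseline_log_tpm + rng.normal(0.0, config.noise_sd, size=n)
        if gene in gly_core:
            row += np.where(gly_up, shift, -shift)
        elif gene in chol_core:
            row += np.where(chol_up, shift, -shift)
        log_tpm[i] = row
    tpm = np.maximum(np.power(10.0, log_tpm) - 1.0, 0.0)
    expression = ExpressionMatrix(genes, sample_ids, tpm, "tpm")

    hazards = np.array(config.baseline_hazards)[subtype_idx]
    event_times = rng.exponential(1.0 / hazards)
    censored = rng.random(n) < config.censor_rate
    observed = np.where(censored, rng.uniform(0.0, event_times), event_times)
    lo, hi = config.purity_range
    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": sample_ids,
        "os_months": observed,
        "os_event": (~censored).astype(int),
        "purity": rng.uniform(lo, hi, size=n),
        "stage": rng.choice(["I", "II", "III", "IV"], size=n),
        "grade": rng.choice(["G1", "G2", "G3"], size=n),
        "age": rng.integers(30, 85, size=n),
        "sex": rng.choice(["F", "M"], size=n),
        "smoking": rng.choice(["never", "former", "current"], size=n),
    }))

    panel = list(config.mutation_freqs)
    gene_coords = GeneCoordinates(pd.DataFrame({
        "gene": panel,
        "chrom": ["1"] * len(panel),
        "start": [100_001 + 200_000 * i for i in range(len(panel))],
        "end": [150_000 + 200_000 * i for i in range(len(panel))],
    }))
    coords_by_gene = gene_coords.df.set_index("gene")

    mut_rows = []
    for gene in panel:
        probs = np.array(config.mutation_freqs[gene])[subtype_idx]
        hit = rng.random(n) < probs
        start = int(coords_by_gene.loc[gene, "start"])
        end = int(coords_by_gene.loc[gene, "end"])
        for i in np.flatnonzero(hit):
            mut_rows.append({
                "sample_id": sample_ids[i],
                "gene": gene,
                "variant_class": "SNV" if rng.random() < 0.8 else "INDEL",
                "chrom": "1",
                "pos": int(rng.integers(start, end + 1)),
            })
    mutations = MutationTable(pd.DataFrame(
        mut_rows, columns=["sample_id", "gene", "variant_class", "chrom", "pos"]))

    seg_rows = []
    for i, sample in enumerate(sample_ids):
        for gene in panel:
            r = rng.random()
            if r < config.cnv_amp_rate:
                mean = rng.uniform(0.3, 1.0)
            elif r < config.cnv_amp_rate + config.cnv_del_rate:
                mean = -rng.uniform(0.3, 1.0)
            else:
                continue
            start = int(coords_by_gene.loc[gene, "start"])
            end = int(coords_by_gene.loc[gene, "end"])
            pad = int(rng.integers(0, 20_000))
            seg_rows.append({"sample_id": sample, "chrom": "1",
                             "start": max(1, start - pad), "end": end + pad,
                             "num_probes": int(rng.integers(10, 200),),
                             "seg_mean": float(mean)})
        for _ in range(config.n_neutral_segments):
            start = int(rng.integers(1, 2_000_000))
            seg_rows.append({"sample_id": sample, "chrom": "1",
                             "start": start, "end": start + int(rng.integers(1, 50_000)),
                             "num_probes": int(rng.integers(10, 200)),
                             "seg_mean": float(rng.uniform(-0.15, 0.15))})
    segments = SegmentTable(pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end",
                           "num_probes", "seg_mean"]))

    gene_sets = (GeneSet("GLYCOLYSIS", tuple(gly_genes)),
                 GeneSet("CHOLESTEROL_BIOSYNTHESIS", tuple(chol_genes)))
    truth_subtypes = pd.Series(subtypes, index=sample_ids, name="subtype")
    truth_core = pd.Series({g: (g in gly_core or g in chol_core) for g in genes},
                           name="is_core")
    return SyntheticCohort(expression, clinical, mutations, segments,
                           gene_coords, gene_sets, truth_subtypes, truth_core)


def _derive_seed(parent_seed: int, code: str) -> int:
    digest = hashlib.sha256(f"{parent_seed}:{code}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**63)


def generate_pan_cancer(configs: Mapping[str, SyntheticCohortConfig],
                        parent_seed: int = 0) -> dict[str, SyntheticCohort]:
    """Independent cohorts keyed by cancer code with disjoint sample ids.

    Per-cohort seeds are derived deterministically from the parent seed and
    the cancer code; each config's own seed field is overridden.
    """
    if not configs:
        raise ValidationError("at least one cohort config required")
    codes = list(configs)
    if len(set(codes)) != len(codes):
        raise ValidationError("duplicate cancer codes")
    cohorts = {}
    for code in codes:
        cfg = replace(configs[code], seed=_derive_seed(parent_seed, code))
        cohorts[code] = generate_cohort(cfg, sample_prefix=f"{code}-")
    return cohorts
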