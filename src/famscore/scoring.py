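"""Allele-count genetic score with per-SNP inheritance coding.

Each marker contributes points to an individual's score: under additive
coding the number of risk alleles carried (0, 1 or 2); under recessive coding
2 points for risk-allele homozygotes and 0 otherwise. The multilocus score S
is the sum over markers, so 0 <= S <= 2K for K markers. An individual with a
missing genotype at any scored marker has an undefined score and is excluded
from score-level analyses (no imputation).

Risk groups partition the score range with configurable cut points; the
defaults reproduce the low (<=4) / intermediate (5-6) / high (>=7) grouping
used with the four-SNP autism panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import PedigreeDataset, SnpDef
from .errors import ValidationError

DEFAULT_LOW_MAX = 4
DEFAULT_INTERMEDIATE_MAX = 6


@dataclass(frozen=True)
class ScoreModel:
    """Ordered marker definitions with risk coding; defines score arithmetic."""

    snps: tuple[SnpDef, ...]
    low_max: int = DEFAULT_LOW_MAX
    intermediate_max: int = DEFAULT_INTERMEDIATE_MAX

    def __post_init__(self):
        for snp in self.snps:
            if snp.risk_allele is None or snp.mode is None:
                raise ValidationError(
                    f"{snp.snp_id}: score model requires risk_allele and mode"
                )
        if not self.snps:
            raise ValidationError("score model has no markers")
        if self.low_max >= self.intermediate_max:
            raise ValidationError("risk-group cut points must increase")

    @property
    def max_score(self) -> int:
        return 2 * len(self.snps)

    def snp(self, snp_id: str) -> SnpDef:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(snp_id)


def code_snp(genotype: tuple[str, str] | None, snp: SnpDef) -> int | None:
    """Points contributed by one genotype under the marker's coding.

    Returns None for a missing genotype (undefined points, not an error).
    """
    if genotype is None:
        return None
    for a in genotype:
        if a not in (snp.allele_a, snp.allele_b):
            raise ValidationError(
                f"{snp.snp_id}: allele {a!r} not in {{{snp.allele_a!r}, "
                f"{snp.allele_b!r}}}"
            )
    n_risk = sum(1 for a in genotype if a == snp.risk_allele)
    if snp.mode == "recessive":
        return 2 if n_risk == 2 else 0
    return n_risk


def compute_score(
    genotypes: list[tuple[str, str] | None], model: ScoreModel
) -> int | None:
    """Multilocus score for one individual; None if any marker is missing."""
    if len(genotypes) != len(model.snps):
        raise ValidationError(
            f"got {len(genotypes)} genotypes for {len(model.snps)} markers"
        )
    total = 0
    for gt, snp in zip(genotypes, model.snps):
        pts = code_snp(gt, snp)
        if pts is None:
            return None
        total += pts
    return total


def assign_risk_group(
    score: int | None,
    low_max: int = DEFAULT_LOW_MAX,
    intermediate_max: int = DEFAULT_INTERMEDIATE_MAX,
) -> str | None:
    """Map a score to low / intermediate / high (None propagates)."""
    if score is None:
        return None
    if score <= low_max:
        return "low"
    if score <= intermediate_max:
        return "intermediate"
    return "high"


def score_table(dataset: PedigreeDataset, model: ScoreModel) -> pd.DataFrame:
    """Per-individual score table.

    Columns: family_id, individual_id, affection, is_index_case, score
    (nullable integer), risk_group. Marker order follows the score model, not
    the dataset.
    """
    cols = [dataset.snp_index(snp.snp_id) for snp in model.snps]
    records = []
    for i, ind in enumerate(dataset.individuals):
        gts = [dataset.genotype(i, j) for j in cols]
        s = compute_score(gts, model)
        records.append(
            {
                "family_id": ind.family_id,
                "individual_id": ind.individual_id,
                "affection": ind.affection,
                "is_index_case": ind.is_index_case,
                "score": s,
                "risk_group": assign_risk_group(s, model.low_max, model.intermediate_max),
            }
        )
    df = pd.DataFrame.from_records(records)
    df["score"] = df["score"].astype("Int64")
    return df


def score_distribution(snps: list[SnpDef] | tuple[SnpDef, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Exact population score distribution under HWE at the configured
    risk-allele frequencies.

    Convolves per-marker point distributions: additive markers contribute
    Binomial(2, p) points, recessive markers contribute 2·Bernoulli(p²).
    Returns (values 0..2K, probabilities).
    """
    pmf = np.array([1.0])
    for snp in snps:
        p = snp.risk_freq
        if p is None:
            raise ValidationError(f"{snp.snp_id}: risk_freq required")
        q = 1.0 - p
        if snp.mode == "recessive":
            per = np.array([1.0 - p * p, 0.0, p * p])
        else:
            per = np.array([q * q, 2 * p * q, p * p])
        pmf = np.convolve(pmf, per)
    values = np.arange(pmf.size)
    return values, pmf
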