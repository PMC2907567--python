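"""Data-quality gates for family genotype data.

Four gates are applied before any association analysis:

* exact Hardy-Weinberg equilibrium tests on founder genotype counts,
* Mendelian-inconsistency detection in parent-child trios, with wholesale
  exclusion of inconsistent families,
* per-SNP missingness reporting (flagging, not removal), and
* index-case selection: the oldest affected child per family is flagged and
  excluded from downstream analyses to reduce ascertainment bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .datatypes import MISSING_ALLELE, PedigreeDataset
from .errors import DegenerateInputError, ValidationError


@dataclass
class MendelInconsistency:
    family_id: str
    snp_id: str
    child_id: str


@dataclass
class SnpQc:
    snp_id: str
    founder_counts: tuple[int, int, int]  # (n_AA, n_Aa, n_aa) w.r.t. allele_a
    hwe_p: float | None
    missing_frac: float
    flagged_missing: bool


@dataclass
class QcReport:
    snp_qc: list[SnpQc] = field(default_factory=list)
    inconsistencies: list[MendelInconsistency] = field(default_factory=list)
    excluded_families: dict[str, str] = field(default_factory=dict)
    index_cases: dict[str, str] = field(default_factory=dict)  # family -> child
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "snp_qc": [
                {
                    "snp_id": s.snp_id,
                    "founder_counts": list(s.founder_counts),
                    "hwe_p": s.hwe_p,
                    "missing_frac": s.missing_frac,
                    "flagged_missing": s.flagged_missing,
                }
                for s in self.snp_qc
            ],
            "inconsistencies": [
                {"family_id": m.family_id, "snp_id": m.snp_id, "child_id": m.child_id}
                for m in self.inconsistencies
            ],
            "excluded_families": self.excluded_families,
            "index_cases": self.index_cases,
            "warnings": self.warnings,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Two-sided exact Hardy-Weinberg test on biallelic genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose probability does not exceed that of the
    observed configuration (the standard "sum of no-more-probable tables"
    convention, no mid-p adjustment).

    Parameters are the counts of the three genotypes (either homozygote
    order). Returns a p-value in (0, 1].
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValidationError("negative genotype count")
    n = n_aa_hom + n_het + n_bb_hom
    if n == 0:
        raise DegenerateInputError("all genotype counts zero")
    n_a = 2 * n_aa_hom + n_het  # minor/major roles don't matter below
    # heterozygote counts share the parity of n_a and satisfy the allele totals
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    if len(hets) == 1:
        return 1.0
    homs_a = (n_a - hets) // 2
    homs_b = n - hets - homs_a
    # P(het = h | allele counts) ∝ n! / (na! nb!) * 2^h / (ha! h! hb!) -- use logs
    logp = (
        hets * np.log(2.0)
        - gammaln(homs_a + 1)
        - gammaln(hets + 1)
        - gammaln(homs_b + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    # 1e-12 relative slack keeps ties counted despite floating-point noise
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _consistent(child: tuple[str, str], father: tuple[str, str],
                mother: tuple[str, str]) -> bool:
    c1, c2 = child
    return (c1 in father and c2 in mother) or (c2 in father and c1 in mother)


def mendel_check(dataset: PedigreeDataset) -> list[MendelInconsistency]:
    """Flag child genotypes impossible under Mendelian transmission.

    Only trios with the child and both parents genotyped at a marker are
    examined; trios with any missing genotype at that marker are skipped.
    """
    out: list[MendelInconsistency] = []
    for child_row, father_row, mother_row in dataset.iter_trios():
        for j, snp in enumerate(dataset.snps):
            c = dataset.genotype(child_row, j)
            f = dataset.genotype(father_row, j)
            m = dataset.genotype(mother_row, j)
            if c is None or f is None or m is None:
                continue
            if not _consistent(c, f, m):
                ind = dataset.individuals[child_row]
                out.append(
                    MendelInconsistency(ind.family_id, snp.snp_id, ind.individual_id)
                )
    return out


def _founder_rows(dataset: PedigreeDataset) -> list[int]:
    return [i for i, ind in enumerate(dataset.individuals) if ind.is_founder]


def apply_qc(
    dataset: PedigreeDataset, max_missing_per_snp: float = 0.05
) -> tuple[PedigreeDataset, QcReport]:
    """Run the QC gates and return (filtered dataset, report).

    Families with at least one Mendelian inconsistency are removed. SNPs at or
    above the missingness threshold are flagged in the report but retained
    (the remedy for high missingness is re-genotyping, not dropping the
    marker). Founder HWE p-values are reported per SNP. Missing fractions are
    computed over individuals with at least one non-missing genotype, so
    deliberately ungenotyped siblings do not count against a marker.
    """
    report = QcReport()
    report.inconsistencies = mendel_check(dataset)
    bad_families = sorted({m.family_id for m in report.inconsistencies})
    for fam in bad_families:
        report.excluded_families[fam] = "mendelian_inconsistency"

    keep_rows = [
        i
        for i, ind in enumerate(dataset.individuals)
        if ind.family_id not in report.excluded_families
    ]
    if not keep_rows:
        raise DegenerateInputError("QC excluded every family")
    filtered = PedigreeDataset(
        snps=list(dataset.snps),
        individuals=[replace(dataset.individuals[i]) for i in keep_rows],
        genotypes=dataset.genotypes[keep_rows],
        provenance={**dataset.provenance, "qc": "applied"},
        age_semantics=dataset.age_semantics,
        warnings=list(dataset.warnings),
    )

    missing = filtered.missing_mask()
    genotyped_rows = ~missing.all(axis=1)
    founders = [i for i in _founder_rows(filtered)]
    for j, snp in enumerate(filtered.snps):
        counts = [0, 0, 0]  # AA, Aa, aa w.r.t. allele_a
        for i in founders:
            gt = filtered.genotype(i, j)
            if gt is None:
                continue
            counts[sum(1 for a in gt if a != snp.allele_a)] += 1
        denom = int(genotyped_rows.sum())
        frac = float(missing[genotyped_rows, j].mean()) if denom else 1.0
        try:
            hwe_p = hwe_exact_test(*counts) if sum(counts) else None
        except DegenerateInputError:
            hwe_p = None
        report.snp_qc.append(
            SnpQc(
                snp_id=snp.snp_id,
                founder_counts=tuple(counts),
                hwe_p=hwe_p,
                missing_frac=frac,
                flagged_missing=frac >= max_missing_per_snp,
            )
        )
    return filtered, report


def select_index_cases(
    dataset: PedigreeDataset, report: QcReport | None = None
) -> PedigreeDataset:
    """Flag the oldest affected child per family as the index case.

    "Oldest" follows the dataset's age semantics: maximum age, or minimum
    birth order. Ties (or wholly missing ordering information) fall back to
    the lexicographically smallest individual ID, with a warning. Families
    with no affected child raise :class:`ValidationError`.
    """
    out = dataset.copy()
    fams = out.families()
    for fam, rows in fams.items():
        affected_children = [
            i
            for i in rows
            if not out.individuals[i].is_founder
            and out.individuals[i].affection == "affected"
        ]
        if not affected_children:
            raise ValidationError(f"family {fam!r} has no affected child")

        def ordinal(i: int) -> float | None:
            return out.individuals[i].birth_order_or_age

        known = [i for i in affected_children if ordinal(i) is not None]
        if known:
            if out.age_semantics == "age":
                best = max(ordinal(i) for i in known)
            else:
                best = min(ordinal(i) for i in known)
            candidates = [i for i in known if ordinal(i) == best]
        else:
            candidates = affected_children
        if len(candidates) > 1 or not known:
            out.warnings.append(
                f"family {fam}: index case chosen by ID tie-break"
            )
        index_row = min(candidates, key=lambda i: out.individuals[i].individual_id)
        out.individuals[index_row].is_index_case = True
        if report is not None:
            report.index_cases[fam] = out.individuals[index_row].individual_id
    return out
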