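"""Matched case/pseudocontrol construction from untransmitted parental alleles.

For each affected, non-index child with a fully genotyped trio, a single
pseudocontrol genotype is built per marker from the two parental alleles NOT
transmitted to the child. The pseudocontrol is uniquely determined as a
multiset regardless of phase ambiguity: it is the parental allele multiset
minus the child's alleles. Case and pseudocontrol are matched 1:1 and scored
with the same model; multiple affected siblings in one family yield multiple
matched sets sharing a family ID, handled downstream by family-clustered
robust variance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .datatypes import PedigreeDataset
from .errors import DegenerateInputError, MendelianInconsistencyError
from .qc import _consistent
from .scoring import ScoreModel, code_snp, compute_score


@dataclass
class MatchedSet:
    """An affected child paired with its untransmitted-allele pseudocontrol."""

    family_id: str
    case_id: str
    case_genotypes: list[tuple[str, str]]
    pseudo_genotypes: list[tuple[str, str]]
    case_score: int
    pseudo_score: int
    case_points: list[int]
    pseudo_points: list[int]


def untransmitted_genotype(
    father_gt: tuple[str, str],
    mother_gt: tuple[str, str],
    child_gt: tuple[str, str],
) -> tuple[str, str]:
    """The two parental alleles not transmitted to the child, as a sorted pair.

    Raises :class:`MendelianInconsistencyError` if the child's genotype cannot
    arise from one allele per parent.
    """
    if not _consistent(child_gt, father_gt, mother_gt):
        raise MendelianInconsistencyError(
            f"child {child_gt} impossible from parents {father_gt} x {mother_gt}"
        )
    pool = Counter(father_gt) + Counter(mother_gt)
    pool.subtract(Counter(child_gt))
    pair = sorted(pool.elements())
    assert len(pair) == 2
    return (pair[0], pair[1])


def build_matched_sets(
    dataset: PedigreeDataset, model: ScoreModel
) -> list[MatchedSet]:
    """One matched set per eligible case: affected, non-index, complete trio.

    A trio is eligible for score-level analysis only if the child and both
    parents are genotyped at every scored marker (no imputation). Raises
    :class:`DegenerateInputError` if no case is eligible.
    """
    cols = [dataset.snp_index(snp.snp_id) for snp in model.snps]
    sets: list[MatchedSet] = []
    for child_row, father_row, mother_row in dataset.iter_trios():
        child = dataset.individuals[child_row]
        if child.affection != "affected" or child.is_index_case:
            continue
        case_gts, pseudo_gts = [], []
        complete = True
        for j in cols:
            c = dataset.genotype(child_row, j)
            f = dataset.genotype(father_row, j)
            m = dataset.genotype(mother_row, j)
            if c is None or f is None or m is None:
                complete = False
                break
            case_gts.append(c)
            pseudo_gts.append(untransmitted_genotype(f, m, c))
        if not complete:
            continue
        case_score = compute_score(case_gts, model)
        pseudo_score = compute_score(pseudo_gts, model)
        sets.append(
            MatchedSet(
                family_id=child.family_id,
                case_id=child.individual_id,
                case_genotypes=case_gts,
                pseudo_genotypes=pseudo_gts,
                case_score=case_score,
                pseudo_score=pseudo_score,
                case_points=[code_snp(g, s) for g, s in zip(case_gts, model.snps)],
                pseudo_points=[code_snp(g, s) for g, s in zip(pseudo_gts, model.snps)],
            )
        )
    if not sets:
        raise DegenerateInputError("no eligible case/pseudocontrol sets")
    return sets


def build_single_snp_sets(
    dataset: PedigreeDataset, model: ScoreModel, snp_id: str
) -> list[MatchedSet]:
    """Matched sets for one marker, using every complete trio at that marker.

    Families missing a parental genotype at some other marker still
    contribute here, maximising per-marker data without imputation. The
    returned sets carry single-marker genotype lists and points; their
    ``case_score``/``pseudo_score`` are the per-marker points.
    """
    snp = model.snp(snp_id)
    j = dataset.snp_index(snp_id)
    sets: list[MatchedSet] = []
    for child_row, father_row, mother_row in dataset.iter_trios():
        child = dataset.individuals[child_row]
        if child.affection != "affected" or child.is_index_case:
            continue
        c = dataset.genotype(child_row, j)
        f = dataset.genotype(father_row, j)
        m = dataset.genotype(mother_row, j)
        if c is None or f is None or m is None:
            continue
        pseudo = untransmitted_genotype(f, m, c)
        cp, pp = code_snp(c, snp), code_snp(pseudo, snp)
        sets.append(
            MatchedSet(
                family_id=child.family_id,
                case_id=child.individual_id,
                case_genotypes=[c],
                pseudo_genotypes=[pseudo],
                case_score=cp,
                pseudo_score=pp,
                case_points=[cp],
                pseudo_points=[pp],
            )
        )
    if not sets:
        raise DegenerateInputError(f"no complete trios at {snp_id}")
    return sets


def matched_set_table(sets: list[MatchedSet], model: ScoreModel) -> pd.DataFrame:
    """Matched sets as a flat table (one row per set)."""
    rows = []
    for s in sets:
        row = {
            "family_id": s.family_id,
            "case_id": s.case_id,
            "case_score": s.case_score,
            "pseudo_score": s.pseudo_score,
        }
        for snp, cp, pp in zip(model.snps, s.case_points, s.pseudo_points):
            row[f"case_{snp.snp_id}"] = cp
            row[f"pseudo_{snp.snp_id}"] = pp
        rows.append(row)
    return pd.DataFrame(rows)
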