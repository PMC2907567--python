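"""QC gates: exact HWE test, Mendelian checks, exclusions, index cases."""

import math
from fractions import Fraction

import numpy as np
import pytest

from famscore.datatypes import Individual, PedigreeDataset, SnpDef
from famscore.errors import DegenerateInputError, ValidationError
from famscore.qc import apply_qc, hwe_exact_test, mendel_check, select_index_cases
from famscore.simulate import SimConfig, inject_errors, simulate_families


def hwe_exact_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Independent exact-rational enumeration of the conditional distribution
    of the heterozygote count given the allele counts."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    probs = {}
    for h in range(na % 2, min(na, 2 * n - na) + 1, 2):
        ha, hb = (na - h) // 2, n - h - (na - h) // 2
        probs[h] = Fraction(
            math.factorial(n) * 2**h, math.factorial(ha) * math.factorial(h) * math.factorial(hb)
        )
    total = sum(probs.values())
    obs = probs[n_ab]
    return float(sum(p for p in probs.values() if p <= obs) / total)


def test_hwe_examples():
    assert hwe_exact_test(50, 0, 0) == 1.0  # monomorphic: single configuration
    assert hwe_exact_test(0, 100, 0) < 1e-6  # extreme heterozygote excess
    assert hwe_exact_test(25, 50, 25) > 0.9  # perfect HWE proportions


@pytest.mark.parametrize(
    "counts",
    [(25, 50, 25), (0, 100, 0), (5, 20, 75), (1, 1, 1), (40, 5, 2), (0, 3, 17)],
)
def test_hwe_matches_exact_enumeration_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(hwe_exact_oracle(*counts), rel=1e-9)


def test_hwe_all_zero_counts_rejected():
    with pytest.raises(DegenerateInputError):
        hwe_exact_test(0, 0, 0)
    with pytest.raises(ValidationError):
        hwe_exact_test(-1, 2, 3)


def test_hwe_type_i_error_is_conservative(rng):
    """On HWE-simulated founder genotypes the exact test rejects at <= 5%."""
    p = 0.3
    n = 200
    genos = rng.multinomial(n, [p * p, 2 * p * (1 - p), (1 - p) ** 2], size=10_000)
    pvals = np.array([hwe_exact_test(*g) for g in genos])
    frac = (pvals < 0.05).mean()
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 10_000)


def _trio_dataset(father_gt, mother_gt, child_gt):
    snps = [SnpDef("s1", "1", "A", "C")]
    inds = [
        Individual("f", "dad", sex="male"),
        Individual("f", "mom", sex="female"),
        Individual("f", "kid", "dad", "mom", affection="affected"),
    ]
    missing = ("0", "0")
    geno = [
        [father_gt or missing],
        [mother_gt or missing],
        [child_gt or missing],
    ]
    return PedigreeDataset(snps, inds, geno)


@pytest.mark.parametrize(
    "father, mother, child, n_flags",
    [
        (("A", "A"), ("A", "A"), ("A", "C"), 1),  # impossible transmission
        (("A", "C"), ("A", "C"), ("C", "C"), 0),
        (None, ("C", "C"), ("C", "C"), 0),  # missing parent: trio skipped
    ],
)
def test_mendel_check(father, mother, child, n_flags):
    flags = mendel_check(_trio_dataset(father, mother, child))
    assert len(flags) == n_flags
    if n_flags:
        assert (flags[0].family_id, flags[0].child_id) == ("f", "kid")


def test_apply_qc_excludes_inconsistent_families(agre_dataset):
    tampered, log = inject_errors(agre_dataset, n_mendel_errors=1, seed=5)
    n_fam = len(tampered.families())
    filtered, report = apply_qc(tampered)
    assert len(filtered.families()) == n_fam - 1
    assert list(report.excluded_families) == [log["mendel"][0]["family_id"]]


def test_injected_errors_are_exactly_recovered(agre_dataset):
    tampered, log = inject_errors(agre_dataset, n_mendel_errors=5, seed=6)
    flags = mendel_check(tampered)
    found = {(f.family_id, f.child_id, f.snp_id) for f in flags}
    injected = {
        (e["family_id"], e["child_id"], e["snp_id"]) for e in log["mendel"]
    }
    assert found == injected


def test_apply_qc_clean_identity_and_idempotence(seattle_dataset):
    once, report = apply_qc(seattle_dataset)
    assert not report.excluded_families and not report.inconsistencies
    assert once.equals(seattle_dataset)
    twice, _ = apply_qc(once)
    assert twice.equals(once)


def test_high_missingness_flagged_not_removed(seattle_dataset):
    n_pos = sum(
        1 for i in range(seattle_dataset.n_individuals)
        if seattle_dataset.genotype(i, 0) is not None
    )
    # push marker 0 over the 5% threshold
    tampered, log = inject_errors(
        seattle_dataset, n_missing=int(0.2 * seattle_dataset.n_individuals), seed=9
    )
    filtered, report = apply_qc(tampered)
    assert filtered.n_snps == tampered.n_snps  # flag only, never dropped
    assert any(s.flagged_missing for s in report.snp_qc)


def test_qc_reports_founder_hwe(seattle_dataset):
    _, report = apply_qc(seattle_dataset)
    for snp_qc in report.snp_qc:
        assert 0 < snp_qc.hwe_p <= 1
        assert sum(snp_qc.founder_counts) == 2 * len(seattle_dataset.families())


def test_select_index_case_oldest_affected():
    snps = [SnpDef("s1", "1", "A", "C")]
    inds = [
        Individual("f", "1", sex="male"),
        Individual("f", "2", sex="female"),
        Individual("f", "3", "1", "2", affection="affected", birth_order_or_age=7),
        Individual("f", "4", "1", "2", affection="affected", birth_order_or_age=10),
        Individual("f", "5", "1", "2", affection="unaffected", birth_order_or_age=12),
    ]
    geno = [[("A", "A")]] * 5
    ds = select_index_cases(PedigreeDataset(snps, inds, geno))
    by_id = {i.individual_id: i for i in ds.individuals}
    assert by_id["4"].is_index_case  # the 10-year-old, not the unaffected 12-year-old
    assert not by_id["3"].is_index_case and not by_id["5"].is_index_case


def test_select_index_case_single_affected_and_tie_break():
    snps = [SnpDef("s1", "1", "A", "C")]
    geno3 = [[("A", "A")]] * 3
    single = PedigreeDataset(
        snps,
        [
            Individual("f", "1", sex="male"),
            Individual("f", "2", sex="female"),
            Individual("f", "3", "1", "2", affection="affected"),
        ],
        geno3,
    )
    assert select_index_cases(single).individuals[2].is_index_case

    tied = PedigreeDataset(
        snps,
        [
            Individual("f", "1", sex="male"),
            Individual("f", "2", sex="female"),
            Individual("f", "4", "1", "2", affection="affected"),
            Individual("f", "3", "1", "2", affection="affected"),
        ],
        [[("A", "A")]] * 4,
    )
    out = select_index_cases(tied)
    flagged = [i.individual_id for i in out.individuals if i.is_index_case]
    assert flagged == ["3"]  # lowest ID wins when ages are missing
    assert any("tie-break" in w for w in out.warnings)


def test_family_without_affected_child_rejected():
    snps = [SnpDef("s1", "1", "A", "C")]
    ds = PedigreeDataset(
        snps,
        [
            Individual("f", "1", sex="male"),
            Individual("f", "2", sex="female"),
            Individual("f", "3", "1", "2", affection="unaffected"),
        ],
        [[("A", "A")]] * 3,
    )
    with pytest.raises(ValidationError):
        select_index_cases(ds)
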