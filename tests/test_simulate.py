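"""Synthetic multiplex-family generator: determinism, calibration,
transmission and ascertainment properties, error injection."""

import numpy as np
import pytest
from scipy.special import expit

from famscore.errors import RunawayRejectionError, ValidationError
from famscore.panels import autism_four_snp_panel
from famscore.scoring import score_distribution
from famscore.simulate import (
    SimConfig,
    calibrate_baseline,
    inject_errors,
    simulate_families,
    simulate_population,
)


def test_same_seed_identical_datasets():
    cfg = dict(n_families=60, ascertainment="agre_like", seed=9)
    a = simulate_families(SimConfig(**cfg))
    b = simulate_families(SimConfig(**cfg))
    assert a.equals(b)
    c = simulate_families(SimConfig(**{**cfg, "seed": 10}))
    assert not a.equals(c)


def test_calibrated_baseline_hits_target_prevalence():
    snps = autism_four_snp_panel()
    betas = np.full(4, np.log(1.33))
    alpha = calibrate_baseline(snps, betas, 0.10)
    values, pmf = score_distribution(snps)
    assert float(pmf @ expit(alpha + betas[0] * values)) == pytest.approx(0.10,
                                                                          abs=1e-10)
    _, affected = simulate_population(150_000, snps, np.log(1.33).item(), 0.10,
                                      seed=4)
    assert affected.mean() == pytest.approx(0.10, abs=0.005)


def test_parental_frequencies_match_configuration_unascertained():
    snps = autism_four_snp_panel()
    ds = simulate_families(
        SimConfig(n_families=2000, ascertainment="none", seed=11)
    )
    founders = [i for i, ind in enumerate(ds.individuals) if ind.is_founder]
    for j, snp in enumerate(snps):
        alleles = ds.genotypes[founders, j, :]
        freq = (alleles == snp.risk_allele).mean()
        se = np.sqrt(snp.risk_freq * (1 - snp.risk_freq) / (2 * len(founders)))
        assert freq == pytest.approx(snp.risk_freq, abs=4 * se)


def test_heterozygous_parents_transmit_risk_allele_half_the_time():
    ds = simulate_families(
        SimConfig(n_families=1500, ascertainment="none", per_point_log_or=0.0,
                  seed=12)
    )
    transmitted = total = 0
    for child_row, father_row, _ in ds.iter_trios():
        for j, snp in enumerate(ds.snps):
            f = ds.genotype(father_row, j)
            if f is None or f[0] == f[1]:
                continue
            c = ds.genotype(child_row, j)
            m_gt = ds.genotype(ds.row(ds.individuals[child_row].family_id, "2"), j)
            # identify the paternal allele unambiguously when the mother is
            # homozygous: the child allele not forced by the mother
            if m_gt[0] != m_gt[1]:
                continue
            maternal = m_gt[0]
            paternal = c[1] if c[0] == maternal else c[0]
            transmitted += paternal == snp.risk_allele
            total += 1
    assert total > 1000
    se = np.sqrt(0.25 / total)
    assert transmitted / total == pytest.approx(0.5, abs=4 * se)


def test_ascertainment_enriches_parental_risk_alleles():
    snps = autism_four_snp_panel()
    asc = simulate_families(
        SimConfig(n_families=800, ascertainment="agre_like", seed=13)
    )
    founders = [i for i, ind in enumerate(asc.individuals) if ind.is_founder]
    enriched = 0
    for j, snp in enumerate(snps):
        freq = (asc.genotypes[founders, j, :] == snp.risk_allele).mean()
        enriched += freq > snp.risk_freq
    assert enriched >= 3  # directional: risk-loaded parents in multiplex families


def test_null_effect_balances_sibling_score_distributions():
    ds = simulate_families(
        SimConfig(n_families=1200, ascertainment="seattle_like",
                  per_point_log_or=0.0, seed=14)
    )
    from famscore.scoring import ScoreModel, score_table

    model = ScoreModel(tuple(autism_four_snp_panel()))
    df = score_table(ds, model)
    kids = df[df["affection"].isin(["affected", "unaffected"])].dropna(
        subset=["score"]
    )
    aff = kids.loc[kids["affection"] == "affected", "score"].astype(float)
    unaff = kids.loc[kids["affection"] == "unaffected", "score"].astype(float)
    pooled_se = np.sqrt(aff.var() / len(aff) + unaff.var() / len(unaff))
    assert abs(aff.mean() - unaff.mean()) < 4 * pooled_se


def test_agre_like_masks_unaffected_genotypes(agre_dataset):
    for i, ind in enumerate(agre_dataset.individuals):
        if ind.affection == "unaffected" and not ind.is_founder:
            assert agre_dataset.missing_mask()[i].all()


def test_mask_override_keeps_controls_genotyped():
    ds = simulate_families(
        SimConfig(n_families=40, ascertainment="agre_like",
                  mask_unaffected=False, seed=15)
    )
    unaff = [
        i for i, ind in enumerate(ds.individuals)
        if ind.affection == "unaffected" and not ind.is_founder
    ]
    if unaff:
        assert not ds.missing_mask()[unaff].any()


def test_runaway_rejection_raises():
    with pytest.raises(RunawayRejectionError):
        simulate_families(
            SimConfig(n_families=10, ascertainment="agre_like",
                      target_prevalence=0.001, seed=16)
        )


def test_iq_independent_of_score(seattle_dataset, agre_model):
    from famscore.scoring import score_table

    df = score_table(seattle_dataset, agre_model)
    df["iq"] = [
        seattle_dataset.individuals[
            seattle_dataset.row(f, i)
        ].iq
        for f, i in zip(df["family_id"], df["individual_id"])
    ]
    kids = df.dropna(subset=["score", "iq"])
    aff = kids[kids["affection"] == "affected"]
    r = np.corrcoef(aff["score"].astype(float), aff["iq"])[0, 1]
    assert abs(r) < 4 / np.sqrt(len(aff))


class TestInjectErrors:
    def test_zero_injection_is_identity(self, seattle_dataset):
        out, log = inject_errors(seattle_dataset, 0, 0, seed=1)
        assert out.equals(seattle_dataset)
        assert log == {"mendel": [], "missing": []}

    def test_exact_counts_logged(self, seattle_dataset):
        out, log = inject_errors(seattle_dataset, 3, 7, seed=2)
        assert len(log["mendel"]) == 3 and len(log["missing"]) == 7
        n_missing_before = seattle_dataset.missing_mask().sum()
        assert out.missing_mask().sum() == n_missing_before + 7

    def test_infeasible_request_rejected(self, seattle_dataset):
        with pytest.raises(ValidationError):
            inject_errors(seattle_dataset, n_missing=10**7, seed=3)
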