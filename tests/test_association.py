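"""Conditional logistic and GEE fits, the OR ladder and the sibling
recurrence risk ratio."""

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from famscore.association import (
    category_or_table,
    fit_conditional_logistic,
    fit_gee_linear,
    fit_gee_logistic,
    lambda_locus,
    lambda_sibs,
)
from famscore.errors import DegenerateInputError, SeparationError, ValidationError
from famscore.panels import autism_four_snp_panel
from famscore.pipeline import _analysis_rows
from famscore.qc import select_index_cases
from famscore.simulate import SimConfig, simulate_families


@dataclass
class FakeSet:
    family_id: str
    case_score: float
    pseudo_score: float


def _sets(diffs, fams=None):
    fams = fams or [str(i) for i in range(len(diffs))]
    return [FakeSet(f, d, 0.0) for f, d in zip(fams, diffs)]


class TestConditionalLogistic:
    def test_balanced_differences_give_null_or(self):
        fit = fit_conditional_logistic(_sets([1, -1, 1, -1]), predictor="score")
        assert fit.beta == pytest.approx(0.0, abs=1e-10)
        assert fit.or_value == pytest.approx(1.0)

    def test_complete_separation_detected(self):
        with pytest.raises(SeparationError):
            fit_conditional_logistic(_sets([1, 1, 1, 1]), predictor="score")

    def test_no_informative_pairs_detected(self):
        with pytest.raises(DegenerateInputError):
            fit_conditional_logistic(_sets([0, 0, 0]), predictor="score")

    def test_matches_statsmodels_conditional_logit(self, agre_matched_sets):
        """Independent oracle: statsmodels ConditionalLogit on case/pseudo rows."""
        ours = fit_conditional_logistic(agre_matched_sets, predictor="score")
        y, x, grp = [], [], []
        for i, s in enumerate(agre_matched_sets):
            y += [1, 0]
            x += [s.case_score, s.pseudo_score]
            grp += [i, i]
        oracle = sm.ConditionalLogit(
            np.array(y), np.array(x, float)[:, None], groups=np.array(grp)
        ).fit(disp=0)
        assert ours.beta == pytest.approx(oracle.params[0], abs=1e-5)

    def test_duplication_invariance(self, agre_matched_sets):
        """k-fold sample replication leaves beta unchanged, halves the SE at k=4."""
        base = fit_conditional_logistic(agre_matched_sets, predictor="score")
        replicated = []
        for k in range(4):
            for s in agre_matched_sets:
                replicated.append(
                    FakeSet(f"{s.family_id}__rep{k}", s.case_score, s.pseudo_score)
                )
        rep = fit_conditional_logistic(replicated, predictor="score")
        assert rep.beta == pytest.approx(base.beta, abs=1e-9)
        assert rep.robust_se == pytest.approx(base.robust_se / 2.0, rel=1e-9)

    def test_recovers_generating_per_point_or(self):
        """Large pseudocontrol simulation recovers the generating OR 1.33."""
        from famscore.pseudocontrol import build_matched_sets
        from famscore.scoring import ScoreModel

        model = ScoreModel(tuple(autism_four_snp_panel()))
        ors = []
        for seed in range(4):
            ds = select_index_cases(
                simulate_families(
                    SimConfig(n_families=1200, ascertainment="agre_like",
                              target_prevalence=0.02, seed=300 + seed)
                )
            )
            fit = fit_conditional_logistic(
                build_matched_sets(ds, model), predictor="score"
            )
            ors.append(fit.or_value)
        assert np.mean(ors) == pytest.approx(1.33, abs=0.05)


class TestGee:
    def test_point_estimates_equal_ordinary_logistic_ml(self, seattle_dataset,
                                                        agre_model):
        rows = _analysis_rows(seattle_dataset, agre_model)
        gee = fit_gee_logistic(rows, predictor="score", covariates=["male"])
        X = sm.add_constant(rows[["score", "male"]].to_numpy(float))
        ml = sm.Logit(rows["affected"].to_numpy(float), X).fit(disp=0)
        np.testing.assert_allclose(
            gee.metadata["params"], ml.params, atol=1e-6
        )

    def test_single_class_outcome_rejected(self):
        rows = pd.DataFrame(
            {"affected": [1, 1, 1], "score": [2, 3, 4], "family_id": list("abc")}
        )
        with pytest.raises(DegenerateInputError):
            fit_gee_logistic(rows, predictor="score")

    def test_constant_predictor_rejected(self):
        rows = pd.DataFrame(
            {"affected": [1, 0, 1, 0], "score": [5, 5, 5, 5],
             "family_id": list("aabb")}
        )
        with pytest.raises(DegenerateInputError):
            fit_gee_logistic(rows, predictor="score")

    def test_linear_gee_exact_fit(self):
        rng = np.random.default_rng(1)
        score = rng.integers(2, 9, size=60).astype(float)
        rows = pd.DataFrame(
            {"iq": 2.0 * score, "score": score,
             "family_id": np.repeat([f"f{i}" for i in range(30)], 2)}
        )
        fit = fit_gee_linear(rows, outcome="iq", predictor="score")
        assert fit.beta == pytest.approx(2.0, abs=1e-8)
        assert fit.p_value < 1e-12

    def test_constant_linear_outcome_rejected(self):
        rows = pd.DataFrame(
            {"iq": [100.0] * 4, "score": [2.0, 3, 4, 5], "family_id": list("aabb")}
        )
        with pytest.raises(DegenerateInputError):
            fit_gee_linear(rows, outcome="iq", predictor="score")

    def test_single_cluster_warns(self):
        rows = pd.DataFrame(
            {"affected": [1, 0, 1, 0, 1, 0], "score": [6.0, 3, 5, 4, 7, 2],
             "family_id": ["f"] * 6}
        )
        with pytest.warns(UserWarning, match="single cluster"):
            fit_gee_logistic(rows, predictor="score")

    def test_rare_disease_designs_agree(self, agre_model):
        """Case/pseudocontrol and sibling case-control per-point estimates
        converge under the rare-disease regime."""
        from famscore.pseudocontrol import build_matched_sets

        ds = select_index_cases(
            simulate_families(
                SimConfig(n_families=1500, ascertainment="seattle_like",
                          mask_unaffected=False, target_prevalence=0.02, seed=55)
            )
        )
        clr = fit_conditional_logistic(
            build_matched_sets(ds, agre_model), predictor="score"
        )
        gee = fit_gee_logistic(_analysis_rows(ds, agre_model), predictor="score")
        pooled_se = math.hypot(clr.robust_se, gee.robust_se)
        assert abs(clr.beta - gee.beta) < 2 * pooled_se


class TestCategoryLadder:
    def test_reference_category_is_unity(self):
        from famscore.association import AssocResult

        fit = AssocResult("conditional_logistic", "score", math.log(1.33), 0.07,
                          1e-5, 100, 80)
        table = category_or_table(fit, 2, range(2, 9))
        assert table.loc[table["score"] == 2, "or"].iloc[0] == pytest.approx(1.0)
        assert table.loc[table["score"] == 5, "or"].iloc[0] == pytest.approx(
            2.35, abs=0.005
        )

    def test_reference_outside_range_rejected(self):
        from famscore.association import AssocResult

        fit = AssocResult("gee_logistic", "score", 0.28, 0.1, 0.01, 50, 40)
        with pytest.raises(ValidationError):
            category_or_table(fit, 1, range(2, 9), observed_range=(2, 8))


# ---------------------------------------------------------------------------
# sibling recurrence risk ratio
# ---------------------------------------------------------------------------


def lambda_sib_pair_oracle(p: float, mode: str, r: float) -> float:
    """Brute-force enumeration of sib-pair joint genotype probabilities."""
    risks = {"additive": (1.0, r, r * r), "recessive": (1.0, 1.0, r)}[mode]
    q = 1 - p
    hwe = {0: q * q, 1: 2 * p * q, 2: p * p}
    k = joint = 0.0
    for gf, pf in hwe.items():
        for gm, pm in hwe.items():
            # transmission probability of the risk allele per parent
            tf, tm = gf / 2.0, gm / 2.0

            def child_dist():
                out = {0: 0.0, 1: 0.0, 2: 0.0}
                for bf, pbf in ((1, tf), (0, 1 - tf)):
                    for bm, pbm in ((1, tm), (0, 1 - tm)):
                        out[bf + bm] += pbf * pbm
                return out

            dist = child_dist()
            mean_risk = sum(pr * risks[g] for g, pr in dist.items())
            k += pf * pm * mean_risk
            joint += pf * pm * mean_risk**2
    return joint / k**2


@pytest.mark.parametrize(
    "p, mode, r",
    [(0.5, "additive", 2.0), (0.45, "recessive", 1.74), (0.75, "additive", 1.38),
     (0.9, "additive", 1.16)],
)
def test_lambda_locus_matches_sib_pair_enumeration(p, mode, r):
    assert lambda_locus(p, mode, r) == pytest.approx(
        lambda_sib_pair_oracle(p, mode, r), rel=1e-9
    )


def test_lambda_null_and_monotonicity():
    snps = autism_four_snp_panel()
    null = lambda_sibs(snps, [1.0] * 4)
    assert all(v == pytest.approx(1.0) for v in null.per_locus.values())
    assert null.combined == pytest.approx(1.0)
    values = [lambda_locus(0.3, "additive", r) for r in (1.0, 1.5, 2.0, 3.0, 5.0)]
    assert values == sorted(values) and values[0] < values[-1]


def test_lambda_combined_is_product():
    snps = autism_four_snp_panel()
    ors = [1.58, 1.74, 1.16, 1.38]
    res = lambda_sibs(snps, ors)
    assert res.combined == pytest.approx(np.prod(list(res.per_locus.values())))
    assert all(v >= 1.0 for v in res.per_locus.values())


def test_lambda_monomorphic_locus_is_neutral():
    snps = autism_four_snp_panel()
    frozen = type(snps[0])(
        snps[0].snp_id, snps[0].chrom, snps[0].allele_a, snps[0].allele_b,
        snps[0].risk_allele, snps[0].mode, 1.0
    )
    res = lambda_sibs([frozen], [2.0])
    assert res.per_locus[frozen.snp_id] == 1.0
    assert res.assumptions["notes"]
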