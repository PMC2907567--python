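"""Synthetic multiplex nuclear families with the statistical structure the
pipeline assumes.

Parents are drawn under Hardy-Weinberg equilibrium at configured risk-allele
frequencies; each child receives one uniformly chosen allele per parent per
marker, independently across markers (no linkage disequilibrium). Affection
is Bernoulli with logit(P) = alpha + sum_k beta_k * points_k, a logistic
liability on the coded genetic score itself (per-marker slopes available for
single-marker experiments). The intercept alpha is calibrated so the
UNASCERTAINED sibling prevalence hits a target (default 10%, the approximate
recurrence risk of autism in siblings of an affected child); ascertainment
then shifts the observed rates, as in real multiplex collections.

Two ascertainment schemes mirror the study designs the pipeline analyses:

* ``agre_like`` - families with >= 2 affected children; unaffected siblings
  are retained but their genotypes are masked (not genotyped).
* ``seattle_like`` - families with >= 1 affected child and >= 1 genotyped
  unaffected child (true sibling controls).

Affected children are male with odds 3.5:1 by default; IQ is drawn
independently of the genetic score (affected ~ N(76.3, 26.1), unaffected ~
N(111, 16.3), the descriptive moments of the genotyped-control collection),
so any apparent IQ-score association in the output is sampling noise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .datatypes import Individual, PedigreeDataset, SnpDef
from .errors import RunawayRejectionError, ValidationError
from .panels import autism_four_snp_panel

DEFAULT_SIBSHIP_DIST = {2: 0.55, 3: 0.33, 4: 0.12}


@dataclass
class SimConfig:
    n_families: int = 200
    snp_defs: list[SnpDef] = field(default_factory=autism_four_snp_panel)
    sibship_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIBSHIP_DIST)
    )
    per_point_log_or: float = math.log(1.33)
    per_snp_log_or: list[float] | None = None  # overrides per_point_log_or
    baseline_log_odds: float | None = None  # calibrated if None
    target_prevalence: float = 0.10
    ascertainment: str = "agre_like"  # agre_like | seattle_like | none
    mask_unaffected: bool | None = None  # default: True iff agre_like
    sex_ratio_affected: float = 3.5
    iq_affected: tuple[float, float] = (76.3, 26.1)
    iq_unaffected: tuple[float, float] = (111.0, 16.3)
    seed: int = 0

    def __post_init__(self):
        if self.ascertainment not in ("agre_like", "seattle_like", "none"):
            raise ValidationError(f"unknown ascertainment {self.ascertainment!r}")
        for snp in self.snp_defs:
            if snp.risk_freq is None or not (0.0 < snp.risk_freq < 1.0):
                raise ValidationError(
                    f"{snp.snp_id}: simulation needs risk_freq in (0, 1)"
                )
        if self.ascertainment != "none" and min(self.sibship_dist) < 2:
            raise ValidationError("ascertained designs require sibships of >= 2")
        total = sum(self.sibship_dist.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValidationError(f"sibship distribution sums to {total}, not 1")

    @property
    def betas(self) -> np.ndarray:
        if self.per_snp_log_or is not None:
            if len(self.per_snp_log_or) != len(self.snp_defs):
                raise ValidationError("need one per-SNP slope per marker")
            return np.asarray(self.per_snp_log_or, float)
        return np.full(len(self.snp_defs), self.per_point_log_or)


def _points_distributions(snps: list[SnpDef]) -> list[list[tuple[int, float]]]:
    dists = []
    for snp in snps:
        p, q = snp.risk_freq, 1.0 - snp.risk_freq
        if snp.mode == "recessive":
            dists.append([(0, 1.0 - p * p), (2, p * p)])
        else:
            dists.append([(0, q * q), (1, 2 * p * q), (2, p * p)])
    return dists


def calibrate_baseline(
    snps: list[SnpDef], betas: np.ndarray, target_prevalence: float
) -> float:
    """Intercept alpha such that E[expit(alpha + sum beta_k x_k)] hits the
    target prevalence, by bisection over the exact genotype-point grid."""
    if not 0.0 < target_prevalence < 1.0:
        raise ValidationError("target prevalence must lie in (0, 1)")
    dists = _points_distributions(snps)
    etas, probs = [], []
    for combo in itertools.product(*dists):
        pts = np.array([c[0] for c in combo], float)
        pr = float(np.prod([c[1] for c in combo]))
        etas.append(float(betas @ pts))
        probs.append(pr)
    etas = np.array(etas)
    probs = np.array(probs)

    def prevalence(alpha: float) -> float:
        return float(probs @ expit(alpha + etas)) - target_prevalence

    return float(brentq(prevalence, -60.0, 20.0, xtol=1e-12))


def _score_points(alleles: np.ndarray, modes_recessive: np.ndarray) -> np.ndarray:
    """Coded points from a (..., K, 2) boolean risk-allele array."""
    n_risk = alleles.sum(axis=-1)
    both = alleles.all(axis=-1)
    return np.where(modes_recessive, 2 * both, n_risk)


def simulate_population(
    n: int,
    snps: list[SnpDef] | None = None,
    per_point_log_or: float = math.log(1.33),
    target_prevalence: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Unrelated individuals under HWE: returns (scores, affected).

    The disease model matches :func:`simulate_families` with a single shared
    per-point slope.
    """
    snps = snps or autism_four_snp_panel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.array([s.risk_freq for s in snps])
    rec = np.array([s.mode == "recessive" for s in snps])
    betas = np.full(len(snps), per_point_log_or)
    alpha = calibrate_baseline(snps, betas, target_prevalence)
    alleles = rng.random((n, len(snps), 2)) < freqs[None, :, None]
    scores = _score_points(alleles, rec).sum(axis=1)
    affected = rng.random(n) < expit(alpha + per_point_log_or * scores)
    return scores.astype(int), affected


def simulate_families(config: SimConfig) -> PedigreeDataset:
    """Generate an ascertained multiplex-family dataset; deterministic given
    the config seed.

    Raises :class:`RunawayRejectionError` when the ascertainment acceptance
    probability is below 1e-4 at the configured parameters.
    """
    rng = np.random.default_rng(config.seed)
    snps = config.snp_defs
    k = len(snps)
    freqs = np.array([s.risk_freq for s in snps])
    rec = np.array([s.mode == "recessive" for s in snps])
    betas = config.betas
    alpha = (
        config.baseline_log_odds
        if config.baseline_log_odds is not None
        else calibrate_baseline(snps, betas, config.target_prevalence)
    )
    sizes_v = np.array(sorted(config.sibship_dist))
    sizes_p = np.array([config.sibship_dist[s] for s in sizes_v], float)
    sizes_p = sizes_p / sizes_p.sum()
    p_male_aff = config.sex_ratio_affected / (1.0 + config.sex_ratio_affected)

    min_acceptance = 1e-4
    attempts_limit = max(500_000, math.ceil(config.n_families / min_acceptance))
    attempts = 0
    kept: list[dict] = []

    while len(kept) < config.n_families:
        if attempts >= attempts_limit:
            raise RunawayRejectionError(
                f"accepted {len(kept)}/{config.n_families} families after "
                f"{attempts} attempts (acceptance {len(kept) / attempts:.2e}); "
                "relax the ascertainment rule or the disease model"
            )
        m = int(min(200_000, max(20_000, 4 * config.n_families)))
        attempts += m
        sizes = rng.choice(sizes_v, size=m, p=sizes_p)
        fam_idx = np.repeat(np.arange(m), sizes)
        total = int(sizes.sum())
        father = rng.random((m, k, 2)) < freqs[None, :, None]
        mother = rng.random((m, k, 2)) < freqs[None, :, None]
        pick_f = rng.integers(0, 2, size=(total, k))
        pick_m = rng.integers(0, 2, size=(total, k))
        child = np.empty((total, k, 2), bool)
        rowsel = np.arange(k)[None, :]
        child[:, :, 0] = father[fam_idx[:, None], rowsel, pick_f]
        child[:, :, 1] = mother[fam_idx[:, None], rowsel, pick_m]
        pts = _score_points(child, rec)
        eta = alpha + pts @ betas
        affected = rng.random(total) < expit(eta)
        sex_male = np.where(
            affected,
            rng.random(total) < p_male_aff,
            rng.random(total) < 0.5,
        )
        iq = np.where(
            affected,
            rng.normal(*config.iq_affected, size=total),
            rng.normal(*config.iq_unaffected, size=total),
        )
        n_aff = np.bincount(fam_idx, weights=affected, minlength=m).astype(int)
        if config.ascertainment == "agre_like":
            accept = n_aff >= 2
        elif config.ascertainment == "seattle_like":
            accept = (n_aff >= 1) & (n_aff < sizes)
        else:
            accept = np.ones(m, bool)
        acc_rows = np.flatnonzero(accept)
        child_start = np.concatenate([[0], np.cumsum(sizes)])
        for fi in acc_rows:
            if len(kept) >= config.n_families:
                break
            lo, hi = child_start[fi], child_start[fi + 1]
            kept.append(
                {
                    "father": father[fi],
                    "mother": mother[fi],
                    "children": child[lo:hi],
                    "affected": affected[lo:hi],
                    "sex_male": sex_male[lo:hi],
                    "iq": iq[lo:hi],
                }
            )

    # assemble the dataset; allele letters from the risk-allele indicator
    risk = np.array([s.risk_allele for s in snps])
    other = np.array([s.other_allele for s in snps])

    def letters(alleles: np.ndarray) -> np.ndarray:
        return np.where(alleles, risk[:, None], other[:, None])

    individuals: list[Individual] = []
    geno_rows: list[np.ndarray] = []
    width = len(str(config.n_families))
    for fnum, fam in enumerate(kept, start=1):
        fid = f"F{fnum:0{width}d}"
        base_age = int(rng.integers(36, 46))
        individuals.append(Individual(fid, "1", sex="male"))
        geno_rows.append(letters(fam["father"]))
        individuals.append(Individual(fid, "2", sex="female"))
        geno_rows.append(letters(fam["mother"]))
        n_kids = len(fam["children"])
        for c in range(n_kids):
            aff = bool(fam["affected"][c])
            individuals.append(
                Individual(
                    family_id=fid,
                    individual_id=str(3 + c),
                    father_id="1",
                    mother_id="2",
                    sex="male" if fam["sex_male"][c] else "female",
                    affection="affected" if aff else "unaffected",
                    birth_order_or_age=float(base_age - 30 - 2 * c),
                    iq=round(float(fam["iq"][c]), 1),
                )
            )
            g = letters(fam["children"][c])
            mask = (
                config.mask_unaffected
                if config.mask_unaffected is not None
                else config.ascertainment == "agre_like"
            )
            if mask and not aff:
                g = np.full_like(g, "0")  # unaffected sibs not genotyped
            geno_rows.append(g)

    dataset = PedigreeDataset(
        snps=list(snps),
        individuals=individuals,
        genotypes=np.stack(geno_rows),
        provenance={
            "simulated": True,
            "seed": config.seed,
            "baseline_log_odds": alpha,
            "attempts": attempts,
            "ascertainment": config.ascertainment,
            "per_point_log_or": config.per_point_log_or,
            "target_prevalence": config.target_prevalence,
        },
        age_semantics="age",
    )
    return dataset


def inject_errors(
    dataset: PedigreeDataset,
    n_mendel_errors: int = 0,
    n_missing: int = 0,
    seed: int = 0,
) -> tuple[PedigreeDataset, dict]:
    """Tamper a clean dataset with known Mendelian errors and missing calls.

    Mendelian errors are constructed to be certainly impossible: a trio with
    at least one homozygous parent has the child set homozygous for the
    allele that parent lacks. Missing calls avoid the tampered trios so the
    injected inconsistencies stay detectable. Returns the tampered dataset
    and a tamper log with the exact positions touched.
    """
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    log: dict = {"mendel": [], "missing": []}

    candidates = []
    for child_row, father_row, mother_row in out.iter_trios():
        for j, snp in enumerate(out.snps):
            f = out.genotype(father_row, j)
            m = out.genotype(mother_row, j)
            if f is None or m is None:
                continue
            hom_parent = f if f[0] == f[1] else (m if m[0] == m[1] else None)
            if hom_parent is None:
                continue
            bad = snp.allele_b if hom_parent[0] == snp.allele_a else snp.allele_a
            candidates.append((child_row, j, bad))
    if n_mendel_errors > len(candidates):
        raise ValidationError(
            f"requested {n_mendel_errors} Mendelian errors but only "
            f"{len(candidates)} injectable trio positions exist"
        )
    chosen = (
        [candidates[i] for i in rng.choice(len(candidates), n_mendel_errors,
                                           replace=False)]
        if n_mendel_errors
        else []
    )
    tampered_keys = set()
    for child_row, j, bad in chosen:
        out.genotypes[child_row, j] = (bad, bad)
        ind = out.individuals[child_row]
        log["mendel"].append(
            {"family_id": ind.family_id, "child_id": ind.individual_id,
             "snp_id": out.snps[j].snp_id}
        )
        tampered_keys.add((ind.family_id, j))

    present = [
        (i, j)
        for i in range(out.n_individuals)
        for j in range(out.n_snps)
        if out.genotype(i, j) is not None
        and (out.individuals[i].family_id, j) not in tampered_keys
    ]
    if n_missing > len(present):
        raise ValidationError(
            f"requested {n_missing} missing calls but only {len(present)} "
            "non-missing positions are available"
        )
    if n_missing:
        for idx in rng.choice(len(present), n_missing, replace=False):
            i, j = present[idx]
            out.genotypes[i, j] = ("0", "0")
            ind = out.individuals[i]
            log["missing"].append(
                {"family_id": ind.family_id, "individual_id": ind.individual_id,
                 "snp_id": out.snps[j].snp_id}
            )
    out.provenance["tampered"] = {
        "n_mendel_errors": n_mendel_errors,
        "n_missing": n_missing,
        "seed": seed,
    }
    return out, log
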