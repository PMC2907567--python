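"""Association models for family-based genetic-score analyses.

Two designs are supported:

* **case/pseudocontrol** — 1:1 matched conditional logistic regression. The
  conditional likelihood for a 1:1 set reduces to an intercept-free logistic
  model on the within-pair predictor difference, which is maximised here by
  Newton-Raphson. Variance is a sandwich estimator clustered on family, so
  multiple affected siblings per family are handled correctly.
* **sibling case-control** — GEE with logit (or identity) link and the
  independence working correlation: point estimates equal ordinary maximum
  likelihood, standard errors are the family-clustered robust sandwich.

Also provided: the log-linear odds-ratio ladder across score categories, and
the marker-attributable sibling recurrence risk ratio λs via the Risch
single-locus variance decomposition with multiplicative combination across
loci.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .datatypes import SnpDef
from .errors import (
    ConvergenceError,
    DegenerateInputError,
    SeparationError,
    ValidationError,
)
from .pseudocontrol import MatchedSet

Z95 = norm.ppf(0.975)


@dataclass
class AssocResult:
    """One fitted coefficient on the log-odds (or linear) scale."""

    model_kind: str  # conditional_logistic | gee_logistic | gee_linear
    predictor: str
    beta: float
    robust_se: float
    p_value: float
    n_obs: int
    n_clusters: int
    metadata: dict = field(default_factory=dict)

    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        lo = self.beta - Z95 * self.robust_se
        hi = self.beta + Z95 * self.robust_se
        if self.model_kind == "gee_linear":
            return (float(lo), float(hi))
        # cap at exp(700) to avoid overflow on degenerate fits
        return (float(np.exp(min(lo, 700.0))), float(np.exp(min(hi, 700.0))))

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "predictor": self.predictor,
            "beta": self.beta,
            "robust_se": self.robust_se,
            "or": self.or_value if self.model_kind != "gee_linear" else None,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
        }


# ---------------------------------------------------------------------------
# conditional logistic (1:1 matched)
# ---------------------------------------------------------------------------


def _pair_differences(
    sets: Sequence[MatchedSet],
    predictor: str | Callable[[MatchedSet], Sequence[float]],
    model=None,
) -> np.ndarray:
    """Within-pair (case - pseudocontrol) predictor differences, (n, p)."""
    if callable(predictor):
        d = np.atleast_2d([np.atleast_1d(predictor(s)) for s in sets])
        return d.astype(float)
    if predictor == "score":
        return np.array([[s.case_score - s.pseudo_score] for s in sets], float)
    # a marker ID: difference of coded points; single-marker sets carry one
    # points entry, score-level sets follow the model's marker order
    if len(sets[0].case_points) == 1:
        idx = 0
    else:
        if model is None:
            raise ValidationError("marker predictors require a score model")
        idx = [snp.snp_id for snp in model.snps].index(predictor)
    return np.array(
        [[s.case_points[idx] - s.pseudo_points[idx]] for s in sets], float
    )


def fit_conditional_logistic(
    matched_sets: Sequence[MatchedSet],
    predictor: str | Callable[[MatchedSet], Sequence[float]] = "score",
    model=None,
    cluster_by_family: bool = True,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> AssocResult | dict[str, AssocResult]:
    """Maximise the 1:1 matched conditional likelihood.

    ``predictor`` may be ``"score"``, a marker ID, or a callable mapping a
    matched set to a predictor vector (for multi-coefficient models such as
    risk-group indicators; then a dict of results keyed by coefficient index
    is returned).

    Raises :class:`SeparationError` when every informative pair difference
    shares one sign (single-predictor case) and :class:`DegenerateInputError`
    when no pair is informative.
    """
    d = _pair_differences(matched_sets, predictor, model)
    n, p = d.shape
    informative = np.any(d != 0, axis=1)
    if not informative.any():
        raise DegenerateInputError("no informative matched pairs")
    if p == 1:
        dz = d[informative, 0]
        if (dz > 0).all() or (dz < 0).all():
            raise SeparationError(
                "all informative within-pair differences share one sign"
            )

    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = d @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = d.T @ (1.0 - mu)
        if np.linalg.norm(grad) < tol:
            break
        w = mu * (1.0 - mu)
        hess = (d * w[:, None]).T @ d
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular Hessian in conditional logistic fit")
        beta = beta + step
        if np.abs(beta).max() > 30:
            raise SeparationError("diverging estimate (quasi-separation)")
    else:
        raise ConvergenceError(f"no convergence in {max_iter} Newton iterations")

    mu = 1.0 / (1.0 + np.exp(-(d @ beta)))
    w = mu * (1.0 - mu)
    bread_inv = (d * w[:, None]).T @ d
    scores = d * (1.0 - mu)[:, None]
    if cluster_by_family:
        fams = np.array([s.family_id for s in matched_sets])
        groups = pd.Series(range(n)).groupby(fams).indices
        meat = np.zeros((p, p))
        for rows in groups.values():
            g = scores[list(rows)].sum(axis=0)
            meat += np.outer(g, g)
        n_clusters = len(groups)
    else:
        meat = scores.T @ scores
        n_clusters = n
    bread = np.linalg.inv(bread_inv)
    cov = bread @ meat @ bread
    ses = np.sqrt(np.diag(cov))

    def result(i: int, name: str) -> AssocResult:
        z = beta[i] / ses[i] if ses[i] > 0 else np.inf
        return AssocResult(
            model_kind="conditional_logistic",
            predictor=name,
            beta=float(beta[i]),
            robust_se=float(ses[i]),
            p_value=float(2 * norm.sf(abs(z))),
            n_obs=n,
            n_clusters=n_clusters,
            metadata={"n_informative": int(informative.sum())},
        )

    if p == 1:
        name = predictor if isinstance(predictor, str) else "custom"
        return result(0, name)
    return {f"x{i}": result(i, f"x{i}") for i in range(p)}


# ---------------------------------------------------------------------------
# GEE (independence working correlation, cluster-robust sandwich)
# ---------------------------------------------------------------------------


def _gee_fit(
    rows: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: Sequence[str],
    cluster: str,
    family_obj,
    model_kind: str,
    max_iter: int = 100,
) -> AssocResult:
    cols = [predictor, *covariates]
    data = rows[[outcome, *cols, cluster]].dropna()
    if data.empty:
        raise DegenerateInputError("no complete rows for GEE fit")
    y = data[outcome].to_numpy(float)
    if model_kind == "gee_logistic" and len(np.unique(y)) < 2:
        raise DegenerateInputError("outcome has a single class")
    if model_kind == "gee_linear" and np.ptp(y) == 0:
        raise DegenerateInputError("outcome is constant")
    X = data[cols].to_numpy(float)
    if np.any(np.ptp(X, axis=0) == 0):
        raise DegenerateInputError("constant predictor or covariate")
    X = sm.add_constant(X, prepend=True)
    groups = data[cluster].to_numpy()
    n_clusters = len(np.unique(groups))
    if n_clusters == 1:
        _warnings.warn(
            "single cluster: robust variance degenerates to one-cluster sandwich",
            stacklevel=2,
        )
    model = sm.GEE(
        y,
        X,
        groups=groups,
        family=family_obj,
        cov_struct=sm.cov_struct.Independence(),
    )
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = model.fit(maxiter=max_iter)
    except Exception as exc:  # statsmodels raises assorted numeric errors
        raise ConvergenceError(f"GEE fit failed: {exc}") from exc
    i = 1  # predictor is the first column after the intercept
    if not np.all(np.isfinite(fit.params)) or not np.isfinite(fit.bse[i]):
        raise ConvergenceError("GEE produced non-finite estimates")
    return AssocResult(
        model_kind=model_kind,
        predictor=predictor,
        beta=float(fit.params[i]),
        robust_se=float(fit.bse[i]),
        p_value=float(fit.pvalues[i]),
        n_obs=int(len(data)),
        n_clusters=n_clusters,
        metadata={
            "covariates": list(covariates),
            "params": fit.params.tolist(),
            "bse": fit.bse.tolist(),
        },
    )


def fit_gee_logistic(
    rows: pd.DataFrame,
    outcome: str = "affected",
    predictor: str = "score",
    covariates: Sequence[str] = (),
    cluster: str = "family_id",
) -> AssocResult:
    """Logit-link GEE: ML point estimates, family-clustered robust SE.

    ``rows`` needs one row per analysed individual with a 0/1 ``outcome``
    column, numeric predictor/covariates and a cluster label column.
    """
    return _gee_fit(
        rows, outcome, predictor, covariates, cluster,
        sm.families.Binomial(), "gee_logistic",
    )


def fit_gee_linear(
    rows: pd.DataFrame,
    outcome: str = "iq",
    predictor: str = "score",
    covariates: Sequence[str] = (),
    cluster: str = "family_id",
) -> AssocResult:
    """Identity-link GEE (= OLS point estimates) with clustered sandwich SE."""
    return _gee_fit(
        rows, outcome, predictor, covariates, cluster,
        sm.families.Gaussian(), "gee_linear",
    )


# ---------------------------------------------------------------------------
# score-category OR ladder
# ---------------------------------------------------------------------------


def category_or_table(
    per_point: AssocResult,
    reference: int,
    scores: Sequence[int],
    observed_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Log-linear odds-ratio ladder: OR(s) = exp(beta · (s - reference)).

    The confidence interval for each category scales the per-point standard
    error by |s - reference|. This is the default reporting mode; a
    categorical (indicator) fit is available by refitting with indicator
    predictors.
    """
    if observed_range is not None and not (
        observed_range[0] <= reference <= observed_range[1]
    ):
        raise ValidationError(
            f"reference {reference} outside observed score range {observed_range}"
        )
    rows = []
    for s in scores:
        delta = s - reference
        beta = per_point.beta * delta
        se = per_point.robust_se * abs(delta)
        rows.append(
            {
                "score": s,
                "or": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - Z95 * se)),
                "ci_high": float(np.exp(beta + Z95 * se)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sibling recurrence risk ratio attributable to the markers
# ---------------------------------------------------------------------------


@dataclass
class LambdaResult:
    per_locus: dict[str, float]
    combined: float
    assumptions: dict

    def to_dict(self) -> dict:
        return {
            "per_locus": self.per_locus,
            "combined": self.combined,
            "assumptions": self.assumptions,
        }


def _genotype_risks(mode: str, r: float) -> tuple[float, float, float]:
    """Relative risks for 0/1/2 risk alleles given the per-allele OR ~ RR."""
    if mode == "recessive":
        return (1.0, 1.0, r)
    return (1.0, r, r * r)


def lambda_locus(p: float, mode: str, r: float) -> float:
    """Single-locus sibling recurrence risk ratio (Risch decomposition).

    With HWE genotype frequencies (q², 2pq, p²) and genotype relative risks
    f0, f1, f2, the locus contributes λs = 1 + (V_A/2 + V_D/4) / K² where K
    is the population mean risk, V_A = 2pq·α² with α = p(f2-f1) + q(f1-f0)
    the average allele-substitution effect, and V_D = (pq)²·(f0 - 2f1 + f2)².
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"risk frequency {p} outside [0, 1]")
    if p in (0.0, 1.0):
        return 1.0
    f0, f1, f2 = _genotype_risks(mode, r)
    q = 1.0 - p
    k = q * q * f0 + 2 * p * q * f1 + p * p * f2
    alpha = p * (f2 - f1) + q * (f1 - f0)
    v_a = 2 * p * q * alpha * alpha
    v_d = (p * q) ** 2 * (f0 - 2 * f1 + f2) ** 2
    return 1.0 + (v_a / 2.0 + v_d / 4.0) / (k * k)


def lambda_sibs(
    snps: Sequence[SnpDef], ors: Sequence[float]
) -> LambdaResult:
    """Marker-attributable λs: per-locus values and their product.

    Loci are assumed independent and multiplicative on the risk scale; the
    per-allele odds ratio stands in for the genotype relative risk (rare
    disease). Monomorphic loci contribute λs = 1 with a warning recorded.
    """
    if len(snps) != len(ors):
        raise ValidationError("need one OR per marker")
    per: dict[str, float] = {}
    notes = []
    for snp, r in zip(snps, ors):
        if snp.risk_freq is None or snp.mode is None:
            raise ValidationError(f"{snp.snp_id}: risk_freq and mode required")
        if snp.risk_freq in (0.0, 1.0):
            notes.append(f"{snp.snp_id}: monomorphic, lambda set to 1")
        per[snp.snp_id] = lambda_locus(snp.risk_freq, snp.mode, r)
    combined = float(np.prod(list(per.values())))
    return LambdaResult(
        per_locus=per,
        combined=combined,
        assumptions={
            "model": "multiplicative across loci; OR treated as genotype RR",
            "ors": list(map(float, ors)),
            "frequencies": [s.risk_freq for s in snps],
            "notes": notes,
        },
    )
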