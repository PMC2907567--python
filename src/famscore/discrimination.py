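"""Discrimination analysis: per-threshold sensitivity/specificity, the
OR-based specificity formula for the pseudocontrol design, likelihood ratios,
ROC curves and AUC.

A score test is "positive" when S >= gamma (ties at the threshold count as
positive), so the lowest observed threshold always gives sensitivity 1 and
specificity 0. With true controls, sensitivity and specificity are direct
proportions with Wald binomial confidence intervals. Without genotyped
controls, the specificity at each threshold is recovered from the matched
case/pseudocontrol odds ratio OR_gamma of the dichotomised score:

    spec = OR_gamma (1 - sens) / (sens + OR_gamma (1 - sens)),

the unique inversion of OR = [sens/(1-sens)] / [(1-spec)/spec]. Applied with
the crude 2x2 odds ratio this identity reproduces the direct specificity
exactly; in the pipeline OR_gamma comes from conditional logistic regression
on the dichotomised score.

The AUC is the Mann-Whitney C-statistic (ties counted one-half), identical
to the trapezoidal area under the ROC staircase over all thresholds.
Confidence intervals resample whole families (the independent sampling
units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .association import Z95, fit_conditional_logistic
from .errors import DegenerateInputError, SeparationError, ValidationError
from .pseudocontrol import MatchedSet


@dataclass
class ThresholdMetrics:
    gamma: float
    sens: float
    spec: float
    sens_ci95: tuple[float, float] | None = None
    spec_ci95: tuple[float, float] | None = None
    or_gamma: float | None = None
    source: str = "direct"  # direct | formula
    boundary: bool = False

    @property
    def lr_plus(self) -> float:
        return lr_plus(self.sens, self.spec)


@dataclass
class RocCurve:
    points: list[tuple[float, float]]  # (1 - spec, sens), sorted by x
    auc: float
    auc_ci95: tuple[float, float] | None = None
    n_boot: int = 0

    def to_dict(self) -> dict:
        return {
            "points": [list(p) for p in self.points],
            "auc": self.auc,
            "auc_ci95": list(self.auc_ci95) if self.auc_ci95 else None,
            "n_boot": self.n_boot,
        }


def _wald_ci(k: int, n: int) -> tuple[float, float]:
    p = k / n
    half = Z95 * np.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def sens_spec_direct(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    gamma: float,
) -> ThresholdMetrics:
    """Direct sensitivity/specificity at one threshold from true controls."""
    cases = np.asarray(case_scores, float)
    controls = np.asarray(control_scores, float)
    if cases.size == 0 or controls.size == 0:
        raise DegenerateInputError("empty score list")
    tp = int((cases >= gamma).sum())
    tn = int((controls < gamma).sum())
    return ThresholdMetrics(
        gamma=gamma,
        sens=tp / cases.size,
        spec=tn / controls.size,
        sens_ci95=_wald_ci(tp, cases.size),
        spec_ci95=_wald_ci(tn, controls.size),
        source="direct",
    )


def spec_from_or(or_gamma: float, sens_gamma: float) -> tuple[float, bool]:
    """Specificity implied by the threshold OR and sensitivity.

    Returns ``(spec, boundary)``; ``boundary`` is True when sensitivity was 0
    or 1, where the formula is undefined and the limiting value (1 or 0) is
    returned instead.
    """
    if or_gamma < 0:
        raise ValidationError(f"or_gamma must be non-negative, got {or_gamma}")
    if sens_gamma < 0 or sens_gamma > 1:
        raise ValidationError(f"sensitivity {sens_gamma} outside [0, 1]")
    if sens_gamma == 1.0:
        return 0.0, True
    if sens_gamma == 0.0:
        return 1.0, True
    if np.isinf(or_gamma):
        return 1.0, False
    num = or_gamma * (1.0 - sens_gamma)
    return num / (sens_gamma + num), False


def lr_plus(sens: float, spec: float) -> float:
    """Positive likelihood ratio sens/(1-spec); inf when spec == 1."""
    if spec >= 1.0:
        return float("inf")
    return sens / (1.0 - spec)


def threshold_table(
    case_scores: Sequence[float],
    control_scores: Sequence[float] | None = None,
    matched_sets: Sequence[MatchedSet] | None = None,
    design: str = "true_controls",
    gammas: Sequence[float] | None = None,
) -> list[ThresholdMetrics]:
    """Sensitivity/specificity at every integer threshold of the score range.

    ``design="true_controls"`` computes both proportions directly.
    ``design="pseudocontrols"`` takes sensitivity directly from the cases and
    recovers specificity from the conditional-logistic OR of the dichotomised
    score (S >= gamma) on the matched sets; where that fit is degenerate or
    separated the crude case/pseudocontrol 2x2 odds ratio is used instead
    (noted in ``source``).
    """
    cases = np.asarray(case_scores, float)
    if cases.size == 0:
        raise DegenerateInputError("no case scores")
    if design == "true_controls":
        if control_scores is None or len(control_scores) == 0:
            raise DegenerateInputError("true_controls design needs control scores")
        pool = np.concatenate([cases, np.asarray(control_scores, float)])
    elif design == "pseudocontrols":
        if not matched_sets:
            raise DegenerateInputError("pseudocontrols design needs matched sets")
        pseudo = np.array([s.pseudo_score for s in matched_sets], float)
        pool = np.concatenate([cases, pseudo])
    else:
        raise ValidationError(f"unknown design {design!r}")
    if gammas is None:
        gammas = np.arange(int(np.floor(pool.min())), int(np.ceil(pool.max())) + 1)
    if len(gammas) == 0:
        raise DegenerateInputError("empty threshold grid")

    out: list[ThresholdMetrics] = []
    for g in gammas:
        if design == "true_controls":
            out.append(sens_spec_direct(cases, control_scores, g))
            continue
        tp = int((cases >= g).sum())
        sens = tp / cases.size
        row = ThresholdMetrics(
            gamma=float(g),
            sens=sens,
            sens_ci95=_wald_ci(tp, cases.size),
            spec=np.nan,
            source="formula",
        )
        try:
            fit = fit_conditional_logistic(
                matched_sets,
                predictor=lambda s, g=g: [
                    float(s.case_score >= g) - float(s.pseudo_score >= g)
                ],
            )
            row.or_gamma = fit.or_value
        except (DegenerateInputError, SeparationError):
            a = tp
            b = cases.size - tp
            c = int((pseudo >= g).sum())
            d = pseudo.size - c
            if b * c == 0:  # crude OR undefined; fall back to direct pseudo spec
                row.spec = d / pseudo.size
                row.source = "crude_direct"
                row.boundary = sens in (0.0, 1.0)
                out.append(row)
                continue
            row.or_gamma = (a * d) / (b * c)
            row.source = "formula_crude"
        row.spec, row.boundary = spec_from_or(row.or_gamma, sens)
        out.append(row)
    return out


def cross_design_spec_ci(
    matched_sets: Sequence[MatchedSet],
    control_scores: Sequence[float],
    control_families: Sequence[str],
    gammas: Sequence[float],
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
    joint: bool = False,
) -> dict[float, tuple[float, float]]:
    """Family-bootstrap CI of (formula spec - direct spec) per threshold.

    Both specificities are recomputed on each family resample, so the CI
    reflects the sampling noise of both designs and their within-family
    correlation; cross-design consistency means 0 lies inside the CI.
    Thresholds where either estimate is undefined in a replicate are skipped
    for that replicate.

    With ``joint=True`` the per-threshold level is Bonferroni-adjusted
    (alpha/k over the k thresholds) so that the band supports the
    simultaneous statement "0 is inside at every threshold" at ~95%.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    controls = np.asarray(control_scores, float)
    control_families = np.asarray(control_families)
    sets_by_fam: dict[str, list[MatchedSet]] = {}
    for s in matched_sets:
        sets_by_fam.setdefault(s.family_id, []).append(s)
    ctrl_by_fam: dict[str, np.ndarray] = {}
    for f in np.unique(control_families):
        ctrl_by_fam[f] = controls[control_families == f]
    fam_ids = np.array(sorted(set(sets_by_fam) | set(ctrl_by_fam)))
    diffs = {g: [] for g in gammas}
    for _ in range(n_boot):
        pick = rng.choice(fam_ids, size=fam_ids.size, replace=True)
        boot_sets = [s for f in pick for s in sets_by_fam.get(f, ())]
        boot_ctrl = np.concatenate(
            [ctrl_by_fam.get(f, np.empty(0)) for f in pick]
        )
        if not boot_sets or boot_ctrl.size == 0:
            continue
        boot_cases = np.array([s.case_score for s in boot_sets], float)
        try:
            formula_rows = threshold_table(
                boot_cases, matched_sets=boot_sets,
                design="pseudocontrols", gammas=gammas,
            )
        except DegenerateInputError:
            continue
        for row in formula_rows:
            if row.source != "formula" or row.boundary or not np.isfinite(row.spec):
                continue
            direct = float((boot_ctrl < row.gamma).mean())
            diffs[row.gamma].append(row.spec - direct)
    alpha = 0.05 / max(1, len(gammas)) if joint else 0.05
    qlo, qhi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    out = {}
    for g in gammas:
        if diffs[g]:
            lo, hi = np.percentile(diffs[g], [qlo, qhi])
            out[g] = (float(lo), float(hi))
        else:
            out[g] = (float("nan"), float("nan"))
    return out


def bootstrap_formula_spec(
    matched_sets: Sequence[MatchedSet],
    gammas: Sequence[float],
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
    joint: bool = False,
) -> dict[float, tuple[float, float]]:
    """Family-bootstrap CI of the formula-based specificity per threshold
    (95% per threshold, or Bonferroni-adjusted across the grid with
    ``joint=True`` to support an "at every threshold" statement).

    Each replicate resamples whole families of matched sets (cases and their
    pseudocontrols travel together) and recomputes sensitivity, the
    conditional-logistic threshold OR and the implied specificity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fams: dict[str, list[MatchedSet]] = {}
    for s in matched_sets:
        fams.setdefault(s.family_id, []).append(s)
    fam_ids = np.array(sorted(fams))
    specs = {g: [] for g in gammas}
    for _ in range(n_boot):
        pick = rng.choice(fam_ids, size=fam_ids.size, replace=True)
        boot_sets = [s for f in pick for s in fams[f]]
        boot_cases = np.array([s.case_score for s in boot_sets], float)
        try:
            rows = threshold_table(
                boot_cases, matched_sets=boot_sets,
                design="pseudocontrols", gammas=gammas,
            )
        except DegenerateInputError:
            continue
        for row in rows:
            if np.isfinite(row.spec):
                specs[row.gamma].append(row.spec)
    alpha = 0.05 / max(1, len(gammas)) if joint else 0.05
    qlo, qhi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    out = {}
    for g in gammas:
        if specs[g]:
            lo, hi = np.percentile(specs[g], [qlo, qhi])
            out[g] = (float(lo), float(hi))
        else:
            out[g] = (float("nan"), float("nan"))
    return out


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def c_statistic(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """Mann-Whitney probability that a case outscores a control, ties 1/2."""
    cases = np.asarray(case_scores, float)
    controls = np.asarray(control_scores, float)
    if cases.size == 0 or controls.size == 0:
        raise DegenerateInputError("empty score list")
    ranks = rankdata(np.concatenate([cases, controls]))
    r_cases = ranks[: cases.size].sum()
    u = r_cases - cases.size * (cases.size + 1) / 2.0
    return float(u / (cases.size * controls.size))


def roc_curve_points(
    metrics: Sequence[ThresholdMetrics],
) -> list[tuple[float, float]]:
    """ROC staircase points (1-spec, sens) with the (0,0) and (1,1) anchors."""
    pts = {(0.0, 0.0), (1.0, 1.0)}
    for m in metrics:
        if np.isfinite(m.spec):
            pts.add((1.0 - m.spec, m.sens))
    return sorted(pts)


def roc_auc(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    case_families: Sequence[str] | None = None,
    control_families: Sequence[str] | None = None,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> RocCurve:
    """ROC curve and C-statistic AUC with a family-bootstrap 95% CI.

    When family labels are given, bootstrap replicates resample whole
    families (cases and controls of a resampled family travel together);
    otherwise individuals are resampled independently within group. Passing
    ``n_boot=0`` skips the CI.
    """
    cases = np.asarray(case_scores, float)
    controls = np.asarray(control_scores, float)
    auc = c_statistic(cases, controls)
    metrics = threshold_table(cases, controls, design="true_controls")
    points = roc_curve_points(metrics)
    ci = None
    if n_boot > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        boots = []
        if case_families is not None and control_families is not None:
            case_families = np.asarray(case_families)
            control_families = np.asarray(control_families)
            fam_ids = np.unique(np.concatenate([case_families, control_families]))
            case_by_fam = {f: cases[case_families == f] for f in fam_ids}
            ctrl_by_fam = {f: controls[control_families == f] for f in fam_ids}
            for _ in range(n_boot):
                pick = rng.choice(fam_ids, size=fam_ids.size, replace=True)
                bc = np.concatenate([case_by_fam[f] for f in pick])
                bu = np.concatenate([ctrl_by_fam[f] for f in pick])
                if bc.size and bu.size:
                    boots.append(c_statistic(bc, bu))
        else:
            for _ in range(n_boot):
                bc = rng.choice(cases, size=cases.size, replace=True)
                bu = rng.choice(controls, size=controls.size, replace=True)
                boots.append(c_statistic(bc, bu))
        if boots:
            lo, hi = np.percentile(boots, [2.5, 97.5])
            ci = (float(lo), float(hi))
    return RocCurve(points=points, auc=auc, auc_ci95=ci, n_boot=n_boot)


def auc_from_points(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under sorted ROC points (oracle-equivalent to the
    C-statistic for integer scores)."""
    pts = sorted(points)
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return float(np.trapezoid(ys, xs))
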