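"""End-to-end orchestration of the two study designs.

``run`` composes the module operations in analysis order — QC, index-case
exclusion, scoring, pseudocontrol or sibling-control assembly, association
models, discrimination, marker-attributable recurrence risk — and writes a
report bundle:

* ``qc_report.json`` — founder HWE, Mendelian exclusions, missingness flags
* ``snp_table.tsv`` — single-marker odds ratios
* ``score_or_table.tsv`` — per-point OR and the category OR ladder
* ``threshold_table.tsv`` — sensitivity/specificity per score threshold
* ``risk_group_table.tsv`` — low/intermediate/high group ORs
* ``roc.json`` / ``roc_points.tsv`` — C-statistic AUC with family-bootstrap CI
* ``lambda.json`` — per-locus and combined sibling recurrence risk ratio
* ``manifest.json`` — seed, version, stage log, config echo

TSV tables round to 2 decimals (report style); JSON keeps full precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    AssocResult,
    category_or_table,
    fit_conditional_logistic,
    fit_gee_linear,
    fit_gee_logistic,
    lambda_sibs,
)
from .datatypes import PedigreeDataset
from .discrimination import lr_plus, roc_auc, threshold_table
from .errors import (
    ConvergenceError,
    DegenerateInputError,
    FamscoreError,
    SeparationError,
    ValidationError,
)
from .family_io import read_ped_map, read_sample_info
from .panels import PANEL_GENES, autism_four_snp_panel
from .pseudocontrol import build_matched_sets, build_single_snp_sets
from .qc import apply_qc, select_index_cases
from .scoring import ScoreModel, score_table
from .simulate import SimConfig, simulate_families


@dataclass
class RunConfig:
    design: str  # agre_pseudocontrol | seattle_case_control
    out_dir: str | Path = "famscore_out"
    ped_path: str | None = None
    map_path: str | None = None
    sample_info_path: str | None = None
    simulate: SimConfig | None = None
    score_model: ScoreModel | None = None  # default: four-SNP autism panel
    seed: int = 0
    n_boot: int = 1000
    reference_score: int | None = None  # default: minimum observed
    analyses: dict = field(
        default_factory=lambda: {
            "single_snp": True,
            "per_point": True,
            "categories": True,
            "risk_groups": True,
            "thresholds": True,
            "roc": True,
            "lambda": True,
            "iq_check": True,
        }
    )

    def __post_init__(self):
        if self.design not in ("agre_pseudocontrol", "seattle_case_control"):
            raise ValidationError(f"unknown design {self.design!r}")
        has_files = self.ped_path is not None and self.map_path is not None
        if has_files == (self.simulate is not None):
            raise ValidationError(
                "provide exactly one of (ped_path, map_path) or a simulate block"
            )


def estimate_risk_freqs(dataset: PedigreeDataset, model: ScoreModel) -> dict[str, float]:
    """Risk-allele frequency per marker among genotyped founders."""
    out = {}
    founders = [i for i, ind in enumerate(dataset.individuals) if ind.is_founder]
    for snp in model.snps:
        j = dataset.snp_index(snp.snp_id)
        n_risk = n_tot = 0
        for i in founders:
            gt = dataset.genotype(i, j)
            if gt is None:
                continue
            n_risk += sum(1 for a in gt if a == snp.risk_allele)
            n_tot += 2
        out[snp.snp_id] = n_risk / n_tot if n_tot else float("nan")
    return out


def _round_df(df: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(ndigits)
    return out


def _analysis_rows(dataset: PedigreeDataset, model: ScoreModel) -> pd.DataFrame:
    """Per-child analysis table: non-index children with a defined score."""
    df = score_table(dataset, model)
    meta = dataset.to_frame()
    df = df.merge(
        meta[["family_id", "individual_id", "sex", "father_id"]],
        on=["family_id", "individual_id"],
    )
    df["iq"] = [
        dataset.individuals[dataset.row(f, i)].iq
        for f, i in zip(df["family_id"], df["individual_id"])
    ]
    children = df["father_id"].notna()
    keep = (
        children
        & ~df["is_index_case"]
        & df["score"].notna()
        & df["affection"].isin(["affected", "unaffected"])
    )
    out = df.loc[keep].copy()
    out["affected"] = (out["affection"] == "affected").astype(int)
    out["male"] = (out["sex"] == "male").astype(int)
    out["score"] = out["score"].astype(int)
    out["grp_intermediate"] = (out["risk_group"] == "intermediate").astype(int)
    out["grp_high"] = (out["risk_group"] == "high").astype(int)
    return out


def run(config: RunConfig) -> dict:
    """Execute one study design end to end; returns the report bundle.

    On any stage failure, files already written to the output directory are
    removed and the error is re-raised with the stage name prefixed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stages: list[str] = []
    report: dict = {"design": config.design}

    def emit(name: str, payload) -> None:
        path = out_dir / name
        if isinstance(payload, pd.DataFrame):
            _round_df(payload).to_csv(path, sep="\t", index=False)
        else:
            path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
        written.append(path)

    stage = "load"
    try:
        model = config.score_model or ScoreModel(tuple(autism_four_snp_panel()))
        if config.simulate is not None:
            dataset = simulate_families(config.simulate)
        else:
            dataset = read_ped_map(config.ped_path, config.map_path)
            if config.sample_info_path:
                dataset = read_sample_info(config.sample_info_path, dataset)
        stages.append(stage)

        stage = "qc"
        dataset, qc_report = apply_qc(dataset)
        stages.append(stage)

        stage = "index_case_exclusion"
        dataset = select_index_cases(dataset, qc_report)
        emit("qc_report.json", qc_report.to_dict())
        report["qc"] = qc_report
        stages.append(stage)

        stage = "score"
        rows = _analysis_rows(dataset, model)
        if rows.empty:
            raise DegenerateInputError("no analysable children after QC")
        report["rows"] = rows
        stages.append(stage)

        pseudo_design = config.design == "agre_pseudocontrol"
        if pseudo_design:
            stage = "pseudocontrols"
            sets = build_matched_sets(dataset, model)
            report["matched_sets"] = sets
            case_scores = np.array([s.case_score for s in sets], float)
            control_scores = np.array([s.pseudo_score for s in sets], float)
            case_fams = [s.family_id for s in sets]
            control_fams = list(case_fams)
            stages.append(stage)
        else:
            stage = "sibling_controls"
            cases = rows[rows["affected"] == 1]
            controls = rows[rows["affected"] == 0]
            if controls.empty:
                raise DegenerateInputError(
                    "case-control design requires genotyped unaffected siblings"
                )
            case_scores = cases["score"].to_numpy(float)
            control_scores = controls["score"].to_numpy(float)
            case_fams = cases["family_id"].tolist()
            control_fams = controls["family_id"].tolist()
            stages.append(stage)

        toggles = config.analyses
        snp_results: dict[str, AssocResult] = {}
        if toggles.get("single_snp", True):
            stage = "single_snp"
            recs = []
            for snp in model.snps:
                try:
                    if pseudo_design:
                        snp_sets = build_single_snp_sets(dataset, model, snp.snp_id)
                        res = fit_conditional_logistic(snp_sets, predictor=snp.snp_id,
                                                       model=model)
                    else:
                        pts_col = f"pts_{snp.snp_id}"
                        snp_rows = rows.copy()
                        j = dataset.snp_index(snp.snp_id)
                        snp_rows[pts_col] = [
                            _snp_points(dataset, model, f, i, j)
                            for f, i in zip(snp_rows["family_id"],
                                            snp_rows["individual_id"])
                        ]
                        res = fit_gee_logistic(snp_rows, predictor=pts_col)
                    snp_results[snp.snp_id] = res
                    recs.append(
                        {
                            "gene": PANEL_GENES.get(snp.snp_id, ""),
                            "snp_id": snp.snp_id,
                            "or": res.or_value,
                            "ci_low": res.ci95[0],
                            "ci_high": res.ci95[1],
                            "p": res.p_value,
                        }
                    )
                except (DegenerateInputError, SeparationError,
                        ConvergenceError) as exc:
                    report.setdefault("warnings", []).append(
                        f"single_snp {snp.snp_id}: {exc}"
                    )
            emit("snp_table.tsv", pd.DataFrame(recs))
            report["snp_fits"] = snp_results
            stages.append(stage)

        per_point: AssocResult | None = None
        if toggles.get("per_point", True):
            stage = "per_point"
            if pseudo_design:
                per_point = fit_conditional_logistic(sets, predictor="score")
            else:
                per_point = fit_gee_logistic(rows, predictor="score")
            report["per_point"] = per_point
            stages.append(stage)

        if toggles.get("categories", True) and per_point is not None:
            stage = "categories"
            observed = (int(case_scores.min() if pseudo_design
                            else rows["score"].min()),
                        int(case_scores.max() if pseudo_design
                            else rows["score"].max()))
            ref = (config.reference_score
                   if config.reference_score is not None else observed[0])
            ladder = category_or_table(
                per_point, ref, range(observed[0], observed[1] + 1),
                observed_range=observed,
            )
            ladder.insert(1, "kind", "category")
            head = pd.DataFrame(
                [{
                    "score": np.nan, "kind": "per_point",
                    "or": per_point.or_value,
                    "ci_low": per_point.ci95[0], "ci_high": per_point.ci95[1],
                }]
            )
            emit("score_or_table.tsv", pd.concat([head, ladder], ignore_index=True))
            report["category_table"] = ladder
            stages.append(stage)

        if toggles.get("risk_groups", True):
            stage = "risk_groups"
            emit("risk_group_table.tsv", _risk_group_table(
                report, rows, pseudo_design, sets if pseudo_design else None))
            stages.append(stage)

        if toggles.get("thresholds", True):
            stage = "thresholds"
            if pseudo_design:
                metrics = threshold_table(
                    case_scores, matched_sets=sets, design="pseudocontrols"
                )
            else:
                metrics = threshold_table(
                    case_scores, control_scores, design="true_controls"
                )
            tt = pd.DataFrame(
                {
                    "gamma": [m.gamma for m in metrics],
                    "sens": [m.sens for m in metrics],
                    "sens_ci_low": [m.sens_ci95[0] if m.sens_ci95 else np.nan
                                    for m in metrics],
                    "sens_ci_high": [m.sens_ci95[1] if m.sens_ci95 else np.nan
                                     for m in metrics],
                    "spec": [m.spec for m in metrics],
                    "spec_ci_low": [m.spec_ci95[0] if m.spec_ci95 else np.nan
                                    for m in metrics],
                    "spec_ci_high": [m.spec_ci95[1] if m.spec_ci95 else np.nan
                                     for m in metrics],
                    "or_gamma": [m.or_gamma if m.or_gamma else np.nan
                                 for m in metrics],
                    "lr_plus": [m.lr_plus for m in metrics],
                    "source": [m.source for m in metrics],
                }
            )
            emit("threshold_table.tsv", tt)
            report["threshold_table"] = tt
            stages.append(stage)

        if toggles.get("roc", True):
            stage = "roc"
            roc = roc_auc(
                case_scores, control_scores,
                case_families=case_fams, control_families=control_fams,
                n_boot=config.n_boot, seed=config.seed,
            )
            emit("roc.json", {**roc.to_dict(), "seed": config.seed})
            emit(
                "roc_points.tsv",
                pd.DataFrame(roc.points, columns=["fpr", "sens"]),
            )
            report["roc"] = roc
            stages.append(stage)

        if toggles.get("lambda", True) and snp_results:
            stage = "lambda"
            freqs = estimate_risk_freqs(dataset, model)
            snps_est = [
                type(s)(s.snp_id, s.chrom, s.allele_a, s.allele_b,
                        s.risk_allele, s.mode,
                        freqs.get(s.snp_id, s.risk_freq))
                for s in model.snps
                if s.snp_id in snp_results
            ]
            lam = lambda_sibs(
                snps_est, [snp_results[s.snp_id].or_value for s in snps_est]
            )
            emit("lambda.json", lam.to_dict())
            report["lambda"] = lam
            stages.append(stage)

        if toggles.get("iq_check", True):
            stage = "iq_check"
            if rows["iq"].notna().sum() >= 4 and not pseudo_design:
                iq_fit = fit_gee_linear(
                    rows, outcome="iq", predictor="score",
                    covariates=["male", "affected"],
                )
                emit("iq_check.json", iq_fit.to_dict())
                report["iq_check"] = iq_fit
            else:
                report.setdefault("warnings", []).append(
                    "iq_check skipped: no IQ data in this design"
                )
            stages.append(stage)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "design": config.design,
            "stages": stages,
            "n_boot": config.n_boot,
            "warnings": report.get("warnings", []),
        }
        emit("manifest.json", manifest)
        report["manifest"] = manifest
        report["out_dir"] = str(out_dir)
        return report
    except FamscoreError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise type(exc)(f"[stage {stage}] {exc}") from exc


def _snp_points(dataset, model, fam, iid, j):
    from .scoring import code_snp

    snp = model.snps[[s.snp_id for s in model.snps].index(dataset.snps[j].snp_id)]
    gt = dataset.genotype(dataset.row(fam, iid), j)
    return code_snp(gt, snp)


def _risk_group_table(report, rows, pseudo_design, sets):
    from .scoring import assign_risk_group

    recs = []
    if pseudo_design:
        case_groups = [assign_risk_group(s.case_score) for s in sets]
        ctrl_groups = [assign_risk_group(s.pseudo_score) for s in sets]
        try:
            fits = fit_conditional_logistic(
                sets,
                predictor=lambda s: [
                    float(assign_risk_group(s.case_score) == "intermediate")
                    - float(assign_risk_group(s.pseudo_score) == "intermediate"),
                    float(assign_risk_group(s.case_score) == "high")
                    - float(assign_risk_group(s.pseudo_score) == "high"),
                ],
            )
            or_int, or_high = fits["x0"], fits["x1"]
        except (DegenerateInputError, SeparationError, ConvergenceError):
            or_int = or_high = None
    else:
        case_groups = rows.loc[rows["affected"] == 1, "risk_group"].tolist()
        ctrl_groups = rows.loc[rows["affected"] == 0, "risk_group"].tolist()
        try:
            or_int = fit_gee_logistic(
                rows, predictor="grp_intermediate", covariates=["grp_high"]
            )
            or_high = fit_gee_logistic(
                rows, predictor="grp_high", covariates=["grp_intermediate"]
            )
        except (DegenerateInputError, ConvergenceError):
            or_int = or_high = None

    def freq(groups, g):
        return sum(x == g for x in groups) / len(groups) if groups else np.nan

    for g, fit in (("low", None), ("intermediate", or_int), ("high", or_high)):
        recs.append(
            {
                "risk_group": g,
                "case_freq": freq(case_groups, g),
                "control_freq": freq(ctrl_groups, g),
                "or": 1.0 if g == "low" else (fit.or_value if fit else np.nan),
                "ci_low": np.nan if g == "low" or fit is None else fit.ci95[0],
                "ci_high": np.nan if g == "low" or fit is None else fit.ci95[1],
            }
        )
    return pd.DataFrame(recs)


def compare_designs(report_a: dict, report_b: dict) -> dict:
    """Per-threshold sensitivity/specificity differences and AUC concordance
    between two report bundles covering the same threshold grid."""
    ta, tb = report_a["threshold_table"], report_b["threshold_table"]
    ga, gb = list(ta["gamma"]), list(tb["gamma"])
    if ga != gb:
        raise ValidationError(f"mismatched threshold grids: {ga} vs {gb}")
    rows = []
    for i, g in enumerate(ga):
        sa, sb = ta["sens"].iloc[i], tb["sens"].iloc[i]
        pa, pb = ta["spec"].iloc[i], tb["spec"].iloc[i]
        rows.append(
            {
                "gamma": g,
                "sens_diff": float(sa - sb),
                "spec_diff": float(pa - pb),
                "sens_ci_overlap": _overlap(ta, tb, i, "sens"),
                "spec_ci_overlap": _overlap(ta, tb, i, "spec"),
            }
        )
    roc_a, roc_b = report_a["roc"], report_b["roc"]
    auc_diff = float(roc_a.auc - roc_b.auc)
    se = None
    if roc_a.auc_ci95 and roc_b.auc_ci95:
        se_a = (roc_a.auc_ci95[1] - roc_a.auc_ci95[0]) / (2 * 1.96)
        se_b = (roc_b.auc_ci95[1] - roc_b.auc_ci95[0]) / (2 * 1.96)
        se = math.hypot(se_a, se_b)
    return {
        "per_gamma": pd.DataFrame(rows),
        "auc_diff": auc_diff,
        "auc_diff_ci95": (
            (auc_diff - 1.96 * se, auc_diff + 1.96 * se) if se is not None else None
        ),
    }


def _overlap(ta, tb, i, what) -> bool:
    lo_a, hi_a = ta[f"{what}_ci_low"].iloc[i], ta[f"{what}_ci_high"].iloc[i]
    lo_b, hi_b = tb[f"{what}_ci_low"].iloc[i], tb[f"{what}_ci_high"].iloc[i]
    if any(pd.isna(v) for v in (lo_a, hi_a, lo_b, hi_b)):
        return True  # no CI available; do not flag
    return not (hi_a < lo_b or hi_b < lo_a)
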