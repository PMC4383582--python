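"""End-to-end analysis runner and report rendering.

``run_all`` chains every stage on one cohort — simulate (or read) -> smooth
-> mask -> vectorize -> [residualize] -> LOO CV -> metrics + ROC ->
TIV-only comparison + DeLong -> global permutation test -> voxel p-value
map -> correlations -> WHO subgroup and SGA analyses — and returns a
structured results dict that ``render_report`` turns into a plain-text
report.  Every stochastic stage records its seed; conventions (p-value
form, sidedness, leakage mode) are stated in the report rather than left
implicit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_cohort, read_fixture
from .evaluation import (
    auc_mann_whitney,
    confusion_metrics,
    delong_compare,
    loo_cv,
    roc_curve,
    split_half_validation,
)
from .associations import (
    UndefinedCorrelationError,
    correlate_scores,
    partial_correlation_after_residualization,
    pairwise_subgroup_classification,
    sga_excluded_analysis,
    subgroup_mean_scores,
    tiv_only_classification,
    who_stratify,
)
from .permutation import permute_global, weight_pvalue_map
from .svm import train_linear_svm, weight_map
from .volumes import build_mask, smooth_volumes, tiv_ml, vectorize, write_volume

__all__ = ["AnalysisConfig", "run_all", "render_report"]


@dataclass
class AnalysisConfig:
    """Settings for an end-to-end run.

    ``input_dir`` reads a written cohort fixture; when None a synthetic
    cohort is generated from ``cohort`` (its seed is derived from ``seed``).
    Covariate modes: 'none', 'age_sex', 'age_sex_tiv'; leakage 'foldwise'
    fits the covariate projection per training fold, 'pooled' once on all
    subjects.  Desk-scale permutation counts by default; ``full_scale``
    raises them to 50000 global / 2000 voxelwise.
    """

    input_dir: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    mask_threshold: float = 0.1
    smooth_fwhm_mm: float = 6.0
    covariates: str = "none"
    leakage: str = "foldwise"
    scheme: str = "loo"
    split_counts: tuple = (37, 35)
    split_repeats: int = 2
    n_perm: int = 999
    n_perm_map: int = 199
    full_scale: bool = False
    perm_statistics: tuple = ("accuracy", "auc")
    seed: int = 0
    out_dir: str = "vbmsvm_out"

    def validate(self):
        if self.covariates not in ("none", "age_sex", "age_sex_tiv"):
            raise ValueError("covariates must be none|age_sex|age_sex_tiv")
        if self.leakage not in ("foldwise", "pooled"):
            raise ValueError("leakage must be foldwise|pooled")
        if self.scheme not in ("loo", "split"):
            raise ValueError("scheme must be loo|split")


def _covariate_matrix(table: pd.DataFrame, tiv: np.ndarray, mode: str):
    if mode == "none":
        return None
    cols = [
        table["age_years"].to_numpy(dtype=float),
        (table["sex"].to_numpy() == "M").astype(float),
    ]
    if mode == "age_sex_tiv":
        cols.append(np.asarray(tiv, dtype=float))
    return np.column_stack(cols)


def _metrics_dict(cv) -> dict:
    m = confusion_metrics(cv.y_true, cv.y_pred)
    return {
        "accuracy": m.accuracy,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "tp": m.tp,
        "fn": m.fn,
        "tn": m.tn,
        "fp": m.fp,
        "n": len(cv.y_true),
    }


def run_all(config: AnalysisConfig) -> dict:
    """Run the complete analysis; writes artifacts under ``config.out_dir``
    and returns the results dict (also saved as results.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_perm = 50000 if config.full_scale else config.n_perm
    n_perm_map = 2000 if config.full_scale else config.n_perm_map
    results: dict = {
        "version": __version__,
        "seed": config.seed,
        "conventions": {
            "positive_class": "+1 (preterm case)",
            "p_value": "(1 + #{null >= observed}) / (1 + n_perm)",
            "voxel_map_sidedness": "two-sided on |w|",
            "tie_at_zero_score": "predicted -1 (control)",
            "leakage_mode": config.leakage,
            "covariate_mode": config.covariates,
        },
    }

    # ---- inputs ---------------------------------------------------------
    if config.input_dir is None:
        cohort_cfg = config.cohort
        cohort_cfg.seed = int(config.seed)
        volset, table, truth = generate_cohort(cohort_cfg)
        results["input"] = {"source": "simulated", "seed": cohort_cfg.seed}
    else:
        volset, table = read_fixture(config.input_dir)
        truth = None
        results["input"] = {"source": str(config.input_dir)}
    y = table["group"].to_numpy(dtype=float)
    results["input"].update(
        n=int(len(y)), n_case=int((y == 1).sum()), n_control=int((y == -1).sum())
    )

    # ---- preprocessing --------------------------------------------------
    tiv = tiv_ml(volset)  # from the unsmoothed input volumes
    smoothed = smooth_volumes(volset, config.smooth_fwhm_mm)
    mask = build_mask(smoothed, config.mask_threshold)
    feats = vectorize(smoothed, mask)
    results["preprocessing"] = {
        "smooth_fwhm_mm": config.smooth_fwhm_mm,
        "mask_threshold": config.mask_threshold,
        "n_voxels_in_mask": mask.n_voxels_in,
    }
    cov = _covariate_matrix(table, tiv, config.covariates)

    # ---- full-data model and weight map ---------------------------------
    model = train_linear_svm(feats.X, y, subject_ids=list(table["id"]))
    wmap = weight_map(model, mask)
    write_volume(wmap, volset.affine, out / "weight_map.nii.gz")
    write_volume(mask.mask.astype(np.float64), volset.affine, out / "mask.nii.gz")
    results["model"] = {
        "bias": float(model.intercept_[0]),
        "n_support_vectors": int(model.support_.size),
        "C_effective": model.C,
    }

    # ---- cross-validation ----------------------------------------------
    cv = loo_cv(feats.X, y, covariates=cov, leakage=config.leakage)
    cv.subject_ids = list(table["id"])
    cv.to_frame().to_csv(out / "cv_loo.tsv", sep="\t", index=False)
    roc_img = roc_curve(cv.scores, y)
    pd.DataFrame(
        {"fpr": roc_img.fpr, "tpr": roc_img.tpr, "threshold": roc_img.thresholds}
    ).to_csv(out / "roc_image.tsv", sep="\t", index=False)
    results["loo"] = _metrics_dict(cv) | {"auc": roc_img.auc, "leakage": config.leakage}

    # covariate-adjusted companions of the unadjusted run
    if config.covariates == "none":
        adj = {}
        for mode in ("age_sex", "age_sex_tiv"):
            cv_adj = loo_cv(
                feats.X, y, covariates=_covariate_matrix(table, tiv, mode),
                leakage=config.leakage,
            )
            adj[mode] = _metrics_dict(cv_adj) | {
                "auc": auc_mann_whitney(cv_adj.scores, y)
            }
        results["loo_covariate_adjusted"] = adj

    if config.scheme == "split" or config.split_repeats > 0:
        halves = []
        for rep in range(config.split_repeats):
            sh = split_half_validation(
                feats.X,
                y,
                n_train_case=min(config.split_counts[0], int((y == 1).sum()) - 1),
                n_train_control=min(config.split_counts[1], int((y == -1).sum()) - 1),
                seed=config.seed * 1000 + rep,
            )
            halves.append(
                _metrics_dict(sh) | {"auc": auc_mann_whitney(sh.scores, sh.y_true)}
            )
        results["split_half"] = halves

    # ---- TIV-only comparison and DeLong ---------------------------------
    cv_tiv, roc_tiv = tiv_only_classification(tiv, y)
    pd.DataFrame(
        {"fpr": roc_tiv.fpr, "tpr": roc_tiv.tpr, "threshold": roc_tiv.thresholds}
    ).to_csv(out / "roc_tiv.tsv", sep="\t", index=False)
    dl = delong_compare(cv.scores, cv_tiv.scores, y)
    results["tiv_only"] = _metrics_dict(cv_tiv) | {
        "auc": roc_tiv.auc,
        "tolerant_fit": cv_tiv.details.get("tolerant_fit", False),
    }
    results["delong"] = {
        "auc_image": dl.auc_a,
        "auc_tiv": dl.auc_b,
        "z": dl.z,
        "p": dl.p,
        "ci_image": list(dl.ci_a),
        "ci_tiv": list(dl.ci_b),
        "ci_level": dl.ci_level,
        "degenerate": dl.degenerate,
    }

    # ---- permutation inference ------------------------------------------
    perm = {}
    for stat in config.perm_statistics:
        pn = permute_global(
            feats.X, y, statistic=stat, n_perm=n_perm, seed=config.seed + 1
        )
        pd.DataFrame({stat: pn.null}).to_csv(
            out / f"null_{stat}.tsv", sep="\t", index=False
        )
        perm[stat] = {
            "observed": pn.observed,
            "p": pn.p_value,
            "p_bound_form": pn.p_bound_form,
            "null_max": float(pn.null.max()),
            "n_perm": pn.n_perm,
            "seed": pn.seed,
        }
    results["permutation_global"] = perm

    pmap = weight_pvalue_map(feats, y, n_perm=n_perm_map, seed=config.seed + 2)
    write_volume(pmap.as_volume(), volset.affine, out / "pmap.nii.gz")
    results["permutation_map"] = {
        "n_perm": pmap.n_perm,
        "seed": pmap.seed,
        "sidedness": pmap.sidedness,
        "min_p": float(pmap.p.min()),
        "frac_p_below_05": float(np.mean(pmap.p < 0.05)),
    }

    # ---- correlations ----------------------------------------------------
    corr_frames = [
        correlate_scores(table, cv.scores, ["ga_weeks", "bw_g"], subset="cases"),
        correlate_scores(table, cv.scores, ["bw_g"], subset="controls"),
        correlate_scores(
            table, cv.scores, ["iq_full", "iq_verbal", "iq_perf"], subset="all"
        ),
        correlate_scores(table, cv.scores, ["iq_full"], subset="cases"),
    ]
    corr = pd.concat(corr_frames, ignore_index=True)
    corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
    results["correlations"] = corr.to_dict(orient="records")

    partial = {}
    Cpart = _covariate_matrix(table, tiv, "age_sex_tiv")
    for var in ("iq_full", "iq_verbal", "iq_perf"):
        try:
            r, p, n = partial_correlation_after_residualization(
                table, cv.scores, var, Cpart
            )
            partial[var] = {"r": r, "p": p, "n": n}
        except UndefinedCorrelationError as exc:
            partial[var] = {"error": str(exc)}
    results["partial_correlations_age_sex_tiv"] = partial

    # ---- WHO subgroups and SGA ------------------------------------------
    codes = who_stratify(table["ga_weeks"].to_numpy(), y)
    sub = subgroup_mean_scores(cv.scores, codes)
    table_out = table.copy()
    table_out["who_category"] = codes
    table_out.to_csv(out / "participants_with_subgroups.tsv", sep="\t", index=False)
    sub.to_csv(out / "subgroup_means.tsv", sep="\t", index=False)
    results["subgroup_means"] = sub.to_dict(orient="records")

    pairwise = {}
    for a, b in (("controls", 3), ("controls", 2), (2, 3)):
        try:
            cvp = pairwise_subgroup_classification(feats, table, a, b)
            pairwise[f"{a}_vs_{b}"] = _metrics_dict(cvp)
        except ValueError as exc:
            pairwise[f"{a}_vs_{b}"] = {"error": str(exc)}
    results["pairwise_subgroups"] = pairwise

    try:
        cv_sga = sga_excluded_analysis(feats, table)
        results["sga_excluded"] = _metrics_dict(cv_sga) | {
            "n_cases_included": cv_sga.details["n_cases_included"],
            "accuracy_delta_vs_full": cv_sga.accuracy - cv.accuracy,
        }
    except ValueError as exc:
        results["sga_excluded"] = {"error": str(exc)}

    if truth is not None:
        sel = y == 1
        if np.ptp(truth.severity[sel]) > 0:
            results["truth_checks"] = {
                "r_score_severity_cases": float(
                    np.corrcoef(cv.scores[sel], truth.severity[sel])[0, 1]
                ),
                "r_tiv_scale": float(np.corrcoef(tiv, truth.scale)[0, 1]),
            }

    (out / "results.json").write_text(json.dumps(results, indent=1, default=float))
    (out / "report.txt").write_text(render_report(results))
    return results


# ---------------------------------------------------------------------------
# rendering

def _fmt(x, nd=4):
    if x is None:
        return "n/a"
    if isinstance(x, float):
        return f"{x:.{nd}g}"
    return str(x)


def render_report(results: dict) -> str:
    """Human-readable report; absent stages are listed as 'not run'."""
    L = []
    add = L.append
    add("=" * 64)
    add("SVM gray-matter biomarker analysis report (vbmsvm "
        f"{results.get('version', '?')})")
    add("=" * 64)
    add(f"seed: {results.get('seed', 'n/a')}")
    conv = results.get("conventions", {})
    for k, v in conv.items():
        add(f"  convention {k}: {v}")

    inp = results.get("input")
    if inp:
        add("")
        add(f"[input] source={inp.get('source')} n={inp.get('n')} "
            f"(cases {inp.get('n_case')}, controls {inp.get('n_control')})")
    pre = results.get("preprocessing")
    if pre:
        add(f"[preprocessing] fwhm={pre['smooth_fwhm_mm']}mm "
            f"mask_threshold={pre['mask_threshold']} "
            f"voxels_in_mask={pre['n_voxels_in_mask']}")

    loo = results.get("loo")
    add("")
    add("[leave-one-out classification]")
    if loo:
        add(f"  accuracy={_fmt(loo['accuracy'])} "
            f"sensitivity={_fmt(loo['sensitivity'])} "
            f"specificity={_fmt(loo['specificity'])} AUC={_fmt(loo['auc'])}")
        add(f"  confusion: TP={loo['tp']} FN={loo['fn']} TN={loo['tn']} FP={loo['fp']}")
    else:
        add("  not run")

    adj = results.get("loo_covariate_adjusted")
    if adj:
        for mode, m in adj.items():
            add(f"  covariate-adjusted ({mode}): accuracy={_fmt(m['accuracy'])} "
                f"AUC={_fmt(m['auc'])}")

    sh = results.get("split_half")
    add("")
    add("[split-half validation]")
    if sh:
        for i, m in enumerate(sh):
            add(f"  cycle {i + 1}: accuracy={_fmt(m['accuracy'])} AUC={_fmt(m['auc'])}")
    else:
        add("  not run")

    tiv = results.get("tiv_only")
    dl = results.get("delong")
    add("")
    add("[TIV-only classifier and DeLong comparison]")
    if tiv:
        flag = " (margin-violation-tolerant fit)" if tiv.get("tolerant_fit") else ""
        add(f"  TIV-only: accuracy={_fmt(tiv['accuracy'])} AUC={_fmt(tiv['auc'])}{flag}")
    if dl:
        if dl.get("degenerate"):
            add("  DeLong: degenerate variance (identical scores); p = 1")
        add(f"  DeLong: AUC(image)={_fmt(dl['auc_image'])} "
            f"CI{int(dl['ci_level'] * 100)}%=({_fmt(dl['ci_image'][0])}, "
            f"{_fmt(dl['ci_image'][1])}) vs AUC(TIV)={_fmt(dl['auc_tiv'])}; "
            f"z={_fmt(dl['z'])} p={_fmt(dl['p'], 3)} (two-sided)")
    if not tiv and not dl:
        add("  not run")

    perm = results.get("permutation_global")
    add("")
    add("[global permutation test]")
    if perm:
        for stat, m in perm.items():
            add(f"  {stat}: observed={_fmt(m['observed'])} "
                f"null_max={_fmt(m['null_max'])} p={_fmt(m['p'], 3)} "
                f"[{m['p_bound_form']}; n_perm={m['n_perm']}, seed={m['seed']}]")
    else:
        add("  not run")

    pm = results.get("permutation_map")
    if pm:
        add(f"  voxel p-map: n_perm={pm['n_perm']} seed={pm['seed']} "
            f"({pm['sidedness']}); min p={_fmt(pm['min_p'], 3)}, "
            f"{_fmt(100 * pm['frac_p_below_05'], 3)}% of voxels p<0.05 (uncorrected)")

    corr = results.get("correlations")
    add("")
    add("[correlations with the decision score]")
    if corr:
        for row in corr:
            if row.get("error"):
                add(f"  {row['variable']} ({row['subset']}): undefined — {row['error']}")
            else:
                add(f"  {row['variable']} ({row['subset']}): r={_fmt(row['r'], 3)} "
                    f"p={_fmt(row['p'], 3)} n={row['n']}")
    else:
        add("  not run")
    part = results.get("partial_correlations_age_sex_tiv")
    if part:
        for var, m in part.items():
            if "error" in m:
                add(f"  partial {var} | age+sex+TIV: undefined — {m['error']}")
            else:
                add(f"  partial {var} | age+sex+TIV: r={_fmt(m['r'], 3)} "
                    f"p={_fmt(m['p'], 3)} n={m['n']}")

    sub = results.get("subgroup_means")
    add("")
    add("[WHO gestational-age subgroups]")
    if sub:
        for row in sub:
            add(f"  {row['category']} (code {row['code']}): n={row['n']} "
                f"mean score={_fmt(row['mean_score'], 3)}")
    else:
        add("  not run")
    pw = results.get("pairwise_subgroups")
    if pw:
        for k, m in pw.items():
            if "error" in m:
                add(f"  {k}: {m['error']}")
            else:
                add(f"  {k}: accuracy={_fmt(m['accuracy'])} (n={m['n']})")

    sga = results.get("sga_excluded")
    add("")
    add("[SGA-excluded analysis]")
    if sga is None:
        add("  not run")
    elif "error" in sga:
        add(f"  {sga['error']}")
    else:
        add(f"  accuracy={_fmt(sga['accuracy'])} with "
            f"{sga['n_cases_included']} non-SGA cases + all controls "
            f"(delta vs full: {_fmt(sga['accuracy_delta_vs_full'], 3)})")

    tc = results.get("truth_checks")
    if tc:
        add("")
        add("[generator ground-truth checks]")
        add(f"  r(score, severity | cases)={_fmt(tc['r_score_severity_cases'], 3)}  "
            f"r(TIV, true scale)={_fmt(tc['r_tiv_scale'], 3)}")
    add("")
    return "\n".join(L)
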