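"""End-to-end orchestration: simulate -> select -> score -> evaluate.

Every stage persists its outputs as TSV under the run directory and the run
ends with a machine-readable ``summary.json``.  Deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, data_io, scoring, selection, survival
from .synthetic import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    selection: selection.SelectionConfig = field(default_factory=selection.SelectionConfig)
    ssgsea: scoring.SSGSEAConfig = field(default_factory=scoring.SSGSEAConfig)
    # precomputed inputs; any provided path skips the corresponding stage
    expression_path: Path | None = None
    clinical_path: Path | None = None
    signature_gmt: Path | None = None
    mutations_path: Path | None = None
    cnv_path: Path | None = None


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def evaluate_subgroups(
    ap: pd.Series, clinical: data_io.CohortClinical
) -> pd.DataFrame:
    """Subgroup evaluation using the GLOBAL median dichotomization.

    For each level of each covariate: KM log-rank of high vs low AP inside the
    level; plus per-covariate composition (high/low x level contingency) and
    AP-distribution (ANOVA over levels) tests.
    """
    tum = clinical.table[clinical.table["tissue_group"] != "NT"].copy()
    tum = tum[tum["sample_id"].isin(ap.index)]
    tum["ap"] = ap.loc[tum["sample_id"]].to_numpy()
    labels = survival.dichotomize_by_median(tum["ap"].to_numpy())
    tum["ap_group"] = labels
    tum["age_group"] = np.where(tum["age"] >= 60, ">=60", "<60")

    rows = []
    covariates = ("age_group", "gender", "grade", "idh", "mgmt", "subtype", "chemo", "radio")
    for cov in covariates:
        levels = [l for l in tum[cov].dropna().unique()]
        # composition: high/low x level
        sub_all = tum.dropna(subset=[cov])
        try:
            tab = pd.crosstab(sub_all["ap_group"], sub_all[cov]).to_numpy()
            comp = association.contingency_test(tab)
            comp_stat, comp_p, comp_test = comp.statistic, comp.p, comp.test
        except (association.AssociationError, ValueError) as exc:
            comp_stat, comp_p, comp_test = np.nan, np.nan, f"NA ({exc})"
        try:
            groups = [
                sub_all.loc[sub_all[cov] == l, "ap"].to_numpy() for l in sorted(levels)
            ]
            an = association.anova_oneway(groups) if len(groups) >= 2 else None
        except association.AssociationError:
            an = None
        rows.append(
            {
                "covariate": cov,
                "level": "(all)",
                "kind": "composition+distribution",
                "test": comp_test,
                "statistic": comp_stat,
                "p": comp_p,
                "anova_f": an.statistic if an else np.nan,
                "anova_p": an.p if an else np.nan,
                "n": len(sub_all),
            }
        )
        for level in sorted(levels):
            sub = tum[tum[cov] == level]
            hi = sub["ap_group"] == "high"
            reason = None
            if hi.sum() < 2 or (~hi).sum() < 2:
                reason = "fewer than 2 samples per arm"
            if reason is None:
                try:
                    lr = survival.logrank_test(
                        sub.loc[hi, "os_days"], sub.loc[hi, "event"],
                        sub.loc[~hi, "os_days"], sub.loc[~hi, "event"],
                    )
                    rows.append(
                        {
                            "covariate": cov,
                            "level": level,
                            "kind": "km_logrank",
                            "test": "logrank",
                            "statistic": lr.chi2,
                            "p": lr.p,
                            "hr": lr.hr,
                            "n": len(sub),
                        }
                    )
                    continue
                except survival.SurvivalError as exc:
                    reason = str(exc)
            rows.append(
                {
                    "covariate": cov,
                    "level": level,
                    "kind": "km_logrank",
                    "test": f"NA ({reason})",
                    "statistic": np.nan,
                    "p": np.nan,
                    "n": len(sub),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the summary dict (also written to disk)."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": []}
    summary: dict = {"seed": cfg.seed}

    def stage(name):
        manifest["stages"].append(name)
        logger.info("stage %s", name)

    try:
        stage("inputs")
        if cfg.expression_path:
            expr = data_io.read_expression(cfg.expression_path)
            clinical = data_io.read_clinical(cfg.clinical_path)
            mutations = (
                data_io.read_mutations(cfg.mutations_path) if cfg.mutations_path else None
            )
            cnv = data_io.read_cnv(cfg.cnv_path) if cfg.cnv_path else None
            truth = None
        else:
            syn_cfg = cfg.synthetic or SyntheticConfig(seed=cfg.seed)
            syn_cfg = dataclasses.replace(syn_cfg, seed=cfg.seed)
            cohort = generate_cohort(syn_cfg)
            expr, clinical = cohort.expression, cohort.clinical
            mutations, cnv, truth = cohort.mutations, cohort.cnv, cohort.truth
            data_io.write_expression(expr, outdir / "expression.tsv")
            data_io.write_clinical(clinical, outdir / "clinical.tsv")
            data_io.write_mutations(mutations, outdir / "mutations.tsv")
            data_io.write_cnv(cnv, outdir / "cnv.tsv")
            data_io.write_gmt([truth.pos, truth.neg], outdir / "truth.gmt")
        summary["n_samples"] = expr.n_samples
        summary["n_genes"] = expr.n_genes

        stage("select")
        if cfg.signature_gmt:
            sets = {s.name: s for s in data_io.read_gmt(cfg.signature_gmt)}
            pair = data_io.GeneSetPair(sets["POS_AP"], sets["NEG_AP"])
            summary["selection"] = {"skipped": True, "gmt": str(cfg.signature_gmt)}
        else:
            pair, audit = selection.select_progression_genes(expr, clinical, cfg.selection)
            audit.to_csv(outdir / "selection_audit.tsv", sep="\t", index=False)
            summary["selection"] = {
                "n_pos": len(pair.pos),
                "n_neg": len(pair.neg),
            }
            if truth is not None:
                found = pair.pos.genes | pair.neg.genes
                planted = truth.pos.genes | truth.neg.genes
                summary["selection"]["sensitivity"] = len(found & planted) / len(planted)
                summary["selection"]["false_positives"] = len(found - planted)
        data_io.write_gmt([pair.pos, pair.neg], outdir / "signature.gmt")
        summary["signature"] = {
            "pos": sorted(pair.pos.genes),
            "neg": sorted(pair.neg.genes),
        }

        stage("score")
        scores = scoring.ap_score(expr, pair, cfg.ssgsea)
        scores.to_frame().to_csv(outdir / "ap_scores.tsv", sep="\t", index=False)
        ap = scores.as_series()

        stage("survival")
        tumours = [s for s in clinical.tumour_samples() if s in ap.index]
        ap_t = ap.loc[tumours]
        labels = pd.Series(
            survival.dichotomize_by_median(ap_t.to_numpy()), index=tumours
        )
        times, events = clinical.survival(tumours)
        hi = (labels == "high").to_numpy()
        lr = survival.logrank_test(times[hi], events[hi], times[~hi], events[~hi])
        km_high = survival.km_estimate(times[hi], events[hi])
        km_low = survival.km_estimate(times[~hi], events[~hi])
        summary["logrank_high_vs_low"] = {
            "chi2": lr.chi2, "p": lr.p, "hr": lr.hr,
            "median_high": km_high.median_survival,
            "median_low": km_low.median_survival,
        }
        uni = survival.cox_fit(
            pd.DataFrame({"os_days": times, "event": events}),
            pd.DataFrame({"ap_high": hi.astype(float)}),
        )
        covs = _cox_covariates(clinical, tumours, hi)
        multi = survival.cox_fit(
            pd.DataFrame({"os_days": times, "event": events}), covs
        )
        uni.to_frame().to_csv(outdir / "cox_univariate.tsv", sep="\t", index=False)
        multi.to_frame().to_csv(outdir / "cox_multivariate.tsv", sep="\t", index=False)
        summary["cox"] = {
            "univariate_hr_ap": float(uni.hr[0]),
            "univariate_p_ap": float(uni.wald_p[0]),
            "multivariate_hr_ap": float(multi.hr[list(covs.columns).index("ap_high")]),
            "multivariate_p_ap": float(multi.wald_p[list(covs.columns).index("ap_high")]),
        }

        stage("subgroups")
        subgroups = evaluate_subgroups(ap, clinical)
        subgroups.to_csv(outdir / "subgroups.tsv", sep="\t", index=False)
        summary["n_subgroup_rows"] = len(subgroups)

        stage("roc")
        try:
            roc = association.roc_auc_outcome(ap_t, clinical)
            summary["roc"] = {
                "auc_ap": roc.auc, "n_pos": roc.n_pos, "n_neg": roc.n_neg,
                "n_excluded": roc.n_excluded, "mean_os": roc.mean_os,
            }
        except association.AssociationError as exc:
            summary["roc"] = {"error": str(exc)}

        stage("genomics")
        if mutations is not None:
            mut = association.compare_mutation_freq(mutations, labels)
            mut.to_csv(outdir / "mutation_assoc.tsv", sep="\t", index=False)
            summary["mutations"] = {
                r["gene"]: {"q": r["q"], "enriched_in": r["enriched_in"]}
                for r in mut.to_dict("records")
            }
        if cnv is not None:
            cnv_tab = association.compare_cnv(cnv, labels)
            cnv_tab.to_csv(outdir / "cnv_assoc.tsv", sep="\t", index=False)
            summary["cnv"] = {
                r["gene"]: {
                    "mean_high": r["mean_high"], "mean_low": r["mean_low"], "q": r["q"]
                }
                for r in cnv_tab.to_dict("records")
            }
    except Exception as exc:  # noqa: BLE001 - abort carries stage context
        failed = manifest["stages"][-1] if manifest["stages"] else "init"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=_jsonable)
        raise PipelineError(failed, exc, manifest) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return summary


def _cox_covariates(
    clinical: data_io.CohortClinical, tumours: list[str], ap_high: np.ndarray
) -> pd.DataFrame:
    """0/1-encoded multivariate design: AP group plus the clinical covariates."""
    t = clinical.table.set_index("sample_id").loc[tumours]
    covs = pd.DataFrame(index=t.index)
    covs["ap_high"] = ap_high.astype(float)
    covs["gbm"] = (t["tissue_group"] == "GBM").astype(float)
    covs["age_ge60"] = (t["age"] >= 60).astype(float)
    covs["male"] = (t["gender"] == "M").astype(float)
    for name, col, level in (
        ("mgmt_unmeth", "mgmt", "unmethylated"),
        ("idh_wt", "idh", "wildtype"),
        ("chemo_yes", "chemo", "yes"),
        ("radio_yes", "radio", "yes"),
    ):
        vals = (t[col] == level).astype(float)
        if vals.nunique() > 1:
            covs[name] = vals
    return covs.reset_index(drop=True)
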