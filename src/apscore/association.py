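"""Non-survival statistics relating the AP score to covariates, mutations,
CNV, genes and immune-cell enrichment."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CNVMatrix, CohortClinical, ExpressionMatrix, GeneSet, MutationTable
from .scoring import APScores, SSGSEAConfig, ssgsea_matrix
from .selection import bh_adjust
from .survival import SurvivalError, dichotomize_by_median, logrank_test

logger = logging.getLogger(__name__)


class AssociationError(ValueError):
    pass


@dataclass
class AssociationResult:
    name: str
    test: str  # anova | chi2 | fisher | welch_t | paired_t | pearson
    statistic: float
    p: float
    q: float = float("nan")
    extra: dict = field(default_factory=dict)


@dataclass
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int
    mean_os: float
    n_excluded: int


def anova_oneway(groups: list) -> AssociationResult:
    """One-way ANOVA: F = MS_between / MS_within, p from F(k-1, n-k)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise AssociationError("need >= 2 groups with >= 2 values each")
    n = sum(g.size for g in gs)
    k = len(gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ssw == 0:
        if ssb == 0:
            return AssociationResult("anova", "anova", 0.0, 1.0)
        return AssociationResult("anova", "anova", float("inf"), 0.0)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return AssociationResult("anova", "anova", float(f), p)


def contingency_test(table, method: str = "auto") -> AssociationResult:
    """Fisher exact (two-sided) for sparse 2x2 tables, else Pearson chi-square
    without continuity correction.  ``method`` in {auto, fisher, chi2}."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or np.any(tab < 0) or np.any(tab != np.rint(tab)):
        raise AssociationError("table must be non-negative integers")
    tab = tab.astype(int)
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise AssociationError("zero margin in contingency table")
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    use_fisher = method == "fisher" or (
        method == "auto" and tab.shape == (2, 2) and (expected < 5).any()
    )
    if use_fisher:
        if tab.shape != (2, 2):
            raise AssociationError("Fisher exact implemented for 2x2 tables only")
        odds, p = stats.fisher_exact(tab, alternative="two-sided")
        return AssociationResult("contingency", "fisher", float(odds), float(p))
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return AssociationResult("contingency", "chi2", float(chi2), float(p))


def pearson_corr(x, y) -> AssociationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise AssociationError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AssociationError("constant vector; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return AssociationResult("pearson", "pearson", float(r), float(p))


def paired_t(x, y) -> AssociationResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise AssociationError("need >= 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise AssociationError("zero difference variance; paired t undefined")
    t = d.mean() / (sd / np.sqrt(d.size))
    p = float(2 * stats.t.sf(abs(t), d.size - 1))
    return AssociationResult("paired_t", "paired_t", float(t), p)


def welch_t(a, b) -> AssociationResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AssociationError("need >= 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return AssociationResult("welch_t", "welch_t", 0.0, 1.0)
        return AssociationResult("welch_t", "welch_t", float("inf"), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return AssociationResult("welch_t", "welch_t", float(t), float(p))


def _auc_mann_whitney(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """AUC as tie-corrected U/(n_pos*n_neg): ties count one half."""
    allv = np.concatenate([scores_pos, scores_neg])
    ranks = stats.rankdata(allv)
    n_pos = scores_pos.size
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * scores_neg.size))


def label_outcomes(clinical_tumours: pd.DataFrame) -> tuple[pd.Series, float, int]:
    """Outcome labels for ROC: mean OS over deceased patients; positive = died
    before mean OS; negative = followed beyond mean OS (any status); censored
    short of mean OS = indeterminate, excluded.

    Returns (label Series indexed by sample_id with values 1/0, mean_os,
    n_excluded)."""
    df = clinical_tumours
    deceased = df["event"] == 1
    if not deceased.any():
        raise AssociationError("no deaths; cannot define mean OS")
    mean_os = float(df.loc[deceased, "os_days"].mean())
    pos = deceased & (df["os_days"] < mean_os)
    neg = df["os_days"] >= mean_os
    excluded = (~deceased) & (df["os_days"] < mean_os)
    labels = pd.Series(np.nan, index=df["sample_id"])
    labels[pos.to_numpy()] = 1.0
    labels[neg.to_numpy()] = 0.0
    return labels, mean_os, int(excluded.sum())


def roc_auc_outcome(scores: pd.Series, clinical: CohortClinical) -> ROCResult:
    """AUC of ``scores`` against the mean-OS outcome labelling."""
    tum = clinical.table[clinical.table["tissue_group"] != "NT"]
    tum = tum[tum["sample_id"].isin(scores.index)]
    labels, mean_os, n_excl = label_outcomes(tum)
    keep = labels.dropna()
    s = scores.loc[keep.index].to_numpy(float)
    y = keep.to_numpy()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise AssociationError(
            f"degenerate labelling: {n_pos} positives, {n_neg} negatives, "
            f"{n_excl} excluded at mean OS {mean_os:.1f}"
        )
    auc = _auc_mann_whitney(s[y == 1], s[y == 0])
    return ROCResult(auc, n_pos, n_neg, mean_os, n_excl)


def combine_predictors(
    binary_outcome, factor_a, factor_b, max_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, bool]:
    """Logistic regression (ML, Newton-Raphson) of outcome on two factors;
    returns (linear predictor, separation_flag).  On perfect separation the
    last iterate's predictor is returned with a warning."""
    y = np.asarray(binary_outcome, dtype=float)
    X = np.column_stack(
        [np.ones(y.size), np.asarray(factor_a, float), np.asarray(factor_b, float)]
    )
    if not np.all(np.isin(y, (0, 1))):
        raise AssociationError("outcome must be 0/1")
    beta = np.zeros(3)
    separated = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            break
        hess = (X * w[:, None]).T @ X
        # lstsq tolerates collinear designs (e.g. a constant second factor)
        step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(beta)) > 30:
            separated = True
            break
    if separated:
        logger.warning("combine_predictors: perfect separation suspected")
    return X @ beta, separated


def compare_mutation_freq(
    mutations: MutationTable, ap_labels: pd.Series
) -> pd.DataFrame:
    """Per gene: 2x2 (mutated x AP group) test, BH across genes, direction =
    group with the higher mutated fraction.  ``ap_labels`` maps sample_id to
    'high'/'low'."""
    rows = []
    for gene in mutations.genes:
        status = mutations.gene_status(gene)
        common = status.index.intersection(ap_labels.index)
        if len(common) == 0 or not status.loc[common].any():
            logger.warning("mutation gene %s skipped (no mutated overlap)", gene)
            continue
        mut = status.loc[common].to_numpy(bool)
        high = (ap_labels.loc[common] == "high").to_numpy()
        tab = np.array(
            [
                [(mut & high).sum(), (mut & ~high).sum()],
                [(~mut & high).sum(), (~mut & ~high).sum()],
            ]
        )
        frac_high = tab[0, 0] / max(tab[:, 0].sum(), 1)
        frac_low = tab[0, 1] / max(tab[:, 1].sum(), 1)
        if mut.all():
            res = AssociationResult(gene, "chi2", 0.0, 1.0)
        else:
            res = contingency_test(tab)
        rows.append(
            {
                "gene": gene,
                "test": res.test,
                "statistic": res.statistic,
                "p": res.p,
                "frac_high": frac_high,
                "frac_low": frac_low,
                "enriched_in": "high" if frac_high >= frac_low else "low",
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def compare_cnv(cnv: CNVMatrix, ap_labels: pd.Series) -> pd.DataFrame:
    """Per gene: group means and Welch two-sided t of copy number by AP group."""
    common = [s for s in cnv.sample_ids if s in ap_labels.index]
    sub = cnv.subset_samples(common)
    high = (ap_labels.loc[common] == "high").to_numpy()
    if high.sum() < 2 or (~high).sum() < 2:
        raise AssociationError("both AP groups need >= 2 samples")
    rows = []
    for i, gene in enumerate(sub.gene_ids):
        x = sub.values[i]
        res = welch_t(x[high], x[~high])
        rows.append(
            {
                "gene": gene,
                "mean_high": float(x[high].mean()),
                "mean_low": float(x[~high].mean()),
                "t": res.statistic,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def correlate_genes_with_score(
    expr: ExpressionMatrix, ap_scores: pd.Series, r_threshold: float = 0.6
) -> tuple[set[str], set[str], dict[str, float]]:
    """Per-gene Pearson r against the AP score; positive set r > threshold,
    negative set r < -threshold (strict).  Constant genes skipped."""
    common = [s for s in expr.sample_ids if s in ap_scores.index]
    if len(common) < 3:
        raise AssociationError("need >= 3 scored samples")
    sub = expr.subset_samples(common)
    ap = ap_scores.loc[common].to_numpy(float)
    r_map: dict[str, float] = {}
    for i, gene in enumerate(sub.gene_ids):
        x = sub.values[i]
        if np.ptp(x) == 0:
            logger.warning("gene %s constant; skipped in correlation", gene)
            continue
        r_map[gene] = float(stats.pearsonr(x, ap)[0])
    pos = {g for g, r in r_map.items() if r > r_threshold}
    neg = {g for g, r in r_map.items() if r < -r_threshold}
    return pos, neg, r_map


def immune_ssgsea_association(
    expr: ExpressionMatrix,
    immune_sets: list[GeneSet],
    ap_scores: pd.Series,
    clinical: CohortClinical,
    ssgsea_config: SSGSEAConfig | None = None,
) -> pd.DataFrame:
    """Per immune set: Pearson r with AP, its p, and the log-rank p for the
    median-dichotomized set score — one row per input set."""
    tumours = [s for s in clinical.tumour_samples() if s in expr.sample_ids]
    sub = expr.subset_samples(tumours)
    times, events = clinical.survival(tumours)
    ap = ap_scores.loc[tumours].to_numpy(float)
    rows = []
    for gs in immune_sets:
        if not (gs.genes & set(sub.gene_ids)):
            logger.warning("immune set %s has no overlap; NA row", gs.name)
            rows.append({"set": gs.name, "r": np.nan, "r_p": np.nan, "logrank_p": np.nan})
            continue
        score = ssgsea_matrix(sub, [gs], ssgsea_config or SSGSEAConfig(normalize=False)).iloc[0]
        r, r_p = stats.pearsonr(score.to_numpy(), ap)
        try:
            labels = dichotomize_by_median(score.to_numpy())
            high = labels == "high"
            lr = logrank_test(times[high], events[high], times[~high], events[~high])
            lr_p = lr.p
        except SurvivalError:
            lr_p = np.nan
        rows.append({"set": gs.name, "r": float(r), "r_p": float(r_p), "logrank_p": lr_p})
    return pd.DataFrame(rows)
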