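"""Five-criterion progression-gene selection cascade.

Criteria, each computed on its own and intersected:

  i.   differential expression tumour vs normal (q < fdr_max, |logFC| >= lfc_min)
  ii.  differential expression GBM vs LGG (same thresholds)
  iii. high variability across tumours (scaled MAD > mad_min)
  iv.  same sign of logFC in both contrasts
  v.   per-gene survival relevance (median-split log-rank p < km_p_max)

The output pair assigns genes with positive trend to POS and negative to NEG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CohortClinical, ExpressionMatrix, GeneSet, GeneSetPair
from .survival import SurvivalError, logrank_test

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


class EmptySignatureError(SelectionError):
    """No gene survived all five criteria; carries the audit table."""

    def __init__(self, audit: pd.DataFrame):
        super().__init__("selection cascade produced an empty POS or NEG set")
        self.audit = audit


@dataclass
class SelectionConfig:
    fdr_max: float = 0.01
    lfc_min: float = 1.5
    mad_min: float = 1.0
    mad_constant: float = 1.4826
    km_p_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max < 1 or not 0 < self.km_p_max < 1:
            raise SelectionError("fdr_max and km_p_max must lie in (0,1)")
        if min(self.lfc_min, self.mad_min, self.mad_constant) <= 0:
            raise SelectionError("thresholds must be positive")


@dataclass
class DEResult:
    gene: str
    logFC: float
    p: float
    q: float = float("nan")


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, clipped to <= 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise SelectionError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # identical values in both groups: no evidence
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)


def differential_expression(
    expr: ExpressionMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
) -> list[DEResult]:
    """Per-gene logFC (mean A - mean B, log2 units) and Wilcoxon rank-sum p,
    BH-adjusted across all genes tested."""
    a_ids, b_ids = list(samples_a), list(samples_b)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise SelectionError("each group needs >= 2 samples")
    if set(a_ids) & set(b_ids):
        raise SelectionError("groups must be disjoint")
    A = expr.subset_samples(a_ids).values
    B = expr.subset_samples(b_ids).values
    logfc = A.mean(axis=1) - B.mean(axis=1)
    pvals = np.array([_ranksum_p(A[i], B[i]) for i in range(expr.n_genes)])
    qvals = bh_adjust(pvals)
    return [
        DEResult(g, float(lfc), float(p), float(q))
        for g, lfc, p, q in zip(expr.gene_ids, logfc, pvals, qvals)
    ]


def mad_filter(
    expr: ExpressionMatrix,
    config: SelectionConfig | None = None,
    samples: Sequence[str] | None = None,
) -> set[str]:
    """Genes whose scaled MAD over the given samples exceeds ``mad_min`` (strict)."""
    cfg = config or SelectionConfig()
    m = expr if samples is None else expr.subset_samples(list(samples))
    if m.n_samples < 2:
        raise SelectionError("MAD filter needs >= 2 samples")
    med = np.median(m.values, axis=1, keepdims=True)
    mad = cfg.mad_constant * np.median(np.abs(m.values - med), axis=1)
    return {g for g, v in zip(m.gene_ids, mad) if v > cfg.mad_min}


def same_trend_filter(
    de_tumour_vs_nt: Sequence[DEResult], de_gbm_vs_lgg: Sequence[DEResult]
) -> set[str]:
    """Genes whose logFC has the same (nonzero) sign in both contrasts."""
    fc1 = {d.gene: d.logFC for d in de_tumour_vs_nt}
    fc2 = {d.gene: d.logFC for d in de_gbm_vs_lgg}
    missing = set(fc1) ^ set(fc2)
    if missing:
        logger.warning("same_trend_filter: %d genes missing from one table", len(missing))
    kept = set()
    for g in set(fc1) & set(fc2):
        if np.sign(fc1[g]) == np.sign(fc2[g]) != 0:
            kept.add(g)
    return kept


def per_gene_km_filter(
    expr: ExpressionMatrix,
    clinical: CohortClinical,
    config: SelectionConfig | None = None,
) -> dict[str, float]:
    """Per gene: median-split (ties low) log-rank p over tumour samples.

    Genes with a degenerate split (constant expression) map to NaN.
    """
    tumours = clinical.tumour_samples()
    tumours = [s for s in tumours if s in expr.sample_ids]
    if len(tumours) < 4:
        raise SelectionError("need >= 4 tumour samples with survival")
    sub = expr.subset_samples(tumours)
    times, events = clinical.survival(tumours)
    pmap: dict[str, float] = {}
    for i, gene in enumerate(sub.gene_ids):
        x = sub.values[i]
        med = np.median(x)
        high = x > med
        if high.all() or not high.any():
            pmap[gene] = float("nan")
            continue
        try:
            res = logrank_test(times[high], events[high], times[~high], events[~high])
        except SurvivalError:
            pmap[gene] = float("nan")
            continue
        pmap[gene] = res.p
    return pmap


def select_progression_genes(
    expr: ExpressionMatrix,
    clinical: CohortClinical,
    config: SelectionConfig | None = None,
) -> tuple[GeneSetPair, pd.DataFrame]:
    """Run the full cascade; returns the signature and the per-gene audit table.

    Audit columns: the two logFCs plus booleans c1..c5 for the five criteria
    and ``selected``.  Raises :class:`EmptySignatureError` (audit attached)
    when either POS or NEG ends empty.
    """
    cfg = config or SelectionConfig()
    ct = clinical.table
    nt = list(ct.loc[ct["tissue_group"] == "NT", "sample_id"])
    lgg = list(ct.loc[ct["tissue_group"] == "LGG", "sample_id"])
    gbm = list(ct.loc[ct["tissue_group"] == "GBM", "sample_id"])
    if not nt or not lgg or not gbm:
        raise SelectionError("cohort must contain NT, LGG and GBM samples")
    tumours = lgg + gbm

    de_tumour = differential_expression(expr, tumours, nt)
    de_grade = differential_expression(expr, gbm, lgg)
    mad_pass = mad_filter(expr, cfg, samples=tumours)
    trend_pass = same_trend_filter(de_tumour, de_grade)
    km_p = per_gene_km_filter(expr, clinical, cfg)

    fc1 = {d.gene: d for d in de_tumour}
    fc2 = {d.gene: d for d in de_grade}
    rows = []
    for g in expr.gene_ids:
        d1, d2 = fc1[g], fc2[g]
        c1 = d1.q < cfg.fdr_max and abs(d1.logFC) >= cfg.lfc_min
        c2 = d2.q < cfg.fdr_max and abs(d2.logFC) >= cfg.lfc_min
        c3 = g in mad_pass
        c4 = g in trend_pass
        p5 = km_p.get(g, float("nan"))
        c5 = bool(p5 < cfg.km_p_max) if np.isfinite(p5) else False
        selected = c1 and c2 and c3 and c4 and c5
        rows.append(
            {
                "gene": g,
                "logFC_tumour_vs_nt": d1.logFC,
                "q_tumour_vs_nt": d1.q,
                "logFC_gbm_vs_lgg": d2.logFC,
                "q_gbm_vs_lgg": d2.q,
                "km_p": p5,
                "c1_de_tumour": c1,
                "c2_de_grade": c2,
                "c3_mad": c3,
                "c4_trend": c4,
                "c5_km": c5,
                "selected": selected,
            }
        )
    audit = pd.DataFrame(rows)

    sel = audit[audit["selected"]]
    pos_genes = frozenset(sel.loc[sel["logFC_gbm_vs_lgg"] > 0, "gene"])
    neg_genes = frozenset(sel.loc[sel["logFC_gbm_vs_lgg"] < 0, "gene"])
    if not pos_genes or not neg_genes:
        raise EmptySignatureError(audit)
    pair = GeneSetPair(GeneSet("POS_AP", pos_genes), GeneSet("NEG_AP", neg_genes))
    return pair, audit
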