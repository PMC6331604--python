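"""Single-sample enrichment scoring and the AP score.

The per-sample enrichment score (ES) is the accumulated difference between a
rank-weighted in-set ECDF and the uniform out-of-set ECDF, walking the genes of
one sample ordered by decreasing expression rank:

    ES = sum_i [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{k <= i, k in S} rank_k^alpha / sum_{k in S} rank_k^alpha
    P_out(i) = #{k <= i, k not in S} / (N - |S|)

The AP score of a sample is POS set score minus NEG set score, with both sets
normalized on a shared global range so the difference lives on one scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import ExpressionMatrix, GeneSet, GeneSetPair


class ScoringError(ValueError):
    pass


@dataclass
class SSGSEAConfig:
    alpha: float = 0.25
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ScoringError("alpha must be >= 0")


@dataclass
class APScores:
    """Per-sample POS, NEG and AP = POS - NEG enrichment values."""

    sample_ids: list[str]
    pos_score: np.ndarray
    neg_score: np.ndarray
    normalized: bool

    @property
    def ap_score(self) -> np.ndarray:
        return self.pos_score - self.neg_score

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "pos_score": self.pos_score,
                "neg_score": self.neg_score,
                "ap_score": self.ap_score,
            }
        )

    def as_series(self) -> pd.Series:
        return pd.Series(self.ap_score, index=self.sample_ids, name="ap_score")


def rank_transform(sample_values: Sequence[float]) -> np.ndarray:
    """Within-sample ranks, 1..N with N = highest expression; ties averaged."""
    x = np.asarray(sample_values, dtype=float)
    if x.size < 2:
        raise ScoringError("need >= 2 genes to rank")
    if not np.all(np.isfinite(x)):
        raise ScoringError("non-finite expression value")
    return rankdata(x, method="average")


def ssgsea_es(
    ranks: Sequence[float], in_set: Sequence[bool] | np.ndarray, alpha: float = 0.25
) -> float:
    """Raw enrichment score for one sample and one gene set.

    ``ranks`` are the within-sample ranks; ``in_set`` flags set membership per
    gene, aligned with ``ranks``.
    """
    r = np.asarray(ranks, dtype=float)
    mask = np.asarray(in_set, dtype=bool)
    if r.shape != mask.shape:
        raise ScoringError("ranks and membership must align")
    n_in = int(mask.sum())
    if n_in == 0:
        raise ScoringError("gene set has no overlap with the ranked genes")
    if n_in == r.size:
        raise ScoringError("gene set covers the whole universe; P_out undefined")

    order = np.argsort(-r, kind="stable")  # decreasing rank value
    mask_o = mask[order]
    w = np.where(mask_o, r[order] ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~mask_o) / (r.size - n_in)
    return float(np.sum(p_in - p_out))


def _membership(gene_ids: Sequence[str], genes: frozenset[str]) -> np.ndarray:
    return np.fromiter((g in genes for g in gene_ids), dtype=bool, count=len(gene_ids))


def ssgsea_matrix(
    expr: ExpressionMatrix,
    gene_sets: Iterable[GeneSet],
    config: SSGSEAConfig | None = None,
) -> pd.DataFrame:
    """Set-by-sample score matrix (rows = sets, columns = samples).

    With ``config.normalize``, every entry of the raw matrix is divided by the
    global (max - min) over all entries.
    """
    cfg = config or SSGSEAConfig()
    sets = list(gene_sets)
    if not sets:
        raise ScoringError("no gene sets given")
    masks = []
    for s in sets:
        present = s.intersect(expr.gene_ids)
        if not present:
            raise ScoringError(f"gene set {s.name!r} has no overlap with the matrix")
        masks.append(_membership(expr.gene_ids, present))

    scores = np.empty((len(sets), expr.n_samples))
    for j in range(expr.n_samples):
        r = rank_transform(expr.values[:, j])
        for i, mask in enumerate(masks):
            scores[i, j] = ssgsea_es(r, mask, cfg.alpha)
    if cfg.normalize:
        rng = scores.max() - scores.min()
        if rng == 0:
            raise ScoringError("zero score range; cannot range-normalize")
        scores = scores / rng
    return pd.DataFrame(scores, index=[s.name for s in sets], columns=expr.sample_ids)


def ap_score(
    expr: ExpressionMatrix, pair: GeneSetPair, config: SSGSEAConfig | None = None
) -> APScores:
    """POS/NEG/AP scores per sample; POS and NEG share one normalization range."""
    cfg = config or SSGSEAConfig()
    mat = ssgsea_matrix(expr, [pair.pos, pair.neg], cfg)
    return APScores(
        sample_ids=list(mat.columns),
        pos_score=mat.iloc[0].to_numpy(),
        neg_score=mat.iloc[1].to_numpy(),
        normalized=cfg.normalize,
    )
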