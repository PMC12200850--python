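"""Single-sample gene-set enrichment (ssGSEA) and immune-feature statistics.

The ssGSEA score of a gene set in one sample is a weighted
Kolmogorov-Smirnov-like statistic over the within-sample expression ranking:
genes are ordered by decreasing expression, and the score is the sum over the
ordered list of the difference between two empirical cumulative
distributions — the in-set CDF, which accumulates ``rank^alpha`` weight
(``alpha = 0.25`` by convention), and the out-of-set CDF, which accumulates
uniformly.  Because only within-sample ranks enter, scores are invariant to
any strictly monotone per-sample transform.

Normalisation options mirror common practice: ``raw`` running sums,
``range_normalized`` (divide every score by the global max-min spread, the
original ssGSEA convention), and ``zscore_by_set`` (per-set z-score across
samples, the usual display scale for immune-infiltration heatmaps).

Class comparisons use the one-sided Wilcoxon rank-sum (Mann-Whitney) test and
gene-versus-cell-score association uses Spearman rank correlation with
Benjamini-Hochberg adjustment across the whole table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_preprocess import ExpressionMatrix, GeneSetCollection

__all__ = [
    "SsgseaScoreMatrix",
    "ssgsea_scores",
    "compare_feature_by_class",
    "gene_cell_correlations",
    "rank_sum_test",
]


@dataclass
class SsgseaScoreMatrix:
    """Gene-set x sample enrichment scores."""

    scores: pd.DataFrame  # sets x samples
    alpha: float
    normalization: str  # raw | range_normalized | zscore_by_set

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def to_tsv(self, path: str | Path) -> None:
        frame = self.scores.copy()
        frame.index.name = "set_name"
        frame.to_csv(path, sep="\t", na_rep="NA")


def _sample_running_sums(
    values: np.ndarray, masks: np.ndarray, alpha: float
) -> np.ndarray:
    """ssGSEA running-sum scores for one sample.

    ``values``: expression vector (NaN allowed); ``masks``: sets x genes
    boolean membership.  Missing genes are dropped from the ranking for this
    sample.  Within-sample rank ties take the average rank for weighting; the
    walking order among tied genes follows the (stable) gene order, which a
    monotone transform cannot change.
    """
    observed = ~np.isnan(values)
    v = values[observed]
    m = masks[:, observed]
    n = v.size
    out = np.full(masks.shape[0], np.nan)
    if n == 0:
        return out
    ranks = stats.rankdata(v, method="average")  # 1..n, highest expression = n
    order = np.argsort(-v, kind="stable")
    w_all = ranks[order] ** alpha
    for k in range(masks.shape[0]):
        inset = m[k][order]
        n_in = int(inset.sum())
        if n_in == 0 or n_in == n:
            continue  # undefined: no in-set gene observed, or no out-of-set gene
        w_in = np.where(inset, w_all, 0.0)
        p_in = np.cumsum(w_in) / w_in.sum()
        p_out = np.cumsum(~inset) / (n - n_in)
        out[k] = float(np.sum(p_in - p_out))
    return out


def ssgsea_scores(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalization: str = "raw",
) -> SsgseaScoreMatrix:
    """Score every gene set in every sample.

    A set with no gene in the matrix scores ``NaN`` everywhere (reported with
    a warning rather than raised, so one absent signature does not abort a
    28-set panel).
    """
    if normalization not in ("raw", "range_normalized", "zscore_by_set"):
        raise ValueError(f"unknown normalization {normalization!r}")
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    names = sets.names
    masks = np.zeros((len(names), len(gene_index)), dtype=bool)
    for k, name in enumerate(names):
        hits = [gene_index[g] for g in sets[name] if g in gene_index]
        if not hits:
            warnings.warn(f"gene set {name!r} has no gene in the matrix; scores are NA", stacklevel=2)
            continue
        masks[k, hits] = True

    X = matrix.values.to_numpy(dtype=float)
    scores = np.column_stack(
        [_sample_running_sums(X[:, s], masks, alpha) for s in range(X.shape[1])]
    )
    frame = pd.DataFrame(scores, index=names, columns=matrix.sample_ids)

    if normalization == "range_normalized":
        spread = np.nanmax(frame.values) - np.nanmin(frame.values)
        if spread > 0:
            frame = frame / spread
    elif normalization == "zscore_by_set":
        mu = frame.mean(axis=1)
        sd = frame.std(axis=1, ddof=1)
        frame = frame.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return SsgseaScoreMatrix(scores=frame, alpha=alpha, normalization=normalization)


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) U of x vs y.

    Exact enumeration when both groups are small (<= 25) and tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction.  Constant pooled data yields p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("constant feature: rank-sum p-value set to 1", stacklevel=2)
        return float(x.size * y.size / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_feature_by_class(
    feature: Sequence[float] | pd.Series,
    labels: Sequence[str] | pd.Series,
    direction: str = "case>control",
    case_label: str = "case",
    control_label: str = "control",
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum comparison of a feature between classes.

    ``direction`` is ``"case>control"`` or ``"case<control"``, naming the
    alternative hypothesis.  Returns ``(U statistic of case vs control, p)``.
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(list(labels), dtype=object)
    case_vals = feature[labels == case_label]
    control_vals = feature[labels == control_label]
    if direction == "case>control":
        alternative = "greater"
    elif direction == "case<control":
        alternative = "less"
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return rank_sum_test(case_vals, control_vals, alternative=alternative)


def gene_cell_correlations(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    score_matrix: SsgseaScoreMatrix,
) -> pd.DataFrame:
    """Spearman rho between each gene's expression and each set's scores.

    BH adjustment is applied across the whole (gene x set) table.  Samples
    are aligned by ID; fewer than 3 aligned samples is an error.
    """
    shared = [s for s in matrix.sample_ids if s in score_matrix.scores.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 aligned samples for correlation")
    sub = matrix.subset_genes(list(genes)).values[shared]
    scores = score_matrix.scores[shared]
    rows = []
    for gene in genes:
        gvals = sub.loc[gene].to_numpy(dtype=float)
        for set_name in score_matrix.set_names:
            svals = scores.loc[set_name].to_numpy(dtype=float)
            ok = ~(np.isnan(gvals) | np.isnan(svals))
            if ok.sum() < 3:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(gvals[ok], svals[ok])
            rows.append({"gene": gene, "set_name": set_name, "rho": rho, "p_value": p})
    table = pd.DataFrame(rows)
    pvals = table["p_value"].to_numpy(dtype=float)
    fdr = np.full_like(pvals, np.nan)
    tested = ~np.isnan(pvals)
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    table["fdr"] = fdr
    return table
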