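"""Differential expression, cross-cohort consistency, co-expression networks
and gene-set over-representation.

Differential expression uses the two-sided Wilcoxon rank-sum test per gene
with Benjamini-Hochberg control of the false discovery rate (cutoff 0.01 by
default).  Direction of change comes from the class medians; a median tie
gives direction ``"none"`` and such genes are excluded from the
consistent-DEG intersection, since a "consistent" change requires a sign.

Co-expression networks connect seed genes (signature genes plus, typically,
inflammation-related genes) to candidate genes (the DEGs) by Spearman rank
correlation; an edge requires both ``|rho|`` strictly above the cutoff (0.6)
and BH FDR below the cutoff (0.01), with one BH family over all tested
seed-candidate pairs.  By default each sample is first reduced to its
within-sample ranks, so the correlations — like every other statistic in
this pipeline — are invariant to per-sample monotone distortions; raw-value
correlation is available via ``within_sample_ranks=False``.

Over-representation of a query gene list in user-supplied sets uses the
upper-tail hypergeometric probability P(X >= overlap), BH-adjusted across
sets.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .immune_ssgsea import rank_sum_test
from .io_preprocess import ExpressionMatrix, GeneSetCollection

__all__ = [
    "wilcoxon_deg",
    "consistent_degs",
    "coexpression_network",
    "hypergeom_enrich",
    "localize_inflammation_genes",
]


def wilcoxon_deg(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    fdr_cutoff: float = 0.01,
    case_label: str = "case",
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum with BH adjustment.

    Returns a frame indexed by gene with columns ``statistic``, ``p_value``,
    ``fdr``, ``direction`` (up_in_case / down_in_case / none),
    ``median_case``, ``median_control`` and ``significant``.
    Constant genes get p = 1 and stay in the table (and the BH family).
    """
    case_samples = [s for s in matrix.sample_ids if labels.get(s) == case_label]
    control_samples = [s for s in matrix.sample_ids if labels.get(s) == control_label]
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError("both classes need at least 2 samples")
    Xc = matrix.values[case_samples].to_numpy(dtype=float)
    Xn = matrix.values[control_samples].to_numpy(dtype=float)

    stats_col = np.empty(matrix.shape[0])
    pvals = np.empty(matrix.shape[0])
    med_case = np.nanmedian(Xc, axis=1)
    med_control = np.nanmedian(Xn, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes warn inside rank_sum_test
        for i in range(matrix.shape[0]):
            x = Xc[i][~np.isnan(Xc[i])]
            y = Xn[i][~np.isnan(Xn[i])]
            if x.size < 2 or y.size < 2:
                stats_col[i], pvals[i] = np.nan, 1.0
                continue
            stats_col[i], pvals[i] = rank_sum_test(x, y, alternative="two-sided")
    fdr = multipletests(pvals, method="fdr_bh")[1]
    direction = np.where(
        med_case > med_control,
        "up_in_case",
        np.where(med_case < med_control, "down_in_case", "none"),
    )
    table = pd.DataFrame(
        {
            "statistic": stats_col,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
            "median_case": med_case,
            "median_control": med_control,
            "significant": fdr < fdr_cutoff,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    return table


def consistent_degs(table_a: pd.DataFrame, table_b: pd.DataFrame) -> list[str]:
    """Genes significant in both tables with the same signed direction."""
    shared = table_a.index.intersection(table_b.index)
    out = []
    for gene in shared:
        ra, rb = table_a.loc[gene], table_b.loc[gene]
        if (
            bool(ra["significant"])
            and bool(rb["significant"])
            and ra["direction"] == rb["direction"]
            and ra["direction"] != "none"
        ):
            out.append(gene)
    return sorted(out)


def _spearman_seed_vs_candidates(
    seed: np.ndarray, cands: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Spearman rho/p of one seed against many candidates.

    Complete data only (no NaN); p-values use the usual t approximation,
    matching :func:`scipy.stats.spearmanr`.
    """
    n = seed.size
    rs = stats.rankdata(seed)
    rc = np.apply_along_axis(stats.rankdata, 1, cands)
    rs = rs - rs.mean()
    rc = rc - rc.mean(axis=1, keepdims=True)
    denom = np.sqrt((rs**2).sum() * (rc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rc @ rs) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def coexpression_network(
    matrix: ExpressionMatrix,
    seed_genes: Sequence[str],
    candidate_genes: Sequence[str],
    rho_cutoff: float = 0.6,
    fdr_cutoff: float = 0.01,
    within_sample_ranks: bool = True,
) -> pd.DataFrame:
    """Seed-to-candidate Spearman edges passing |rho| > cutoff and FDR < cutoff.

    All seed x candidate tests form one BH family.  A candidate equal to a
    seed is skipped.  With ``within_sample_ranks`` (the default) every sample
    is rank-transformed over the *whole* matrix before correlating, which
    makes the edges invariant to per-sample monotone distortion.  Returns an
    edge table with columns ``seed_gene``, ``partner_gene``, ``rho``,
    ``p_value``, ``fdr`` and ``sign``; the full test table is attached under
    ``frame.attrs["tested"]``.
    """
    if matrix.shape[1] < 4:
        raise ValueError("need at least 4 samples for a correlation network")
    if within_sample_ranks:
        ranked = matrix.values.rank(axis=0)  # NaN stays NaN
        matrix = ExpressionMatrix(ranked, matrix.labels)
    seeds = list(dict.fromkeys(seed_genes))
    cands = list(dict.fromkeys(candidate_genes))
    sub = matrix.subset_genes(sorted(set(seeds) | set(cands)))
    X = sub.values.to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(sub.gene_ids)}
    has_nan = np.isnan(X).any()

    rows = []
    cand_list_per_seed = {s: [c for c in cands if c != s] for s in seeds}
    for seed in seeds:
        clist = cand_list_per_seed[seed]
        if not clist:
            continue
        sv = X[idx[seed]]
        cv = X[[idx[c] for c in clist]]
        if not has_nan:
            rho, p = _spearman_seed_vs_candidates(sv, cv)
        else:
            rho = np.empty(len(clist))
            p = np.empty(len(clist))
            for k in range(len(clist)):
                ok = ~(np.isnan(sv) | np.isnan(cv[k]))
                if ok.sum() < 4:
                    rho[k], p[k] = np.nan, np.nan
                else:
                    rho[k], p[k] = stats.spearmanr(sv[ok], cv[k][ok])
        for k, cand in enumerate(clist):
            rows.append({"seed_gene": seed, "partner_gene": cand, "rho": rho[k], "p_value": p[k]})
    tested = pd.DataFrame(rows, columns=["seed_gene", "partner_gene", "rho", "p_value"])
    if tested.empty:
        edges = tested.assign(fdr=pd.Series(dtype=float), sign=pd.Series(dtype=object))
        edges.attrs["tested"] = tested
        return edges
    pvals = tested["p_value"].to_numpy(dtype=float)
    fdr = np.full_like(pvals, np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        fdr[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    tested["fdr"] = fdr
    keep = (tested["rho"].abs() > rho_cutoff) & (tested["fdr"] < fdr_cutoff)
    edges = tested[keep.fillna(False)].copy()
    edges["sign"] = np.where(edges["rho"] > 0, "+", "-")
    edges = edges.reset_index(drop=True)
    edges.attrs["tested"] = tested
    return edges


def hypergeom_enrich(
    query_genes: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a query list.

    For each set: p = P(X >= overlap) with X ~ Hypergeom(universe, set-in-
    universe, query).  Sets with no gene in the universe are skipped with a
    warning.  BH across the tested sets; rows sorted by p-value.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError(f"query genes outside universe: {sorted(query - universe)[:5]}")
    rows = []
    for name in sets.names:
        members = sets.members(name) & universe
        if not members:
            warnings.warn(f"gene set {name!r} has no gene in the universe; skipped", stacklevel=2)
            continue
        overlap = len(query & members)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
        rows.append(
            {
                "set_name": name,
                "overlap_count": overlap,
                "set_size": len(members),
                "query_size": len(query),
                "universe_size": len(universe),
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "overlap_count",
            "set_size",
            "query_size",
            "universe_size",
            "p_value",
        ],
    )
    if not table.empty:
        table["fdr"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
        table = table.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
    return table


def localize_inflammation_genes(
    deg_table: pd.DataFrame,
    inflammation_sets: GeneSetCollection,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tag genes with the inflammation categories they belong to.

    ``genes`` defaults to every gene in ``deg_table``.  Output keeps untagged
    genes (empty ``categories``) so the full table remains inspectable.
    """
    if genes is None:
        genes = list(deg_table.index)
    membership = {name: inflammation_sets.members(name) for name in inflammation_sets.names}
    rows = []
    for gene in genes:
        cats = sorted(name for name, members in membership.items() if gene in members)
        row = {"gene": gene, "categories": ";".join(cats)}
        if gene in deg_table.index:
            row["direction"] = deg_table.loc[gene, "direction"]
            row["fdr"] = deg_table.loc[gene, "fdr"]
            row["significant"] = bool(deg_table.loc[gene, "significant"])
        else:
            row["direction"] = "none"
            row["fdr"] = np.nan
            row["significant"] = False
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", "categories", "direction", "fdr", "significant"])
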