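"""Differential expression between cell groups and signed rank statistics.

Markers between two groups of cells (clones, clusters, samples) are scored
on log-normalized expression with a two-sided Wilcoxon rank-sum test
(exact for small tie-free groups, normal approximation with tie correction
otherwise), a natural-log fold change of mean normalized expression with
pseudo-count 1, and Benjamini-Hochberg FDR over the tested genes. Genes
with |logFC| below a floor (0.10 here) are excluded before testing.

The signed rank statistic for pre-ranked enrichment input is
``-log10(FDR) * sign(logFC)``: upregulated genes positive, downregulated
negative, FDR = 0 capped at +-cap for finiteness. Enrichment-score
computation itself is out of scope; this module only produces the ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix

MIN_LFC = 0.10
RANK_CAP = 300.0


def _log_normalize(counts: CountMatrix) -> np.ndarray:
    X = counts.matrix.T.astype(float).toarray()  # cells x genes
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(X / totals * 1e4)


def wilcoxon_de(
    counts: CountMatrix,
    group_labels: np.ndarray,
    group1=None,
    group2=None,
    min_lfc: float = MIN_LFC,
) -> pd.DataFrame:
    """Two-group differential expression on log-normalized expression.

    Returns a table with natural-log fold change of group means
    (pseudo-count 1 on the de-logged normalized means), two-sided Wilcoxon
    rank-sum p-values, BH-adjusted FDR, and per-group detection fractions.
    Genes failing the |logFC| floor are excluded before testing (and from
    the BH family).
    """
    labels = np.asarray(group_labels)
    if group1 is None or group2 is None:
        uniq = sorted(set(labels))
        if len(uniq) != 2:
            raise ValueError("group_labels must contain exactly two groups")
        group1, group2 = uniq
    m1, m2 = labels == group1, labels == group2
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 cells")
    X = _log_normalize(counts)
    names = counts.gene_names if counts.gene_names is not None else counts.gene_ids
    # fold change on the normalized (de-logged) scale, pseudo-count 1
    mean1 = np.expm1(X[m1]).mean(axis=0)
    mean2 = np.expm1(X[m2]).mean(axis=0)
    lfc = np.log((mean1 + 1.0) / (mean2 + 1.0))
    det1 = (counts.matrix.T[m1] > 0).mean(axis=0).A.ravel()
    det2 = (counts.matrix.T[m2] > 0).mean(axis=0).A.ravel()

    tested = np.abs(lfc) >= min_lfc
    pvals = np.ones(tested.sum())
    for out_i, g in enumerate(np.where(tested)[0]):
        a, b = X[m1, g], X[m2, g]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[out_i] = 1.0
            continue
        pvals[out_i] = mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
    fdr = benjamini_hochberg(pvals) if len(pvals) else pvals

    out = pd.DataFrame(
        {
            "gene": np.asarray(names, object),
            "logFC": lfc,  # natural log
            "pct_1": det1,
            "pct_2": det2,
        }
    )
    out = out.loc[tested].reset_index(drop=True)
    out["p_value"] = pvals
    out["fdr"] = fdr
    return out


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (delegates to statsmodels)."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def rank_statistic(de: pd.DataFrame, cap: float = RANK_CAP) -> pd.DataFrame:
    """Signed pre-ranked enrichment scores: -log10(FDR) * sign(logFC).

    FDR of exactly 0 maps to +-cap; FDR 1 to 0. Output is sorted by score
    descending with ties broken by gene name, ready to write as an RNK file.
    """
    if "fdr" not in de.columns:
        raise ValueError("DE table lacks an 'fdr' column")
    fdr = de["fdr"].to_numpy(float)
    if np.isnan(fdr).any():
        raise ValueError("missing FDR values")
    sign = np.sign(de["logFC"].to_numpy(float))
    with np.errstate(divide="ignore"):
        mag = -np.log10(fdr)
    mag = np.where(np.isinf(mag), cap, np.minimum(mag, cap))
    out = pd.DataFrame({"gene": de["gene"], "score": mag * sign})
    return out.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def write_rnk(ranked: pd.DataFrame, path) -> None:
    ranked[["gene", "score"]].to_csv(path, sep="\t", header=False, index=False)
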