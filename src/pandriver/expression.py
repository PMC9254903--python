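"""Expression evidence: broad-expression filter, paired tumour/normal
differential expression, and expression–copy-number correlation.

Differences are taken on log2(FPKM + 1). The signed-rank test drops zero
differences, uses the exact null distribution of the rank sum for effective
n ≤ 25 when the absolute differences are untied (computed once per n by the
standard convolution recurrence), and a normal approximation with tie
correction otherwise; per-cancer q-values are Benjamini–Hochberg across the
panel. A gene is differentially expressed when q < 0.05 and the median
log2 fold change clears the 1.5-fold floor.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

FPKM_MIN_DEFAULT = 1.0
FRACTION_DEFAULT = 0.9
MIN_PAIRS_DEFAULT = 10
DE_Q_DEFAULT = 0.05
FC_MIN_DEFAULT = 1.5
P_CORR_DEFAULT = 0.001
EXACT_N_MAX = 25


def broad_expression_filter(expression: ExpressionMatrix,
                            fpkm_min: float = FPKM_MIN_DEFAULT,
                            fraction: float = FRACTION_DEFAULT) -> pd.Series:
    """True for genes with FPKM ≥ fpkm_min in at least ``fraction`` of
    tumour specimens (both bounds inclusive)."""
    tumours = expression.tumour_samples()
    if not tumours:
        raise ValueError("no tumour specimens in expression matrix")
    vals = expression.values[tumours].to_numpy(dtype=float)
    frac = (vals >= fpkm_min).mean(axis=1)
    return pd.Series(frac >= fraction, index=expression.values.index,
                     name="broadly_expressed")


@lru_cache(maxsize=64)
def _signed_rank_counts(n: int) -> np.ndarray:
    """Exact null counts of the positive rank sum W+ for n untied pairs.

    ``counts[w]`` = number of the 2^n sign assignments with W+ = w, from the
    generating-polynomial recurrence Π_{k=1..n} (1 + z^k).
    """
    counts = np.zeros(n * (n + 1) // 2 + 1, dtype=float)
    counts[0] = 1.0
    top = 0
    for k in range(1, n + 1):
        counts[k:top + k + 1] += counts[:top + 1]
        top += k
    return counts


def exact_signed_rank_p(w_plus: float, n: int,
                        ranks: np.ndarray | None = None) -> float:
    """Two-sided exact p for the signed-rank statistic: twice the smaller
    inclusive tail of the 2^n sign-assignment null, capped at 1.

    With tied absolute differences, pass the midranks: the null is then built
    over doubled midranks (integers) by the same convolution."""
    if ranks is not None and np.unique(ranks).size < n:
        doubled = np.sort(np.asarray(ranks) * 2).astype(int)
        counts = np.zeros(int(doubled.sum()) + 1)
        counts[0] = 1.0
        top = 0
        for k in doubled:
            counts[k:top + k + 1] += counts[:top + 1]
            top += k
        w = int(round(w_plus * 2))
    else:
        counts = _signed_rank_counts(n)
        w = int(round(w_plus))
    total = 2.0 ** n
    cdf = counts[:w + 1].sum() / total
    sf = counts[w:].sum() / total
    return min(1.0, 2.0 * min(cdf, sf))


def _approx_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Normal approximation with tie correction (no continuity correction)."""
    n = ranks.size
    mn = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, t = np.unique(ranks, return_counts=True)
    var -= (t ** 3 - t).sum() / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mn) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def signed_rank_test(diffs: np.ndarray) -> tuple[float, float, int]:
    """Paired signed-rank test on a vector of differences.

    Zero differences are dropped; returns ``(w_plus, p, n_effective)``. With
    no non-zero difference the test is vacuous: p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        return w_plus, exact_signed_rank_p(w_plus, n, ranks), n
    return w_plus, _approx_signed_rank_p(w_plus, ranks), n


def paired_wilcoxon_de(expression: ExpressionMatrix, cancer_type: str,
                       min_pairs: int = MIN_PAIRS_DEFAULT,
                       de_q: float = DE_Q_DEFAULT,
                       fc_min: float = FC_MIN_DEFAULT) -> pd.DataFrame:
    """Per-gene paired tumour/normal differential expression.

    Differences d_i = log2(FPKM_tumour + 1) − log2(FPKM_normal + 1) per
    matched patient; de_flag = (BH q < de_q) AND |median d| ≥ log2(fc_min).
    Cohorts with fewer than ``min_pairs`` matched pairs report every gene
    unflagged with the reason recorded.
    """
    tum, nor = expression.paired()
    n_pairs = tum.shape[1]
    genes = expression.values.index
    base = pd.DataFrame({"gene_id": genes, "cancer_type": cancer_type,
                         "n_pairs": n_pairs})
    if n_pairs < min_pairs:
        reason = ("no matched normals" if n_pairs == 0 else "insufficient pairs")
        return base.assign(median_log2fc=np.nan, p=np.nan, q=np.nan,
                           direction="none", de_flag=False, reason=reason)
    d = (np.log2(tum.to_numpy(dtype=float) + 1.0)
         - np.log2(nor.to_numpy(dtype=float) + 1.0))
    med = np.median(d, axis=1)
    p = np.array([signed_rank_test(row)[1] for row in d])
    q = stats.false_discovery_control(p, method="bh")
    flag = (q < de_q) & (np.abs(med) >= np.log2(fc_min))
    direction = np.where(~flag, "none", np.where(med > 0, "up", "down"))
    return base.assign(median_log2fc=med, p=p, q=q, direction=direction,
                       de_flag=flag,
                       reason=np.where(flag, "q<de_q and |fc| floor met", "ns"))


def expr_cnv_correlation(expression: ExpressionMatrix,
                         gene_cn_matrix: pd.DataFrame, cancer_type: str,
                         p_corr: float = P_CORR_DEFAULT,
                         fpkm_min: float = FPKM_MIN_DEFAULT,
                         fraction: float = FRACTION_DEFAULT) -> pd.DataFrame:
    """Pearson correlation of log2(FPKM+1) with the gene copy ratio over
    shared tumour samples, for broadly expressed genes.

    ``correlated`` requires a positive r at p < p_corr. Genes failing the
    broad-expression filter, with < 3 shared samples, or with a zero-variance
    vector are reported not correlated with the reason.
    """
    broad = broad_expression_filter(expression, fpkm_min, fraction)
    shared = [s for s in expression.tumour_samples()
              if s in set(gene_cn_matrix.columns)]
    genes = expression.values.index
    common_genes = genes.intersection(gene_cn_matrix.index)
    n = len(shared)
    r = np.full(len(genes), np.nan)
    p = np.full(len(genes), np.nan)
    reason = np.full(len(genes), "ok", dtype=object)
    reason[~broad.to_numpy()] = "not broadly expressed"
    if n < 3:
        reason[:] = "fewer than 3 shared tumour samples"
    else:
        expr = np.log2(expression.values[shared].to_numpy(dtype=float) + 1.0)
        cn = gene_cn_matrix.reindex(index=genes, columns=shared).to_numpy(dtype=float)
        missing_cn = ~genes.isin(common_genes)
        ex = expr - expr.mean(axis=1, keepdims=True)
        cx = cn - np.nanmean(cn, axis=1, keepdims=True)
        sxx = (ex ** 2).sum(axis=1)
        syy = (cx ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rr = (ex * cx).sum(axis=1) / np.sqrt(sxx * syy)
        degenerate = (sxx <= 0) | (syy <= 0) | missing_cn
        rr = np.clip(rr, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rr * np.sqrt((n - 2) / (1.0 - rr ** 2))
        pp = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        pp[np.abs(rr) == 1.0] = 0.0
        keep = broad.to_numpy() & ~degenerate
        r[keep] = rr[keep]
        p[keep] = pp[keep]
        reason[degenerate & broad.to_numpy() & ~missing_cn] = "zero variance"
        reason[missing_cn & broad.to_numpy()] = "gene absent from copy-number matrix"
    correlated = np.zeros(len(genes), dtype=bool)
    ok = ~np.isnan(r)
    correlated[ok] = (p[ok] < p_corr) & (r[ok] > 0)
    return pd.DataFrame({
        "gene_id": genes, "cancer_type": cancer_type, "n_samples": n,
        "r": r, "p": p, "correlated": correlated,
        "broadly_expressed": broad.to_numpy(), "reason": reason,
    }).reset_index(drop=True)
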