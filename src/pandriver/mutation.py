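"""Somatic mutation evidence: per-gene frequency and driver-caller consensus.

The frequency of a gene is the number of mutated specimens over the total
number of specimens (a specimen with several events in one gene counts once).
Driver calls from up to five external algorithms are aggregated into the
m-index — the number of algorithms that call the gene — and a gene with
m-index ≥ 2 is regarded as significantly mutated. The five published callers
are consumed, never re-implemented; for simulated cohorts a set of
pseudo-callers based on binomial tail tests stands in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import FormatError

M_MIN_DEFAULT = 2

PSEUDO_CALLER_NAMES = ("BinomA", "BinomB", "BinomC", "BinomD", "BinomE")


def mutation_frequency(mutations: pd.DataFrame, sample_registry: set[str],
                       panel_genes: list[str]) -> pd.DataFrame:
    """Per-gene mutated-specimen count and frequency.

    ``frequency = n_mutated_samples / n_samples`` where n_samples is the size
    of the cohort sample registry.
    """
    n_samples = len(sample_registry)
    if n_samples == 0:
        raise ValueError("empty sample registry")
    if len(mutations):
        unknown = set(mutations["sample_id"].astype(str)) - sample_registry
        if unknown:
            raise FormatError(f"mutations reference unregistered samples: "
                              f"{sorted(unknown)[:5]}")
        counts = (mutations.drop_duplicates(["sample_id", "gene_id"])
                  .groupby("gene_id").size())
    else:
        counts = pd.Series(dtype=np.int64)
    n_mut = pd.Series(0, index=pd.Index(panel_genes, name="gene_id"),
                      dtype=np.int64)
    shared = counts.index.intersection(n_mut.index)
    n_mut.loc[shared] = counts.loc[shared]
    return pd.DataFrame({
        "gene_id": n_mut.index,
        "n_mutated_samples": n_mut.to_numpy(),
        "n_samples": n_samples,
        "frequency": n_mut.to_numpy() / n_samples,
    }).reset_index(drop=True)


def m_index(call_matrix: pd.DataFrame, m_min: int = M_MIN_DEFAULT) -> pd.DataFrame:
    """Count concordant driver calls per gene and apply the m-index rule.

    ``significant = m_index >= m_min``; with fewer than ``m_min`` algorithm
    columns available no gene can satisfy the rule, so every gene is reported
    not significant with reason "insufficient coverage" (absent columns never
    count as false calls — coverage is recorded instead).
    """
    if call_matrix.shape[1] < 1:
        raise ValueError("need at least one algorithm column")
    if call_matrix.columns.duplicated().any():
        raise FormatError("duplicated algorithm column in driver-call matrix")
    if call_matrix.shape[1] > 5:
        raise FormatError("at most 5 driver-call algorithms supported")
    m = call_matrix.astype(bool).sum(axis=1).astype(np.int64)
    coverage = call_matrix.shape[1]
    out = pd.DataFrame({
        "gene_id": call_matrix.index,
        "m_index": m.to_numpy(),
        "n_algorithms": coverage,
        "significant": (m >= m_min).to_numpy() if coverage >= m_min
        else np.zeros(len(m), bool),
    })
    out["reason"] = np.where(
        coverage >= m_min,
        np.where(out["significant"], f"m_index>={m_min}", f"m_index<{m_min}"),
        "insufficient coverage")
    return out


def mutation_results(mutations: pd.DataFrame, sample_registry: set[str],
                     panel_genes: list[str], cancer_type: str,
                     call_matrix: pd.DataFrame | None,
                     m_min: int = M_MIN_DEFAULT) -> pd.DataFrame:
    """Combined per-gene mutation evidence table for one cancer type."""
    freq = mutation_frequency(mutations, sample_registry, panel_genes)
    freq.insert(1, "cancer_type", cancer_type)
    if call_matrix is not None:
        mi = m_index(call_matrix.reindex(panel_genes).fillna(False), m_min)
        out = freq.merge(mi, on="gene_id", how="left")
    else:
        out = freq.assign(m_index=0, n_algorithms=0, significant=False,
                          reason="no driver-call matrix")
    out["mutation_flag"] = out["significant"].astype(bool)
    return out


def pseudo_callers(freq_table: pd.DataFrame, background_rate: float,
                   alphas: tuple[float, ...] = (1e-3, 1e-3, 1e-3, 1e-3, 1e-3),
                   flip_noise: tuple[float, ...] = (0.0,) * 5,
                   seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for the five external driver callers.

    Caller j flags gene g when the one-sided binomial tail
    ``P(X >= n_mutated | n, background_rate)`` is below its alpha, then each
    call is independently flipped with its noise rate. Deterministic under
    ``seed``.
    """
    if background_rate <= 0:
        raise ValueError("background_rate must be > 0")
    if len(alphas) != len(flip_noise) or len(alphas) > 5:
        raise ValueError("need matching alphas/flip_noise for <= 5 callers")
    k = freq_table["n_mutated_samples"].to_numpy()
    n = freq_table["n_samples"].to_numpy()
    # P(X >= k) with the inclusive tail
    tail = stats.binom.sf(k - 1, n, background_rate)
    rng = np.random.default_rng(seed)
    calls = {}
    for j, (alpha, eps) in enumerate(zip(alphas, flip_noise)):
        call = tail < alpha
        if eps > 0:
            flip = rng.random(call.shape) < eps
            call = call ^ flip
        calls[PSEUDO_CALLER_NAMES[j]] = call
    return pd.DataFrame(calls, index=pd.Index(freq_table["gene_id"],
                                              name="gene_id"))
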