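"""Focal copy-number recurrence evidence ("GISTIC-lite").

Segments are collapsed to a gene × sample log2-ratio matrix by
length-weighted averaging; per-gene amplification/deletion G-scores combine
alteration frequency and amplitude above a threshold; significance comes from
a gene-permutation null with Benjamini–Hochberg q-values; a gene is
"recurrent" when q ≤ 0.25 and G ≥ 0.1 in the matching direction.

Externally computed scores (e.g. real GISTIC 2.0 output) can be ingested
instead; the same recurrence thresholds are then re-applied, with an optional
in-peak boolean ANDed in. Output provenance records which mode produced each
flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import FormatError

logger = logging.getLogger("pandriver")

Q_MAX_DEFAULT = 0.25
G_MIN_DEFAULT = 0.1
AMP_THRESHOLD_DEFAULT = 0.1


@dataclass
class GeneCopyNumberMatrix:
    """Gene × sample log2 copy-ratio matrix with its mapping provenance."""
    values: pd.DataFrame                 # index gene_id, columns sample_id
    provenance: str = "length_weighted_mean"
    imputed: pd.DataFrame | None = None  # boolean mask of no-segment cells


def segments_to_gene_matrix(segments: pd.DataFrame,
                            gene_model: pd.DataFrame) -> GeneCopyNumberMatrix:
    """Collapse segments to one log2 ratio per (gene, sample).

    The value is the length-weighted mean of all segments overlapping the
    gene's span; genes with no overlapping segment in a sample get 0 (diploid)
    and are flagged as imputed. A gene on a chromosome absent from every
    segment yields an all-zero row and a warning.
    """
    samples = sorted(segments["sample_id"].unique().astype(str)) if len(segments) else []
    genes = gene_model["gene_id"].to_list()
    values = np.zeros((len(genes), len(samples)))
    imputed = np.ones((len(genes), len(samples)), dtype=bool)
    sample_pos = {s: j for j, s in enumerate(samples)}
    seg_chroms = set(segments["chrom"].astype(str)) if len(segments) else set()

    # per-chromosome numpy views, sample ids factorized once
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    if len(segments):
        all_codes = segments["sample_id"].astype(str).map(sample_pos).to_numpy()
        for chrom, grp_idx in segments.groupby("chrom").indices.items():
            by_chrom[str(chrom)] = (
                segments["start"].to_numpy()[grp_idx],
                segments["end"].to_numpy()[grp_idx],
                segments["log2_ratio"].to_numpy()[grp_idx],
                all_codes[grp_idx])
    gm = gene_model.reset_index(drop=True)
    g_chroms = gm["chrom"].astype(str).to_numpy()
    g_starts = gm["start"].to_numpy()
    g_ends = gm["end"].to_numpy()
    for i in range(len(gm)):
        chrom = g_chroms[i]
        if chrom not in seg_chroms:
            logger.warning("gene %s on chromosome %s absent from all segments; "
                           "copy ratio imputed as 0", gm["gene_id"].iat[i], chrom)
            continue
        seg_start, seg_end, seg_val, seg_codes = by_chrom[chrom]
        ov_len = (np.minimum(seg_end, g_ends[i])
                  - np.maximum(seg_start, g_starts[i]) + 1).clip(min=0)
        hit = ov_len > 0
        if not hit.any():
            continue
        w = ov_len[hit].astype(float)
        codes = seg_codes[hit]
        wsum = np.zeros(len(samples))
        wxsum = np.zeros(len(samples))
        np.add.at(wsum, codes, w)
        np.add.at(wxsum, codes, w * seg_val[hit])
        covered = wsum > 0
        values[i, covered] = wxsum[covered] / wsum[covered]
        imputed[i, covered] = False

    vdf = pd.DataFrame(values, index=genes, columns=samples)
    idf = pd.DataFrame(imputed, index=genes, columns=samples)
    return GeneCopyNumberMatrix(values=vdf, imputed=idf)


def _directional(values: np.ndarray, direction: str) -> np.ndarray:
    if direction == "amp":
        return values
    if direction == "del":
        return -values
    raise ValueError(f"direction must be 'amp' or 'del', got {direction!r}")


def gscore(matrix: GeneCopyNumberMatrix | pd.DataFrame, direction: str,
           amplitude_threshold: float = AMP_THRESHOLD_DEFAULT) -> pd.Series:
    """Per-gene G-score: mean over samples of amplitude above the threshold.

    ``G_amp(g) = (1/N) Σ_s max(0, x_gs − θ)`` and symmetrically for
    deletions with ``−x``; the score grows with both carrier frequency and
    amplitude, the simplified analogue of GISTIC's frequency × amplitude
    recurrence score.
    """
    if amplitude_threshold <= 0:
        raise ValueError("amplitude_threshold must be > 0")
    vdf = matrix.values if isinstance(matrix, GeneCopyNumberMatrix) else matrix
    if vdf.shape[1] == 0:
        raise ValueError("G-score undefined for a matrix with no samples")
    x = _directional(vdf.to_numpy(dtype=float), direction)
    g = np.maximum(0.0, x - amplitude_threshold).mean(axis=1)
    return pd.Series(g, index=vdf.index, name=f"g_{direction}")


def gscore_qvalues(matrix: GeneCopyNumberMatrix | pd.DataFrame, direction: str,
                   n_perm: int = 1000, seed: int = 0,
                   amplitude_threshold: float = AMP_THRESHOLD_DEFAULT,
                   ) -> tuple[pd.Series, pd.Series]:
    """Permutation p- and BH q-values for per-gene G-scores.

    The null is built by independently permuting each sample's gene-value
    vector across genes; null G-scores are pooled across genes and
    permutations, so per-gene p = fraction of the pooled null ≥ observed.
    Returns ``(p, q)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    vdf = matrix.values if isinstance(matrix, GeneCopyNumberMatrix) else matrix
    x = _directional(vdf.to_numpy(dtype=float), direction)
    n_genes, n_samples = x.shape
    observed = np.maximum(0.0, x - amplitude_threshold).mean(axis=1)

    contrib = np.maximum(0.0, x - amplitude_threshold)  # gene × sample
    rng = np.random.default_rng(seed)
    # Permute each sample's contribution column across genes, n_perm times.
    # Only above-threshold entries are non-zero, so a permutation is realized
    # sparsely: each sample's k positive contributions land on k distinct
    # uniformly random genes (rejection-resampled until distinct).
    null = np.zeros((n_perm, n_genes))
    for s in range(n_samples):
        vals = contrib[contrib[:, s] > 0, s]
        k = vals.size
        if k == 0:
            continue
        if k > n_genes // 8:
            # dense column: rejection sampling degenerates, permute directly
            col = np.broadcast_to(contrib[:, s], (n_perm, n_genes))
            null += rng.permuted(col, axis=1)
            continue
        pos = rng.integers(0, n_genes, size=(n_perm, k))
        if k > 1:
            bad = np.flatnonzero(
                (np.sort(pos, axis=1)[:, 1:] == np.sort(pos, axis=1)[:, :-1])
                .any(axis=1))
            while bad.size:
                pos[bad] = rng.integers(0, n_genes, size=(bad.size, k))
                srt = np.sort(pos[bad], axis=1)
                bad = bad[(srt[:, 1:] == srt[:, :-1]).any(axis=1)]
        np.add.at(null, (np.repeat(np.arange(n_perm), k), pos.ravel()),
                  np.tile(vals, n_perm))
    null /= n_samples
    pooled = np.sort(null.ravel())
    # p = fraction of pooled null >= observed (right tail, inclusive)
    p = 1.0 - np.searchsorted(pooled, observed, side="left") / pooled.size
    q = stats.false_discovery_control(p, method="bh")
    genes = vdf.index
    return (pd.Series(p, index=genes, name=f"p_{direction}"),
            pd.Series(q, index=genes, name=f"q_{direction}"))


def scna_results(matrix: GeneCopyNumberMatrix | pd.DataFrame, cancer_type: str,
                 n_perm: int = 1000, seed: int = 0,
                 amplitude_threshold: float = AMP_THRESHOLD_DEFAULT,
                 q_max: float = Q_MAX_DEFAULT,
                 g_min: float = G_MIN_DEFAULT) -> pd.DataFrame:
    """Full per-gene SCNA result table for one cancer type (lite mode)."""
    vdf = matrix.values if isinstance(matrix, GeneCopyNumberMatrix) else matrix
    out = pd.DataFrame({"gene_id": vdf.index, "cancer_type": cancer_type})
    for direction, child in (("amp", 0), ("del", 1)):
        g = gscore(vdf, direction, amplitude_threshold)
        # distinct child seeds per direction, derived from the stage seed
        p, q = gscore_qvalues(vdf, direction, n_perm=n_perm,
                              seed=np.random.SeedSequence([seed, child]).generate_state(1)[0] % (2**31),
                              amplitude_threshold=amplitude_threshold)
        out[f"g_{direction}"] = g.to_numpy()
        out[f"q_{direction}"] = q.to_numpy()
    out["n_samples"] = vdf.shape[1]
    out["provenance"] = "gistic_lite"
    return flag_recurrent(out, q_max=q_max, g_min=g_min)


def flag_recurrent(results: pd.DataFrame, q_max: float = Q_MAX_DEFAULT,
                   g_min: float = G_MIN_DEFAULT) -> pd.DataFrame:
    """Apply the recurrence filter: q ≤ q_max AND G ≥ g_min, per direction.

    The SCNA evidence flag used downstream is ``recurrent_amp OR
    recurrent_del``. An ``in_peak_amp``/``in_peak_del`` column, when present
    (ingested GISTIC results), is ANDed in.
    """
    out = results.copy()
    for direction in ("amp", "del"):
        flag = ((out[f"q_{direction}"] <= q_max)
                & (out[f"g_{direction}"] >= g_min))
        peak_col = f"in_peak_{direction}"
        if peak_col in out.columns:
            in_peak = out[peak_col].map(lambda v: True if pd.isna(v) else bool(v))
            flag &= in_peak.astype(bool)
        out[f"recurrent_{direction}"] = flag
    out["scna_flag"] = out["recurrent_amp"] | out["recurrent_del"]
    return out


def pan_cancer_gscore(per_cancer_results: pd.DataFrame) -> pd.DataFrame:
    """Unweighted sum of per-cancer G-scores per gene and direction."""
    if not len(per_cancer_results):
        raise ValueError("need results for at least one cancer type")
    rows = []
    for direction in ("amp", "del"):
        s = per_cancer_results.groupby("gene_id")[f"g_{direction}"].sum()
        rows.append(pd.DataFrame({"gene_id": s.index, "direction": direction,
                                  "pan_g": s.to_numpy()}))
    return pd.concat(rows, ignore_index=True)


EXTERNAL_REQUIRED = ("gene_id", "cancer_type", "direction", "g", "q")


def ingest_external_scna(table: pd.DataFrame, q_max: float = Q_MAX_DEFAULT,
                         g_min: float = G_MIN_DEFAULT) -> pd.DataFrame:
    """Ingest externally computed G/q scores (long format, one row per
    gene × cancer × direction) and recompute recurrence flags.

    Accepted columns: gene_id (or gene), cancer_type (or cancer), direction
    ∈ {amp, del}, g (G-score), q, optional in_peak boolean.
    """
    t = table.rename(columns={"gene": "gene_id", "cancer": "cancer_type",
                              "G": "g", "in-peak": "in_peak"})
    missing = [c for c in EXTERNAL_REQUIRED if c not in t.columns]
    if missing:
        raise FormatError(f"external SCNA table missing column(s): "
                          f"{', '.join(missing)}")
    bad_dir = ~t["direction"].isin(["amp", "del"])
    if bad_dir.any():
        raise FormatError("external SCNA direction must be 'amp' or 'del'")
    wide_rows = []
    for (gene, cancer), grp in t.groupby(["gene_id", "cancer_type"]):
        row: dict = {"gene_id": gene, "cancer_type": cancer,
                     "g_amp": 0.0, "q_amp": 1.0, "g_del": 0.0, "q_del": 1.0,
                     "n_samples": grp["n_samples"].iloc[0] if "n_samples" in grp else np.nan,
                     "provenance": "external"}
        for _, r in grp.iterrows():
            d = r["direction"]
            row[f"g_{d}"] = float(r["g"])
            row[f"q_{d}"] = float(r["q"])
            if "in_peak" in grp.columns and pd.notna(r.get("in_peak")):
                row[f"in_peak_{d}"] = bool(r["in_peak"])
        wide_rows.append(row)
    wide = pd.DataFrame(wide_rows)
    return flag_recurrent(wide, q_max=q_max, g_min=g_min)
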