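"""Evidence integration: CS-scores per gene × cancer type and PCO-scores.

The five binary conditions per gene per cancer type are (1) recurrent focal
SCNA, (2) significant mutation (caller consensus m-index ≥ 2), (3) recurrent
fusion, (4) significant tumour/normal differential expression, (5) good or
poor prognosis. CS = Σ_k X_k ∈ [0, 5]; the pan-cancer PCO score is the sum of
CS over cancer types, with a per-channel decomposition that must conserve the
total. A stage that is unevaluable for a cancer (e.g. no matched normals)
contributes a false flag with its reason, never a smaller denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CHANNELS = ("x_scna", "x_mut", "x_fus", "x_de", "x_surv")

_STAGE_FLAG = {
    "x_scna": ("scna", "scna_flag"),
    "x_mut": ("mutation", "mutation_flag"),
    "x_fus": ("fusion", "fusion_flag"),
    "x_de": ("de", "de_flag"),
    "x_surv": ("survival", "surv_flag"),
}


@dataclass
class ScoreTable:
    """CS gene × cancer matrix, per-gene PCO scores and channel components."""
    cs: pd.DataFrame          # index gene_id, columns cancer_type, int in [0,5]
    pco: pd.Series            # per-gene integer
    components: pd.DataFrame  # index gene_id, columns CHANNELS, pan-cancer sums
    flags: pd.DataFrame       # long table of EvidenceFlags with reasons
    rank: pd.DataFrame | None = None

    def check_conservation(self) -> None:
        """pco == row sums of cs == row sums of components, always."""
        if not np.array_equal(self.cs.sum(axis=1).to_numpy(),
                              self.pco.to_numpy()):
            raise AssertionError("PCO != sum of CS-scores")
        if not np.array_equal(self.components.sum(axis=1).to_numpy(),
                              self.pco.to_numpy()):
            raise AssertionError("PCO != sum of channel components")


def _stage_lookup(table: pd.DataFrame, flag_col: str, panel: list[str],
                  cancer_type: str, stage: str) -> tuple[pd.Series, pd.Series]:
    sub = table[table["cancer_type"] == cancer_type]
    sub = sub.set_index("gene_id")
    missing = [g for g in panel if g not in sub.index]
    if missing:
        raise KeyError(f"stage '{stage}' does not cover panel gene(s) "
                       f"{missing[:5]} for cancer type {cancer_type}")
    flags = sub[flag_col].reindex(panel).astype(bool)
    if "reason" in sub.columns:
        reasons = sub["reason"].reindex(panel).astype(str)
    else:
        reasons = pd.Series(np.where(flags, f"{stage}: flag", f"{stage}: no flag"),
                            index=flags.index)
    return flags, stage + ":" + reasons


def assemble_flags(scna: pd.DataFrame, mutation: pd.DataFrame,
                   fusion: pd.DataFrame, de: pd.DataFrame,
                   survival: pd.DataFrame, panel: list[str],
                   cancer_types: list[str]) -> pd.DataFrame:
    """Join the five stage tables into one EvidenceFlags long table.

    Every (gene, cancer) cell carries the five booleans plus a provenance
    reason per flag naming the stage row it came from. A panel gene missing
    from any stage table is an error — stages must cover the panel.
    """
    stage_tables = {"x_scna": scna, "x_mut": mutation, "x_fus": fusion,
                    "x_de": de, "x_surv": survival}
    out = []
    for ct in cancer_types:
        block = pd.DataFrame({"gene_id": panel, "cancer_type": ct})
        for channel, (stage, flag_col) in _STAGE_FLAG.items():
            flags, reasons = _stage_lookup(stage_tables[channel], flag_col,
                                           panel, ct, stage)
            block[channel] = flags.to_numpy()
            block[f"reason_{channel}"] = reasons.to_numpy()
        out.append(block)
    return pd.concat(out, ignore_index=True)


def cs_score(flags: pd.DataFrame) -> pd.DataFrame:
    """CS = number of satisfied conditions, appended as an integer column."""
    out = flags.copy()
    out["cs"] = out[list(CHANNELS)].astype(int).sum(axis=1)
    return out


def pco_score(flags_with_cs: pd.DataFrame) -> ScoreTable:
    """Sum CS over cancer types into PCO scores with channel decomposition."""
    f = flags_with_cs
    if "cs" not in f.columns:
        f = cs_score(f)
    cs = (f.pivot(index="gene_id", columns="cancer_type", values="cs")
          .fillna(0).astype(int))
    cs = cs.sort_index()
    pco = cs.sum(axis=1)
    pco.name = "pco"
    components = (f.groupby("gene_id")[list(CHANNELS)].sum().astype(int)
                  .sort_index())
    table = ScoreTable(cs=cs, pco=pco, components=components, flags=f)
    table.check_conservation()
    return table


def rank_candidates(table: ScoreTable,
                    pan_gscore: pd.DataFrame | None = None) -> pd.DataFrame:
    """Deterministic candidate ranking.

    Descending PCO; ties broken by (1) the gene's maximum single-cancer CS,
    (2) pan-cancer G-score magnitude (largest of |pan_g| over directions, 0
    when no table given), (3) gene_id lexicographic.
    """
    genes = table.pco.index
    max_cs = table.cs.max(axis=1)
    if pan_gscore is not None and len(pan_gscore):
        pan_mag = (pan_gscore.assign(mag=pan_gscore["pan_g"].abs())
                   .groupby("gene_id")["mag"].max()
                   .reindex(genes, fill_value=0.0))
    else:
        pan_mag = pd.Series(0.0, index=genes)
    ranked = pd.DataFrame({
        "gene_id": genes,
        "pco": table.pco.to_numpy(),
        "max_cs": max_cs.to_numpy(),
        "pan_g_magnitude": pan_mag.to_numpy(),
    })
    ranked = ranked.sort_values(
        ["pco", "max_cs", "pan_g_magnitude", "gene_id"],
        ascending=[False, False, False, True], kind="mergesort")
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked.reset_index(drop=True)
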