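"""Configuration-driven orchestration of the five evidence stages.

``run_pipeline`` loads a cohort directory (one sub-directory per cancer type
plus a shared gene panel), runs SCNA → mutation → fusion → expression →
survival → scoring in dependency order, and writes every stage table, the
score tables and a JSON run summary with thresholds, seeds, input hashes and
row counts. Stage functions are shared with the per-stage CLI subcommands, so
composing stages manually reproduces ``run`` byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, fields, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as omio
from . import scna as scna_mod
from . import mutation as mut_mod
from . import fusion as fus_mod
from . import expression as expr_mod
from . import survival as surv_mod
from . import scoring

logger = logging.getLogger("pandriver")


@dataclass
class RunConfig:
    """All stage thresholds; defaults are the published ones where stated."""
    q_max: float = 0.25
    g_min: float = 0.1
    amp_threshold: float = 0.1
    m_min: int = 2
    r_min: int = 2
    fusion_mode: str = "within_cancer"
    ordered_pairs: bool = True
    min_pairs: int = 10
    de_q: float = 0.05
    fc_min: float = 1.5
    p_corr: float = 0.001
    surv_p: float = 0.1
    covariate: str = "continuous"
    n_perm: int = 1000
    seed: int = 0
    scna_mode: str = "lite"            # lite | ingest
    external_scna_path: str | None = None

    def validate(self) -> list[str]:
        """Range checks; returns the list of non-default settings."""
        checks = [
            (0 < self.q_max <= 1, "q_max must be in (0, 1]"),
            (self.g_min >= 0, "g_min must be >= 0"),
            (self.amp_threshold > 0, "amp_threshold must be > 0"),
            (self.m_min >= 1, "m_min must be >= 1"),
            (self.r_min >= 1, "r_min must be >= 1"),
            (self.fusion_mode in fus_mod.FUSION_MODES,
             f"fusion_mode must be one of {fus_mod.FUSION_MODES}"),
            (self.min_pairs >= 1, "min_pairs must be >= 1"),
            (0 < self.de_q < 1, "de_q must be in (0, 1)"),
            (self.fc_min >= 1, "fc_min must be >= 1"),
            (0 < self.p_corr < 1, "p_corr must be in (0, 1)"),
            (0 < self.surv_p < 1, "surv_p must be in (0, 1)"),
            (self.covariate in ("continuous", "median"),
             "covariate must be 'continuous' or 'median'"),
            (self.n_perm >= 100, "n_perm must be >= 100"),
            (self.scna_mode in ("lite", "ingest"),
             "scna_mode must be 'lite' or 'ingest'"),
        ]
        errors = [msg for ok, msg in checks if not ok]
        if errors:
            raise ValueError("; ".join(errors))
        defaults = RunConfig()
        return [f.name for f in fields(RunConfig)
                if getattr(self, f.name) != getattr(defaults, f.name)]


def validate_config(source: str | Path | dict | None) -> tuple[RunConfig, list[str]]:
    """Build a RunConfig from a YAML/JSON file or dict.

    Unknown keys are an error (no silent typos); returns the normalized
    config and the list of settings that deviate from the defaults.
    """
    if source is None:
        data: dict = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**data)
    deviations = cfg.validate()
    return cfg, deviations


REQUIRED_FILES = ("segments.seg", "mutations.maf", "fusions.tsv",
                  "expression.tsv", "sample_meta.tsv", "clinical.tsv")


def load_cohorts(cohort_dir: str | Path,
                 cancer_types: list[str] | None = None
                 ) -> tuple[dict[str, omio.CohortBundle], dict]:
    """Load every cancer-type sub-directory of a cohort directory."""
    cohort_dir = Path(cohort_dir)
    gene_model = omio.read_gene_model_bed(cohort_dir / "genes.bed")
    if cancer_types is None:
        cancer_types = sorted(p.name for p in cohort_dir.iterdir()
                              if p.is_dir())
    bundles: dict[str, omio.CohortBundle] = {}
    reports: dict[str, dict] = {}
    for ct in cancer_types:
        d = cohort_dir / ct
        missing = [f for f in REQUIRED_FILES if not (d / f).exists()]
        if missing:
            raise FileNotFoundError(
                f"cancer type {ct}: missing input file(s) {missing}")
        seg, seg_rep = omio.read_seg(d / "segments.seg")
        mut, mut_rep = omio.read_maf_lite(d / "mutations.maf")
        fus, fus_rep = omio.read_fusions(d / "fusions.tsv")
        clin, clin_rep = omio.read_clinical(d / "clinical.tsv")
        expr = omio.read_expression(d / "expression.tsv", d / "sample_meta.tsv")
        calls = (omio.read_driver_calls(d / "driver_calls.tsv")
                 if (d / "driver_calls.tsv").exists() else None)
        bundles[ct] = omio.CohortBundle(
            cancer_type=ct, gene_model=gene_model, segments=seg,
            mutations=mut, fusions=fus, expression=expr, clinical=clin,
            driver_calls=calls)
        reports[ct] = {"segments": seg_rep.as_dict(),
                       "mutations": mut_rep.as_dict(),
                       "fusions": fus_rep.as_dict(),
                       "clinical": clin_rep.as_dict()}
    return bundles, reports


# ---------------------------------------------------------------------------
# stages (shared between `run` and the per-stage subcommands)
# ---------------------------------------------------------------------------

def stage_scna(bundles: dict[str, omio.CohortBundle], cfg: RunConfig
               ) -> tuple[pd.DataFrame, pd.DataFrame,
                          dict[str, scna_mod.GeneCopyNumberMatrix]]:
    """Per-cancer SCNA results, pan-cancer G-scores and the CN matrices."""
    results = []
    matrices: dict[str, scna_mod.GeneCopyNumberMatrix] = {}
    for i, (ct, b) in enumerate(sorted(bundles.items())):
        matrices[ct] = scna_mod.segments_to_gene_matrix(b.segments, b.gene_model)
        if cfg.scna_mode == "lite":
            res = scna_mod.scna_results(
                matrices[ct], ct, n_perm=cfg.n_perm, seed=cfg.seed + i,
                amplitude_threshold=cfg.amp_threshold,
                q_max=cfg.q_max, g_min=cfg.g_min)
        else:
            ext = pd.read_csv(cfg.external_scna_path, sep="\t")
            res = scna_mod.ingest_external_scna(ext, q_max=cfg.q_max,
                                                g_min=cfg.g_min)
            res = res[res["cancer_type"] == ct]
        results.append(res)
    all_res = pd.concat(results, ignore_index=True)
    pan = scna_mod.pan_cancer_gscore(all_res)
    return all_res, pan, matrices


def stage_mutation(bundles: dict[str, omio.CohortBundle],
                   cfg: RunConfig) -> pd.DataFrame:
    out = []
    for ct, b in sorted(bundles.items()):
        panel = b.gene_model["gene_id"].to_list()
        registry = set(b.tumour_samples) or b.sample_registry
        out.append(mut_mod.mutation_results(
            b.mutations, registry, panel, ct, b.driver_calls, m_min=cfg.m_min))
    return pd.concat(out, ignore_index=True)


def stage_fusion(bundles: dict[str, omio.CohortBundle], cfg: RunConfig
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fusion flags per cancer plus the pan-cancer pair table (recurrence is
    counted over the pooled events of all cancer types)."""
    pooled = pd.concat([b.fusions for b in bundles.values()],
                       ignore_index=True)
    any_bundle = next(iter(bundles.values()))
    panel = any_bundle.gene_model["gene_id"].to_list()
    summary = fus_mod.count_fusions(pooled, panel, r_min=cfg.r_min,
                                    ordered_pairs=cfg.ordered_pairs)
    out = [fus_mod.fusion_evidence_flag(summary, ct, panel,
                                        mode=cfg.fusion_mode)
           for ct in sorted(bundles)]
    return pd.concat(out, ignore_index=True), summary.pair_counts


def stage_expression(bundles: dict[str, omio.CohortBundle], cfg: RunConfig,
                     matrices: dict[str, scna_mod.GeneCopyNumberMatrix]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    de_out, corr_out = [], []
    for ct, b in sorted(bundles.items()):
        de_out.append(expr_mod.paired_wilcoxon_de(
            b.expression, ct, min_pairs=cfg.min_pairs,
            de_q=cfg.de_q, fc_min=cfg.fc_min))
        corr_out.append(expr_mod.expr_cnv_correlation(
            b.expression, matrices[ct].values, ct, p_corr=cfg.p_corr))
    return (pd.concat(de_out, ignore_index=True),
            pd.concat(corr_out, ignore_index=True))


def stage_survival(bundles: dict[str, omio.CohortBundle],
                   cfg: RunConfig) -> pd.DataFrame:
    out = [surv_mod.survival_results(b.expression, b.clinical, ct,
                                     p_threshold=cfg.surv_p,
                                     covariate=cfg.covariate)
           for ct, b in sorted(bundles.items())]
    return pd.concat(out, ignore_index=True)


def score_stages(scna_res: pd.DataFrame, mut_res: pd.DataFrame,
                 fus_res: pd.DataFrame, de_res: pd.DataFrame,
                 surv_res: pd.DataFrame, panel: list[str],
                 cancer_types: list[str],
                 pan_gscore: pd.DataFrame | None = None
                 ) -> tuple[scoring.ScoreTable, pd.DataFrame]:
    flags = scoring.assemble_flags(scna_res, mut_res, fus_res, de_res,
                                   surv_res, panel, cancer_types)
    table = scoring.pco_score(scoring.cs_score(flags))
    ranked = scoring.rank_candidates(table, pan_gscore)
    return table, ranked


def run_stages(bundles: dict[str, omio.CohortBundle], cfg: RunConfig
               ) -> dict[str, object]:
    """Run every stage in dependency order, in memory."""
    scna_res, pan_g, matrices = stage_scna(bundles, cfg)
    mut_res = stage_mutation(bundles, cfg)
    fus_res, pair_counts = stage_fusion(bundles, cfg)
    de_res, corr_res = stage_expression(bundles, cfg, matrices)
    surv_res = stage_survival(bundles, cfg)
    any_bundle = next(iter(bundles.values()))
    panel = any_bundle.gene_model["gene_id"].to_list()
    table, ranked = score_stages(scna_res, mut_res, fus_res, de_res, surv_res,
                                 panel, sorted(bundles), pan_gscore=pan_g)
    return {"scna": scna_res, "pan_gscore": pan_g, "mutation": mut_res,
            "fusion": fus_res, "fusion_pairs": pair_counts, "de": de_res,
            "correlation": corr_res, "survival": surv_res,
            "scores": table, "ranking": ranked}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cohort_dir: str | Path, config: RunConfig | dict | None,
                 out_dir: str | Path) -> dict[str, object]:
    """End-to-end run on a cohort directory; writes all output tables plus
    ``run_summary.json`` and returns the in-memory results."""
    cfg, deviations = (config, config.validate()) \
        if isinstance(config, RunConfig) else validate_config(config)
    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundles, reports = load_cohorts(cohort_dir)
    logger.info("loaded %d cancer types from %s", len(bundles), cohort_dir)
    results = run_stages(bundles, cfg)

    table: scoring.ScoreTable = results["scores"]  # type: ignore[assignment]
    omio.write_stage_table(results["scna"], out_dir / "scna_results.tsv")
    omio.write_stage_table(results["pan_gscore"], out_dir / "pan_cancer_gscore.tsv")
    omio.write_stage_table(results["mutation"], out_dir / "mutation_results.tsv")
    omio.write_stage_table(results["fusion"], out_dir / "fusion_results.tsv")
    omio.write_stage_table(results["fusion_pairs"], out_dir / "fusion_pairs.tsv")
    omio.write_stage_table(results["de"], out_dir / "de_results.tsv")
    omio.write_stage_table(results["correlation"],
                           out_dir / "expr_cnv_correlation.tsv")
    omio.write_stage_table(results["survival"], out_dir / "survival_results.tsv")
    omio.write_stage_table(table.flags, out_dir / "evidence_flags.tsv")
    cs_long = (table.cs.reset_index()
               .melt(id_vars="gene_id", var_name="cancer_type", value_name="cs"))
    omio.write_stage_table(cs_long, out_dir / "cs_scores.tsv")
    pco_tab = table.components.copy()
    pco_tab.insert(0, "pco", table.pco)
    omio.write_stage_table(pco_tab.reset_index(), out_dir / "pco_scores.tsv")
    omio.write_stage_table(results["ranking"], out_dir / "ranking.tsv",
                           sort=False)

    input_hashes = {str(p.relative_to(cohort_dir)): _sha256(p)
                    for p in sorted(cohort_dir.rglob("*")) if p.is_file()}
    summary = {
        "config": asdict(cfg),
        "non_default_settings": deviations,
        "seeds": {"pipeline": cfg.seed,
                  "scna_permutations": [cfg.seed + i
                                        for i in range(len(bundles))]},
        "cancer_types": sorted(bundles),
        "n_genes": len(next(iter(bundles.values())).gene_model),
        "input_reports": reports,
        "input_hashes": input_hashes,
        "top_candidates": results["ranking"].head(10).to_dict("records"),  # type: ignore[union-attr]
    }
    omio.write_run_summary(summary, out_dir / "run_summary.json")
    return results
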