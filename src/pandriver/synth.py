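"""Synthetic multi-cancer cohorts with planted driver genes.

Emulates the data layers the scoring pipeline consumes — segmented copy
number, a mutation catalog, driver-caller calls, fusion events, paired
tumour/normal FPKM expression and overall-survival follow-up — for a gene
panel plus decoy genes, with ground truth serialized next to the cohort.

The generative model, per cancer type:

* copy number: every sample carries arm-scale background blocks with
  log2 ratio ~ Normal(0, 0.05); a gene planted in an ``scna_amp``/``scna_del``
  channel receives, in a carrier fraction of samples, a focal 0.5–5 Mb
  segment covering the gene with amplitude centred on ±0.5 — straddling the
  ±0.1 amplitude threshold the recurrence score uses;
* mutations: per gene per sample Bernoulli with background rate 0.01,
  multiplied by 8 for planted mutation drivers (echoing an 8% driver
  frequency against a ~1% background); five binomial pseudo-callers with
  independent flip noise stand in for the external driver-call algorithms;
* fusions: a low Poisson background of random ordered pairs plus planted
  recurrent pairs (default 4 events) whose partner symbols lie outside the
  scored panel;
* expression: log2 FPKM = gene baseline + dosage_slope × copy ratio
  (+ planted log2 shift for ``de_up``/``de_down``) + Normal noise, so the
  copy-number–expression correlation stage has signal by construction;
  normals omit the tumour effects;
* survival: exponential proportional hazards with linear predictor
  θ × standardized tumour expression of ``prognosis``-channel genes,
  administratively censored at a horizon plus exponential dropout
  (~40–60% events at the defaults).

One master seed; every stream draws from deterministically spawned child
seeds, so identical (config, seed) reproduce byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CohortBundle, ExpressionMatrix, write_stage_table
from .mutation import pseudo_callers, mutation_frequency

EVIDENCE_CHANNELS = ("scna_amp", "scna_del", "mutation", "fusion",
                     "de_up", "de_down", "prognosis")

#: ATP-dependent chromatin-remodeller panel (SWI/SNF, ISWI, CHD, INO80 and
#: SNF2-like families plus actin-module subunits); configurable.
ATPCR_PANEL = (
    "ACTB", "ACTL6A", "ACTL6B", "ACTR5", "ACTR8", "ATRX", "BTAF1",
    "CHD1", "CHD1L", "CHD2", "CHD3", "CHD4", "CHD5", "CHD6", "CHD7",
    "CHD8", "CHD9", "EP400", "ERCC6", "ERCC6L", "ERCC6L2", "HELLS",
    "HLTF", "INO80", "RAD54B", "RAD54L", "RAD54L2", "SHPRH", "SMARCA1",
    "SMARCA2", "SMARCA4", "SMARCA5", "SMARCAD1", "SMARCAL1", "SRCAP",
    "TTF2", "ZRANB3",
)

_N_CHROM = 22
_CHROM_LEN = 130_000_000
_BLOCK_LEN = 32_500_000       # four arm-scale background blocks per chromosome
_GENE_LEN = 100_000
_GENE_SPACING = 8_000_000

_VARIANT_CLASSES = ("missense", "nonsense", "frameshift_indel",
                    "inframe_indel", "splice", "other")
_VARIANT_PROBS = (0.68, 0.10, 0.10, 0.03, 0.06, 0.03)


def default_gene_model(panel: tuple[str, ...] = ATPCR_PANEL,
                       n_decoys: int = 200) -> pd.DataFrame:
    """Panel plus decoy genes laid out round-robin over 22 chromosomes."""
    genes = list(panel) + [f"DECOY{i:03d}" for i in range(n_decoys)]
    rows = []
    for i, g in enumerate(genes):
        chrom = str(i % _N_CHROM + 1)
        slot = i // _N_CHROM
        start = 5_000_000 + slot * _GENE_SPACING
        if start + _GENE_LEN >= _CHROM_LEN:
            raise ValueError("too many genes for the synthetic genome layout")
        rows.append({"gene_id": g, "chrom": chrom, "start": start,
                     "end": start + _GENE_LEN - 1,
                     "strand": "+" if i % 2 == 0 else "-"})
    return pd.DataFrame(rows)


@dataclass
class CancerSimConfig:
    """Per-cancer-type cohort shape and planted drivers."""
    name: str
    n_tumour: int = 100
    n_normal_pairs: int = 30
    #: gene_id -> subset of EVIDENCE_CHANNELS
    planted: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """All distributional parameters of the generator (defaults are the
    study conditions; see docs/methods.md for rationale)."""
    cancers: list[CancerSimConfig] = field(default_factory=list)
    panel: tuple[str, ...] = ATPCR_PANEL
    n_decoys: int = 200
    # copy number
    scna_background_sd: float = 0.05
    focal_amp_mean: float = 0.5       # mu_amp, log2 units
    focal_amp_sd: float = 0.05
    focal_carrier_fraction: float = 0.4   # f_amp (= f_del)
    focal_del_mean: float = 0.5       # magnitude of planted deletions
    focal_len_range: tuple[float, float] = (500_000.0, 5_000_000.0)
    # mutations
    mutation_background_rate: float = 0.01   # lambda_bg per gene per sample
    driver_rate_multiplier: float = 8.0      # rho
    caller_alphas: tuple[float, ...] = (1e-3, 7e-4, 5e-4, 1.2e-3, 9e-4)
    caller_flip_noise: tuple[float, ...] = (0.005,) * 5
    # fusions
    fusion_background_rate: float = 0.01     # expected events per sample
    planted_fusion_events: int = 4
    # expression
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.5
    de_effect: float = 1.5            # delta, log2 units
    dosage_slope: float = 1.0         # beta_cn
    expr_noise_sd: float = 0.5        # sigma
    # survival
    baseline_hazard: float = 1e-3     # lambda0, events per day
    survival_log_hazard: float = 0.7  # theta per SD of expression
    dropout_rate: float = 8e-4        # exponential censoring hazard
    admin_horizon: float = 2000.0     # days

    def validate(self) -> None:
        if not self.cancers:
            raise ValueError("config declares no cancer types")
        genome = set(default_gene_model(self.panel, self.n_decoys)["gene_id"])
        for rate in (self.scna_background_sd, self.mutation_background_rate,
                     self.fusion_background_rate, self.baseline_hazard,
                     self.dropout_rate, self.expr_noise_sd):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if not 0 <= self.focal_carrier_fraction <= 1:
            raise ValueError("carrier fraction must be in [0, 1]")
        for c in self.cancers:
            if c.n_normal_pairs > c.n_tumour:
                raise ValueError(f"{c.name}: n_normal_pairs > n_tumour")
            unknown = set(c.planted) - genome
            if unknown:
                raise ValueError(f"{c.name}: planted genes not in genome: "
                                 f"{sorted(unknown)[:5]}")
            for g, channels in c.planted.items():
                bad = set(channels) - set(EVIDENCE_CHANNELS)
                if bad:
                    raise ValueError(f"{c.name}/{g}: unknown channels {bad}")
            n_fus = sum("fusion" in ch for ch in c.planted.values())
            if n_fus * self.planted_fusion_events > c.n_tumour:
                raise ValueError(f"{c.name}: more planted fusion events than "
                                 "tumour samples")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every simulated cohort."""
    planted_drivers: dict[str, dict[str, tuple[str, ...]]]
    generator_params: dict
    seed: int

    def as_dict(self) -> dict:
        return {"planted_drivers": {ct: {g: list(ch) for g, ch in d.items()}
                                    for ct, d in self.planted_drivers.items()},
                "generator_params": self.generator_params, "seed": self.seed}


def default_config(n_cancer_types: int = 3, n_tumour: int = 100,
                   n_normal_pairs: int = 30,
                   planted: dict[str, dict[str, tuple[str, ...]]] | None = None,
                   **overrides) -> SimulationConfig:
    """Convenience builder: named cancer types CT01..CTnn, optional plants."""
    cancers = []
    for i in range(n_cancer_types):
        name = f"CT{i + 1:02d}"
        cancers.append(CancerSimConfig(
            name=name, n_tumour=n_tumour, n_normal_pairs=n_normal_pairs,
            planted=dict((planted or {}).get(name, {}))))
    return SimulationConfig(cancers=cancers, **overrides)


# ---------------------------------------------------------------------------
# per-layer generators
# ---------------------------------------------------------------------------

def _planted_in(cancer: CancerSimConfig, channel: str) -> list[str]:
    return sorted(g for g, ch in cancer.planted.items() if channel in ch)


def _simulate_scna(cfg: SimulationConfig, cancer: CancerSimConfig,
                   genes: pd.DataFrame, samples: list[str],
                   rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segments table plus the true gene × sample copy-ratio matrix."""
    n = len(samples)
    n_blocks = _CHROM_LEN // _BLOCK_LEN
    block_vals = rng.normal(0.0, cfg.scna_background_sd,
                            size=(n, _N_CHROM, n_blocks))
    gene_chrom = genes["chrom"].astype(int).to_numpy() - 1
    gene_block = (genes["start"].to_numpy() // _BLOCK_LEN).astype(int)
    cn = block_vals[:, gene_chrom, gene_block].T.copy()   # gene × sample

    # focal events: (sample_idx, chrom_idx, start, end, delta)
    focal: dict[tuple[int, int], list[tuple[int, int, float]]] = {}
    gene_pos = {g: i for i, g in enumerate(genes["gene_id"])}
    for channel, sign, mu in (("scna_amp", 1.0, cfg.focal_amp_mean),
                              ("scna_del", -1.0, cfg.focal_del_mean)):
        for g in _planted_in(cancer, channel):
            gi = gene_pos[g]
            carriers = np.flatnonzero(
                rng.random(n) < cfg.focal_carrier_fraction)
            g_start = int(genes["start"].iat[gi])
            g_end = int(genes["end"].iat[gi])
            for s in carriers:
                length = rng.uniform(*cfg.focal_len_range)
                lo = max(1, int(g_end - length + 1))
                start = int(rng.uniform(lo, g_start + 1))
                end = min(_CHROM_LEN, start + int(length) - 1)
                delta = sign * rng.normal(mu, cfg.focal_amp_sd)
                focal.setdefault((s, gene_chrom[gi]), []).append(
                    (start, end, delta))

    rows_sample, rows_chrom, rows_start, rows_end, rows_val = [], [], [], [], []
    block_edges = [(b * _BLOCK_LEN + 1, min((b + 1) * _BLOCK_LEN, _CHROM_LEN))
                   for b in range(n_blocks)]
    # untouched chromosomes: one row per background block (vectorized below);
    # chromosomes with focal events are rebuilt from breakpoints
    plain = np.ones((n, _N_CHROM), dtype=bool)
    for (s, c) in focal:
        plain[s, c] = False
    s_idx, c_idx = np.nonzero(plain)
    for b, (bs, be) in enumerate(block_edges):
        rows_sample.append(s_idx)
        rows_chrom.append(c_idx)
        rows_start.append(np.full(s_idx.size, bs))
        rows_end.append(np.full(s_idx.size, be))
        rows_val.append(block_vals[s_idx, c_idx, b])

    touched_gene_vals: list[tuple[int, int, float]] = []  # gene, sample, value
    for (s, c), events in sorted(focal.items()):
        cuts = {1, _CHROM_LEN + 1}
        cuts.update(bs for bs, _ in block_edges[1:])
        for start, end, _ in events:
            cuts.update((start, end + 1))
        edges = np.array(sorted(cuts))
        seg_s, seg_e = edges[:-1], edges[1:] - 1
        vals = block_vals[s, c][np.minimum((seg_s - 1) // _BLOCK_LEN,
                                           n_blocks - 1)]
        for start, end, delta in events:
            vals = vals + np.where((seg_s >= start) & (seg_e <= end), delta, 0.0)
        rows_sample.append(np.full(seg_s.size, s))
        rows_chrom.append(np.full(seg_s.size, c))
        rows_start.append(seg_s)
        rows_end.append(seg_e)
        rows_val.append(vals)
        on_chrom = np.flatnonzero(gene_chrom == c)
        for gi in on_chrom:
            gs, ge = int(genes["start"].iat[gi]), int(genes["end"].iat[gi])
            ov = (np.minimum(seg_e, ge) - np.maximum(seg_s, gs) + 1).clip(min=0)
            if ov.sum():
                touched_gene_vals.append((gi, s, float((ov * vals).sum() / ov.sum())))

    for gi, s, v in touched_gene_vals:
        cn[gi, s] = v

    seg = pd.DataFrame({
        "sample_id": np.array(samples)[np.concatenate(rows_sample)],
        "chrom": (np.concatenate(rows_chrom) + 1).astype(str),
        "start": np.concatenate(rows_start).astype(np.int64),
        "end": np.concatenate(rows_end).astype(np.int64),
        "n_markers": ((np.concatenate(rows_end)
                       - np.concatenate(rows_start)) // 10_000).astype(np.int64),
        "log2_ratio": np.concatenate(rows_val),
    })
    seg = seg.sort_values(["sample_id", "chrom", "start"],
                          kind="mergesort").reset_index(drop=True)
    cn_df = pd.DataFrame(cn, index=genes["gene_id"].to_list(), columns=samples)
    return seg, cn_df


def _simulate_mutations(cfg: SimulationConfig, cancer: CancerSimConfig,
                        genes: pd.DataFrame, samples: list[str],
                        rng: np.random.Generator) -> pd.DataFrame:
    rates = np.full(len(genes), cfg.mutation_background_rate)
    drivers = set(_planted_in(cancer, "mutation"))
    is_driver = genes["gene_id"].isin(drivers).to_numpy()
    rates[is_driver] = np.minimum(
        1.0, cfg.mutation_background_rate * cfg.driver_rate_multiplier)
    hits = rng.random((len(genes), len(samples))) < rates[:, None]
    gi, si = np.nonzero(hits)
    classes = rng.choice(_VARIANT_CLASSES, size=gi.size, p=_VARIANT_PROBS)
    return pd.DataFrame({
        "sample_id": np.array(samples)[si],
        "gene_id": genes["gene_id"].to_numpy()[gi],
        "variant_class": classes,
    }).sort_values(["sample_id", "gene_id"], kind="mergesort").reset_index(drop=True)


def _simulate_fusions(cfg: SimulationConfig, cancer: CancerSimConfig,
                      genes: pd.DataFrame, samples: list[str],
                      rng: np.random.Generator) -> pd.DataFrame:
    gene_ids = genes["gene_id"].to_list()
    rows = []
    n_bg = rng.poisson(cfg.fusion_background_rate * len(samples))
    for _ in range(n_bg):
        g5, g3 = rng.choice(len(gene_ids), size=2, replace=False)
        rows.append({"sample_id": samples[rng.integers(len(samples))],
                     "cancer_type": cancer.name,
                     "gene_5p": gene_ids[g5], "gene_3p": gene_ids[g3]})
    for k, g in enumerate(_planted_in(cancer, "fusion")):
        partner = f"PARTNER_{cancer.name}_{k}"
        carriers = rng.choice(len(samples), size=cfg.planted_fusion_events,
                              replace=False)
        for s in carriers:
            rows.append({"sample_id": samples[s], "cancer_type": cancer.name,
                         "gene_5p": g, "gene_3p": partner})
    df = pd.DataFrame(rows, columns=["sample_id", "cancer_type",
                                     "gene_5p", "gene_3p"])
    return df.sort_values(["sample_id", "gene_5p", "gene_3p"],
                          kind="mergesort").reset_index(drop=True)


def _simulate_expression(cfg: SimulationConfig, cancer: CancerSimConfig,
                         genes: pd.DataFrame, tumour_samples: list[str],
                         patients: list[str], cn: pd.DataFrame,
                         rng: np.random.Generator
                         ) -> tuple[ExpressionMatrix, np.ndarray]:
    """FPKM matrix for tumours plus paired normals; returns the matrix and
    the tumour log2-expression array (gene × tumour) reused for survival."""
    n_genes = len(genes)
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                          size=n_genes)
    de = np.zeros(n_genes)
    ids = genes["gene_id"].to_list()
    pos = {g: i for i, g in enumerate(ids)}
    for g in _planted_in(cancer, "de_up"):
        de[pos[g]] += cfg.de_effect
    for g in _planted_in(cancer, "de_down"):
        de[pos[g]] -= cfg.de_effect
    n_t = len(tumour_samples)
    log2_t = (baseline[:, None] + cfg.dosage_slope * cn.to_numpy()
              + de[:, None]
              + rng.normal(0, cfg.expr_noise_sd, size=(n_genes, n_t)))
    n_n = cancer.n_normal_pairs
    log2_n = (baseline[:, None]
              + rng.normal(0, cfg.expr_noise_sd, size=(n_genes, n_n)))
    normal_samples = [f"{p}-N" for p in patients[:n_n]]
    values = pd.DataFrame(
        np.hstack([2.0 ** log2_t, 2.0 ** log2_n]),
        index=ids, columns=tumour_samples + normal_samples)
    meta = pd.DataFrame(
        [{"sample_id": s, "patient_id": p, "tissue": "tumour"}
         for s, p in zip(tumour_samples, patients)]
        + [{"sample_id": s, "patient_id": p, "tissue": "normal"}
           for s, p in zip(normal_samples, patients[:n_n])])
    return ExpressionMatrix(values=values, sample_meta=meta), log2_t


def _simulate_survival(cfg: SimulationConfig, cancer: CancerSimConfig,
                       genes: pd.DataFrame, tumour_samples: list[str],
                       log2_t: np.ndarray,
                       rng: np.random.Generator) -> pd.DataFrame:
    prog = _planted_in(cancer, "prognosis")
    eta = np.zeros(len(tumour_samples))
    if prog and cfg.survival_log_hazard != 0:
        pos = {g: i for i, g in enumerate(genes["gene_id"])}
        for g in prog:
            x = log2_t[pos[g]]
            sd = x.std()
            if sd > 0:
                eta += cfg.survival_log_hazard * (x - x.mean()) / sd
    rate = cfg.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    t_drop = (rng.exponential(1.0 / cfg.dropout_rate, size=rate.size)
              if cfg.dropout_rate > 0 else np.full(rate.size, np.inf))
    t_cens = np.minimum(t_drop, cfg.admin_horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)
    return pd.DataFrame({"sample_id": tumour_samples,
                         "os_time": time, "os_event": event})


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig, seed: int
                    ) -> tuple[dict[str, CohortBundle], SyntheticTruth]:
    """Generate one CohortBundle per configured cancer type plus the truth."""
    config.validate()
    genes = default_gene_model(config.panel, config.n_decoys)
    root = np.random.SeedSequence(seed)
    bundles: dict[str, CohortBundle] = {}
    for cancer, child in zip(config.cancers,
                             root.spawn(len(config.cancers))):
        streams = [np.random.default_rng(s) for s in child.spawn(5)]
        patients = [f"{cancer.name}-P{i:04d}" for i in range(cancer.n_tumour)]
        tumour_samples = [f"{p}-T" for p in patients]
        seg, cn = _simulate_scna(config, cancer, genes, tumour_samples,
                                 streams[0])
        mutations = _simulate_mutations(config, cancer, genes, tumour_samples,
                                        streams[1])
        fusions = _simulate_fusions(config, cancer, genes, tumour_samples,
                                    streams[2])
        expression, log2_t = _simulate_expression(
            config, cancer, genes, tumour_samples, patients, cn, streams[3])
        clinical = _simulate_survival(config, cancer, genes, tumour_samples,
                                      log2_t, streams[4])
        freq = mutation_frequency(mutations, set(tumour_samples),
                                  genes["gene_id"].to_list())
        calls = pseudo_callers(
            freq, config.mutation_background_rate,
            alphas=config.caller_alphas, flip_noise=config.caller_flip_noise,
            seed=int(child.generate_state(1)[0] % (2 ** 31)))
        bundles[cancer.name] = CohortBundle(
            cancer_type=cancer.name, gene_model=genes, segments=seg,
            mutations=mutations, fusions=fusions, expression=expression,
            clinical=clinical, driver_calls=calls)
    truth = SyntheticTruth(
        planted_drivers={c.name: {g: tuple(ch) for g, ch in
                                  sorted(c.planted.items())}
                         for c in config.cancers},
        generator_params=asdict(config), seed=seed)
    return bundles, truth


def null_cohort(config: SimulationConfig, seed: int
                ) -> tuple[dict[str, CohortBundle], SyntheticTruth]:
    """Same generator with every planted effect removed (type-I-error runs)."""
    import copy
    null_cfg = copy.deepcopy(config)
    for c in null_cfg.cancers:
        c.planted = {}
    null_cfg.survival_log_hazard = 0.0
    return simulate_cohort(null_cfg, seed)


def write_cohort(bundles: dict[str, CohortBundle], truth: SyntheticTruth,
                 outdir: str | Path) -> None:
    """Serialize a cohort directory in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    any_bundle = next(iter(bundles.values()))
    bed = any_bundle.gene_model
    with open(outdir / "genes.bed", "w") as fh:
        for r in bed.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")
    for ct, b in sorted(bundles.items()):
        d = outdir / ct
        d.mkdir(exist_ok=True)
        seg = b.segments.rename(columns={
            "sample_id": "sample", "start": "loc.start", "end": "loc.end",
            "n_markers": "num.mark", "log2_ratio": "seg.mean"})
        write_stage_table(seg, d / "segments.seg")
        maf = b.mutations.rename(columns={
            "sample_id": "Tumor_Sample_Barcode", "gene_id": "Hugo_Symbol"})
        maf["Variant_Classification"] = maf.pop("variant_class").map({
            "missense": "Missense_Mutation", "nonsense": "Nonsense_Mutation",
            "frameshift_indel": "Frame_Shift_Del",
            "inframe_indel": "In_Frame_Del", "splice": "Splice_Site",
            "other": "Nonstop_Mutation"})
        write_stage_table(maf, d / "mutations.maf")
        fus = b.fusions.rename(columns={"sample_id": "sample",
                                        "gene_5p": "gene5", "gene_3p": "gene3"})
        write_stage_table(fus, d / "fusions.tsv")
        expr = b.expression.values.reset_index(names="gene_id")
        write_stage_table(expr, d / "expression.tsv")
        write_stage_table(b.expression.sample_meta, d / "sample_meta.tsv")
        clin = b.clinical.rename(columns={"sample_id": "sample",
                                          "os_time": "OS.time",
                                          "os_event": "OS.event"})
        write_stage_table(clin, d / "clinical.tsv")
        if b.driver_calls is not None:
            write_stage_table(b.driver_calls.reset_index(), d / "driver_calls.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
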