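"""Reading, validation and writing of the tabular formats the pipeline consumes.

All tables are tab-delimited text. Internally every table is a
:class:`pandas.DataFrame` with canonical column names; genomic coordinates are
1-based inclusive (the SEG/MAF convention; BED input is shifted on read).

Readers return ``(table, report)`` style results where row-level repairs and
drops are counted, so a run summary can always assert
``rows_in == rows_kept + rows_dropped``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("pandriver")

VARIANT_CLASSES = ("missense", "nonsense", "frameshift_indel", "inframe_indel",
                   "splice", "other")

#: MAF ``Variant_Classification`` -> internal closed enum. ``None`` marks
#: silent/non-coding classes that are excluded from driver evidence.
MAF_CLASS_MAP: dict[str, str | None] = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "other",
    "Frame_Shift_Del": "frameshift_indel",
    "Frame_Shift_Ins": "frameshift_indel",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
    "Splice_Site": "splice",
    "Translation_Start_Site": "other",
    "Silent": None,
    "Synonymous": None,
    "3'UTR": None,
    "5'UTR": None,
    "3'Flank": None,
    "5'Flank": None,
    "Intron": None,
    "IGR": None,
    "RNA": None,
}


class FormatError(ValueError):
    """A file does not conform to its declared tabular format."""


@dataclass
class ReadReport:
    """Bookkeeping for one table read: every input row is kept or dropped."""
    rows_in: int = 0
    rows_kept: int = 0
    rows_dropped: int = 0
    repairs: int = 0
    messages: list[str] = field(default_factory=list)

    def note(self, msg: str) -> None:
        self.messages.append(msg)
        logger.warning(msg)

    def as_dict(self) -> dict:
        return {"rows_in": self.rows_in, "rows_kept": self.rows_kept,
                "rows_dropped": self.rows_dropped, "repairs": self.repairs,
                "messages": list(self.messages)}


@dataclass
class ExpressionMatrix:
    """FPKM gene × sample matrix plus per-sample metadata.

    ``values``: DataFrame indexed by gene_id, columns sample_id, all ≥ 0.
    ``sample_meta``: DataFrame with columns sample_id, patient_id, tissue
    (``tumour`` or ``normal``); a tumour/normal pair shares patient_id.
    """
    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if vals.size and (not np.all(np.isfinite(vals)) or vals.min() < 0):
            raise FormatError("expression values must be finite and >= 0")
        meta = self.sample_meta
        required = {"sample_id", "patient_id", "tissue"}
        if not required.issubset(meta.columns):
            raise FormatError(f"sample meta needs columns {sorted(required)}")
        bad = set(meta["tissue"]) - {"tumour", "normal"}
        if bad:
            raise FormatError(f"unknown tissue labels: {sorted(bad)}")
        if meta.duplicated(["patient_id", "tissue"]).any():
            raise FormatError("duplicated (patient_id, tissue) in sample meta")
        unknown = set(self.values.columns) - set(meta["sample_id"])
        if unknown:
            raise FormatError(f"expression columns missing from sample meta: "
                              f"{sorted(unknown)[:5]}")

    def tumour_samples(self) -> list[str]:
        meta = self.sample_meta
        keep = meta.loc[meta["tissue"] == "tumour", "sample_id"]
        return [s for s in self.values.columns if s in set(keep)]

    def paired(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Tumour and normal sub-matrices with columns aligned by patient."""
        meta = self.sample_meta.set_index(["patient_id", "tissue"])["sample_id"]
        patients = sorted({p for p, t in meta.index if t == "normal"}
                          & {p for p, t in meta.index if t == "tumour"})
        t_cols = [meta[(p, "tumour")] for p in patients]
        n_cols = [meta[(p, "normal")] for p in patients]
        t = self.values[t_cols]
        n = self.values[n_cols]
        t.columns = patients
        n.columns = patients
        return t, n


@dataclass
class CohortBundle:
    """One cancer type's aligned multi-omic tables.

    Every sample referenced by any omic table must be present in the sample
    registry (the union of declared samples), enforced by :meth:`validate`.
    """
    cancer_type: str
    gene_model: pd.DataFrame            # gene_id, chrom, start, end, strand
    segments: pd.DataFrame              # sample_id, chrom, start, end, n_markers, log2_ratio
    mutations: pd.DataFrame             # sample_id, gene_id, variant_class
    fusions: pd.DataFrame               # sample_id, cancer_type, gene_5p, gene_3p
    expression: ExpressionMatrix
    clinical: pd.DataFrame              # sample_id, os_time, os_event
    driver_calls: pd.DataFrame | None = None  # gene × algorithm booleans
    sample_registry: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sample_registry:
            self.sample_registry = self._infer_registry()
        self.validate()

    def _infer_registry(self) -> set[str]:
        reg: set[str] = set()
        for df, col in ((self.segments, "sample_id"),
                        (self.mutations, "sample_id"),
                        (self.fusions, "sample_id"),
                        (self.clinical, "sample_id")):
            if len(df):
                reg.update(df[col].astype(str))
        reg.update(map(str, self.expression.values.columns))
        return reg

    def validate(self) -> None:
        for name, df in (("segments", self.segments),
                         ("mutations", self.mutations),
                         ("fusions", self.fusions),
                         ("clinical", self.clinical)):
            if len(df):
                missing = set(df["sample_id"].astype(str)) - self.sample_registry
                if missing:
                    raise FormatError(
                        f"{name} references unregistered samples: "
                        f"{sorted(missing)[:5]}")
        if self.gene_model["gene_id"].duplicated().any():
            dup = self.gene_model.loc[
                self.gene_model["gene_id"].duplicated(), "gene_id"]
            raise FormatError(f"duplicate gene_ids in panel: {sorted(set(dup))[:5]}")

    @property
    def tumour_samples(self) -> list[str]:
        return self.expression.tumour_samples()


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def normalize_chrom(chrom: str) -> str:
    """Accept '17', 'chr17', 'Chr17'; return the bare name."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def _require_columns(df: pd.DataFrame, aliases: Mapping[str, Iterable[str]],
                     path: str | Path, optional: Iterable[str] = ()) -> dict[str, str]:
    """Map canonical column names onto whatever alias the file uses."""
    lower = {c.lower(): c for c in df.columns}
    out: dict[str, str] = {}
    for canon, names in aliases.items():
        for cand in names:
            if cand.lower() in lower:
                out[canon] = lower[cand.lower()]
                break
        else:
            if canon not in optional:
                raise FormatError(
                    f"{path}: missing mandatory column '{canon}' "
                    f"(accepted names: {', '.join(names)})")
    return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

SEG_ALIASES = {
    "sample_id": ("sample", "sample_id", "id", "sampleid"),
    "chrom": ("chrom", "chromosome", "chr"),
    "start": ("loc.start", "start", "loc_start"),
    "end": ("loc.end", "end", "loc_end"),
    "n_markers": ("num.mark", "num_mark", "n_markers", "markers"),
    "log2_ratio": ("seg.mean", "seg_mean", "log2", "log2_ratio", "segmean"),
}


def read_seg(path: str | Path, dialect: str = "seg") -> tuple[pd.DataFrame, ReadReport]:
    """Read a SEG-style segmented copy-number table.

    Returns validated records with normalized chromosome names. Overlapping
    segments within one (sample, chromosome) are resolved by keeping the
    segment that covers more bases of the conflict region; each resolution is
    logged and counted as a repair.
    """
    if dialect != "seg":
        raise ValueError(f"unknown SEG dialect: {dialect!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    report = ReadReport(rows_in=len(raw))
    cols = _require_columns(raw, SEG_ALIASES, path, optional=("n_markers",))
    df = pd.DataFrame({
        "sample_id": raw[cols["sample_id"]].astype(str),
        "chrom": raw[cols["chrom"]].map(normalize_chrom),
        "start": pd.to_numeric(raw[cols["start"]], errors="coerce"),
        "end": pd.to_numeric(raw[cols["end"]], errors="coerce"),
        "n_markers": (pd.to_numeric(raw[cols["n_markers"]], errors="coerce")
                      if "n_markers" in cols else 0),
        "log2_ratio": pd.to_numeric(raw[cols["log2_ratio"]], errors="coerce"),
    })
    bad = df[["start", "end", "log2_ratio"]].isna().any(axis=1)
    for i in np.flatnonzero(bad.to_numpy()):
        report.note(f"{path}: line {i + 2}: non-numeric coordinate or seg mean; "
                    "row dropped")
    df = df[~bad]
    malformed = df["start"] >= df["end"]
    for i in np.flatnonzero(malformed.to_numpy()):
        report.note(f"{path}: segment with start >= end dropped")
    df = df[~malformed]
    df = df.astype({"start": np.int64, "end": np.int64})
    df["n_markers"] = df["n_markers"].fillna(0).astype(np.int64)
    df = _resolve_overlaps(df, report)
    report.rows_kept = len(df)
    report.rows_dropped = report.rows_in - report.rows_kept
    return df.reset_index(drop=True), report


def _resolve_overlaps(df: pd.DataFrame, report: ReadReport) -> pd.DataFrame:
    """Drop the shorter of any two overlapping segments of one sample/chrom."""
    keep_idx: list[int] = []
    for (_, _), grp in df.groupby(["sample_id", "chrom"], sort=False):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        idx = grp.index.to_list()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        lengths = ends - starts + 1
        alive = np.ones(len(grp), bool)
        for i in range(len(grp)):
            if not alive[i]:
                continue
            for j in range(i + 1, len(grp)):
                if not alive[j] or starts[j] > ends[i]:
                    if starts[j] > ends[i]:
                        break
                    continue
                loser = i if lengths[i] < lengths[j] else j
                alive[loser] = False
                report.repairs += 1
                report.note(
                    f"overlapping segments for sample "
                    f"{grp['sample_id'].iat[0]} on chr{grp['chrom'].iat[0]}: "
                    "kept the longer segment")
                if loser == i:
                    break
        keep_idx.extend(ix for ix, a in zip(idx, alive) if a)
    return df.loc[sorted(keep_idx)]


MAF_ALIASES = {
    "sample_id": ("Tumor_Sample_Barcode", "sample", "sample_id"),
    "gene_id": ("Hugo_Symbol", "gene", "gene_id"),
    "variant_class": ("Variant_Classification", "variant_class"),
}


def read_maf_lite(path: str | Path) -> tuple[pd.DataFrame, ReadReport]:
    """Read a MAF-lite mutation table (sample, gene, variant classification).

    Variant classes are mapped onto the internal closed enum via
    :data:`MAF_CLASS_MAP`; silent/non-coding rows are excluded and counted,
    unmappable classes are dropped (not fatal) and counted.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    report = ReadReport(rows_in=len(raw))
    cols = _require_columns(raw, MAF_ALIASES, path)
    vc = raw[cols["variant_class"]].astype(str)
    mapped = vc.map(MAF_CLASS_MAP)
    known = vc.isin(MAF_CLASS_MAP)
    n_unmappable = int((~known).sum())
    if n_unmappable:
        report.note(f"{path}: {n_unmappable} rows with unmappable variant "
                    f"classes dropped: {sorted(set(vc[~known]))[:5]}")
    silent = known & mapped.isna()
    n_silent = int(silent.sum())
    if n_silent:
        report.note(f"{path}: {n_silent} silent/non-coding rows excluded")
    keep = known & mapped.notna()
    df = pd.DataFrame({
        "sample_id": raw.loc[keep, cols["sample_id"]].astype(str),
        "gene_id": raw.loc[keep, cols["gene_id"]].astype(str),
        "variant_class": mapped[keep],
    }).reset_index(drop=True)
    report.rows_kept = len(df)
    report.rows_dropped = report.rows_in - report.rows_kept
    return df, report


def read_gene_model_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 gene panel; 0-based half-open → 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene_id", "score", "strand"],
                     dtype={"chrom": str, "gene_id": str, "strand": str})
    out = pd.DataFrame({
        "gene_id": df["gene_id"],
        "chrom": df["chrom"].map(normalize_chrom),
        "start": df["start"].astype(np.int64) + 1,
        "end": df["end"].astype(np.int64),
        "strand": df["strand"].fillna("+"),
    })
    if (out["start"] > out["end"]).any():
        raise FormatError(f"{path}: gene with start > end after BED conversion")
    if out["gene_id"].duplicated().any():
        dup = sorted(set(out.loc[out["gene_id"].duplicated(), "gene_id"]))
        raise FormatError(f"{path}: duplicate gene_ids in panel: {dup[:5]}")
    bad_strand = ~out["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(f"{path}: strand must be '+' or '-'")
    return out


FUSION_ALIASES = {
    "sample_id": ("sample", "sample_id"),
    "cancer_type": ("cancer_type", "cancer", "disease"),
    "gene_5p": ("gene5", "gene_5p", "five_prime"),
    "gene_3p": ("gene3", "gene_3p", "three_prime"),
}


def read_fusions(path: str | Path) -> tuple[pd.DataFrame, ReadReport]:
    """Read a fusion event table; self-fusions are rejected and counted."""
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    report = ReadReport(rows_in=len(raw))
    cols = _require_columns(raw, FUSION_ALIASES, path)
    df = pd.DataFrame({c: raw[cols[c]].astype(str) for c in FUSION_ALIASES})
    selfs = df["gene_5p"] == df["gene_3p"]
    if selfs.any():
        report.note(f"{path}: {int(selfs.sum())} self-fusion rows rejected")
    df = df[~selfs].reset_index(drop=True)
    report.rows_kept = len(df)
    report.rows_dropped = report.rows_in - report.rows_kept
    return df, report


CLINICAL_ALIASES = {
    "sample_id": ("sample", "sample_id"),
    "os_time": ("os.time", "os_time", "time"),
    "os_event": ("os.event", "os_event", "event", "status"),
}


def read_clinical(path: str | Path) -> tuple[pd.DataFrame, ReadReport]:
    """Read overall-survival follow-up: time in days > 0, event ∈ {0, 1}."""
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    report = ReadReport(rows_in=len(raw))
    cols = _require_columns(raw, CLINICAL_ALIASES, path)
    df = pd.DataFrame({
        "sample_id": raw[cols["sample_id"]].astype(str),
        "os_time": pd.to_numeric(raw[cols["os_time"]], errors="coerce"),
        "os_event": pd.to_numeric(raw[cols["os_event"]], errors="coerce"),
    })
    bad = (df["os_time"].isna() | (df["os_time"] <= 0)
           | ~df["os_event"].isin([0, 1]))
    if bad.any():
        report.note(f"{path}: {int(bad.sum())} clinical rows with non-positive "
                    "time or non-binary event dropped")
    df = df[~bad].reset_index(drop=True)
    df["os_event"] = df["os_event"].astype(np.int64)
    report.rows_kept = len(df)
    report.rows_dropped = report.rows_in - report.rows_kept
    return df, report


def read_expression(values_path: str | Path, meta_path: str | Path | None = None,
                    patient_delimiter: str | None = None,
                    patient_fields: int = 3) -> ExpressionMatrix:
    """Read a gene × sample FPKM matrix plus sample metadata.

    Pairing comes from an explicit meta table when given; otherwise
    patient_id is derived by truncating TCGA-like barcodes at
    ``patient_delimiter`` (keeping ``patient_fields`` fields) and tissue is
    inferred from the barcode's sample-type code. An explicit column wins.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        missing = {"sample_id", "patient_id", "tissue"} - set(meta.columns)
        if missing:
            raise FormatError(f"{meta_path}: missing columns {sorted(missing)}")
    elif patient_delimiter is not None:
        rows = []
        for s in values.columns:
            parts = s.split(patient_delimiter)
            patient = patient_delimiter.join(parts[:patient_fields])
            code = parts[patient_fields] if len(parts) > patient_fields else "01"
            tissue = "normal" if code[:2].isdigit() and int(code[:2]) >= 10 else "tumour"
            rows.append({"sample_id": s, "patient_id": patient, "tissue": tissue})
        meta = pd.DataFrame(rows)
    else:
        raise ValueError("need either meta_path or patient_delimiter")
    return ExpressionMatrix(values=values, sample_meta=meta)


def read_driver_calls(path: str | Path) -> pd.DataFrame:
    """Read a gene × algorithm boolean driver-call matrix (≤ 5 algorithms)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicated algorithm column")
    if df.shape[1] > 5:
        raise FormatError(f"{path}: at most 5 algorithm columns supported")
    return df.astype(bool)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(x: object) -> str:
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return "NA"
        return f"{x:.6g}"
    if isinstance(x, (bool, np.bool_)):
        return "True" if x else "False"
    return str(x)


def write_stage_table(table: pd.DataFrame, path: str | Path,
                      sort: bool = True) -> None:
    """Write a stage result as deterministic TSV.

    Floats at 6 significant digits; rows sorted by (gene_id, cancer_type)
    lexicographically when those columns exist, so re-runs are byte-identical.
    ``sort=False`` preserves the caller's (already deterministic) row order,
    e.g. for rank-ordered tables.
    """
    df = table.copy()
    sort_cols = [c for c in ("gene_id", "cancer_type") if c in df.columns]
    if sort and sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_stage_table(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_stage_table` output."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_run_summary(summary: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
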