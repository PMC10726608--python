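"""Cohort construction from standard files.

Applies the data-preparation rules used for TCGA-style cohorts: TCGA
barcode parsing into patient / sample-type / group, seeded removal of
duplicated samples (one kept per patient-group-cancer class), exclusion
of genes with zero TPM across all samples, the log2(TPM+1) transform,
promoter methylation restricted to TSS1500 CpG-island probes, and GMT
gene-set parsing.  A cohort round-trips through a plain-text directory
bundle with a YAML manifest.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, TUMOR, NORMAL

__all__ = ["parse_barcode", "build_cohort", "aggregate_promoter_methylation",
           "read_gmt", "save_cohort", "load_cohort", "IngestReport"]


class BarcodeError(ValueError):
    pass


@dataclass
class IngestReport:
    n_samples_in: int = 0
    n_duplicates_removed: int = 0
    n_genes_in: int = 0
    n_zero_genes_removed: int = 0
    n_probes_in: int = 0
    n_promoter_probes_kept: int = 0
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def parse_barcode(barcode: str) -> tuple[str, str, str]:
    """Split a TCGA-style barcode into (patient_id, sample_code, group).

    The patient is the first three dash-delimited fields; the 4th
    field's leading two digits encode the sample type: 01-09 tumor,
    10-19 normal.  Codes >= 20 (control lines) are rejected rather than
    silently grouped.
    """
    fields = barcode.split("-")
    if len(fields) < 4:
        raise BarcodeError(
            f"barcode {barcode!r} has {len(fields)} fields; need >= 4 "
            "(project-center-patient-sample)")
    code = fields[3][:2]
    if len(code) < 2 or not code.isdigit():
        raise BarcodeError(
            f"barcode {barcode!r}: sample field must start with two digits")
    code_num = int(code)
    if code_num >= 20:
        raise BarcodeError(
            f"barcode {barcode!r}: sample code {code} is a control/unsupported type")
    group = TUMOR if 1 <= code_num <= 9 else NORMAL
    return "-".join(fields[:3]), code, group


def read_gmt(path) -> dict:
    """Parse a Broad-dialect GMT file into {set name: gene list}.

    One set per line: name, description, then member genes, all
    tab-separated.  Duplicate genes within a set are collapsed keeping
    first occurrence; blank lines are skipped.
    """
    catalog: dict[str, list] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno} has {len(fields)} fields; "
                             "GMT needs name, description and >= 1 gene")
        name = fields[0]
        if name in catalog:
            raise ValueError(f"{path}: duplicate gene-set name {name!r} at line {lineno}")
        catalog[name] = list(dict.fromkeys(g for g in fields[2:] if g))
    return catalog


def aggregate_promoter_methylation(beta: pd.DataFrame,
                                   annotation: pd.DataFrame,
                                   how: str = "mean") -> pd.DataFrame:
    """Aggregate probe-level betas to per-gene promoter methylation.

    Only probes annotated to the TSS1500 region AND lying in a CpG
    island define the promoter.  Per gene the promoter beta is the
    unweighted mean (optionally median) over kept probes, ignoring
    missing values; genes without any kept probe are absent from the
    result.  ``beta`` is probes x samples; the result is genes x samples.
    """
    vals = beta.to_numpy(dtype=float)
    ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
    if not ok.all():
        raise ValueError("beta values must lie in [0, 1] or be missing")
    if how not in ("mean", "median"):
        raise ValueError(f"unknown aggregation {how!r}")
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns \
        else annotation
    keep = ann.index[(ann["region"] == "TSS1500") & (ann["island_status"] == "island")]
    keep = keep.intersection(beta.index)
    if not len(keep):
        return pd.DataFrame(columns=beta.columns)
    sub = beta.loc[keep]
    groups = sub.groupby(ann.loc[keep, "gene"])
    agg = groups.mean() if how == "mean" else groups.median()
    agg.index.name = "gene"
    return agg


def build_cohort(expression_tpm: pd.DataFrame, meta: pd.DataFrame,
                 seed: int,
                 tmb: pd.Series | None = None,
                 msi: pd.Series | None = None,
                 immune_ratio: pd.DataFrame | None = None,
                 immune_score: pd.DataFrame | None = None,
                 methylation_beta: pd.DataFrame | None = None,
                 probe_annotation: pd.DataFrame | None = None,
                 families: dict | None = None,
                 catalogs: dict | None = None,
                 gene_whitelist=None,
                 log_transformed: bool = False) -> tuple[Cohort, IngestReport]:
    """Build a validated :class:`Cohort` from raw tables.

    ``expression_tpm`` is samples x genes of raw TPM (>= 0) indexed by
    barcode; ``meta`` maps barcodes (or patients) to cancer_type plus
    clinical columns.  Duplicated (patient, group, cancer) samples are
    removed by a seeded uniform draw over the lexicographically sorted
    duplicates, so ingest is deterministic given the seed.  All-zero
    genes are dropped and values stored as log2(TPM+1) unless the input
    is already on that scale (``log_transformed``).
    """
    report = IngestReport(seed=seed)
    expr = expression_tpm.copy()
    if gene_whitelist is not None:
        expr = expr[[g for g in expr.columns if g in set(gene_whitelist)]]
    vals = expr.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative TPM values in the expression input")
    report.n_samples_in = len(expr)
    report.n_genes_in = expr.shape[1]

    parsed = {bc: parse_barcode(bc) for bc in expr.index}
    cancer_map = _cancer_of(meta, parsed)
    ann = pd.DataFrame(
        {"patient_id": [parsed[bc][0] for bc in expr.index],
         "group": [parsed[bc][2] for bc in expr.index],
         "cancer_type": [cancer_map[bc] for bc in expr.index]},
        index=expr.index)

    # seeded dedup: one sample per (patient, group, cancer)
    rng = np.random.default_rng(seed)
    keep = []
    for _, members in sorted(
            ann.groupby(["patient_id", "group", "cancer_type"]).groups.items()):
        candidates = sorted(members)
        keep.append(candidates[int(rng.integers(len(candidates)))])
    keep = sorted(keep)
    report.n_duplicates_removed = len(expr) - len(keep)
    expr = expr.loc[keep]
    ann = ann.loc[keep]

    zero = (expr.to_numpy() == 0).all(axis=0)
    report.n_zero_genes_removed = int(zero.sum())
    expr = expr.loc[:, ~zero]
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("empty expression matrix after dedup/zero-gene filters")
    if not log_transformed:
        expr = np.log2(expr + 1.0)

    clinical = _clinical_table(meta)
    metrics = {}
    if tmb is not None:
        metrics["TMB"] = tmb.astype(float)
    if msi is not None:
        metrics["MSI"] = msi.astype(float)

    methylation = pd.DataFrame()
    if methylation_beta is not None:
        if probe_annotation is None:
            raise ValueError("methylation betas require a probe annotation table")
        report.n_probes_in = len(methylation_beta)
        methylation = aggregate_promoter_methylation(methylation_beta,
                                                     probe_annotation)
        ann_idx = probe_annotation.set_index("probe_id") \
            if "probe_id" in probe_annotation.columns else probe_annotation
        kept = ((ann_idx["region"] == "TSS1500")
                & (ann_idx["island_status"] == "island"))
        report.n_promoter_probes_kept = int(
            kept.loc[kept.index.intersection(methylation_beta.index)].sum())

    cohort = Cohort(
        expression=expr, annotations=ann, clinical=clinical, metrics=metrics,
        immune_ratio=immune_ratio if immune_ratio is not None else pd.DataFrame(),
        immune_score=immune_score if immune_score is not None else pd.DataFrame(),
        methylation=methylation,
        families=families or {}, catalogs=catalogs or {})
    return cohort, report


def _cancer_of(meta: pd.DataFrame, parsed: dict) -> dict:
    """Map each barcode to its cancer code via barcode or patient rows."""
    out = {}
    meta_idx = meta.index.astype(str)
    by_patient = {}
    if "cancer_type" not in meta.columns:
        raise ValueError("meta table must carry a cancer_type column")
    for key, cancer in zip(meta_idx, meta["cancer_type"]):
        by_patient.setdefault(key, cancer)
    for bc, (patient, _, _) in parsed.items():
        if bc in by_patient:
            out[bc] = by_patient[bc]
        elif patient in by_patient:
            out[bc] = by_patient[patient]
        else:
            raise ValueError(f"no meta row for sample {bc} (patient {patient})")
    return out


_STAGE_MAP = {"I": "I", "II": "II", "III": "III", "IV": "IV"}


def normalize_stage(raw) -> str:
    """Collapse AJCC stage strings to I/II/III/IV or 'missing'.

    Sub-stages (IA, IIB, ...) collapse to the main stage; 'Stage X' and
    anything unrecognized become missing.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "missing"
    s = str(raw).strip().upper().removeprefix("STAGE").strip()
    s = s.rstrip("ABC")
    return _STAGE_MAP.get(s, "missing")


def _clinical_table(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-patient clinical table with normalized stage and explicit missing."""
    cols = {}
    idx = meta.index.astype(str)
    patients = [("-".join(i.split("-")[:3]) if len(i.split("-")) >= 4 else i)
                for i in idx]
    out = pd.DataFrame(index=pd.Index(patients, name="patient_id"))
    for col in ("age", "os_time", "os_event"):
        if col in meta.columns:
            cols[col] = pd.to_numeric(meta[col], errors="coerce").to_numpy()
    if "gender" in meta.columns:
        cols["gender"] = [str(g).lower() if str(g).lower() in ("male", "female")
                          else "missing" for g in meta["gender"]]
    if "stage" in meta.columns:
        cols["stage"] = [normalize_stage(s) for s in meta["stage"]]
    for name, values in cols.items():
        out[name] = values
    out = out[~out.index.duplicated(keep="first")]
    if "os_event" in out.columns:
        bad = out["os_event"].dropna()
        if not bad.isin([0, 1]).all():
            raise ValueError("os_event must be 0 (censored) or 1 (death)")
    if "os_time" in out.columns and (out["os_time"].dropna() < 0).any():
        raise ValueError("os_time must be nonnegative")
    return out


# ---------------------------------------------------------------------------
# directory bundle round-trip
# ---------------------------------------------------------------------------

_EXPR_FILE = "expression.tsv"


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_cohort(cohort: Cohort, path, seed: int | None = None) -> Path:
    """Serialize a cohort to a plain-text directory bundle with manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {}

    def write(name, frame, index_label):
        f = path / name
        # default float repr is shortest-round-trip: the bundle reloads
        # bit-for-bit
        frame.to_csv(f, sep="\t", index_label=index_label)
        files[name] = _checksum(f)

    write(_EXPR_FILE, cohort.expression, "sample_id")
    meta = cohort.annotations.merge(cohort.clinical, left_on="patient_id",
                                    right_index=True, how="left")
    meta.index = cohort.annotations.index
    write("meta.tsv", meta, "sample_id")
    for name, fname in (("TMB", "tmb.tsv"), ("MSI", "msi.tsv")):
        if name in cohort.metrics:
            write(fname, cohort.metrics[name].to_frame(name), "sample_id")
    if len(cohort.immune_ratio):
        write("immune_ratio.tsv", cohort.immune_ratio, "sample_id")
    if len(cohort.immune_score):
        write("immune_score.tsv", cohort.immune_score, "sample_id")
    if len(cohort.methylation):
        write("promoter_methylation.tsv", cohort.methylation, "gene")
    if cohort.families:
        (path / "families.yaml").write_text(
            yaml.safe_dump({k: list(v) for k, v in cohort.families.items()}))
        files["families.yaml"] = _checksum(path / "families.yaml")
    if cohort.catalogs:
        catdir = path / "catalogs"
        catdir.mkdir(exist_ok=True)
        for cat_name, catalog in cohort.catalogs.items():
            f = catdir / f"{cat_name}.gmt"
            lines = [f"{s}\tna\t" + "\t".join(genes)
                     for s, genes in catalog.items()]
            f.write_text("\n".join(lines) + "\n")
            files[f"catalogs/{cat_name}.gmt"] = _checksum(f)
    manifest = {"format": "pancankit-cohort/1", "seed": seed, "files": files}
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return path


def load_cohort(path) -> Cohort:
    """Load a cohort bundle written by :func:`save_cohort`."""
    path = Path(path)
    expr = pd.read_csv(path / _EXPR_FILE, sep="\t", index_col=0)
    meta = pd.read_csv(path / "meta.tsv", sep="\t", index_col=0)
    ann = meta[["patient_id", "group", "cancer_type"]]
    clin_cols = [c for c in ("age", "gender", "stage", "os_time", "os_event")
                 if c in meta.columns]
    clinical = meta.set_index("patient_id")[clin_cols]
    clinical = clinical[~clinical.index.duplicated(keep="first")]
    metrics = {}
    for name, fname in (("TMB", "tmb.tsv"), ("MSI", "msi.tsv")):
        f = path / fname
        if f.exists():
            metrics[name] = pd.read_csv(f, sep="\t", index_col=0)[name]

    def read_opt(fname):
        f = path / fname
        return pd.read_csv(f, sep="\t", index_col=0) if f.exists() else pd.DataFrame()

    families = {}
    fam_file = path / "families.yaml"
    if fam_file.exists():
        families = yaml.safe_load(fam_file.read_text())
    catalogs = {}
    catdir = path / "catalogs"
    if catdir.is_dir():
        for f in sorted(catdir.glob("*.gmt")):
            catalogs[f.stem] = read_gmt(f)
    return Cohort(
        expression=expr, annotations=ann, clinical=clinical, metrics=metrics,
        immune_ratio=read_opt("immune_ratio.tsv"),
        immune_score=read_opt("immune_score.tsv"),
        methylation=read_opt("promoter_methylation.tsv"),
        families=families, catalogs=catalogs)
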