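"""End-to-end orchestration: files in, models and outlier report out.

Stages: read coding sequences and annotation tracks, tabulate filtered
mutation counts, assemble the complete-case feature matrix, fit the
type-specific and pan-mutation regressions, standardize residuals and
call positive outliers.  Every stage consumes and produces plain TSV /
FASTA / BED / JSON files so the stages are independently scriptable,
and a run manifest records the seed and configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import codon, covariates, models, mutations, outliers

logger = logging.getLogger(__name__)


@dataclass
class InputPaths:
    fasta: str
    mutations: str
    expression: str
    covariates: str
    genes_bed: str
    reptime_bed: str
    fit_exclusion_lists: list[str] = field(default_factory=list)
    ts_list: str | None = None
    og_list: str | None = None


@dataclass
class ModelSettings:
    p_enter: float = 0.05
    p_remove: float = 0.10
    silent_as_density: bool = False  # divide observed silent counts by CDS length
    log_pseudocount: float = 0.0
    candidates: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class OutlierSettings:
    alpha: float = 0.05
    studentized: bool = False
    two_sided: bool = False  # flags use one-sided positive Z by default


@dataclass
class PipelineConfig:
    inputs: InputPaths
    output_dir: str
    seed: int = 0
    model: ModelSettings = field(default_factory=ModelSettings)
    outliers: OutlierSettings = field(default_factory=OutlierSettings)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        known = {"inputs", "output_dir", "seed", "model", "outliers"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(klass, section):
            data = dict(raw.get(section, {}) or {})
            names = {f.name for f in dataclasses.fields(klass)}
            bad = set(data) - names
            if bad:
                raise ValueError(f"unknown keys in {section!r}: {sorted(bad)}")
            return klass(**data)

        if "inputs" not in raw:
            raise ValueError("config requires an 'inputs' section")
        if "output_dir" not in raw:
            raise ValueError("config requires 'output_dir'")
        return cls(
            inputs=build(InputPaths, "inputs"),
            output_dir=str(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            model=build(ModelSettings, "model"),
            outliers=build(OutlierSettings, "outliers"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        """Hash of inputs and settings; the output destination is excluded
        so reruns into different directories are recognizably the same run."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_inputs(config: PipelineConfig, min_overlap: int = 2) -> list[str]:
    """Check file existence, required columns, and gene-id overlap.

    Returns a list of failure messages (empty when everything is
    consistent); never modifies the inputs.
    """
    failures: list[str] = []
    ip = config.inputs
    paths = {
        "fasta": ip.fasta,
        "mutations": ip.mutations,
        "expression": ip.expression,
        "covariates": ip.covariates,
        "genes_bed": ip.genes_bed,
        "reptime_bed": ip.reptime_bed,
        **{f"exclusion[{i}]": p for i, p in enumerate(ip.fit_exclusion_lists)},
    }
    if ip.ts_list:
        paths["ts_list"] = ip.ts_list
    if ip.og_list:
        paths["og_list"] = ip.og_list
    for name, p in paths.items():
        if not Path(p).exists():
            failures.append(f"{name}: missing file {p}")
    if failures:
        return failures

    cols = mutations.COSMIC_PROFILE
    header = pd.read_csv(ip.mutations, sep="\t", nrows=0).columns
    for c in (cols.gene, cols.sample, cols.description, cols.snp, cols.screen):
        if c not in header:
            failures.append(f"mutations: missing mapped column {c!r}")

    cov_header = pd.read_csv(ip.covariates, sep="\t", nrows=0).columns
    for c in (
        "n_orthologs",
        "n_unique_snps",
        "chromatin_accessibility",
        "mutsig_expr",
        "mutsig_hic",
        "mutsig_reptime",
    ):
        if c not in cov_header:
            failures.append(f"covariates: missing column {c!r}")

    fasta_genes = set(codon.read_cds_fasta(ip.fasta))
    mut_genes = set(
        pd.read_csv(ip.mutations, sep="\t", usecols=[cols.gene], dtype=str)[cols.gene]
    )
    overlap = fasta_genes & mut_genes
    if len(overlap) < min_overlap:
        failures.append(
            f"gene-id overlap between FASTA ({len(fasta_genes)}) and mutation "
            f"table ({len(mut_genes)}) is {len(overlap)} < {min_overlap}"
        )
    return failures


@dataclass
class PipelineResult:
    features: covariates.FeatureMatrix
    counts: mutations.MutationCountTable
    models: dict[str, models.FittedModel]
    report: outliers.OutlierReport
    pan_vs_specific: pd.DataFrame
    group_summary: list | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute features -> counts -> fits -> outliers and write artifacts."""
    failures = validate_inputs(config)
    if failures:
        raise RuntimeError("input validation failed: " + "; ".join(failures))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ip = config.inputs

    # --- stage: sequences and counts
    sequences = codon.read_cds_fasta(ip.fasta)
    seq_feats = codon.sequence_features(sequences.values())
    records = mutations.filter_records(mutations.read_mutation_tsv(ip.mutations))
    count_table = mutations.count_by_gene(records, sequences.keys())

    # --- stage: covariates and feature matrix
    expr = pd.read_csv(ip.expression, sep="\t", index_col=0)
    cov = pd.read_csv(ip.covariates, sep="\t", index_col=0)
    intervals = covariates.read_gene_intervals(ip.genes_bed)
    track = covariates.ProbeTrack.from_bed(ip.reptime_bed)
    replication = covariates.assign_track_to_genes(track, intervals)

    exclusions: list[str] = []
    for p in ip.fit_exclusion_lists:
        exclusions.extend(covariates.read_exclusion_list(p))

    silent = count_table.counts["n_silent"]
    if config.model.silent_as_density:
        silent = silent / seq_feats["cds_length"].reindex(silent.index)
    fm = covariates.build_feature_matrix(
        seq_feats,
        cov["n_orthologs"],
        cov["n_unique_snps"],
        expr,
        replication,
        cov["chromatin_accessibility"],
        mutsig=cov[["mutsig_expr", "mutsig_hic", "mutsig_reptime"]],
        silent_counts=silent,
        pseudocount=config.model.log_pseudocount,
        fit_exclusions=exclusions,
    )

    # --- stage: models
    counts_fit = count_table.counts.loc[fm.fitting.index]
    fits = models.fit_all_outcomes(
        fm.fitting,
        counts_fit,
        candidates=config.model.candidates or None,
        p_enter=config.model.p_enter,
        p_remove=config.model.p_remove,
    )
    pan_cmp = models.compare_pan_vs_specific(
        fm.fitting,
        counts_fit,
        candidates=config.model.candidates or None,
        p_enter=config.model.p_enter,
        p_remove=config.model.p_remove,
    )

    # --- stage: outliers (all complete genes are scored, including any
    # excluded from fitting)
    z = outliers.zscore_table(
        fits, fm.scoring, count_table.counts, studentized=config.outliers.studentized
    )
    n_tests = len(fm.fitting)
    cutoff = outliers.significance_cutoff(config.outliers.alpha, n_tests)
    if config.outliers.two_sided:
        flag_z = z.abs()
    else:
        flag_z = z
    report = outliers.call_outliers(
        flag_z, cutoff, alpha=config.outliers.alpha, n_tests=n_tests
    )

    group_summary = None
    annotations: dict[str, str] = {}
    if ip.ts_list:
        annotations.update({g: "TS" for g in covariates.read_exclusion_list(ip.ts_list)})
    if ip.og_list:
        annotations.update({g: "OG" for g in covariates.read_exclusion_list(ip.og_list)})
    if annotations:
        group_summary = outliers.group_zscore_summary(z, annotations)

    _write_artifacts(config, out_dir, fm, count_table, seq_feats, fits, pan_cmp, report,
                     group_summary)
    return PipelineResult(
        features=fm,
        counts=count_table,
        models=fits,
        report=report,
        pan_vs_specific=pan_cmp,
        group_summary=group_summary,
    )


def _write_artifacts(config, out_dir, fm, count_table, seq_feats, fits, pan_cmp,
                     report, group_summary) -> None:
    fm.scoring.to_csv(out_dir / "features.tsv", sep="\t")
    fm.drop_log.to_csv(out_dir / "feature_drop_log.tsv", sep="\t", index=False)
    mutations.write_count_table(
        count_table, seq_feats["cds_length"], out_dir / "counts.tsv"
    )
    for name, model in fits.items():
        model.to_json(out_dir / f"model_{name}.json")
        model.report_frame().to_csv(
            out_dir / f"model_report_{name}.tsv", sep="\t", index=False
        )
    pan_cmp.to_csv(out_dir / "pan_vs_specific.tsv", sep="\t", index=False)
    report.table.to_csv(out_dir / "outliers.tsv", sep="\t")
    report.negative.to_csv(out_dir / "negative_outliers.tsv", sep="\t")

    # moving-average curve of gene size vs per-type counts, for plotting
    merged = fm.scoring.join(count_table.counts)
    for col in ("n_missense", "n_nonsense", "n_fs"):
        window = min(100, max(2, len(merged) // 2))
        curve = outliers.moving_average_curve(
            merged["cds_length"], merged[col], window=window
        )
        curve.to_csv(out_dir / f"curve_size_vs_{col}.tsv", sep="\t", index=False)

    if group_summary is not None:
        pd.DataFrame([dataclasses.asdict(s) for s in group_summary]).to_csv(
            out_dir / "group_zscores.tsv", sep="\t", index=False
        )
    manifest = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "cutoff": report.cutoff,
        "n_tests": report.n_tests,
        "n_flagged": len(report.flagged_genes),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
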