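"""Somatic mutation record ingestion, filtering and per-gene tabulation.

Records arrive pre-classified (COSMIC-style export: gene symbol, sample
id, mutation description, SNP flag, screen type).  Two filters define the
analysis set: only mutations detected by whole-genome screens are kept,
so every gene is interrogated uniformly, and mutations reported as
germline SNPs are excluded.  Retained records are tallied per gene into
missense / nonsense / frameshift / silent counts, and densities
(mutations per nucleotide of coding sequence) are derived from the CDS
lengths.  Duplicate reports of the same allele count as distinct
occurrences: the tallies measure mutation reports, not unique alleles.
"""

from __future__ import annotations

import enum
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class MutationClass(enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SILENT = "silent"
    FRAMESHIFT_INS = "frameshift_ins"
    FRAMESHIFT_DEL = "frameshift_del"
    OTHER = "other"


@dataclass(frozen=True)
class MutationRecord:
    gene_id: str
    sample_id: str
    mut_class: MutationClass
    is_reported_snp: bool = False
    genome_wide_screen: bool = True


#: COSMIC "Mutation Description" strings -> class.  In-frame indels and
#: anything unrecognized map to OTHER and never enter the modeled counts.
COSMIC_DESCRIPTION_MAP: Mapping[str, MutationClass] = {
    "substitution - missense": MutationClass.MISSENSE,
    "substitution - nonsense": MutationClass.NONSENSE,
    "substitution - coding silent": MutationClass.SILENT,
    "insertion - frameshift": MutationClass.FRAMESHIFT_INS,
    "deletion - frameshift": MutationClass.FRAMESHIFT_DEL,
}


def classify_description(description: str) -> MutationClass:
    return COSMIC_DESCRIPTION_MAP.get(description.strip().lower(), MutationClass.OTHER)


@dataclass(frozen=True)
class MutationTableColumns:
    """Column mapping from a source TSV to MutationRecord fields."""

    gene: str = "Gene name"
    sample: str = "Sample name"
    description: str = "Mutation Description"
    snp: str = "SNP"
    screen: str = "Genome-wide screen"
    snp_true_values: tuple[str, ...] = ("y", "yes", "true", "1")
    screen_true_values: tuple[str, ...] = ("y", "yes", "true", "1")


COSMIC_PROFILE = MutationTableColumns()


def read_mutation_tsv(
    path: str | Path, columns: MutationTableColumns = COSMIC_PROFILE
) -> list[MutationRecord]:
    """Read mutation records from a (possibly gzipped) TSV export."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    missing = [
        c
        for c in (columns.gene, columns.sample, columns.description, columns.snp, columns.screen)
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"{path}: missing mapped columns {missing}")
    snp_true = {v.lower() for v in columns.snp_true_values}
    screen_true = {v.lower() for v in columns.screen_true_values}
    return [
        MutationRecord(
            gene_id=g,
            sample_id=s,
            mut_class=classify_description(d),
            is_reported_snp=snp.strip().lower() in snp_true,
            genome_wide_screen=scr.strip().lower() in screen_true,
        )
        for g, s, d, snp, scr in zip(
            df[columns.gene],
            df[columns.sample],
            df[columns.description],
            df[columns.snp],
            df[columns.screen],
        )
    ]


def filter_records(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Keep whole-genome-screen records that are not reported SNPs."""
    kept = [r for r in records if r.genome_wide_screen and not r.is_reported_snp]
    logger.info(
        "mutation filter: %d in, %d retained, %d removed",
        len(records),
        len(kept),
        len(records) - len(kept),
    )
    return kept


COUNT_COLUMNS = ["n_missense", "n_nonsense", "n_fs", "n_silent"]
_CLASS_TO_COLUMN = {
    MutationClass.MISSENSE: "n_missense",
    MutationClass.NONSENSE: "n_nonsense",
    MutationClass.FRAMESHIFT_INS: "n_fs",
    MutationClass.FRAMESHIFT_DEL: "n_fs",
    MutationClass.SILENT: "n_silent",
}


@dataclass
class MutationCountTable:
    """Per-gene mutation counts and densities.

    ``counts`` is indexed by gene_id with integer columns n_missense,
    n_nonsense, n_fs, n_silent.  ``densities(cds_lengths)`` divides each
    count by the gene's coding length (per-nucleotide scale; multiply by
    1000 for the per-kb scale used in reports).
    """

    counts: pd.DataFrame
    n_dropped_unknown_gene: int = 0

    def densities(self, cds_lengths: pd.Series) -> pd.DataFrame:
        lengths = cds_lengths.reindex(self.counts.index)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()].tolist()
            raise ValueError(f"no CDS length for genes {missing[:5]}...")
        dens = self.counts.div(lengths, axis=0)
        dens.columns = [c.replace("n_", "density_") for c in self.counts.columns]
        return dens


def count_by_gene(
    records: Iterable[MutationRecord], gene_ids: Iterable[str]
) -> MutationCountTable:
    """Tally filtered records per gene and class over a known gene set.

    Genes with no records get all-zero rows; records for unknown genes are
    dropped (their number is logged and recorded on the returned table).
    OTHER-class records are ignored in the tallies.
    """
    index = pd.Index(sorted(set(gene_ids)), name="gene_id")
    counts = pd.DataFrame(0, index=index, columns=COUNT_COLUMNS, dtype=np.int64)
    known = set(index)
    dropped = 0
    for rec in records:
        if rec.gene_id not in known:
            dropped += 1
            continue
        col = _CLASS_TO_COLUMN.get(rec.mut_class)
        if col is not None:
            counts.at[rec.gene_id, col] += 1
    if dropped:
        logger.info("count_by_gene: dropped %d records with unknown gene ids", dropped)
    return MutationCountTable(counts=counts, n_dropped_unknown_gene=dropped)


@dataclass(frozen=True)
class GroupDensitySummary:
    group: str
    mut_type: str
    n_genes: int
    mean_per_kb: float
    sem_per_kb: float
    sem_defined: bool = True


def group_density_summary(
    table: MutationCountTable,
    cds_lengths: pd.Series,
    group_labels: Mapping[str, str],
    mut_type: str,
) -> list[GroupDensitySummary]:
    """Mean density ± SEM per gene group, on the per-kb scale.

    ``mut_type`` is one of missense/nonsense/fs/silent.  SEM is the sample
    standard deviation over genes divided by sqrt(n); groups of a single
    gene are flagged as having undefined SEM.
    """
    col = f"density_{mut_type}"
    dens = table.densities(cds_lengths)[col] * 1000.0
    labels = pd.Series(group_labels).reindex(dens.index)
    out = []
    for group, values in dens.groupby(labels):
        n = len(values)
        sem_ok = n >= 2
        sem = float(values.std(ddof=1) / np.sqrt(n)) if sem_ok else float("nan")
        out.append(
            GroupDensitySummary(
                group=str(group),
                mut_type=mut_type,
                n_genes=n,
                mean_per_kb=float(values.mean()),
                sem_per_kb=sem,
                sem_defined=sem_ok,
            )
        )
    return out


def write_count_table(
    table: MutationCountTable, cds_lengths: pd.Series, path: str | Path
) -> None:
    """Write the per-gene count/density TSV."""
    out = table.counts.join(table.densities(cds_lengths))
    out.to_csv(path, sep="\t")
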