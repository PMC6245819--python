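"""Join per-gene annotation tracks with sequence features into one matrix.

The regression models consume a complete-case feature matrix per gene:
sequence-derived characteristics (from :mod:`mutburden.codon`), mean
expression across cancer cell lines, relative replication time (negative
early, positive late), chromatin accessibility, germline SNP density,
ortholog-based conservation, observed silent-mutation counts, and three
passthrough covariates on the MutsigCV scale ("expr", "hic", "reptime").

Probe tracks (replication timing, chromatin) are assigned to genes by
averaging the probes inside the gene interval, falling back to the
nearest probe when a gene contains none.  Gene intervals are 0-based
half-open internally (BED native); GFF-style 1-based closed coordinates
are converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: columns every complete modeling record must have
FEATURE_COLUMNS = [
    "cds_length",
    "n_potential_missense",
    "n_potential_nonsense",
    "n_potential_silent",
    "pct_a",
    "pct_c",
    "pct_g",
    "pct_t",
    "pct_cpg",
    "nd",
    "conservation_index",
    "snp_density",
    "mean_expression",
    "log_mean_expression",
    "replication_time",
    "chromatin_accessibility",
    "n_silent_observed",
    "mutsig_expr",
    "mutsig_hic",
    "mutsig_reptime",
]


@dataclass
class ProbeTrack:
    """Genomic probe measurements: per-chromosome sorted positions/values."""

    positions: dict[str, np.ndarray]
    values: dict[str, np.ndarray]

    @classmethod
    def from_bed(cls, path: str | Path) -> "ProbeTrack":
        """Read a 4-column BED/bedGraph (chrom, start, end, value).

        The probe position is the interval midpoint.
        """
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "value"],
            comment="#",
        )
        df["pos"] = (df["start"] + df["end"]) // 2
        df = df.sort_values(["chrom", "pos"], kind="mergesort")
        positions, values = {}, {}
        for chrom, sub in df.groupby("chrom", sort=False):
            positions[str(chrom)] = sub["pos"].to_numpy(dtype=np.int64)
            values[str(chrom)] = sub["value"].to_numpy(dtype=float)
        return cls(positions=positions, values=values)


def read_gene_intervals(path: str | Path, one_based_closed: bool = False) -> pd.DataFrame:
    """Read gene intervals from BED (default) or 1-based closed coordinates.

    Returns a frame indexed by gene_id with chrom/start/end, half-open
    0-based.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"],
        comment="#",
    )
    if one_based_closed:
        df["start"] = df["start"] - 1
    return df.set_index("gene_id")


def assign_track_to_genes(track: ProbeTrack, genes: pd.DataFrame) -> pd.Series:
    """Per-gene track value: mean of in-gene probes, else nearest probe.

    Distance for the fallback is measured from the probe to the closer
    interval edge; exact ties go to the lower-coordinate probe.  A gene on
    a chromosome absent from the track raises ``KeyError`` naming it.
    """
    out = {}
    for gene_id, row in genes.iterrows():
        chrom = str(row["chrom"])
        if chrom not in track.positions:
            raise KeyError(f"gene {gene_id}: chromosome {chrom!r} absent from track")
        pos = track.positions[chrom]
        val = track.values[chrom]
        lo = np.searchsorted(pos, row["start"], side="left")
        hi = np.searchsorted(pos, row["end"], side="left")  # end excluded
        if hi > lo:
            out[gene_id] = float(val[lo:hi].mean())
            continue
        # nearest probe: candidates are the flanking probes at lo-1 and lo
        best_val, best_dist = None, None
        for i in (lo - 1, lo):
            if 0 <= i < len(pos):
                if pos[i] < row["start"]:
                    dist = row["start"] - pos[i]
                elif pos[i] >= row["end"]:
                    dist = pos[i] - (row["end"] - 1)
                else:  # pragma: no cover - in-gene probes handled above
                    dist = 0
                # strict < keeps the lower-coordinate probe on exact ties
                if best_dist is None or dist < best_dist:
                    best_val, best_dist = float(val[i]), dist
        out[gene_id] = best_val
    return pd.Series(out, name="track_value")


def aggregate_expression(
    matrix: pd.DataFrame, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Mean expression per gene across cell lines, plus log10(mean + pc).

    ``matrix`` is genes x cell lines.  Rows that are entirely missing are
    excluded (logged).  With the default pseudocount 0, genes whose mean
    is 0 get ``-inf`` log expression and are later dropped as incomplete.
    """
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        logger.info(
            "aggregate_expression: excluding %d genes with no expression values",
            int(all_missing.sum()),
        )
    mat = matrix.loc[~all_missing]
    mean = mat.mean(axis=1, skipna=True)
    with np.errstate(divide="ignore"):
        log_mean = np.log10(mean + pseudocount)
    out = pd.DataFrame(
        {"mean_expression": mean, "log_mean_expression": log_mean}
    )
    out.index.name = "gene_id"
    return out


def snp_density(n_unique_snps: int | np.ndarray, cds_length: int | np.ndarray):
    """Unique SNPs per nucleotide of coding sequence."""
    n = np.asarray(n_unique_snps, dtype=float)
    length = np.asarray(cds_length, dtype=float)
    if (n < 0).any():
        raise ValueError("SNP count cannot be negative")
    if (length <= 0).any():
        raise ValueError("cds_length must be positive")
    out = n / length
    return float(out) if out.ndim == 0 else out


@dataclass
class FeatureMatrix:
    """Complete-case feature matrix with a fitting/scoring split.

    ``scoring`` holds every gene with complete data; ``fit_mask`` marks
    the rows admitted to model fitting (genes on exclusion lists are
    scored but not fitted).  ``drop_log`` records (gene_id, reason) for
    every gene that fell out of the assembly.
    """

    scoring: pd.DataFrame
    fit_mask: pd.Series
    drop_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "reason"])
    )

    @property
    def fitting(self) -> pd.DataFrame:
        return self.scoring.loc[self.fit_mask]


def assemble_features(
    sources: Mapping[str, pd.DataFrame | pd.Series],
    fit_exclusions: Iterable[str] = (),
) -> FeatureMatrix:
    """Inner-join per-gene sources into one complete-case matrix.

    Each source is a frame or series indexed by gene_id; overlapping
    column names are not allowed.  Genes missing from any source, or with
    any NaN/inf cell, are dropped with a reason.  ``fit_exclusions`` are
    removed from the fitting subset only — they remain scored.
    """
    frames = []
    for name, src in sources.items():
        df = src.to_frame() if isinstance(src, pd.Series) else src
        frames.append((name, df))
    common = frames[0][1].index
    for _, df in frames[1:]:
        common = common.intersection(df.index)
    if len(common) == 0:
        raise ValueError("no genes shared by all feature sources")

    drops: list[tuple[str, str]] = []
    for name, df in frames:
        for g in df.index.difference(common):
            drops.append((g, f"absent from some source (present in {name})"))

    merged = pd.concat([df.loc[common] for _, df in frames], axis=1)
    finite = merged.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(finite).all(axis=1)
    for g in merged.index[bad]:
        cols = finite.columns[~np.isfinite(finite.loc[g])].tolist()
        drops.append((g, f"missing/non-finite: {cols}"))
    complete = merged.loc[~bad].sort_index()
    complete.index.name = "gene_id"

    excluded = set(fit_exclusions)
    fit_mask = pd.Series(
        [g not in excluded for g in complete.index], index=complete.index, name="fit"
    )
    drop_log = pd.DataFrame(sorted(set(drops)), columns=["gene_id", "reason"])
    if len(drop_log):
        logger.info(
            "assemble_features: %d genes complete, %d dropped",
            len(complete),
            drop_log["gene_id"].nunique(),
        )
    return FeatureMatrix(scoring=complete, fit_mask=fit_mask, drop_log=drop_log)


def pairwise_spearman(
    features: pd.DataFrame, columns: Sequence[str] | None = None, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlations between feature columns.

    Returns (rho, p, significant) square frames; the diagonal of rho is
    1.0.  Constant columns yield NaN rho for their pairs (flagged
    non-significant).
    """
    cols = list(columns) if columns is not None else list(features.columns)
    if len(features) < 3:
        raise ValueError("need at least 3 complete rows")
    sub = features[cols]
    rho, p = stats.spearmanr(sub.to_numpy(), axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the two-column case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    np.fill_diagonal(rho, 1.0)
    constant = sub.nunique().to_numpy() <= 1
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    sig = (p_df < alpha) & rho_df.notna()
    return rho_df, p_df, sig


def build_feature_matrix(
    seq_features: pd.DataFrame,
    n_orthologs: pd.Series,
    n_unique_snps: pd.Series,
    expression_matrix: pd.DataFrame,
    replication_time: pd.Series,
    chromatin_accessibility: pd.Series,
    mutsig: pd.DataFrame,
    silent_counts: pd.Series | None = None,
    pseudocount: float = 0.0,
    fit_exclusions: Iterable[str] = (),
) -> FeatureMatrix:
    """Assemble the full per-gene predictor matrix from its raw pieces.

    This is the one authoritative join used both by the file-based
    pipeline and by the synthetic generator, so an exported cohort
    re-imported from disk reproduces the in-memory matrix exactly.
    ``silent_counts`` may be omitted while observed counts do not exist
    yet (the generator's first pass).
    """
    from .codon import conservation_index as _ci

    cons = pd.Series(
        [_ci(int(v)).index for v in n_orthologs],
        index=n_orthologs.index,
        name="conservation_index",
        dtype=np.int64,
    )
    lengths = seq_features["cds_length"]
    snps = n_unique_snps.reindex(lengths.index).dropna()
    dens = pd.Series(
        snp_density(snps.to_numpy(), lengths.loc[snps.index].to_numpy()),
        index=snps.index,
        name="snp_density",
    )
    sources: dict[str, pd.DataFrame | pd.Series] = {
        "sequence": seq_features,
        "conservation": cons,
        "snp": dens,
        "expression": aggregate_expression(expression_matrix, pseudocount),
        "replication": replication_time.rename("replication_time"),
        "chromatin": chromatin_accessibility.rename("chromatin_accessibility"),
    }
    if silent_counts is not None:
        sources["silent"] = silent_counts.rename("n_silent_observed")
    sources["mutsig"] = mutsig[["mutsig_expr", "mutsig_hic", "mutsig_reptime"]]
    return assemble_features(sources, fit_exclusions=fit_exclusions)


def read_exclusion_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
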