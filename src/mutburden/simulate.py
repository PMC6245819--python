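"""Fully synthetic cohorts with a known background model and drivers.

The generator emulates the statistical structure of a pan-cancer
mutation-burden study: per-gene coding sequences with controllable
length and nucleotide composition, inter-correlated gene
characteristics, and per-gene mutation counts whose expectations are
linear in the characteristics, with Poisson noise and a multiplicative
excess injected for a designated driver subset.

Structure of one cohort
-----------------------
* CDS lengths are log-normal; each sequence is ATG + composition-driven
  internal codons (stop codons rejected) + one stop codon.
* Non-sequence covariates (expression, replication time, chromatin,
  SNP density, ortholog counts) and a latent per-gene mutability factor
  come from a Gaussian copula correlated with log CDS length, then are
  mapped to their marginal scales.
* For each mutation type t the expectation is
  ``lambda_t(g) = max(0, a_t + b_t * u_t(g))`` where ``u_t`` is a
  standardized linear combination of characteristics (plus, optionally,
  the latent mutability factor) and ``b_t`` is calibrated so that an
  OLS fit on the characteristics attains a configured target R^2:
  ``b_t = sqrt(a_t * R2 / (1 - R2))`` (Poisson residual variance is
  approximately the mean count ``a_t``).
* Driver genes multiply ``lambda`` by ``(1 + delta_t)`` for their
  designated types; silent counts are always generated driver-free.

Every stochastic draw derives from one integer seed through
``numpy.random.SeedSequence`` spawning, so each stage is independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import codon, covariates, mutations

logger = logging.getLogger(__name__)

MUTATION_TYPES = ("missense", "nonsense", "frameshift", "silent")

# copula dimensions, in order
_COPULA_VARS = (
    "log_length",
    "expression",
    "replication",
    "chromatin",
    "snp_density",
    "orthologs",
    "mutability",
)

#: default latent correlation structure: big genes are conserved and
#: slightly SNP-poor; expressed genes replicate early in open chromatin;
#: the latent mutability factor tracks late replication and low expression.
DEFAULT_COPULA_CORR = np.array(
    [
        # loglen  expr    rt    chrom   snpd   orth    h
        [1.00, -0.10, -0.05, 0.00, -0.10, 0.27, 0.00],
        [-0.10, 1.00, -0.20, 0.20, 0.00, 0.00, -0.30],
        [-0.05, -0.20, 1.00, 0.18, 0.00, 0.00, 0.30],
        [0.00, 0.20, 0.18, 1.00, 0.00, 0.00, -0.15],
        [-0.10, 0.00, 0.00, 0.00, 1.00, 0.00, 0.00],
        [0.27, 0.00, 0.00, 0.00, 0.00, 1.00, 0.00],
        [0.00, -0.30, 0.30, -0.15, 0.00, 0.00, 1.00],
    ]
)


@dataclass
class BackgroundSpec:
    """Background mutation-count model for one mutation type.

    Either give ``weights`` (direction over standardized feature columns,
    optionally with ``latent_weight`` on the unobserved mutability
    factor) together with ``mean_count`` and ``target_r2`` — the
    coefficient scale is then calibrated to the target — or give
    ``raw_beta``/``raw_intercept`` to fix raw-scale coefficients
    directly.
    """

    mean_count: float
    target_r2: float = 0.0
    weights: dict[str, float] = field(default_factory=dict)
    latent_weight: float = 0.0
    raw_beta: dict[str, float] | None = None
    raw_intercept: float | None = None


@dataclass
class DriverSpec:
    """Injected driver genes: TS-like get an excess of all three types,
    OG-like an excess of missense only."""

    n_ts: int = 10
    n_og: int = 10
    delta_missense: float = 2.0
    delta_nonsense: float = 2.5
    delta_fs: float = 3.0


def _default_backgrounds() -> dict[str, BackgroundSpec]:
    # mean counts per gene follow a large pan-cancer cohort's totals over
    # ~15,610 genes: 2,233,115 missense / 163,823 nonsense / 85,272 FS
    return {
        "missense": BackgroundSpec(
            mean_count=143.0,
            target_r2=0.88,
            weights={
                "n_potential_missense": 0.45,
                "replication_time": 0.20,
                "log_mean_expression": -0.20,
                "pct_cpg": 0.15,
            },
            latent_weight=0.60,
        ),
        "nonsense": BackgroundSpec(
            mean_count=10.5,
            target_r2=0.40,
            weights={
                "n_potential_nonsense": 0.80,
                "pct_a": 0.30,
                "replication_time": 0.15,
            },
            latent_weight=0.30,
        ),
        "frameshift": BackgroundSpec(
            mean_count=5.5,
            target_r2=0.23,
            weights={"cds_length": 0.80, "nd": -0.50},
            latent_weight=0.20,
        ),
        "silent": BackgroundSpec(
            mean_count=55.0,
            target_r2=0.80,
            weights={
                "n_potential_silent": 0.40,
                "replication_time": 0.20,
                "log_mean_expression": -0.20,
            },
            latent_weight=0.80,
        ),
    }


def _feature_only_backgrounds(
    targets: Sequence[float] = (0.88, 0.40, 0.23)
) -> dict[str, BackgroundSpec]:
    r2_mis, r2_non, r2_fs = targets
    return {
        "missense": BackgroundSpec(
            mean_count=143.0,
            target_r2=r2_mis,
            weights={
                "n_potential_missense": 0.75,
                "replication_time": 0.35,
                "log_mean_expression": -0.35,
                "pct_cpg": 0.25,
            },
        ),
        "nonsense": BackgroundSpec(
            mean_count=10.5,
            target_r2=r2_non,
            weights={
                "n_potential_nonsense": 0.80,
                "pct_a": 0.40,
                "replication_time": 0.30,
            },
        ),
        "frameshift": BackgroundSpec(
            mean_count=5.5,
            target_r2=r2_fs,
            weights={"cds_length": 0.80, "nd": -0.50},
        ),
        "silent": BackgroundSpec(
            mean_count=55.0,
            target_r2=0.80,
            weights={
                "n_potential_silent": 0.60,
                "replication_time": 0.30,
                "log_mean_expression": -0.30,
            },
        ),
    }


@dataclass
class SimulationConfig:
    """Everything that determines a synthetic cohort, seed included."""

    n_genes: int = 15000
    seed: int = 0
    cds_log_mean_nt: float = 7.2  # ln scale; median CDS ~1340 nt
    cds_log_sd_nt: float = 0.55
    min_codons: int = 40
    composition_mean: tuple[float, float, float, float] = (0.25, 0.26, 0.27, 0.22)
    composition_concentration: float = 60.0
    n_cell_lines: int = 25
    copula_corr: np.ndarray = field(default_factory=lambda: DEFAULT_COPULA_CORR.copy())
    backgrounds: dict[str, BackgroundSpec] = field(default_factory=_default_backgrounds)
    drivers: DriverSpec = field(default_factory=DriverSpec)

    def __post_init__(self) -> None:
        corr = np.asarray(self.copula_corr, dtype=float)
        if corr.shape != (len(_COPULA_VARS),) * 2:
            raise ValueError(f"copula correlation must be {len(_COPULA_VARS)}x{len(_COPULA_VARS)}")
        if not np.allclose(corr, corr.T):
            raise ValueError("copula correlation must be symmetric")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("copula correlation is not positive semi-definite")
        self.copula_corr = corr
        missing = set(MUTATION_TYPES) - set(self.backgrounds)
        if missing:
            raise ValueError(f"backgrounds missing for {sorted(missing)}")
        for spec in self.backgrounds.values():
            if spec.mean_count < 0:
                raise ValueError("mean_count must be non-negative")

    @classmethod
    def default(cls, seed: int = 0, n_genes: int = 15000) -> "SimulationConfig":
        """The standard study-conditions cohort: correlated covariates, a
        shared latent mutability factor (so observed silent counts are an
        informative predictor), and 20 injected drivers."""
        return cls(n_genes=n_genes, seed=seed)

    @classmethod
    def feature_only(
        cls,
        seed: int = 0,
        n_genes: int = 15000,
        targets: Sequence[float] = (0.88, 0.40, 0.23),
    ) -> "SimulationConfig":
        """A cohort whose count expectations are linear in the *observed*
        characteristics only (no latent factor, no drivers), so the
        generating coefficients are exactly recoverable by regression."""
        return cls(
            n_genes=n_genes,
            seed=seed,
            backgrounds=_feature_only_backgrounds(targets),
            drivers=DriverSpec(n_ts=0, n_og=0),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["copula_corr"] = self.copula_corr.tolist()
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SyntheticCohort:
    """A generated cohort plus its generating truth.

    Truth columns (per-gene lambdas, driver labels, raw-scale
    coefficients, the latent mutability factor) never appear in the
    exported analysis inputs — they are written to separate
    ``truth_*`` files.
    """

    config: SimulationConfig
    sequences: dict[str, codon.CodingSequence]
    features: pd.DataFrame
    counts: mutations.MutationCountTable
    expression_matrix: pd.DataFrame
    covariate_table: pd.DataFrame  # n_orthologs, n_unique_snps, chromatin, mutsig_*
    replication_time: pd.Series
    gene_intervals: pd.DataFrame
    truth_lambda: pd.DataFrame
    truth_beta: pd.DataFrame
    truth_drivers: pd.DataFrame
    truth_latent: pd.Series

    @property
    def driver_genes(self) -> list[str]:
        return self.truth_drivers.index.tolist()


# ---------------------------------------------------------------------------
# coding sequences

_STOP_TRIPLES = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA as base4 digits
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_cds(
    n_codons: int,
    composition_target: Sequence[float],
    rng: np.random.Generator,
    gene_id: str = "gene",
) -> codon.CodingSequence:
    """ATG + (n_codons - 2) stop-free composition-driven codons + stop."""
    if n_codons < 2:
        raise ValueError("need at least 2 codons (start + stop)")
    p = np.asarray(composition_target, dtype=float)
    p = p / p.sum()
    body = _sample_codon_digits(n_codons - 2, p, rng)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    seq = "ATG" + _digits_to_str(body) + stop
    return codon.CodingSequence(gene_id=gene_id, sequence=seq)


def _sample_codon_digits(n: int, p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(n, 3) base-index codons sampled base-wise from p, stops rejected."""
    p_stop = p[3] * p[0] * (p[0] + p[2]) + p[3] * p[2] * p[0]
    if 1.0 - p_stop <= 0:
        raise ValueError("composition admits only stop codons; rejection impossible")
    cum = np.cumsum(p)
    digits = np.searchsorted(cum, rng.random((n, 3)), side="right")
    for _ in range(200):
        is_stop = (
            (digits[:, 0] == 3)
            & (
                ((digits[:, 1] == 0) & ((digits[:, 2] == 0) | (digits[:, 2] == 2)))
                | ((digits[:, 1] == 2) & (digits[:, 2] == 0))
            )
        )
        k = int(is_stop.sum())
        if k == 0:
            return digits
        digits[is_stop] = np.searchsorted(cum, rng.random((k, 3)), side="right")
    raise RuntimeError("stop-codon rejection did not converge")


def _digits_to_str(digits: np.ndarray) -> str:
    return _BASE_BYTES[digits.ravel()].tobytes().decode()


# ---------------------------------------------------------------------------
# cohort generation


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    m, s = float(x.mean()), float(x.std())
    if s == 0:
        raise ValueError("constant column cannot be standardized")
    return (x - m) / s, m, s


def _lambda_for_type(
    spec: BackgroundSpec, X: pd.DataFrame, h: np.ndarray
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-gene expectation and the raw-scale generating coefficients."""
    if spec.raw_beta is not None:
        lam = np.full(len(X), float(spec.raw_intercept or 0.0))
        beta = {"intercept": float(spec.raw_intercept or 0.0)}
        for col, b in spec.raw_beta.items():
            lam = lam + b * X[col].to_numpy(dtype=float)
            beta[col] = float(b)
        return np.clip(lam, 0.0, None), beta

    a = spec.mean_count
    if not spec.weights and spec.latent_weight == 0:
        return np.full(len(X), a), {"intercept": a}
    v = np.zeros(len(X))
    parts: dict[str, tuple[float, float]] = {}  # col -> (w/s, m)
    for col, w in spec.weights.items():
        xs, m, s = _standardize(X[col].to_numpy(dtype=float))
        v = v + w * xs
        parts[col] = (w / s, m)
    if spec.latent_weight:
        v = v + spec.latent_weight * h
    u, mv, sv = _standardize(v)
    r2 = spec.target_r2
    b = float(np.sqrt(a * r2 / (1.0 - r2))) if r2 > 0 else 0.0
    lam = a + b * u
    beta = {"intercept": a - (b / sv) * mv - sum((b / sv) * ws * m for ws, m in parts.values())}
    for col, (ws, _) in parts.items():
        beta[col] = (b / sv) * ws
    if spec.latent_weight:
        beta["latent_mutability"] = (b / sv) * spec.latent_weight
    n_clipped = int((lam < 0).sum())
    if n_clipped:
        logger.info("lambda clipped at zero for %d genes", n_clipped)
    return np.clip(lam, 0.0, None), beta


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from the configuration."""
    ss = np.random.SeedSequence(config.seed)
    (
        rng_len,
        rng_comp,
        rng_seq,
        rng_copula,
        rng_expr,
        rng_snp,
        rng_mutsig,
        rng_counts,
        rng_drivers,
    ) = [np.random.default_rng(s) for s in ss.spawn(9)]

    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]

    # latent copula draws
    chol = np.linalg.cholesky(
        config.copula_corr + 1e-12 * np.eye(len(_COPULA_VARS))
    )
    Z = rng_copula.standard_normal((n, len(_COPULA_VARS))) @ chol.T
    z = {name: Z[:, i] for i, name in enumerate(_COPULA_VARS)}

    # CDS lengths correlated with the copula's log-length coordinate
    log_len = config.cds_log_mean_nt + config.cds_log_sd_nt * z["log_length"]
    n_codons = np.maximum(config.min_codons, np.round(np.exp(log_len) / 3)).astype(int)

    alpha = np.asarray(config.composition_mean) * config.composition_concentration
    compositions = rng_comp.dirichlet(alpha, size=n)

    sequences = {
        gid: generate_cds(int(nc), comp, rng_seq, gene_id=gid)
        for gid, nc, comp in zip(gene_ids, n_codons, compositions)
    }
    seq_feats = codon.sequence_features(sequences.values())
    lengths = seq_feats["cds_length"]

    # expression matrix: gene-level log-normal mean, cell-line noise
    gene_mean = np.exp(3.5 + 1.2 * z["expression"])
    noise = rng_expr.normal(0.0, 0.3, size=(n, config.n_cell_lines))
    expr = pd.DataFrame(
        gene_mean[:, None] * np.exp(noise - 0.045),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"cl{j:03d}" for j in range(config.n_cell_lines)],
    )

    replication = pd.Series(z["replication"], index=gene_ids, name="replication_time")
    chromatin = pd.Series(
        np.exp(0.8 + 0.4 * z["chromatin"]), index=gene_ids, name="chromatin_accessibility"
    )
    snp_rate = 0.005 * np.exp(0.3 * z["snp_density"])
    n_snps = pd.Series(
        rng_snp.poisson(snp_rate * lengths.to_numpy()), index=gene_ids, name="n_unique_snps"
    )
    n_orth = pd.Series(
        stats.binom.ppf(stats.norm.cdf(z["orthologs"]), 20, 0.7).astype(int),
        index=gene_ids,
        name="n_orthologs",
    )
    h = z["mutability"]

    # first-pass features (no silent counts yet) for the count model
    fm0 = covariates.build_feature_matrix(
        seq_feats,
        n_orth,
        n_snps,
        expr,
        replication,
        chromatin,
        mutsig=pd.DataFrame(
            {
                "mutsig_expr": np.log10(gene_mean) + 0.3 * rng_mutsig.standard_normal(n),
                "mutsig_hic": np.log(chromatin.to_numpy())
                + 0.3 * rng_mutsig.standard_normal(n),
                "mutsig_reptime": replication.to_numpy()
                + 0.3 * rng_mutsig.standard_normal(n),
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
    )
    X0 = fm0.scoring
    mutsig_df = X0[["mutsig_expr", "mutsig_hic", "mutsig_reptime"]].copy()
    h_series = pd.Series(h, index=gene_ids, name="latent_mutability").loc[X0.index]

    # driver designation
    perm = rng_drivers.permutation(np.asarray(X0.index))
    ts = list(perm[: config.drivers.n_ts])
    og = list(perm[config.drivers.n_ts : config.drivers.n_ts + config.drivers.n_og])
    drivers = pd.DataFrame(
        {"kind": ["TS"] * len(ts) + ["OG"] * len(og)},
        index=pd.Index(ts + og, name="gene_id"),
    )
    delta = {
        "missense": config.drivers.delta_missense,
        "nonsense": config.drivers.delta_nonsense,
        "frameshift": config.drivers.delta_fs,
        "silent": 0.0,  # silent mutations are background by construction
    }
    og_types = {"missense"}

    lam_cols, beta_cols, count_cols = {}, {}, {}
    for t in MUTATION_TYPES:
        lam, beta = _lambda_for_type(
            config.backgrounds[t], X0, h_series.to_numpy()
        )
        lam = pd.Series(lam, index=X0.index)
        if t != "silent":
            boost = np.ones(len(lam))
            for g, kind in drivers["kind"].items():
                if kind == "TS" or (kind == "OG" and t in og_types):
                    boost[lam.index.get_loc(g)] += delta[t]
            lam = lam * boost
        lam_cols[f"lambda_{t}"] = lam
        beta_cols[t] = beta
        count_cols[t] = rng_counts.poisson(lam.to_numpy())
        if float(lam.sum()) == 0:
            logger.warning("all-zero lambda for %s: degenerate cohort", t)

    counts_df = pd.DataFrame(
        {
            "n_missense": count_cols["missense"],
            "n_nonsense": count_cols["nonsense"],
            "n_fs": count_cols["frameshift"],
            "n_silent": count_cols["silent"],
        },
        index=X0.index,
    )
    count_table = mutations.MutationCountTable(counts=counts_df)

    # final features, now with observed silent counts
    fm = covariates.build_feature_matrix(
        seq_feats,
        n_orth,
        n_snps,
        expr,
        replication,
        chromatin,
        mutsig=mutsig_df,
        silent_counts=counts_df["n_silent"],
    )

    truth_beta = pd.DataFrame(beta_cols).fillna(0.0)
    truth_beta.index.name = "predictor"

    covariate_table = pd.DataFrame(
        {
            "n_orthologs": n_orth,
            "n_unique_snps": n_snps,
            "chromatin_accessibility": chromatin,
            "mutsig_expr": mutsig_df["mutsig_expr"].reindex(gene_ids),
            "mutsig_hic": mutsig_df["mutsig_hic"].reindex(gene_ids),
            "mutsig_reptime": mutsig_df["mutsig_reptime"].reindex(gene_ids),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # synthetic genomic placement: genes laid end to end on one contig
    starts = np.concatenate([[0], np.cumsum(lengths.reindex(gene_ids).to_numpy() + 1000)[:-1]])
    intervals = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + lengths.reindex(gene_ids).to_numpy(),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    return SyntheticCohort(
        config=config,
        sequences=sequences,
        features=fm.scoring,
        counts=count_table,
        expression_matrix=expr,
        covariate_table=covariate_table,
        replication_time=replication,
        gene_intervals=intervals,
        truth_lambda=pd.DataFrame(lam_cols),
        truth_beta=truth_beta,
        truth_drivers=drivers,
        truth_latent=h_series,
    )


# ---------------------------------------------------------------------------
# export


def export_cohort(
    cohort: SyntheticCohort,
    directory: str | Path,
    contaminant_fraction: float = 0.01,
) -> dict[str, Path]:
    """Write a cohort as the exact file set the pipeline consumes.

    Analysis inputs: ``cds.fasta``, ``mutations.tsv`` (record-level,
    COSMIC-style, including a small admixture of SNP-flagged and
    targeted-screen contaminant records that the filters must remove),
    ``expression.tsv``, ``covariates.tsv``, ``genes.bed``,
    ``reptime.bed``.  Ground truth goes to ``truth_*.tsv`` files and the
    seed/config hash to ``manifest.json``; pipeline loaders never read
    ``truth_*`` or ``manifest`` files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = directory / "cds.fasta"
    with open(fasta, "w") as fh:
        for gid, cds in cohort.sequences.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(cds.sequence), 80):
                fh.write(cds.sequence[i : i + 80] + "\n")
    paths["fasta"] = fasta

    paths["mutations"] = directory / "mutations.tsv"
    _write_mutation_records(cohort, paths["mutations"], contaminant_fraction)

    paths["expression"] = directory / "expression.tsv"
    cohort.expression_matrix.to_csv(paths["expression"], sep="\t")

    paths["covariates"] = directory / "covariates.tsv"
    cohort.covariate_table.to_csv(paths["covariates"], sep="\t")

    paths["genes_bed"] = directory / "genes.bed"
    iv = cohort.gene_intervals
    pd.DataFrame(
        {"chrom": iv["chrom"], "start": iv["start"], "end": iv["end"], "gene": iv.index}
    ).to_csv(paths["genes_bed"], sep="\t", header=False, index=False)

    # one replication probe at each gene midpoint carrying the gene value
    paths["reptime_bed"] = directory / "reptime.bed"
    mid = (iv["start"] + iv["end"]) // 2
    pd.DataFrame(
        {
            "chrom": iv["chrom"],
            "start": mid,
            "end": mid + 1,
            "value": cohort.replication_time.reindex(iv.index),
        }
    ).to_csv(paths["reptime_bed"], sep="\t", header=False, index=False)

    paths["truth_lambda"] = directory / "truth_lambda.tsv"
    cohort.truth_lambda.to_csv(paths["truth_lambda"], sep="\t")
    paths["truth_beta"] = directory / "truth_beta.tsv"
    cohort.truth_beta.to_csv(paths["truth_beta"], sep="\t")
    paths["truth_drivers"] = directory / "truth_drivers.tsv"
    cohort.truth_drivers.to_csv(paths["truth_drivers"], sep="\t")
    paths["truth_latent"] = directory / "truth_latent.tsv"
    cohort.truth_latent.to_frame().to_csv(paths["truth_latent"], sep="\t")

    manifest = {
        "seed": cohort.config.seed,
        "n_genes": cohort.config.n_genes,
        "config_hash": cohort.config.content_hash(),
    }
    paths["manifest"] = directory / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths


_DESCRIPTIONS = {
    "n_missense": ["Substitution - Missense"],
    "n_nonsense": ["Substitution - Nonsense"],
    "n_silent": ["Substitution - coding silent"],
    "n_fs": ["Insertion - Frameshift", "Deletion - Frameshift"],
}


def _write_mutation_records(
    cohort: SyntheticCohort, path: Path, contaminant_fraction: float
) -> None:
    rng = np.random.default_rng(
        np.random.SeedSequence([cohort.config.seed, 0xE0F])
    )
    genes, descs = [], []
    for col, names in _DESCRIPTIONS.items():
        cts = cohort.counts.counts[col]
        for gid, k in cts[cts > 0].items():
            genes.extend([gid] * int(k))
            if len(names) == 1:
                descs.extend(names * int(k))
            else:  # frameshifts split between insertions and deletions
                picks = rng.integers(0, 2, size=int(k))
                descs.extend([names[p] for p in picks])
    n = len(genes)
    df = pd.DataFrame(
        {
            "Gene name": genes,
            "Sample name": [f"S{int(s):05d}" for s in rng.integers(0, 19147, size=n)],
            "Mutation Description": descs,
            "SNP": ["n"] * n,
            "Genome-wide screen": ["y"] * n,
        }
    )
    n_cont = int(round(contaminant_fraction * n))
    if n_cont:
        idx = rng.integers(0, n, size=n_cont)
        cont = df.iloc[idx].copy().reset_index(drop=True)
        half = n_cont // 2
        cont.loc[: half - 1, "SNP"] = "y"  # germline-lookalike reports
        cont.loc[half:, "Genome-wide screen"] = "n"  # targeted-screen reports
        df = pd.concat([df, cont], ignore_index=True)
    df = df.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(
        drop=True
    )
    df.to_csv(path, sep="\t", index=False)
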