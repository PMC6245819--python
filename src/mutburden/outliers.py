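"""Residual Z-scores, multiplicity-corrected cutoff, and outlier calls.

A gene's involvement in cancer shows up as an excess of observed
mutations over the background model's prediction.  Residuals are
standardized by the model's root-mean-square residual into Z-scores,
separately for missense, nonsense and frameshift mutations.  Because
each gene is tested three times (once per type) and n genes are tested,
the significance threshold for the per-type Z is

    cutoff = Phi^-1( (1 - alpha/n)^(1/3) )

i.e. a Bonferroni correction over genes combined with a max-of-three
correction over mutation types (assuming independence of the three
scores).  At alpha = 0.05 and n = 15,610 genes this is 4.74.  Genes
whose Z strictly exceeds the cutoff for at least one type are positive
outliers — candidate cancer-associated genes.  Negative outliers
(mutation deficits) are reported separately for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import FittedModel, predict_expected

logger = logging.getLogger(__name__)

Z_COLUMNS = {"missense": "z_missense", "nonsense": "z_nonsense", "frameshift": "z_fs"}


def residual_zscores(
    observed: pd.Series, predicted: pd.Series, residual_sd: float
) -> pd.Series:
    """(observed - predicted) / residual_sd, aligned on the gene index."""
    if not residual_sd > 0:
        raise ValueError("residual_sd must be positive")
    pred = predicted.loc[observed.index]
    return (observed.astype(float) - pred) / residual_sd


def significance_cutoff(alpha: float, n_tests: int) -> float:
    """Standard-normal quantile of the cube root of (1 - alpha/n_tests)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not alpha / n_tests < 1:
        raise ValueError("alpha/n_tests must be < 1")
    return float(stats.norm.ppf((1.0 - alpha / n_tests) ** (1.0 / 3.0)))


@dataclass
class OutlierReport:
    """Per-gene Z-scores and outlier flags for the three mutation types.

    ``table`` is sorted by max_z descending with columns z_missense,
    z_nonsense, z_fs, max_z, flags (comma-joined types whose Z strictly
    exceeds the cutoff) and n_flags.  ``negative`` lists genes whose
    minimum Z falls below -cutoff (mutation deficits).
    """

    table: pd.DataFrame
    cutoff: float
    alpha: float
    n_tests: int
    negative: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def flagged_genes(self) -> list[str]:
        return self.table.index[self.table["n_flags"] > 0].tolist()


def call_outliers(
    z_table: pd.DataFrame, cutoff: float, alpha: float = 0.05, n_tests: int | None = None
) -> OutlierReport:
    """Flag positive outliers (Z strictly above the cutoff) per type.

    ``z_table`` must carry columns z_missense, z_nonsense, z_fs.  The
    report is sorted by the per-gene maximum Z, descending.
    """
    cols = list(Z_COLUMNS.values())
    missing = [c for c in cols if c not in z_table.columns]
    if missing:
        raise ValueError(f"z_table lacks columns {missing}")
    tab = z_table[cols].astype(float).copy()
    tab["max_z"] = tab[cols].max(axis=1)
    flag_names = {"z_missense": "missense", "z_nonsense": "nonsense", "z_fs": "frameshift"}
    exceed = tab[cols].gt(cutoff)
    tab["flags"] = exceed.apply(
        lambda row: ",".join(flag_names[c] for c in cols if row[c]), axis=1
    )
    tab["n_flags"] = exceed.sum(axis=1)
    tab = tab.sort_values("max_z", ascending=False, kind="mergesort")
    neg = tab[tab[cols].min(axis=1) < -cutoff].copy()
    neg["min_z"] = neg[cols].min(axis=1)
    neg = neg.sort_values("min_z", kind="mergesort")[cols + ["min_z"]]
    return OutlierReport(
        table=tab,
        cutoff=cutoff,
        alpha=alpha,
        n_tests=n_tests if n_tests is not None else len(z_table),
        negative=neg,
    )


def zscore_table(
    models: Mapping[str, FittedModel],
    features: pd.DataFrame,
    counts: pd.DataFrame,
    studentized: bool = False,
) -> pd.DataFrame:
    """Z-scores for the three mutation types over the scoring matrix.

    With ``studentized=True`` the residual scale is inflated by
    1/sqrt(1 - p/n), the average-leverage adjustment; per-gene leverages
    are not tracked outside the fitting set.
    """
    col = {"missense": "n_missense", "nonsense": "n_nonsense", "frameshift": "n_fs"}
    out = {}
    for t, zcol in Z_COLUMNS.items():
        model = models[t]
        pred = predict_expected(model, features)
        scale = model.residual_sd
        if studentized:
            p = len(model.selected_predictors) + 1
            scale = scale / np.sqrt(max(1e-12, 1.0 - p / model.n_genes_fit))
        out[zcol] = residual_zscores(counts[col[t]].loc[features.index], pred, scale)
    return pd.DataFrame(out, index=features.index)


@dataclass(frozen=True)
class GroupZSummary:
    group: str
    mut_type: str
    n_genes: int
    mean_z: float
    sem_z: float
    sem_defined: bool
    p_vs_reference: float


def group_zscore_summary(
    z_table: pd.DataFrame,
    annotations: Mapping[str, str],
    reference: str = "other",
) -> list[GroupZSummary]:
    """Mean Z ± SEM per annotated group and mutation type.

    ``annotations`` maps gene -> group label (e.g. TS / OG); unannotated
    genes fall into the reference group.  Each non-reference group is
    compared with the reference by a two-sided Welch t-test.
    """
    labels = pd.Series(
        [annotations.get(g, reference) for g in z_table.index], index=z_table.index
    )
    out = []
    for zcol, t in [("z_missense", "missense"), ("z_nonsense", "nonsense"), ("z_fs", "frameshift")]:
        ref_vals = z_table.loc[labels == reference, zcol].to_numpy()
        for group in sorted(labels.unique()):
            vals = z_table.loc[labels == group, zcol].to_numpy()
            n = len(vals)
            if n == 0:
                raise ValueError(f"group {group!r} is empty")
            sem_ok = n >= 2
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if sem_ok else float("nan")
            if group == reference or not sem_ok or len(ref_vals) < 2:
                p = float("nan")
            else:
                p = float(stats.ttest_ind(vals, ref_vals, equal_var=False).pvalue)
            out.append(
                GroupZSummary(
                    group=str(group),
                    mut_type=t,
                    n_genes=n,
                    mean_z=float(vals.mean()),
                    sem_z=sem,
                    sem_defined=sem_ok,
                    p_vs_reference=p,
                )
            )
    return out


def moving_average_curve(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    window: int = 100,
    step: int = 1,
) -> pd.DataFrame:
    """Moving-average smoothing over genes ranked by x.

    Genes are sorted ascending by x; a window of ``window`` genes slides
    in steps of ``step`` genes, and the arithmetic means of x and y in
    each window form one curve point.  Output has n - window + 1 rows at
    step 1.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > xv.size:
        raise ValueError("window exceeds the number of genes")
    order = np.argsort(xv, kind="mergesort")
    xs, ys = xv[order], yv[order]
    cx = np.concatenate([[0.0], np.cumsum(xs)])
    cy = np.concatenate([[0.0], np.cumsum(ys)])
    starts = np.arange(0, xs.size - window + 1, step)
    mean_x = (cx[starts + window] - cx[starts]) / window
    mean_y = (cy[starts + window] - cy[starts]) / window
    return pd.DataFrame({"mean_x": mean_x, "mean_y": mean_y})


def null_familywise_rate(
    n_genes: int,
    alpha: float = 0.05,
    n_replicates: int = 1000,
    rng: np.random.Generator | None = None,
    n_types: int = 3,
) -> float:
    """Monte-Carlo family-wise false-flag rate of the cutoff under the null.

    Draws Z ~ N(0,1) for every gene and mutation type, applies the
    multiplicity-corrected cutoff, and returns the fraction of replicate
    cohorts with at least one flagged gene.  Under the formula this
    converges to 1 - (1 - alpha/n)^n ~ alpha.
    """
    rng = rng if rng is not None else np.random.default_rng()
    cutoff = significance_cutoff(alpha, n_genes)
    hits = 0
    for _ in range(n_replicates):
        z = rng.standard_normal((n_genes, n_types))
        if (z > cutoff).any():
            hits += 1
    return hits / n_replicates
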