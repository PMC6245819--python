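"""Univariate screening and stepwise multiple linear regression.

Per-gene mutation counts (missense, nonsense, frameshift, and their
"pan" sum) are modeled by ordinary least squares on gene
characteristics.  Because the characteristics are strongly
inter-correlated, the multivariate fit uses stepwise selection: forward
entry of the most significant remaining candidate (p < p_enter) with
backward elimination of any included predictor whose partial p-value
rises above p_remove.  An exhaustive best-subset mode (BIC-minimizing)
is available for small candidate sets as a sensitivity check.

Counts are modeled on the raw scale; predictions may therefore be
negative and are deliberately not clipped, so that residuals stay
centered for the downstream Z-score outlier analysis.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: default candidate predictors per outcome.  The per-type differences
#: reflect which characteristics showed a usable (significant, linear)
#: univariate association with each mutation type.
DEFAULT_CANDIDATES: dict[str, list[str]] = {
    "missense": [
        "snp_density",
        "conservation_index",
        "log_mean_expression",
        "cds_length",
        "nd",
        "n_potential_missense",
        "n_silent_observed",
        "pct_c",
        "pct_g",
        "pct_t",
        "pct_cpg",
        "replication_time",
        "chromatin_accessibility",
        "mutsig_expr",
        "mutsig_hic",
        "mutsig_reptime",
    ],
    "nonsense": [
        "conservation_index",
        "log_mean_expression",
        "cds_length",
        "nd",
        "n_potential_nonsense",
        "n_silent_observed",
        "pct_a",
        "pct_c",
        "pct_g",
        "pct_t",
        "pct_cpg",
        "replication_time",
        "chromatin_accessibility",
        "mutsig_expr",
        "mutsig_hic",
        "mutsig_reptime",
    ],
    "frameshift": [
        "snp_density",
        "cds_length",
        "nd",
        "n_potential_missense",
        "n_silent_observed",
        "pct_a",
        "pct_g",
        "pct_cpg",
        "mutsig_expr",
        "mutsig_hic",
        "mutsig_reptime",
    ],
    "pan": [
        "snp_density",
        "conservation_index",
        "log_mean_expression",
        "cds_length",
        "nd",
        "n_potential_missense",
        "n_silent_observed",
        "pct_a",
        "pct_c",
        "pct_g",
        "pct_t",
        "pct_cpg",
        "replication_time",
        "chromatin_accessibility",
        "mutsig_expr",
        "mutsig_hic",
        "mutsig_reptime",
    ],
}


@dataclass
class FittedModel:
    """A fitted per-gene mutation-count regression.

    ``residual_sd`` is the root-mean-square residual on the fitting set —
    the scale used to standardize residuals into Z-scores downstream.
    ``standardized_beta`` of predictor j is coef_j * sd(x_j) / sd(y).
    """

    outcome: str
    selected_predictors: list[str]
    intercept: float
    coefficients: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    standardized_beta: dict[str, float]
    residual_sd: float
    r2: float
    n_genes_fit: int

    def predict(self, features: pd.DataFrame) -> pd.Series:
        return predict_expected(self, features)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, default=float)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))

    def report_frame(self) -> pd.DataFrame:
        """Model report in the conventional layout: predictor, t, p, beta."""
        rows = [
            (p, self.t_values[p], self.p_values[p], self.standardized_beta[p])
            for p in self.selected_predictors
        ]
        df = pd.DataFrame(rows, columns=["predictor", "t", "p", "beta"])
        return df.reindex(df["t"].abs().sort_values(ascending=False).index).reset_index(
            drop=True
        )


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def univariate_screen(
    features: pd.DataFrame, outcome: pd.Series, predictors: Sequence[str] | None = None
) -> pd.DataFrame:
    """One simple linear regression per predictor.

    Returns a frame (predictor, t, p, beta, r2) sorted by |t| descending.
    Constant predictors are skipped with a warning.
    """
    preds = list(predictors) if predictors is not None else list(features.columns)
    if len(features) < 3:
        raise ValueError("need at least 3 rows")
    y = outcome.loc[features.index].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")
    sd_y = y.std()
    rows = []
    for name in preds:
        x = features[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("univariate_screen: predictor %s is constant, skipped", name)
            continue
        res = _ols(y, features[[name]])
        beta = float(res.params[name]) * x.std() / sd_y
        rows.append(
            (name, float(res.tvalues[name]), float(res.pvalues[name]), beta,
             float(res.rsquared))
        )
    df = pd.DataFrame(rows, columns=["predictor", "t", "p", "beta", "r2"])
    return df.reindex(df["t"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


def _finalize(outcome: str, y: np.ndarray, X: pd.DataFrame, selected: list[str],
              n: int) -> FittedModel:
    if selected:
        res = _ols(y, X[selected])
        resid = res.resid
        coefs = {p: float(res.params[p]) for p in selected}
        tvals = {p: float(res.tvalues[p]) for p in selected}
        pvals = {p: float(res.pvalues[p]) for p in selected}
        sd_y = y.std()
        betas = {p: coefs[p] * X[p].to_numpy().std() / sd_y for p in selected}
        intercept = float(res.params["const"])
        r2 = float(res.rsquared)
    else:
        logger.warning("stepwise_fit(%s): no predictor entered; intercept-only", outcome)
        intercept = float(y.mean())
        resid = y - intercept
        coefs, tvals, pvals, betas = {}, {}, {}, {}
        r2 = 0.0
    residual_sd = float(np.sqrt(np.mean(np.asarray(resid) ** 2)))
    return FittedModel(
        outcome=outcome,
        selected_predictors=list(selected),
        intercept=intercept,
        coefficients=coefs,
        t_values=tvals,
        p_values=pvals,
        standardized_beta=betas,
        residual_sd=residual_sd,
        r2=r2,
        n_genes_fit=n,
    )


def stepwise_fit(
    features: pd.DataFrame,
    outcome: pd.Series,
    candidate_predictors: Sequence[str],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    outcome_name: str = "outcome",
) -> FittedModel:
    """Forward selection with backward elimination on OLS p-values.

    Entry: the candidate with the smallest partial p-value joins if
    p < p_enter (ties broken by smaller p, then alphabetically).
    Removal: any included predictor with p > p_remove leaves, worst
    first.  Deterministic given the input.
    """
    if not p_enter < p_remove:
        raise ValueError("p_enter must be smaller than p_remove")
    candidates = [c for c in candidate_predictors if features[c].nunique() > 1]
    for c in set(candidate_predictors) - set(candidates):
        logger.warning("stepwise_fit: constant candidate %s skipped", c)
    y = outcome.loc[features.index].to_numpy(dtype=float)
    selected: list[str] = []
    while True:
        changed = False
        # forward step
        remaining = [c for c in candidates if c not in selected]
        best: tuple[float, str] | None = None
        for c in sorted(remaining):
            res = _ols(y, features[selected + [c]])
            p = float(res.pvalues[c])
            if np.isnan(p):
                continue  # collinear with current model
            if best is None or (p, c) < best:
                best = (p, c)
        if best is not None and best[0] < p_enter:
            selected.append(best[1])
            changed = True
        # backward steps
        while len(selected) > 0:
            res = _ols(y, features[selected])
            pvals = res.pvalues.drop("const")
            worst = pvals.idxmax()
            if float(pvals[worst]) > p_remove:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return _finalize(outcome_name, y, features, selected, len(features))


def best_subset_fit(
    features: pd.DataFrame,
    outcome: pd.Series,
    candidate_predictors: Sequence[str],
    max_candidates: int = 15,
    outcome_name: str = "outcome",
) -> FittedModel:
    """Exhaustive best-subset OLS minimizing BIC (sensitivity mode)."""
    candidates = list(candidate_predictors)
    if len(candidates) > max_candidates:
        raise ValueError(
            f"{len(candidates)} candidates exceed the exhaustive limit "
            f"{max_candidates}"
        )
    y = outcome.loc[features.index].to_numpy(dtype=float)
    best_bic, best_subset = np.inf, []
    for k in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, k):
            res = _ols(y, features[list(subset)]) if subset else sm.OLS(
                y, np.ones((len(y), 1))
            ).fit()
            if res.bic < best_bic:
                best_bic, best_subset = res.bic, list(subset)
    return _finalize(outcome_name, y, features, best_subset, len(features))


def predict_expected(model: FittedModel, features: pd.DataFrame) -> pd.Series:
    """Expected counts on the raw scale (no clipping; may be negative)."""
    missing = [p for p in model.selected_predictors if p not in features.columns]
    if missing:
        raise KeyError(f"features lack selected predictors {missing}")
    pred = np.full(len(features), model.intercept, dtype=float)
    for p in model.selected_predictors:
        pred += model.coefficients[p] * features[p].to_numpy(dtype=float)
    return pd.Series(pred, index=features.index, name=f"expected_{model.outcome}")


def model_r2(observed: pd.Series | np.ndarray, predicted: pd.Series | np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length, n >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed vector is constant; R^2 undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


OUTCOME_TYPES = ("missense", "nonsense", "frameshift")


def fit_all_outcomes(
    features: pd.DataFrame,
    counts: pd.DataFrame,
    candidates: Mapping[str, Sequence[str]] | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> dict[str, FittedModel]:
    """Fit the three type-specific models plus the pan-mutation model.

    ``counts`` has columns n_missense, n_nonsense, n_fs aligned to the
    feature index; the pan outcome is their per-gene sum.
    """
    cand = dict(DEFAULT_CANDIDATES)
    if candidates:
        cand.update({k: list(v) for k, v in candidates.items()})
    outcomes = {
        "missense": counts["n_missense"],
        "nonsense": counts["n_nonsense"],
        "frameshift": counts["n_fs"],
        "pan": counts["n_missense"] + counts["n_nonsense"] + counts["n_fs"],
    }
    models = {}
    for name, y in outcomes.items():
        models[name] = stepwise_fit(
            features,
            y,
            [c for c in cand[name] if c in features.columns],
            p_enter=p_enter,
            p_remove=p_remove,
            outcome_name=name,
        )
        logger.info(
            "fit %s: %d predictors, R^2=%.3f",
            name,
            len(models[name].selected_predictors),
            models[name].r2,
        )
    return models


def compare_pan_vs_specific(
    features: pd.DataFrame,
    counts: pd.DataFrame,
    candidates: Mapping[str, Sequence[str]] | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> pd.DataFrame:
    """R^2 of the pan-mutation model scored per type vs type-specific fits.

    The specific R^2 is the fit's own coefficient of determination.  The
    pan model predicts the summed count, so its per-type accuracy is the
    squared Pearson correlation between the pan prediction and the
    observed type-specific counts (scale-free; identical to R^2 on the
    fitting set when outcome and prediction share a scale).
    """
    models = fit_all_outcomes(features, counts, candidates, p_enter, p_remove)
    pan_pred = predict_expected(models["pan"], features)
    rows = []
    col = {"missense": "n_missense", "nonsense": "n_nonsense", "frameshift": "n_fs"}
    for t in OUTCOME_TYPES:
        obs = counts[col[t]].loc[features.index].to_numpy(dtype=float)
        r_pan = float(np.corrcoef(pan_pred.to_numpy(), obs)[0, 1]) ** 2
        rows.append((t, models[t].r2, r_pan))
    return pd.DataFrame(rows, columns=["outcome", "r2_specific", "r2_pan"])
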