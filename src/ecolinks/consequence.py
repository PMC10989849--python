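"""Relate quantified association strengths (plus abiotic variables) to
alpha and beta diversity.

Forward-selection ordinary least squares for per-sample diversity, and
per-factor Mantel tests against community dissimilarity for turnover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform

from .data_model import AbundanceTable, DistanceMatrix, ValidationError, to_relative
from .processes import mantel_test

__all__ = [
    "AlphaModelReport",
    "BetaMantelReport",
    "alpha_diversity",
    "forward_select_ols",
    "alpha_contribution",
    "mantel_beta",
]


def alpha_diversity(table: AbundanceTable, metric: str = "richness") -> pd.Series:
    """Per-sample richness (taxa with abundance > 0) or Shannon entropy (nats)."""
    if metric not in ("richness", "shannon"):
        raise ValueError(f"unknown alpha metric {metric!r}")
    values = table.values
    if metric == "richness":
        out = (values > 0).sum(axis=1).astype(float)
    else:
        sums = values.sum(axis=1)
        if (sums == 0).any():
            warnings.warn("all-zero sample(s); Shannon reported as 0", stacklevel=2)
        out = np.zeros(len(sums))
        for i, s in enumerate(sums):
            if s == 0:
                continue
            p = values[i] / s
            p = p[p > 0]
            out[i] = float(-(p * np.log(p)).sum())
    if metric == "richness" and (out == 0).any():
        warnings.warn("all-zero sample(s); richness 0", stacklevel=2)
    return pd.Series(out, index=table.samples, name=metric)


@dataclass
class AlphaModelReport:
    """Forward-selection OLS path and final fit."""

    selected: list
    path_adj_r2: list
    coefficients: pd.DataFrame  # index term; coef, se, p_value
    adj_r2: float
    n: int
    offered: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "path_adj_r2": [float(v) for v in self.path_adj_r2],
            "adj_r2": float(self.adj_r2),
            "n": int(self.n),
            "coefficients": {
                term: {
                    "coef": float(row["coef"]),
                    "se": float(row["se"]),
                    "p_value": float(row["p_value"]),
                }
                for term, row in self.coefficients.iterrows()
            },
        }


def _fit(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    return sm.OLS(y, design).fit()


def forward_select_ols(
    response,
    predictors: pd.DataFrame,
    alpha_enter: float = 0.05,
    min_adj_r2_gain: float = 0.001,
    max_condition: float = 1e10,
) -> AlphaModelReport:
    """Forward selection with a partial-F entry criterion.

    At each step the candidate giving the largest adjusted-R-squared increase
    is entered, provided its partial-F p-value (equivalently the t-test of
    its coefficient in the expanded model) is below ``alpha_enter`` and the
    gain is at least ``min_adj_r2_gain``.  Candidates whose entry makes the
    design matrix condition number exceed ``max_condition`` are skipped with
    a warning.  An empty selection yields an intercept-only report.
    """
    y = np.asarray(response, dtype=float)
    predictors = pd.DataFrame(predictors)
    n, k = len(y), predictors.shape[1]
    if predictors.shape[0] != n:
        raise ValidationError("response and predictors have different lengths")
    if predictors.isna().any().any() or np.isnan(y).any():
        raise ValidationError("missing values in response or predictors")
    if n <= k + 2:
        raise ValidationError(f"need n > n_predictors + 2 (n={n}, predictors={k})")
    selected: list = []
    path: list = []
    current = 0.0  # adjusted R^2 of the intercept-only model
    while True:
        best_name = None
        best_fit = None
        best_adj = current
        for cand in predictors.columns:
            if cand in selected:
                continue
            X = predictors[selected + [cand]]
            design = sm.add_constant(X, has_constant="add")
            if np.linalg.cond(design.to_numpy()) > max_condition:
                warnings.warn(f"predictor {cand!r} skipped: collinear design", stacklevel=2)
                continue
            fit = sm.OLS(y, design).fit()
            p_enter = float(fit.pvalues[cand])
            adj = float(fit.rsquared_adj)
            if p_enter < alpha_enter and adj - current >= min_adj_r2_gain and adj > best_adj:
                best_name, best_fit, best_adj = cand, fit, adj
        if best_name is None:
            break
        selected.append(best_name)
        current = best_adj
        path.append(current)
    final = _fit(y, predictors[selected]) if selected else _fit(y, pd.DataFrame(index=predictors.index))
    coef = pd.DataFrame(
        {"coef": final.params, "se": final.bse, "p_value": final.pvalues}
    )
    adj = float(final.rsquared_adj) if selected else 0.0
    return AlphaModelReport(selected, path, coef, adj, n, offered=list(predictors.columns))


def alpha_contribution(
    response,
    abiotic: pd.DataFrame,
    biotic: pd.DataFrame,
    alpha_enter: float = 0.05,
    **kwargs,
) -> dict:
    """Compare forward-selection fits without and with the biotic factors.

    Returns the two reports plus their final adjusted R-squared values —
    the per-dataset analogue of reporting the gain in explained alpha
    diversity when association strengths join the abiotic predictors.
    """
    without = forward_select_ols(response, abiotic, alpha_enter=alpha_enter, **kwargs)
    combined = pd.concat([abiotic, biotic], axis=1)
    with_b = forward_select_ols(response, combined, alpha_enter=alpha_enter, **kwargs)
    return {
        "without_biotic": without,
        "with_biotic": with_b,
        "adj_r2_without": without.adj_r2,
        "adj_r2_with": with_b.adj_r2,
    }


@dataclass
class BetaMantelReport:
    """Per-factor Mantel statistics against community dissimilarity."""

    table: pd.DataFrame  # index factor; r, p
    community_metric: str
    n_permutations: int


def _factor_to_distance(name, value, samples) -> DistanceMatrix:
    if isinstance(value, DistanceMatrix):
        return value.reorder(samples)
    v = pd.Series(value)
    missing = [s for s in samples if s not in v.index]
    if missing:
        raise ValidationError(f"factor {name!r} missing samples: {missing[:5]}")
    x = v.loc[samples].to_numpy(dtype=float)
    d = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(samples, d)


def mantel_beta(
    table: AbundanceTable,
    factors: dict,
    community_metric: str = "braycurtis",
    n_perm: int = 999,
    seed: int = 0,
) -> BetaMantelReport:
    """Mantel test of each factor against Bray-Curtis community dissimilarity.

    Scalar per-sample factors become absolute-difference (1-D Euclidean)
    distance matrices; precomputed :class:`DistanceMatrix` values are used
    as-is.  Constant factors yield r = 0, p = 1 with a warning.
    """
    if community_metric != "braycurtis":
        raise ValueError(f"unknown community metric {community_metric!r}")
    rel = table if table.is_relative else to_relative(table)
    comm = DistanceMatrix(rel.samples, squareform(pdist(rel.values, metric="braycurtis")))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(len(factors), 1))
    rows = []
    for k, (name, value) in enumerate(factors.items()):
        d = _factor_to_distance(name, value, rel.samples)
        res = mantel_test(comm, d, n_perm=n_perm, seed=children[k])
        rows.append({"factor": name, "r": res.r, "p": res.p})
    df = pd.DataFrame(rows, columns=["factor", "r", "p"]).set_index("factor")
    return BetaMantelReport(df, community_metric, n_perm)
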