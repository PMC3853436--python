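"""SAM-style permutation differential expression and subtype-trend labels.

The per-feature statistic is the moderated mean difference

    d_i = (mean_A - mean_B) / (s_i + s0),

where s_i is the pooled standard error of the mean difference,

    s_i = sqrt((1/n_A + 1/n_B) * pooled within-class variance),

and s0 a small "fudge" constant that stabilises d for low-variance
features (default: the median of the s_i). Significance comes from label
permutations with a pooled null — every feature's permuted d contributes
to one common null distribution, which buys p-value resolution at modest
permutation counts — and Benjamini-Hochberg FDR on the permutation p's.

A feature earns a subtype trend label only under stricter thresholds
(default p < 0.001 and FDR < 0.05) and a strict class-mean inequality;
exact ties in the means yield no trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError, ParameterError
from .io import ExpressionMatrix

__all__ = [
    "DiffExprResult",
    "sam_statistic",
    "permutation_test",
    "select_differential",
    "assign_trend",
]

NO_TREND = "none"


@dataclass
class DiffExprResult:
    """Per-feature d, permutation p, BH FDR, class means and trend label.

    ``table`` columns: feature, d, p_value, fdr, mean_a, mean_b, trend.
    ``class_a``/``class_b`` name the two classes (sorted order).
    """

    table: pd.DataFrame
    class_a: str
    class_b: str
    s0: float
    n_perm: int
    seed: int

    def feature_row(self, feature_id: str) -> pd.Series:
        return self.table.set_index("feature").loc[feature_id]


def _class_split(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    mask_a, mask_b = matrix.class_columns()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise InputError("each class needs at least 2 samples")
    return mask_a, mask_b


def _d_values(values: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray, s0: float):
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    xa, xb = values[:, mask_a], values[:, mask_b]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    ss = ((xa - ma[:, None]) ** 2).sum(axis=1) + ((xb - mb[:, None]) ** 2).sum(axis=1)
    pooled_var = ss / (na + nb - 2)
    s = np.sqrt((1.0 / na + 1.0 / nb) * pooled_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (ma - mb) / (s + s0)
    d = np.where(np.isfinite(d), d, 0.0)  # constant feature with s0 = 0
    return d, s, ma, mb


def sam_statistic(matrix: ExpressionMatrix, s0: float | None = None) -> pd.Series:
    """Per-feature SAM d statistic; s0 defaults to the median of the s_i."""
    mask_a, mask_b = _class_split(matrix)
    if s0 is not None and s0 < 0:
        raise ParameterError("s0 must be >= 0")
    _, s, _, _ = _d_values(matrix.values, mask_a, mask_b, 0.0)
    if s0 is None:
        s0 = float(np.median(s))
    d, _, _, _ = _d_values(matrix.values, mask_a, mask_b, s0)
    return pd.Series(d, index=matrix.feature_ids, name="d")


def permutation_test(
    matrix: ExpressionMatrix,
    n_perm: int = 1000,
    s0: float | None = None,
    seed: int = 0,
) -> DiffExprResult:
    """Pooled-null permutation p-values and BH FDR for every feature."""
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    mask_a, mask_b = _class_split(matrix)
    na = int(mask_a.sum())
    values = matrix.values
    m, n = values.shape

    _, s, _, _ = _d_values(values, mask_a, mask_b, 0.0)
    if s0 is None:
        s0 = float(np.median(s))
    d_obs, _, mean_a, mean_b = _d_values(values, mask_a, mask_b, s0)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, m))
    for b in range(n_perm):
        perm = rng.permutation(n)
        pa = np.zeros(n, dtype=bool)
        pa[perm[:na]] = True
        null[b], _, _, _ = _d_values(values, pa, ~pa, s0)
    pooled = np.sort(np.abs(null).ravel())
    # p = (1 + #{pooled |d*| >= |d|}) / (1 + pooled size)
    ge = pooled.size - np.searchsorted(pooled, np.abs(d_obs), side="left")
    p = (1.0 + ge) / (1.0 + pooled.size)
    fdr = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "feature": matrix.feature_ids,
            "d": d_obs,
            "p_value": p,
            "fdr": fdr,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "trend": NO_TREND,
        }
    )
    class_a, class_b = matrix.classes
    result = DiffExprResult(table=table, class_a=class_a, class_b=class_b,
                            s0=s0, n_perm=n_perm, seed=seed)
    result.table = assign_trend(result).table  # default trend labelling
    return result


def select_differential(result: DiffExprResult, p_max: float = 0.05, fdr_max: float = 0.1) -> list[str]:
    """Features with p < p_max and FDR < fdr_max, input order preserved."""
    t = result.table
    keep = (t["p_value"] < p_max) & (t["fdr"] < fdr_max)
    return t.loc[keep, "feature"].tolist()


def assign_trend(
    result: DiffExprResult, p_max: float = 0.001, fdr_max: float = 0.05
) -> DiffExprResult:
    """Label each significant feature with the class showing the higher mean.

    The label is the class name itself (e.g. ``luminal_A``); exact mean ties
    or non-significance yield ``"none"``. Returns a result with the trend
    column replaced; the input is not mutated.
    """
    t = result.table.copy()
    sig = (t["p_value"] < p_max) & (t["fdr"] < fdr_max)
    trend = np.where(
        sig & (t["mean_a"] > t["mean_b"]), result.class_a,
        np.where(sig & (t["mean_b"] > t["mean_a"]), result.class_b, NO_TREND),
    )
    t["trend"] = trend
    return DiffExprResult(table=t, class_a=result.class_a, class_b=result.class_b,
                          s0=result.s0, n_perm=result.n_perm, seed=result.seed)


def write_result(result: DiffExprResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False, float_format="%.9g")
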