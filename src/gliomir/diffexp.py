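"""Per-platform two-group differential expression.

Each platform is reduced to the contract the cross-grade meta step needs:
per feature, a log2 fold change, its standard error, a standard-normal
score ``z``, a p-value and a BH-adjusted p-value.

The test is a Welch contrast of per-group means on the log2 scale.  The
p-value uses the Student-t reference with Welch-Satterthwaite degrees of
freedom, and ``z`` is the probit (normal-quantile) transform of that
p-value carrying the sign of the fold change.  This makes ``z`` exactly
standard normal under the null whatever the group sizes, which is the
property the downstream z-combination relies on; the raw Welch statistic
(``statistic = logfc / se``) is reported alongside.

Counts are first transformed to log2 counts-per-million with a 0.5
pseudocount (:func:`normalize_counts`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import COUNTS, INTENSITY, ExpressionMatrix, ValidationError

__all__ = ["normalize_counts", "differential_expression", "benjamini_hochberg"]

# p-values are clipped away from 0 so the probit transform stays finite.
_P_MIN = 1e-300


def normalize_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Transform raw counts to log2(CPM + 0.5).

    CPM = 1e6 * count / library size, where the library size is the
    column sum.  The 0.5 pseudocount avoids log of zero.
    """
    if matrix.platform_kind != COUNTS:
        raise ValidationError("normalize_counts expects a counts matrix")
    lib = matrix.values.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValidationError(f"zero library size for sample(s): {zero}")
    cpm = matrix.values * 1e6 / lib
    return ExpressionMatrix(np.log2(cpm + 0.5), INTENSITY)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch(a: np.ndarray, b: np.ndarray, se_floor_frac: float = 0.1):
    """Vectorised Welch contrast, rows = features.

    Returns (logfc, se, df, floored) with logfc = mean(b) - mean(a).
    Features whose pooled SE is zero get the configured floor (a fraction
    of the median positive SE) and are flagged.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sa2, sb2 = va / na, vb / nb
    se2 = sa2 + sb2
    se = np.sqrt(se2)
    floored = se == 0.0
    positive = se[~floored]
    if floored.any():
        if positive.size == 0:
            raise ValidationError("all features have zero variance in both groups")
        se = np.where(floored, se_floor_frac * np.median(positive), se)
        se2 = se**2
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2**2 / (sa2**2 / (na - 1) + sb2**2 / (nb - 1))
    df = np.where(np.isfinite(df), df, na + nb - 2)
    df = np.maximum(df, 1.0)
    return mb - ma, se, df, floored


def differential_expression(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    contrast: tuple[str, str] = ("good", "poor"),
    group_col: str = "group",
    se_floor_frac: float = 0.1,
) -> pd.DataFrame:
    """Per-feature differential expression between two annotated groups.

    ``logfc`` is mean(log2 in ``contrast[1]``) minus mean(log2 in
    ``contrast[0]``); with the default contrast this is poor minus good.
    Counts matrices are normalised internally via :func:`normalize_counts`.

    Returns a DataFrame indexed by feature id with columns
    ``logfc, se, statistic, df, z, p, p_adj, se_floored``.
    """
    if matrix.platform_kind == COUNTS:
        matrix = normalize_counts(matrix)
    group_a, group_b = contrast
    groups = annotation[group_col]
    ids_a = groups.index[groups == group_a].intersection(matrix.sample_ids)
    ids_b = groups.index[groups == group_b].intersection(matrix.sample_ids)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError(
            f"need >=2 samples per group, got {len(ids_a)} {group_a!r} "
            f"and {len(ids_b)} {group_b!r}"
        )
    a = matrix.values[list(ids_a)].to_numpy(dtype=float)
    b = matrix.values[list(ids_b)].to_numpy(dtype=float)
    logfc, se, df, floored = _welch(a, b, se_floor_frac=se_floor_frac)
    statistic = logfc / se
    p = 2.0 * stats.t.sf(np.abs(statistic), df)
    p = np.clip(p, _P_MIN, 1.0)
    z = np.sign(statistic) * stats.norm.isf(p / 2.0)
    z = np.where(statistic == 0.0, 0.0, z)
    return pd.DataFrame(
        {
            "logfc": logfc,
            "se": se,
            "statistic": statistic,
            "df": df,
            "z": z,
            "p": p,
            "p_adj": benjamini_hochberg(p),
            "se_floored": floored,
        },
        index=matrix.feature_ids,
    )
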