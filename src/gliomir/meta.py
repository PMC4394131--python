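"""Cross-grade combination of per-platform differential results.

Each grade contributes a per-feature standard-normal score z (grade III
from the sequencing cohort, grade IV from the microarray cohort).  Under
the joint null both scores are N(0,1) and independent, so their sum is
N(0,2); dividing by sqrt(2) (the Stouffer convention) yields a combined
score that is again standard normal and can be thresholded as a z-value.
A ``denominator="2"`` switch divides the sum by 2 instead, for
comparison with analyses that used that scaling.

Combination runs over the intersection of feature ids; features measured
on only one platform cannot be combined and are reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ValidationError
from .diffexp import benjamini_hochberg

__all__ = ["CombinedResult", "Signature", "combine_grades", "select_signature", "select_de_mrnas"]

_DENOMINATORS = {"sqrt2": math.sqrt(2.0), "2": 2.0}


@dataclass
class CombinedResult:
    """Combined statistics over platform-shared features.

    ``table`` is indexed by feature id with columns
    ``z_III, z_IV, logfc_III, logfc_IV, logfc_combined, z_combined,
    p_joint, fdr, selected``.  ``only_III`` / ``only_IV`` carry the
    per-grade rows for features absent from the other platform.
    """

    table: pd.DataFrame
    only_III: pd.DataFrame
    only_IV: pd.DataFrame
    denominator: str = "sqrt2"


@dataclass
class Signature:
    """Selected prognostic features partitioned by direction in poor prognosis."""

    up_in_poor: pd.Index
    down_in_poor: pd.Index

    @property
    def features(self) -> pd.Index:
        return self.up_in_poor.append(self.down_in_poor)

    def __len__(self) -> int:
        return len(self.up_in_poor) + len(self.down_in_poor)


def combine_grades(
    de_III: pd.DataFrame,
    de_IV: pd.DataFrame,
    denominator: str = "sqrt2",
    fdr_threshold: float = 0.05,
    z_threshold: float = 2.0,
) -> CombinedResult:
    """Combine two per-grade differential tables into joint statistics.

    Both inputs are tables from
    :func:`gliomir.diffexp.differential_expression` (need columns ``z``
    and ``logfc``).  The joint p-value is two-sided normal on the
    combined score; FDR is BH over the shared features.
    """
    if denominator not in _DENOMINATORS:
        raise ValidationError(f"denominator must be one of {sorted(_DENOMINATORS)}")
    if de_III.empty or de_IV.empty:
        raise ValidationError("both differential tables must be non-empty")
    shared = de_III.index.intersection(de_IV.index)
    if len(shared) == 0:
        raise ValidationError("no features shared between the two grades")
    z3 = de_III.loc[shared, "z"].to_numpy(dtype=float)
    z4 = de_IV.loc[shared, "z"].to_numpy(dtype=float)
    zc = (z3 + z4) / _DENOMINATORS[denominator]
    p_joint = np.clip(2.0 * stats.norm.sf(np.abs(zc)), 1e-300, 1.0)
    fdr = benjamini_hochberg(p_joint)
    lfc3 = de_III.loc[shared, "logfc"].to_numpy(dtype=float)
    lfc4 = de_IV.loc[shared, "logfc"].to_numpy(dtype=float)
    table = pd.DataFrame(
        {
            "z_III": z3,
            "z_IV": z4,
            "logfc_III": lfc3,
            "logfc_IV": lfc4,
            "logfc_combined": (lfc3 + lfc4) / 2.0,
            "z_combined": zc,
            "p_joint": p_joint,
            "fdr": fdr,
            "selected": (fdr < fdr_threshold) & (np.abs(zc) >= z_threshold),
        },
        index=shared,
    )
    return CombinedResult(
        table=table,
        only_III=de_III.loc[de_III.index.difference(de_IV.index)],
        only_IV=de_IV.loc[de_IV.index.difference(de_III.index)],
        denominator=denominator,
    )


def select_signature(
    combined: CombinedResult,
    fdr_threshold: float = 0.05,
    z_threshold: float = 2.0,
) -> Signature:
    """Select features with FDR < threshold and |z_combined| >= threshold,
    partitioned by sign (positive z = up in poor prognosis)."""
    t = combined.table
    keep = (t["fdr"] < fdr_threshold) & (t["z_combined"].abs() >= z_threshold)
    sel = t.loc[keep]
    return Signature(
        up_in_poor=sel.index[sel["z_combined"] > 0],
        down_in_poor=sel.index[sel["z_combined"] < 0],
    )


def select_de_mrnas(
    combined: CombinedResult,
    p_threshold: float = 0.05,
    min_abs_logfc: float = 1.0,
) -> pd.Index:
    """Differentially expressed mRNA pool: joint p below threshold and at
    least a 2-fold combined change (|mean log2FC| >= 1 by default)."""
    t = combined.table
    keep = (t["p_joint"] < p_threshold) & (t["logfc_combined"].abs() >= min_abs_logfc)
    return t.index[keep]
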