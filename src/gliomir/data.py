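"""Core containers and exceptions shared across the analysis stages.

Expression data travel as features x samples tables with an explicit
platform kind, because counts (miRNA-seq) and log2 intensities
(microarray) must be treated differently before any contrast is formed.
Sample annotation stays a plain :class:`pandas.DataFrame` indexed by
sample id with the columns documented in :func:`validate_annotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COUNTS = "counts"
INTENSITY = "intensity"
PLATFORM_KINDS = (COUNTS, INTENSITY)

GRADE_GIIIA = "GIIIA"
GRADE_GBM = "GBM"
GROUP_GOOD = "good"
GROUP_POOR = "poor"
GROUP_UNASSIGNED = "unassigned"

#: Annotation columns understood by the pipeline.  ``survival_months`` and
#: ``event`` are required wherever survival models run; ``idh_status`` is
#: optional ("mut" / "wt" / "unknown").
ANNOTATION_COLUMNS = ("grade", "group", "survival_months", "event", "idh_status")


class GliomirError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(GliomirError):
    """A configuration value violates its documented constraints."""


class ValidationError(GliomirError):
    """An input table violates a documented invariant."""


@dataclass
class ExpressionMatrix:
    """Features x samples expression table with a platform kind.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
        Counts must be non-negative integers; intensities must be finite
        log2-scale values.
    platform_kind
        Either ``"counts"`` (sequencing) or ``"intensity"``
        (already-normalised microarray / log2 scale).
    """

    values: pd.DataFrame
    platform_kind: str

    def __post_init__(self) -> None:
        if self.platform_kind not in PLATFORM_KINDS:
            raise ValidationError(
                f"platform_kind must be one of {PLATFORM_KINDS}, got {self.platform_kind!r}"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if self.platform_kind == COUNTS:
            if arr.size and (np.any(arr < 0) or np.any(arr != np.floor(arr))):
                raise ValidationError("counts must be non-negative integers")
        else:
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValidationError("intensity values must be finite")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(features)], self.platform_kind)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.platform_kind)

    # -- I/O ----------------------------------------------------------------

    def write_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, platform_kind: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, platform_kind)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-annotation table (indexed by sample id).

    Enforces unique sample ids and that ``survival_months`` is present and
    non-negative wherever an ``event`` flag is present.
    """
    if annotation.index.has_duplicates:
        dups = annotation.index[annotation.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids in annotation: {dups[:5]}")
    if "event" in annotation.columns:
        has_event = annotation["event"].notna()
        if "survival_months" not in annotation.columns:
            raise ValidationError("event flags present but survival_months column missing")
        months = annotation.loc[has_event, "survival_months"]
        if months.isna().any():
            bad = months.index[months.isna()].tolist()
            raise ValidationError(f"samples with event flag but no survival time: {bad[:5]}")
        if (months < 0).any():
            raise ValidationError("survival_months must be non-negative")
    return annotation


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "event" in df.columns:
        df["event"] = df["event"].astype(bool)
    return validate_annotation(df)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
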