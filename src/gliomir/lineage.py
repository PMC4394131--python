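"""Oligodendrocyte-precursor lineage correlation analyses.

Two related questions are answered here.  First, do the expression
*changes* between consecutive differentiation stages (ESC -> EB -> NP ->
GP -> OP1 -> OP2 -> OP3 -> OL) resemble the expression changes between
poor- and good-prognosis tumors?  That is a Spearman correlation between
two per-feature fold-change vectors, restricted to features that pass
the per-transition filter (two-sided p < 0.05 and at least a 2-fold
change between the stages).  Second, how similar is each individual
tumor to each stage?  That is a Spearman correlation between the tumor's
profile and the stage mean profile over the platform-shared features,
yielding a tumors x stages similarity matrix whose OP1 column is the
covariate carried into the survival model.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, ValidationError

__all__ = [
    "STAGE_ORDER",
    "StageProfileSet",
    "TransitionFoldChange",
    "TransitionCorrelation",
    "TumorStageCorrelationMatrix",
    "spearman",
    "transition_foldchanges",
    "correlate_transition_with_contrast",
    "control_lineage_correlation",
    "tumor_stage_correlations",
]

STAGE_ORDER = ("ESC", "EB", "NP", "GP", "OP1", "OP2", "OP3", "OL")


@dataclass
class StageProfileSet:
    """Replicate expression profiles for each differentiation stage.

    ``replicates`` maps stage name -> DataFrame (features x replicates)
    on the log2 scale; every stage shares one feature universe and has
    at least two replicates.
    """

    replicates: dict
    stage_order: tuple = STAGE_ORDER

    def __post_init__(self) -> None:
        missing = [s for s in self.stage_order if s not in self.replicates]
        if missing:
            raise ValidationError(f"missing stage profiles: {missing}")
        ref = self.replicates[self.stage_order[0]].index
        for stage in self.stage_order:
            df = self.replicates[stage]
            if df.shape[1] < 2:
                raise ValidationError(
                    f"stage {stage} has {df.shape[1]} replicates; need >=2"
                )
            if not df.index.equals(ref):
                raise ValidationError(f"stage {stage} has a different feature universe")

    @property
    def feature_ids(self) -> pd.Index:
        return self.replicates[self.stage_order[0]].index

    @property
    def n_replicates(self) -> int:
        return min(self.replicates[s].shape[1] for s in self.stage_order)

    @property
    def mean_profile(self) -> pd.DataFrame:
        """Features x stages table of replicate means."""
        return pd.DataFrame(
            {s: self.replicates[s].mean(axis=1) for s in self.stage_order}
        )

    def transitions(self):
        return list(zip(self.stage_order[:-1], self.stage_order[1:]))

    # -- I/O: wide TSV with columns "<stage>.<rep>" ------------------------

    def write_tsv(self, path) -> None:
        wide = pd.concat(
            {s: self.replicates[s].set_axis(
                [f"{s}.{k+1}" for k in range(self.replicates[s].shape[1])], axis=1)
             for s in self.stage_order},
            axis=1,
        )
        wide.columns = wide.columns.droplevel(0)
        wide.index.name = "feature_id"
        wide.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, stage_order: tuple = STAGE_ORDER) -> "StageProfileSet":
        wide = pd.read_csv(path, sep="\t", index_col=0)
        reps = {}
        for stage in stage_order:
            cols = [c for c in wide.columns if c.split(".")[0] == stage]
            reps[stage] = wide[cols]
        return cls(replicates=reps, stage_order=stage_order)


@dataclass
class TransitionFoldChange:
    """Per-feature fold changes across one consecutive stage transition.

    ``table`` is indexed by feature with columns ``logfc`` (log2, stage_to
    minus stage_from), ``p`` (Welch two-sample across replicates),
    ``passing`` (p below threshold and |logfc| above the fold cut) and
    ``degenerate`` (undefined p from zero replicate variance).  A
    transition with fewer passing features than the configured minimum is
    flagged ``omitted``.
    """

    transition: tuple
    table: pd.DataFrame
    omitted: bool

    @property
    def passing_features(self) -> pd.Index:
        return self.table.index[self.table["passing"]]

    @property
    def label(self) -> str:
        return f"{self.transition[0]}->{self.transition[1]}"


@dataclass
class TransitionCorrelation:
    """Spearman correlation between a transition (or control) fold-change
    vector and a prognosis-contrast fold-change vector."""

    transition: tuple | None
    contrast_label: str
    rho: float
    p: float
    n_features: int

    @property
    def transition_label(self) -> str:
        if self.transition is None:
            return self.contrast_label
        return f"{self.transition[0]}->{self.transition[1]}"


@dataclass
class TumorStageCorrelationMatrix:
    """Tumors x stages Spearman similarity matrix over shared features."""

    rho: pd.DataFrame
    n_shared_features: int

    @property
    def argmax_stage(self) -> pd.Series:
        return self.rho.idxmax(axis=1)


# ---------------------------------------------------------------------------
# Spearman correlation


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        return math.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def _exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p-value for Spearman's rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (ry[perms] * rx).mean(axis=1)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y, exact_max_n: int = 9):
    """Spearman rank correlation with average ranks for ties.

    Returns ``(rho, p)``.  The p-value is exact (full permutation
    enumeration) for n <= ``exact_max_n`` and the t-approximation
    otherwise.  A constant input vector makes rho undefined; (nan, nan)
    is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman expects two equal-length 1-d vectors")
    if len(x) < 3:
        raise ValidationError("spearman needs at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("spearman inputs must be finite")
    rho = _rank_rho(x, y)
    if math.isnan(rho):
        return math.nan, math.nan
    if len(x) <= exact_max_n:
        return rho, _exact_p(x, y, rho)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Stage transitions


def transition_foldchanges(
    stages: StageProfileSet,
    p_threshold: float = 0.05,
    min_abs_logfc: float = 1.0,
    min_passing: int = 5,
) -> list:
    """Fold changes and the pass/fail filter for every consecutive transition.

    Per feature: logfc = mean(stage_to) - mean(stage_from) on the log2
    scale; p from a Welch two-sample test across replicates.  ``passing``
    requires p < ``p_threshold`` and |logfc| >= ``min_abs_logfc`` (>= 2-fold
    on the linear scale by default).  Transitions with fewer than
    ``min_passing`` passing features are flagged omitted.
    """
    if stages.n_replicates < 2:
        raise ValidationError("need >=2 replicates per stage")
    out = []
    for frm, to in stages.transitions():
        a = stages.replicates[frm].to_numpy(dtype=float)
        b = stages.replicates[to].to_numpy(dtype=float)
        logfc = b.mean(axis=1) - a.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(b, a, axis=1, equal_var=False)
            p = np.asarray(res.pvalue, dtype=float)
        degenerate = ~np.isfinite(p)
        passing = (~degenerate) & (p < p_threshold) & (np.abs(logfc) >= min_abs_logfc)
        table = pd.DataFrame(
            {"logfc": logfc, "p": p, "passing": passing, "degenerate": degenerate},
            index=stages.feature_ids,
        )
        out.append(
            TransitionFoldChange(
                transition=(frm, to),
                table=table,
                omitted=int(passing.sum()) < min_passing,
            )
        )
    return out


def correlate_transition_with_contrast(
    tfc: TransitionFoldChange,
    contrast_fc: pd.Series,
    contrast_label: str,
) -> TransitionCorrelation:
    """Spearman correlation between a transition's passing fold changes and a
    prognosis-contrast fold-change vector, over the shared features."""
    feats = tfc.passing_features.intersection(contrast_fc.index)
    if len(feats) < 3:
        raise ValidationError(
            f"only {len(feats)} shared passing features for {tfc.label}; need >=3"
        )
    rho, p = spearman(
        tfc.table.loc[feats, "logfc"].to_numpy(),
        contrast_fc.loc[feats].to_numpy(),
    )
    return TransitionCorrelation(
        transition=tfc.transition,
        contrast_label=contrast_label,
        rho=rho,
        p=p,
        n_features=len(feats),
    )


def control_lineage_correlation(
    control_fc: pd.Series,
    contrast_fc: pd.Series,
    control_label: str,
) -> TransitionCorrelation:
    """Correlation of a control-lineage fold-change vector (e.g. ESC->HP,
    NSC->NP from a non-oligodendrocyte differentiation series) with the
    prognosis contrast.  The control vector carries its own feature subset."""
    feats = control_fc.index.intersection(contrast_fc.index)
    if len(feats) < 3:
        raise ValidationError(
            f"only {len(feats)} shared features for control {control_label}; need >=3"
        )
    rho, p = spearman(control_fc.loc[feats].to_numpy(), contrast_fc.loc[feats].to_numpy())
    return TransitionCorrelation(
        transition=None,
        contrast_label=control_label,
        rho=rho,
        p=p,
        n_features=len(feats),
    )


# ---------------------------------------------------------------------------
# Per-tumor stage similarity


def _rank_columns(arr: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(arr, axis=0).astype(float)
    ranks -= ranks.mean(axis=0)
    norms = np.sqrt((ranks**2).sum(axis=0))
    norms[norms == 0.0] = np.nan
    return ranks / norms


def tumor_stage_correlations(
    tumors: ExpressionMatrix,
    stages: StageProfileSet,
    shared_features,
) -> TumorStageCorrelationMatrix:
    """Spearman similarity of every tumor to every stage mean profile.

    All correlations use the identical, explicitly supplied shared
    feature set (the microRNAs detected on every platform).
    """
    shared = pd.Index(shared_features)
    if len(shared) < 3:
        raise ValidationError("need >=3 shared features")
    missing = shared.difference(tumors.feature_ids)
    if len(missing) > 0:
        raise ValidationError(f"tumor matrix missing shared features: {list(missing)[:5]}")
    missing = shared.difference(stages.feature_ids)
    if len(missing) > 0:
        raise ValidationError(f"stage profiles missing shared features: {list(missing)[:5]}")
    tvals = tumors.values.loc[shared]
    bad = tvals.columns[tvals.isna().any(axis=0)].tolist()
    if bad:
        raise ValidationError(f"tumor(s) with missing values on shared features: {bad[:5]}")
    tr = _rank_columns(tvals.to_numpy(dtype=float))
    sr = _rank_columns(stages.mean_profile.loc[shared].to_numpy(dtype=float))
    rho = pd.DataFrame(tr.T @ sr, index=tumors.sample_ids, columns=list(stages.stage_order))
    return TumorStageCorrelationMatrix(rho=rho, n_shared_features=len(shared))
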